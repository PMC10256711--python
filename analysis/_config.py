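"""Shared study configuration for the analysis drivers.

One deterministic synthetic three-line village is used across all numbered
scripts so each driver can be run independently (the generator is cheap and
fully reproducible from the seed).
"""

from pathlib import Path

from villagevp.sim import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

SEED = 2024

#: three lines x three sites x three replicates, half village / half uni,
#: with two-dozen genotype-driven eQTLs injected
STUDY = SimConfig(
    n_lines=3,
    n_cells=4000,
    n_genes=120,
    sites=("site1", "site2", "site3"),
    replicates_per_site=3,
    village_fraction=0.5,
    pseudotime_fraction=0.05,
    dynamic_gene_fraction=0.2,
    doublet_rate=0.05,
    eqtl_spec=[(f"G{20 + i:04d}", f"rs{i}", beta)
               for i, beta in enumerate([0.9, -0.9, 0.7, -0.7, 1.1, -1.1,
                                         0.8, -0.8, 0.9, -0.9, 0.6, -0.6,
                                         1.0, -1.0, 0.9, -0.9, 0.7, -0.7,
                                         0.8, -0.8])],
    seed=SEED,
)


def load_study():
    from villagevp.sim import simulate_village

    return simulate_village(STUDY)
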