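"""Spliced/unspliced batch correction and line population dynamics.

Runs the velocity preprocessing chain (prefilter, combine, per-gene
location-scale batch correction over site x line x village, re-split) and
verifies its conservation identity on the study data; then tracks line
proportions per site and relates growth rates to proportions in a
multi-passage village simulation.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, load_study  # noqa: E402

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from villagevp import demux, popdyn, velo  # noqa: E402
from villagevp.io import write_table  # noqa: E402


def main() -> None:
    ds = load_study()
    out = RESULTS
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(99)

    # --- velocity preprocessing ---------------------------------------------
    S = ds.spliced.toarray().astype(float)
    U = ds.unspliced.toarray().astype(float)
    S_f, U_f, report = velo.velocity_prefilter(
        S, U, cell_ids=ds.counts.barcodes, gene_ids=ds.counts.genes,
        min_unspliced_per_cell=200)  # scaled to the simulated library sizes
    kept_cells = [c for c in ds.counts.barcodes if c not in set(report.removed_cells)]
    print(f"velocity prefilter: removed {len(report.removed_cells)} cells, "
          f"{len(report.removed_genes)} genes -> {S_f.shape[0]} genes x "
          f"{S_f.shape[1]} cells")

    md = ds.metadata.set_index("barcode").loc[kept_cells]
    M, R = velo.combine(S_f, U_f)
    labels = velo.composite_batch_labels(md.reset_index())
    sizes = labels.value_counts()
    labels = labels.where(labels.map(sizes) >= 2, "pooled_small")
    M_b = velo.batch_correct(M, labels)
    S_b, U_b = velo.split(M_b, R)
    err = np.abs(S_b + U_b - M_b).max()
    print(f"conservation |S_b + U_b - M_b| max = {err:.2e} over "
          f"{M_b.size} entries ({labels.nunique()} batches)")

    # --- line proportions per site -------------------------------------------
    consensus = demux.consensus_threeline(ds.caller_tables)
    assign = (consensus.merge(ds.metadata[["barcode", "site", "replicate"]],
                              on="barcode")
              .rename(columns={"site": "sample"}))
    props = popdyn.line_proportions(assign, replicate_col="replicate")
    write_table(props, out / "line_proportions.tsv")
    print("line proportions per site:")
    for _, r in props.iterrows():
        se = "" if np.isnan(r["se"]) else f" +/- {r['se']:.4f}"
        print(f"  {r['sample']} {r['line']}: {r['proportion']:.3f}{se}")

    # --- growth rates vs proportions over passages ----------------------------
    days = np.array([4.0, 5.0, 6.0, 7.0])
    rates = {}
    for i, line in enumerate(sorted(ds.metadata["line"].unique())):
        true_rate = 0.35 + 0.15 * i
        counts = 5e4 * np.exp(true_rate * days) * np.exp(rng.normal(0, 0.04, 4))
        fit = popdyn.growth_rate_fit(days, counts, line=line)
        rates[line] = fit.rate
        print(f"growth fit {line}: rate {fit.rate:.3f}/day "
              f"(true {true_rate:.2f}, R^2 {fit.r_squared:.3f})")
    rates = pd.Series(rates)

    pop = pd.Series(1.0, index=rates.index)
    rows = []
    for passage in range(1, 7):
        pop = pop * np.exp(rates * 2.0)
        pop = pop / pop.sum()
        sampled = rng.multinomial(20_000, pop.to_numpy())
        props_p = pd.Series(sampled, index=pop.index) / sampled.sum()
        rho, p = popdyn.proportion_growth_correlation(rates, props_p)
        rows.append({"passage": passage, "rho": rho, "p": p,
                     **{f"prop_{l}": props_p[l] for l in pop.index}})
    dyn = pd.DataFrame(rows)
    write_table(dyn, out / "passage_dynamics.tsv")
    print("rate-vs-proportion Spearman rho by passage:",
          ", ".join(f"P{r.passage}: {r.rho:.2f}" for r in dyn.itertuples()))


if __name__ == "__main__":
    main()
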