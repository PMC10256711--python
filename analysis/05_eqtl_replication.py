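"""Replication of the injected eQTLs in uni-culture and village cells.

Filters the reference (snp, gene) pairs for polymorphic dosage and a
significant line variance contribution, fits per-(line, site) mean
expression on dosage separately in uni-culture and village cells, tests
sign concordance against the injected effects with the 1-df chi-squared
test, and correlates uni vs village effect sizes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, load_study  # noqa: E402

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from villagevp import demux, eqtl, qc, varpart  # noqa: E402
from villagevp.io import write_table  # noqa: E402


def main() -> None:
    ds = load_study()
    out = RESULTS
    out.mkdir(parents=True, exist_ok=True)

    consensus = demux.consensus_threeline(ds.caller_tables)
    md = ds.metadata.merge(
        consensus.rename(columns={"line": "assigned_line"}), on="barcode")
    retained = md[md["status"] == "retained"].reset_index(drop=True)
    cols = [ds.counts.barcodes.index(b) for b in retained["barcode"]]
    expr = qc.normalize(ds.counts.matrix[:, cols]).matrix
    design = retained.assign(line=retained["assigned_line"])

    # gate: genes whose variance has a significant line component
    table = varpart.decompose_all(
        expr, design, ["line", "village", "site", "replicate"],
        genes=ds.counts.genes, compute_tests=True)
    line_rows = table[table["component"] == "line"]
    sig_genes = set(line_rows.loc[line_rows["q"] < 0.05, "gene"])

    reference = ds.truth["eqtl"]
    testable = eqtl.filter_testable(reference, ds.genotypes, sig_genes)
    print(f"reference eQTLs: {len(reference)}; testable after filters: "
          f"{len(testable)} (line-significant genes: {len(sig_genes)})")

    gene_idx = {g: i for i, g in enumerate(ds.counts.genes)}
    results = {"uni": [], "village": []}
    for condition in ("uni", "village"):
        mask = (design["village"] == condition).to_numpy()
        for _, row in testable.iterrows():
            means = (pd.DataFrame({
                "line": design.loc[mask, "line"],
                "site": design.loc[mask, "site"],
                "expression": expr[gene_idx[row["gene"]], mask]})
                .groupby(["line", "site"], observed=True)
                .mean(numeric_only=True).reset_index())
            results[condition].append(eqtl.fit_eqtl(
                means, ds.genotypes, row["snp"], row["gene"], condition,
                reference_beta=row["beta"]))

    for condition, res in results.items():
        conc = eqtl.concordance_test(res)
        print(f"{condition}: {conc['concordant']}/{conc['n']} concordant "
              f"({conc['concordance_pct']:.1f}%), chi2 = {conc['chi2']:.2f}, "
              f"p = {conc['p']:.2e}")
        write_table(pd.DataFrame([r.__dict__ for r in res]),
                    out / f"eqtl_{condition}.tsv")

    b_uni = np.array([r.beta for r in results["uni"]])
    b_vil = np.array([r.beta for r in results["village"]])
    rho, p = eqtl.uni_village_correlation(b_uni, b_vil)
    print(f"uni vs village effect sizes: Spearman rho = {rho:.3f} (p = {p:.2e})")


if __name__ == "__main__":
    main()
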