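# villagevp

Variance partitioning and population dynamics for pooled ("village") hiPSC
single-cell experiments.

In a village culture, several donor induced-pluripotent-stem-cell lines are
pooled, cultured and captured in a single dish, and every droplet is
assigned back to its donor line by genetic demultiplexing. The design
scales stem-cell experiments dramatically, but raises the questions this
package answers quantitatively: how much of each gene's expression variance
is attributable to the line versus the shared culture environment (village
status, site, replicate, cryopreservation)? Do line-specific effects change
along differentiation pseudotime? Are known eQTLs still detectable inside a
village? And how do line proportions drift with line growth rates?

It is aimed at analysts of pooled single-cell designs and at
methods-minded readers who want every stage testable without any data
download: a synthetic-data generator with known ground truth is a
first-class module, and every downstream statistic is exercised against it.

## The core model

For each gene, normalized expression *y* is fit with a linear mixed model

y = Xβ + Σ<sub>k</sub> Z<sub>k</sub>u<sub>k</sub> + ε,  u<sub>k</sub> ~ N(0, σ²<sub>k</sub>I),  ε ~ N(0, σ²<sub>e</sub>I)

with categorical design covariates as random intercepts and pseudotime as a
fixed effect. The variance explained by covariate *var* is the intra-class
correlation

ICC<sub>var</sub> = 100 · σ²<sub>var</sub> / Σ<sub>i</sub> σ²<sub>i</sub>

with the denominator running over every component including the residual,
so ICCs sum to 100 per gene. Covariate significance comes from
likelihood-ratio tests between nested ML refits (boundary-corrected
χ²₀:χ²₁ mixture for variance components), with Benjamini–Hochberg FDR
across genes. Around this core sit consensus donor assignment, droplet QC,
logistic-regression differential expression, eQTL sign-concordance tests,
the spliced/unspliced batch-correction identities
(M = S + U, R = S/(S+U), S_b = M_b·R, U_b = M_b·(1−R)), and
log-linear growth-rate estimation. See `docs/methods.md` for the full
account.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a
deterministic synthetic village (3 lines x 3 sites x 3 replicates, 4,000
droplets, 120 genes, 5% doublets, 20 injected eQTLs). Running

```sh
python analysis/01_simulate_village.py
python analysis/02_demux_consensus.py
python analysis/04_variance_partition.py
python analysis/05_eqtl_replication.py
```

prints (abridged):

```
simulated 3800 droplets x 120 genes (200 doublets, 8 caller tables)
threeline: retained 3568/3800 | singlet recall 0.991 | doublet false retention 0.000 | line accuracy 1.0000
mean ICC (%) vs generator truth:
  line       est  13.31   truth  14.46
  village    est   4.46   truth   4.49
  site       est   3.47   truth   4.49
  replicate  est   1.36   truth   1.80
genes with significant line contribution (FDR<0.05): 119/120
uni: 20/20 concordant (100.0%), chi2 = 20.00, p = 7.74e-06
village: 20/20 concordant (100.0%), chi2 = 20.00, p = 7.74e-06
uni vs village effect sizes: Spearman rho = 0.929 (p = 3.23e-09)
```

Reading this: the consensus rule retains 94% of droplets with no doublet
leakage and perfect line assignment at the simulated caller error rates;
the mixed model recovers the injected variance shares to within ~1 ICC
point on average (the residual picks up count noise on top of the latent
truth, so line/village/site estimates sit slightly below their latent
shares); and all 20 genotype-driven eQTLs are re-detected with the injected
sign in both culture conditions, with uni-culture and village effect sizes
strongly rank-correlated — the village does not erase genetic signal.

A thin CLI wraps the same stages
(`villagevp all --config cfg.yaml --out outdir`), with thresholds
defaulting to the standard settings (4 MADs, 1750 genes, 25% mito,
10% expression filter, FDR 0.05).

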