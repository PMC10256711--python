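# Methods

`villagevp` implements the statistical machinery used to analyse pooled
("village") hiPSC single-cell experiments: several donor lines are cultured
and captured together, each droplet is assigned back to its line by
combining demultiplexing callers, and per-gene linear mixed models partition
expression variance among the design covariates. Everything is exercised
end-to-end on a bundled synthetic-data generator with known ground truth.

## Consensus donor assignment

Per-caller assignment tables carry one call per droplet: a line label
(SNP-based demultiplexers), or singlet/doublet (transcription-based doublet
detectors and hashtag demultiplexing, which carry no line label). Two
integration rules are provided.

*Three-line rule.* A droplet is retained iff (a) at least four callers from
the pooled SNP + transcription set call it a singlet, (b) every hashtag
caller calls it a singlet, and (c) at least three SNP callers assign the
identical line label, with a unique winner; the first failing clause is
recorded per excluded droplet. *At-least-half rule.* With K callers, retain
iff at least ceil(K/2) call singlet and the SNP singlet calls have a unique
plurality line. Droplets missing from a caller's table count as
"unassigned" — a non-singlet vote, the conservative choice. Ties on the
line label exclude the droplet in both rules; the tie conventions are ours,
as the integration methods are usually described without them.

The expected doublet count among N captured droplets is N^2 x 0.008 / 1000,
the standard per-thousand-cells doublet-rate scaling of droplet capture.

## Quality control and normalization

Droplets are excluded when their mitochondrial percentage deviates from the
median by more than `mito_mads` (default 4) median absolute deviations —
raw MAD without the 1.4826 consistency factor, two-sided — or when fewer
than `min_genes` (default 1750) genes are detected; a separate hard cap
removes droplets above `max_mito` (default 25%). Both the MAD convention
and two-sidedness are configurable because the filter is usually reported
as just "N MADs from the median".

Normalization is log1p of counts scaled to a 10,000-count library
(log-CPM), optionally followed by per-gene linear residualization against
continuous nuisance covariates (e.g. mitochondrial %), re-centred on the
gene mean. This deliberately replaces regularized negative-binomial
normalization: the downstream statistics need normalized expression, not a
particular variance-stabilizing transform, and the simpler transform is
exactly reproducible. Zero-count droplets stay zero and are reported, and
zeros are preserved prior to residualization.

Group downsampling (for condition comparisons) samples every covariate
combination down to the global minimum group size, without replacement,
deterministically from a seed.

## Variance partitioning (the core computation)

For each gene, normalized expression y is fit with

    y = X beta + sum_k Z_k u_k + e,  u_k ~ N(0, s2_k I),  e ~ N(0, s2_e I)

where categorical covariates (line, village status, site, replicate,
cryopreservation, and pairwise interactions via crossed level labels) are
random intercepts and continuous covariates (pseudotime) are fixed effects.
Components are estimated by REML with each variance bounded at zero. The
intra-class correlation attributes variance:

    ICC_var = 100 * s2_var / sum_i s2_i,

the sum running over all components including the residual. A continuous
covariate's component is the empirical variance across cells of its fitted
contribution x_j beta_j — a definitional choice we make explicit, since
"variance explained by pseudotime" is otherwise undefined in a mixed model
with pseudotime as a fixed effect. ICCs therefore sum to exactly 100 per
converged gene.

The solver is a purpose-built variance-components engine: the marginal
covariance is handled through the Woodbury identity on the q x q scale
(q = total random-effect levels), so one likelihood evaluation costs
O(q^3) after an O(n q^2) setup shared by every gene on the same design.
This is what makes genome-wide per-gene fits and simulation-based
calibration checks cheap. Optimization is L-BFGS-B over the variance vector
(two starts, Nelder-Mead fallback on line-search failure). The engine is
validated against the closed-form balanced one-way method-of-moments
components and against lme4 REML/ML fits on crossed designs (agreement to
~1e-6).

*Covariate significance.* Nested maximum-likelihood refits are compared by
likelihood ratio. For a variance component tested at its boundary the
default reference is the 50:50 chi2_0:chi2_1 mixture (p = 0.5 P(chi2_1 > T)
for T > 0, p = 1 at T = 0); a plain chi-squared reference is available.
The mixture is asymptotic in the number of levels *and* the per-level
count: with the 2-6 levels typical of design covariates it is markedly
conservative (rejection ~0.01 at nominal 0.05 with 3 levels), approaching
nominal (~0.046) only for factors with ~100 levels and hundreds of cells
per level. Tests on few-level covariates therefore under-reject, never
over-reject. Benjamini-Hochberg FDR is applied across genes per covariate.

*Dynamic (line x pseudotime) effects.* Genes are gated on both the line and
pseudotime terms being significant contributors (BH-FDR < 0.05 across all
genes). The pseudotime gate compares the model with per-line slopes against
the no-pseudotime model (chi2 with L df), so lines with opposite slopes
that cancel in the average still pass. Gated genes are tested for slope
heterogeneity with per-line slopes as *fixed* effects against the
common-slope model (chi2 with L - 1 df), keeping the random line
intercepts. With the two or three lines of a village, a random-slope
variance is essentially unidentified and its boundary LRT rejects far below
nominal; the fixed-slope LRT keeps the null p-value uniform and detects
sign-opposed slopes. Per-line slope estimates (common + deviation) are
reported, and a second BH correction runs over the gated set.

Model presets mirror the three experimental designs: fresh (line, village,
site, replicate), cryopreserved (line, village, cryopreservation,
replicate) and the large 18-line village (line, passage).

## eQTL replication

Reference (SNP, gene) pairs are testable when the SNP has at least two
distinct effect-allele dosages across the pooled lines and the gene's
variance has a significant line component (the varpart FDR < 0.05 gate,
configurable). Effects are estimated per condition (uni-culture vs village)
by OLS of per-(line, site) mean expression on dosage plus covariates.
Concordance with the reference is a 1-df chi-squared goodness-of-fit of the
concordant/discordant sign counts against 50:50 (beta = 0 counts as
discordant; the construction is one of several "chi-squared test" readings
and is stated explicitly). Uni vs village effect sizes are compared with a
two-sided Spearman correlation.

## Spliced/unspliced batch correction

The velocity preprocessing chain: cells with fewer than 1000 total
unspliced counts are removed, then genes expressed in fewer than 20
remaining cells or with fewer than 10 unspliced counts. Spliced and
unspliced counts combine as M = S + U with splicing ratio R = S / (S + U)
(R = 0 where M = 0 — no evidence of splicing); M is batch-corrected over
the joint site x line x village label; and corrected matrices are
re-derived as S_b = M_b R, U_b = M_b (1 - R), so S_b + U_b = M_b to
floating-point precision regardless of the correction.

The correction itself is a deterministic per-gene location-scale
adjustment on the log1p scale (standardize within batch, rescale to the
pooled mean/SD, invert): it removes additive log-scale batch shifts
exactly, is a no-op on a single batch, and passes through genes with zero
within-batch variance. Empirical-Bayes shrinkage across genes is not
implemented; the re-split identities hold for any corrected M_b.

## Population dynamics

Line proportions per sample are retained-cell fractions, with the standard
error of per-replicate proportions when replicates exist. Growth rates are
log-linear least squares of counts (or confluency) on time — the minimal
estimator consistent with exponential growth, exact on noise-free data
(doubling series gives exactly ln 2 per day). Growth rates and proportions
are related by a two-sided Spearman correlation; in multi-passage village
simulations the rank agreement reaches 1 at late passages as fast lines
take over.

## Synthetic-data generator

The generator emulates the village design: cells are assigned uniformly to
lines, sites, replicates-within-site and village status; pseudotime is
Uniform(0, 1) per cell (the real quantity is estimated from data; no
generative model is claimed). Per gene, the latent log-mean is a sum of
level effects for each categorical covariate, a pseudotime slope term, and
latent residual noise. Each component is drawn Normal and then centred and
rescaled so its realized variance equals the configured share exactly —
between-level variance (ddof = 1) for categorical effects, matching the
quantity a mixed model's s2_k estimates, and across-cell variance for
pseudotime and residual. Configured variance fractions (including residual)
must sum to one; the pseudotime share is carved out first, scaling the
rest by (1 - pseudotime_fraction). With this standardization the recorded
truth shares equal the configuration exactly and recovery error in tests
reflects estimation alone.

eQTL effects are line-level shifts beta x (dosage - mean dosage) added to
the line component (dosages drawn in {0,1,2} per line, kept polymorphic).
A configurable fraction of genes is "dynamic", receiving line-specific
pseudotime slope deviations (Normal with configurable SD). Counts are
negative-binomial on the exponentiated latent mean (single dispersion
scalar, lognormal cell size factors, SD 0.1); a Beta-distributed per-gene
spliced fraction splits counts binomially into spliced/unspliced, so
S + U equals the total exactly. The first ~5% of genes are named "MT-*"
and pinned to a fixed expression share (~8%) so mitochondrial percentages
are meaningful. Doublets sum the counts of two random droplets from
distinct lines (consuming the parents; QC statistics recomputed; parents
recorded), with "auto" giving N^2 x 0.008 / 1000 doublets. Caller tables
are derived from the truth labels with per-caller miscall and doublet-miss
rates.

What the generator does *not* emulate: gene-gene correlation, cell-cycle
structure, ambient RNA, empty droplets, and the mean-variance coupling of
real UMI data beyond the NB family. Passing tests therefore demonstrate
correctness of the statistical machinery under a faithful design, not
robustness to every artefact of real data. One consequence visible in the
bundled analysis: on NB counts the per-line noise variance differs between
lines with different means, which can mildly inflate the dynamic-effect
test relative to its Gaussian calibration.

## Numerical choices and problem sizes

Variances are bounded at zero (residual at ~1e-9 of the response variance);
LRT statistics are clamped at zero; zero-variance genes are skipped with a
recorded reason and fit failures are flagged, never silently dropped.
Simulation-based checks run at sizes chosen to make their Monte-Carlo error
small relative to the tolerance being asserted: 50-200 genes and 2,000-6,000
cells for recovery and calibration of ICCs, 1,000 replicates for type-I
rates (on a balanced 100-level factor with 200 cells per level, the regime
where the boundary-mixture reference applies), and 800 null genes over four
independent design draws for the dynamic-effect calibration.
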