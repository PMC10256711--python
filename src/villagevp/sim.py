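"""Synthetic village scRNA-seq experiments with known ground truth.

Emulates the pooled-line ("village") design: L hiPSC lines cultured together
across sites and replicates, with per-gene log-scale variance injected for
line, village status, site, replicate, line:village interaction and
cryopreservation, genotype-driven eQTL effects, a pseudotime axis with
optional line-specific slopes, spliced/unspliced count pairs, doublets, and
per-droplet QC statistics.

Each drawn effect vector is centred and rescaled so that its realized
variance across cells equals the configured share of the latent log-mean
variance exactly; calibration error in downstream estimates then reflects
estimation, not Monte-Carlo noise in the generator.  Counts are drawn
negative-binomial on a log link — a standard generative stand-in, since the
underlying study estimates from real UMI data and states no generative
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

CALLER_CLASSES = ("snp", "transcription", "hashtag")
SINGLET = "singlet"
DOUBLET = "doublet"
UNASSIGNED = "unassigned"

#: covariates that may carry a variance share (plus "residual")
COVARIATE_KEYS = (
    "line", "village", "site", "replicate", "line:village", "cryopreservation",
)

DEFAULT_VARIANCE_FRACTIONS = {
    "line": 0.10,
    "village": 0.05,
    "site": 0.05,
    "replicate": 0.02,
    "line:village": 0.03,
    "cryopreservation": 0.0,
    "residual": 0.75,
}

DEFAULT_CALLER_PROFILES = [
    ("snp", 0.02, 0.05),
    ("snp", 0.02, 0.05),
    ("snp", 0.02, 0.05),
    ("snp", 0.02, 0.05),
    ("snp", 0.02, 0.05),
    ("transcription", 0.0, 0.2),
    ("transcription", 0.0, 0.2),
    ("hashtag", 0.01, 0.1),
]


@dataclass
class SimConfig:
    """Parameters of one simulated village experiment.

    Variance fractions (including ``residual``) must be non-negative and sum
    to one; they define shares of the latent log-mean variance after the
    pseudotime share ``pseudotime_fraction`` is carved out, i.e. the
    effective share of covariate j is fractions[j] * (1 - pseudotime_fraction).
    """

    n_lines: int = 3
    n_cells: int = 3000
    n_genes: int = 200
    sites: tuple[str, ...] = ("site1", "site2", "site3")
    replicates_per_site: int = 3
    village_fraction: float = 0.5
    variance_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_FRACTIONS))
    pseudotime_fraction: float = 0.05
    dynamic_gene_fraction: float = 0.2
    dynamic_slope_sd: float = 0.5
    eqtl_spec: list = field(default_factory=list)  # (gene, snp, beta)
    doublet_rate: float | str = 0.0  # proportion, or "auto" for N^2*0.008/1000 doublets
    nb_dispersion: float = 10.0
    library_size_mean: float = 5000.0
    mito_gene_fraction: float = 0.05
    mito_expression_share: float = 0.08
    latent_variance: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        fr = self.variance_fractions
        if "residual" not in fr:
            raise ValueError("variance_fractions must include 'residual'")
        unknown = set(fr) - set(COVARIATE_KEYS) - {"residual"}
        if unknown:
            raise ValueError(f"unknown variance fraction keys: {sorted(unknown)}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("variance fractions must be non-negative")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(
                f"variance fractions must sum to 1 (got {sum(fr.values()):.6f})")
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        for name in ("village_fraction", "pseudotime_fraction",
                     "dynamic_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    spliced: CountMatrix
    unspliced: CountMatrix
    metadata: pd.DataFrame  # per-droplet covariates and QC stats
    genotypes: pd.DataFrame  # lines x snps dosage table
    truth: dict
    caller_tables: list[pd.DataFrame] = field(default_factory=list)
    config: SimConfig | None = None


def _standardize(values: np.ndarray, target_var: float) -> np.ndarray:
    """Centre and rescale so the realized variance equals target_var exactly."""
    v = values - values.mean()
    sd = v.std()
    if target_var == 0.0 or sd == 0.0:
        return np.zeros_like(v)
    return v * (np.sqrt(target_var) / sd)


def _standardize_levels(effects: np.ndarray, target_var: float) -> np.ndarray:
    """Centre level effects and rescale so their between-level variance
    (ddof = 1 across levels — the quantity a mixed model's sigma^2 estimates)
    equals target_var exactly."""
    e = effects - effects.mean()
    v = e.var(ddof=1) if len(e) > 1 else 0.0
    if target_var == 0.0 or v == 0.0:
        return np.zeros_like(e)
    return e * np.sqrt(target_var / v)


def _level_variance(effects: np.ndarray) -> float:
    """Between-level variance (ddof = 1) of realized level effects."""
    return float(np.var(effects, ddof=1)) if len(effects) > 1 else 0.0


def expected_doublet_count(n_droplets: int) -> float:
    # imported lazily to avoid a cycle; the formula lives with the demux rules
    from .demux import expected_doublet_count as _edc
    return _edc(n_droplets)


def simulate_village(config: SimConfig) -> SimulatedDataset:
    """Generate a full synthetic experiment (counts, metadata, truth tables)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_cells, config.n_genes
    lines = [f"line{i + 1}" for i in range(config.n_lines)]

    # --- cell-level design ---------------------------------------------------
    line = rng.choice(lines, size=n)
    site = rng.choice(list(config.sites), size=n)
    rep_within = rng.integers(1, config.replicates_per_site + 1, size=n)
    replicate = np.array([f"{s}_rep{r}" for s, r in zip(site, rep_within)])
    village = np.where(rng.random(n) < config.village_fraction, "village", "uni")
    frac = config.variance_fractions
    if frac.get("cryopreservation", 0.0) > 0:
        cryo = np.where(rng.random(n) < 0.5, "cryopreserved", "fresh")
    else:
        cryo = np.full(n, "fresh")
    pseudotime = rng.random(n)
    barcodes = [f"BC{i:06d}" for i in range(n)]

    labels = {
        "line": line,
        "village": village,
        "site": site,
        "replicate": replicate,
        "line:village": np.char.add(np.char.add(line.astype(str), "|"), village),
        "cryopreservation": cryo,
    }

    # --- per-gene latent log-means ------------------------------------------
    v0 = config.latent_variance
    pt_share = config.pseudotime_fraction
    cat_scale = 1.0 - pt_share

    # gene abundances: lognormal, mito genes pinned to a fixed expression share
    n_mito = max(1, int(round(config.mito_gene_fraction * g))) if g else 0
    gene_names = [f"MT-G{i:04d}" for i in range(n_mito)] + [
        f"G{i:04d}" for i in range(n_mito, g)]
    rel = np.exp(rng.normal(0.0, 1.2, size=g))
    if n_mito and g > n_mito:
        mito_share = config.mito_expression_share
        rel[:n_mito] *= mito_share / rel[:n_mito].sum()
        rel[n_mito:] *= (1 - mito_share) / rel[n_mito:].sum()
    else:
        rel /= rel.sum()
    base_mean = config.library_size_mean * rel  # expected counts per cell

    is_dynamic = rng.random(g) < config.dynamic_gene_fraction

    # genotypes for eQTL injection
    snps = sorted({snp for _, snp, _ in config.eqtl_spec})
    geno = {}
    for snp in snps:
        while True:
            dos = rng.integers(0, 3, size=config.n_lines)
            if len(np.unique(dos)) >= 2:
                break
        geno[snp] = dos
    genotypes = pd.DataFrame(geno, index=lines, dtype=int)
    eqtl_by_gene: dict[str, list[tuple[str, float]]] = {}
    for gene_idx_or_name, snp, beta in config.eqtl_spec:
        eqtl_by_gene.setdefault(str(gene_idx_or_name), []).append((snp, float(beta)))

    eta = np.empty((g, n))
    truth_shares = {k: np.zeros(g) for k in list(COVARIATE_KEYS) + ["pseudotime", "residual"]}
    truth_slopes = np.zeros((g, config.n_lines))
    truth_common_slope = np.zeros(g)
    truth_eqtl = []

    line_index = {l: i for i, l in enumerate(lines)}
    line_codes = np.array([line_index[l] for l in line])

    level_codes = {}
    for key in COVARIATE_KEYS:
        codes, lv = pd.factorize(labels[key])
        level_codes[key] = (codes, list(lv))

    for j in range(g):
        parts: dict[str, np.ndarray] = {}
        comp_var: dict[str, float] = {}  # on the scale the LMM estimates
        for key in COVARIATE_KEYS:
            f = frac.get(key, 0.0) * cat_scale * v0
            if f <= 0:
                continue
            codes, levels = level_codes[key]
            eff = _standardize_levels(rng.normal(0.0, 1.0, size=len(levels)), f)
            # genotype-driven eQTL effects are line-level shifts; align the
            # dosage vector to the factorized level order
            if key == "line":
                gname = gene_names[j]
                for lookup in (gname, str(j)):
                    if lookup in eqtl_by_gene:
                        for snp, beta in eqtl_by_gene[lookup]:
                            dos = genotypes.loc[levels, snp].to_numpy(float)
                            eff = eff + beta * (dos - dos.mean())
                            truth_eqtl.append(
                                {"gene": gname, "snp": snp, "beta": beta})
                        break
            parts[key] = eff[codes]
            comp_var[key] = _level_variance(eff)
        # pseudotime: common slope, plus line-specific deviations for dynamic genes
        if pt_share > 0:
            slope_dev = (rng.normal(0.0, config.dynamic_slope_sd, size=config.n_lines)
                         if is_dynamic[j] else np.zeros(config.n_lines))
            sgn = rng.choice([-1.0, 1.0])
            raw = (sgn + slope_dev[line_codes]) * pseudotime
            pt_part = _standardize(raw, pt_share * v0)
            scale_fac = (np.std(pt_part) / np.std(raw)) if np.std(raw) > 0 else 0.0
            truth_common_slope[j] = sgn * scale_fac
            truth_slopes[j] = (sgn + slope_dev) * scale_fac
            parts["pseudotime"] = pt_part
            comp_var["pseudotime"] = float(np.var(pt_part))
        f_res = frac["residual"] * cat_scale * v0
        parts["residual"] = _standardize(rng.normal(0.0, 1.0, size=n), f_res)
        comp_var["residual"] = f_res

        eta[j] = np.log(base_mean[j]) + sum(parts.values())
        tv = sum(comp_var.values())
        if tv > 0:
            for key, v in comp_var.items():
                truth_shares[key][j] = v / tv

    # --- counts: NB via gamma-poisson, spliced/unspliced split ---------------
    size_factor = np.exp(rng.normal(0.0, 0.1, size=n))
    mu = np.exp(eta) * size_factor[None, :]
    theta = config.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam)
    rho = rng.beta(15.0, 5.0, size=g)  # per-gene spliced fraction
    spliced = rng.binomial(counts, rho[:, None])
    unspliced = counts - spliced

    metadata = pd.DataFrame({
        "barcode": barcodes,
        "line": line,
        "site": site,
        "replicate": replicate,
        "village": village,
        "cryopreservation": cryo,
        "pseudotime": pseudotime,
        "is_doublet": False,
        "doublet_parents": "",
    })
    _recompute_qc_stats(metadata, counts, gene_names)

    truth = {
        "variance_shares": pd.DataFrame(truth_shares, index=gene_names),
        "pseudotime_slopes": pd.DataFrame(
            truth_slopes, index=gene_names, columns=lines),
        "common_slope": pd.Series(truth_common_slope, index=gene_names),
        "is_dynamic": pd.Series(is_dynamic, index=gene_names),
        "eqtl": pd.DataFrame(truth_eqtl, columns=["gene", "snp", "beta"]),
        "spliced_fraction": pd.Series(rho, index=gene_names),
        "labels": pd.Series(line, index=barcodes),
        # latent log-means (pre count noise): variance shares are defined here
        "latent": eta,
    }

    dataset = SimulatedDataset(
        counts=CountMatrix(sp.csr_matrix(counts), gene_names, barcodes),
        spliced=CountMatrix(sp.csr_matrix(spliced), gene_names, barcodes),
        unspliced=CountMatrix(sp.csr_matrix(unspliced), gene_names, barcodes),
        metadata=metadata,
        genotypes=genotypes,
        truth=truth,
        config=config,
    )

    # --- doublets and caller tables ------------------------------------------
    rate = config.doublet_rate
    if rate == "auto":
        n_doublets = int(round(n * (n * 0.008 / 1000.0)))
    else:
        n_doublets = int(round(float(rate) * n))
    if n_doublets > 0:
        dataset = inject_doublets(dataset, n_doublets,
                                  seed=int(rng.integers(0, 2**31 - 1)))

    truth_calls = np.where(dataset.metadata["is_doublet"], DOUBLET,
                           dataset.metadata["line"])
    dataset.caller_tables = simulate_caller_outputs(
        pd.Series(truth_calls, index=dataset.metadata["barcode"].to_numpy()),
        DEFAULT_CALLER_PROFILES,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return dataset


def _recompute_qc_stats(metadata: pd.DataFrame, counts: np.ndarray,
                        gene_names: list[str]) -> None:
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts)
    totals = dense.sum(axis=0)
    mito_mask = np.array([gn.startswith("MT-") for gn in gene_names])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(
            totals > 0, 100.0 * dense[mito_mask].sum(axis=0) / totals, 0.0)
    metadata["total_umis"] = totals.astype(int)
    metadata["n_genes"] = (dense > 0).sum(axis=0).astype(int)
    metadata["mito_pct"] = mito_pct


def inject_doublets(dataset: SimulatedDataset, n_doublets: int,
                    seed: int) -> SimulatedDataset:
    """Merge pairs of droplets from distinct lines into doublet droplets.

    2 * n_doublets singlet droplets are consumed; each pair is summed into a
    single doublet droplet whose QC statistics are recomputed.  Truth labels
    and the parent pair are recorded in the metadata.
    """
    if n_doublets == 0:
        return dataset
    md = dataset.metadata
    n = len(md)
    if n_doublets > n // 2:
        raise ValueError(f"n_doublets={n_doublets} exceeds available pairs ({n // 2})")
    rng = np.random.default_rng(seed)
    singlet_idx = np.flatnonzero(~md["is_doublet"].to_numpy())
    rng.shuffle(singlet_idx)
    lines_arr = md["line"].to_numpy()
    pairs: list[tuple[int, int]] = []
    pool = list(singlet_idx)
    while len(pairs) < n_doublets:
        if len(pool) < 2:
            raise ValueError("not enough distinct-line droplet pairs available")
        a = pool.pop()
        partner = next((i for i, b in enumerate(pool) if lines_arr[b] != lines_arr[a]), None)
        if partner is None:
            raise ValueError("not enough distinct-line droplet pairs available")
        pairs.append((a, pool.pop(partner)))

    counts = dataset.counts.toarray()
    spliced = dataset.spliced.toarray()
    unspliced = dataset.unspliced.toarray()
    consumed = {i for pair in pairs for i in pair}
    keep = [i for i in range(n) if i not in consumed]

    new_cols_c, new_cols_s, new_cols_u, new_rows = [], [], [], []
    for k, (a, b) in enumerate(pairs):
        new_cols_c.append(counts[:, a] + counts[:, b])
        new_cols_s.append(spliced[:, a] + spliced[:, b])
        new_cols_u.append(unspliced[:, a] + unspliced[:, b])
        row = md.iloc[a].copy()
        row["barcode"] = f"DBL{k:05d}"
        row["is_doublet"] = True
        row["doublet_parents"] = f"{md.iloc[a]['barcode']}+{md.iloc[b]['barcode']}"
        new_rows.append(row)

    counts_new = np.column_stack([counts[:, keep]] + new_cols_c) if new_cols_c else counts[:, keep]
    spliced_new = np.column_stack([spliced[:, keep]] + new_cols_s)
    unspliced_new = np.column_stack([unspliced[:, keep]] + new_cols_u)
    md_new = pd.concat([md.iloc[keep], pd.DataFrame(new_rows)], ignore_index=True)
    _recompute_qc_stats(md_new, counts_new, dataset.counts.genes)
    barcodes_new = md_new["barcode"].tolist()

    genes = dataset.counts.genes
    truth = dict(dataset.truth)
    truth["labels"] = pd.Series(
        np.where(md_new["is_doublet"], DOUBLET, md_new["line"]),
        index=barcodes_new)
    parent_counts = {
        f"DBL{k:05d}": (md.iloc[a]["barcode"], md.iloc[b]["barcode"])
        for k, (a, b) in enumerate(pairs)}
    truth["doublet_parents"] = parent_counts

    return replace(
        dataset,
        counts=CountMatrix(sp.csr_matrix(counts_new), genes, barcodes_new),
        spliced=CountMatrix(sp.csr_matrix(spliced_new), genes, barcodes_new),
        unspliced=CountMatrix(sp.csr_matrix(unspliced_new), genes, barcodes_new),
        metadata=md_new,
        truth=truth,
    )


def simulate_caller_outputs(truth_labels: pd.Series,
                            profiles: list[tuple[str, float, float]],
                            seed: int) -> list[pd.DataFrame]:
    """Per-caller assignment tables derived from true droplet labels.

    ``truth_labels`` maps barcode -> line label or "doublet".  Each profile is
    (caller_class, miscall_rate, doublet_miss_rate): singlets are miscalled to
    a uniformly random *other* line (snp) or flipped to "doublet"
    (transcription / hashtag, which carry no line labels) at the miscall
    rate; true doublets are called singlet at the doublet-miss rate.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    for cls, mis, dmiss in profiles:
        if cls not in CALLER_CLASSES:
            raise ValueError(f"unknown caller class {cls!r}")
        if not (0.0 <= mis <= 1.0 and 0.0 <= dmiss <= 1.0):
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    barcodes = truth_labels.index.to_numpy()
    labels = truth_labels.to_numpy()
    is_doublet = labels == DOUBLET
    all_lines = sorted(set(labels) - {DOUBLET, UNASSIGNED})
    tables = []
    for k, (cls, miscall, dmiss) in enumerate(profiles):
        calls = labels.astype(object).copy()
        # doublets missed -> reported singlet
        miss = is_doublet & (rng.random(len(labels)) < dmiss)
        if cls == "snp":
            calls[miss] = rng.choice(all_lines, size=int(miss.sum()))
        else:
            calls[miss] = SINGLET
        # singlets miscalled
        singlet = ~is_doublet
        flip = singlet & (rng.random(len(labels)) < miscall)
        if cls == "snp":
            for i in np.flatnonzero(flip):
                others = [l for l in all_lines if l != labels[i]]
                calls[i] = others[rng.integers(len(others))] if others else labels[i]
        else:
            calls[singlet] = SINGLET
            calls[flip] = DOUBLET
        tables.append(pd.DataFrame({
            "barcode": barcodes,
            "call": calls,
            "caller_id": f"{cls}{k}",
            "caller_class": cls,
        }))
    return tables
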