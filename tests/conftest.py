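import numpy as np
import pandas as pd
import pytest

from villagevp.sim import SimConfig, simulate_village


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated village (doublets, callers, eQTLs)."""
    cfg = SimConfig(
        n_cells=1200, n_genes=80, doublet_rate=0.05, seed=7,
        eqtl_spec=[("G0010", "rs1", 0.8), ("G0011", "rs2", -0.6)],
    )
    return simulate_village(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def brute_force_threeline(calls_by_class: dict[str, list[str]]) -> tuple[str, str]:
    """Independent re-statement of the three-line retention rule.

    ``calls_by_class`` maps caller class to the list of that class's calls
    for one droplet.  Returns (status, line).
    """
    snp = calls_by_class.get("snp", [])
    trans = calls_by_class.get("transcription", [])
    hashtag = calls_by_class.get("hashtag", [])
    non_line = {"doublet", "unassigned", "singlet"}
    snp_lines = [c for c in snp if c not in non_line]
    votes = len(snp_lines) + sum(c == "singlet" for c in trans)
    if votes < 4:
        return "excluded", ""
    if not hashtag or any(c != "singlet" for c in hashtag):
        return "excluded", ""
    counts: dict[str, int] = {}
    for c in snp_lines:
        counts[c] = counts.get(c, 0) + 1
    if not counts:
        return "excluded", ""
    best = max(counts.values())
    winners = [l for l, c in counts.items() if c == best]
    if best >= 3 and len(winners) == 1:
        return "retained", winners[0]
    return "excluded", ""


def brute_force_at_least_half(calls_by_class: dict[str, list[str]]) -> tuple[str, str]:
    """Independent re-statement of the >= ceil(K/2)-singlet rule."""
    import math

    non_line = {"doublet", "unassigned", "singlet"}
    snp = calls_by_class.get("snp", [])
    others = calls_by_class.get("transcription", []) + calls_by_class.get("hashtag", [])
    snp_lines = [c for c in snp if c not in non_line]
    K = sum(len(v) for v in calls_by_class.values())
    n_singlet = len(snp_lines) + sum(c == "singlet" for c in others)
    if n_singlet < math.ceil(K / 2):
        return "excluded", ""
    counts: dict[str, int] = {}
    for c in snp_lines:
        counts[c] = counts.get(c, 0) + 1
    if not counts:
        return "excluded", ""
    best = max(counts.values())
    winners = [l for l, c in counts.items() if c == best]
    if len(winners) == 1:
        return "retained", winners[0]
    return "excluded", ""


def random_caller_tables(rng, n_droplets, lines=("A", "B", "C")):
    """Random toy assignment tables: 3-6 snp, 0-2 transcription, 0-1 hashtag."""
    n_snp = rng.integers(3, 7)
    n_trans = rng.integers(0, 3)
    n_hash = rng.integers(1, 2)  # three-line rule needs a hashtag caller
    barcodes = [f"d{i}" for i in range(n_droplets)]
    tables = []
    snp_choices = list(lines) + ["doublet", "unassigned"]
    for k in range(n_snp):
        tables.append(pd.DataFrame({
            "barcode": barcodes,
            "call": rng.choice(snp_choices, size=n_droplets),
            "caller_id": f"snp{k}", "caller_class": "snp"}))
    for k in range(n_trans):
        tables.append(pd.DataFrame({
            "barcode": barcodes,
            "call": rng.choice(["singlet", "doublet"], size=n_droplets),
            "caller_id": f"tr{k}", "caller_class": "transcription"}))
    for k in range(n_hash):
        tables.append(pd.DataFrame({
            "barcode": barcodes,
            "call": rng.choice(["singlet", "doublet", "unassigned"], size=n_droplets),
            "caller_id": f"ht{k}", "caller_class": "hashtag"}))
    return tables
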