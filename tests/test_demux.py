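import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from villagevp import demux
from villagevp.sim import SimConfig, simulate_caller_outputs, simulate_village

from conftest import (
    brute_force_at_least_half, brute_force_threeline, random_caller_tables,
)


def _tables(per_class: dict[str, list[str]], barcode="d0") -> list[pd.DataFrame]:
    out = []
    for cls, calls in per_class.items():
        for k, call in enumerate(calls):
            out.append(pd.DataFrame({
                "barcode": [barcode], "call": [call],
                "caller_id": [f"{cls}{k}"], "caller_class": [cls]}))
    return out


class TestExpectedDoubletCount:
    @pytest.mark.parametrize("n,expected", [(0, 0.0), (1000, 8.0), (20000, 3200.0)])
    def test_formula(self, n, expected):
        assert demux.expected_doublet_count(n) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            demux.expected_doublet_count(-1)


class TestThreelineRule:
    def test_unanimous_retained(self):
        tables = _tables({"snp": ["A"] * 5,
                          "transcription": ["singlet"] * 2,
                          "hashtag": ["singlet"]})
        out = demux.consensus_threeline(tables)
        assert out.iloc[0]["status"] == "retained"
        assert out.iloc[0]["line"] == "A"

    def test_three_singlet_votes_insufficient(self):
        # 3 snp call A, 2 snp + 2 transcription call doublet: only 3 singlet
        # votes in the pooled set -> clause (a) fails despite line agreement
        tables = _tables({"snp": ["A", "A", "A", "doublet", "doublet"],
                          "transcription": ["doublet", "doublet"],
                          "hashtag": ["singlet"]})
        out = demux.consensus_threeline(tables)
        assert out.iloc[0]["status"] == "excluded"
        assert out.iloc[0]["reason"] == demux.REASON_SINGLET_VOTES

    def test_line_split_excluded(self):
        # 4 snp singlets split 2 A / 2 B: clause (c) has no 3-way agreement
        tables = _tables({"snp": ["A", "A", "B", "B"],
                          "transcription": ["singlet"],
                          "hashtag": ["singlet"]})
        out = demux.consensus_threeline(tables)
        assert out.iloc[0]["status"] == "excluded"
        assert out.iloc[0]["reason"] == demux.REASON_LINE_AGREEMENT

    def test_hashtag_doublet_excluded(self):
        tables = _tables({"snp": ["A"] * 5, "hashtag": ["doublet"]})
        out = demux.consensus_threeline(tables)
        assert out.iloc[0]["reason"] == demux.REASON_HASHTAG

    def test_missing_caller_classes_rejected(self):
        tables = _tables({"snp": ["A", "A"], "hashtag": ["singlet"]})
        with pytest.raises(ValueError, match="3 snp"):
            demux.consensus_threeline(tables)

    def test_droplet_missing_from_one_table_counts_unassigned(self):
        # droplet d1 appears only in 4 of 5 snp tables; with 4 line votes it
        # is still retained, but with 3 it is not
        rows = []
        for k in range(5):
            barcodes = ["d0", "d1"] if k < 4 else ["d0"]
            rows.append(pd.DataFrame({
                "barcode": barcodes, "call": ["A"] * len(barcodes),
                "caller_id": f"snp{k}", "caller_class": "snp"}))
        rows.append(pd.DataFrame({
            "barcode": ["d0", "d1"], "call": ["singlet", "singlet"],
            "caller_id": "ht0", "caller_class": "hashtag"}))
        out = demux.consensus_threeline(rows).set_index("barcode")
        assert out.loc["d1", "status"] == "retained"

    def test_agreeing_extra_caller_never_flips_to_excluded(self, rng):
        """Monotonicity: adding an agreeing snp caller preserves retention."""
        for trial in range(20):
            tables = random_caller_tables(rng, n_droplets=6)
            out = demux.consensus_threeline(tables).set_index("barcode")
            retained = out[out["status"] == "retained"]
            if retained.empty:
                continue
            extra = pd.DataFrame({
                "barcode": out.index,
                "call": [retained["line"].get(b, "A") for b in out.index],
                "caller_id": "snpX", "caller_class": "snp"})
            out2 = demux.consensus_threeline(tables + [extra]).set_index("barcode")
            for b in retained.index:
                assert out2.loc[b, "status"] == "retained"
                assert out2.loc[b, "line"] == retained.loc[b, "line"]


class TestAtLeastHalfRule:
    def test_half_singlet_retained(self):
        tables = _tables({"snp": ["A", "A", "doublet", "doublet"]})
        out = demux.consensus_at_least_half(tables)
        assert out.iloc[0]["status"] == "retained"
        assert out.iloc[0]["line"] == "A"

    def test_all_doublet_excluded(self):
        tables = _tables({"snp": ["doublet"] * 4})
        out = demux.consensus_at_least_half(tables)
        assert out.iloc[0]["status"] == "excluded"

    def test_line_tie_excluded(self):
        tables = _tables({"snp": ["A", "A", "B", "B"],
                          "transcription": ["singlet", "singlet"]})
        out = demux.consensus_at_least_half(tables)
        assert out.iloc[0]["status"] == "excluded"
        assert out.iloc[0]["reason"] == demux.REASON_LINE_TIE

    def test_empty_tables_rejected(self):
        with pytest.raises(ValueError):
            demux.consensus_at_least_half([])


class TestBruteForceEquivalence:
    """Both consensus rules match an independent rule evaluator."""

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n_droplets = int(rng.integers(1, 13))
            tables = random_caller_tables(rng, n_droplets)
            by_class_per_droplet = {}
            for t in tables:
                cls = t["caller_class"].iloc[0]
                for b, call in zip(t["barcode"], t["call"]):
                    by_class_per_droplet.setdefault(b, {}).setdefault(cls, []).append(call)
            for fn, oracle in [
                (demux.consensus_threeline, brute_force_threeline),
                (demux.consensus_at_least_half, brute_force_at_least_half),
            ]:
                try:
                    out = fn(tables).set_index("barcode")
                except ValueError:
                    continue  # missing required classes for threeline
                for b, by_class in by_class_per_droplet.items():
                    status, line = oracle(by_class)
                    assert out.loc[b, "status"] == status, (trial, b, by_class)
                    if status == "retained":
                        assert out.loc[b, "line"] == line

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_property_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        tables = random_caller_tables(rng, int(rng.integers(1, 10)))
        out = demux.consensus_at_least_half(tables).set_index("barcode")
        for t in tables:
            pass
        by_class = {}
        for t in tables:
            cls = t["caller_class"].iloc[0]
            for b, call in zip(t["barcode"], t["call"]):
                by_class.setdefault(b, {}).setdefault(cls, []).append(call)
        for b, cbc in by_class.items():
            status, line = brute_force_at_least_half(cbc)
            assert out.loc[b, "status"] == status


class TestOnSimulatedCallers:
    def test_perfect_callers_give_perfect_consensus(self):
        ds = simulate_village(SimConfig(n_cells=600, n_genes=20,
                                        doublet_rate=0.08, seed=11))
        truth = ds.truth["labels"]
        profiles = [("snp", 0.0, 0.0)] * 5 + [("transcription", 0.0, 0.0)] * 2 \
            + [("hashtag", 0.0, 0.0)]
        tables = simulate_caller_outputs(truth, profiles, seed=1)
        out = demux.consensus_threeline(tables).set_index("barcode")
        singlets = truth[truth != "doublet"]
        assert (out.loc[singlets.index, "status"] == "retained").all()
        assert (out.loc[singlets.index, "line"] == singlets).all()
        doublets = truth[truth == "doublet"]
        assert (out.loc[doublets.index, "status"] == "excluded").all()


class TestSummary:
    def test_partition_and_counts(self):
        tables = _tables({"snp": ["A"] * 5, "hashtag": ["singlet"]})
        # 6 droplets with a mix of outcomes
        rows = []
        for i, (snp_call, ht) in enumerate([
                ("A", "singlet"), ("A", "singlet"), ("B", "singlet"),
                ("doublet", "singlet"), ("A", "doublet"), ("unassigned", "singlet")]):
            rows.append((f"d{i}", snp_call, ht))
        tables = []
        for k in range(5):
            tables.append(pd.DataFrame({
                "barcode": [r[0] for r in rows],
                "call": [r[1] for r in rows],
                "caller_id": f"snp{k}", "caller_class": "snp"}))
        tables.append(pd.DataFrame({
            "barcode": [r[0] for r in rows], "call": [r[2] for r in rows],
            "caller_id": "ht0", "caller_class": "hashtag"}))
        cons = demux.consensus_threeline(tables)
        summary = demux.consensus_summary(cons)
        assert summary["n_droplets"] == 6
        assert summary["n_retained"] + summary["n_excluded"] == 6
        # hand enumeration: d0, d1 retained A; d2 retained B; d3 excluded
        # (no singlet votes); d4 hashtag doublet; d5 unassigned everywhere
        assert summary["retained_per_line"] == {"A": 2, "B": 1}
        assert summary["n_retained"] == 3
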