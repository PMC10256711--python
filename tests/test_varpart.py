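import numpy as np
import pandas as pd
import pytest

from villagevp import varpart
from villagevp.varpart import VarianceComponents, icc


class TestIcc:
    def test_two_component_arithmetic(self):
        out = icc({"A": 25.0, "residual": 75.0})
        assert out == {"A": 25.0, "residual": 75.0}

    def test_three_components(self):
        out = icc({"A": 1.0, "B": 1.0, "residual": 2.0})
        assert out == {"A": 25.0, "B": 25.0, "residual": 50.0}

    def test_sums_to_100(self, rng):
        comps = {f"c{i}": float(v) for i, v in enumerate(rng.uniform(0, 5, 6))}
        comps["residual"] = 1.0
        assert sum(icc(comps).values()) == pytest.approx(100.0, abs=1e-9)

    def test_missing_residual_rejected(self):
        with pytest.raises(ValueError, match="residual"):
            icc({"A": 1.0})

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            icc({"A": 0.0, "residual": 0.0})


class TestFitGeneLmm:
    def test_pure_noise_gives_residual_dominated_icc(self, rng):
        n = 3000
        design = pd.DataFrame({"line": rng.choice(list("abc"), n)})
        y = rng.normal(size=n)
        vc = varpart.fit_gene_lmm(y, design, ["line"])
        out = icc(vc)
        assert out["residual"] > 95.0

    def test_half_line_variance_recovered(self, rng):
        """Line shifts with between-line variance 1 + noise SD 1 -> ICC ~50%.

        Shifts are rescaled so their realized between-line variance is
        exactly 1, matching what the model's sigma^2_line estimates; the
        average ICC over genes should then sit at 50%.
        """
        n_per, trials = 2000, 20
        line = np.repeat(list("abc"), n_per)
        design = pd.DataFrame({"line": line})
        model = varpart.build_model(design, ["line"])
        iccs = []
        for _ in range(trials):
            shifts = rng.normal(0, 1, 3)
            shifts = (shifts - shifts.mean()) / shifts.std(ddof=1)
            y = shifts[pd.factorize(line)[0]] + rng.normal(0, 1, 3 * n_per)
            vc = varpart.fit_gene_lmm(y, design, ["line"], model=model)
            iccs.append(icc(vc)["line"])
        assert abs(np.mean(iccs) - 50.0) <= 5.0

    def test_constant_covariate_rejected(self):
        design = pd.DataFrame({"line": ["a"] * 10})
        with pytest.raises(ValueError, match="line"):
            varpart.fit_gene_lmm(np.arange(10.0), design, ["line"])

    def test_continuous_term_component_is_fitted_contribution_variance(self, rng):
        n = 2000
        pt = rng.random(n)
        design = pd.DataFrame({"line": rng.choice(list("ab"), n), "pseudotime": pt})
        y = 2.0 * pt + rng.normal(0, 0.5, n)
        vc = varpart.fit_gene_lmm(y, design, ["line"], ["pseudotime"])
        # var(2 * pt) = 4/12 = 1/3; noise var 0.25 -> share ~ 57%
        assert vc.components["pseudotime"] == pytest.approx(4.0 / 12.0, rel=0.1)
        assert icc(vc)["pseudotime"] == pytest.approx(100 * (1 / 3) / (1 / 3 + 0.25),
                                                      abs=6.0)


class TestCovariateTest:
    def test_lrt_nonnegative_any_input(self, rng):
        n = 300
        design = pd.DataFrame({"g": rng.choice(list("abcd"), n)})
        for _ in range(10):
            t = varpart.test_covariate(rng.normal(size=n), design, ["g"], "g")
            assert t.lrt >= 0.0
            assert 0.0 <= t.p <= 1.0

    def test_strong_component_detected(self, rng):
        n = 1000
        g = rng.choice([f"l{i}" for i in range(10)], n)
        design = pd.DataFrame({"g": g})
        hits = 0
        for _ in range(10):
            eff = rng.normal(0, 0.65, 10)  # ~30% ICC against noise SD 1
            y = eff[pd.factorize(g)[0]] + rng.normal(0, 1, n)
            t = varpart.test_covariate(y, design, ["g"], "g")
            hits += t.p < 1e-4
        assert hits >= 9

    def test_few_level_null_is_conservative(self, rng):
        """With 3 levels the boundary mixture under-rejects (documented)."""
        n = 500
        design = pd.DataFrame({"line": rng.choice(list("abc"), n)})
        models = (varpart.build_model(design, ["line"]),
                  varpart.build_model(design, []))
        ps = np.array([
            varpart.test_covariate(rng.normal(size=n), design, ["line"], "line",
                                   models=models).p
            for _ in range(200)])
        assert (ps < 0.05).mean() <= 0.05

    def test_unknown_term_rejected(self, rng):
        design = pd.DataFrame({"g": list("aabb")})
        with pytest.raises(ValueError, match="not in model"):
            varpart.test_covariate(np.arange(4.0), design, ["g"], "h")


class TestInteraction:
    def test_crossed_levels_bounded(self):
        design = pd.DataFrame({"a": list("xxyy") * 25, "b": list("uv") * 50})
        rng = np.random.default_rng(0)
        t = varpart.test_interaction(rng.normal(size=100), design, "a", "b")
        assert t.covariate == "a:b"
        assert t.lrt >= 0

    def test_injected_interaction_detected(self, rng):
        n = 2000
        a = rng.choice(list("abc"), n)
        b = rng.choice(list("uv"), n)
        design = pd.DataFrame({"a": a, "b": b})
        combo = pd.factorize(pd.Series(a) + pd.Series(b))[0]
        eff = rng.normal(0, 0.55, combo.max() + 1)  # ~20% share
        y = eff[combo] + rng.normal(0, 1, n)
        t = varpart.test_interaction(y, design, "a", "b")
        assert t.p < 0.05


class TestDynamicEffects:
    def test_opposite_slopes_detected_with_opposite_signs(self, rng):
        n_per = 1000
        line = np.repeat(["a", "b"], n_per)
        pt = rng.random(2 * n_per)
        design = pd.DataFrame({"line": line, "pseudotime": pt})
        sl = np.where(line == "a", 1.0, -1.0)
        expr = np.vstack([sl * pt + rng.normal(0, 1, 2 * n_per) for _ in range(3)])
        eff = varpart.dynamic_effects(expr, design)
        assert len(eff) == 3
        for e in eff:
            assert e.q < 0.05
            assert np.sign(e.slopes["a"]) != np.sign(e.slopes["b"])

    def test_gated_out_genes_absent(self, rng):
        n = 600
        line = np.repeat(["a", "b"], n // 2)
        pt = rng.random(n)
        design = pd.DataFrame({"line": line, "pseudotime": pt})
        # gene 0: pure noise (fails gate); gene 1: strong dynamic effect
        sl = np.where(line == "a", 1.5, -1.5)
        expr = np.vstack([rng.normal(0, 1, n), sl * pt + rng.normal(0, 0.5, n)])
        eff = varpart.dynamic_effects(expr, design, genes=["null", "dyn"])
        names = [e.gene for e in eff]
        assert "null" not in names
        assert "dyn" in names

    def test_constant_pseudotime_rejected(self, rng):
        design = pd.DataFrame({"line": list("ab") * 5, "pseudotime": [0.5] * 10})
        with pytest.raises(ValueError, match="constant"):
            varpart.dynamic_effects(rng.normal(size=(1, 10)), design)


class TestDecomposeAll:
    def test_output_shape_and_icc_sums(self, rng):
        n = 400
        design = pd.DataFrame({
            "line": rng.choice(list("abc"), n),
            "village": rng.choice(["uni", "village"], n)})
        expr = rng.normal(size=(8, n))
        table = varpart.decompose_all(expr, design, ["line", "village"],
                                      compute_tests=False)
        # genes x (terms + residual) rows
        assert len(table) == 8 * 3
        sums = table.groupby("gene")["icc_pct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-6)

    def test_zero_variance_gene_flagged_not_dropped(self, rng):
        n = 100
        design = pd.DataFrame({"line": rng.choice(list("ab"), n)})
        expr = np.vstack([np.zeros(n), rng.normal(size=n)])
        table = varpart.decompose_all(expr, design, ["line"], compute_tests=False)
        flagged = table[table["gene"] == "gene0"]
        assert (~flagged["fitted"]).all()
        assert "zero variance" in flagged["note"].iloc[0]

    def test_qvalues_present_and_ordered(self, rng):
        n = 300
        g = rng.choice(list("abcde"), n)
        design = pd.DataFrame({"g": g})
        eff = rng.normal(0, 1, 5)
        expr = np.vstack([eff[pd.factorize(g)[0]] * (j % 2) + rng.normal(size=n)
                          for j in range(6)])
        table = varpart.decompose_all(expr, design, ["g"], compute_tests=True)
        rows = table[table["component"] == "g"]
        assert rows["p"].notna().all()
        assert (rows["q"] >= rows["p"] - 1e-12).all()

    def test_cryopreserved_model_preset_recovers_cryo_share(self):
        """The cryopreserved design (line, village, cryopreservation,
        replicate) attributes an injected cryopreservation share."""
        from villagevp.sim import DEFAULT_VARIANCE_FRACTIONS, SimConfig, simulate_village
        from villagevp.varpart import MODEL_SPECS

        fr = dict(DEFAULT_VARIANCE_FRACTIONS)
        fr.update({"cryopreservation": 0.10, "residual": 0.65})
        ds = simulate_village(SimConfig(
            n_cells=2000, n_genes=10, variance_fractions=fr,
            pseudotime_fraction=0.0, doublet_rate=0.0, seed=31))
        table = varpart.decompose_all(
            ds.truth["latent"], ds.metadata,
            MODEL_SPECS["cryopreserved"]["random"], compute_tests=False)
        est = table.groupby("component")["icc_pct"].mean()
        assert abs(est["cryopreservation"] - 10.0) < 5.0

    def test_threshold_scan_matches_direct_count(self, rng):
        n = 300
        design = pd.DataFrame({"g": rng.choice(list("abc"), n)})
        expr = rng.normal(size=(10, n))
        table = varpart.decompose_all(expr, design, ["g"], compute_tests=False)
        sub = table[table["component"] == "g"]
        count = (sub["icc_pct"] > 1.0).sum()
        direct = sum(
            icc(varpart.fit_gene_lmm(expr[j], design, ["g"]))["g"] > 1.0
            for j in range(10))
        assert count == direct
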