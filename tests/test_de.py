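import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirmaster import de


def _meta(n_per_group=3, batches=("b1",)):
    rows = []
    for i, cond in enumerate(["control"] * n_per_group + ["treated"] * n_per_group):
        rows.append({"sample": f"s{i}", "condition": cond,
                     "batch": batches[i % len(batches)], "assay": "rna"})
    return pd.DataFrame(rows)


SPEC = de.DesignSpec(("batch", "condition"), ("condition", "treated", "control"))


class TestSizeFactors:
    def test_hand_median_of_ratios(self):
        counts = pd.DataFrame([[2, 4], [4, 8], [6, 12]], columns=["a", "b"])
        sf = de.size_factors(counts)
        assert sf["a"] == pytest.approx(0.7071, abs=1e-4)
        assert sf["b"] == pytest.approx(1.4142, abs=1e-4)

    def test_identical_columns_unity(self):
        counts = pd.DataFrame({"a": [5, 10, 2], "b": [5, 10, 2]})
        assert np.allclose(de.size_factors(counts), 1.0)

    def test_single_sample_unity(self):
        assert de.size_factors(pd.DataFrame({"a": [3, 7]}))["a"] == pytest.approx(1.0)

    def test_no_all_positive_gene_errors(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            de.size_factors(counts)
        assert (de.size_factors(counts, allow_pseudo_reference=True) > 0).all()

    def test_column_scaling_scales_factor(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, size=(200, 4)),
                              columns=list("abcd"))
        sf = de.size_factors(counts)
        scaled = counts.copy()
        scaled["b"] = counts["b"] * 2
        sf2 = de.size_factors(scaled)
        # the scaled sample's factor doubles relative to the geometric reference
        assert sf2["b"] / sf["b"] == pytest.approx(2.0 ** (3 / 4), rel=1e-6)


class TestDispersion:
    def test_poisson_counts_hit_floor(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(200, size=(2000, 40)))
        counts.columns = [f"s{i}" for i in range(40)]
        sf = de.size_factors(counts)
        disp = de.estimate_dispersion(counts, sf, np.zeros(40, dtype=int))
        assert disp["alpha_gw"].mean() < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(1)
        alpha, mean = 0.2, 500.0
        r = 1 / alpha
        counts = pd.DataFrame(rng.negative_binomial(r, r / (r + mean), size=(500, 50)))
        counts.columns = [f"s{i}" for i in range(50)]
        sf = de.size_factors(counts)
        disp = de.estimate_dispersion(counts, sf, np.zeros(50, dtype=int))
        assert 0.1 <= disp["alpha_gw"].median() <= 0.3

    def test_constant_counts_floor_and_zero_gene_na(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [10, 0], "c": [10, 0]})
        sf = pd.Series(1.0, index=counts.columns)
        disp = de.estimate_dispersion(counts, sf, np.zeros(3, dtype=int))
        assert disp.loc[0, "alpha_gw"] == pytest.approx(de.ALPHA_FLOOR)
        assert np.isnan(disp.loc[1, "alpha_gw"])

    def test_final_between_genewise_and_trend(self):
        rng = np.random.default_rng(2)
        r = 1 / 0.1
        counts = pd.DataFrame(rng.negative_binomial(r, r / (r + 300), size=(300, 6)))
        counts.columns = [f"s{i}" for i in range(6)]
        sf = de.size_factors(counts)
        disp = de.estimate_dispersion(counts, sf, np.zeros(6, dtype=int)).dropna()
        lo = np.minimum(np.clip(disp["alpha_gw"], disp["alpha_trend"] / 8, disp["alpha_trend"] * 8),
                        disp["alpha_trend"])
        hi = np.maximum(np.clip(disp["alpha_gw"], disp["alpha_trend"] / 8, disp["alpha_trend"] * 8),
                        disp["alpha_trend"])
        assert ((disp["alpha_final"] >= lo - 1e-12) & (disp["alpha_final"] <= hi + 1e-12)).all()


class TestNbWald:
    def test_planted_effect_detected(self):
        rng = np.random.default_rng(7)
        r = 1 / 0.01
        mu = np.tile(rng.uniform(300, 3000, 500)[:, None], (1, 6))
        mu[:10, 3:] = mu[:10, :1] * 2 ** 2.0  # 10 planted genes, lfc = 2
        y = rng.negative_binomial(r, r / (r + mu))
        counts = pd.DataFrame(y, columns=[f"s{i}" for i in range(6)])
        res = de.run_de(counts, _meta(), SPEC)
        assert (res["p"].iloc[:10] < 1e-4).all()
        assert np.abs(res["log2fc"].iloc[:10] - 2.0).max() < 0.3

    def test_self_contrast_zero(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, (50, 6)), columns=[f"s{i}" for i in range(6)])
        res = de.run_de(counts, _meta(),
                        de.DesignSpec(("condition",), ("condition", "control", "control")))
        assert (res["log2fc"] == 0).all()

    def test_all_zero_gene_na(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, (20, 6)), columns=[f"s{i}" for i in range(6)])
        counts.iloc[0] = 0
        res = de.run_de(counts, _meta(), SPEC)
        assert np.isnan(res["p"].iloc[0]) and np.isnan(res["padj"].iloc[0])

    def test_separation_handled(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, (20, 6)), columns=[f"s{i}" for i in range(6)])
        counts.iloc[0, :3] = 0  # all control zero
        res = de.run_de(counts, _meta(), SPEC)
        assert res["flagged"].iloc[0]
        assert np.isfinite(res["log2fc"].iloc[0])

    def test_matches_statsmodels_glm(self):
        """Per-gene IRLS agrees with an independent NB GLM fit."""
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        r = 1 / 0.05
        y = rng.negative_binomial(r, r / (r + 400), size=(20, 6))
        counts = pd.DataFrame(y, columns=[f"s{i}" for i in range(6)])
        meta = _meta()
        sf = de.size_factors(counts)
        X, names = de.design_matrix(meta, ["condition"], references={"condition": "control"})
        cells = de._design_cells(meta, ["condition"])
        disp = de.estimate_dispersion(counts, sf, cells)
        res = de.nb_wald(counts, sf, disp, X, names, "condition_treated", cells=cells)
        for i in range(20):
            alpha = disp["alpha_final"].iloc[i]
            model = sm.GLM(y[i], X, family=sm.families.NegativeBinomial(alpha=alpha),
                           offset=np.log(sf.to_numpy()))
            fit = model.fit()
            assert res["log2fc"].iloc[i] == pytest.approx(fit.params[1] / np.log(2), abs=1e-5)
            assert res["se"].iloc[i] == pytest.approx(fit.bse[1] / np.log(2), rel=1e-3)

    def test_log2fc_recovery_near_information_floor(self):
        """lfc MAE tracks the oracle estimator's sampling floor (alpha=0.05, n=3)."""
        rng = np.random.default_rng(11)
        G, r = 2000, 1 / 0.05
        lfc = rng.normal(0, 1, G)
        mu = np.tile(np.full(G, 500.0)[:, None], (1, 6))
        mu[:, 3:] = (500 * 2 ** lfc)[:, None]
        y = rng.negative_binomial(r, r / (r + mu))
        counts = pd.DataFrame(y, columns=[f"s{i}" for i in range(6)])
        res = de.run_de(counts, _meta(), SPEC)
        mae = np.abs(res["log2fc"] - lfc).mean()
        with np.errstate(divide="ignore"):
            oracle = np.abs(np.log2(y[:, 3:].mean(1) / y[:, :3].mean(1)) - lfc)
        assert mae < 0.25
        assert mae < 1.15 * oracle[np.isfinite(oracle)].mean()


class TestBH:
    def test_hand_example(self):
        out = de.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert de.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])

    def test_na_excluded_from_m(self):
        out = de.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(0.02)

    @staticmethod
    def _oracle(p):
        """Brute force: sort, scale by m/rank, cumulative min from the right."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_bruteforce_oracle(self, p):
        assert np.allclose(de.bh_adjust(p), self._oracle(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        assert np.allclose(de.bh_adjust(p), multipletests(p, method="fdr_bh")[1])


class TestSignificantFeatures:
    BASE = {"padj": 0.04, "log2fc": 0.6, "baseMean": 501.0}

    def _res(self, **kw):
        row = dict(self.BASE)
        row.update(kw)
        return pd.DataFrame(row, index=["g"])

    def test_up_call(self):
        up, down = de.significant_features(self._res())
        assert up == ["g"] and down == []

    def test_down_call(self):
        up, down = de.significant_features(self._res(log2fc=-0.9))
        assert down == ["g"]

    @pytest.mark.parametrize("kw", [{"log2fc": 0.5}, {"baseMean": 500.0}, {"padj": 0.05}])
    def test_strict_inequalities(self, kw):
        up, down = de.significant_features(self._res(**kw))
        assert up == [] and down == []


class TestQc:
    def test_duplicated_samples_identical_coordinates(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, (100, 3)), columns=list("abc"))
        counts["d"] = counts["c"]
        sf = pd.Series(1.0, index=counts.columns)
        coords, corr = de.qc_transform_and_pca(counts, sf)
        assert np.allclose(coords.loc["c"], coords.loc["d"])
        assert corr.loc["c", "d"] == pytest.approx(1.0)

    def test_batch_offset_removed(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(200, (200, 6)).astype(float)
        counts = pd.DataFrame(base, columns=[f"s{i}" for i in range(6)])
        counts.iloc[:, 3:] *= 4.0  # constant multiplicative batch offset
        sf = pd.Series(1.0, index=counts.columns)
        batch = pd.Series(["b1"] * 3 + ["b2"] * 3, index=counts.columns)
        raw, _ = de.qc_transform_and_pca(counts, sf)
        fixed, _ = de.qc_transform_and_pca(counts, sf, batch=batch)
        def sep(c):
            return abs(c["PC1"].iloc[:3].mean() - c["PC1"].iloc[3:].mean())
        assert sep(fixed) < 0.05 * sep(raw)

    def test_fewer_samples_than_pcs(self):
        counts = pd.DataFrame([[1, 2], [3, 4], [5, 9]], columns=["a", "b"])
        coords, _ = de.qc_transform_and_pca(counts, pd.Series(1.0, index=["a", "b"]), n_pcs=3)
        assert coords.shape[1] <= 2


def test_design_spec_validation():
    with pytest.raises(ValueError):
        de.DesignSpec(("batch",), ("condition", "a", "b"))
    with pytest.raises(ValueError):
        de.DesignSpec(("condition", "assay:condition"), ("condition", "a", "b"))
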