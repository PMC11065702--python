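"""Normalization, precision weights, linear models and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mutstim as ms
from mutstim import diffexpr


def brute_force_bh(p):
    """BH step-up straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for pos, idx in enumerate(order):
        rank = pos + 1
        out[idx] = min(
            min(p[order[j]] * m / (j + 1) for j in range(pos, m)), 1.0
        )
    return out


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 5, 100], "b": [10, 20, 30, 5, 100]})
        factors = ms.tmm_factors(counts)
        assert np.allclose(factors, 1.0)

    def test_pure_depth_scaling_gives_unit_factors(self):
        counts = pd.DataFrame(
            {"a": [10, 20, 30, 5, 100], "b": [20, 40, 60, 10, 200], "c": [10, 20, 30, 5, 100]}
        )
        factors = ms.tmm_factors(counts)
        assert np.allclose(factors, 1.0, atol=1e-12)

    def test_upshifted_gene_matches_hand_computation(self):
        """One strongly up-shifted gene in sample b: its M value is trimmed
        or pulls the factor below 1; the result must equal the arithmetic of
        M/A computation, double trim, and precision-weighted mean."""
        counts = pd.DataFrame(
            {"a": [100, 200, 300, 400, 50], "b": [100, 200, 300, 400, 5000]}
        )
        factors = ms.tmm_factors(counts)

        # independent hand computation (sample a is the reference: its
        # upper-quartile CPM is closer to the mean upper quartile)
        Na, Nb = 1050, 6000
        pa = np.array([100, 200, 300, 400, 50]) / Na
        pb = np.array([100, 200, 300, 400, 5000]) / Nb
        M = np.log2(pb / pa)
        A = 0.5 * np.log2(pb * pa)
        n = 5
        keepM = np.argsort(np.argsort(M))  # ordinal ranks 0..4
        keepA = np.argsort(np.argsort(A))
        lo, hi = int(np.floor(n * 0.3)), n - int(np.floor(n * 0.3))
        loA, hiA = int(np.floor(n * 0.05)), n - int(np.floor(n * 0.05))
        keep = (keepM >= lo) & (keepM < hi) & (keepA >= loA) & (keepA < hiA)
        cb = np.array([100, 200, 300, 400, 5000])
        ca = np.array([100, 200, 300, 400, 50])
        v = (Nb - cb) / (Nb * cb) + (Na - ca) / (Na * ca)
        f_b = 2 ** (np.sum(M[keep] / v[keep]) / np.sum(1 / v[keep]))
        expected = np.array([1.0, f_b])
        expected = expected / np.exp(np.mean(np.log(expected)))
        assert factors["b"] < 1.0
        assert np.allclose(factors.to_numpy(), expected)

    def test_all_zero_library_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            ms.tmm_factors(counts)

    def test_factors_have_unit_geometric_mean(self, small_dataset):
        *_, counts = small_dataset
        factors = ms.tmm_factors(counts)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0)


class TestLog2CPM:
    def test_matches_stated_formula(self):
        # one sample whose library size is exactly 1e6
        counts = pd.DataFrame({"s": [1023, 0, 10**6 - 1023]})
        norm = ms.log2_cpm(counts)
        # direct evaluation of log2((c + 0.5) / (lib + 1) * 1e6)
        assert norm.values.iloc[0, 0] == pytest.approx(
            np.log2(1023.5 / (1e6 + 1) * 1e6)
        )
        assert norm.values.iloc[1, 0] == pytest.approx(np.log2(0.5 / (1e6 + 1) * 1e6))
        assert norm.values.iloc[0, 0] == pytest.approx(9.9993, abs=1e-4)
        assert norm.values.iloc[1, 0] == pytest.approx(-1.0, abs=1e-4)

    def test_depth_scale_invariance_up_to_offsets(self):
        counts = pd.DataFrame({"a": [100, 900], "b": [200, 1800]})
        norm = ms.log2_cpm(counts)
        assert np.allclose(norm.values["a"], norm.values["b"], atol=0.01)


class TestLowExpressionFilter:
    def test_mean_below_zero_excluded(self):
        values = pd.DataFrame({"s1": [-1.0, 0.0], "s2": [0.5, 0.0]}, index=["g1", "g2"])
        mask = ms.filter_low_expression(values)
        assert not mask["g1"]  # mean -0.25
        assert mask["g2"]  # boundary: exactly zero is kept

    def test_empty_matrix_gives_empty_mask(self):
        assert len(ms.filter_low_expression(pd.DataFrame())) == 0


class TestMeanVarianceWeights:
    def _norm(self, values, lib=1e6):
        lib_s = pd.Series(lib, index=values.columns)
        fac = pd.Series(1.0, index=values.columns)
        return diffexpr.NormalizedMatrix(values, lib_s, fac)

    def test_homoscedastic_input_gives_flat_weights(self):
        rng = np.random.default_rng(0)
        n = 2000
        base = rng.uniform(2, 10, size=n)
        values = pd.DataFrame(
            base[:, None] + rng.normal(scale=0.5, size=(n, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        design = pd.DataFrame({"intercept": 1.0}, index=values.columns)
        w = ms.mean_variance_weights(self._norm(values), design)
        assert w.to_numpy().max() / w.to_numpy().min() < 1.5

    def test_decreasing_variance_gives_weights_increasing_with_expression(self):
        rng = np.random.default_rng(1)
        n = 2000
        base = rng.uniform(2, 10, size=n)
        sd = 1.5 / np.sqrt(2.0**base * 1e-2)  # variance ~ 1/mean
        values = pd.DataFrame(
            base[:, None] + rng.normal(size=(n, 6)) * sd[:, None],
            columns=[f"s{i}" for i in range(6)],
        )
        design = pd.DataFrame({"intercept": 1.0}, index=values.columns)
        w = ms.mean_variance_weights(self._norm(values), design)
        mean_w = w.mean(axis=1)
        low = mean_w[base < 4].mean()
        high = mean_w[base > 8].mean()
        assert high > low

    def test_single_gene_returns_unit_weights_with_warning(self, caplog):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        design = pd.DataFrame({"intercept": 1.0}, index=values.columns)
        with caplog.at_level("WARNING"):
            w = ms.mean_variance_weights(self._norm(values), design)
        assert (w.to_numpy() == 1.0).all()

    def test_rank_deficient_design_rejected(self):
        values = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 4)))
        design = pd.DataFrame({"a": [1.0] * 4, "b": [2.0] * 4}, index=values.columns)
        with pytest.raises(ValueError, match="rank"):
            ms.mean_variance_weights(self._norm(values), design)


class TestLinearModels:
    def two_group_spec(self, a, b, weights=None):
        values = pd.DataFrame([a + b], index=["g"], columns=["s1", "s2", "s3", "s4"])
        design = pd.DataFrame(
            {"intercept": [1.0] * 4, "grp": [0.0, 0.0, 1.0, 1.0]}, index=values.columns
        )
        return diffexpr.ModelSpec(values, design, weights)

    def test_two_group_contrast_matches_pooled_t_test(self):
        """A={1,3}, B={5,7}: coefficient 4, SE sqrt(2), t ~ 2.828, df 2."""
        fit = ms.fit_linear_models(self.two_group_spec([1.0, 3.0], [5.0, 7.0]))
        row = fit[fit.coefficient == "grp"].iloc[0]
        assert row.log2FC == pytest.approx(4.0)
        assert row.SE == pytest.approx(np.sqrt(2.0))
        assert row.log2FC / row.SE == pytest.approx(2.8284, abs=1e-4)
        assert row.df == 2
        assert row.p == pytest.approx(0.1056, abs=1e-3)

    def test_identical_groups_give_zero_effect_p_one(self):
        fit = ms.fit_linear_models(self.two_group_spec([2.0, 4.0], [2.0, 4.0]))
        row = fit[fit.coefficient == "grp"].iloc[0]
        assert row.log2FC == pytest.approx(0.0, abs=1e-12)
        assert row.p == pytest.approx(1.0, abs=1e-9)

    def test_random_intercept_matches_ols_when_batch_variance_zero(self):
        """With no real batch signal the profiled variance ratio goes to the
        boundary and the coefficients agree with the fixed-mode fit."""
        rng = np.random.default_rng(3)
        n = 12
        design = pd.DataFrame(
            {"intercept": 1.0, "grp": [0.0] * 6 + [1.0] * 6},
            index=[f"s{i}" for i in range(n)],
        )
        values = pd.DataFrame(
            rng.normal(size=(20, n)) + design["grp"].to_numpy() * 1.5,
            columns=design.index,
        )
        batch = pd.Series((["b1", "b2"] * 6)[:n], index=design.index)
        fit_rand = ms.fit_linear_models(
            diffexpr.ModelSpec(values, design, None, batch, "random_intercept")
        )
        fit_fixed = ms.fit_linear_models(diffexpr.ModelSpec(values, design))
        merged = fit_rand.merge(fit_fixed, on=["gene", "coefficient"], suffixes=("_r", "_f"))
        sub = merged[merged.coefficient == "grp"]
        assert np.allclose(sub.log2FC_r, sub.log2FC_f, atol=1e-6)

    def test_random_intercept_recovers_effect_under_strong_batch(self):
        """Strong per-gene batch offsets inflate the naive no-batch SE; the
        random-intercept fit absorbs them and still estimates the planted
        group effect."""
        cfg = ms.SimulationConfig(
            n_genes=300, conditions=["unstim"], n_replicates=6, n_batches=3,
            batch_sd=1.0, batch_per_gene=True, archetype_fractions={}, seed=21,
        )
        design, truth, _ = ms.simulate_dataset(cfg)
        rng = np.random.default_rng(cfg.seed)
        truth.loc[truth.index[:50], "beta_mut"] = 2.0
        counts = ms.simulate_counts(design, truth, cfg, rng)
        norm = ms.log2_cpm(counts, ms.tmm_factors(counts))
        keep = ms.filter_low_expression(norm)
        norm = diffexpr.NormalizedMatrix(norm.values.loc[keep], norm.lib_size, norm.factors)
        X = ms.make_design(design)
        fit = ms.fit_linear_models(
            diffexpr.ModelSpec(norm.values, X, None, design["experiment_id"], "random_intercept")
        )
        est = fit[fit.coefficient == "mut_MUT"].set_index("gene")
        planted = truth.index[:50].intersection(est.index)
        nulls = truth.index[50:].intersection(est.index)
        # measure against the null-gene baseline: with 1/6 of genes shifted
        # 4-fold the CPM composition offset moves all genes equally
        contrast = est.loc[planted, "log2FC"].mean() - est.loc[nulls, "log2FC"].mean()
        assert contrast == pytest.approx(2.0, abs=0.25)
        # batch noise must be absorbed: planted effects clearly significant
        assert (est.loc[planted, "padj"] < 0.05).mean() > 0.9

    def test_aliased_design_error_names_columns(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"])
        design = pd.DataFrame(
            {"intercept": 1.0, "x": [0, 0, 1, 1], "y": [0, 0, 2, 2]},
            index=values.columns, dtype=float,
        )
        with pytest.raises(ValueError, match="aliased.*y"):
            ms.fit_linear_models(diffexpr.ModelSpec(values, design))

    def test_confounded_batch_falls_back_to_fixed(self, caplog):
        values = pd.DataFrame(
            np.random.default_rng(0).normal(size=(5, 6)), columns=[f"s{i}" for i in range(6)]
        )
        design = pd.DataFrame(
            {"intercept": 1.0, "grp": [0, 0, 0, 1, 1, 1]}, index=values.columns, dtype=float
        )
        batch = pd.Series(["a", "a", "a", "b", "b", "b"], index=values.columns)
        with caplog.at_level("WARNING"):
            fit = ms.fit_linear_models(
                diffexpr.ModelSpec(values, design, None, batch, "random_intercept")
            )
        assert any("confounded" in rec.message for rec in caplog.records)
        assert set(fit.coefficient) == {"intercept", "grp"}


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.07], [0.07]),
            ([0.005, 0.04, 0.5], [0.015, 0.06, 0.5]),
        ],
    )
    def test_hand_computed_examples(self, p, expected):
        assert np.allclose(ms.bh_adjust(p), expected)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=0, max_size=6)
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_brute_force_definition(self, p):
        assert np.allclose(ms.bh_adjust(p), brute_force_bh(p)) if p else True

    def test_monotone_in_each_input(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=6)
        base = ms.bh_adjust(p)
        for i in range(6):
            bumped = p.copy()
            bumped[i] = min(1.0, bumped[i] + 0.1)
            assert (ms.bh_adjust(bumped) >= base - 1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ms.bh_adjust([0.5, 1.5])

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        assert np.allclose(ms.bh_adjust(p), multipletests(p, method="fdr_bh")[1])
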