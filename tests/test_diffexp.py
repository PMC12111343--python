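"""Moderated t-test, variance-prior fitting, BH adjustment, DE calling, qPCR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirpair.core_data import Comparison, CtTable, ExpressionMatrix, SampleDesign
from mirpair.diffexp import (
    VariancePrior,
    benjamini_hochberg,
    call_differential,
    fit_variance_prior,
    moderated_t_test,
    qpcr_ddct,
    volcano_table,
)

CMP = Comparison("A_vs_B", "A", "B")


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"f{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
        "log2",
    )


class TestVariancePrior:
    def test_equal_variances_give_infinite_d0(self):
        prior = fit_variance_prior(np.full(100, 0.04), d_g=4)
        assert np.isinf(prior.d0)
        assert prior.s0_sq > 0

    def test_two_features_with_spread_give_finite_d0(self):
        prior = fit_variance_prior(np.array([0.001, 10.0]), d_g=4)
        assert np.isfinite(prior.d0) and prior.d0 > 0

    def test_parameter_recovery_on_generator_model(self):
        """Moment matching recovers (d0, s0^2) from variances drawn from the
        generator's own scaled inverse-chi-square hierarchy."""
        rng = np.random.default_rng(42)
        sigma2 = 4 * 0.0625 / rng.chisquare(4, 10_000)
        s_sq = sigma2 * rng.chisquare(4, 10_000) / 4
        prior = fit_variance_prior(s_sq, d_g=4)
        assert 3.0 <= prior.d0 <= 5.5
        assert abs(prior.s0_sq / 0.0625 - 1) < 0.15

    def test_zero_variances_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            prior = fit_variance_prior(np.array([0.0, 0.1, 0.2, 0.15]), d_g=4)
        assert prior.s0_sq > 0

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            fit_variance_prior(np.array([0.1]), d_g=4)

    def test_invalid_prior_params_rejected(self):
        with pytest.raises(ValueError):
            VariancePrior(-1, 0.1)
        with pytest.raises(ValueError):
            VariancePrior(4, 0.0)


class TestModeratedT:
    def test_d0_zero_equals_ordinary_pooled_t(self, rng, two_group_design):
        x = rng.normal(7, 1, size=(50, 6))
        res = moderated_t_test(_matrix(x), two_group_design, CMP, VariancePrior(0.0, 1.0))
        t_ref, p_ref = stats.ttest_ind(x[:, :3], x[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_mod"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p_raw"], p_ref, atol=1e-10)

    def test_identical_group_means_give_t_zero(self, two_group_design):
        x = np.array([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]])  # equal means, nonzero var
        res = moderated_t_test(_matrix(x), two_group_design, CMP, VariancePrior(4.0, 0.05))
        assert res["t_mod"].iloc[0] == 0
        assert res["p_raw"].iloc[0] == 1

    def test_fixed_prior_matches_direct_formula(self, rng, two_group_design):
        """t_mod recomputed from first principles (posterior-variance formula)."""
        x = rng.normal(0, 1, size=(200, 6))
        d0, s0 = 4.0, 0.05
        res = moderated_t_test(_matrix(x), two_group_design, CMP, VariancePrior(d0, s0))
        xa, xb = x[:, :3], x[:, 3:]
        sg = (2 * xa.var(axis=1, ddof=1) + 2 * xb.var(axis=1, ddof=1)) / 4
        stilde = (d0 * s0 + 4 * sg) / (d0 + 4)
        t_ref = (xa.mean(axis=1) - xb.mean(axis=1)) / np.sqrt(stilde * (2 / 3))
        np.testing.assert_allclose(res["t_mod"], t_ref, atol=1e-12)
        p_ref = 2 * stats.t.sf(np.abs(t_ref), d0 + 4)
        np.testing.assert_allclose(res["p_raw"], p_ref, atol=1e-12)

    def test_moderation_shrinks_between_sample_and_prior(self, rng, two_group_design):
        x = rng.normal(0, 1, size=(100, 6))
        d0, s0 = 4.0, 0.05
        xa, xb = x[:, :3], x[:, 3:]
        sg = (2 * xa.var(axis=1, ddof=1) + 2 * xb.var(axis=1, ddof=1)) / 4
        stilde = (d0 * s0 + 4 * sg) / (d0 + 4)
        lo = np.minimum(sg, s0)
        hi = np.maximum(sg, s0)
        differ = np.abs(sg - s0) > 1e-12
        assert np.all(stilde[differ] > lo[differ]) and np.all(stilde[differ] < hi[differ])

    def test_infinite_d0_uses_prior_variance_only(self, rng, two_group_design):
        x = rng.normal(0, 1, size=(20, 6))
        res = moderated_t_test(_matrix(x), two_group_design, CMP, VariancePrior(np.inf, 0.05))
        lfc = x[:, :3].mean(axis=1) - x[:, 3:].mean(axis=1)
        np.testing.assert_allclose(res["t_mod"], lfc / np.sqrt(0.05 * 2 / 3), atol=1e-12)

    def test_signed_fc_definition(self, two_group_design):
        x = np.array([[3.0, 3.1, 2.9, 1.0, 1.1, 0.9], [1.0, 1.1, 0.9, 3.0, 3.1, 2.9]])
        res = moderated_t_test(_matrix(x), two_group_design, CMP, VariancePrior(4.0, 0.05))
        assert res["signed_fc"].iloc[0] == pytest.approx(2 ** res["log2fc"].iloc[0])
        assert res["signed_fc"].iloc[1] == pytest.approx(-(2 ** -res["log2fc"].iloc[1]))
        assert (res["signed_fc"].abs() >= 1).all()

    def test_small_group_rejected(self):
        design = SampleDesign({"s0": "A", "s1": "B", "s2": "B"}, ["A", "B"])
        m = _matrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match=">= 2"):
            moderated_t_test(m, design, CMP, VariancePrior(0, 1))

    def test_missing_group_rejected(self, small_matrix):
        design = SampleDesign({f"s{j}": "A" for j in range(6)}, ["A"])
        with pytest.raises(ValueError, match="missing"):
            moderated_t_test(small_matrix, design, CMP, VariancePrior(0, 1))


def _bh_brute(p):
    """Step-up definition evaluated literally: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p[i] / rank)
        q[i] = prev
    return q


class TestBenjaminiHochberg:
    def test_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_exhaustive_grid_matches_brute_force(self):
        """Every p-vector of length <= 6 over a coarse grid matches the
        literal step-up definition."""
        from itertools import product

        grid = [0.0, 0.01, 0.04, 0.05, 0.2, 0.5, 1.0]
        for n in range(1, 4):
            for p in product(grid, repeat=n):
                np.testing.assert_allclose(
                    benjamini_hochberg(np.array(p)), _bh_brute(p), atol=1e-12
                )
        rng = np.random.default_rng(0)
        for _ in range(300):
            p = rng.choice(grid, size=rng.integers(4, 7))
            np.testing.assert_allclose(benjamini_hochberg(p), _bh_brute(p), atol=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=6))
    def test_matches_brute_force_property(self, p):
        np.testing.assert_allclose(benjamini_hochberg(p), _bh_brute(p), atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 50)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestCallDifferential:
    def _row(self, log2fc, p_raw, p_adj):
        return pd.DataFrame(
            {"log2fc": [log2fc], "p_raw": [p_raw], "p_adj": [p_adj], "status": ["ns"]},
            index=["f"],
        )

    def test_strong_up_called(self):
        out, (nd, nu) = call_differential(self._row(2.0, 0.001, 0.01))
        assert out["status"].iloc[0] == "up" and (nd, nu) == (0, 1)

    def test_fold_gate_blocks_significant_feature(self):
        out, counts = call_differential(self._row(0.9, 1e-6, 1e-5))
        assert out["status"].iloc[0] == "ns" and counts == (0, 0)

    def test_down_mirror(self):
        out, (nd, nu) = call_differential(self._row(-1.4, 0.01, 0.1))
        assert out["status"].iloc[0] == "down" and (nd, nu) == (1, 0)

    def test_counts_invariant_to_order(self, rng, two_group_design):
        x = rng.normal(0, 1, size=(60, 6))
        x[:10, :3] += 2
        res = moderated_t_test(_matrix(x), two_group_design, CMP, "estimate")
        _, counts = call_differential(res)
        shuffled = res.sample(frac=1, random_state=1)
        shuffled.attrs = dict(res.attrs)
        _, counts_shuffled = call_differential(shuffled)
        assert counts == counts_shuffled

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_differential(self._row(1, 0.1, 0.1), fc_threshold=0)

    def test_null_simulation_false_positive_rate(self, two_group_design):
        """Under the null the compound gate calls far fewer than 5% of features."""
        total_calls = 0
        n_features = 1000
        for seed in range(5):
            rng = np.random.default_rng(seed)
            sigma = np.sqrt(4 * 0.0625 / rng.chisquare(4, n_features))
            x = rng.normal(0, 1, size=(n_features, 6)) * sigma[:, None]
            res = moderated_t_test(_matrix(x), two_group_design, CMP, "estimate")
            _, (nd, nu) = call_differential(res)
            total_calls += nd + nu
        assert total_calls / 5 <= 0.05 * n_features


class TestQpcr:
    def _ct(self, cmp_dct_shift=0.0):
        design = SampleDesign(
            {"r1": "R", "r2": "R", "r3": "R", "c1": "C", "c2": "C", "c3": "C"},
            ["R", "C"],
        )
        ref = 18.0
        base = np.array([22.0, 22.5, 21.5])
        ct = np.zeros((6, 2))
        ct[:3, 0] = base
        ct[3:, 0] = base + cmp_dct_shift
        ct[:, 1] = ref
        return CtTable(["r1", "r2", "r3", "c1", "c2", "c3"], ["gene1", "RNU1A1"], ct, design)

    def test_identical_groups_fold_one(self):
        res = qpcr_ddct(self._ct(0.0), "RNU1A1", "R", "C")
        assert res.loc["gene1", "fold_change"] == pytest.approx(1.0)
        assert res.loc["gene1", "p"] == pytest.approx(1.0)

    def test_ddct_minus_one_doubles(self):
        res = qpcr_ddct(self._ct(-1.0), "RNU1A1", "R", "C")
        assert res.loc["gene1", "fold_change"] == pytest.approx(2.0)

    def test_p_matches_textbook_pooled_t(self, rng):
        design = SampleDesign(
            {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)},
            ["A", "B"],
        )
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        ct = np.column_stack([rng.uniform(20, 26, 8), rng.uniform(17, 19, 8)])
        table = CtTable(samples, ["g", "ref"], ct, design)
        res = qpcr_ddct(table, "ref", "A", "B")
        dct = ct[:, 0] - ct[:, 1]
        da, db = dct[4:], dct[:4]
        sp = np.sqrt(((3) * da.var(ddof=1) + 3 * db.var(ddof=1)) / 6)
        t = (da.mean() - db.mean()) / (sp * np.sqrt(0.5))
        p_ref = 2 * stats.t.sf(abs(t), 6)
        assert res.loc["g", "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            qpcr_ddct(self._ct(), "nope", "R", "C")


class TestVolcano:
    def test_projection_preserves_rows(self, rng, two_group_design):
        x = rng.normal(0, 1, size=(7, 6))
        res = moderated_t_test(_matrix(x), two_group_design, CMP, "estimate")
        res, _ = call_differential(res)
        v = volcano_table(res)
        assert len(v) == 7
        np.testing.assert_allclose(v["neg_log10_p"], -np.log10(res["p_raw"]))
        assert (v["status"] == res["status"]).all()

    def test_empty_table(self):
        empty = pd.DataFrame(columns=["log2fc", "p_raw", "status"])
        assert len(volcano_table(empty)) == 0
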