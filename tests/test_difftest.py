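"""Regularized t-test: shrinkage behaviour, classical reduction, symmetry,
classification and the replicate-concordance density grid."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from acetylscan import (
    GroupComparison,
    RegTTestParams,
    background_variance,
    classify_regions,
    differential_test,
    regularized_t,
    replicate_density_grid,
)


def frame(arr, prefix="s"):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    return pd.DataFrame(arr, columns=[f"{prefix}{i}" for i in range(arr.shape[1])])


class TestBackgroundVariance:
    def test_constant_variance_is_identity(self):
        rng = np.random.default_rng(0)
        means = rng.normal(size=(50, 1))
        scores = frame(means + np.array([[-1.0, 1.0]]))  # every row var = 2
        sigma0 = background_variance(scores, 5)
        assert np.allclose(sigma0, 2.0)

    def test_window_spanning_all_regions_gives_grand_mean(self):
        rng = np.random.default_rng(1)
        scores = frame(rng.normal(size=(21, 3)))
        sigma0 = background_variance(scores, 21)
        assert np.allclose(sigma0, scores.var(axis=1, ddof=1).mean())

    def test_matches_bruteforce_rank_and_average(self):
        rng = np.random.default_rng(2)
        scores = frame(rng.gamma(2.0, 1.0, size=(500, 4)))
        w = 101
        got = background_variance(scores, w).to_numpy()
        means = scores.mean(axis=1).to_numpy()
        variances = scores.var(axis=1, ddof=1).to_numpy()
        order = np.argsort(means, kind="stable")
        half = (w - 1) // 2
        expected = np.empty(500)
        for rank, idx in enumerate(order):
            lo = min(max(0, rank - half), 500 - w)
            expected[idx] = variances[order[lo : lo + w]].mean()
        assert np.allclose(got, expected)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            background_variance(frame(np.zeros((10, 1))), 3)


class TestRegularizedT:
    def params(self, nu0=0.0, **kw):
        return RegTTestParams(prior_df=nu0, **kw)

    def test_reduces_to_classical_t_at_zero_prior(self):
        rng = np.random.default_rng(3)
        a = frame(rng.normal(size=(200, 4)), "a")
        b = frame(rng.normal(0.3, 1.2, size=(200, 4)), "b")
        res = regularized_t(a, b, np.zeros(200), np.zeros(200), self.params(0.0))
        t_ref, p_ref = stats.ttest_ind(b.to_numpy(), a.to_numpy(), axis=1)
        assert np.allclose(res["t"], t_ref, atol=1e-10)
        assert np.allclose(res["p"], p_ref, atol=1e-10)

    def test_pooled_t_closed_form_example(self):
        a, b = frame([[1.0, 2.0, 3.0]], "a"), frame([[4.0, 5.0, 6.0]], "b")
        res = regularized_t(a, b, np.zeros(1), np.zeros(1), self.params(0.0))
        # pooled two-sample t: diff 3, sp^2 = 1, t = 3 / sqrt(2/3)
        assert res["t"].iloc[0] == pytest.approx(3.674, abs=1e-3)

    def test_infinite_background_drives_p_to_one(self):
        a, b = frame([[1.0, 2.0, 3.0]], "a"), frame([[4.0, 5.0, 6.0]], "b")
        res = regularized_t(
            a, b, np.array([1e12]), np.array([1e12]), self.params(5.0)
        )
        assert res["p"].iloc[0] > 0.999

    def test_zero_variance_zero_difference(self):
        a = frame([[2.0, 2.0]], "a")
        b = frame([[2.0, 2.0]], "b")
        res = regularized_t(a, b, np.zeros(1), np.zeros(1), self.params(0.0))
        assert res["t"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0

    def test_group_swap_antisymmetry(self):
        rng = np.random.default_rng(4)
        a = frame(rng.normal(size=(100, 3)), "a")
        b = frame(rng.normal(0.5, 1, size=(100, 3)), "b")
        s0a, s0b = np.full(100, 0.7), np.full(100, 1.3)
        p = self.params(4.0)
        fwd = regularized_t(a, b, s0a, s0b, p)
        rev = regularized_t(b, a, s0b, s0a, p)
        assert np.allclose(fwd["t"], -rev["t"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        a = frame(rng.gamma(3, 1, size=(100, 3)), "a")
        b = frame(rng.gamma(3, 1, size=(100, 3)), "b")
        s0a = a.var(axis=1, ddof=1).to_numpy()
        s0b = b.var(axis=1, ddof=1).to_numpy()
        p = self.params(6.0)
        base = regularized_t(a, b, s0a, s0b, p)
        c = 37.5
        scaled = regularized_t(a * c, b * c, s0a * c**2, s0b * c**2, p)
        assert np.allclose(base["t"], scaled["t"])
        assert np.allclose(base["p"], scaled["p"])

    @given(st.floats(0.0, 50.0), st.floats(1.0, 10.0))
    def test_shrinkage_toward_large_background_reduces_t(self, nu0, sigma0):
        """|t| is non-increasing in nu0 when sigma0^2 >= s^2 in both groups."""
        a = frame([[1.0, 2.0, 3.0]], "a")  # s^2 = 1
        b = frame([[4.0, 5.0, 6.0]], "b")
        s0 = np.array([float(sigma0)])
        t_small = regularized_t(a, b, s0, s0, self.params(nu0))["t"].iloc[0]
        t_large = regularized_t(a, b, s0, s0, self.params(nu0 + 5.0))["t"].iloc[0]
        assert abs(t_large) <= abs(t_small) + 1e-12

    def test_cybert_variance_denominator_variant(self):
        a, b = frame([[1.0, 2.0, 3.0]], "a"), frame([[4.0, 5.0, 6.0]], "b")
        s0 = np.array([4.0])
        loose = regularized_t(a, b, s0, s0, self.params(3.0))
        tight = regularized_t(
            a, b, s0, s0, RegTTestParams(prior_df=3.0, variance_denominator="n-2")
        )
        # smaller denominator -> larger shrunken variance -> smaller |t|
        assert abs(tight["t"].iloc[0]) < abs(loose["t"].iloc[0])


class TestClassifyRegions:
    def make(self, p, mean_a, mean_b):
        return pd.DataFrame(
            {"mean_A": [mean_a], "mean_B": [mean_b], "t": [0.0], "p": [p]}
        )

    @pytest.mark.parametrize(
        "p,ma,mb,expected",
        [
            (0.049, 5.0, 2.0, "deprived"),
            (0.049, 2.0, 5.0, "enriched"),
            (0.051, 2.0, 5.0, "stable"),
            (0.05, 2.0, 5.0, "enriched"),  # threshold inclusive
        ],
    )
    def test_threshold_edges(self, p, ma, mb, expected):
        out = classify_regions(self.make(p, ma, mb), 0.05)
        assert out["class"].iloc[0] == expected

    def test_recovery_on_planted_score_matrix(self):
        """6 vs 6 design, 2,000 regions, 10% planted at fold 0.25:
        sensitivity >= 0.8, false-positive rate among nulls <= 0.07."""
        rng = np.random.default_rng(17)
        n, n_de = 2000, 200
        base = rng.gamma(20.0, 1.0, size=n)
        fold = np.ones(n)
        fold[:n_de] = 0.25
        a = base[:, None] * rng.normal(1.0, 0.15, size=(n, 6))
        b = (base * fold)[:, None] * rng.normal(1.0, 0.15, size=(n, 6))
        scores = pd.DataFrame(
            np.column_stack([a, b]),
            columns=[f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)],
        )
        comp = GroupComparison([f"A{i}" for i in range(6)], [f"B{i}" for i in range(6)])
        res = differential_test(scores, comp, RegTTestParams())
        cls = res["class"].to_numpy()
        sensitivity = (cls[:n_de] == "deprived").mean()
        fpr = (cls[n_de:] != "stable").mean()
        assert sensitivity >= 0.8
        assert fpr <= 0.07


class TestReplicateDensityGrid:
    def test_mass_normalized(self):
        rng = np.random.default_rng(6)
        x = rng.gamma(5, 1, 300)
        gx, gy, d = replicate_density_grid(x, x * rng.normal(1, 0.05, 300))
        dx = gx[1] - gx[0]
        assert d.sum() * dx * dx == pytest.approx(1.0, abs=1e-6)

    def test_single_point_mode_at_point(self):
        gx, gy, d = replicate_density_grid([4.0], [4.0], bandwidth=0.5)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        assert gx[i] == pytest.approx(np.log2(5.0), abs=0.1)
        assert gy[j] == pytest.approx(np.log2(5.0), abs=0.1)

    def test_correlated_replicates_mass_near_diagonal(self):
        rng = np.random.default_rng(7)
        x = rng.gamma(10, 1, 1000)
        y = x * rng.normal(1.0, 0.02, 1000)
        gx, gy, d = replicate_density_grid(x, y, grid_size=80)
        dx = gx[1] - gx[0]
        band = np.abs(gx[:, None] - gy[None, :]) <= 1.0
        assert (d * band).sum() * dx * dx >= 0.95

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            replicate_density_grid([], [])


def test_type_one_error_calibrated_on_pure_null():
    """Fraction of p <= 0.05 on null data is within 3 binomial SDs of 0.05."""
    rng = np.random.default_rng(23)
    n = 5000
    scores = pd.DataFrame(
        rng.normal(10.0, 1.0, size=(n, 12)),
        columns=[f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)],
    )
    comp = GroupComparison([f"A{i}" for i in range(6)], [f"B{i}" for i in range(6)])
    res = differential_test(scores, comp, RegTTestParams(prior_df=0.0))
    frac = (res["p"] <= 0.05).mean()
    assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n)
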