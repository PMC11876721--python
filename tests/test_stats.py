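"""GFP/GDI algebra, TANOVA permutation machinery, effect sizes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import topoperm as tp
from topoperm.stats import ErpStack

from conftest import make_stack

maps = hnp.arrays(
    float, st.integers(3, 16),
    elements=st.floats(-50, 50, allow_nan=False, width=32),
)


class TestGfpGdi:
    def test_gfp_closed_forms(self):
        assert tp.gfp(np.full(7, 3.2)) == pytest.approx(0.0, abs=1e-12)
        assert tp.gfp(np.array([1.0, -1.0])) == 1.0

    def test_gfp_matches_formula_on_random_map(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=64)
        brute = np.sqrt(np.mean((v - v.mean()) ** 2))
        assert tp.gfp(v) == pytest.approx(brute, abs=1e-12)

    def test_gdi_closed_forms(self):
        a, b = np.array([1.0, -1.0]), np.array([-1.0, 1.0])
        assert tp.gdi(a, a) == 0.0
        assert tp.gdi(a, b) == pytest.approx(2.0)

    def test_gdi_channel_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            tp.gdi(np.zeros(3), np.zeros(4))

    @settings(max_examples=50, deadline=None)
    @given(a=maps, b=maps, c=maps)
    def test_gdi_metric_properties(self, a, b, c):
        n = min(a.size, b.size, c.size)
        a, b, c = a[:n], b[:n], c[:n]
        assert tp.gdi(a, b) == tp.gdi(b, a)
        assert tp.gdi(a, c) <= tp.gdi(a, b) + tp.gdi(b, c) + 1e-9

    @settings(max_examples=50, deadline=None)
    @given(a=maps, b=maps)
    def test_gdi_equals_gfp_of_difference_for_average_reference(self, a, b):
        n = min(a.size, b.size)
        a, b = a[:n] - a[:n].mean(), b[:n] - b[:n].mean()
        assert tp.gdi(a, b) == pytest.approx(tp.gfp(a - b), abs=1e-9)


class TestNormalizeByGfp:
    def test_output_has_unit_gfp(self):
        rng = np.random.default_rng(1)
        series = rng.normal(size=(16, 20))
        out = tp.normalize_by_gfp(series)
        np.testing.assert_allclose(tp.gfp(out), 1.0, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        series = rng.normal(size=(16, 20))
        np.testing.assert_allclose(
            tp.normalize_by_gfp(series), tp.normalize_by_gfp(10.0 * series),
            atol=1e-12,
        )

    def test_gdi_of_normalized_maps_invariant_to_rescaling(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=16), rng.normal(size=16)
        d1 = tp.gdi(tp.normalize_by_gfp(a), tp.normalize_by_gfp(b))
        d2 = tp.gdi(tp.normalize_by_gfp(3.7 * a), tp.normalize_by_gfp(0.2 * b))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_flat_map_raises_with_timepoint(self):
        series = np.ones((4, 5))
        series[:, :3] = np.random.default_rng(4).normal(size=(4, 3))
        with pytest.raises(ValueError, match="timepoint index 3"):
            tp.normalize_by_gfp(series)


def two_condition_stack(diffs: np.ndarray) -> ErpStack:
    """Stack with cells (A, B) whose per-subject difference maps are given.

    diffs: (subjects, channels, time).
    """
    s, ch, t = diffs.shape
    data = np.stack([diffs / 2.0, -diffs / 2.0], axis=1)
    return ErpStack(
        data, tuple(f"S{i}" for i in range(s)), ("A", "B"),
        np.arange(t, dtype=float) * 4.0,
    )


class TestTanovaPointwise:
    def test_identical_condition_maps_give_zero_stat_and_p_one(self, ring32):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(8, 1, 32, 10)).repeat(4, axis=1)
        stack = ErpStack(base, tuple(f"S{i}" for i in range(8)), tp.CELL_LABELS,
                         np.arange(10.0))
        res = tp.tanova_pointwise(stack, "repetition_main", n_perm=200, seed=0)
        np.testing.assert_allclose(res.observed_stat, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.p_values, 1.0)

    def test_p_values_never_zero_and_reproducible(self, ring32):
        topo = tp.make_topography(ring32, ["ch05"], 0.3)
        eff = tp.EffectSpec("rep", "repetition_main", topo, (200, 300), 5.0)
        stack = make_stack(ring32, n_subjects=10, effects=(eff,), seed=6)
        a = tp.tanova_pointwise(stack, "repetition_main", n_perm=300, seed=7)
        b = tp.tanova_pointwise(stack, "repetition_main", n_perm=300, seed=7)
        assert a.p_values.min() >= 1.0 / 301.0
        np.testing.assert_array_equal(a.p_values, b.p_values)
        np.testing.assert_array_equal(a.perm_stats, b.perm_stats)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """On a 6-subject, 2-condition instance the permutation null is the
        2^6-point sign-flip distribution; the Monte-Carlo p must agree with
        the exhaustively enumerated p within twice its binomial SE."""
        rng = np.random.default_rng(8)
        diffs = rng.normal(0.6, 1.0, size=(6, 5, 3))
        stack = two_condition_stack(diffs)
        n_perm = 5000
        res = tp.tanova_pointwise(stack, "between_sets", n_perm=n_perm, seed=9)

        for t in range(diffs.shape[-1]):
            obs = np.sqrt(np.mean(diffs[..., t].mean(axis=0) ** 2))
            stats = [
                np.sqrt(np.mean((np.array(signs)[:, None] * diffs[..., t])
                                .mean(axis=0) ** 2))
                for signs in itertools.product([1, -1], repeat=6)
            ]
            p_exact = np.mean(np.asarray(stats) >= obs - 1e-12)
            se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
            assert abs(res.p_values[t] - p_exact) <= 2 * se + 2.0 / (n_perm + 1)

    def test_null_rejection_rate_near_alpha(self, ring32):
        """Global-null data: the pointwise rejection fraction across many
        timepoints and replicates stays near alpha."""
        rates = []
        for seed in range(5):
            stack = make_stack(ring32, n_subjects=20, effects=(), seed=100 + seed)
            res = tp.tanova_pointwise(stack, "repetition_main", n_perm=500,
                                      seed=seed)
            rates.append(np.mean(res.p_values < 0.05))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.03)

    def test_restricted_scheme_valid_for_main_effects(self, ring32):
        stack = make_stack(ring32, n_subjects=8, seed=11)
        res = tp.tanova_pointwise(stack, "repetition_main", n_perm=200, seed=1,
                                  scheme="restricted")
        assert np.all((res.p_values > 0) & (res.p_values <= 1))
        with pytest.raises(ValueError, match="restricted"):
            tp.tanova_pointwise(stack, "interaction", n_perm=100, seed=1,
                                scheme="restricted")

    def test_missing_cells_rejected(self):
        data = np.zeros((3, 2, 4, 5))
        stack = ErpStack(data, ("a", "b", "c"), ("Exp_Rep", "Exp_Alt"),
                         np.arange(5.0))
        with pytest.raises(ValueError, match="interaction"):
            tp.tanova_pointwise(stack, "interaction", n_perm=100, seed=0)


class TestTanovaWindow:
    def test_single_sample_window_reduces_to_pointwise(self, ring32):
        topo = tp.make_topography(ring32, ["ch08"], 0.3)
        eff = tp.EffectSpec("rep", "repetition_main", topo, (200, 300), 3.0)
        stack = make_stack(ring32, n_subjects=8, effects=(eff,), seed=12)
        t = stack.times_ms[100]
        point = tp.tanova_pointwise(stack, "repetition_main", n_perm=400, seed=3)
        window = tp.tanova_window(stack, "repetition_main", (t, t), n_perm=400,
                                  seed=3)
        assert window.p_values[0] == point.p_values[100]
        assert window.observed_stat[0] == pytest.approx(point.observed_stat[100])

    def test_identical_window_means_give_p_one(self):
        diffs = np.zeros((6, 4, 8))
        stack = two_condition_stack(diffs)
        res = tp.tanova_window(stack, "between_sets", (0.0, 28.0), n_perm=200,
                               seed=0)
        assert res.p_values[0] == 1.0


class TestDispersion:
    def test_two_sets_match_pairwise_p(self):
        """The k-set heterogeneity statistic is proportional to the GDI for
        k = 2, so the permutation p-values coincide seed-for-seed."""
        rng = np.random.default_rng(13)
        diffs = rng.normal(0.3, 1.0, size=(7, 6, 4))
        stack = two_condition_stack(diffs)
        a = tp.tanova_pointwise(stack, "between_sets", n_perm=500, seed=5)
        b = tp.tanova_dispersion(stack, n_perm=500, seed=5)
        np.testing.assert_allclose(b.observed_stat * 2.0, a.observed_stat,
                                   atol=1e-12)
        np.testing.assert_array_equal(a.p_values, b.p_values)


class TestEffectSizes:
    def test_eta2_matches_hand_computed_partition(self):
        """3 subjects x 2 channels, one timepoint: variance partition done
        by hand."""
        diffs = np.array(
            [[[2.0], [-2.0]],
             [[1.0], [-1.0]],
             [[3.0], [-3.0]]]
        )  # contrast maps per subject: (2,-2), (1,-1), (3,-3)
        stack = two_condition_stack(diffs)
        # grand mean contrast = (2, -2); SS_eff = 3 * (4+4) = 24
        # residuals: (0,0), (-1,1), (1,-1) -> SS_err = 4
        eta2 = tp.effect_size_eta2(stack, "between_sets", (0.0, 0.0))
        assert eta2 == pytest.approx(24.0 / 28.0)

    def test_eta2_limits(self, ring32):
        topo = tp.make_topography(ring32, ["ch02"], 0.3)
        eff = tp.EffectSpec("rep", "repetition_main", topo, (200, 300), 2.0)
        clean = make_stack(ring32, n_subjects=6, effects=(eff,), noise_sd=0.0,
                           subject_sd=0.0, seed=14)
        assert tp.effect_size_eta2(clean, "repetition_main", (240, 260)) == (
            pytest.approx(1.0)
        )
        null = make_stack(ring32, n_subjects=30, effects=(), seed=15)
        assert tp.effect_size_eta2(null, "repetition_main", (240, 260)) < 0.3

    @pytest.mark.parametrize(
        "eta2, d",
        [
            (0.25, 1.15), (0.21, 1.03), (0.15, 0.84), (0.08, 0.59),
            (0.09, 0.63), (0.13, 0.77), (0.29, 1.28), (0.11, 0.70),
            (0.18, 0.94), (0.19, 0.97), (0.12, 0.74), (0.0, 0.0),
        ],
    )
    def test_eta2_to_cohens_d_pairs(self, eta2, d):
        assert round(tp.eta2_to_cohens_d(eta2), 2) == d

    def test_eta2_to_cohens_d_domain(self):
        with pytest.raises(ValueError):
            tp.eta2_to_cohens_d(1.0)
        with pytest.raises(ValueError):
            tp.eta2_to_cohens_d(-0.1)

    def test_permutation_d_matches_direct_formula(self):
        times = np.arange(4, dtype=float)
        rng = np.random.default_rng(16)
        perm = rng.normal(2.0, 0.5, size=(400, 4))
        res = tp.TanovaResult(
            effect="x", times_ms=times, observed_stat=np.full(4, 3.0),
            p_values=np.full(4, 0.01), perm_stats=perm, n_perm=400, seed=0,
        )
        z, d = tp.cohens_d_permutation(res, (0.0, 3.0), 0.5, 0.5, 4)
        perm_means = perm.mean(axis=1)
        z_expected = (3.0 - perm_means.mean()) / perm_means.std(ddof=1)
        assert z == pytest.approx(z_expected, abs=1e-12)
        # p1 = p2 = 0.5, N = 4 -> denominator exactly 1
        assert d == pytest.approx(z_expected, abs=1e-12)

    def test_observed_equal_to_permutation_mean_gives_zero(self):
        perm = np.tile(np.linspace(1.0, 3.0, 101)[:, None], (1, 2))
        res = tp.TanovaResult(
            effect="x", times_ms=np.arange(2, dtype=float),
            observed_stat=np.full(2, 2.0), p_values=np.full(2, 0.5),
            perm_stats=perm, n_perm=101, seed=0,
        )
        z, d = tp.cohens_d_permutation(res, (0.0, 1.0), 0.5, 0.5, 16)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_zero_permutation_variance_raises(self):
        res = tp.TanovaResult(
            effect="x", times_ms=np.arange(2, dtype=float),
            observed_stat=np.full(2, 2.0), p_values=np.full(2, 0.5),
            perm_stats=np.ones((50, 2)), n_perm=50, seed=0,
        )
        with pytest.raises(ValueError, match="variance"):
            tp.cohens_d_permutation(res, (0.0, 1.0), 0.5, 0.5, 16)
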