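"""Skewness series, asymmetry threshold, HP classification, and the
nonparametric statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from anchortrack import subpopulations as sp
from anchortrack.errors import (
    DegenerateDistributionError,
    InsufficientSampleError,
    InvalidInputError,
)
from anchortrack.kinetics import CellTrace
from _util import final_deltas


def trace_from_deltas(deltas, track_id=0):
    d = np.asarray(deltas, dtype=float)
    t = np.arange(d.size, dtype=float) * 2
    return CellTrace(
        track_id=track_id, anchor_id=track_id, time_h=t, i_cell=d,
        i_back=np.zeros_like(d), intensity=d, delta=d,
    )


class TestSkewness:
    def test_symmetric_sample_is_unskewed(self):
        assert sp.sample_skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0)

    def test_bias_adjusted_value(self):
        # g1 = n^2/((n-1)(n-2)) * m3 / s^3 for {0,0,0,10}
        assert sp.sample_skewness([0.0, 0.0, 0.0, 10.0]) == pytest.approx(2.0)

    def test_too_small_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            sp.sample_skewness([1.0, 2.0])

    def test_series_grows_with_subpopulation_separation(self):
        # two-component mixture: skewness increases as the components separate
        rng = np.random.default_rng(11)
        slopes = np.where(rng.random(400) < 0.15, 32.0, 8.0) + rng.normal(0, 1, 400)
        t = np.arange(0, 63, 2, dtype=float)
        traces = [trace_from_deltas(s * t, i) for i, s in enumerate(slopes)]
        series = sp.skewness_series(traces)
        assert series[-1] > 0.5  # strong right tail at 62 h


class TestThreshold:
    def test_normal_sample_threshold_near_mu_plus_3_sigma(self):
        rng = np.random.default_rng(5)
        x = rng.normal(50.0, 4.0, size=1000)
        t = sp.compute_threshold(x)
        assert t == pytest.approx(50.0 + 3 * 4.0, rel=0.10)
        assert (x > t).mean() <= 0.005

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            sp.compute_threshold(np.full(100, 7.0))

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            sp.compute_threshold(np.arange(10.0))

    def test_separated_mixture_recovered(self):
        # 90/10 mixture, HP mean 6 sigma above the bulk
        rng = np.random.default_rng(8)
        n = 1000
        is_hp = rng.random(n) < 0.10
        x = np.where(is_hp, 80.0, 50.0) + rng.normal(0, 5.0, n)
        t = sp.compute_threshold(x)
        called = x > t
        recall = (called & is_hp).sum() / is_hp.sum()
        precision = (called & is_hp).sum() / max(called.sum(), 1)
        assert recall >= 0.9 and precision >= 0.9

    @given(st.floats(-1e4, 1e4))
    def test_translation_equivariance(self, c):
        rng = np.random.default_rng(13)
        x = rng.normal(10.0, 2.0, size=200)
        t0 = sp.compute_threshold(x)
        t1 = sp.compute_threshold(x + c)
        assert t1 - t0 == pytest.approx(c, abs=1e-6 * max(1.0, abs(c)))


class TestClassifyHP:
    def test_no_cell_above_threshold(self):
        t = np.arange(0, 63, 2, dtype=float)
        traces = [trace_from_deltas(5.0 * t * (1 + 0.01 * i), i) for i in range(5)]
        cls = sp.classify_hp(traces, threshold=1e6)
        assert cls.hp_percentage == 0.0
        assert np.isnan(cls.hp_mean_delta).all()

    def test_mixture_identity(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 63, 2, dtype=float)
        traces = [
            trace_from_deltas(s * t, i)
            for i, s in enumerate(rng.uniform(2, 40, size=50))
        ]
        cls = sp.classify_hp(traces, threshold=float(np.median([tr.delta_final for tr in traces])))
        p = cls.n_hp / cls.n_cells
        whole = np.mean([tr.delta for tr in traces], axis=0)
        mixture = p * cls.hp_mean_delta + (1 - p) * cls.lp_mean_delta
        np.testing.assert_allclose(whole, mixture, rtol=1e-9)

    def test_recovers_preset_prevalence(self):
        finals, is_hp = final_deltas(seed=21, viability=1.0)
        t = sp.compute_threshold(finals)
        called = finals > t
        p = is_hp.mean()  # realized truth prevalence
        n = finals.size
        assert abs(called.mean() - p) < 1.96 * np.sqrt(p * (1 - p) / n) + 0.01


class TestMorphology:
    def test_identical_groups(self):
        areas = np.tile(np.array([100.0, 110.0, 120.0, 130.0]), 2)
        labels = np.array([True] * 4 + [False] * 4)
        comp = sp.compare_morphology(labels, areas)
        assert comp.effect_summary["hp_lp_mean_area_ratio"] == pytest.approx(1.0)
        assert comp.p_value > 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            sp.compare_morphology(np.array([True, True]), np.array([1.0, 2.0]))


class TestRankStatistics:
    def test_kruskal_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        comp = sp.kruskal_wallis([g, g.copy(), g.copy()])
        assert comp.statistic == pytest.approx(0.0, abs=1e-9)
        assert comp.p_value == pytest.approx(1.0, abs=1e-9)

    def test_kruskal_undersized_rejected(self):
        with pytest.raises(InvalidInputError):
            sp.kruskal_wallis([np.array([1.0]), np.array([2.0, 3.0])])

    def test_wilcoxon_matches_exhaustive_permutation(self):
        """Rank-sum statistic and p value against brute-force enumeration of
        all 20 labelings of the pooled sample."""
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([10.0, 20.0, 30.0])
        comp = sp.wilcoxon_rank_sum(a, b)
        pooled = np.concatenate([a, b])
        order = pooled.argsort().argsort() + 1.0  # ranks, no ties here
        w_obs = float(order[:3].sum())
        assert comp.statistic == w_obs == 6.0
        # exhaustive null distribution of W over all C(6,3) group assignments
        ws = [
            sum(sorted(order)[i] for i in combo)
            for combo in itertools.combinations(range(6), 3)
        ]
        mu = np.mean(ws)
        p_exact = np.mean([abs(w - mu) >= abs(w_obs - mu) - 1e-12 for w in ws])
        assert comp.p_value == pytest.approx(p_exact)

    def test_mean_deviation(self):
        assert sp.mean_deviation([0.0, 10.0]) == 5.0

    def test_anderson_darling_decisions(self):
        rng = np.random.default_rng(17)
        stat_n, normal = sp.anderson_darling_normal(rng.normal(0, 1, 500))
        stat_e, exp_normal = sp.anderson_darling_normal(rng.exponential(1, 500))
        assert normal and not exp_normal
        assert stat_e > stat_n


class TestDetectionOperatingCharacteristics:
    def test_false_hp_rate_controlled_without_hps(self):
        """Type-I control: with no true HPs the classifier flags at most 2%
        of cells on average across seeds."""
        rates = []
        for seed in range(20):
            finals, _ = final_deltas(
                seed=seed, rows=25, cols=25, hp_prevalence=0.0, viability=1.0
            )
            t = sp.compute_threshold(finals)
            rates.append((finals > t).mean())
        assert np.mean(rates) <= 0.02

    def test_recall_monotone_in_effect_size(self):
        """Power grows with the HP/LP slope ratio (paired seeds)."""
        recalls = []
        for mult in (2.0, 4.0, 8.0):
            hits = total = 0
            for seed in range(5):
                finals, is_hp = final_deltas(
                    seed=seed, viability=1.0, hp_slope_multiplier=mult
                )
                t = sp.compute_threshold(finals)
                hits += ((finals > t) & is_hp).sum()
                total += is_hp.sum()
            recalls.append(hits / total)
        assert recalls[0] <= recalls[1] + 1e-9 <= recalls[2] + 2e-9

    def test_skewness_larger_late_than_early(self):
        """With HPs present, g1 at 62 h exceeds g1 at 12 h in >=95% of seeds."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            layout_kw = dict(rows=25, cols=25, viability=1.0)
            rng = np.random.default_rng(seed + 7_777)
            finals12, _ = final_deltas(seed=seed, t_final=12.0, **layout_kw)
            finals62, _ = final_deltas(seed=seed, t_final=62.0, **layout_kw)
            wins += sp.sample_skewness(finals62) > sp.sample_skewness(finals12)
        assert wins >= 0.95 * n_seeds

    def test_no_trend_in_skewness_without_hps(self):
        """Null behaviour: g1(t) has no systematic upward trend when the
        population has a single component."""
        from scipy import stats as sps

        t = np.arange(2, 63, 2, dtype=float)
        slopes_of_g1 = []
        for seed in range(10):
            finals, _ = final_deltas(
                seed=seed, rows=25, cols=25, hp_prevalence=0.0, viability=1.0,
                noise_sd=0.0,
            )
            rng = np.random.default_rng(seed + 31)
            series = []
            for tk in t:
                deltas_tk = finals / 62.0 * tk + rng.normal(0, 2.0, finals.size)
                series.append(sp.sample_skewness(deltas_tk))
            slopes_of_g1.append(np.polyfit(t, series, 1)[0])
        res = sps.ttest_1samp(slopes_of_g1, 0.0, alternative="greater")
        assert res.pvalue > 0.05
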