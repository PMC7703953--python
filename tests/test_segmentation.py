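import numpy as np
import pytest

from regimeshift import (
    HazardPrior,
    NormalGammaPrior,
    SegmentationConstraints,
    SMCSettings,
    TimeSeries,
    UniformPriorBounds,
    conjugate_filter,
    map_segmentation,
    regime_summaries,
    smooth_run_lengths,
)
from regimeshift.exact import brute_force_map_segmentation, enumerate_smoothed

from conftest import make_two_regime_series


def _smooth(vals, lam=10.0, ng=NormalGammaPrior(0, 0.5, 1.5, 1.0)):
    series = TimeSeries(np.arange(len(vals)), np.asarray(vals, float))
    hz = HazardPrior(lam)
    filtered = conjugate_filter(series, hz, ng)
    return filtered, smooth_run_lengths(filtered, hz), hz, ng


class TestSmoothing:
    def test_last_step_equals_filtered(self):
        vals = np.random.default_rng(0).normal(0, 1, 12)
        filtered, smoothed, _, _ = _smooth(vals)
        np.testing.assert_allclose(
            smoothed.probs[-1], filtered.probs[-1], atol=1e-12
        )

    def test_rows_sum_to_one(self):
        vals = np.random.default_rng(1).normal(0, 1, 15)
        _, smoothed, _, _ = _smooth(vals)
        for row in smoothed.probs:
            assert row.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed,n", [(2, 3), (3, 8), (4, 11)])
    def test_matches_enumeration_marginals(self, seed, n):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(3, 1, n - n // 2)])
        _, smoothed, hz, ng = _smooth(vals)
        rows = enumerate_smoothed(vals, hz, ng)
        for t in range(n):
            dense = np.zeros(t + 1)
            dense[smoothed.support[t]] = smoothed.probs[t]
            np.testing.assert_allclose(dense, rows[t], atol=1e-10)


class TestMapSegmentation:
    def test_single_regime_for_stationary_series(self):
        vals = np.random.default_rng(5).normal(0, 1, 20)
        _, smoothed, _, _ = _smooth(vals, lam=50.0)
        seg = map_segmentation(smoothed, SegmentationConstraints(5))
        assert seg.n_regimes == 1
        assert seg.regimes[0].start == 0 and seg.regimes[0].end == 19

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("min_len,exempt", [(3, True), (2, False), (4, True)])
    def test_dp_equals_brute_force(self, seed, min_len, exempt):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([rng.normal(0, 1, 6), rng.normal(2.5, 1, 6)])
        _, smoothed, _, ng = _smooth(vals)
        cons = SegmentationConstraints(min_len, exempt)
        seg = map_segmentation(smoothed, cons)
        rows = enumerate_smoothed(vals, HazardPrior(10.0), ng)
        bf_cps, bf_score = brute_force_map_segmentation(rows, cons)
        assert tuple(seg.change_points) == bf_cps
        assert seg.objective == pytest.approx(bf_score, abs=1e-9)

    def test_interior_regimes_respect_minimum_length(self):
        series = make_two_regime_series(8, n1=20, n2=25)
        _, smoothed, _, _ = _smooth(series.values, lam=25.0)
        seg = map_segmentation(smoothed, SegmentationConstraints(10))
        for reg in seg.regimes[1:-1]:
            assert reg.length >= 10

    def test_infeasible_constraints_raise(self):
        vals = np.random.default_rng(6).normal(0, 1, 5)
        _, smoothed, _, _ = _smooth(vals)
        with pytest.raises(ValueError, match="smaller minimum regime length"):
            map_segmentation(
                smoothed, SegmentationConstraints(10, exempt_first_last=False)
            )


class TestRegimeSummaries:
    def test_long_gaussian_regime_cpi_matches_population_interval(self):
        # posterior predictive of a long Normal(0,1) regime ~ the data law
        from regimeshift import Segmentation, Regime

        vals = np.random.default_rng(9).normal(0, 1, 1000)
        series = TimeSeries(np.arange(1000), vals)
        seg = Segmentation((Regime(0, 999),))
        regs = regime_summaries(
            series, seg, UniformPriorBounds(-4, 4, 0.01, 6),
            SMCSettings(n_particles=2000), rng=5,
        )
        lo, hi = regs[0].cpi68
        assert lo == pytest.approx(-1.0, abs=0.1)
        assert hi == pytest.approx(1.0, abs=0.1)
        assert regs[0].post_mean_mu == pytest.approx(0.0, abs=0.1)
        assert not regs[0].low_confidence

    def test_constant_regime_recovers_its_value(self):
        from regimeshift import Segmentation, Regime

        series = TimeSeries(np.arange(30), np.full(30, 4.2))
        seg = Segmentation((Regime(0, 29),))
        regs = regime_summaries(
            series, seg, UniformPriorBounds(0, 8, 0.001, 1.0),
            SMCSettings(n_particles=1000), rng=2,
        )
        assert regs[0].post_mean_mu == pytest.approx(4.2, abs=0.02)
        assert regs[0].cpi68[0] < regs[0].cpi68[1]

    def test_single_observation_regime_flagged(self):
        from regimeshift import Segmentation, Regime

        series = TimeSeries(np.arange(12), np.r_[np.zeros(11), 5.0])
        seg = Segmentation((Regime(0, 10), Regime(11, 11)))
        regs = regime_summaries(
            series, seg, UniformPriorBounds(-8, 8, 0.01, 8),
            SMCSettings(n_particles=500), rng=0,
        )
        assert regs[1].low_confidence
        assert np.isfinite(regs[1].post_mean_mu)

    def test_deterministic_given_seed(self):
        from regimeshift import Segmentation, Regime

        series = TimeSeries(np.arange(40), np.random.default_rng(3).normal(1, 2, 40))
        seg = Segmentation((Regime(0, 39),))
        kw = dict(
            priors=UniformPriorBounds(-10, 10, 0.01, 10),
            settings=SMCSettings(n_particles=500),
        )
        a = regime_summaries(series, seg, rng=7, **kw)
        b = regime_summaries(series, seg, rng=7, **kw)
        assert a[0].post_mean_mu == b[0].post_mean_mu
        assert a[0].cpi68 == b[0].cpi68
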