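import numpy as np
import pytest
from scipy import stats

from regimeshift import (
    RegimeSpec,
    SyntheticScenario,
    generate_piecewise_normal,
    generate_study_like,
)
from regimeshift.synthetic import (
    STUDY_FIXTURES,
    read_scenario_file,
    write_scenario_outputs,
)


def scenario(*regs, **kw):
    kw.setdefault("seed", 42)
    return SyntheticScenario(regimes=tuple(RegimeSpec(*r) for r in regs), **kw)


class TestGeneratePiecewiseNormal:
    def test_single_regime_has_no_change_points(self):
        series, cps = generate_piecewise_normal(scenario((50, 0.0, 1.0)))
        assert cps == []
        assert len(series) == 50

    def test_mean_step_recovered_within_standard_error(self):
        # difference of sample means ~ Normal(3, 2/30); 3-sigma band
        sc = scenario((30, 0.0, 1.0), (30, 3.0, 1.0), seed=7)
        series, cps = generate_piecewise_normal(sc)
        assert cps == [30]
        diff = series.values[30:].mean() - series.values[:30].mean()
        assert abs(diff - 3.0) < 3.0 * np.sqrt(2.0 / 30.0)

    def test_variance_ratio_within_f_band(self):
        # ratio of sample variances ~ 9 * F(29, 29); central 99% band
        sc = scenario((30, 1.0, 1.0), (30, 1.0, 3.0), seed=11)
        series, _ = generate_piecewise_normal(sc)
        ratio = series.values[30:].var(ddof=1) / series.values[:30].var(ddof=1)
        lo, hi = 9.0 * stats.f.ppf([0.005, 0.995], 29, 29)
        assert lo < ratio < hi

    def test_reproducible_and_seed_sensitive(self):
        sc = scenario((40, 1.0, 2.0), seed=5)
        s1, _ = generate_piecewise_normal(sc)
        s2, _ = generate_piecewise_normal(sc)
        np.testing.assert_array_equal(s1.values, s2.values)
        s3, _ = generate_piecewise_normal(scenario((40, 1.0, 2.0), seed=6))
        assert not np.array_equal(s1.values, s3.values)

    def test_moment_recovery_long_regime(self):
        series, _ = generate_piecewise_normal(scenario((10_000, 2.0, 1.5), seed=3))
        n = 10_000
        assert abs(series.values.mean() - 2.0) < 3.0 * 1.5 / np.sqrt(n)
        assert abs(series.values.std(ddof=1) - 1.5) < 3.0 * 1.5 / np.sqrt(2 * n)

    def test_missing_fraction_consistent_with_binomial(self):
        sc = scenario((2000, 0.0, 1.0), seed=9, missing_fraction=0.2)
        series, _ = generate_piecewise_normal(sc)
        n_missing = 2000 - len(series)
        lo, hi = stats.binom.ppf([0.001, 0.999], 2000, 0.2)
        assert lo <= n_missing <= hi
        assert series.has_gaps

    def test_change_point_times_respect_start_time(self):
        sc = scenario((10, 0, 1), (5, 1, 1), (5, 2, 1), start_time=1900)
        _, cps = generate_piecewise_normal(sc)
        assert cps == [1910, 1915]

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            RegimeSpec(10, 0.0, 0.0)
        with pytest.raises(ValueError):
            RegimeSpec(0, 0.0, 1.0)
        with pytest.raises(ValueError):
            SyntheticScenario(regimes=(), seed=1)
        with pytest.raises(ValueError):
            scenario((10, 0, 1), missing_fraction=1.0)


class TestStudyFixtures:
    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(ValueError, match="cod"):
            generate_study_like("herring")

    def test_cod_first_two_regimes_differ_only_in_spread(self):
        regs = STUDY_FIXTURES["cod"].regimes
        assert len(regs) == 4
        assert regs[0].mu == regs[1].mu
        assert regs[0].sigma > regs[1].sigma
        # then two stepwise declines in the mean
        assert regs[1].mu > regs[2].mu > regs[3].mu

    def test_sst_fixture_steps_one_to_two_units(self):
        regs = STUDY_FIXTURES["sst_month"].regimes
        assert len(regs) == 2
        assert 1.0 <= regs[1].mu - regs[0].mu <= 2.0

    def test_nao_fixture_shift_directions_down_up_down(self):
        regs = STUDY_FIXTURES["nao"].regimes
        deltas = np.diff([r.mu for r in regs])
        assert np.sign(deltas).tolist() == [-1.0, 1.0, -1.0]
        assert abs(regs[0].mu) < 0.5  # first regime near zero

    def test_fixtures_are_fixed_seed(self):
        a, _ = generate_study_like("fishing")
        b, _ = generate_study_like("fishing")
        np.testing.assert_array_equal(a.values, b.values)


def test_scenario_file_round_trip(tmp_path):
    cfg = tmp_path / "sc.cfg"
    cfg.write_text(
        "# two regimes\nstart_time = 1950\nseed = 12\nmissing_fraction = 0.0\n"
        "regime = 20 0.0 1.0\nregime = 10 2.5 0.5\n"
    )
    sc = read_scenario_file(cfg)
    assert sc.start_time == 1950 and sc.seed == 12
    assert [r.length for r in sc.regimes] == [20, 10]
    series_path, cps_path = write_scenario_outputs(sc, tmp_path, "demo")
    assert series_path.exists() and cps_path.exists()
    assert "1970" in cps_path.read_text()


def test_scenario_file_requires_seed(tmp_path):
    cfg = tmp_path / "bad.cfg"
    cfg.write_text("regime = 10 0 1\n")
    with pytest.raises(ValueError, match="seed"):
        read_scenario_file(cfg)
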