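"""Nonparametric circadian metrics: closed forms, oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from actimood.cohort import generate_actigraphy
from actimood.config import ActigraphyParams
from actimood.rhythm import (
    HourlySeries,
    average_acceleration,
    bin_hourly,
    interdaily_stability,
    intradaily_variability,
    relative_amplitude,
)

from conftest import make_series


def hourly(values):
    values = np.asarray(values, dtype=float)
    return HourlySeries(values=values, completeness=np.ones(values.size), start_clock_hour=0)


class TestBinHourly:
    def test_constant_hour(self):
        s = make_series(np.full(120, 5.0))
        h = bin_hourly(s)
        np.testing.assert_allclose(h.values, [5.0, 5.0])

    def test_partial_wear(self):
        wear = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        s = make_series(np.full(60, 10.0), wear=wear)
        h = bin_hourly(s, completeness_min=0.5)
        assert h.values[0] == 10.0
        assert h.completeness[0] == 0.5

    def test_below_completeness_is_missing_and_strict_raises(self):
        wear = np.r_[np.ones(10, bool), np.zeros(50, bool)]
        s = make_series(np.full(60, 10.0), wear=wear)
        assert np.isnan(bin_hourly(s).values[0])
        with pytest.raises(ValueError, match="completeness"):
            bin_hourly(s, strict=True)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        vals = rng.gamma(2.0, 10.0, 1440)
        wear = rng.random(1440) < 0.9
        s = make_series(vals, wear=wear)
        h = bin_hourly(s, completeness_min=0.0)
        for i in range(24):
            v = vals[i * 60:(i + 1) * 60]
            w = wear[i * 60:(i + 1) * 60]
            expected = v[w].mean() if w.any() else np.nan
            if np.isnan(expected):
                assert np.isnan(h.values[i])
            else:
                assert abs(h.values[i] - expected) < 1e-12


class TestAverageAcceleration:
    def test_constant(self):
        assert average_acceleration(make_series(np.full(100, 30.0))) == 30.0

    def test_alternating(self):
        assert average_acceleration(make_series(np.tile([0.0, 60.0], 50))) == 30.0

    def test_ignores_nonwear(self):
        wear = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        vals = np.r_[np.full(50, 10.0), np.full(50, 99.0)]
        assert average_acceleration(make_series(vals, wear=wear)) == 10.0

    def test_no_worn_epochs_errors(self):
        with pytest.raises(ValueError, match="worn"):
            average_acceleration(make_series(np.ones(10), wear=np.zeros(10, bool)))


class TestInterdailyStability:
    def test_repeated_day_gives_one(self):
        rng = np.random.default_rng(1)
        day = rng.gamma(2.0, 10.0, 24)
        assert interdaily_stability(hourly(np.tile(day, 7))) == pytest.approx(1.0, abs=1e-9)

    def test_constant_signal_undefined(self):
        assert np.isnan(interdaily_stability(hourly(np.full(48, 3.0))))

    def test_iid_noise_expectation(self):
        """For i.i.d. noise over d days the expected IS is about 1/d."""
        vals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.normal(10.0, 2.0, 24 * 7).clip(0)
            vals.append(interdaily_stability(hourly(x)))
        assert abs(float(np.mean(vals)) - 1.0 / 7.0) < 0.02


class TestIntradailyVariability:
    def test_hourly_alternation_is_four(self):
        x = np.tile([2.0, 0.0], 12 * 7)
        assert intradaily_variability(hourly(x)) == pytest.approx(4.0, abs=1e-12)

    def test_cosine_closed_form(self):
        x = np.cos(2 * np.pi * np.arange(24 * 100) / 24) + 2.0
        target = 2.0 * (1.0 - np.cos(np.pi / 12.0))
        assert intradaily_variability(hourly(x)) == pytest.approx(target, abs=1e-4)

    def test_white_noise_tends_to_two(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10.0, 2.0, 168 * 20).clip(0)
        assert abs(intradaily_variability(hourly(x)) - 2.0) < 0.1

    def test_constant_signal_undefined(self):
        assert np.isnan(intradaily_variability(hourly(np.full(48, 3.0))))


class TestRelativeAmplitude:
    def test_square_day(self):
        # 10 h at 100 starting at 13:00, the rest 0
        day = np.zeros(1440)
        day[60:660] = 100.0
        m10, l5, ra = relative_amplitude(make_series(day))
        assert m10 == pytest.approx(100.0)
        assert l5 == pytest.approx(0.0)
        assert ra == pytest.approx(1.0)

    def test_constant_signal_zero(self):
        _, _, ra = relative_amplitude(make_series(np.full(1440, 25.0)))
        assert ra == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_day_dropped(self):
        _, _, ra = relative_amplitude(make_series(np.zeros(1440)))
        assert np.isnan(ra)

    def test_matches_exhaustive_oracle(self):
        """Sliding-window M10/L5 equals brute force over all window starts."""
        rng = np.random.default_rng(7)
        epoch_s = 600  # 144 epochs/day keeps the brute force cheap
        per_day = 86400 // epoch_s
        w10, w5 = 10 * 3600 // epoch_s, 5 * 3600 // epoch_s
        for _ in range(100):
            day = rng.gamma(2.0, 10.0, per_day)
            m10, l5, _ = relative_amplitude(make_series(day, epoch_s=epoch_s))
            brute_m10 = max(day[i:i + w10].mean() for i in range(per_day - w10 + 1))
            brute_l5 = min(day[i:i + w5].mean() for i in range(per_day - w5 + 1))
            assert m10 == pytest.approx(brute_m10, abs=1e-9)
            assert l5 == pytest.approx(brute_l5, abs=1e-9)


day_arrays = hnp.arrays(
    np.float64,
    st.integers(min_value=2, max_value=5).map(lambda d: 24 * d),
    elements=st.floats(min_value=0.0, max_value=1e3, allow_nan=False),
)


@given(day_arrays)
@settings(max_examples=50)
def test_metric_bounds_property(x):
    """0 <= IS <= 1 and IV >= 0 on any nonnegative hourly input."""
    h = hourly(x)
    is_ = interdaily_stability(h)
    iv = intradaily_variability(h)
    if not np.isnan(is_):
        assert -1e-9 <= is_ <= 1.0 + 1e-9
    if not np.isnan(iv):
        assert iv >= 0.0


def test_ra_scale_invariance_aa_linearity():
    rng = np.random.default_rng(5)
    day = rng.gamma(2.0, 10.0, 1440) + 1.0
    s1 = make_series(day)
    s3 = make_series(3.0 * day)
    _, _, ra1 = relative_amplitude(s1)
    _, _, ra3 = relative_amplitude(s3)
    assert ra3 == pytest.approx(ra1, rel=1e-12)
    assert average_acceleration(s3) == pytest.approx(3.0 * average_acceleration(s1), rel=1e-12)


def test_is_decreases_with_phase_jitter_iv_increases_with_fragmentation():
    """Generator-level monotonicity of IS and IV (in expectation)."""
    def mean_metric(param_kwargs, metric, seeds=6):
        out = []
        for seed in range(seeds):
            p = ActigraphyParams(n_days=5, **param_kwargs)
            s = generate_actigraphy(p, seed=seed)
            h = bin_hourly(s)
            out.append(metric(h))
        return float(np.mean(out))

    is_vals = [mean_metric({"phase_jitter_sd_h": j, "sleep_onset_sd_h": 0.0}, interdaily_stability)
               for j in (0.0, 1.5, 3.0)]
    assert is_vals[0] > is_vals[1] > is_vals[2]

    iv_vals = [mean_metric({"fragmentation_rate_per_h": f}, intradaily_variability)
               for f in (0.0, 2.0, 5.0)]
    assert iv_vals[0] < iv_vals[1] < iv_vals[2]
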