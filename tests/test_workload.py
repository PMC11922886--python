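"""Bandpower ratios, task trends and variation extents."""

import numpy as np
import pandas as pd
import pytest

from ssmvep.synth_eeg import (ResponseModel, SessionLayout, TrialTensor,
                              generate_session)
from ssmvep.workload import bandpowers, fatigue_report, ratio_trend

FS = 1200.0


def _tensor_from_signal(x, n_trials=4):
    data = np.tile(x, (n_trials, 1, 1))
    labels = pd.DataFrame({"subject": 1, "paradigm": "bimodal",
                           "task": np.arange(n_trials) % 4 + 1,
                           "trial": np.arange(n_trials)})
    return TrialTensor(data, labels, FS, channels=("Oz",))


class TestBandpowers:
    def test_alpha_tone_dominates_alpha_band(self):
        t = np.arange(6000) / FS
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        bp = bandpowers(_tensor_from_signal(x))
        assert (bp.alpha_power > 50 * bp.theta_power).all()
        assert (bp.alpha_power > 50 * bp.beta_power).all()

    def test_white_noise_band_powers_proportional_to_width(self, rng):
        data = rng.standard_normal((20, 1, 6000))
        labels = pd.DataFrame({"subject": 1, "paradigm": "x",
                               "task": np.ones(20, dtype=int), "trial": range(20)})
        bp = bandpowers(TrialTensor(data, labels, FS, channels=("Oz",)))
        widths = {"theta": 4.0, "alpha": 5.0, "beta": 17.0}
        theta_density = bp.theta_power[0] / widths["theta"]
        for name in ("alpha", "beta"):
            assert bp[f"{name}_power"][0] / widths[name] == pytest.approx(
                theta_density, rel=0.1)

    def test_doubled_alpha_component_measured(self, rng, small_layout):
        base = ResponseModel(harmonic_amplitudes=(0.0,), harmonic_phases=(0.0,))
        double = ResponseModel(harmonic_amplitudes=(0.0,), harmonic_phases=(0.0,),
                               band_powers={"theta": 1.0, "alpha": 8.0,
                                            "beta": 0.6})
        s1 = generate_session(small_layout, base, 2, paradigms=("bimodal",))
        s2 = generate_session(small_layout, double, 2, paradigms=("bimodal",))
        a1 = bandpowers(s1).alpha_power.mean()
        a2 = bandpowers(s2).alpha_power.mean()
        assert a2 / a1 == pytest.approx(2.0, rel=0.15)

    def test_band_outside_spectrum_rejected(self, bimodal_session):
        with pytest.raises(ValueError):
            bandpowers(bimodal_session, bands={"hf": (500.0, 700.0)})


def _series(ratios, subject=1, paradigm="bimodal"):
    """BandpowerSeries-shaped frame with prescribed load ratios."""
    return pd.DataFrame({
        "subject": subject, "paradigm": paradigm, "task": [1, 2, 3, 4],
        "theta_power": np.asarray(ratios), "alpha_power": 1.0,
        "beta_power": 1.0, "load_ratio": np.asarray(ratios),
        "fatigue_ratio": np.asarray(ratios) + 1.0,
    })


class TestRatioTrend:
    def test_constant_ratios_give_zero_extent(self):
        out = ratio_trend(_series([2.0, 2.0, 2.0, 2.0]))
        assert out.load_extent_pct.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_exact_linear_ratios(self):
        out = ratio_trend(_series([1.0, 1.1, 1.2, 1.3]))
        assert out.load_extent_pct.iloc[0] == pytest.approx(30.0)
        assert out.load_slope.iloc[0] == pytest.approx(0.1)

    def test_scale_invariance(self):
        a = ratio_trend(_series([1.0, 1.3, 1.1, 1.6]))
        b = ratio_trend(_series([10.0, 13.0, 11.0, 16.0]))
        assert a.load_extent_pct.iloc[0] == pytest.approx(
            b.load_extent_pct.iloc[0])

    def test_zero_baseline_reported_as_nan_not_blowup(self):
        # fitted task-1 value is exactly 0 -> extent undefined, not huge
        out = ratio_trend(_series([0.0, 1.0, 2.0, 3.0]))
        assert np.isnan(out.load_extent_pct.iloc[0])

    def test_single_task_rejected(self):
        df = _series([1.0, 1.1, 1.2, 1.3])
        df["task"] = 1
        with pytest.raises(ValueError):
            ratio_trend(df)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ratio_trend(pd.DataFrame({"subject": [1]}))


class TestDriftRecovery:
    def test_injected_theta_drift_recovered(self):
        # +10%/task on the theta component, rhythmic components isolated
        # (no evoked response, whose harmonics overlap the theta band)
        layout = SessionLayout(n_subjects=1, trials_per_run=8,
                               brightness_levels=("medium",))
        model = ResponseModel(harmonic_amplitudes=(0.0,), harmonic_phases=(0.0,),
                              band_drift_slopes={"theta": 0.1, "alpha": 0.0,
                                                 "beta": 0.0})
        ext = []
        for seed in range(8):
            sess = generate_session(layout, model, seed, paradigms=("bimodal",))
            ext.append(ratio_trend(bandpowers(sess)).load_extent_pct.iloc[0])
        from ssmvep.synth_eeg import expected_band_power

        r = [expected_band_power(model, FS, 6000, "theta", k)
             / expected_band_power(model, FS, 6000, "alpha", k)
             for k in range(1, 5)]
        x = np.arange(1, 5)
        slope, icept = np.polyfit(x, r, 1)
        analytic = 100 * (slope * 4 + icept - (slope + icept)) / (slope + icept)
        assert np.mean(ext) == pytest.approx(analytic, abs=8.0)

    def test_report_structure_and_normalization(self, bimodal_session):
        series = bandpowers(bimodal_session)
        report = fatigue_report(series)
        assert set(report) == {"trends", "normalized", "paradigm_means"}
        z = report["normalized"].groupby("subject")["load_ratio_z"]
        for _, vals in z:
            assert vals.mean() == pytest.approx(0.0, abs=1e-9)
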