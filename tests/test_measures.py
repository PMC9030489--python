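import math

import numpy as np
import pytest

import swaylab as sl
from swaylab.measures import (
    MEASURE_NAMES,
    area_measures,
    basic_stats,
    compute_measures,
    copv_ap,
    fractal_dimension,
    integrate_measures,
    mean_frequency,
    trajectory_length,
)
from swaylab.preprocessing import derive_directions

FS = 240.0
T = np.arange(0, 10, 1 / FS)


def _dirs(ap=None, ml=None, is_=None, detrend=True, rate=FS):
    n = len(ap if ap is not None else ml if ml is not None else is_)
    acc = np.zeros((n, 3))
    if ap is not None:
        acc[:, 0] = ap
    if ml is not None:
        acc[:, 1] = ml
    if is_ is not None:
        acc[:, 2] = is_
    return derive_directions(acc, rate, detrend_axes=detrend)


class TestMeasureRegistry:
    def test_family_expansion_counts(self):
        assert len(MEASURE_NAMES) == 43
        fams = {}
        for name in MEASURE_NAMES:
            fams.setdefault(name.split("_")[0], []).append(name)
        assert {k: len(v) for k, v in fams.items()} == {
            "AVG": 5, "RNG": 5, "RMS": 5, "ARE": 3, "FD": 2, "LEN": 4,
            "MD": 4, "MF": 4, "MV": 4, "PD": 2, "PP": 1, "RMSD": 4,
        }


class TestBasicStats:
    def test_unit_sinusoid_closed_forms(self):
        d = _dirs(ap=np.sin(2 * np.pi * 1.0 * T))
        out = basic_stats(d)
        assert out["RMS_AP"] == pytest.approx(1 / math.sqrt(2), rel=1e-6)
        assert out["RNG_AP"] == pytest.approx(2.0, rel=1e-6)
        assert out["AVG_AP"] == pytest.approx(2 / math.pi, rel=1e-4)

    def test_all_zero_signals(self):
        out = basic_stats(_dirs(ap=np.zeros(100)))
        assert all(v == 0.0 for v in out.values())

    def test_rayleigh_moments_for_gaussian_axes(self, rng):
        # AP, ML iid N(0, sigma^2): resultant is Rayleigh; MD -> sigma
        # sqrt(pi/2), RMSD -> sigma sqrt(2)
        sigma = 0.3
        n = 200_000
        d = _dirs(
            ap=rng.normal(0, sigma, n), ml=rng.normal(0, sigma, n)
        )
        out = basic_stats(d)
        assert out["MD_2DR"] == pytest.approx(sigma * math.sqrt(math.pi / 2), rel=0.01)
        assert out["RMSD_2DR"] == pytest.approx(sigma * math.sqrt(2), rel=0.01)

    def test_rmsd_dominates_md_and_pythagorean_rms(self, rng):
        d = _dirs(
            ap=rng.standard_normal(2400),
            ml=rng.standard_normal(2400),
            is_=rng.standard_normal(2400),
        )
        out = basic_stats(d)
        for dd in ("AP", "ML", "2DR", "3DR"):
            assert out[f"RMSD_{dd}"] >= out[f"MD_{dd}"]
        assert out["RMS_2DR"] ** 2 == pytest.approx(
            out["RMS_AP"] ** 2 + out["RMS_ML"] ** 2, rel=1e-9
        )


class TestTrajectoryLength:
    def test_monotone_ramp_telescopes(self):
        d = _dirs(ap=np.linspace(0, 1, 101), detrend=False)
        assert trajectory_length(d)["LEN_AP"] == pytest.approx(1.0)

    def test_constant_trajectory_zero(self):
        d = _dirs(ap=np.ones(50), detrend=False)
        assert all(v == 0 for v in trajectory_length(d).values())

    def test_homogeneity(self, rng):
        acc = rng.standard_normal((500, 3))
        a = trajectory_length(derive_directions(acc, FS))
        b = trajectory_length(derive_directions(3.5 * acc, FS))
        for k in a:
            assert b[k] == pytest.approx(3.5 * a[k], rel=1e-9)

    def test_per_second_divides_by_duration(self, rng):
        d = derive_directions(rng.standard_normal((2400, 3)), FS)
        per_trial = trajectory_length(d)
        per_sec = trajectory_length(d, per_second=True)
        for k in per_trial:
            assert per_sec[k] == pytest.approx(per_trial[k] / 10.0)


class TestAreaMeasures:
    def test_zero_input_flagged_zeros(self):
        out, flags = area_measures(_dirs(ap=np.zeros(100)))
        assert out == {"ARE_SW": 0.0, "ARE_CC": 0.0, "ARE_CE": 0.0}
        assert flags == {"ARE_SW", "ARE_CC", "ARE_CE"}

    def test_quadratic_homogeneity(self, rng):
        acc = rng.standard_normal((1000, 3))
        a, _ = area_measures(derive_directions(acc, FS))
        b, _ = area_measures(derive_directions(2.0 * acc, FS))
        for k in a:
            assert b[k] == pytest.approx(4.0 * a[k], rel=1e-9)

    def test_confidence_ellipse_gaussian_closed_form(self, rng):
        # for iid Gaussian axes the 95% ellipse area tends to
        # 2*pi*F(2,n-2)*sigma^2 with F -> 3.0
        sigma = 0.5
        n = 2400
        areas = []
        for _ in range(40):
            d = _dirs(ap=rng.normal(0, sigma, n), ml=rng.normal(0, sigma, n))
            out, _ = area_measures(d, time_normalized=False)
            areas.append(out["ARE_CE"])
        assert np.mean(areas) == pytest.approx(6 * math.pi * sigma**2, rel=0.05)


class TestFractalDimension:
    def test_scale_invariance(self, rng):
        acc = rng.standard_normal((800, 3))
        a, _ = fractal_dimension(derive_directions(acc, FS))
        b, _ = fractal_dimension(derive_directions(7.0 * acc, FS))
        for k in a:
            assert b[k] == pytest.approx(a[k], rel=1e-9)

    def test_near_line_has_dimension_near_one(self, rng):
        n = 500
        ap = np.linspace(-1, 1, n) + rng.normal(0, 1e-4, n)
        ml = 1e-4 * rng.standard_normal(n)
        d = _dirs(ap=ap, ml=ml)
        out, flags = fractal_dimension(d)
        assert not flags
        # the confidence-circle diameter matches the segment extent, so a
        # monotone traversal is almost one-dimensional
        assert out["FD_CC"] == pytest.approx(1.0, abs=0.05)

    def test_degenerate_trajectory_flagged(self):
        out, flags = fractal_dimension(_dirs(ap=np.zeros(50)))
        assert flags == {"FD_CC", "FD_CE"}
        assert all(math.isnan(v) for v in out.values())


class TestMeanFrequency:
    def test_pure_tone(self):
        d = _dirs(ap=np.sin(2 * np.pi * 1.5 * T))
        out, _ = mean_frequency(d)
        assert out["MF_AP"] == pytest.approx(1.5, abs=0.1)

    def test_two_equal_tones_average(self):
        x = np.sin(2 * np.pi * 1.0 * T) + np.sin(2 * np.pi * 3.0 * T)
        out, _ = mean_frequency(_dirs(ap=x))
        assert out["MF_AP"] == pytest.approx(2.0, abs=0.1)

    def test_white_noise_near_half_nyquist(self, rng):
        vals = []
        for _ in range(10):
            out, _ = mean_frequency(_dirs(ap=rng.standard_normal(2400)))
            vals.append(out["MF_AP"])
        assert np.mean(vals) == pytest.approx(FS / 4, rel=0.05)

    def test_zero_power_flagged(self):
        out, flags = mean_frequency(_dirs(ap=np.zeros(100)))
        assert "MF_AP" in flags and math.isnan(out["MF_AP"])


class TestIntegrateMeasures:
    def test_all_zero_acc(self):
        out = integrate_measures(_dirs(ap=np.zeros(100)))
        assert all(v == 0.0 for v in out.values())

    def test_linear_homogeneity(self, rng):
        acc = rng.standard_normal((1000, 3))
        a = integrate_measures(derive_directions(acc, FS))
        b = integrate_measures(derive_directions(2.5 * acc, FS))
        for k in a:
            assert b[k] == pytest.approx(2.5 * a[k], rel=1e-9)

    def test_sinusoid_velocity_closed_form(self):
        # a(t)=sin(2 pi t): v = -cos(2 pi t)/(2 pi), mean |v| = (2/pi)/(2 pi)
        d = _dirs(ap=np.sin(2 * np.pi * 1.0 * T))
        out = integrate_measures(d)
        assert out["MV_AP"] == pytest.approx((2 / math.pi) / (2 * math.pi), rel=1e-3)


class TestComputeAllMeasures:
    def test_full_vector_names_and_determinism(self, tiny_study):
        trial = tiny_study.trials[0]
        a = sl.compute_all_measures(trial, "pelvis")
        b = sl.compute_all_measures(trial, "pelvis")
        assert list(a.values) == list(MEASURE_NAMES)
        assert a.values == b.values

    def test_unknown_sensor_rejected(self, tiny_study):
        with pytest.raises(KeyError):
            sl.compute_all_measures(tiny_study.trials[0], "head")

    def test_zero_acc_flags_spectral_and_fractal(self):
        d = _dirs(ap=np.zeros(2400))
        vec = compute_measures(d)
        assert vec.flags >= {"FD_CC", "FD_CE", "MF_AP"}
        zeroed = [
            n for n in MEASURE_NAMES
            if not n.startswith(("FD", "MF"))
        ]
        assert all(vec.values[n] == 0.0 for n in zeroed)

    def test_amplitude_measures_track_latent_instability(self):
        # monotone ladder of latent intensities -> monotone RMS_AP
        from scipy.stats import spearmanr

        from swaylab.simulate import band_limited_noise

        rng = np.random.default_rng(3)
        ladder = np.linspace(0.5, 5.0, 10)
        rms = []
        for k in ladder:
            x = band_limited_noise(rng, 2400, FS, (0.1, 3.0), k, shape=(3,))
            rms.append(basic_stats(derive_directions(x, FS))["RMS_AP"])
        rho, _ = spearmanr(ladder, rms)
        assert rho > 0.9


class TestCopVelocity:
    def test_linear_ramp(self):
        cop = np.zeros((400, 2))
        cop[:, 0] = np.linspace(0, 30, 400)  # 30 mm over 10 s at 40 Hz
        assert copv_ap(cop, 40.0) == pytest.approx(3.0, rel=1e-6)

    def test_constant_cop_zero(self):
        assert copv_ap(np.ones((100, 2)), 40.0) == 0.0

    def test_triangular_wave(self):
        # four 10 mm segments in 10 s -> 4 mm/s
        seg = np.linspace(0, 10, 101)
        ap = np.concatenate([seg, seg[::-1][1:], seg[1:], seg[::-1][1:]])
        cop = np.column_stack([ap, np.zeros_like(ap)])
        assert copv_ap(cop, len(ap) / 10.0) == pytest.approx(4.0, rel=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            copv_ap(np.zeros((1, 2)), 40.0)


def test_study_measures_table_shape(tiny_study):
    wide = sl.compute_study_measures(tiny_study, sensors=["pelvis", "T8"])
    assert len(wide) == len(tiny_study.trials) * 2
    assert set(MEASURE_NAMES) <= set(wide.columns)
    tidy = sl.measures.measures_to_tidy(wide)
    assert set(tidy["measure"].unique()) == set(MEASURE_NAMES)
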