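"""Force-quantification pipeline tests."""

import numpy as np
import pytest

from morphoforce.errors import (
    InsufficientDataError,
    InvalidArgumentError,
    InvalidTraceError,
)
from morphoforce.inference import (
    DeformationTrace,
    ForceProfile,
    atp_equivalent,
    cohort_profile,
    compare_groups,
    elastic_energy,
    infer_profile,
    max_impulse,
    strain_to_force,
    widths_to_strain,
)


def _trace(times, width, width0=None):
    return DeformationTrace(times=np.asarray(times, float),
                            width=np.asarray(width, float), width0=width0)


def _profile(times, force):
    times = np.asarray(times, float)
    force = np.asarray(force, float)
    return ForceProfile(times=times, strain=np.zeros_like(force), force=force,
                        energy=np.zeros_like(force),
                        valid=np.ones(force.size, bool), k=7.15)


class TestStrain:
    @pytest.mark.parametrize("width,expected", [
        (162.0, +10.0),   # narrowing = compression
        (198.0, -10.0),   # widening, e.g. under ROCK inhibition
        (180.0, 0.0),
    ])
    def test_strain_sign_convention(self, width, expected):
        tr = _trace([0, 30], [180.0, width])
        assert widths_to_strain(tr)[1] == pytest.approx(expected)

    def test_zero_width0_rejected(self):
        with pytest.raises(InvalidTraceError):
            _trace([0, 30], [0.0, 162.0])


class TestForce:
    def test_force_from_narrowing(self):
        tr = _trace([0, 30], [180.0, 172.0])
        force, valid = strain_to_force(tr, 7.15)
        assert force[1] == pytest.approx(57.2, abs=1e-10)
        assert valid.all()

    def test_beyond_linear_range_is_flagged_not_dropped(self):
        tr = _trace([0, 30], [180.0, 140.0])      # 22% strain
        force, valid = strain_to_force(tr, 7.15)
        assert force[1] == pytest.approx(7.15 * 40.0)
        assert not valid[1]

    def test_zero_narrowing_zero_force(self):
        tr = _trace([0, 30], [180.0, 180.0])
        force, _ = strain_to_force(tr, 7.15)
        assert np.all(force == 0.0)

    def test_nonpositive_stiffness_rejected(self):
        with pytest.raises(InvalidArgumentError):
            strain_to_force(_trace([0, 30], [180, 170]), 0.0)


class TestEnergy:
    def test_zero_path(self):
        d = np.zeros(10)
        assert np.all(elastic_energy(np.zeros(10), d) == 0.0)

    def test_linear_loading_half_k_delta_squared(self):
        k = 7.15
        d = np.linspace(0, 15.0, 51)         # 50 steps
        e = elastic_energy(k * d, d)
        assert e[-1] == pytest.approx(0.5 * k * 15.0 ** 2 * 1e-3, rel=5e-3)

    def test_quadratic_loading_matches_calculus(self):
        c = 0.1
        d = np.linspace(0, 10.0, 101)        # 100 steps
        e = elastic_energy(c * d ** 2, d)
        assert e[-1] == pytest.approx(c * 10.0 ** 3 / 3.0 * 1e-3, rel=5e-3)

    def test_mismatched_lengths(self):
        with pytest.raises(InvalidArgumentError):
            elastic_energy(np.zeros(5), np.zeros(4))


class TestImpulse:
    def test_constant_force_carries_no_impulse(self):
        p = _profile(np.arange(0, 121, 30), np.full(5, 40.0))
        assert max_impulse(p) == pytest.approx(0.0)

    def test_linear_ramp(self):
        t = np.arange(0, 121, 30.0)
        p = _profile(t, 1.0 * t)              # 1 nN/min
        assert max_impulse(p) == pytest.approx(3600.0)

    def test_rise_then_plateau_window_scan(self):
        t = np.arange(0, 241, 30.0)
        f = np.where(t <= 60, 50.0 * t / 60.0, 50.0)
        p = _profile(t, f)
        assert max_impulse(p) == pytest.approx(3000.0)

    def test_short_trace_rejected(self):
        p = _profile([0.0, 30.0], [0.0, 10.0])
        with pytest.raises(InsufficientDataError):
            max_impulse(p)


class TestAtpEquivalent:
    @pytest.mark.parametrize("energy,expected", [
        (1.0, 1e7), (0.0, 0.0), (0.8, 8e6)])
    def test_conversion(self, energy, expected):
        assert atp_equivalent(energy) == pytest.approx(expected, rel=1e-12)

    def test_negative_energy_rejected(self):
        with pytest.raises(InvalidArgumentError):
            atp_equivalent(-1.0)


class TestCohort:
    def test_identical_profiles_have_zero_ci_width(self):
        t = np.arange(0, 121, 30.0)
        profiles = [_profile(t, 2.0 * t) for _ in range(5)]
        summary = cohort_profile(profiles)
        assert np.allclose(summary.mean, 2.0 * t)
        assert np.allclose(summary.ci_high - summary.ci_low, 0.0, atol=1e-12)

    def test_ci_half_width_matches_t_quantile(self, rng):
        t = np.arange(0, 61, 30.0)
        values = rng.normal(50.0, 5.0, 10)
        profiles = [_profile(t, np.full(3, v)) for v in values]
        summary = cohort_profile(profiles)
        sem = values.std(ddof=1) / np.sqrt(10)
        # t_{0.975, 9} = 2.262
        assert summary.ci_high[0] - summary.mean[0] == pytest.approx(
            2.262 * sem, rel=1e-3)

    def test_single_profile_warns_and_omits_ci(self):
        t = np.arange(0, 61, 30.0)
        with pytest.warns(UserWarning, match="confidence interval omitted"):
            summary = cohort_profile([_profile(t, np.full(3, 5.0))])
        assert np.all(np.isnan(summary.ci_low))
        assert np.allclose(summary.mean, 5.0)

    def test_no_extrapolation_beyond_short_profiles(self):
        t_long = np.arange(0, 121, 30.0)
        short = _profile(np.arange(0, 61, 30.0), np.full(3, 5.0))
        long_ = _profile(t_long, np.full(5, 9.0))
        summary = cohort_profile([short, long_, long_], t_long)
        assert summary.n[0] == 3 and summary.n[-1] == 2
        assert summary.mean[-1] == pytest.approx(9.0)


class TestCompareGroups:
    def test_identical_samples_p_one(self):
        stat, p = compare_groups([1.0, 2, 3], [1.0, 2, 3])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_clearly_shifted_samples_significant(self):
        _, p = compare_groups([1.0, 2, 3], [11.0, 12, 13])
        assert p < 0.05

    def test_t_statistic_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 4.0, 4.5])
        b = np.array([3.0, 5.0, 6.0, 7.5])
        stat, _ = compare_groups(a, b)
        sp = np.sqrt(((a.size - 1) * a.var(ddof=1)
                      + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2))
        expected = (a.mean() - b.mean()) / (sp * np.sqrt(1 / a.size + 1 / b.size))
        assert stat == pytest.approx(expected, rel=1e-10)

    def test_mann_whitney_mode(self):
        _, p = compare_groups([1.0, 2, 3, 4], [10.0, 11, 12, 13],
                              test="mannwhitney")
        assert p < 0.05

    def test_tiny_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0], [1.0, 2.0])


class TestPipelineProperties:
    def test_linearity_in_narrowing(self):
        t = np.arange(0, 121, 30.0)
        w0 = 180.0
        narrow = np.array([0.0, 2.0, 4.0, 5.0, 6.0])
        p1 = infer_profile(_trace(t, w0 - narrow), 7.15)
        p2 = infer_profile(_trace(t, w0 - 3.0 * narrow), 7.15)
        assert np.allclose(p2.force, 3.0 * p1.force)
        assert np.allclose(p2.energy, 9.0 * p1.energy)

    def test_compression_stretch_mirror_symmetry(self):
        t = np.arange(0, 121, 30.0)
        w0 = 180.0
        narrow = np.array([0.0, 2.0, 4.0, 5.0, 6.0])
        comp = infer_profile(_trace(t, w0 - narrow), 7.15)
        stretch = infer_profile(_trace(t, w0 + narrow), 7.15)
        assert np.allclose(stretch.force, -comp.force)
        assert np.allclose(np.abs(stretch.energy), np.abs(comp.energy))

    def test_cohort_mean_of_identical_profiles_is_the_profile(self):
        t = np.arange(0, 121, 30.0)
        p = infer_profile(_trace(t, 180.0 - np.linspace(0, 8, 5)), 7.15)
        summary = cohort_profile([p] * 4)
        assert np.allclose(summary.mean, p.force)
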