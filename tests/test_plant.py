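import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from whisknovelty.plant import (
    BilinearPlant,
    ContactResponse,
    ContactSchedule,
    IllConditionedIdentificationError,
    NoContactsError,
    compose_sensory,
    default_plant,
    generate_contact_schedule,
    identify_linear_plant,
    infer_contact_response,
    make_contact_response,
    render_exafferent,
    simulate_reafferent,
)
from whisknovelty.signals import TimeSeries, make_bandpass_noise, make_sine, periodogram_peaks


def linear_reference(u, a1, a2, b1, b2):
    """Pure-Python linear difference-equation simulator (independent of the
    compiled path, same accumulation order so outputs can match bit-exactly)."""
    r = np.zeros(len(u))
    for t in range(len(u)):
        acc = 0.0
        if t >= 1:
            acc += -a1 * r[t - 1] + b1 * u[t - 1]
        if t >= 2:
            acc += -a2 * r[t - 2] + b2 * u[t - 2]
        r[t] = acc
    return r


class TestLinearPlantParams:
    def test_rejects_unstable_coefficients(self):
        from whisknovelty.plant import LinearPlantParams

        with pytest.raises(ValueError, match="unstable"):
            LinearPlantParams(a1=-2.1, a2=1.2, b1=0.1, b2=0.1, sample_rate_hz=200.0)

    def test_default_plant_unit_dc_gain(self):
        lp = default_plant().linear
        gain = (lp.b1 + lp.b2) / (1 + lp.a1 + lp.a2)
        assert gain == pytest.approx(1.0, rel=1e-9)


class TestSimulateReafferent:
    def test_zero_input_gives_zero_output(self):
        u = TimeSeries(np.zeros(500), 200.0)
        r = simulate_reafferent(default_plant(k=0.03), u)
        assert np.all(r.values == 0.0)

    def test_linear_path_bit_identical_to_reference(self):
        u = make_bandpass_noise(2, 4, 5, 200, seed=2)
        lp = default_plant().linear
        r = simulate_reafferent(default_plant(), u)
        ref = linear_reference(u.values, lp.a1, lp.a2, lp.b1, lp.b2)
        assert np.array_equal(r.values, ref)

    def test_impulse_response_matches_scipy_oracle(self):
        lp = default_plant().linear
        impulse = TimeSeries(np.eye(1, 60).ravel(), 200.0)
        r = simulate_reafferent(default_plant(), impulse)
        _, h = sps.dimpulse(
            ([0.0, lp.b1, lp.b2], [1.0, lp.a1, lp.a2], 1 / 200.0), n=50
        )
        assert np.allclose(r.values[:50], np.squeeze(h), atol=1e-12)

    def test_bilinear_term_generates_harmonics(self):
        u = make_sine(3.0, 1.0, 60.0, 200.0)
        r0 = simulate_reafferent(default_plant(k=0.0), u)
        r5 = simulate_reafferent(default_plant(k=0.05), u)
        skip = 2000
        f0, _ = periodogram_peaks(r0.with_values(r0.values[skip:]), rel_threshold=0.01)
        f5, _ = periodogram_peaks(r5.with_values(r5.values[skip:]), rel_threshold=0.01)
        assert f0 == pytest.approx([3.0], abs=0.05)
        assert any(abs(f - 6.0) < 0.05 for f in f5)

    def test_rate_mismatch_rejected(self):
        u = TimeSeries(np.zeros(100), 100.0)
        with pytest.raises(ValueError, match="rate mismatch"):
            simulate_reafferent(default_plant(sample_rate_hz=200.0), u)

    def test_stability_regression_bounded_inputs(self):
        # |u| <= 1 and k = 0.05 must never trigger the divergence guard
        plant = default_plant(k=0.05)
        sine = make_sine(3.0, 1.0, 1000.0, 200.0)
        simulate_reafferent(plant, sine)  # must not raise
        noise = make_bandpass_noise(2, 4, 1000, 200, seed=11)
        clipped = noise.with_values(np.clip(noise.values, -1, 1))
        simulate_reafferent(plant, clipped)  # must not raise


class TestContactSchedule:
    def test_threshold_one_gives_no_contacts(self):
        s = generate_contact_schedule(100.0, 200.0, threshold=1.0, seed=0)
        assert len(s) == 0

    def test_seeded_reproducibility(self):
        a = generate_contact_schedule(100.0, 200.0, 0.999, seed=5)
        b = generate_contact_schedule(100.0, 200.0, 0.999, seed=5)
        assert np.array_equal(a.times, b.times)

    def test_count_matches_binomial_statistics(self):
        # N = 2e5 draws at p = 1e-3: mean 200, sd ~14.1; 3 sd either side
        s = generate_contact_schedule(1000.0, 200.0, 0.999, seed=42)
        n, p = 200_000, 1e-3
        sd = np.sqrt(n * p * (1 - p))
        assert abs(len(s) - n * p) < 3 * sd

    def test_threshold_bounds(self):
        for bad in (0.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                generate_contact_schedule(10.0, 200.0, bad, seed=0)


class TestRenderExafferent:
    def test_empty_schedule_gives_zeros(self):
        s = generate_contact_schedule(10.0, 200.0, 1.0, seed=0)
        h = make_contact_response()
        x = render_exafferent(s, h, 2000)
        assert np.all(x.values == 0.0)

    def test_single_contact_copies_response_exactly(self):
        s = ContactSchedule(np.array([100]), 0.999, 10.0, 200.0)
        h = make_contact_response(peak_amplitude=2.0)
        x = render_exafferent(s, h, 2000)
        assert np.array_equal(x.values[100 : 100 + len(h.h)], h.h)
        assert np.all(x.values[:100] == 0.0)

    def test_overlapping_contacts_superpose(self):
        h = make_contact_response()
        s12 = ContactSchedule(np.array([50, 60]), 0.999, 10.0, 200.0)
        s1 = ContactSchedule(np.array([50]), 0.999, 10.0, 200.0)
        s2 = ContactSchedule(np.array([60]), 0.999, 10.0, 200.0)
        x12 = render_exafferent(s12, h, 2000)
        x1 = render_exafferent(s1, h, 2000)
        x2 = render_exafferent(s2, h, 2000)
        assert np.allclose(x12.values, x1.values + x2.values, atol=0)

    def test_truncation_at_record_end(self):
        h = make_contact_response()
        s = ContactSchedule(np.array([1990]), 0.999, 10.0, 200.0)
        x = render_exafferent(s, h, 2000)
        assert np.array_equal(x.values[1990:], h.h[:10])

    @settings(max_examples=25, deadline=None)
    @given(st.sets(st.integers(0, 500), min_size=1, max_size=10))
    def test_linearity_over_disjoint_schedules(self, indices):
        idx = np.array(sorted(indices))
        half = len(idx) // 2 or 1
        h = make_contact_response()
        mk = lambda t: ContactSchedule(t, 0.999, 5.0, 200.0)
        whole = render_exafferent(mk(idx), h, 1000)
        if len(idx) > 1:
            part = render_exafferent(mk(idx[:half]), h, 1000).values + render_exafferent(
                mk(idx[half:]), h, 1000
            ).values
            assert np.allclose(whole.values, part, atol=0)


class TestComposeSensory:
    def test_additive_identities_bit_exact(self, rng):
        r = TimeSeries(rng.standard_normal(100), 200.0)
        zeros = TimeSeries(np.zeros(100), 200.0)
        assert np.array_equal(compose_sensory(r, zeros).values, r.values)
        assert np.array_equal(compose_sensory(zeros, r).values, r.values)

    def test_variance_additivity_for_independent_components(self):
        u = make_bandpass_noise(2, 4, 1000, 200, seed=1)
        r = simulate_reafferent(default_plant(), u)
        s = generate_contact_schedule(1000.0, 200.0, 0.999, seed=2)
        x = render_exafferent(s, make_contact_response(peak_amplitude=2.0), len(r))
        z = compose_sensory(r, x)
        lhs = np.var(z.values)
        assert abs(lhs - np.var(r.values) - np.var(x.values)) / lhs < 0.05

    def test_length_mismatch_rejected(self):
        a = TimeSeries(np.zeros(10), 200.0)
        b = TimeSeries(np.zeros(11), 200.0)
        with pytest.raises(ValueError):
            compose_sensory(a, b)


class TestIdentifyLinearPlant:
    def test_recovers_known_coefficients_exactly(self):
        u = make_bandpass_noise(2, 4, 500, 200, seed=3)
        true = default_plant().linear
        r = simulate_reafferent(default_plant(), u)
        fit = identify_linear_plant(u, r)
        assert fit.a[0] == pytest.approx(true.a1, abs=1e-6)
        assert fit.a[1] == pytest.approx(true.a2, abs=1e-6)
        assert fit.b[0] == pytest.approx(true.b1, abs=1e-6)
        assert fit.b[1] == pytest.approx(true.b2, abs=1e-6)
        assert fit.residual_variance < 1e-12

    def test_constant_input_is_ill_conditioned(self):
        u = TimeSeries(np.ones(2000), 200.0)
        r = TimeSeries(np.ones(2000), 200.0)
        with pytest.raises(IllConditionedIdentificationError, match="condition"):
            identify_linear_plant(u, r)

    def test_unmodelled_nonlinearity_inflates_residuals(self):
        u = make_bandpass_noise(2, 4, 300, 200, seed=4)
        u = u.with_values(u.values * 0.5)
        r_lin = simulate_reafferent(default_plant(k=0.0), u)
        r_nl = simulate_reafferent(default_plant(k=0.05), u)
        fit_lin = identify_linear_plant(u, r_lin)
        fit_nl = identify_linear_plant(u, r_nl)
        assert fit_nl.residual_variance > fit_lin.residual_variance


class TestInferContactResponse:
    def test_exact_recovery_with_perfect_prediction(self):
        u = make_sine(3.0, 1.0, 20.0, 200.0)
        r = simulate_reafferent(default_plant(), u)
        true_h = make_contact_response(peak_amplitude=1.5)
        s = ContactSchedule(np.array([1000]), 0.999, 20.0, 200.0)
        z = compose_sensory(r, render_exafferent(s, true_h, len(r)))
        got = infer_contact_response(z, r, s, len(true_h.h))
        assert np.allclose(got.h, true_h.h, atol=1e-14)

    def test_many_identical_windows_average_to_same(self):
        u = make_sine(3.0, 1.0, 60.0, 200.0)
        r = simulate_reafferent(default_plant(), u)
        true_h = make_contact_response(peak_amplitude=1.5)
        times = np.arange(1000, 11000, 500)
        s = ContactSchedule(times, 0.999, 60.0, 200.0)
        z = compose_sensory(r, render_exafferent(s, true_h, len(r)))
        got = infer_contact_response(z, r, s, len(true_h.h))
        assert np.allclose(got.h, true_h.h, atol=1e-12)

    def test_averaging_suppresses_prediction_noise(self, rng):
        # error RMS should shrink roughly as 1/sqrt(n_contacts)
        n = 60_000
        true_h = make_contact_response(peak_amplitude=1.0)
        r = TimeSeries(np.zeros(n), 200.0)
        noise = 0.1 * rng.standard_normal(n)
        r_noisy = TimeSeries(noise, 200.0)
        m = len(true_h.h)

        def recovery_rms(times):
            s = ContactSchedule(times, 0.999, n / 200.0, 200.0)
            z = render_exafferent(s, true_h, n)
            got = infer_contact_response(z, r_noisy, s, m)
            return np.sqrt(np.mean((got.h - true_h.h) ** 2))

        rms_1 = recovery_rms(np.array([500]))
        rms_50 = recovery_rms(np.arange(500, 500 + 50 * 100, 100))
        ratio = rms_50 / rms_1
        assert 0.05 < ratio < 0.35  # ideal 1/sqrt(50) ~ 0.14

    def test_empty_schedule_rejected(self):
        s = generate_contact_schedule(10.0, 200.0, 1.0, seed=0)
        z = TimeSeries(np.zeros(2000), 200.0)
        with pytest.raises(NoContactsError):
            infer_contact_response(z, z, s, 40)
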