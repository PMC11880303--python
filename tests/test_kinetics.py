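import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import quad

from aggphot import (
    ClassificationRules,
    ConfigError,
    DecayChannel,
    ExpComponent,
    InputError,
    IRFSpec,
    KineticTrace,
    amplitude_fractions,
    classify_decay_components,
    convolved_multiexp,
    fit_multiexponential,
    lifetime_consistency,
    select_component_count,
)
from aggphot import MultiExpFit
from aggphot.kinetics import FWHM_TO_SIGMA
from aggphot.synthetic import TraceConfig, default_delay_grid, gen_ta_trace, preset


def _numeric_convolution(t, tau, fwhm, t0=0.0):
    """Brute-force oracle: quad of exp(-v/tau) * Gaussian(t - v; t0, sigma)."""
    s = fwhm / FWHM_TO_SIGMA

    def integrand(v, ti):
        return (
            math.exp(-v / tau)
            * math.exp(-((ti - v - t0) ** 2) / (2 * s**2))
            / (s * math.sqrt(2 * math.pi))
        )

    def one(ti):
        # the integrand peaks near v = ti - t0; split there so quad sees it
        mid = max(ti - t0, 0.0)
        hi = mid + 12.0 * s
        a, _ = quad(integrand, 0.0, mid, args=(ti,), epsabs=1e-13, epsrel=1e-13, limit=200)
        b, _ = quad(integrand, mid, hi, args=(ti,), epsabs=1e-13, epsrel=1e-13, limit=200)
        return a + b

    return np.array([one(ti) for ti in t])


class TestConvolvedMultiexp:
    def test_matches_brute_force_convolution(self):
        """Closed form vs numerical convolution for random parameter sets."""
        rng = np.random.default_rng(42)
        t = np.array([-0.5, -0.1, 0.0, 0.05, 0.2, 0.5, 1.0, 3.0, 10.0, 40.0])
        for _ in range(50):
            tau = float(rng.uniform(0.1, 50.0))
            fwhm = float(rng.uniform(0.05, 0.5))
            amp = float(rng.uniform(-2.0, 2.0)) or 1.0
            got = convolved_multiexp(t, [ExpComponent(tau, amp)], IRFSpec(fwhm))
            oracle = amp * _numeric_convolution(t, tau, fwhm)
            scale = np.max(np.abs(oracle))
            np.testing.assert_allclose(got, oracle, atol=1e-6 * scale)

    def test_delta_irf_limit_is_step_multiexponential(self):
        t = np.concatenate([np.linspace(-1, -0.01, 20), np.linspace(0.01, 50, 200)])
        comps = [ExpComponent(0.5, -0.6), ExpComponent(20.0, -0.4)]
        narrow = convolved_multiexp(t, comps, IRFSpec(1e-6))
        step = np.where(
            t >= 0, -0.6 * np.exp(-np.clip(t, 0, None) / 0.5) - 0.4 * np.exp(-np.clip(t, 0, None) / 20.0), 0.0
        )
        assert np.max(np.abs(narrow - step)) < 1e-8

    def test_long_time_log_slope_equals_decay_rate(self):
        tau, offset = 10.0, 0.02
        t = np.linspace(60, 100, 400)
        y = convolved_multiexp(t, [ExpComponent(tau, -1.0)], IRFSpec(0.12), offset)
        slope = np.polyfit(t, np.log(np.abs(y - offset)), 1)[0]
        assert slope == pytest.approx(-1 / tau, rel=1e-6)

    def test_stable_at_extreme_delay_width_ratios(self):
        # long delays with a fast component must not overflow
        t = np.array([-1.0, 0.0, 1.0, 100.0, 1500.0])
        y = convolved_multiexp(t, [ExpComponent(0.05, -1.0)], IRFSpec(0.12))
        assert np.all(np.isfinite(y))

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(InputError):
            ExpComponent(-1.0, 1.0)


class TestFitMultiexponential:
    def test_noiseless_single_exponential_exact(self):
        cfg = TraceConfig(taus_ps=(10.0,), fractions=(1.0,), irf=IRFSpec(1e-6), noise_rel=0.0)
        trace = gen_ta_trace(cfg)
        fit = fit_multiexponential(trace, 1, irf_fixed=IRFSpec(1e-6))
        assert fit.taus_ps[0] == pytest.approx(10.0, abs=1e-6)
        # with a delta IRF, t0 slides freely within one grid gap and trades
        # off against amplitude; A * exp(t0/tau) is the identified quantity
        identified = fit.components[0].amplitude * math.exp(fit.irf.t0_ps / fit.taus_ps[0])
        assert identified == pytest.approx(-1.0, abs=1e-6)

    def test_noiseless_biexponential_recovered(self):
        cfg = TraceConfig(taus_ps=(1.0, 100.0), fractions=(0.5, 0.5), noise_rel=0.0)
        fit = fit_multiexponential(gen_ta_trace(cfg), 2, irf_fixed=IRFSpec(0.12))
        assert fit.taus_ps[0] == pytest.approx(1.0, rel=1e-3)
        assert fit.taus_ps[1] == pytest.approx(100.0, rel=1e-3)

    def test_aggregate_preset_taus_recovered_within_ten_percent(self, irf120):
        taus = np.array(
            [fit_multiexponential(gen_ta_trace(preset("np1s_gsb"), seed=s), 3, irf_fixed=irf120).taus_ps
             for s in range(1, 6)]
        )
        np.testing.assert_allclose(taus.mean(axis=0), [0.43, 7.73, 179.0], rtol=0.10)

    def test_free_irf_width_recovered(self):
        cfg = TraceConfig(taus_ps=(5.0, 150.0), fractions=(0.6, 0.4), noise_rel=0.0)
        fit = fit_multiexponential(gen_ta_trace(cfg), 2, irf_fixed=None)
        assert fit.irf.fwhm_ps == pytest.approx(0.12, rel=0.05)

    def test_recovery_bias_small_for_separated_taus(self, irf120):
        """τ ratio >= 5 at 1% noise: per-τ bias < 5%, fraction bias < 0.02."""
        cfg = TraceConfig(taus_ps=(2.0, 50.0), fractions=(0.7, 0.3), noise_rel=0.01)
        taus, fracs = [], []
        for seed in range(1, 31):
            fit = fit_multiexponential(gen_ta_trace(cfg, seed=seed), 2, irf_fixed=irf120)
            taus.append(fit.taus_ps)
            fracs.append(fit.fractions)
        np.testing.assert_allclose(np.mean(taus, axis=0), [2.0, 50.0], rtol=0.05)
        np.testing.assert_allclose(np.mean(fracs, axis=0), [0.7, 0.3], atol=0.02)

    def test_n_out_of_range_rejected(self, irf120):
        trace = gen_ta_trace(preset("np1s_gsb"), seed=1)
        with pytest.raises(ConfigError):
            fit_multiexponential(trace, 5, irf_fixed=irf120)


class TestAmplitudeFractions:
    def test_equal_amplitudes(self):
        comps = (ExpComponent(1.0, -0.5), ExpComponent(10.0, -0.5))
        assert amplitude_fractions(comps) == pytest.approx([0.5, 0.5])

    def test_hand_arithmetic(self):
        comps = (ExpComponent(0.5, -0.8), ExpComponent(8.0, -0.15), ExpComponent(200.0, -0.05))
        assert amplitude_fractions(comps) == pytest.approx([0.80, 0.15, 0.05])

    def test_invariant_under_trace_gain(self, irf120):
        trace = gen_ta_trace(preset("np3s_gsb"), seed=3)
        scaled = KineticTrace(trace.delays_ps, 7.5 * trace.delta_od, trace.probe_nm)
        f1 = fit_multiexponential(trace, 3, irf_fixed=irf120).fractions
        f2 = fit_multiexponential(scaled, 3, irf_fixed=irf120).fractions
        np.testing.assert_allclose(f1, f2, atol=1e-6)

    def test_long_component_fraction_recovered(self, irf120):
        """Low-aggregation preset: monomer-fluorescence share near 20.2%."""
        fr = [
            fit_multiexponential(gen_ta_trace(preset("np3s_gsb"), seed=s), 3, irf_fixed=irf120).fractions[-1]
            for s in range(1, 11)
        ]
        assert np.mean(fr) == pytest.approx(0.202, abs=0.02)


class TestSelectComponentCount:
    @pytest.mark.parametrize(
        "preset_name, expected_n",
        [("f4_thf_gsb", 2), ("np1s_gsb", 3)],
    )
    def test_study_presets_select_published_counts(self, irf120, preset_name, expected_n):
        cfg = dataclasses.replace(preset(preset_name), noise_rel=0.005)
        hits = sum(
            select_component_count(gen_ta_trace(cfg, seed=s), max_n=3, irf_fixed=irf120).chosen_n
            == expected_n
            for s in range(1, 11)
        )
        assert hits >= 9  # >= 90% of seeds

    def test_pure_single_exponential_selects_one(self, irf120):
        cfg = TraceConfig(taus_ps=(15.0,), fractions=(1.0,), noise_rel=0.005)
        sel = select_component_count(gen_ta_trace(cfg, seed=1), max_n=3, irf_fixed=irf120)
        assert sel.chosen_n == 1
        assert set(sel.candidates) == {1, 2, 3}


class TestClassification:
    @pytest.mark.parametrize(
        "tau, channel",
        [
            (0.43, DecayChannel.INTER_NR),
            (7.7, DecayChannel.DIMER_EMISSION),
            (179.0, DecayChannel.MONOMER_FLUORESCENCE),
            (0.98, DecayChannel.INTER_NR),
            (11.6, DecayChannel.DIMER_EMISSION),
            (496.0, DecayChannel.MONOMER_FLUORESCENCE),
        ],
    )
    def test_default_tau_windows(self, tau, channel):
        assert ClassificationRules().label(tau) is channel

    def test_relabels_fit_components(self, irf120):
        fit = fit_multiexponential(gen_ta_trace(preset("np1s_gsb"), seed=1), 3, irf_fixed=irf120)
        labelled = classify_decay_components(fit)
        assert [c.label for c in labelled.components] == [
            DecayChannel.INTER_NR,
            DecayChannel.DIMER_EMISSION,
            DecayChannel.MONOMER_FLUORESCENCE,
        ]


class TestLifetimeConsistency:
    def _fit_with_long(self, tau_long):
        comps = (ExpComponent(1.0, -0.5), ExpComponent(tau_long, -0.5))
        return classify_decay_components(
            MultiExpFit(comps, IRFSpec(0.12), 0.0, 0.0)
        )

    def test_published_pair_passes(self):
        report = lifetime_consistency(self._fit_with_long(496.0), 435.0)
        assert report.consistent and report.relative_difference == pytest.approx(0.1402, abs=1e-3)

    def test_exact_match_zero_difference(self):
        report = lifetime_consistency(self._fit_with_long(435.0), 435.0)
        assert report.consistent and report.relative_difference == 0.0

    def test_large_mismatch_fails(self):
        assert not lifetime_consistency(self._fit_with_long(100.0), 435.0).consistent

    def test_no_long_component_reported_inconsistent(self):
        comps = (ExpComponent(0.5, -0.5), ExpComponent(8.0, -0.5))
        fit = classify_decay_components(MultiExpFit(comps, IRFSpec(0.12), 0.0, 0.0))
        report = lifetime_consistency(fit, 435.0)
        assert not report.consistent and report.tau_long_ps is None


class TestTraceValidation:
    def test_requires_negative_and_positive_delays(self):
        t = np.linspace(0.1, 10, 30)
        with pytest.raises(InputError):
            KineticTrace(t, np.exp(-t))

    def test_default_grid_spans_study_range(self):
        t = default_delay_grid()
        assert t[0] == -1.0 and t[-1] == pytest.approx(1500.0)
        assert np.all(np.diff(t) > 0)
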