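"""Six-parameter log-logistic model: evaluation, fitting, hook decisions."""

import math

import numpy as np
import pytest

from hookdetect.calls import STATUS_INSUFFICIENT_TAIL, STATUS_NEGATIVE_REACTION, STATUS_OK
from hookdetect.curve import AmplificationCurve
from hookdetect.hookregnl import (InsufficientDataError, fit_l6, hookregnl_call,
                                  l6_model)
from hookdetect.synth import CurveSpec, generate


def direct_l6(x, b, c, d, e, f, k):
    """Independent direct transcription of the model formula."""
    return c + k * x + (d - c) / (1.0 + math.exp(b * (math.log(x) - math.log(e)))) ** f


class TestModel:
    def test_midpoint_identity(self):
        assert l6_model(20.0, b=-8, c=0, d=1, e=20, f=1, k=0) == pytest.approx(0.5)

    def test_collapsed_sigmoid_pure_linear_term(self):
        assert l6_model(10.0, b=-7, c=0, d=0, e=20, f=1.3, k=0.01) == pytest.approx(0.1)

    def test_matches_direct_transcription(self):
        params = dict(b=-10, c=0.1, d=1.0, e=22, f=0.7, k=-0.004)
        got = l6_model(35.0, **params)
        assert got == pytest.approx(direct_l6(35.0, **params), abs=1e-12)
        xs = np.arange(1, 46, dtype=float)
        np.testing.assert_allclose(l6_model(xs, **params),
                                   [direct_l6(x, **params) for x in xs], atol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            l6_model(0.0, b=-8, c=0, d=1, e=20, f=1, k=0)
        with pytest.raises(ValueError):
            l6_model(5.0, b=-8, c=0, d=1, e=-1, f=1, k=0)
        with pytest.raises(ValueError):
            l6_model(5.0, b=-8, c=0, d=1, e=20, f=0, k=0)

    def test_extreme_steepness_does_not_overflow(self):
        vals = l6_model(np.arange(1, 46, dtype=float), b=-500, c=0, d=1, e=20, f=1, k=0)
        assert np.all(np.isfinite(vals))


class TestFit:
    def test_noise_free_zero_drift_ci_contains_zero(self):
        curve, _ = generate(CurveSpec(shape="sigmoid", noise_sd=0.0))
        fit = fit_l6(curve)
        assert fit.converged
        assert abs(fit.k) < 1e-6
        assert fit.k_ci_low <= 0.0 <= fit.k_ci_high

    def test_noise_free_parameter_recovery(self):
        true = dict(steepness=-9.0, baseline=0.1, amplitude=1.2, midpoint=22.0,
                    asymmetry=0.8, drift=-0.004)
        curve, _ = generate(CurveSpec(shape="hook", noise_sd=0.0, **true))
        fit = fit_l6(curve, normalize=False)
        assert fit.converged
        assert fit.b == pytest.approx(true["steepness"], rel=1e-4)
        assert fit.c == pytest.approx(true["baseline"], rel=1e-4)
        assert fit.d == pytest.approx(true["baseline"] + true["amplitude"], rel=1e-4)
        assert fit.e == pytest.approx(true["midpoint"], rel=1e-4)
        assert fit.f == pytest.approx(true["asymmetry"], rel=1e-4)
        assert fit.k == pytest.approx(true["drift"], rel=1e-4)

    def test_noisy_drift_recovery_with_exclusive_ci(self):
        curve, _ = generate(CurveSpec(shape="hook", drift=-0.005, noise_sd=1e-3,
                                      seed=3))
        fit = fit_l6(curve, normalize=False)
        assert fit.converged
        assert fit.k == pytest.approx(-0.005, abs=0.002)
        assert fit.k_ci_high < 0.0

    def test_flat_noise_never_spuriously_negative(self, rng):
        x = np.arange(1, 46, dtype=float)
        for seed in range(25):
            y = 0.5 + np.random.default_rng(seed).normal(0, 0.01, 45)
            fit = fit_l6(AmplificationCurve("F", x, y), normalize=False)
            if fit.converged:
                assert not (fit.k_ci_high < 0.0), f"spurious negative CI at seed {seed}"

    def test_too_few_points_raise(self):
        x = np.arange(1, 15, dtype=float)
        y = np.linspace(0, 1, 14)
        with pytest.raises(InsufficientDataError):
            fit_l6(AmplificationCurve("S", x, y), trim=5)


class TestCall:
    def test_flat_plateau_sigmoid_not_hook(self):
        curve, _ = generate(CurveSpec(shape="sigmoid", noise_sd=0.0))
        call = hookregnl_call(curve)
        assert call.hook is False

    def test_hook_curve_detected(self):
        curve, _ = generate(CurveSpec(shape="hook", drift=-0.008, noise_sd=1e-3,
                                      seed=1))
        call = hookregnl_call(curve)
        assert call.hook is True and call.status == STATUS_OK
        assert call.p_value is None  # CI-only decision
        assert call.ci_high < 0.0

    def test_negative_reaction_gated(self, rng):
        x = np.arange(1, 41, dtype=float)
        call = hookregnl_call(AmplificationCurve("N", x, rng.normal(0, 1, 40)))
        assert call.status == STATUS_NEGATIVE_REACTION and call.hook is False

    def test_short_curve_insufficient(self):
        curve, _ = generate(CurveSpec(shape="hook", drift=-0.01, noise_sd=0.0,
                                      n_cycles=14, midpoint=12, steepness=-30))
        call = hookregnl_call(curve)
        assert call.status == STATUS_INSUFFICIENT_TAIL and call.hook is False

    def test_decision_invariant_under_positive_scaling(self, rng):
        for seed in range(15):
            shape = "hook" if seed % 2 else "sigmoid"
            drift = -0.01 if shape == "hook" else 0.0
            curve, _ = generate(CurveSpec(shape=shape, drift=drift,
                                          noise_sd=0.003, seed=seed))
            a = float(rng.uniform(0.2, 30))
            scaled = curve.with_fluorescence(a * curve.fluorescence)
            assert hookregnl_call(curve).hook == hookregnl_call(scaled).hook
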