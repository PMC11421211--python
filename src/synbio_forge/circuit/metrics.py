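"""Adaptation metrics and the optimization loss.

Following the step-input framework for biochemical adaptation, a circuit's
response is summarized by its *sensitivity* (relative peak excursion per
relative input change) and its *precision error* (relative steady-state
shift per relative input change):

    sensitivity     = (|O_peak − O1| / O1) / (|u2 − u1| / u1)
    precision_error = (|O2  − O1| / O1) / (|u2 − u1| / u1)

with O1 the pre-step output steady state, O_peak the largest post-step
deviation (earliest in case of ties), and O2 the output at the horizon.
Perfect adaptation means precision_error → 0 with sensitivity bounded away
from zero.  The training loss is the smooth scalar

    loss = precision_error² + w · softplus(s_min − sensitivity)

which drives the steady-state shift to zero while penalizing circuits whose
transient response falls below the target sensitivity ``s_min``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import StepInput, Trajectory

__all__ = [
    "AdaptationResult", "DegenerateBaselineError", "NotSteadyError",
    "adaptation_metrics", "adaptation_loss", "softplus",
    "STEADY_DRIFT_TOL", "PENALTY_LOSS",
]

STEADY_DRIFT_TOL = 1e-4  # relative output drift allowed over the last 10% of the pre-step window
PENALTY_LOSS = 1e3  # score for circuits that never settle before the step


class DegenerateBaselineError(ValueError):
    """Pre-step output steady state is zero; relative metrics are undefined."""


class NotSteadyError(ValueError):
    """The output had not reached steady state before the input step."""


@dataclass(frozen=True)
class AdaptationResult:
    O1: float
    O_peak: float
    O2: float
    sensitivity: float
    precision_error: float
    loss: float
    peak_time: float = np.nan


def softplus(x):
    # overflow-safe: softplus(x) = max(x, 0) + log1p(exp(-|x|))
    x = np.asarray(x, dtype=float)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def _metric_indices(times: np.ndarray, inp: StepInput) -> tuple[int, int]:
    i_step = int(np.argmin(np.abs(times - inp.t_step)))
    if abs(times[i_step] - inp.t_step) > 1e-9 * max(1.0, inp.t_step):
        raise ValueError("trajectory grid does not contain t_step")
    i_drift = int(np.argmin(np.abs(times - 0.9 * inp.t_step)))
    return i_step, i_drift


def _raw_metrics(y: np.ndarray, times: np.ndarray, inp: StepInput):
    """Shared metric geometry; returns (i1, m, O1, O_peak, O2, drift)."""
    i1, i_drift = _metric_indices(times, inp)
    O1 = y[i1]
    drift = abs(O1 - y[i_drift]) / max(abs(O1), 1e-300)
    dev = np.abs(y[i1:] - O1)
    m = i1 + int(np.argmax(dev))  # argmax takes the earliest tie
    return i1, m, O1, y[m], y[-1], drift


def adaptation_metrics(traj: Trajectory, inp: StepInput, output_index: int,
                       s_min: float = 0.5, w: float = 1.0) -> AdaptationResult:
    """Sensitivity, precision error and loss of one simulated response.

    Raises :class:`NotSteadyError` if the output still drifted by more than
    ``STEADY_DRIFT_TOL`` (relative) over the last 10% of the pre-step window,
    and :class:`DegenerateBaselineError` if the pre-step steady state is 0.
    """
    if inp.u1 == inp.u2:
        raise ValueError("adaptation metrics need a genuine step (u2 != u1)")
    y = traj.output(output_index)
    i1, m, O1, O_peak, O2, drift = _raw_metrics(y, traj.times, inp)
    if drift >= STEADY_DRIFT_TOL:
        raise NotSteadyError(
            f"output drifted by {drift:.2e} (tol {STEADY_DRIFT_TOL}) before the step")
    if O1 == 0.0:
        raise DegenerateBaselineError("pre-step output steady state is zero")
    rel_u = abs(inp.u2 - inp.u1) / inp.u1
    sensitivity = abs(O_peak - O1) / abs(O1) / rel_u
    precision_error = abs(O2 - O1) / abs(O1) / rel_u
    loss = float(adaptation_loss(sensitivity, precision_error, s_min=s_min, w=w))
    return AdaptationResult(
        O1=float(O1), O_peak=float(O_peak), O2=float(O2),
        sensitivity=float(sensitivity), precision_error=float(precision_error),
        loss=loss, peak_time=float(traj.times[m]),
    )


def adaptation_loss(sensitivity, precision_error, s_min: float = 0.5, w: float = 1.0):
    """precision_error² + w·softplus(s_min − sensitivity); smooth everywhere."""
    if w <= 0 or s_min <= 0:
        raise ValueError("need w > 0 and s_min > 0")
    return np.asarray(precision_error) ** 2 + w * softplus(s_min - np.asarray(sensitivity))


def loss_and_gradient_from_tangents(y: np.ndarray, S: np.ndarray, times: np.ndarray,
                                    inp: StepInput, s_min: float, w: float):
    """Loss and its gradient w.r.t. the tangent parameterization.

    ``S[t]`` is d y(t)/d θ.  Returns (loss, grad, result, penalized): when
    the pre-step steady-state check fails or the baseline degenerates the
    circuit receives the flat penalty loss with a zero gradient instead of
    raising, so one bad batch member cannot abort the others.
    """
    i1, m, O1, O_peak, O2, drift = _raw_metrics(y, times, inp)
    P = S.shape[1]
    if drift >= STEADY_DRIFT_TOL or O1 <= 0.0:
        return PENALTY_LOSS, np.zeros(P), None, True
    rel_u = abs(inp.u2 - inp.u1) / inp.u1
    S1, Sm, S2 = S[i1], S[m], S[-1]
    sens = abs(O_peak - O1) / (O1 * rel_u)
    prec = abs(O2 - O1) / (O1 * rel_u)
    sgn_p = np.sign(O_peak - O1)
    sgn_2 = np.sign(O2 - O1)
    g_sens = (sgn_p * (Sm - S1) * O1 - abs(O_peak - O1) * S1) / (O1**2 * rel_u)
    g_prec = (sgn_2 * (S2 - S1) * O1 - abs(O2 - O1) * S1) / (O1**2 * rel_u)
    loss = float(adaptation_loss(sens, prec, s_min=s_min, w=w))
    sig = 1.0 / (1.0 + np.exp(-(s_min - sens)))
    grad = 2.0 * prec * g_prec - w * sig * g_sens
    result = AdaptationResult(
        O1=float(O1), O_peak=float(O_peak), O2=float(O2), sensitivity=float(sens),
        precision_error=float(prec), loss=loss, peak_time=float(times[m]),
    )
    return loss, grad, result, False
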