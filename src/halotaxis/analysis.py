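"""Classification of methanol-release patterns and CheYp adaptation metrics.

The experimental literature distinguishes two qualitative methanol-release
behaviors.  In the Halobacterium-type pattern, demethylation (methanol
release) increases transiently at *every* stimulus transition — attractant
or repellent, on or off.  In the E. coli-type pattern, release decreases
transiently on attractant stimulation and increases on repellent
stimulation (off-transitions mirrored, since removing an attractant acts
like a repellent step and vice versa).  These operations turn a simulated
(or measured) release trace into those discrete labels, and quantify the
excitation and adaptation of a CheYp trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DIRECTIONS",
    "PATTERNS",
    "TransitionResponse",
    "classify_transition",
    "classify_pattern",
    "AdaptationMetrics",
    "adaptation_metrics",
]

DIRECTIONS = ("attractant_on", "attractant_off", "repellent_on", "repellent_off")
PATTERNS = ("halobacterium", "ecoli", "ecoli_inverted", "flat", "other")

#: expected response sign of the E. coli-type pattern per transition;
#: off-transitions mirror the on-transitions (stimulus relief)
_ECOLI_SIGN = {
    "attractant_on": -1,
    "attractant_off": +1,
    "repellent_on": +1,
    "repellent_off": -1,
}


@dataclass(frozen=True)
class TransitionResponse:
    """Sign and size of the transient release response at one transition."""

    t_transition: float
    direction: str
    response: str  # positive | negative | flat
    amplitude: float  # |peak deviation| / baseline

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.response not in ("positive", "negative", "flat"):
            raise ValueError("response must be positive, negative, or flat")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def classify_transition(
    t: np.ndarray,
    series: np.ndarray,
    t_transition: float,
    direction: str,
    window: float = 120.0,
    epsilon: float = 0.05,
) -> TransitionResponse:
    """Classify the transient response of a release trace at one transition.

    The baseline is the mean over [t_transition - window, t_transition); the
    response is the signed extremal deviation over [t_transition,
    t_transition + window], relative to the baseline.  Deviations below
    ``epsilon`` (relative) are flat.  The pre-window must be
    quasi-stationary (coefficient of variation below epsilon), otherwise the
    trace was not adapted long enough before the transition.
    """
    t = np.asarray(t, dtype=float)
    series = np.asarray(series, dtype=float)
    pre = (t >= t_transition - window) & (t < t_transition)
    post = (t >= t_transition) & (t <= t_transition + window)
    if not pre.any() or not post.any():
        raise ValueError("series does not cover the transition window")
    baseline = float(series[pre].mean())
    if baseline <= 0:
        raise ValueError("release baseline must be positive")
    cv = float(series[pre].std() / baseline)
    if cv >= epsilon:
        raise ValueError(
            f"pre-transition baseline not stationary (CV {cv:.3f} >= {epsilon}); "
            "extend the pre-equilibration or the inter-stimulus spacing"
        )
    deviations = series[post] - baseline
    extremum = float(deviations[np.argmax(np.abs(deviations))])
    amplitude = abs(extremum) / baseline
    if amplitude < epsilon:
        response = "flat"
    else:
        response = "positive" if extremum > 0 else "negative"
    return TransitionResponse(t_transition, direction, response, amplitude)


def classify_pattern(responses) -> str:
    """Map a set of transition responses to a release-pattern label.

    halobacterium: every transition is a transient increase;
    ecoli: attractant transitions decrease, repellent transitions increase
    (off-transitions mirrored); ecoli_inverted: the ecoli mapping with all
    signs flipped; flat: no transition responds; other: anything else.
    """
    responses = list(responses)
    if not responses:
        raise ValueError("at least one transition response is required")
    if all(r.response == "flat" for r in responses):
        return "flat"
    if all(r.response == "positive" for r in responses):
        return "halobacterium"
    signs = {"positive": 1, "negative": -1, "flat": 0}
    if all(signs[r.response] == _ECOLI_SIGN[r.direction] for r in responses):
        return "ecoli"
    if all(signs[r.response] == -_ECOLI_SIGN[r.direction] for r in responses):
        return "ecoli_inverted"
    return "other"


@dataclass(frozen=True)
class AdaptationMetrics:
    """Excitation and adaptation summary of a CheYp trace around one step."""

    peak_sign: int
    peak_amplitude: float  # |peak - baseline|
    precision: float  # fraction of the deviation reversed by t_end
    half_time: float | None  # first time the deviation halves after the peak
    adapted: bool  # |CheYp(t_end) - baseline| < adapted_tol * baseline


def adaptation_metrics(
    t: np.ndarray,
    che_yp: np.ndarray,
    t_step: float,
    t_end: float,
    adapted_tol: float = 0.05,
) -> AdaptationMetrics:
    """Quantify the CheYp response to a sustained step applied at ``t_step``.

    The trace must be stationary before the step; ``t_end`` should lie long
    after the adaptation transient.  Precision is
    1 - |CheYp(t_end) - baseline| / |peak - baseline| (1.0 by convention for
    a flat trace).
    """
    t = np.asarray(t, dtype=float)
    che_yp = np.asarray(che_yp, dtype=float)
    pre = t < t_step
    seg = (t >= t_step) & (t <= t_end)
    if not pre.any() or not seg.any():
        raise ValueError("trace does not cover the step and evaluation window")
    baseline = float(che_yp[pre].mean())
    deviations = che_yp[seg] - baseline
    i_peak = int(np.argmax(np.abs(deviations)))
    peak_dev = float(deviations[i_peak])
    end_dev = float(np.interp(t_end, t, che_yp) - baseline)
    scale = max(abs(baseline), 1e-300)
    if abs(peak_dev) / scale < 1e-12:
        return AdaptationMetrics(0, 0.0, 1.0, None, True)
    precision = 1.0 - abs(end_dev) / abs(peak_dev)
    half_time = None
    t_seg = t[seg]
    after_peak = np.arange(len(deviations)) > i_peak
    crossed = after_peak & (np.abs(deviations) <= abs(peak_dev) / 2.0)
    if crossed.any():
        half_time = float(t_seg[np.argmax(crossed)] - t_seg[i_peak])
    adapted = abs(end_dev) < adapted_tol * abs(baseline)
    return AdaptationMetrics(
        peak_sign=1 if peak_dev > 0 else -1,
        peak_amplitude=abs(peak_dev),
        precision=precision,
        half_time=half_time,
        adapted=adapted,
    )
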