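"""Detection of the maximal horizontal deceleration phase.

The deceleration phase starts immediately after the maximum velocity of a
sprint-then-stop trial and ends at the lowest velocity that follows. The
early-deceleration metric is the mean (secant) acceleration from the peak
to the instant speed first falls to 50% of the peak; it is negative by
convention.

Radar speed is noisy, so landmarks are located on a centered moving-average
copy of the trace (window 5 samples by default). The peak *value* is the
smoothed maximum; the peak *time* is refined by extending the least-squares
line of the deceleration limb (smoothed speeds between 55% and 92% of the
peak) back to the peak level. This refinement matters: near the end of a
30 m sprint the speed curve is almost flat, so the raw argmax of a noisy
trace can land hundreds of milliseconds before deceleration actually
begins, which would systematically dilute the secant estimate. Anchoring
both secant endpoints on the deceleration line makes the estimator unbiased
for a constant planted deceleration.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError, PhaseNotFoundError
from .models import DecelResult, VelocityTrace

_LIMB_LO = 0.55
_LIMB_HI = 0.92


def _smooth_valid(speeds: np.ndarray, window: int) -> tuple[np.ndarray, int]:
    """Centered moving average, 'valid' mode; returns (smoothed, left offset)."""
    if window <= 1:
        return speeds.astype(float), 0
    kernel = np.full(window, 1.0 / window)
    return np.convolve(speeds, kernel, mode="valid"), (window - 1) // 2


def detect_decel_phase(trace: VelocityTrace, smooth_window: int = 5,
                       method: str = "secant") -> DecelResult:
    """Locate the deceleration phase and compute its mean decelerations.

    Parameters
    ----------
    trace:
        Sprint-then-decelerate radar trace.
    smooth_window:
        Moving-average window (samples) used for landmark detection.
    method:
        ``"secant"`` (default): decel_early is the secant slope from the
        peak to the 50%-of-peak instant. ``"regression"``: decel_early is
        the least-squares slope of the smoothed deceleration limb instead.

    Raises
    ------
    PhaseNotFoundError
        If the speed never falls below 50% of its maximum after the peak.
    """
    if smooth_window < 1:
        raise InputError("smooth_window must be >= 1")
    if method not in ("secant", "regression"):
        raise InputError("method must be 'secant' or 'regression'")
    vs, off = _smooth_valid(trace.speeds, smooth_window)
    ts = trace.times[off:off + len(vs)]

    i_pk = int(np.argmax(vs))
    v_peak = float(vs[i_pk])
    half = 0.5 * v_peak

    below = np.nonzero(vs[i_pk + 1:] < half)[0]
    if len(below) == 0:
        raise PhaseNotFoundError(
            "speed never falls below 50% of its maximum after the peak")
    j = i_pk + 1 + int(below[0])
    # linear interpolation between the straddling smoothed samples
    frac = (vs[j - 1] - half) / (vs[j - 1] - vs[j])
    t_half = float(ts[j - 1] + frac * (ts[j] - ts[j - 1]))

    # deceleration limb: smoothed samples clearly inside the decline
    dt = 1.0 / trace.sampling_hz
    limb = np.arange(i_pk + 1, j + 1)
    in_band = limb[(vs[limb] <= _LIMB_HI * v_peak) & (vs[limb] >= _LIMB_LO * v_peak)]
    if len(in_band) >= 3:
        limb = in_band
    slope, intercept = np.polyfit(ts[limb], vs[limb], 1)

    def _peak_time(b, a):
        if b < 0:
            return float(np.clip((v_peak - a) / b, ts[i_pk], t_half - dt / 2.0))
        return float(ts[i_pk])

    t_peak = _peak_time(slope, intercept)
    # second pass: the moving average smears the speed corner, so limb
    # samples within one window of it bias the line flat; refit without them
    if smooth_window > 1:
        clear = limb[ts[limb] >= t_peak + smooth_window * dt]
        if len(clear) >= 3:
            slope, intercept = np.polyfit(ts[clear], vs[clear], 1)
            t_peak = _peak_time(slope, intercept)

    tail = vs[i_pk:]
    i_end = i_pk + int(np.argmin(tail))
    v_end = float(vs[i_end])
    t_end = float(ts[i_end])

    secant = (half - v_peak) / (t_half - t_peak)
    decel_early = float(slope) if method == "regression" else float(secant)
    if not decel_early < 0:
        raise PhaseNotFoundError("no decelerating segment found after the peak")
    decel_overall = (v_end - v_peak) / max(t_end - t_peak, dt / 2.0)
    return DecelResult(v_peak=v_peak, t_peak=t_peak, v_end=v_end,
                       t_end=max(t_end, t_half), t_half=t_half,
                       decel_early=decel_early, decel_overall=float(decel_overall))
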