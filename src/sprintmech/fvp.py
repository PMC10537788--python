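"""Horizontal sprint force-velocity profiling from a velocity-time trace.

The pipeline is the field radar method: fit the mono-exponential speed model
v(t) = vmax (1 - exp(-(t - t0)/tau)) to the trace, evaluate the modelled
kinematics analytically on a fine grid, reconstruct the net horizontal
ground-reaction force

    FH(t) = m aH(t) + Faero(t),    Faero(t) = k (vH(t) - vw)^2

with the vertical force equal to body weight (FV = m g), and summarize the
linear force-velocity relation by its intercept F0, velocity-axis crossing
V0, slope Sfv and Pmax = F0 V0 / 4. Mechanical effectiveness is quantified
by the ratio of force RF = 100 FH / sqrt(FH^2 + FV^2), reported only for
t > 0.3 s after motion onset (the start-push phase is excluded), and by its
slope against speed, DRF.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import EstimationError, FitFailureError, InputError
from .models import (
    AeroModel,
    AthleteRecord,
    ForceProfile,
    GRAVITY,
    SplitTimes,
    SprintFVP,
    VelocityModel,
    VelocityTrace,
)

RF_ONSET_EXCLUSION_S = 0.3
"""RF and DRF are computed only for t > 0.3 s after motion onset."""

# multi-start grid for the nonlinear fit (offsets relative to the first sample)
_T0_STARTS = (0.0, 0.1, 0.2)
_TAU_STARTS = (0.8, 1.2, 1.6)


def _model_speed(ts: np.ndarray, vmax: float, tau: float, t0: float) -> np.ndarray:
    s = np.clip(ts - t0, 0.0, None)
    return vmax * -np.expm1(-s / tau)


def fit_velocity_model(trace: VelocityTrace) -> VelocityModel:
    """Least-squares fit of the mono-exponential sprint model.

    Multi-start trust-region least squares over (vmax, tau, t0) with an
    analytic Jacobian; t0 absorbs any constant shift of the time stamps, so
    the fit is invariant to re-zeroing the clock.

    Raises :class:`FitFailureError` (carrying the best residual sum of
    squares seen) on degenerate input or non-convergence.
    """
    t = trace.times
    v = trace.speeds
    if len(t) < 10:
        raise InputError("velocity-model fit needs at least 10 samples")
    ts = t - t[0]
    vmax0 = float(v.max())
    if vmax0 < 0.5:
        raise FitFailureError(
            "trace speeds are (near) zero; no sprint to fit", best_rss=float("inf"))

    def residuals(p):
        return _model_speed(ts, *p) - v

    def jacobian(p):
        vmax, tau, t0 = p
        s = np.clip(ts - t0, 0.0, None)
        e = np.exp(-s / tau)
        moving = (ts > t0).astype(float)
        return np.column_stack([
            -np.expm1(-s / tau),            # d/dvmax
            -vmax * e * s / tau**2,         # d/dtau
            -(vmax / tau) * e * moving,     # d/dt0 (s = t - t0 where moving)
        ])

    span = float(ts[-1])
    bounds = ([0.1, 0.05, 0.0], [3.0 * vmax0 + 1.0, 10.0, max(span / 2.0, 1.0)])

    # data-driven start: time to reach 63.2% of the observed peak
    idx63 = int(np.argmax(v >= 0.632 * vmax0))
    tau_smart = max(float(ts[idx63]), 0.2)
    starts = [(vmax0, tau_smart, 0.0)]
    starts += [(vmax0, tau, t0) for t0 in _T0_STARTS for tau in _TAU_STARTS]

    best = None
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            res = least_squares(residuals, p0, jac=jacobian, bounds=bounds,
                                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # numerical failure on this start only
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        rss = float("inf") if best is None else 2.0 * float(best.cost)
        raise FitFailureError("velocity-model fit did not converge", best_rss=rss)
    vmax, tau, t0 = best.x
    rss = 2.0 * float(best.cost)
    if vmax < 1.0 or vmax > 2.0 * vmax0 + 5.0:
        raise FitFailureError(
            f"velocity-model fit implausible (vmax={vmax:.2f} m/s)", best_rss=rss)
    return VelocityModel(vmax=float(vmax), tau=float(tau),
                         t0=float(t0 + t[0]), rss=rss)


def aero_coefficient(athlete: AthleteRecord, temperature_c: float = 20.0,
                     pressure_mmhg: float = 760.0, *, wind_mps: float = 0.0,
                     cd: float = 0.9, k_override: float | None = None) -> AeroModel:
    """Estimate the aerodynamic friction coefficient k (kg/m).

    Air density from ambient conditions, frontal area from stature and body
    mass via the Du Bois body-surface-area scaling:

        rho = 1.293 (P/760) (273 / (273 + T))
        Af  = 0.266 * (0.2025 h^0.725 m^0.425)
        k   = 0.5 rho Af Cd      (Cd = 0.9 by default)

    Every component is overridable; ``k_override`` short-circuits the
    computation entirely (e.g. k = 0 for drag-free analyses).
    """
    if pressure_mmhg <= 0:
        raise InputError("pressure must be positive")
    if temperature_c <= -273:
        raise InputError("temperature below absolute zero")
    rho = 1.293 * (pressure_mmhg / 760.0) * (273.0 / (273.0 + temperature_c))
    af = 0.266 * (0.2025 * athlete.stature**0.725 * athlete.mass**0.425)
    k = 0.5 * rho * af * cd if k_override is None else float(k_override)
    return AeroModel(k=k, vw=wind_mps, rho=rho, Af=af, Cd=cd)


def compute_forces(model: VelocityModel, athlete: AthleteRecord,
                   aero: AeroModel, grid_hz: float = 1000.0) -> ForceProfile:
    """Evaluate modelled horizontal/vertical/resultant forces and RF.

    The analytic model (not the noisy samples) is evaluated on a uniform
    grid from motion onset until the speed reaches 99.9% of vmax, so no
    numerical differentiation of raw radar data is involved.
    """
    if not grid_hz > 0:
        raise InputError("grid_hz must be positive")
    horizon = model.tau * np.log(1000.0)  # v reaches 99.9% vmax
    n = int(np.ceil(horizon * grid_hz)) + 1
    times = model.t0 + np.arange(n) / grid_hz
    v = model.speed(times)
    a = model.acceleration(times)
    fh = athlete.mass * a + aero.k * (v - aero.vw) ** 2
    fv = athlete.mass * aero.g
    fres = np.hypot(fh, fv)
    rf = np.where(times - model.t0 > RF_ONSET_EXCLUSION_S,
                  100.0 * fh / fres, np.nan)
    return ForceProfile(times=times, speeds_model=v, fh=fh, fv=fv, fres=fres,
                        rf=rf, onset_time=model.t0, mass=athlete.mass)


def estimate_fvp(profile: ForceProfile, athlete: AthleteRecord, *,
                 v_lo_frac: float = 0.3, v_hi_frac: float = 0.95) -> SprintFVP:
    """Summarize a force profile into the sprint force-velocity profile.

    The F-v line is the least-squares fit of FH/m against v over modelled
    samples with v between ``v_lo_frac`` and ``v_hi_frac`` of the peak speed
    and t > 0.3 s after onset (excluding both the start push and the
    near-asymptotic tail where aH ~ 0). F0_rel is its intercept, V0 its
    velocity-axis crossing, Sfv_rel its slope; Pmax_rel = F0_rel V0 / 4.
    RFmax and DRF come from the RF-v relation on the same t > 0.3 s domain.
    """
    v = profile.speeds_model
    vpk = float(v.max())
    if vpk - float(v.min()) < 1e-6:
        raise EstimationError("constant-speed profile: force-velocity line "
                              "is undefined")
    after_push = profile.times - profile.onset_time > RF_ONSET_EXCLUSION_S
    line_mask = after_push & (v >= v_lo_frac * vpk) & (v <= v_hi_frac * vpk)
    if line_mask.sum() < 3:
        raise EstimationError("too few samples in the force-velocity fitting "
                              "band; profile does not cover the acceleration")
    slope, intercept = np.polyfit(v[line_mask], profile.fh[line_mask] / profile.mass, 1)
    if slope >= 0:
        raise EstimationError("non-negative force-velocity slope; not a "
                              "sprint acceleration profile")
    f0_rel = float(intercept)
    v0 = float(-intercept / slope)
    rf_mask = np.isfinite(profile.rf)
    drf, _ = np.polyfit(v[rf_mask], profile.rf[rf_mask], 1)
    return SprintFVP(
        f0_abs=f0_rel * athlete.mass,
        f0_rel=f0_rel,
        v0=v0,
        sfv_rel=float(slope),
        pmax_rel=f0_rel * v0 / 4.0,
        pmax_abs=f0_rel * v0 / 4.0 * athlete.mass,
        rfmax=float(np.nanmax(profile.rf)),
        drf=float(drf),
        vmax_measured=vpk,
    )


def time_to_distance(model: VelocityModel, distance: float) -> float:
    """Time from motion onset to cover ``distance`` m, by bisection on the
    closed-form position function (|position error| < 1e-6 m)."""
    if distance <= 0:
        raise InputError("distance must be positive")
    lo, hi = 0.0, model.tau
    while model.position(model.t0 + hi) < distance:
        hi *= 2.0
        if hi > 1e6:
            raise EstimationError(f"distance {distance} m unreachable on the "
                                  "model's support")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if model.position(model.t0 + mid) < distance:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    t = 0.5 * (lo + hi)
    if abs(model.position(model.t0 + t) - distance) > 1e-6:
        raise EstimationError("bisection failed to invert the position function")
    return t


def split_times(model: VelocityModel,
                distances: Sequence[float] = (5.0, 15.0, 30.0)) -> SplitTimes:
    """Split times from motion onset for the requested distances (m)."""
    distances = tuple(float(d) for d in distances)
    if any(d <= 0 for d in distances) or any(
            b <= a for a, b in zip(distances, distances[1:])):
        raise InputError("distances must be positive and strictly increasing")
    times = tuple(time_to_distance(model, d) for d in distances)
    return SplitTimes(distances=distances, times=times)
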