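"""Synthetic cohorts, radar traces, and outcome variables with known truth.

The generators emulate a field-hockey testing session: each athlete runs a
maximal 30 m sprint recorded by a Doppler radar (nominally 46.9 Hz, speed
accuracy ±1.61 km/h, modelled as i.i.d. zero-mean Gaussian speed noise of
sd 1.61/3.6 ≈ 0.447 m/s), and a sprint-then-maximal-deceleration trial.
Sprint kinematics follow the mono-exponential model

    v(t) = vmax (1 - exp(-(t - t0)/tau)),  t >= t0

with a trigger delay t0 before motion onset. Cohort parameters are drawn
independently per athlete from Gaussians whose default moments reproduce the
descriptive statistics of an elite female field-hockey squad (n = 26,
V0 7.93 ± 0.47 m/s, body mass 63.1 ± 5.3 kg, stature 1.662 ± 0.041 m, early
deceleration −3.37 ± 0.87 m/s²), truncated at physiological floors by
resampling so the distributions stay smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .models import AthleteRecord, FeatureTable, TrueParams, VelocityTrace

RADAR_HZ = 46.9
"""Nominal radar sampling rate (Hz)."""

RADAR_NOISE_SD = 1.61 / 3.6
"""Radar speed accuracy ±1.61 km/h expressed as Gaussian sd in m/s."""

PARAM_NAMES = ("vmax", "tau", "t0", "mass", "stature", "decel_rate")

DEFAULT_MEANS: dict[str, float] = {
    "vmax": 7.93,       # m/s, asymptotic sprint speed
    "tau": 1.39,        # s, acceleration time constant (~V0 / relative F0)
    "t0": 0.2,          # s, radar trigger delay before first movement
    "mass": 63.1,       # kg
    "stature": 1.662,   # m
    "decel_rate": -3.37,  # m/s^2, maximal early deceleration
}

DEFAULT_SDS: dict[str, float] = {
    "vmax": 0.47,
    "tau": 0.09,
    "t0": 0.05,
    "mass": 5.3,
    "stature": 0.041,
    "decel_rate": 0.87,
}

# physiological truncation bounds enforced by resampling
_LOWER = {"vmax": 4.0, "tau": 0.5, "t0": 0.0, "mass": 40.0, "stature": 1.30,
          "decel_rate": -np.inf}
_UPPER = {"vmax": np.inf, "tau": np.inf, "t0": np.inf, "mass": np.inf,
          "stature": np.inf, "decel_rate": -0.5}

_POSITION_CYCLE = ("defender", "midfield", "forward")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort and its radar instrument."""

    n: int = 26
    seed: int = 0
    parameter_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEANS))
    parameter_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SDS))
    sampling_hz: float = RADAR_HZ
    noise_sd: float = RADAR_NOISE_SD

    def __post_init__(self):
        if self.n < 2:
            raise InputError(f"cohort size must be >= 2, got {self.n}")
        if not self.sampling_hz > 0:
            raise InputError("sampling_hz must be positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        unknown = set(self.parameter_means) - set(PARAM_NAMES)
        unknown |= set(self.parameter_sds) - set(PARAM_NAMES)
        if unknown:
            raise InputError(f"unknown parameters {sorted(unknown)}; "
                             f"valid names: {PARAM_NAMES}")
        for name, sd in self.parameter_sds.items():
            if sd < 0:
                raise InputError(f"sd for {name!r} must be >= 0, got {sd}")

    def mean(self, name: str) -> float:
        return float(self.parameter_means.get(name, DEFAULT_MEANS[name]))

    def sd(self, name: str) -> float:
        return float(self.parameter_sds.get(name, DEFAULT_SDS[name]))


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    """One Gaussian draw, resampled (not clipped) into [lo, hi]."""
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise InputError(
        f"truncation bounds [{lo}, {hi}] unreachable from N({mean}, {sd})")


def generate_cohort(spec: CohortSpec) -> list[tuple[AthleteRecord, TrueParams]]:
    """Draw a cohort of athletes with latent sprint/deceleration parameters.

    Deterministic in ``spec`` (including its seed): identical specs yield
    bitwise-identical cohorts. Parameters are drawn independently per
    athlete and truncated at physiological floors by resampling.
    """
    rng = np.random.default_rng(spec.seed)
    cohort = []
    for i in range(spec.n):
        draws = {
            name: _draw_truncated(rng, spec.mean(name), spec.sd(name),
                                  _LOWER[name], _UPPER[name])
            for name in PARAM_NAMES
        }
        athlete = AthleteRecord(
            athlete_id=f"ath{i + 1:03d}",
            mass=draws["mass"],
            stature=draws["stature"],
            position=_POSITION_CYCLE[i % len(_POSITION_CYCLE)],
        )
        params = TrueParams(
            vmax_true=draws["vmax"],
            tau_true=draws["tau"],
            t0_true=draws["t0"],
            mass=draws["mass"],
            stature=draws["stature"],
            decel_rate_true=draws["decel_rate"],
        )
        cohort.append((athlete, params))
    return cohort


def _noise_free_speed(t: np.ndarray, params: TrueParams) -> np.ndarray:
    s = np.clip(t - params.t0_true, 0.0, None)
    return params.vmax_true * -np.expm1(-s / params.tau_true)


def _noise_free_position(t: np.ndarray, params: TrueParams) -> np.ndarray:
    s = np.clip(t - params.t0_true, 0.0, None)
    return (params.vmax_true * s
            + params.vmax_true * params.tau_true * np.expm1(-s / params.tau_true))


def _finalize(times: np.ndarray, clean: np.ndarray, spec: CohortSpec,
              seed) -> VelocityTrace:
    rng = np.random.default_rng(seed)
    if spec.noise_sd > 0:
        speeds = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    else:
        speeds = clean.copy()
    np.clip(speeds, 0.0, None, out=speeds)
    return VelocityTrace(times, speeds, spec.sampling_hz)


def generate_sprint_trace(params: TrueParams, spec: CohortSpec,
                          duration: float, seed=0) -> VelocityTrace:
    """Simulate a radar trace of a maximal sprint of the given duration (s).

    The noise-free speed follows the mono-exponential model; Gaussian noise
    of sd ``spec.noise_sd`` is added and speeds are clipped at zero.
    ``duration`` must allow the athlete to reach >= 99% of vmax
    (duration >= t0 + 5 tau).
    """
    minimum = params.t0_true + 5.0 * params.tau_true
    if duration < minimum:
        raise InputError(
            f"duration {duration:.3f} s too short to reach the speed plateau; "
            f"need at least t0 + 5*tau = {minimum:.3f} s")
    n = int(np.floor(duration * spec.sampling_hz)) + 1
    times = np.arange(n) / spec.sampling_hz
    return _finalize(times, _noise_free_speed(times, params), spec, seed)


def generate_decel_trace(params: TrueParams, spec: CohortSpec, seed=0, *,
                         sprint_distance: float = 30.0, floor: float = 0.0,
                         tail: float = 0.5) -> VelocityTrace:
    """Simulate a sprint over ``sprint_distance`` m followed by a maximal
    constant deceleration at ``decel_rate_true`` down to ``floor`` m/s.

    The switch point is located on the noise-free position function; the
    trailing ``tail`` seconds stay constant at the floor. Sampling and noise
    follow the same contract as :func:`generate_sprint_trace`.
    """
    if params.decel_rate_true is None or not params.decel_rate_true < 0:
        raise InputError("decel_rate_true must be negative to simulate a "
                         "deceleration trial")
    if floor < 0:
        raise InputError("floor speed must be >= 0")
    t_switch = _time_to_distance(params, sprint_distance)
    v_switch = float(_noise_free_speed(np.array([t_switch]), params)[0])
    if v_switch <= floor:
        raise InputError("floor speed exceeds the speed at the switch point")
    t_floor = t_switch + (v_switch - floor) / -params.decel_rate_true
    duration = t_floor + tail
    n = int(np.floor(duration * spec.sampling_hz)) + 1
    times = np.arange(n) / spec.sampling_hz
    clean = _noise_free_speed(times, params)
    dec = times > t_switch
    clean[dec] = np.maximum(
        v_switch + params.decel_rate_true * (times[dec] - t_switch), floor)
    return _finalize(times, clean, spec, seed)


def _time_to_distance(params: TrueParams, distance: float) -> float:
    """Invert the noise-free position function by bisection (1e-9 m)."""
    if distance <= 0:
        raise InputError("distance must be positive")
    lo, hi = params.t0_true, params.t0_true + params.tau_true
    while _noise_free_position(np.array([hi]), params)[0] < distance:
        hi += params.tau_true
        if hi > 1e6:
            raise InputError("distance unreachable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _noise_free_position(np.array([mid]), params)[0] < distance:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)


def generate_outcomes(features: FeatureTable | "pd.DataFrame",
                      coefficients: Mapping[str, float], intercept: float,
                      noise_sd: float, seed: int) -> np.ndarray:
    """Planted-truth outcome vector y = intercept + X w + N(0, noise_sd).

    An empty coefficient map yields a pure-noise outcome (the null design).
    Unknown feature keys raise an error listing the valid columns.
    """
    frame = features.frame if isinstance(features, FeatureTable) else features
    unknown = set(coefficients) - set(frame.columns)
    if unknown:
        raise InputError(f"unknown feature(s) {sorted(unknown)}; "
                         f"valid columns: {list(frame.columns)}")
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    y = np.full(len(frame), float(intercept))
    for name, w in coefficients.items():
        y = y + w * frame[name].to_numpy(dtype=float)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(y))
    return y
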