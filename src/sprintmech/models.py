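"""Domain types for sprint mechanics analysis.

All quantities are SI unless the field name says otherwise: times in s,
speeds in m/s, forces in N (or N/kg when relative to body mass), power in
W/kg, RF (ratio of force) in percent, DRF in %·s/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError, InputError

GRAVITY = 9.81
"""Gravitational acceleration (m/s^2)."""

POSITIONS = ("defender", "midfield", "forward", "unknown")


@dataclass(frozen=True)
class AthleteRecord:
    """One athlete: identity, body mass (kg), stature (m), field position."""

    athlete_id: str
    mass: float
    stature: float
    position: str = "unknown"

    def __post_init__(self):
        if not self.mass > 0:
            raise InputError(f"mass must be positive, got {self.mass}")
        if not self.stature > 0:
            raise InputError(f"stature must be positive, got {self.stature}")
        if self.position not in POSITIONS:
            raise InputError(
                f"position must be one of {POSITIONS}, got {self.position!r}"
            )


@dataclass(frozen=True)
class TrueParams:
    """Latent per-athlete parameters behind a simulated radar trace.

    ``vmax_true`` is the asymptotic sprint speed (m/s), ``tau_true`` the
    acceleration time constant (s), ``t0_true`` the trigger delay before
    movement (s), and ``decel_rate_true`` the constant deceleration applied
    after the sprint phase (m/s^2, negative; ``None`` for sprint-only use).
    """

    vmax_true: float
    tau_true: float
    t0_true: float
    mass: float
    stature: float
    decel_rate_true: float | None = None

    def __post_init__(self):
        if not self.vmax_true > 0:
            raise InputError("vmax_true must be positive")
        if not self.tau_true > 0:
            raise InputError("tau_true must be positive")
        if self.t0_true < 0:
            raise InputError("t0_true must be non-negative")
        if not self.mass > 0:
            raise InputError("mass must be positive")
        if not self.stature > 0:
            raise InputError("stature must be positive")
        if self.decel_rate_true is not None and not self.decel_rate_true < 0:
            raise InputError(
                f"decel_rate_true must be negative, got {self.decel_rate_true}"
            )


class VelocityTrace:
    """A radar velocity-time trace: strictly increasing sample instants and
    non-negative horizontal speeds, with the instrument's nominal rate (Hz)."""

    __slots__ = ("times", "speeds", "sampling_hz")

    def __init__(self, times, speeds, sampling_hz: float):
        times = np.asarray(times, dtype=float)
        speeds = np.asarray(speeds, dtype=float)
        if times.ndim != 1 or speeds.ndim != 1 or len(times) != len(speeds):
            raise InputError("times and speeds must be 1-D arrays of equal length")
        if len(times) < 10:
            raise InputError(f"trace needs at least 10 samples, got {len(times)}")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(speeds)):
            raise InputError("trace contains non-finite values")
        if np.any(np.diff(times) <= 0):
            bad = int(np.argmax(np.diff(times) <= 0)) + 1
            raise InputError(f"times must be strictly increasing (sample {bad})")
        if np.any(speeds < 0):
            raise InputError("speeds must be non-negative")
        if not sampling_hz > 0:
            raise InputError("sampling_hz must be positive")
        self.times = times
        self.speeds = speeds
        self.sampling_hz = float(sampling_hz)

    def __len__(self):
        return len(self.times)

    def __repr__(self):
        return (
            f"VelocityTrace(n={len(self)}, span={self.times[-1] - self.times[0]:.2f}s,"
            f" vmax={self.speeds.max():.2f}m/s, {self.sampling_hz}Hz)"
        )


@dataclass(frozen=True)
class AeroModel:
    """Aerodynamic drag model: Faero = k (v - vw)^2 with k = rho Af Cd / 2."""

    k: float
    vw: float = 0.0
    rho: float = float("nan")
    Af: float = float("nan")
    Cd: float = float("nan")
    g: float = GRAVITY

    def __post_init__(self):
        if self.k < 0:
            raise InputError("aerodynamic coefficient k must be >= 0")
        if not self.g > 0:
            raise InputError("g must be positive")


@dataclass(frozen=True)
class VelocityModel:
    """Fitted mono-exponential sprint model
    v(t) = vmax (1 - exp(-(t - t0)/tau)) for t >= t0, 0 before."""

    vmax: float
    tau: float
    t0: float
    rss: float = 0.0

    def __post_init__(self):
        if not self.vmax > 0:
            raise InputError("vmax must be positive")
        if not self.tau > 0:
            raise InputError("tau must be positive")
        if self.t0 < 0:
            raise InputError("t0 must be non-negative")

    def speed(self, t) -> np.ndarray:
        """Model speed at time(s) ``t`` (same clock as the fitted trace)."""
        s = np.clip(np.asarray(t, dtype=float) - self.t0, 0.0, None)
        return self.vmax * -np.expm1(-s / self.tau)

    def position(self, t) -> np.ndarray:
        """Distance covered since motion onset at time(s) ``t``."""
        s = np.clip(np.asarray(t, dtype=float) - self.t0, 0.0, None)
        return self.vmax * s - self.vmax * self.tau * -np.expm1(-s / self.tau)

    def acceleration(self, t) -> np.ndarray:
        """Analytic horizontal acceleration a(t) = (vmax - v(t))/tau."""
        return (self.vmax - self.speed(t)) / self.tau


@dataclass(frozen=True)
class ForceProfile:
    """Modelled forces on a uniform grid over the acceleration phase.

    ``fv`` (vertical force, body weight) is constant; ``rf`` is NaN-masked
    before 0.3 s after motion onset, where the ratio of force is undefined
    by convention.
    """

    times: np.ndarray
    speeds_model: np.ndarray
    fh: np.ndarray
    fv: float
    fres: np.ndarray
    rf: np.ndarray
    onset_time: float
    mass: float


@dataclass(frozen=True)
class SprintFVP:
    """Sprint force-velocity profile.

    F0 is the force-axis intercept of the linear F-v relation, V0 its
    velocity-axis crossing, Sfv the slope, Pmax = F0 V0 / 4. RFmax is the
    maximal ratio of force after 0.3 s; DRF the slope of RF against speed.
    ``vmax_measured`` is the peak modelled speed, distinct from the
    theoretical asymptote V0.
    """

    f0_abs: float
    f0_rel: float
    v0: float
    sfv_rel: float
    pmax_rel: float
    pmax_abs: float
    rfmax: float
    drf: float
    vmax_measured: float

    def __post_init__(self):
        if abs(self.f0_rel + self.sfv_rel * self.v0) > 1e-6 * max(abs(self.f0_rel), 1.0):
            raise EstimationError("inconsistent profile: F0_rel != -Sfv_rel * V0")
        if abs(self.pmax_rel - self.f0_rel * self.v0 / 4.0) > 1e-6 * max(abs(self.pmax_rel), 1.0):
            raise EstimationError("inconsistent profile: Pmax_rel != F0_rel * V0 / 4")
        if not self.drf < 0:
            raise EstimationError(f"DRF must be negative, got {self.drf}")
        if not 0 < self.rfmax <= 100:
            raise EstimationError(f"RFmax must lie in (0, 100], got {self.rfmax}")
        if self.v0 < 0.95 * self.vmax_measured:
            raise EstimationError("V0 implausibly below the measured peak speed")

    def as_dict(self) -> dict[str, float]:
        return {
            "f0_abs_n": self.f0_abs,
            "f0_rel_nkg": self.f0_rel,
            "v0_mps": self.v0,
            "sfv_rel_nskg_per_m": self.sfv_rel,
            "pmax_rel_wkg": self.pmax_rel,
            "pmax_abs_w": self.pmax_abs,
            "rfmax_pct": self.rfmax,
            "drf_pct_s_per_m": self.drf,
            "vmax_measured_mps": self.vmax_measured,
        }


@dataclass(frozen=True)
class SplitTimes:
    """Times (s) from motion onset to cover each requested distance (m)."""

    distances: tuple[float, ...]
    times: tuple[float, ...]

    def __post_init__(self):
        if len(self.distances) != len(self.times):
            raise InputError("distances and times must align")
        if any(t <= 0 for t in self.times) or any(
            b <= a for a, b in zip(self.times, self.times[1:])
        ):
            raise EstimationError("split times must be positive and increasing")

    def time_at(self, distance: float) -> float:
        for d, t in zip(self.distances, self.times):
            if abs(d - distance) < 1e-9:
                return t
        raise KeyError(f"no split computed for {distance} m")

    @property
    def t5(self) -> float:
        return self.time_at(5.0)

    @property
    def t15(self) -> float:
        return self.time_at(15.0)

    @property
    def t30(self) -> float:
        return self.time_at(30.0)

    def as_dict(self) -> dict[str, float]:
        return {f"t{d:g}_s": t for d, t in zip(self.distances, self.times)}


@dataclass(frozen=True)
class DecelResult:
    """Landmarks and magnitudes of a maximal horizontal deceleration phase.

    Sign convention: decelerations are negative; use
    :attr:`decel_early_magnitude` for report-style positive values.
    """

    v_peak: float
    t_peak: float
    v_end: float
    t_end: float
    t_half: float
    decel_early: float
    decel_overall: float

    def __post_init__(self):
        if not self.t_peak < self.t_half <= self.t_end + 1e-12:
            raise EstimationError("deceleration landmarks out of order")
        if not self.decel_early < 0:
            raise EstimationError("decel_early must be negative")

    @property
    def decel_early_magnitude(self) -> float:
        return abs(self.decel_early)

    def as_dict(self) -> dict[str, float]:
        return {
            "v_peak_mps": self.v_peak,
            "t_peak_s": self.t_peak,
            "v_end_mps": self.v_end,
            "t_end_s": self.t_end,
            "t_half_s": self.t_half,
            "decel_early_mps2": self.decel_early,
            "decel_overall_mps2": self.decel_overall,
        }


@dataclass(frozen=True)
class CodaResult:
    """One change-of-direction-ability (CODA) test attempt."""

    athlete_id: str
    time: float
    attempt: int = 1

    def __post_init__(self):
        if not self.time > 0:
            raise InputError("CODA time must be positive")


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive summary: n, mean, SD (n-1 denominator), range, quartiles.

    ``sd_defined`` is False for singletons, where the SD is reported as 0.
    """

    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    median: float
    q25: float
    q75: float
    sd_defined: bool = True


class FeatureTable:
    """Athletes x mechanical predictors with one performance target column.

    ``frame`` holds the predictors (one row per athlete, index = athlete id)
    and ``target`` the aligned outcome vector in seconds.
    """

    def __init__(self, frame: pd.DataFrame, target: pd.Series, target_name: str):
        if len(frame) != len(target):
            raise InputError("feature frame and target must have equal length")
        if len(frame) < 5:
            raise InputError("feature table needs at least 5 rows")
        if frame.isna().any().any() or target.isna().any():
            raise InputError("feature table must not contain missing values")
        if target_name in frame.columns:
            raise InputError("target must not appear among the predictors")
        self.frame = frame
        self.target = target.rename(target_name)
        self.target_name = target_name

    @property
    def athlete_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self):
        return len(self.frame)

    def with_frame(self, frame: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(frame, self.target.loc[frame.index], self.target_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.frame, self.target], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="athlete_id")

    @classmethod
    def from_csv(cls, path, target_name: str) -> "FeatureTable":
        df = pd.read_csv(path, index_col="athlete_id")
        if target_name not in df.columns:
            raise InputError(
                f"target {target_name!r} not found; columns: {list(df.columns)}"
            )
        return cls(df.drop(columns=[target_name]), df[target_name], target_name)


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the determinant analysis."""

    families: tuple[str, ...] = ("ols", "ridge", "lasso")
    alpha_grid: tuple[float, ...] = (0.0001, 0.001, 0.01, 0.1, 1.0, 10.0)
    n_folds: int = 5
    test_fraction: float = 0.2
    seed: int = 0
    collinearity_threshold: float = 0.8

    def __post_init__(self):
        if not set(self.families) <= {"ols", "ridge", "lasso"}:
            raise InputError(f"unknown model families in {self.families}")
        if not self.families:
            raise InputError("at least one model family required")
        if any(a <= 0 for a in self.alpha_grid):
            raise InputError("alphas must be positive")
        if self.n_folds < 2:
            raise InputError("n_folds must be >= 2")
        if not 0 < self.test_fraction < 0.5:
            raise InputError("test_fraction must lie in (0, 0.5)")
        if not 0 < self.collinearity_threshold <= 1:
            raise InputError("collinearity_threshold must lie in (0, 1]")


@dataclass
class FitResult:
    """One fitted candidate model.

    Coefficients are exposed on both scales: ``coefficients`` /
    ``intercept`` are raw-scale (original predictor units), while
    ``coefficients_std`` / ``intercept_std`` apply to predictors
    standardized on the training rows.
    """

    family: str
    alpha: float
    intercept: float
    coefficients: dict[str, float]
    intercept_std: float
    coefficients_std: dict[str, float]
    r2_train: float
    r2_test: float
    mae: float
    mse: float
    rmse: float
    train_index: np.ndarray = field(repr=False, default=None)
    test_index: np.ndarray = field(repr=False, default=None)
    selected: bool = False

    def __post_init__(self):
        if self.r2_train > 1 + 1e-12 or self.r2_test > 1 + 1e-12:
            raise EstimationError("R^2 cannot exceed 1")
        if abs(self.rmse - self.mse**0.5) > 1e-9:
            raise EstimationError("rmse must equal sqrt(mse)")
        if self.mae < 0:
            raise EstimationError("mae must be non-negative")

    @property
    def n_nonzero(self) -> int:
        return sum(1 for w in self.coefficients_std.values() if w != 0.0)

    def as_dict(self) -> dict:
        return {
            "family": self.family,
            "alpha": self.alpha,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "intercept_std": self.intercept_std,
            "coefficients_std": dict(self.coefficients_std),
            "r2_train": self.r2_train,
            "r2_test": self.r2_test,
            "mae": self.mae,
            "mse": self.mse,
            "rmse": self.rmse,
            "selected": self.selected,
        }


@dataclass(frozen=True)
class DiagnosticsResult:
    """Residual diagnostics: Shapiro-Wilk normality and Breusch-Pagan
    heteroscedasticity tests, with pass flags at the 0.05 level."""

    shapiro_stat: float
    shapiro_p: float
    bp_stat: float
    bp_p: float
    pass_normality: bool
    pass_homoscedasticity: bool
    degenerate: bool = False

    def __post_init__(self):
        for p in (self.shapiro_p, self.bp_p):
            if np.isfinite(p) and not 0 <= p <= 1:
                raise EstimationError("p-values must lie in [0, 1]")
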