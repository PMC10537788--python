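"""End-to-end cohort processing: simulate -> fit -> profile -> decelerate.

Glue used by the CLI and by reproduction scripts: run every athlete of a
(synthetic or measured) cohort through trace fitting, force-velocity
profiling, split-time computation and deceleration detection, and collect
per-athlete metrics for reporting and determinant analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decel import detect_decel_phase
from .fvp import (
    aero_coefficient,
    compute_forces,
    estimate_fvp,
    fit_velocity_model,
    split_times,
)
from .models import (
    AthleteRecord,
    DecelResult,
    SplitTimes,
    SprintFVP,
    TrueParams,
    VelocityModel,
    VelocityTrace,
)
from .synthetic import CohortSpec, generate_cohort, generate_decel_trace, \
    generate_sprint_trace

CODA_MEAN_S = 9.28
CODA_SD_S = 0.30

METRIC_KEYS = ("t5", "t15", "t30", "f0_rel", "v0", "pmax_rel", "sfv_rel",
               "rfmax", "drf", "decel_early", "coda")


@dataclass
class AthleteResult:
    """Everything the pipeline derives for one athlete."""

    athlete: AthleteRecord
    params: TrueParams | None
    model: VelocityModel
    fvp: SprintFVP
    splits: SplitTimes
    decel: DecelResult


def analyze_athlete(athlete: AthleteRecord, sprint: VelocityTrace,
                    decel_trace: VelocityTrace, *, temperature_c: float = 20.0,
                    pressure_mmhg: float = 760.0, wind_mps: float = 0.0,
                    params: TrueParams | None = None) -> AthleteResult:
    """Fit one athlete's sprint trace and deceleration trial."""
    model = fit_velocity_model(sprint)
    aero = aero_coefficient(athlete, temperature_c, pressure_mmhg,
                            wind_mps=wind_mps)
    profile = compute_forces(model, athlete, aero)
    return AthleteResult(
        athlete=athlete,
        params=params,
        model=model,
        fvp=estimate_fvp(profile, athlete),
        splits=split_times(model),
        decel=detect_decel_phase(decel_trace),
    )


def process_cohort(spec: CohortSpec, *, analytic: bool = False,
                   temperature_c: float = 20.0, pressure_mmhg: float = 760.0,
                   duration_taus: float = 6.0) -> list[AthleteResult]:
    """Simulate a cohort and push every athlete through the full pipeline.

    With ``analytic=True`` the velocity model is built directly from each
    athlete's true parameters (no trace synthesis or nonlinear fitting);
    profiles and split times are then exact functions of the ground truth,
    which is useful for fast planted-truth studies of the downstream
    statistics.
    """
    results = []
    for i, (athlete, params) in enumerate(generate_cohort(spec)):
        aero = aero_coefficient(athlete, temperature_c, pressure_mmhg)
        if analytic:
            model = VelocityModel(vmax=params.vmax_true, tau=params.tau_true,
                                  t0=params.t0_true)
            decel_spec = CohortSpec(
                n=spec.n, seed=spec.seed, parameter_means=spec.parameter_means,
                parameter_sds=spec.parameter_sds, sampling_hz=spec.sampling_hz,
                noise_sd=0.0)
            decel_trace = generate_decel_trace(
                params, decel_spec, seed=np.random.SeedSequence((spec.seed, i, 1)))
        else:
            duration = params.t0_true + duration_taus * params.tau_true
            sprint = generate_sprint_trace(
                params, spec, duration,
                seed=np.random.SeedSequence((spec.seed, i, 0)))
            decel_trace = generate_decel_trace(
                params, spec, seed=np.random.SeedSequence((spec.seed, i, 1)))
            model = fit_velocity_model(sprint)
        profile = compute_forces(model, athlete, aero)
        results.append(AthleteResult(
            athlete=athlete,
            params=params,
            model=model,
            fvp=estimate_fvp(profile, athlete),
            splits=split_times(model),
            decel=detect_decel_phase(decel_trace),
        ))
    return results


def simulate_coda_times(n: int, seed, mean: float = CODA_MEAN_S,
                        sd: float = CODA_SD_S) -> np.ndarray:
    """Best-attempt CODA times, independent of the mechanical variables
    (the null design the agility findings correspond to)."""
    rng = np.random.default_rng(seed)
    times = rng.normal(mean, sd, size=n)
    while np.any(times <= 0):  # pathological sds only
        bad = times <= 0
        times[bad] = rng.normal(mean, sd, size=bad.sum())
    return times


def cohort_metrics(results: list[AthleteResult],
                   coda: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Per-athlete metric vectors keyed for :func:`sprintmech.report.cohort_table`."""
    m = {
        "t5": np.array([r.splits.t5 for r in results]),
        "t15": np.array([r.splits.t15 for r in results]),
        "t30": np.array([r.splits.t30 for r in results]),
        "f0_rel": np.array([r.fvp.f0_rel for r in results]),
        "v0": np.array([r.fvp.v0 for r in results]),
        "pmax_rel": np.array([r.fvp.pmax_rel for r in results]),
        "sfv_rel": np.array([r.fvp.sfv_rel for r in results]),
        "rfmax": np.array([r.fvp.rfmax for r in results]),
        "drf": np.array([r.fvp.drf for r in results]),
        "decel_early": np.array([r.decel.decel_early for r in results]),
    }
    if coda is not None:
        m["coda"] = np.asarray(coda, dtype=float)
    return m
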