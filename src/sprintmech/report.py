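"""Cohort reporting and comparison against published reference models.

Two artifacts live here:

* a quartile table of sprint, mechanical, deceleration and agility
  variables in the exact layout used for elite female field-hockey
  reference data (deceleration printed as a magnitude, per that layout);
* a consistency check of published regression equations for the 5/15/30 m
  sprint times against the published cohort means and mean ± 1 SD bands.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .io import descriptive_summary

#: Quartile-table layout: (row label, metric key, magnitude flag).
TABLE_ROWS = (
    ("5-m (s)", "t5", False),
    ("15-m (s)", "t15", False),
    ("30-m (s)", "t30", False),
    ("F0 (N/kg)", "f0_rel", False),
    ("V0 (m/s)", "v0", False),
    ("Pmax (W/kg)", "pmax_rel", False),
    ("FV profile (N/s/m)", "sfv_rel", False),
    ("RF max (%)", "rfmax", False),
    ("DRF (%/s/m)", "drf", False),
    ("Deceleration (m/s^2)", "decel_early", True),
    ("CODA (s)", "coda", False),
)

TABLE_COLUMNS = ("Q25", "Median", "Q75")

#: Published best-explanatory models for each sprint distance (m). Keys
#: suffixed ``_std`` are coefficients reported on the standardized scale;
#: they contribute zero when predicting at the cohort means.
PUBLISHED_MODELS: dict[float, dict[str, float]] = {
    5.0: {"intercept": 2.8204, "f0_rel": -0.1493, "vmax": -0.0481},
    15.0: {"intercept": 5.6568, "f0_rel": -0.2172, "vmax": -0.1611,
           "f0_abs_std": 1.5058},
    30.0: {"intercept": 9.6188, "f0_rel": -0.2514, "vmax": -0.3827},
}

#: Published cohort means of the mechanical predictors used above.
PUBLISHED_PREDICTOR_MEANS: dict[str, float] = {"f0_rel": 5.72, "vmax": 7.93}

#: Published split-time mean ± SD bands (s) per distance (m).
PUBLISHED_SPLIT_BANDS: dict[float, tuple[float, float]] = {
    5.0: (1.60, 0.02),
    15.0: (3.21, 0.14),
    30.0: (5.30, 0.21),
}


def cohort_table(metrics: Mapping[str, "np.ndarray | list"],
                 decimals: int | None = 2) -> pd.DataFrame:
    """Quartile report in the fixed reference layout.

    ``metrics`` maps metric keys (``t5`` ... ``coda``) to per-athlete value
    vectors; every key in the layout must be present. Deceleration rows are
    printed as magnitudes even though the internal sign convention is
    negative.
    """
    missing = [k for _, k, _ in TABLE_ROWS if k not in metrics]
    if missing:
        raise InputError(f"missing metric vectors: {missing}")
    rows = {}
    for label, key, magnitude in TABLE_ROWS:
        x = np.abs(np.asarray(metrics[key], dtype=float)) if magnitude \
            else np.asarray(metrics[key], dtype=float)
        s = descriptive_summary(x)
        rows[label] = [s.q25, s.median, s.q75]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(TABLE_COLUMNS))
    if decimals is not None:
        df = df.round(decimals)
    return df


def predict_published(distance: float,
                      predictor_means: Mapping[str, float] | None = None,
                      ) -> float:
    """Evaluate a published sprint-time equation at cohort predictor means.

    Raw-scale coefficients are applied to the means; standardized-scale
    coefficients (``*_std`` keys) vanish because a predictor at its cohort
    mean standardizes to zero.
    """
    if distance not in PUBLISHED_MODELS:
        raise InputError(f"no published model for {distance} m; "
                         f"available: {sorted(PUBLISHED_MODELS)}")
    means = dict(PUBLISHED_PREDICTOR_MEANS)
    if predictor_means:
        means.update(predictor_means)
    model = PUBLISHED_MODELS[distance]
    y = model["intercept"]
    for name, coef in model.items():
        if name == "intercept" or name.endswith("_std"):
            continue
        if name not in means:
            raise InputError(f"no mean supplied for predictor {name!r}")
        y += coef * means[name]
    return float(y)


def published_model_consistency(
        predictor_means: Mapping[str, float] | None = None,
        bands: Mapping[float, tuple[float, float]] | None = None,
        ) -> pd.DataFrame:
    """Sanity check: published equations evaluated at cohort means should
    predict split times inside the published mean ± 1 SD bands.

    Returns one row per distance with the prediction, the band, and an
    ``inside`` flag. Defaults reproduce the published cohort; pass your own
    means/bands to check a different squad.
    """
    bands = dict(PUBLISHED_SPLIT_BANDS if bands is None else bands)
    rows = []
    for distance in sorted(bands):
        mean, sd = bands[distance]
        pred = predict_published(distance, predictor_means)
        rows.append({
            "distance_m": distance,
            "predicted_s": round(pred, 4),
            "band_low_s": round(mean - sd, 4),
            "band_high_s": round(mean + sd, 4),
            "inside": bool(mean - sd <= pred <= mean + sd),
        })
    return pd.DataFrame(rows).set_index("distance_m")
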