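"""Phenotype and exposure preparation.

Turns raw cohort measurements into the analysis-ready variables used by the
interaction scan: averaged blood pressure with optional medication imputation,
hypertension status, and daily sodium consumption estimated from a casual
spot-urine sample via a configurable Tanaka-style formula.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

# Milligrams of sodium per mEq (= per mmol). The nutrition convention rounds
# the atomic mass to 23; the published cohort tables are only reproduced with
# this convention (164.8 mEq/day -> 3,790 mg/day).
MG_PER_MEQ = 23.0

#: mm Hg added back to treated subjects' SBP/DBP to impute untreated pressure.
MEDICATION_IMPUTATION = (10.0, 5.0)

#: Hypertension definition thresholds (mm Hg), inclusive.
HYPERTENSION_SBP = 140.0
HYPERTENSION_DBP = 90.0


@dataclass(frozen=True)
class SodiumFormulaCoefficients:
    """Coefficients of a spot-urine 24-h sodium excretion estimator.

    The estimator has the shape

        Na24 = scale * (spot_na / (cr_unit_factor * spot_cr) * PRCr) ** exponent

    where PRCr, the predicted 24-h creatinine excretion (mg/day), is the
    linear function

        PRCr = pr_cr_intercept + pr_cr_age*age + pr_cr_weight*weight
               + pr_cr_height*height

    with age in years, weight in kg, height in cm, spot_na in mEq/L and
    spot_cr in mg/dL.  ``cr_unit_factor`` converts the creatinine unit so the
    ratio is dimensionally consistent with PRCr (10 for mg/dL vs mg/day).
    All values are configuration, never hard-coded downstream.
    """

    scale: float = 21.98
    exponent: float = 0.392
    cr_unit_factor: float = 10.0
    pr_cr_intercept: float = -2244.45
    pr_cr_age: float = -2.04
    pr_cr_weight: float = 14.89
    pr_cr_height: float = 16.14

    def __post_init__(self) -> None:
        if not (self.scale > 0 and self.exponent > 0 and self.cr_unit_factor > 0):
            raise ValueError("scale, exponent and cr_unit_factor must be positive")

    def predicted_creatinine(self, age, weight, height):
        """Predicted 24-h urinary creatinine excretion, mg/day."""
        return (
            self.pr_cr_intercept
            + self.pr_cr_age * np.asarray(age, dtype=float)
            + self.pr_cr_weight * np.asarray(weight, dtype=float)
            + self.pr_cr_height * np.asarray(height, dtype=float)
        )

    def to_dict(self) -> dict:
        return asdict(self)


#: Published coefficient set for the Tanaka spot-urine estimator (defaults).
TANAKA = SodiumFormulaCoefficients()

#: Degenerate coefficient set: estimate equals the raw spot Na/Cr ratio.
IDENTITY_COEFFS = SodiumFormulaCoefficients(
    scale=1.0, exponent=1.0, cr_unit_factor=1.0,
    pr_cr_intercept=1.0, pr_cr_age=0.0, pr_cr_weight=0.0, pr_cr_height=0.0,
)


def prepare_bp(sbp_measurements, dbp_measurements, on_antihypertensive,
               use_imputed: bool = True):
    """Average the available BP measurements and optionally impute medication.

    Parameters
    ----------
    sbp_measurements, dbp_measurements
        Sequences of one or two finite readings (scalars accepted), or for the
        vectorised path 2-d arrays of shape ``(n_subjects, n_readings)`` with
        NaN marking an absent second reading.
    on_antihypertensive
        Boolean (or boolean array) medication flag.
    use_imputed
        When true, treated subjects get +10 mm Hg SBP and +5 mm Hg DBP to
        approximate untreated pressure; false returns measured averages
        (the sensitivity-analysis mode).

    Returns
    -------
    (sbp, dbp)
        Floats (or arrays); NaN where no measurement was available — such
        subjects are dropped later by :func:`exclude_incomplete`.
    """
    sbp = np.atleast_2d(np.asarray(sbp_measurements, dtype=float))
    dbp = np.atleast_2d(np.asarray(dbp_measurements, dtype=float))
    med = np.asarray(on_antihypertensive, dtype=bool)
    scalar = np.ndim(on_antihypertensive) == 0

    import warnings as _warnings
    with _warnings.catch_warnings():
        # all-NaN rows (no measurement) legitimately average to NaN
        _warnings.simplefilter("ignore", RuntimeWarning)
        sbp_mean = np.nanmean(sbp, axis=1) if sbp.size else np.full(med.shape, np.nan)
        dbp_mean = np.nanmean(dbp, axis=1) if dbp.size else np.full(med.shape, np.nan)
    if use_imputed:
        add_s, add_d = MEDICATION_IMPUTATION
        sbp_mean = sbp_mean + np.where(med, add_s, 0.0)
        dbp_mean = dbp_mean + np.where(med, add_d, 0.0)
    if scalar:
        return float(sbp_mean[0]), float(dbp_mean[0])
    return sbp_mean, dbp_mean


def classify_hypertension(sbp, dbp, on_antihypertensive):
    """True iff SBP >= 140 mm Hg, DBP >= 90 mm Hg, or on medication."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    med = np.asarray(on_antihypertensive, dtype=bool)
    out = (sbp >= HYPERTENSION_SBP) | (dbp >= HYPERTENSION_DBP) | med
    return bool(out) if out.ndim == 0 else out


def estimate_daily_sodium(spot_na, spot_cr, age, height, weight,
                          coeffs: SodiumFormulaCoefficients = TANAKA):
    """Estimate 24-h sodium excretion (mEq/day) from a spot urine sample.

    Raises on non-positive spot creatinine or a non-positive predicted 24-h
    creatinine (both make the ratio argument meaningless).
    """
    spot_na = np.asarray(spot_na, dtype=float)
    spot_cr = np.asarray(spot_cr, dtype=float)
    if np.any(spot_cr <= 0):
        bad = np.atleast_1d(spot_cr <= 0).nonzero()[0]
        raise ValueError(f"non-positive spot creatinine for subject index {bad[0]}")
    pr_cr = coeffs.predicted_creatinine(age, weight, height)
    if np.any(np.atleast_1d(pr_cr) <= 0):
        bad = np.atleast_1d(pr_cr <= 0).nonzero()[0]
        raise ValueError(
            f"non-positive predicted 24-h creatinine for subject index {bad[0]}"
        )
    ratio = spot_na / (coeffs.cr_unit_factor * spot_cr) * pr_cr
    est = coeffs.scale * np.power(ratio, coeffs.exponent)
    return float(est) if est.ndim == 0 else est


_UNIT_TO_MEQ = {
    "mEq/day": 1.0,
    "mmol/day": 1.0,
    "mg/day": 1.0 / MG_PER_MEQ,
    "g/day": 1000.0 / MG_PER_MEQ,
}


def convert_sodium_units(value, from_unit: str, to_unit: str):
    """Convert sodium amounts between mEq/day, mmol/day, mg/day and g/day.

    1 mEq = 1 mmol = 23 mg of sodium. No rounding is applied here; use
    :func:`round_half_up` at the presentation layer.
    """
    try:
        f = _UNIT_TO_MEQ[from_unit]
        t = _UNIT_TO_MEQ[to_unit]
    except KeyError as exc:
        raise ValueError(f"unknown sodium unit {exc.args[0]!r}") from None
    value = np.asarray(value, dtype=float)
    out = value * (f / t)
    return float(out) if out.ndim == 0 else out


def round_half_up(x) -> int:
    """Round to nearest integer, ties away from zero (presentation rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


_CORE_COLUMNS = ("bmi", "sbp", "dbp", "daily_sodium")


def exclude_incomplete(cohort: pd.DataFrame):
    """Drop subjects missing BMI, SBP, DBP or daily sodium.

    Returns the filtered cohort and a log dict with per-reason counts; a
    subject missing several core variables is counted under every reason but
    excluded once.
    """
    log = {}
    bad = pd.Series(False, index=cohort.index)
    for col in _CORE_COLUMNS:
        miss = cohort[col].isna() if col in cohort else pd.Series(True, index=cohort.index)
        log[col] = int(miss.sum())
        bad |= miss
    log["excluded_total"] = int(bad.sum())
    return cohort.loc[~bad].copy(), log


def write_exclusion_log(log: dict, path) -> None:
    with open(path, "w") as fh:
        for reason, count in log.items():
            fh.write(json.dumps({"reason": reason, "count": count}) + "\n")


def prepare_cohort(cohort: pd.DataFrame,
                   coeffs: SodiumFormulaCoefficients = TANAKA,
                   use_imputed: bool = True) -> pd.DataFrame:
    """Apply the full phenotype preparation to a raw cohort table.

    Expects raw measurement columns ``sbp1``/``sbp2``, ``dbp1``/``dbp2`` (the
    second may be NaN) and ``on_antihypertensive``; computes ``sbp``, ``dbp``,
    ``hypertension`` and, where ``daily_sodium`` is absent but spot-urine
    analytes are present, the estimated daily sodium.
    """
    out = cohort.copy()
    sbp_cols = [c for c in ("sbp1", "sbp2") if c in out]
    dbp_cols = [c for c in ("dbp1", "dbp2") if c in out]
    if sbp_cols and dbp_cols:
        sbp, dbp = prepare_bp(
            out[sbp_cols].to_numpy(float),
            out[dbp_cols].to_numpy(float),
            out["on_antihypertensive"].to_numpy(bool),
            use_imputed=use_imputed,
        )
        out["sbp"] = sbp
        out["dbp"] = dbp
    out["hypertension"] = classify_hypertension(
        out["sbp"], out["dbp"], out["on_antihypertensive"]
    )
    need_na = ("daily_sodium" not in out) or out["daily_sodium"].isna().any()
    if need_na and {"spot_urine_na", "spot_urine_cr"}.issubset(out.columns):
        est = estimate_daily_sodium(
            out["spot_urine_na"], out["spot_urine_cr"],
            out["age"], out["height"], out["weight"], coeffs,
        )
        if "daily_sodium" in out:
            out["daily_sodium"] = out["daily_sodium"].where(
                out["daily_sodium"].notna(), est
            )
        else:
            out["daily_sodium"] = est
    return out
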