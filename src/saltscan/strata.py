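"""Stratified post-hoc analyses around a replicated interaction locus.

Given a carrier/non-carrier split of the cohort at a sentinel variant, this
module estimates the sodium-on-BP slope within each genotype subgroup,
tabulates BP by sodium-consumption tertile (raw means with covariate-adjusted
mean differences vs the low tertile), computes hypertension odds ratios
between carriers and non-carriers within sodium strata, and re-runs the whole
set under the sensitivity modes (measured BP, medicated excluded,
hypertensives excluded).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phenotype import prepare_cohort, exclude_incomplete, convert_sodium_units

_ADJUST = ("age", "sex", "bmi")

SENSITIVITY_MODES = ("measured_bp", "drop_medicated", "drop_hypertensive")


def _design(cohort: pd.DataFrame, covariates=_ADJUST) -> pd.DataFrame:
    X = pd.DataFrame(index=cohort.index)
    for c in covariates:
        if c == "sex":
            X["male"] = (cohort["sex"].astype(str) == "male").astype(float)
        else:
            X[c] = cohort[c].astype(float)
    return X


def subgroup_slopes(cohort: pd.DataFrame, carrier_flag, trait: str = "sbp",
                    covariates=_ADJUST) -> pd.DataFrame:
    """Sodium slope on the trait within carriers and non-carriers.

    Fits ``trait ~ daily_sodium + age + male + bmi`` by OLS per subgroup.
    Returns one row per subgroup with slope (mm Hg per mEq/day), SE, p and n;
    degenerate subgroups are marked untestable.
    """
    carrier = pd.Series(np.asarray(carrier_flag, dtype=bool), index=cohort.index)
    rows = []
    for label, mask in (("non_carrier", ~carrier), ("carrier", carrier)):
        sub = cohort.loc[mask]
        X = _design(sub, covariates)
        X.insert(0, "daily_sodium", sub["daily_sodium"].astype(float))
        X = sm.add_constant(X, has_constant="add")
        y = sub[trait].astype(float)
        ok = X.notna().all(axis=1) & y.notna()
        X, y = X.loc[ok], y.loc[ok]
        if len(y) <= X.shape[1] or X["daily_sodium"].nunique() < 2:
            rows.append({"subgroup": label, "n": int(len(y)), "beta": np.nan,
                         "se": np.nan, "p": np.nan, "untestable": True})
            continue
        fit = sm.OLS(y, X).fit()
        rows.append({
            "subgroup": label, "n": int(fit.nobs),
            "beta": float(fit.params["daily_sodium"]),
            "se": float(fit.bse["daily_sodium"]),
            "p": float(fit.pvalues["daily_sodium"]),
            "untestable": False,
        })
    return pd.DataFrame(rows)


def assign_tertiles(sodium: pd.Series):
    """Whole-cohort sodium tertile labels (1..3); boundary ties go low.

    Returns ``(labels, (q1, q2))`` with boundaries in mEq/day.
    """
    x = sodium.astype(float)
    if x.nunique() < 3:
        raise ValueError("fewer than 3 distinct sodium values; cannot form tertiles")
    q1, q2 = np.quantile(x.dropna(), [1 / 3, 2 / 3])
    labels = pd.Series(np.where(x <= q1, 1, np.where(x <= q2, 2, 3)),
                       index=x.index)
    labels[x.isna()] = pd.NA
    return labels, (float(q1), float(q2))


def _adjusted_differences(sub: pd.DataFrame, tert: pd.Series, trait: str,
                          covariates=_ADJUST):
    """Covariate-adjusted mean differences of T2/T3 vs T1 with p-values."""
    X = _design(sub, covariates)
    X.insert(0, "t3", (tert == 3).astype(float))
    X.insert(0, "t2", (tert == 2).astype(float))
    X = sm.add_constant(X, has_constant="add")
    y = sub[trait].astype(float)
    ok = X.notna().all(axis=1) & y.notna()
    fit = sm.OLS(y.loc[ok], X.loc[ok]).fit()
    return ((float(fit.params["t2"]), float(fit.bse["t2"]),
             float(fit.pvalues["t2"])),
            (float(fit.params["t3"]), float(fit.bse["t3"]),
             float(fit.pvalues["t3"])))


def tertile_table(cohort: pd.DataFrame, carrier_flag, trait: str = "sbp",
                  covariates=_ADJUST):
    """BP by whole-cohort sodium tertile, overall and per genotype subgroup.

    Tertile boundaries are computed on the whole cohort before genotype
    stratification. Cells report the raw mean and SD; the mean differences vs
    the low tertile are covariate-adjusted, with their p-values from the same
    linear model. Returns ``(table, boundaries)`` where boundaries are given
    in mEq/day and mg/day.
    """
    carrier = pd.Series(np.asarray(carrier_flag, dtype=bool), index=cohort.index)
    tert, (q1, q2) = assign_tertiles(cohort["daily_sodium"])
    bounds = {
        "q1_meq": q1, "q2_meq": q2,
        "q1_mg": convert_sodium_units(q1, "mEq/day", "mg/day"),
        "q2_mg": convert_sodium_units(q2, "mEq/day", "mg/day"),
    }
    rows = []
    groups = (("all", pd.Series(True, index=cohort.index)),
              ("non_carrier", ~carrier), ("carrier", carrier))
    for label, mask in groups:
        sub = cohort.loc[mask]
        tsub = tert.loc[mask]
        (d2, s2, p2), (d3, s3, p3) = _adjusted_differences(
            sub, tsub, trait, covariates)
        for t, diff, se, p in ((1, 0.0, np.nan, np.nan), (2, d2, s2, p2),
                               (3, d3, s3, p3)):
            vals = sub.loc[tsub == t, trait].astype(float)
            rows.append({
                "group": label, "tertile": t, "n": int(vals.notna().sum()),
                "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                "adj_diff_vs_low": diff, "se_vs_low": se, "p_vs_low": p,
            })
    return pd.DataFrame(rows), bounds


def hypertension_or(a: int, b: int, c: int, d: int):
    """Odds ratio for hypertension, carriers vs non-carriers.

    The 2x2 table is (a, b) = carriers (hypertensive, normotensive) and
    (c, d) = non-carriers. Returns ``(or, ci_low, ci_high, p)`` with a Woolf
    log-SE 95% CI and a two-sided normal p. A zero cell triggers the Haldane
    continuity correction (+0.5 to every cell) with a warning.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(cells == 0):
        warnings.warn("zero cell in 2x2 table; applying +0.5 continuity "
                      "correction", stacklevel=2)
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = np.log(or_) / se
    ci = (float(np.exp(np.log(or_) - 1.959963984540054 * se)),
          float(np.exp(np.log(or_) + 1.959963984540054 * se)))
    p = float(2 * stats.norm.sf(abs(z)))
    return float(or_), ci[0], ci[1], p


def hypertension_or_cohort(cohort: pd.DataFrame, carrier_flag,
                           sodium_stratum: str | None = None,
                           adjusted: bool = False, covariates=_ADJUST):
    """Hypertension OR from a cohort, optionally within a sodium stratum.

    ``sodium_stratum`` restricts to the low (bottom) or high (top)
    whole-cohort sodium tertile. ``adjusted=True`` uses logistic regression
    with the covariates (constant covariates are dropped) and a Wald CI;
    the default is the unadjusted 2x2 path.
    """
    carrier = pd.Series(np.asarray(carrier_flag, dtype=bool), index=cohort.index)
    sub, csub = cohort, carrier
    if sodium_stratum is not None:
        tert, _ = assign_tertiles(cohort["daily_sodium"])
        t = {"low": 1, "high": 3}.get(sodium_stratum)
        if t is None:
            raise ValueError(f"sodium_stratum must be 'low' or 'high', "
                             f"got {sodium_stratum!r}")
        keep = tert == t
        sub, csub = cohort.loc[keep], carrier.loc[keep]
    ht = sub["hypertension"].astype(bool)
    if not adjusted:
        a = int((csub & ht).sum())
        b = int((csub & ~ht).sum())
        c = int((~csub & ht).sum())
        d = int((~csub & ~ht).sum())
        return hypertension_or(a, b, c, d)
    X = _design(sub, covariates)
    X = X.loc[:, X.nunique() > 1]  # constant covariates carry no information
    X.insert(0, "carrier", csub.astype(float))
    X = sm.add_constant(X, has_constant="add")
    fit = sm.Logit(ht.astype(float), X).fit(disp=False)
    beta, se = float(fit.params["carrier"]), float(fit.bse["carrier"])
    return (float(np.exp(beta)),
            float(np.exp(beta - 1.959963984540054 * se)),
            float(np.exp(beta + 1.959963984540054 * se)),
            float(fit.pvalues["carrier"]))


def sensitivity_rerun(raw_cohort: pd.DataFrame, carrier_flag, mode: str,
                      trait: str = "sbp", covariates=_ADJUST):
    """Re-run the stratified analyses under one sensitivity mode.

    ``raw_cohort`` must carry the raw measurement columns used by the
    preparation stage. Modes: ``measured_bp`` (no medication imputation),
    ``drop_medicated`` and ``drop_hypertensive``. Output schema matches the
    primary analysis: a dict with ``slopes``, ``tertiles``, ``boundaries``
    and ``n``.
    """
    if mode not in SENSITIVITY_MODES:
        raise ValueError(f"unknown sensitivity mode {mode!r}")
    carrier = pd.Series(np.asarray(carrier_flag, dtype=bool),
                        index=raw_cohort.index)
    prepared = prepare_cohort(raw_cohort, use_imputed=(mode != "measured_bp"))
    if mode == "drop_medicated":
        keep = ~prepared["on_antihypertensive"].astype(bool)
    elif mode == "drop_hypertensive":
        keep = ~prepared["hypertension"].astype(bool)
    else:
        keep = pd.Series(True, index=prepared.index)
    prepared = prepared.loc[keep]
    carrier = carrier.loc[keep]
    prepared, _ = exclude_incomplete(prepared)
    carrier = carrier.loc[prepared.index]
    if carrier.nunique() < 2:
        return {"mode": mode, "n": int(len(prepared)), "untestable": True,
                "slopes": None, "tertiles": None, "boundaries": None}
    slopes = subgroup_slopes(prepared, carrier, trait, covariates)
    tertiles, bounds = tertile_table(prepared, carrier, trait, covariates)
    return {"mode": mode, "n": int(len(prepared)), "untestable": False,
            "slopes": slopes, "tertiles": tertiles, "boundaries": bounds}
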