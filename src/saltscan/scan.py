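"""Genome-wide gene x environment interaction engine.

For each variant the sodium x genotype interaction is tested by comparing two
nested Gaussian linear models,

    model 1:  BP = b0 + bG*G + bE*E + covariates
    model 2:  BP = b0 + bG*G + bE*E + bGE*(G x E) + covariates

with the 1-df likelihood-ratio statistic n*ln(RSS1/RSS2) referred to a
chi-square(1) distribution. Genome-wide p-values are corrected by genomic
control, and loci are staged through suggestive (discovery), nominal
(replication, direction-consistent) and genome-wide (combined, site-adjusted)
significance gates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import qc as qcmod

#: Median of the chi-square distribution with 1 df (genomic-control reference).
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))

#: Default staging thresholds.
SUGGESTIVE_P = 1e-5
REPLICATION_P = 0.05
GENOME_WIDE_P = 5e-8

#: Posterior probabilities closer than this are treated as tied best guesses.
_POSTERIOR_TIE_TOL = 1e-9

CODING_MODELS = ("dosage", "additive", "dominant", "recessive")


@dataclass
class ScanRecord:
    """Result of one interaction test."""

    variant_id: str
    coding_model: str
    coded_genotype_freq: float = np.nan
    beta_G: float = np.nan
    beta_E: float = np.nan
    beta_GE: float = np.nan
    se_GE: float = np.nan
    lrt_stat: float = np.nan
    p_raw: float = np.nan
    p_gc: float = np.nan
    n_used: int = 0
    site_adjusted: bool = False
    untestable: bool = False
    reason: str = ""


@dataclass
class TwoStageDecision:
    """Staged significance decision for one variant."""

    variant_id: str
    p_discovery: float
    p_replication: float
    p_combined: float
    direction_consistent: bool
    status: str  # none | suggestive | replicated | genome_wide


def code_genotype(posteriors=None, hard_calls=None, model: str = "dosage",
                  effect_allele: str = "alt"):
    """Code genotypes under one of the four genetic-effect models.

    ``posteriors`` is an (n, 3) array of genotype posterior mass on
    (hom-ref, het, hom-alt); ``hard_calls`` are alt-allele counts (-1 =
    missing) used when posteriors are absent. The dosage model returns the
    expected effect-allele count; additive the best-guess count; dominant a
    carrier indicator; recessive a homozygote indicator. ``effect_allele``
    ('alt' or 'ref') selects which allele the coding counts.

    Returns ``(coded, tie_flags)``: coded values as float with NaN for
    missing, and a boolean array flagging posterior best-guess ties (broken
    toward the lower genotype count).
    """
    if model not in CODING_MODELS:
        raise ValueError(f"unknown coding model {model!r}")
    if effect_allele not in ("alt", "ref"):
        raise ValueError(f"effect_allele must be 'alt' or 'ref', got {effect_allele!r}")

    if posteriors is not None:
        gp = np.asarray(posteriors, dtype=float)
        gp = np.atleast_2d(gp)
        sums = gp.sum(axis=1)
        valid = np.isfinite(sums) & (np.abs(sums - 1.0) <= 1e-3)
        if model == "dosage":
            alt_count = gp[:, 1] + 2.0 * gp[:, 2]
            ties = np.zeros(gp.shape[0], dtype=bool)
        else:
            # best guess = modal class; ties broken toward the lower
            # genotype count and flagged
            top = gp.max(axis=1)
            is_top = gp >= top[:, None] - _POSTERIOR_TIE_TOL
            best = is_top.argmax(axis=1)
            ties = is_top.sum(axis=1) > 1
            alt_count = best.astype(float)
        alt_count = np.where(valid, alt_count, np.nan)
    else:
        if hard_calls is None:
            raise ValueError("either posteriors or hard_calls is required")
        hc = np.asarray(hard_calls, dtype=float)
        alt_count = np.where(hc >= 0, hc, np.nan)
        ties = np.zeros(alt_count.shape, dtype=bool)

    count = alt_count if effect_allele == "alt" else 2.0 - alt_count
    if model in ("dosage", "additive"):
        coded = count
    elif model == "dominant":
        coded = np.where(np.isnan(count), np.nan, (count >= 1.0).astype(float))
    else:  # recessive
        coded = np.where(np.isnan(count), np.nan, (count >= 2.0 - 1e-9).astype(float))
    return coded, ties


def _ols(X: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), int(rank)


def fit_interaction_lrt(G, E, bp, covariates=None, variant_id: str = "",
                        coding_model: str = "", site_adjusted: bool = False,
                        joint_2df: bool = False) -> ScanRecord:
    """Fit the nested interaction models for one variant.

    ``covariates`` is an optional (n, k) array (e.g. PCs, age, sex, BMI and,
    for the combined analysis, a study-site indicator). Rows with any
    non-finite value are dropped (complete-case). A constant coded genotype or
    a rank-deficient design yields a record flagged untestable rather than an
    exception.

    With ``joint_2df=True`` the reduced model drops both G and G x E and the
    statistic has 2 df (not part of the default pipeline).
    """
    G = np.asarray(G, dtype=float)
    E = np.asarray(E, dtype=float)
    bp = np.asarray(bp, dtype=float)
    C = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if C is not None and C.shape[0] != G.shape[0]:
        C = C.T

    ok = np.isfinite(G) & np.isfinite(E) & np.isfinite(bp)
    if C is not None:
        ok &= np.all(np.isfinite(C), axis=1)
    G, E, bp = G[ok], E[ok], bp[ok]
    C = None if C is None else C[ok]
    n = G.size

    rec = ScanRecord(variant_id=variant_id, coding_model=coding_model,
                     n_used=n, site_adjusted=site_adjusted)
    n_params = 4 + (0 if C is None else C.shape[1]) + (1 if joint_2df else 0)
    if n <= n_params:
        rec.untestable, rec.reason = True, "insufficient complete cases"
        return rec
    if np.ptp(G) == 0:
        rec.untestable, rec.reason = True, "constant coded genotype"
        return rec

    ones = np.ones(n)
    base_cols = [ones, G, E]
    if C is not None:
        base_cols.extend(C.T)
    X2 = np.column_stack(base_cols + [G * E])
    if joint_2df:
        X1 = np.column_stack([ones, E] + ([] if C is None else list(C.T)))
    else:
        X1 = np.column_stack(base_cols)

    beta2, rss2, rank2 = _ols(X2, bp)
    if rank2 < X2.shape[1]:
        rec.untestable, rec.reason = True, "rank-deficient design"
        return rec
    _, rss1, _ = _ols(X1, bp)

    if rss2 <= 0.0:
        rec.untestable, rec.reason = True, "zero residual variance"
        return rec
    lrt = n * np.log(rss1 / rss2)
    df = 2 if joint_2df else 1
    rec.lrt_stat = float(max(lrt, 0.0))
    rec.p_raw = float(stats.chi2.sf(rec.lrt_stat, df))

    sigma2 = rss2 / (n - X2.shape[1])
    xtx_inv = np.linalg.inv(X2.T @ X2)
    rec.beta_G = float(beta2[1])
    rec.beta_E = float(beta2[2])
    rec.beta_GE = float(beta2[-1])
    rec.se_GE = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    return rec


def design_covariates(cohort: pd.DataFrame, n_pcs: int = 20,
                      extra: tuple = ("age", "sex", "bmi"),
                      site_adjust: bool = False) -> np.ndarray:
    """Covariate matrix for the scan: PCs, age, sex (male=1), BMI [, site]."""
    cols = []
    for i in range(1, n_pcs + 1):
        name = f"pc{i}"
        if name not in cohort:
            raise KeyError(f"cohort lacks principal component column {name!r}")
        cols.append(cohort[name].to_numpy(float))
    for name in extra:
        if name == "sex":
            cols.append((cohort["sex"].astype(str) == "male").to_numpy(float))
        else:
            cols.append(cohort[name].to_numpy(float))
    if site_adjust:
        cols.append((cohort["site"].astype(str) == "replication").to_numpy(float))
    return np.column_stack(cols) if cols else None


def genome_scan(cohort: pd.DataFrame, genotypes, model: str,
                trait: str = "sbp", n_pcs: int = 20,
                site_adjust: bool = False, effect_allele: str = "alt",
                qc_thresholds: dict | None = None,
                apply_qc: bool = True,
                variant_subset=None) -> list:
    """Run the interaction test over all (QC-passing) variants.

    Returns one :class:`ScanRecord` per variant that passes the
    model-appropriate filters, in input order. ``variant_subset`` restricts
    the scan to the given variant ids (e.g. replication of suggestive loci),
    bypassing the frequency filters.
    """
    if trait not in cohort:
        raise KeyError(f"trait column {trait!r} absent from cohort")
    if model not in CODING_MODELS:
        raise ValueError(f"unknown coding model {model!r}")

    geno = genotypes
    if geno.subject_ids and "subject_id" in cohort:
        geno = geno.subset_subjects(list(cohort["subject_id"]))

    E = cohort["daily_sodium"].to_numpy(float)
    y = cohort[trait].to_numpy(float)
    C = design_covariates(cohort, n_pcs=n_pcs, site_adjust=site_adjust)

    subset = None if variant_subset is None else set(variant_subset)
    qc_effect = "minor" if effect_allele == "minor" else effect_allele
    records = []
    for i, vid in enumerate(geno.variant_ids):
        if subset is not None and vid not in subset:
            continue
        report = qcmod.compute_variant_qc(
            geno.hard_calls[i], geno.r2[i], variant_id=vid,
            thresholds=qc_thresholds, effect_allele=qc_effect)
        if subset is None and apply_qc and not report.passes_model(model):
            continue
        if model == "dosage":
            G = geno.dosages[i].astype(float)
            if effect_allele == "ref":
                G = 2.0 - G
        else:
            G, _ = code_genotype(posteriors=geno.gp[i], model=model,
                                 effect_allele=effect_allele)
        rec = fit_interaction_lrt(G, E, y, covariates=C, variant_id=vid,
                                  coding_model=model, site_adjusted=site_adjust)
        if model in ("dominant", "recessive"):
            rec.coded_genotype_freq = float(np.nanmean(G))
        else:
            af = float(np.nanmean(G)) / 2.0
            rec.coded_genotype_freq = af
        records.append(rec)
    return records


def genomic_control(records: list, floor_at_one: bool = True):
    """Apply genomic-control correction to a list of scan records.

    lambda = median(LRT statistic) / median of chi-square(1); corrected
    statistics are LRT / max(lambda, 1) (no deflation below 1 by default) and
    ``p_gc`` is filled in place. Returns ``(lambda, records)``.
    """
    stats_ = np.array([r.lrt_stat for r in records
                       if not r.untestable and np.isfinite(r.lrt_stat)])
    if stats_.size == 0:
        raise ValueError("no testable records for genomic control")
    if stats_.size < 100:
        warnings.warn(
            f"genomic control on only {stats_.size} records; "
            "lambda estimate will be noisy", stacklevel=2)
    lam = float(np.median(stats_) / CHI2_MEDIAN_1DF)
    divisor = max(lam, 1.0) if floor_at_one else lam
    for r in records:
        if r.untestable or not np.isfinite(r.lrt_stat):
            continue
        r.p_gc = float(stats.chi2.sf(r.lrt_stat / divisor, 1))
    return lam, records


def two_stage_evaluate(discovery: ScanRecord, replication: ScanRecord,
                       combined: ScanRecord,
                       suggestive_p: float = SUGGESTIVE_P,
                       replication_p: float = REPLICATION_P,
                       genome_wide_p: float = GENOME_WIDE_P) -> TwoStageDecision:
    """Stage a locus through the discovery/replication/combined gates.

    suggestive: discovery GC-corrected p below ``suggestive_p``;
    replicated: additionally replication p below ``replication_p`` with the
    interaction effect in the same direction; genome_wide: additionally
    combined p below ``genome_wide_p`` from a site-adjusted combined fit.
    """
    ids = {discovery.variant_id, replication.variant_id, combined.variant_id}
    if len(ids) != 1:
        raise ValueError(f"mismatched variant ids in two-stage evaluation: {ids}")
    models = {discovery.coding_model, replication.coding_model, combined.coding_model}
    if len(models) != 1:
        raise ValueError(f"mismatched coding models in two-stage evaluation: {models}")

    p_disc = discovery.p_gc if np.isfinite(discovery.p_gc) else discovery.p_raw
    p_repl = replication.p_raw
    p_comb = combined.p_raw
    consistent = (np.sign(discovery.beta_GE) == np.sign(replication.beta_GE)
                  and discovery.beta_GE != 0)

    status = "none"
    if np.isfinite(p_disc) and p_disc < suggestive_p:
        status = "suggestive"
        if np.isfinite(p_repl) and p_repl < replication_p and consistent:
            status = "replicated"
            if (np.isfinite(p_comb) and p_comb < genome_wide_p
                    and combined.site_adjusted):
                status = "genome_wide"
    return TwoStageDecision(
        variant_id=discovery.variant_id,
        p_discovery=float(p_disc), p_replication=float(p_repl),
        p_combined=float(p_comb), direction_consistent=bool(consistent),
        status=status,
    )


def scan_table(records: list) -> pd.DataFrame:
    """Scan records as a tidy DataFrame (one row per variant)."""
    return pd.DataFrame([{
        "variant_id": r.variant_id,
        "coding_model": r.coding_model,
        "coded_genotype_freq": r.coded_genotype_freq,
        "beta_G": r.beta_G,
        "beta_E": r.beta_E,
        "beta_GE": r.beta_GE,
        "se_GE": r.se_GE,
        "lrt_stat": r.lrt_stat,
        "p_raw": r.p_raw,
        "p_gc": r.p_gc,
        "n_used": r.n_used,
        "untestable": r.untestable,
        "reason": r.reason,
    } for r in records])


def qq_data(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot, as plot-ready data."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    return pd.DataFrame({"expected_neglog10p": expected,
                         "observed_neglog10p": observed})
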