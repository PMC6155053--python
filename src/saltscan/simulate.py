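"""Synthetic cohort generator.

Produces cohorts with the statistical structure the interaction analysis
assumes — Hardy–Weinberg genotypes with configurable imputation noise, daily
sodium intake ~ Normal(164.8, 37.9) mEq/day, blood pressure from a linear
model with genetic main and interaction effects plus Gaussian residual noise,
and an optional second study site with shifted age/SBP/sodium means — so every
downstream stage is testable without access-restricted cohort data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .phenotype import SodiumFormulaCoefficients, TANAKA

#: Site mean shifts (replication minus discovery) for age (years), SBP (mm Hg)
#: and daily sodium (mEq/day), matching the two study populations emulated.
DEFAULT_SITE_OFFSETS = {"replication": {"age": 3.6, "sbp": 3.3, "sodium": 11.8}}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Phenotype model (applied to SBP at the causal variant, coded per
    ``coding_model``):

        SBP = beta0 + beta_G*G + beta_E*E + beta_GE*G*E
              + beta_age*age + beta_male*male + beta_bmi*BMI + N(0, resid_sd)

    E is daily sodium ~ Normal(mu_na, sigma_na) mEq/day. DBP follows its own
    linear model in E (no genetic terms by default). Defaults for the
    demographic distributions match the discovery population's summary
    statistics; covariate effect sizes default to zero because the source
    analysis adjusts for them without reporting their magnitudes.
    """

    n_subjects: int = 1000
    n_replication: int = 0
    n_variants: int = 50
    maf: float | tuple = 0.2
    causal_index: int | None = None
    beta0: float = 121.4
    beta_G: float = 0.0
    beta_E: float = 0.041426
    beta_GE: float = 0.0
    mu_na: float = 164.8
    sigma_na: float = 37.9
    resid_sd: float = 19.2
    coding_model: str = "additive"
    effect_allele: str = "alt"
    imputation_quality: float = 0.99
    site_offsets: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_SITE_OFFSETS.items()})
    seed: int = 0
    # demographics (discovery defaults)
    age_mean: float = 59.0
    age_sd: float = 11.8
    female_prop: float = 0.664
    bmi_mean: float = 23.6
    bmi_sd: float = 3.6
    height_mean: float = 158.0
    height_sd: float = 8.0
    med_prop: float = 0.237
    n_pcs: int = 20
    measurement_sd: float = 3.0
    missing_rate: float = 0.0
    # covariate effects on SBP (mm Hg per unit)
    beta_age: float = 0.0
    beta_male: float = 0.0
    beta_bmi: float = 0.0
    # DBP model
    beta0_dbp: float = 73.4
    beta_E_dbp: float = 0.019897
    resid_sd_dbp: float = 11.9

    def __post_init__(self) -> None:
        mafs = np.atleast_1d(np.asarray(self.maf, dtype=float))
        if mafs.size not in (1, self.n_variants):
            raise ValueError("maf must be scalar or of length n_variants")
        bad = ~np.isfinite(mafs) | (mafs <= 0) | (mafs >= 1)
        if bad.any():
            raise ValueError(
                f"maf out of (0,1) or non-finite at variant index {int(bad.argmax())}")
        if not (0 < self.imputation_quality <= 1):
            raise ValueError("imputation_quality must be in (0, 1]")
        if self.sigma_na <= 0 or self.resid_sd <= 0:
            raise ValueError("sigma_na and resid_sd must be positive")
        if self.causal_index is not None and not (
                0 <= self.causal_index < self.n_variants):
            raise ValueError(
                f"causal_index {self.causal_index} out of range "
                f"for {self.n_variants} variants")
        if self.coding_model not in ("dosage", "additive", "dominant", "recessive"):
            raise ValueError(f"unknown coding_model {self.coding_model!r}")

    @property
    def maf_vector(self) -> np.ndarray:
        mafs = np.atleast_1d(np.asarray(self.maf, dtype=float))
        if mafs.size == 1:
            mafs = np.full(self.n_variants, float(mafs[0]))
        return mafs

    @property
    def n_total(self) -> int:
        return self.n_subjects + self.n_replication

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def gen_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None
                  ) -> GenotypeMatrix:
    """Draw HWE genotypes with calibrated imputation noise.

    True genotypes are Binomial(2, maf) per variant. Each entry independently
    keeps a degenerate posterior on the true genotype with probability equal
    to ``imputation_quality`` (the target dosage-vs-truth R²); otherwise the
    posterior collapses to the variant's HWE prior and the recorded call is
    redrawn from that prior, which keeps the hard-call margins exactly HWE
    while making the empirical R² equal the target in expectation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_total, config.n_variants
    mafs = config.maf_vector
    eps = 1.0 - config.imputation_quality

    true_g = rng.binomial(2, mafs[:, None], size=(m, n)).astype(np.int8)
    noisy = rng.random((m, n)) < eps
    redraw = rng.binomial(2, mafs[:, None], size=(m, n)).astype(np.int8)
    hard = np.where(noisy, redraw, true_g).astype(np.int8)

    gp = np.zeros((m, n, 3))
    eye = np.eye(3)
    gp[~noisy] = eye[true_g[~noisy]]
    p = mafs[:, None] * np.ones((m, n))
    prior = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=-1)
    gp[noisy] = prior[noisy]
    dosages = gp[:, :, 1] + 2.0 * gp[:, :, 2]

    r2 = np.empty(m)
    for j in range(m):
        tv = np.var(true_g[j])
        if tv == 0 or np.var(dosages[j]) == 0:
            r2[j] = 1.0 if eps == 0 else 0.0
        else:
            c = np.corrcoef(dosages[j], true_g[j])[0, 1]
            r2[j] = c * c

    return GenotypeMatrix(
        variant_ids=[f"var{j + 1}" for j in range(m)],
        chrom=np.ones(m, dtype=int),
        pos=np.arange(1, m + 1) * 1000,
        ref=["G"] * m,
        alt=["A"] * m,
        dosages=dosages,
        gp=gp,
        hard_calls=hard,
        r2=r2,
        subject_ids=[f"S{i + 1:06d}" for i in range(n)],
        true_genotypes=true_g,
    )


def _code_true(g: np.ndarray, model: str, effect_allele: str) -> np.ndarray:
    count = g.astype(float) if effect_allele == "alt" else 2.0 - g
    if model in ("dosage", "additive"):
        return count
    if model == "dominant":
        return (count >= 1).astype(float)
    return (count >= 2).astype(float)


def gen_cohort(config: SimulationConfig):
    """Generate a cohort table and genotype matrix under the configured model.

    Returns ``(cohort, genotypes)``. The cohort holds raw paired BP
    measurements (``sbp1``/``sbp2``, ``dbp1``/``dbp2``) from which the
    preparation stage computes analysis BP: medicated subjects' recorded
    pressure is lowered by exactly the imputation constants (10/5 mm Hg), so
    medication imputation recovers the generated untreated value.
    """
    rng = np.random.default_rng(config.seed)
    genotypes = gen_genotypes(config, rng)
    n = config.n_total

    site = np.array(["discovery"] * config.n_subjects
                    + ["replication"] * config.n_replication)
    off = config.site_offsets.get("replication", {})
    is_rep = site == "replication"

    age = rng.normal(config.age_mean, config.age_sd, n) + np.where(
        is_rep, off.get("age", 0.0), 0.0)
    female = rng.random(n) < config.female_prop
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, n)
    height = rng.normal(config.height_mean, config.height_sd, n)
    weight = bmi * (height / 100.0) ** 2
    sodium = rng.normal(config.mu_na, config.sigma_na, n) + np.where(
        is_rep, off.get("sodium", 0.0), 0.0)
    pcs = rng.normal(size=(n, config.n_pcs))
    on_med = rng.random(n) < config.med_prop

    if config.causal_index is not None:
        g_true = genotypes.true_genotypes[config.causal_index]
        G = _code_true(g_true, config.coding_model, config.effect_allele)
    else:
        G = np.zeros(n)

    sbp = (config.beta0 + config.beta_G * G + config.beta_E * sodium
           + config.beta_GE * G * sodium
           + config.beta_age * age + config.beta_male * (~female)
           + config.beta_bmi * bmi
           + rng.normal(0.0, config.resid_sd, n)
           + np.where(is_rep, off.get("sbp", 0.0), 0.0))
    dbp = (config.beta0_dbp + config.beta_E_dbp * sodium
           + rng.normal(0.0, config.resid_sd_dbp, n))

    # recorded readings: treated pressure is lower than the modelled
    # untreated value by exactly the imputation constants
    sbp_obs = sbp - np.where(on_med, 10.0, 0.0)
    dbp_obs = dbp - np.where(on_med, 5.0, 0.0)
    sbp1 = sbp_obs + rng.normal(0.0, config.measurement_sd, n)
    sbp2 = sbp_obs + rng.normal(0.0, config.measurement_sd, n)
    dbp1 = dbp_obs + rng.normal(0.0, config.measurement_sd, n)
    dbp2 = dbp_obs + rng.normal(0.0, config.measurement_sd, n)

    cohort = pd.DataFrame({
        "subject_id": genotypes.subject_ids,
        "age": age,
        "sex": np.where(female, "female", "male"),
        "bmi": bmi,
        "height": height,
        "weight": weight,
        "sbp1": sbp1, "sbp2": sbp2,
        "dbp1": dbp1, "dbp2": dbp2,
        "on_antihypertensive": on_med,
        "daily_sodium": sodium,
        "site": site,
    })
    for i in range(config.n_pcs):
        cohort[f"pc{i + 1}"] = pcs[:, i]

    if config.missing_rate > 0:
        for col in ("bmi", "daily_sodium"):
            drop = rng.random(n) < config.missing_rate
            cohort.loc[drop, col] = np.nan
    return cohort, genotypes


def gen_spot_urine(cohort: pd.DataFrame,
                   coeffs: SodiumFormulaCoefficients = TANAKA,
                   noise_sd: float = 0.0,
                   rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Emit spot-urine analytes whose formula estimate returns daily sodium.

    Inverts the spot-urine estimator: chooses a plausible spot creatinine and
    solves for the spot sodium that makes the configured formula reproduce
    each subject's ``daily_sodium``. ``noise_sd`` applies multiplicative
    log-normal noise on the implied 24-h excretion scale, emulating the
    estimator's real-world imprecision; at 0 the round trip is exact.
    """
    if "daily_sodium" not in cohort or cohort["daily_sodium"].isna().any():
        raise ValueError("daily_sodium must be present for every subject")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    out = cohort.copy()
    n = len(out)
    pr_cr = coeffs.predicted_creatinine(out["age"], out["weight"], out["height"])
    pr_cr = np.asarray(pr_cr, dtype=float)
    if np.any(pr_cr <= 0):
        bad = out.index[pr_cr <= 0][0]
        raise ValueError(f"predicted creatinine non-positive for subject {bad}; "
                         "formula inversion is not monotone there")

    target = out["daily_sodium"].to_numpy(float)
    if noise_sd > 0:
        target = target * np.exp(rng.normal(0.0, noise_sd, n))
    spot_cr = np.exp(rng.normal(np.log(100.0), 0.4, n))  # mg/dL, plausible spread
    ratio_arg = np.power(target / coeffs.scale, 1.0 / coeffs.exponent)
    spot_na = ratio_arg / pr_cr * coeffs.cr_unit_factor * spot_cr
    out["spot_urine_na"] = spot_na
    out["spot_urine_cr"] = spot_cr
    return out
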