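"""Monte-Carlo power of the 1-df interaction likelihood-ratio test.

Simulates cohorts under the generative model

    BP = beta_E * E + beta_GE * G * E + Normal(0, resid_sd),

with E ~ Normal(mu_na, sigma_na) and G drawn Binomial(2, freq) (additive
coding) or Bernoulli(freq) (dominant/recessive coding), fits the nested
interaction models, and records how often the interaction term reaches the
significance threshold. An analytic cross-check uses the noncentral
chi-square approximation with noncentrality

    NCP = n * beta_GE^2 * Var(G) * sigma_na^2 / resid_sd^2,

exact for this design because G x E is orthogonal to (1, G, E) up to the
product of centred moments when G and E are independent.

The BP outcome the generative model describes is covariate-adjusted residual
blood pressure, so ``resid_sd`` is the SD of BP after age/sex/BMI adjustment,
not the raw phenotype SD. That residual SD is not published for the study
populations; the defaults below (17.3 mm Hg SBP, 10.9 mm Hg DBP) are obtained
by inverting the exact 1-df noncentral power formula at the published power
operating points (see :func:`resid_sd_from_power` and docs/methods.md), and
imply covariate R^2 of about 0.19/0.16 — realistic for age, sex and BMI.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd
from scipy import stats, optimize

from .scan import fit_interaction_lrt

#: Per-trait defaults: sodium main effect (mm Hg per mEq/day) estimated in the
#: discovery population, and the reconstructed adjusted-BP residual SD (mm Hg).
TRAIT_DEFAULTS = {
    "sbp": {"beta_E": 0.041426, "resid_sd": 17.3},
    "dbp": {"beta_E": 0.019897, "resid_sd": 10.9},
}

_GRID_RATIOS = (0.5, 1.0, 1.5, 2.0)
_GRID_FREQS = (0.2, 0.5)
_GRID_MODELS = ("additive", "dominant", "recessive")


@dataclass(frozen=True)
class PowerSpec:
    """One cell of the power grid.

    ``freq`` is the effect *allele* frequency under the additive model and the
    effect *genotype* (carrier or homozygote) frequency under the
    dominant/recessive models, where G is a 0/1 indicator. ``beta_E`` and
    ``resid_sd`` default per trait.
    """

    trait: str = "sbp"
    n: int = 4527
    mu_na: float = 164.8
    sigma_na: float = 37.9
    beta_E: float | None = None
    beta_GE_ratio: float = 2.0
    model: str = "additive"
    freq: float = 0.2
    resid_sd: float | None = None
    alpha: float = 1e-5
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trait not in TRAIT_DEFAULTS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.model not in ("additive", "dominant", "recessive"):
            raise ValueError(f"unknown power model {self.model!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.freq < 1):
            raise ValueError("freq must be in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def beta_E_value(self) -> float:
        return (TRAIT_DEFAULTS[self.trait]["beta_E"]
                if self.beta_E is None else self.beta_E)

    @property
    def resid_sd_value(self) -> float:
        return (TRAIT_DEFAULTS[self.trait]["resid_sd"]
                if self.resid_sd is None else self.resid_sd)

    @property
    def beta_GE(self) -> float:
        return self.beta_GE_ratio * self.beta_E_value

    @property
    def var_G(self) -> float:
        f = self.freq
        return 2 * f * (1 - f) if self.model == "additive" else f * (1 - f)


@dataclass(frozen=True)
class PowerResult:
    spec: PowerSpec
    power: float
    mc_se: float
    analytic_power: float


def _draw_G(spec: PowerSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.model == "additive":
        return rng.binomial(2, spec.freq, spec.n).astype(float)
    return (rng.random(spec.n) < spec.freq).astype(float)


def simulate_once(spec: PowerSpec, rng: np.random.Generator) -> bool:
    """One Monte-Carlo replicate: True iff the interaction p falls below alpha."""
    E = rng.normal(spec.mu_na, spec.sigma_na, spec.n)
    G = _draw_G(spec, rng)
    bp = (spec.beta_E_value * E + spec.beta_GE * G * E
          + rng.normal(0.0, spec.resid_sd_value, spec.n))
    rec = fit_interaction_lrt(G, E, bp)
    return (not rec.untestable) and rec.p_raw < spec.alpha


def analytic_power(spec: PowerSpec) -> float:
    """Noncentral chi-square(1) power at the spec's operating point."""
    ncp = (spec.n * spec.beta_GE ** 2 * spec.var_G * spec.sigma_na ** 2
           / spec.resid_sd_value ** 2)
    crit = stats.chi2.isf(spec.alpha, 1)
    if ncp == 0:
        return float(spec.alpha)
    return float(stats.ncx2.sf(crit, 1, ncp))


def estimate_power(spec: PowerSpec) -> PowerResult:
    """Monte-Carlo power estimate with its binomial SE and analytic check."""
    rng = np.random.default_rng(spec.seed)
    hits = sum(simulate_once(spec, rng) for _ in range(spec.iterations))
    p = hits / spec.iterations
    mc_se = float(np.sqrt(p * (1 - p) / spec.iterations))
    return PowerResult(spec=spec, power=float(p), mc_se=mc_se,
                       analytic_power=analytic_power(spec))


def power_grid(base_spec: PowerSpec | None = None,
               traits: tuple = ("sbp", "dbp"),
               models: tuple = _GRID_MODELS,
               freqs: tuple = _GRID_FREQS,
               ratios: tuple = _GRID_RATIOS) -> pd.DataFrame:
    """Power over the trait x model x frequency x effect-ratio grid."""
    if base_spec is None:
        base_spec = PowerSpec()
    rows = []
    for trait in traits:
        for model in models:
            for freq in freqs:
                for ratio in ratios:
                    spec = replace(base_spec, trait=trait, model=model,
                                   freq=freq, beta_GE_ratio=ratio,
                                   beta_E=None, resid_sd=None)
                    res = estimate_power(spec)
                    row = asdict(spec)
                    row.update(beta_E=spec.beta_E_value,
                               resid_sd=spec.resid_sd_value,
                               power=res.power, mc_se=res.mc_se,
                               analytic_power=res.analytic_power)
                    rows.append(row)
    return pd.DataFrame(rows)


def resid_sd_from_power(target_power: float, n: int, beta_GE: float,
                        var_G: float, sigma_E: float,
                        alpha: float = 1e-5) -> float:
    """Residual SD implied by a published power value.

    Inverts the exact 1-df noncentral chi-square power at the stated design
    (the inversion that fixes the trait default residual SDs).
    """
    crit = stats.chi2.isf(alpha, 1)

    def gap(ncp):
        return stats.ncx2.sf(crit, 1, ncp) - target_power

    ncp = optimize.brentq(gap, 1e-9, 1e6)
    return float(np.sqrt(n * beta_GE ** 2 * var_G * sigma_E ** 2 / ncp))
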