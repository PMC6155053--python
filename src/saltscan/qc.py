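"""Variant-level quality control.

Implements the scan's variant filters — call rate, Hardy–Weinberg exact test,
minor allele frequency, imputation R², and coded-genotype frequency for the
dominant/recessive codings — with the conventional two-sided HWE exact test
computed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default thresholds; values printed as "<" in the source filters exclude,
#: so equality passes.
DEFAULT_THRESHOLDS = {
    "call_rate": 0.95,
    "hwe_p": 1e-6,
    "maf": 0.01,
    "r2": 0.8,
    "coded_genotype_freq": 0.01,
}

# Relative tie tolerance when comparing outcome probabilities to the observed
# one: configurations with probability equal up to rounding are included in
# the tail, as in the conventional implementation.
_TIE_RTOL = 1e-10


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy–Weinberg exact test P-value.

    Conditional on the allele counts, sums the probabilities of every
    heterozygote count whose conditional probability does not exceed that of
    the observed count. The distribution is built by the standard ratio
    recurrence P(h+2)/P(h) = 4·n_AA(h)·n_BB(h) / ((h+1)(h+2)) accumulated in
    the log domain, so large samples neither overflow nor underflow.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers, got {counts}")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("total genotype count must be positive")

    n_a = 2 * n_hom_ref + n_het           # ref allele count
    n_b = 2 * n_hom_alt + n_het
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0                         # monomorphic: single configuration

    # attainable het counts share the parity of the rare allele count
    h_min = rare % 2
    hs = np.arange(h_min, rare + 1, 2)
    # log ratio of successive terms, accumulated from h_min upward
    h_lo = hs[:-1].astype(float)
    hom_a = (n_a - h_lo) / 2.0             # n_AA at h_lo
    hom_b = (n_b - h_lo) / 2.0
    log_ratio = np.log(4.0 * hom_a * hom_b) - np.log((h_lo + 1.0) * (h_lo + 2.0))
    log_p = np.concatenate(([0.0], np.cumsum(log_ratio)))
    log_p -= log_p.max()
    probs = np.exp(log_p)
    probs /= probs.sum()

    obs = probs[(n_het - h_min) // 2]
    p = probs[probs <= obs * (1.0 + _TIE_RTOL)].sum()
    return float(min(p, 1.0))


@dataclass
class VariantQCReport:
    """Per-variant QC metrics and pass flags.

    ``genotype_freqs`` are the hard-call frequencies of (hom-ref, het,
    hom-alt) among non-missing calls; ``coded_genotype_freq`` holds the coded
    class frequency per dominant/recessive coding of the minor allele.
    """

    variant_id: str
    call_rate: float
    maf: float
    hwe_p: float
    imputation_r2: float
    genotype_freqs: tuple = (np.nan, np.nan, np.nan)
    coded_genotype_freq: dict = field(default_factory=dict)
    passes: dict = field(default_factory=dict)

    def passes_model(self, model: str) -> bool:
        """True iff the variant passes all filters relevant to a coding model."""
        base = self.passes.get("call_rate", False) and \
            self.passes.get("hwe_p", False) and self.passes.get("r2", False)
        if model in ("dosage", "additive"):
            return base and self.passes.get("maf", False)
        if model in ("dominant", "recessive"):
            return base and self.passes.get(f"cgf_{model}", False)
        raise ValueError(f"unknown coding model {model!r}")


def genotype_class_frequencies(hard_calls: np.ndarray) -> tuple:
    """(f_hom_ref, f_het, f_hom_alt) among non-missing calls (-1 = missing)."""
    ok = hard_calls >= 0
    n = int(ok.sum())
    if n == 0:
        return (np.nan, np.nan, np.nan)
    counts = np.bincount(hard_calls[ok], minlength=3)
    return tuple(counts[:3] / n)


def compute_variant_qc(hard_calls: np.ndarray, imputation_r2: float,
                       variant_id: str = "", thresholds: dict | None = None,
                       effect_allele: str = "minor") -> VariantQCReport:
    """QC metrics for one variant from hard calls (0/1/2, -1 missing).

    ``effect_allele`` selects the allele whose carrier (dominant) and
    homozygote (recessive) classes are frequency-checked: ``"minor"`` (the
    default, matching the scan's coding), ``"ref"`` or ``"alt"``.
    An all-missing variant yields an all-fail report rather than an error.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    hard_calls = np.asarray(hard_calls)
    n_total = hard_calls.size
    ok = hard_calls >= 0
    n = int(ok.sum())
    call_rate = n / n_total if n_total else 0.0

    if n == 0:
        report = VariantQCReport(variant_id, 0.0, np.nan, np.nan,
                                 float(imputation_r2))
        report.passes = {k: False for k in
                         ("call_rate", "hwe_p", "maf", "r2",
                          "cgf_dominant", "cgf_recessive")}
        return report

    counts = np.bincount(hard_calls[ok], minlength=3)[:3]
    n_ref, n_het, n_alt = (int(c) for c in counts)
    alt_freq = (n_het + 2 * n_alt) / (2 * n)
    maf = min(alt_freq, 1.0 - alt_freq)
    hwe_p = hwe_exact_test(n_ref, n_het, n_alt)
    freqs = tuple(counts / n)

    if effect_allele == "minor":
        allele_is_alt = alt_freq <= 0.5
    elif effect_allele in ("ref", "alt"):
        allele_is_alt = effect_allele == "alt"
    else:
        raise ValueError(f"unknown effect_allele {effect_allele!r}")
    if allele_is_alt:
        carrier = freqs[1] + freqs[2]
        homozygote = freqs[2]
    else:
        carrier = freqs[0] + freqs[1]
        homozygote = freqs[0]
    cgf = {"dominant": carrier, "recessive": homozygote}

    report = VariantQCReport(
        variant_id=variant_id, call_rate=call_rate, maf=maf, hwe_p=hwe_p,
        imputation_r2=float(imputation_r2), genotype_freqs=freqs,
        coded_genotype_freq=cgf,
    )
    r2 = float(imputation_r2)
    report.passes = {
        "call_rate": call_rate >= thr["call_rate"],
        "hwe_p": hwe_p >= thr["hwe_p"],
        "maf": maf >= thr["maf"],
        "r2": (np.isnan(r2) or r2 >= thr["r2"]),
        "cgf_dominant": cgf["dominant"] >= thr["coded_genotype_freq"],
        "cgf_recessive": cgf["recessive"] >= thr["coded_genotype_freq"],
    }
    return report


def qc_table(genotypes, thresholds: dict | None = None,
             effect_allele: str = "minor") -> pd.DataFrame:
    """Run :func:`compute_variant_qc` over a GenotypeMatrix; one row/variant."""
    rows = []
    for i, vid in enumerate(genotypes.variant_ids):
        rep = compute_variant_qc(
            genotypes.hard_calls[i], genotypes.r2[i], variant_id=vid,
            thresholds=thresholds, effect_allele=effect_allele,
        )
        row = {
            "variant_id": rep.variant_id,
            "call_rate": rep.call_rate,
            "maf": rep.maf,
            "hwe_p": rep.hwe_p,
            "imputation_r2": rep.imputation_r2,
            "freq_hom_ref": rep.genotype_freqs[0],
            "freq_het": rep.genotype_freqs[1],
            "freq_hom_alt": rep.genotype_freqs[2],
            "cgf_dominant": rep.coded_genotype_freq.get("dominant", np.nan),
            "cgf_recessive": rep.coded_genotype_freq.get("recessive", np.nan),
        }
        row.update({f"pass_{k}": v for k, v in rep.passes.items()})
        rows.append(row)
    return pd.DataFrame(rows)
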