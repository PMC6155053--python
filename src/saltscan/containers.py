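"""In-memory containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GenotypeMatrix:
    """Per-variant genotypes for a cohort.

    Arrays are variant-major: ``dosages`` is ``(n_variants, n_subjects)``,
    ``gp`` is ``(n_variants, n_subjects, 3)`` with genotype posterior mass on
    (hom-ref, het, hom-alt), and ``hard_calls`` holds best-guess genotypes as
    alt-allele counts with -1 marking missing. ``r2`` is the per-variant
    imputation quality. ``true_genotypes`` is populated only by the synthetic
    generator (the simulation truth; never serialised).
    """

    variant_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    ref: list
    alt: list
    dosages: np.ndarray
    gp: np.ndarray
    hard_calls: np.ndarray
    r2: np.ndarray
    subject_ids: list = field(default_factory=list)
    true_genotypes: np.ndarray | None = None

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[1]

    def subset_subjects(self, subject_ids) -> "GenotypeMatrix":
        """Column subset/reorder aligned to the given subject id order."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in index]
        if missing:
            raise KeyError(f"subjects absent from genotype matrix: {missing[:5]}")
        cols = np.array([index[s] for s in subject_ids], dtype=int)
        return GenotypeMatrix(
            variant_ids=list(self.variant_ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=list(self.ref),
            alt=list(self.alt),
            dosages=self.dosages[:, cols],
            gp=self.gp[:, cols, :],
            hard_calls=self.hard_calls[:, cols],
            r2=self.r2.copy(),
            subject_ids=list(subject_ids),
            true_genotypes=None if self.true_genotypes is None
            else self.true_genotypes[:, cols],
        )
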