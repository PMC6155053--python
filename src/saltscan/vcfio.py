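"""Genotype and phenotype file interchange.

VCF v4.2 is the canonical genotype format (FORMAT GT/DS/GP, INFO R2, 1-based
coordinates); phenotype/covariate tables travel as TSV. VCF reading goes
through pysam; note that VCF Float FORMAT fields are 32-bit, so dosages
round-trip at float32 precision.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pysam

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality (dosage R-square)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Best-guess genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">
##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior probabilities">
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write the matrix as an uncompressed VCF v4.2 text file."""
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for chrom in dict.fromkeys(str(c) for c in genotypes.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.subject_ids) + "\n")
        for i, vid in enumerate(genotypes.variant_ids):
            fields = [
                str(genotypes.chrom[i]), str(int(genotypes.pos[i])), vid,
                genotypes.ref[i], genotypes.alt[i], ".", "PASS",
                f"R2={genotypes.r2[i]:.9g}", "GT:DS:GP",
            ]
            calls = []
            for j in range(genotypes.n_subjects):
                gt = _GT_STRINGS[int(genotypes.hard_calls[i, j])]
                ds = f"{genotypes.dosages[i, j]:.9g}"
                gp = ",".join(f"{p:.9g}" for p in genotypes.gp[i, j])
                calls.append(f"{gt}:{ds}:{gp}")
            fh.write("\t".join(fields + calls) + "\n")


def _empirical_r2(dosage: np.ndarray) -> float:
    """MaCH-style imputation quality: Var(DS) / (2p(1-p)) with p from DS."""
    p = float(np.nanmean(dosage)) / 2.0
    denom = 2.0 * p * (1.0 - p)
    if denom <= 0:
        return np.nan
    return float(min(np.nanvar(dosage) / denom, 1.0))


def read_genotypes(path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    Missing GP is reconstructed as degenerate mass on the GT call; missing DS
    is computed from GP. INFO R2 is used when present, otherwise an empirical
    dosage-based estimate. Multiallelic records are skipped with a warning.
    Records with none of GT, DS or GP raise an error naming the record.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    n = len(samples)
    ids, chroms, poss, refs, alts, r2s = [], [], [], [], [], []
    ds_rows, gp_rows, hc_rows = [], [], []
    n_multiallelic = 0

    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multiallelic += 1
            logger.warning("skipping multiallelic record %s:%s", rec.chrom, rec.pos)
            continue
        fmt = set(rec.format.keys())
        if not fmt & {"GT", "DS", "GP"}:
            raise ValueError(f"record {rec.chrom}:{rec.pos} has none of GT/DS/GP")

        gp = np.full((n, 3), np.nan)
        hc = np.full(n, -1, dtype=np.int8)
        ds = np.full(n, np.nan)
        for j, s in enumerate(samples):
            call = rec.samples[s]
            g = None
            if "GT" in fmt and call.get("GT") is not None:
                alleles = call["GT"]
                if alleles is not None and None not in alleles:
                    g = int(sum(alleles))
                    hc[j] = g
            if "GP" in fmt and call.get("GP") is not None:
                vals = call["GP"]
                if vals is not None and len(vals) == 3 and vals[0] is not None:
                    gp[j] = np.asarray(vals, dtype=np.float32)
            elif g is not None:
                row = np.zeros(3, dtype=np.float32)
                row[g] = 1.0
                gp[j] = row
            if "DS" in fmt and call.get("DS") is not None:
                ds[j] = np.float32(call["DS"])
            elif np.isfinite(gp[j]).all():
                ds[j] = gp[j, 1] + 2.0 * gp[j, 2]
            if hc[j] < 0 and np.isfinite(gp[j]).all():
                hc[j] = int(np.argmax(gp[j]))

        ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        chroms.append(rec.chrom)
        poss.append(rec.pos)  # pysam yields the 1-based VCF POS here
        refs.append(rec.ref)
        alts.append(rec.alts[0])
        r2 = rec.info.get("R2")
        r2s.append(float(r2) if r2 is not None else _empirical_r2(ds))
        ds_rows.append(ds)
        gp_rows.append(gp)
        hc_rows.append(hc)

    if n_multiallelic:
        logger.warning("skipped %d multiallelic records", n_multiallelic)
    matrix = GenotypeMatrix(
        variant_ids=ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=int),
        ref=refs, alt=alts,
        dosages=np.array(ds_rows) if ds_rows else np.empty((0, n)),
        gp=np.array(gp_rows) if gp_rows else np.empty((0, n, 3)),
        hard_calls=np.array(hc_rows, dtype=np.int8) if hc_rows
        else np.empty((0, n), dtype=np.int8),
        r2=np.array(r2s, dtype=float),
        subject_ids=samples,
    )
    matrix.n_multiallelic_skipped = n_multiallelic
    return matrix


def write_phenotypes(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
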