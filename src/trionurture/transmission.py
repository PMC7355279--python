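"""Transmitted / non-transmitted dosage construction from genotyped trios.

For a biallelic, Mendelian-consistent trio the pseudo-control genotype made
of the two parental alleles not passed to the child is, in dosage form,
simply ``father + mother - child`` — no phasing needed.  This module
performs that split, detects Mendelian inconsistencies, and applies the
trio-level SNP filters (autosomal ACGT biallelic SNPs, unique positions,
MAF, exact HWE, call rate).

Not every genotyping error is detectable from dosages: for example, any
child dosage is consistent with two heterozygous parents.  Such errors pass
silently; the detectable set is characterised exactly by the interval
bounds used in :func:`mendelian_check`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .qc import SnpThresholds, hwe_test_genotypes
from .types import (GenotypeSet, Pedigree, SplitGenotypes, STATUS_MENDEL_ERROR,
                    STATUS_MISSING, STATUS_OK)

AUTOSOMES = {str(i) for i in range(1, 23)}
_ACGT = set("ACGT")

#: Sample-level exclusion threshold: more than this many Mendelian errors.
MAX_SAMPLE_MENDEL_ERRORS = 20
#: SNP-level exclusion threshold: error rate at or above this fraction.
MAX_SNP_MENDEL_RATE = 0.02


def mendelian_check(father: np.ndarray, mother: np.ndarray,
                    child: np.ndarray) -> np.ndarray:
    """Vectorised trio consistency status.

    Each parent transmits between ``max(0, d - 1)`` and ``min(1, d)`` copies
    of the counted allele, so the child dosage must lie in the sum of those
    intervals.  Any missing member yields MISSING.
    """
    father = np.asarray(father, dtype=float)
    mother = np.asarray(mother, dtype=float)
    child = np.asarray(child, dtype=float)
    missing = np.isnan(father) | np.isnan(mother) | np.isnan(child)
    lo = np.maximum(0, father - 1) + np.maximum(0, mother - 1)
    hi = np.minimum(1, father) + np.minimum(1, mother)
    with np.errstate(invalid="ignore"):
        ok = (child >= lo) & (child <= hi)
    status = np.where(ok, STATUS_OK, STATUS_MENDEL_ERROR).astype(np.int8)
    status[missing] = STATUS_MISSING
    return status


def split_transmission(genotypes: GenotypeSet,
                       pedigree: Pedigree) -> SplitGenotypes:
    """Build the transmitted and non-transmitted dosage sets per offspring.

    Offspring lacking two genotyped parents are excluded with a logged
    reason.  Entries with a Mendelian error or a missing trio member
    propagate as missing in both outputs.  Samples with more than
    ``MAX_SAMPLE_MENDEL_ERRORS`` errors and SNPs with an error rate of at
    least ``MAX_SNP_MENDEL_RATE`` among informative trios are flagged in
    the exclusion tables.
    """
    offspring = pedigree.offspring().reset_index(drop=True)
    genotyped = set(genotypes.sample_ids)
    has_parents = offspring.apply(
        lambda r: r["individual_id"] in genotyped
        and r["father_id"] in genotyped and r["mother_id"] in genotyped, axis=1)
    excluded_samples = [
        {"sample_id": r["individual_id"], "reason": "missing genotyped parent or self"}
        for _, r in offspring[~has_parents].iterrows()]
    offspring = offspring[has_parents].reset_index(drop=True)
    if offspring.empty:
        raise ValueError("no offspring with two genotyped parents")

    f = genotypes.dosages[genotypes.sample_index(offspring["father_id"])]
    m = genotypes.dosages[genotypes.sample_index(offspring["mother_id"])]
    c = genotypes.dosages[genotypes.sample_index(offspring["individual_id"])]
    status = mendelian_check(f, m, c)

    ok = status == STATUS_OK
    transmitted = np.where(ok, c, np.nan)
    nontransmitted = np.where(ok, f + m - c, np.nan)

    err_per_sample = (status == STATUS_MENDEL_ERROR).sum(axis=1)
    for i in np.flatnonzero(err_per_sample > MAX_SAMPLE_MENDEL_ERRORS):
        excluded_samples.append({
            "sample_id": offspring["individual_id"].iloc[i],
            "reason": f"{err_per_sample[i]} Mendelian errors "
                      f"(> {MAX_SAMPLE_MENDEL_ERRORS})"})

    informative = (status != STATUS_MISSING).sum(axis=0)
    errors = (status == STATUS_MENDEL_ERROR).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(informative > 0, errors / np.maximum(informative, 1), 0.0)
    excluded_snps = [
        {"snp_id": genotypes.snps["snp_id"].iloc[j],
         "reason": f"Mendelian error rate {rate[j]:.3f} (>= {MAX_SNP_MENDEL_RATE})"}
        for j in np.flatnonzero(rate >= MAX_SNP_MENDEL_RATE)]

    ids = offspring["individual_id"].tolist()
    return SplitGenotypes(
        transmitted=GenotypeSet(transmitted, ids, genotypes.snps.copy()),
        nontransmitted=GenotypeSet(nontransmitted, ids, genotypes.snps.copy()),
        status=status,
        excluded_samples=pd.DataFrame(excluded_samples,
                                      columns=["sample_id", "reason"]),
        excluded_snps=pd.DataFrame(excluded_snps, columns=["snp_id", "reason"]),
    )


def trio_snp_filter(genotypes: GenotypeSet,
                    thresholds: SnpThresholds | None = None,
                    extra_alleles: pd.Series | None = None,
                    ) -> tuple[GenotypeSet, pd.DataFrame]:
    """Trio-stage SNP filters; returns the filtered set and removal counts.

    Criteria: ACGT single-base alleles only; autosomes only; unique
    (chrom, pos); biallelic (``extra_alleles`` marks records that carried
    additional ALT alleles on input); MAF above threshold; exact HWE p above
    threshold; call rate above threshold.
    """
    thr = thresholds or SnpThresholds()
    snps = genotypes.snps
    freq = genotypes.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)

    acgt = np.array([e in _ACGT and o in _ACGT and e != o
                     for e, o in zip(snps["effect_allele"], snps["other_allele"])])
    autosomal = snps["chrom"].astype(str).isin(AUTOSOMES).to_numpy()
    dup = snps.duplicated(subset=["chrom", "pos"], keep=False).to_numpy()
    multiallelic = (extra_alleles.to_numpy().astype(bool)
                    if extra_alleles is not None
                    else np.zeros(len(snps), dtype=bool))
    hwe_p = hwe_test_genotypes(genotypes.dosages)
    call_rate = genotypes.call_rate_snp()

    criteria = {
        "non_acgt": ~acgt,
        "non_autosomal": ~autosomal,
        "duplicate_position": dup,
        "multiallelic": multiallelic,
        "low_maf": maf <= thr.min_maf,
        "hwe_fail": hwe_p <= thr.min_hwe_p,
        "low_call_rate": call_rate <= thr.min_call_rate,
    }
    removed_any = np.zeros(len(snps), dtype=bool)
    log_rows = []
    for name, bad in criteria.items():
        log_rows.append({"criterion": name, "removed": int(bad.sum())})
        removed_any |= bad
    log_rows.append({"criterion": "total_removed", "removed": int(removed_any.sum())})
    return genotypes.subset_snps(~removed_any), pd.DataFrame(log_rows)
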