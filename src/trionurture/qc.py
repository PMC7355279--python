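"""Sample- and SNP-level genotype quality control plus ancestry PCA.

Filters follow standard array-QC practice: per-sample call rate and
heterozygosity F statistic, per-SNP minor-allele frequency, exact
Hardy-Weinberg test, call rate, reference-frequency deviation and
high-MAF palindrome removal.  Principal components are computed on
founders and projected onto all samples for use as ancestry covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeSet, Pedigree


@dataclass
class SampleThresholds:
    min_call_rate: float = 0.90
    het_f_bounds: tuple[float, float] = (-0.10, 0.10)
    max_mendel_errors: int = 20


@dataclass
class SnpThresholds:
    min_maf: float = 0.01
    min_hwe_p: float = 1e-5
    # trio-stage default; platform-stage QC customarily uses 0.95
    min_call_rate: float = 0.99
    max_ref_freq_dev: float = 0.10
    palindrome_maf: float = 0.40
    max_mendel_rate: float = 0.02


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value (plain exact, no mid-p).

    Enumerates all heterozygote counts consistent with the observed allele
    counts and sums the probabilities of tables no more likely than the
    observed one.  Monomorphic sites return 1 by convention.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("empty genotype table")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # log-probability of each possible het count, conditional on allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (_lgamma_arr(n + 1) - _lgamma_arr(rare_hom + 1)
            - _lgamma_arr(hets + 1) - _lgamma_arr(common_hom + 1)
            + hets * math.log(2.0))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def _lgamma_arr(x):
    return np.vectorize(math.lgamma)(np.asarray(x, dtype=float))


def hwe_test_genotypes(dosages: np.ndarray) -> np.ndarray:
    """Column-wise exact HWE p-values for a dosage matrix (NaN = missing)."""
    out = np.ones(dosages.shape[1])
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        out[j] = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                                int((col == 2).sum()))
    return out


def sample_qc(genotypes: GenotypeSet,
              thresholds: SampleThresholds | None = None,
              mendel_errors: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample call rate, heterozygosity F and QC flags.

    F = 1 - observed_het / expected_het with the expectation taken over the
    sample's non-missing SNPs using cohort allele frequencies.
    """
    if genotypes.n_samples == 0 or genotypes.n_snps == 0:
        raise ValueError("empty genotype set")
    thr = thresholds or SampleThresholds()
    d = genotypes.dosages
    observed = ~np.isnan(d)
    call_rate = observed.mean(axis=1)
    p = genotypes.allele_freq()
    exp_het_per_snp = 2.0 * p * (1.0 - p)
    exp_het = observed @ np.nan_to_num(exp_het_per_snp)
    obs_het = np.nansum(d == 1, axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        het_f = np.where(exp_het > 0, 1.0 - obs_het / exp_het, 0.0)

    report = pd.DataFrame({
        "sample_id": genotypes.sample_ids,
        "call_rate": call_rate,
        "het_f": het_f,
    })
    report["mendel_errors"] = (
        mendel_errors.reindex(report["sample_id"]).fillna(0).to_numpy().astype(int)
        if mendel_errors is not None else 0)
    lo, hi = thr.het_f_bounds
    flags = []
    for _, row in report.iterrows():
        f = set()
        if row["call_rate"] < thr.min_call_rate:
            f.add("LOW_CALL")
        if not (lo <= row["het_f"] <= hi):
            f.add("HET_OUT")
        if row["mendel_errors"] > thr.max_mendel_errors:
            f.add("MENDEL_FAIL")
        flags.append(f)
    report["flags"] = flags
    return report


def _is_palindromic(effect: np.ndarray, other: np.ndarray) -> np.ndarray:
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return np.array([comp.get(e) == o for e, o in zip(effect, other)])


def snp_qc(genotypes: GenotypeSet,
           reference_freqs: pd.Series | None = None,
           thresholds: SnpThresholds | None = None,
           mendel_rates: np.ndarray | None = None) -> pd.DataFrame:
    """Per-SNP QC report with flags; reference deviation skipped if absent."""
    thr = thresholds or SnpThresholds()
    freq = genotypes.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = hwe_test_genotypes(genotypes.dosages)
    call_rate = genotypes.call_rate_snp()
    palindromic = _is_palindromic(genotypes.snps["effect_allele"].to_numpy(),
                                  genotypes.snps["other_allele"].to_numpy())
    report = pd.DataFrame({
        "snp_id": genotypes.snps["snp_id"],
        "maf": maf,
        "hwe_p": hwe_p,
        "call_rate": call_rate,
        "palindromic": palindromic,
    })
    if reference_freqs is not None:
        ref = reference_freqs.reindex(report["snp_id"]).to_numpy()
        report["ref_freq_dev"] = np.abs(freq - ref)
    else:
        report["ref_freq_dev"] = np.nan
    report["mendel_rate"] = mendel_rates if mendel_rates is not None else 0.0

    flags = []
    for _, r in report.iterrows():
        f = set()
        if r["maf"] < thr.min_maf:
            f.add("LOW_MAF")
        if r["hwe_p"] < thr.min_hwe_p:
            f.add("HWE_FAIL")
        if r["call_rate"] <= thr.min_call_rate:
            f.add("LOW_CALL")
        if np.isfinite(r["ref_freq_dev"]) and r["ref_freq_dev"] >= thr.max_ref_freq_dev:
            f.add("REF_FREQ_DEV")
        if r["palindromic"] and r["maf"] > thr.palindrome_maf:
            f.add("PALINDROME")
        if r["mendel_rate"] >= thr.max_mendel_rate:
            f.add("MENDEL_FAIL")
        flags.append(f)
    report["flags"] = flags
    return report


def genotype_pca(genotypes: GenotypeSet, k: int,
                 pedigree: Pedigree | None = None) -> pd.DataFrame:
    """Top-k ancestry principal components of frequency-scaled dosages.

    Loadings are estimated on founders (unrelated under the generative
    model) and projected onto every sample; component signs are fixed by
    making the largest-magnitude loading positive.  A zero-variance cohort
    yields all-zero scores.
    """
    if pedigree is not None:
        present = set(genotypes.sample_ids)
        founders = [s for s in pedigree.founders()["individual_id"] if s in present]
        if not founders:
            raise ValueError("no genotyped founders available for PCA fit")
        fit_set = genotypes.subset_samples(founders)
    else:
        fit_set = genotypes
    p = np.clip(np.nan_to_num(fit_set.allele_freq(), nan=0.0), 0.0, 1.0)
    scale = np.sqrt(2.0 * p * (1.0 - p))
    keep = scale > 0
    if k > int(keep.sum()) and keep.sum() > 0:
        raise ValueError(f"k={k} exceeds usable rank {int(keep.sum())}")

    def standardized(gs: GenotypeSet) -> np.ndarray:
        d = gs.dosages[:, keep]
        centered = np.nan_to_num(d - 2.0 * p[keep], nan=0.0)
        return centered / scale[keep]

    if keep.sum() == 0:  # monomorphic cohort: documented all-zero scores
        scores = np.zeros((genotypes.n_samples, k))
    else:
        x = standardized(fit_set)
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        vt = vt[:k]
        sign = np.sign(vt[np.arange(vt.shape[0]),
                          np.argmax(np.abs(vt), axis=1)])
        sign[sign == 0] = 1.0
        vt = vt * sign[:, None]
        scores = standardized(genotypes) @ vt.T
    out = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)])
    out.insert(0, "sample_id", genotypes.sample_ids)
    return out


def apply_qc(genotypes: GenotypeSet,
             sample_report: pd.DataFrame | None = None,
             snp_report: pd.DataFrame | None = None) -> GenotypeSet:
    """Drop flagged samples and SNPs; idempotent on an already-clean set."""
    gs = genotypes
    if sample_report is not None:
        keep = [s for s, f in zip(sample_report["sample_id"],
                                  sample_report["flags"]) if not f]
        gs = gs.subset_samples(keep)
    if snp_report is not None:
        mask = np.array([not f for f in snp_report["flags"]])
        gs = gs.subset_snps(mask)
    return gs
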