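"""Core in-memory containers shared across the pipeline.

Genotypes are held as a dense dosage matrix (samples x SNPs, counted-allele
dosage 0/1/2, ``NaN`` = missing) plus a SNP metadata frame.  Weight tables and
score tables are plain :class:`pandas.DataFrame` objects with documented
column contracts, following common summary-statistics tooling practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a SNP metadata frame.
SNP_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele"]

#: Required columns of a GWAS weight table.
WEIGHT_COLUMNS = [
    "snp_id", "effect_allele", "other_allele",
    "beta_marginal", "se", "p", "n_gwas", "beta_adjusted",
]


@dataclass
class GenotypeSet:
    """Samples x biallelic SNPs dosage matrix with SNP metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` float array of counted-allele dosages in
        ``{0, 1, 2}``; ``NaN`` marks a missing call.
    sample_ids
        Sample identifiers, one per row.
    snps
        Frame with columns :data:`SNP_COLUMNS`; ``effect_allele`` is the
        counted (ALT) allele.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snps: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs array")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match dosage rows")
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError("snps frame length does not match dosage columns")
        missing = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snps frame missing columns: {missing}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per SNP over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def call_rate_snp(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"sample {exc.args[0]!r} not in genotype set") from exc

    def subset_samples(self, ids) -> "GenotypeSet":
        idx = self.sample_index(ids)
        return GenotypeSet(self.dosages[idx], [self.sample_ids[i] for i in idx],
                           self.snps.copy())

    def subset_snps(self, mask) -> "GenotypeSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return GenotypeSet(self.dosages[:, idx], list(self.sample_ids),
                           self.snps.iloc[idx].reset_index(drop=True))


# Pedigree column contract: one row per individual.  Parent id "0" means
# founder (parent not in the cohort), as in the classic 6-column family file.
PEDIGREE_COLUMNS = ["family_id", "individual_id", "father_id", "mother_id",
                    "sex", "zygosity"]


@dataclass
class Pedigree:
    """Nuclear-family pedigree with zygosity labels for offspring.

    ``zygosity`` is ``MZ``/``DZ`` for twins, ``SIB`` for non-twin siblings,
    ``SINGLETON`` for only children and ``FOUNDER`` for parents.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEDIGREE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"pedigree missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        dup = self.table["individual_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate individual ids: {self.table.loc[dup, 'individual_id'].tolist()}")

    def offspring(self) -> pd.DataFrame:
        t = self.table
        return t[(t["father_id"] != "0") & (t["mother_id"] != "0")]

    def founders(self) -> pd.DataFrame:
        t = self.table
        return t[(t["father_id"] == "0") & (t["mother_id"] == "0")]

    def family_of(self) -> dict[str, str]:
        return dict(zip(self.table["individual_id"], self.table["family_id"]))


@dataclass
class SplitGenotypes:
    """Per-offspring transmitted and non-transmitted dosage sets.

    ``transmitted`` and ``nontransmitted`` share sample ids (the offspring)
    and SNP metadata.  ``status`` is an ``(n_offspring, n_snps)`` int8 array
    with codes :data:`STATUS_OK`, :data:`STATUS_MENDEL_ERROR`,
    :data:`STATUS_MISSING`.
    """

    transmitted: GenotypeSet
    nontransmitted: GenotypeSet
    status: np.ndarray
    excluded_samples: pd.DataFrame
    excluded_snps: pd.DataFrame

    @property
    def offspring_ids(self) -> list[str]:
        return self.transmitted.sample_ids


STATUS_OK = 0
STATUS_MENDEL_ERROR = 1
STATUS_MISSING = 2


def validate_weight_table(weights: pd.DataFrame) -> pd.DataFrame:
    """Check the weight-table column contract and return a copy."""
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    if weights["snp_id"].duplicated().any():
        raise ValueError("weight table has duplicate snp_id rows")
    return weights.reset_index(drop=True)
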