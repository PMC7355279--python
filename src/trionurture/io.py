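"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as minimal VCF v4.2 (GT-only, biallelic records); the
pedigree as a 6-column tab-delimited family file (family, individual,
father, mother, sex, zygosity); phenotypes and weight tables as
header-bearing TSV.  All writers emit LF line endings; readers accept CRLF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (GenotypeSet, Pedigree, PEDIGREE_COLUMNS,
                    validate_weight_table)

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeSet, path: str | Path) -> None:
    """Write a minimal biallelic GT-only VCF v4.2."""
    path = Path(path)
    snps = genotypes.snps
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        dosages = genotypes.dosages
        for j in range(genotypes.n_snps):
            row = snps.iloc[j]
            gts = [_GT.get(d, "./.") for d in dosages[:, j]]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                     f"{row['other_allele']}\t{row['effect_allele']}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_vcf(path: str | Path) -> tuple[GenotypeSet, np.ndarray]:
    """Read a VCF into a GenotypeSet counting the first ALT allele.

    Returns the genotype set and a boolean mask of records that carried
    more than one ALT allele (for the trio-stage multiallelic filter).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta, multi = [], [], []
    for var in vcf:
        gts = np.array([a[:2] for a in var.genotypes], dtype=float)
        gts[gts < 0] = np.nan
        alt = var.ALT[0] if var.ALT else "N"
        # any non-first ALT allele call becomes missing
        dose = np.where(np.isnan(gts).any(axis=1), np.nan,
                        (gts == 1).sum(axis=1).astype(float))
        dose[np.nanmax(np.where(np.isnan(gts), 0, gts), axis=1) > 1] = np.nan
        rows.append(dose)
        meta.append((var.ID or f"{var.CHROM}:{var.POS}",
                     str(var.CHROM), int(var.POS), alt, var.REF))
        multi.append(len(var.ALT) > 1)
    if not rows:
        raise ValueError(f"no variant records in {path}")
    snps = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos",
                                       "effect_allele", "other_allele"])
    return (GenotypeSet(np.array(rows).T, samples, snps),
            np.array(multi, dtype=bool))


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    pedigree.table[PEDIGREE_COLUMNS].to_csv(path, sep="\t", index=False,
                                            lineterminator="\n")


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 6-column family file; unknown parent ids are parse errors."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PEDIGREE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing pedigree columns {missing}")
    known = set(table["individual_id"]) | {"0"}
    for i, row in table.iterrows():
        for col in ("father_id", "mother_id"):
            if row[col] not in known:
                # +2 accounts for the header line, 1-based
                raise ValueError(f"{path}: line {i + 2}: unknown {col} "
                                 f"{row[col]!r}")
    table["sex"] = table["sex"].astype(int)
    return Pedigree(table)


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t",
                      dtype={"individual_id": str, "family_id": str})
    return out


def write_weights(weights: pd.DataFrame, path: str | Path) -> None:
    validate_weight_table(weights).to_csv(path, sep="\t", index=False,
                                          lineterminator="\n")


def read_weights(path: str | Path) -> pd.DataFrame:
    return validate_weight_table(pd.read_csv(path, sep="\t",
                                             dtype={"snp_id": str}))


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index=False, lineterminator="\n")
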