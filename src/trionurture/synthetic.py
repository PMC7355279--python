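"""Synthetic trio cohorts with a built-in genetic-nurture decomposition.

The generator produces nuclear families (MZ/DZ twin pairs, singletons,
twin-plus-sibling), founder genotypes at Hardy-Weinberg proportions,
Mendelian transmission to offspring, and phenotypes of the form

    Y = delta * S_T + eta * (S_f + S_m) + c_fam + e

where ``S_T`` is the offspring's true polygenic value, ``S_f + S_m`` the
summed parental true values, ``c_fam`` a genotype-independent family
environment and ``e`` residual noise.  Because at every locus
``transmitted + non-transmitted = father + mother``, the parental sum equals
``S_T + S_NT``, so a regression of Y on the transmitted and non-transmitted
true scores has expected coefficients ``(delta + eta, eta)`` — the central
parameter-recovery property the downstream analysis is tested against.
All true scores are expressed in units of one SD of the offspring
transmitted score so that delta and eta live on a common scale and the
identity above holds without rescaling.

Four offspring phenotypes are generated: a continuous achievement score, an
ordinal 4-level adult educational-attainment (EA) variable obtained by
thresholding a latent liability, and two L-shaped attention-problem (ADHD)
symptom counts (home/school report) built as a floored, scaled square of a
shifted latent normal — a shape whose square root is approximately linear in
the latent variable, matching the analysis pipeline's square-root transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeSet, Pedigree

FAMILY_TYPES = ("mz", "dz", "singleton", "dz_sib")

# Offspring counts and zygosity labels per family type.
_FAMILY_LAYOUT = {
    "mz": ("MZ", "MZ"),
    "dz": ("DZ", "DZ"),
    "singleton": ("SINGLETON",),
    "dz_sib": ("DZ", "DZ", "SIB"),
}

_BASES = np.array(list("ACGT"))

# Per-stage RNG stream ids, so each operation is deterministic given the
# config seed no matter the call order.
_STREAM_PEDIGREE = 1
_STREAM_FOUNDERS = 2
_STREAM_TRANSMIT = 3
_STREAM_WEIGHTS = 4
_STREAM_PHENO = 5
_STREAM_GWAS = 6
_STREAM_MENDEL = 7

# Liability thresholds reproducing adult EA category frequencies of
# 0.5% / 8.6% / 32.0% / 59.0% (levels 0-3).
DEFAULT_EA_THRESHOLDS = tuple(stats.norm.ppf([0.005, 0.091, 0.411]))

# Attention-problem count calibration: count = floor(s * max(0, Z + a)^2),
# clipped to the instrument range; s is solved at generation time so the
# sample mean matches the target.
ADHD_SHAPES = {
    "adhd_home": {"offset": 0.6, "target_mean": 2.92, "max_count": 18},
    "adhd_school": {"offset": 1.1, "target_mean": 6.09, "max_count": 43},
}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    ``delta`` is the direct genetic effect per SD of the true transmitted
    score; ``eta`` the genetic-nurture effect of the summed parental true
    scores, on the same scale.  ``delta_adhd``/``eta_adhd`` play the same
    roles for the independent ADHD-like trait.
    """

    n_families: int = 1000
    family_type_probs: Mapping[str, float] = field(
        default_factory=lambda: {"mz": 0.45, "dz": 0.35,
                                 "singleton": 0.05, "dz_sib": 0.15})
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_fraction: float = 0.2
    delta: float = 0.3
    eta: float = 0.1
    delta_adhd: float = 0.25
    eta_adhd: float = 0.0
    var_family: float = 0.2
    var_resid: float = 0.7
    gwas_n: int = 100_000
    ea_thresholds: tuple[float, float, float] = DEFAULT_EA_THRESHOLDS
    seed: int = 0
    mendel_error_rate: float = 0.0
    sex_effect_ea: float = 0.0
    birth_year_effect_ea: float = 0.0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_snps < 1:
            raise ValueError("n_families and n_snps must be >= 1")
        probs = dict(self.family_type_probs)
        unknown = set(probs) - set(FAMILY_TYPES)
        if unknown:
            raise ValueError(f"unknown family types: {sorted(unknown)}")
        total = sum(probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"family_type_probs must sum to 1, got {total}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValueError("causal_fraction must be in (0, 1]")
        if self.var_family < 0 or self.var_resid < 0:
            raise ValueError("variances must be non-negative")
        if self.gwas_n <= 0:
            raise ValueError("gwas_n must be positive")
        if not (0.0 <= self.mendel_error_rate < 1.0):
            raise ValueError("mendel_error_rate must be in [0, 1)")
        if list(self.ea_thresholds) != sorted(self.ea_thresholds):
            raise ValueError("ea_thresholds must be increasing")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, self.seed])


@dataclass
class Cohort:
    """A simulated study: genotypes, pedigree, phenotypes and ground truth."""

    genotypes: GenotypeSet
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    truth: dict


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Draw family structures from ``family_type_probs``."""
    rng = config.rng(_STREAM_PEDIGREE)
    probs = [dict(config.family_type_probs).get(t, 0.0) for t in FAMILY_TYPES]
    types = rng.choice(len(FAMILY_TYPES), size=config.n_families, p=probs)
    rows = []
    for i, ti in enumerate(types):
        fam = f"FAM{i:05d}"
        father, mother = f"{fam}_F", f"{fam}_M"
        rows.append((fam, father, "0", "0", 1, "FOUNDER"))
        rows.append((fam, mother, "0", "0", 2, "FOUNDER"))
        for j, zyg in enumerate(_FAMILY_LAYOUT[FAMILY_TYPES[ti]]):
            rows.append((fam, f"{fam}_C{j}", father, mother,
                         int(rng.integers(1, 3)), zyg))
    table = pd.DataFrame(rows, columns=["family_id", "individual_id",
                                        "father_id", "mother_id", "sex",
                                        "zygosity"])
    return Pedigree(table)


def _snp_metadata(config: SimulationConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_snps
    chrom = (np.arange(n) % 22) + 1
    pos = 10_000 + (np.arange(n) // 22) * 50_000
    a1 = rng.integers(0, 4, size=n)
    a2 = (a1 + rng.integers(1, 4, size=n)) % 4
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=n)
    return pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(n)],
        "chrom": chrom.astype(str),
        "pos": pos,
        "effect_allele": _BASES[a1],
        "other_allele": _BASES[a2],
        "maf_true": maf,
    })


def simulate_founders(config: SimulationConfig,
                      pedigree: Pedigree | None = None) -> GenotypeSet:
    """Parental genotypes at Hardy-Weinberg proportions, no missingness."""
    if pedigree is None:
        pedigree = simulate_pedigree(config)
    rng = config.rng(_STREAM_FOUNDERS)
    snps = _snp_metadata(config, rng)
    founders = pedigree.founders()["individual_id"].tolist()
    maf = snps["maf_true"].to_numpy()
    dosages = rng.binomial(2, maf, size=(len(founders), config.n_snps)).astype(float)
    return GenotypeSet(dosages, founders, snps)


def transmit(config: SimulationConfig, founders: GenotypeSet,
             pedigree: Pedigree) -> GenotypeSet:
    """Mendelian transmission: one uniformly chosen allele per parent per SNP.

    DZ twins and siblings receive independent transmissions; MZ co-twins
    share a single transmission realization.
    """
    rng = config.rng(_STREAM_TRANSMIT)
    offspring = pedigree.offspring()
    missing_parents = (set(offspring["father_id"]) | set(offspring["mother_id"])) \
        - set(founders.sample_ids)
    if missing_parents:
        raise KeyError(f"parents absent from founder genotypes: "
                       f"{sorted(missing_parents)[:5]}")

    # MZ co-twins map to one shared transmission unit (first-born of the pair).
    unit_of: dict[str, str] = {}
    for fam, grp in offspring.groupby("family_id", sort=False):
        mz = grp[grp["zygosity"] == "MZ"]["individual_id"].tolist()
        for child in grp["individual_id"]:
            unit_of[child] = mz[0] if (mz and child in mz) else child

    order = {c: i for i, c in enumerate(offspring["individual_id"])}
    units = sorted(set(unit_of.values()), key=order.__getitem__)
    ped_idx = offspring.set_index("individual_id")
    fa = founders.dosages[founders.sample_index(ped_idx.loc[units, "father_id"])]
    mo = founders.dosages[founders.sample_index(ped_idx.loc[units, "mother_id"])]

    def draw(parent: np.ndarray) -> np.ndarray:
        # transmitted allele count: 0 if hom-ref, 1 if hom-alt, fair coin if het
        het = parent == 1
        out = (parent == 2).astype(float)
        out[het] = rng.integers(0, 2, size=int(het.sum()))
        return out

    child_units = draw(fa) + draw(mo)
    unit_row = {u: i for i, u in enumerate(units)}
    child_ids = offspring["individual_id"].tolist()
    dosages = np.vstack([child_units[unit_row[unit_of[c]]] for c in child_ids])
    return GenotypeSet(dosages, child_ids, founders.snps.copy())


def simulate_true_weights(config: SimulationConfig, snps: pd.DataFrame,
                          stream_offset: int = 0) -> pd.DataFrame:
    """Sparse per-allele causal effects; exactly round(f * m) nonzero."""
    rng = config.rng(_STREAM_WEIGHTS + 100 * stream_offset)
    m = len(snps)
    n_causal = int(round(config.causal_fraction * m))
    n_causal = max(n_causal, 1)
    w = np.zeros(m)
    causal = rng.choice(m, size=n_causal, replace=False)
    w[causal] = rng.normal(0.0, 1.0, size=n_causal)
    return pd.DataFrame({"snp_id": snps["snp_id"].to_numpy(), "w": w})


def _true_scores(genotypes: GenotypeSet, weights: pd.DataFrame) -> pd.Series:
    w = weights.set_index("snp_id").loc[genotypes.snps["snp_id"], "w"].to_numpy()
    return pd.Series(genotypes.dosages @ w, index=genotypes.sample_ids)


def _latent(config: SimulationConfig, cohort_parts, delta: float, eta: float,
            rng: np.random.Generator, scores: pd.Series) -> np.ndarray:
    """delta*S_T + eta*(S_f+S_m) + family effect + residual, in T-score SD units."""
    offspring, fam_ids = cohort_parts
    s_child = scores.loc[offspring["individual_id"]].to_numpy()
    s_f = scores.loc[offspring["father_id"]].to_numpy()
    s_m = scores.loc[offspring["mother_id"]].to_numpy()
    scale = np.std(s_child)
    if scale == 0:
        scale = 1.0
    gen = delta * s_child / scale + eta * (s_f + s_m) / scale
    fam_levels, fam_codes = np.unique(fam_ids, return_inverse=True)
    c = rng.normal(0.0, np.sqrt(config.var_family), size=len(fam_levels))
    e = rng.normal(0.0, np.sqrt(config.var_resid), size=len(offspring))
    return gen + c[fam_codes] + e


def _count_from_latent(latent: np.ndarray, offset: float, target_mean: float,
                       max_count: int) -> np.ndarray:
    z = (latent - latent.mean()) / latent.std()
    base = np.maximum(0.0, z + offset) ** 2
    scale = target_mean / base.mean() if base.mean() > 0 else 0.0
    return np.clip(np.floor(scale * base), 0, max_count).astype(int)


def simulate_phenotypes(config: SimulationConfig, cohort: Cohort) -> Cohort:
    """Attach achievement, ordinal EA, ADHD counts, sex/birth-year/platform."""
    rng = config.rng(_STREAM_PHENO)
    offspring = cohort.pedigree.offspring().reset_index(drop=True)
    fam_ids = offspring["family_id"].to_numpy()
    parts = (offspring, fam_ids)

    w_ea = cohort.truth["weights_ea"]
    w_adhd = cohort.truth["weights_adhd"]
    s_ea = _true_scores(cohort.genotypes, w_ea)
    s_adhd = _true_scores(cohort.genotypes, w_adhd)

    achievement = _latent(config, parts, config.delta, config.eta, rng, s_ea)

    ea_latent = _latent(config, parts, config.delta, config.eta, rng, s_ea)
    sex = rng.integers(0, 2, size=len(offspring))
    birth_year = rng.integers(1985, 1996, size=len(offspring))
    ea_latent = ea_latent + config.sex_effect_ea * sex \
        + config.birth_year_effect_ea * (birth_year - 1990)
    ea_std = (ea_latent - ea_latent.mean()) / ea_latent.std()
    ea_level = np.searchsorted(np.asarray(config.ea_thresholds), ea_std)

    counts = {}
    for name, shape in ADHD_SHAPES.items():
        lat = _latent(config, parts, config.delta_adhd, config.eta_adhd,
                      rng, s_adhd)
        counts[name] = _count_from_latent(lat, **{
            "offset": shape["offset"], "target_mean": shape["target_mean"],
            "max_count": shape["max_count"]})

    platform = rng.choice(["A", "B"], size=len(offspring))
    phenotypes = pd.DataFrame({
        "individual_id": offspring["individual_id"].to_numpy(),
        "family_id": fam_ids,
        "achievement": achievement,
        "ea_level": ea_level,
        "adhd_home": counts["adhd_home"],
        "adhd_school": counts["adhd_school"],
        "sex": sex,
        "birth_year": birth_year,
        "platform": platform,
    })
    truth = dict(cohort.truth)
    truth.update({"delta": config.delta, "eta": config.eta,
                  "delta_adhd": config.delta_adhd, "eta_adhd": config.eta_adhd,
                  "scores_ea": s_ea, "scores_adhd": s_adhd})
    return Cohort(cohort.genotypes, cohort.pedigree, phenotypes, truth)


def simulate_gwas_weights(config: SimulationConfig, truth: pd.DataFrame,
                          snps: pd.DataFrame,
                          stream_offset: int = 0) -> pd.DataFrame:
    """Noisy marginal GWAS estimates of the true per-allele effects.

    Sampling variance of a marginal beta at a SNP with allele frequency p in
    a discovery GWAS of size N is 1 / (2 p (1-p) N) on the standardized-
    phenotype scale.
    """
    rng = config.rng(_STREAM_GWAS + 100 * stream_offset)
    merged = snps.merge(truth, on="snp_id", validate="1:1")
    p = merged["maf_true"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * p * (1.0 - p) * config.gwas_n)
    beta = merged["w"].to_numpy() + rng.normal(0.0, se)
    z = beta / se
    return pd.DataFrame({
        "snp_id": merged["snp_id"],
        "effect_allele": merged["effect_allele"],
        "other_allele": merged["other_allele"],
        "beta_marginal": beta,
        "se": se,
        "p": 2.0 * stats.norm.sf(np.abs(z)),
        "n_gwas": config.gwas_n,
        "beta_adjusted": beta,
    })


def inject_mendel_errors(config: SimulationConfig, genotypes: GenotypeSet,
                         pedigree: Pedigree) -> GenotypeSet:
    """Randomly perturb offspring dosages at rate ``mendel_error_rate``.

    Not every perturbation is detectable from dosages (e.g. inside an
    all-heterozygous trio); detection power is a property of the checker,
    not of this injector.
    """
    rate = config.mendel_error_rate
    if rate == 0.0:
        return genotypes
    rng = config.rng(_STREAM_MENDEL)
    dosages = genotypes.dosages.copy()
    child_rows = genotypes.sample_index(pedigree.offspring()["individual_id"])
    mask = rng.random((len(child_rows), genotypes.n_snps)) < rate
    shift = rng.integers(1, 3, size=mask.sum())
    rows = np.repeat(child_rows, mask.sum(axis=1))
    cols = np.concatenate([np.flatnonzero(m) for m in mask])
    dosages[rows, cols] = (dosages[rows, cols] + shift) % 3
    return GenotypeSet(dosages, genotypes.sample_ids, genotypes.snps.copy())


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Full generator: pedigree -> founders -> transmission -> phenotypes."""
    pedigree = simulate_pedigree(config)
    founders = simulate_founders(config, pedigree)
    children = transmit(config, founders, pedigree)
    dosages = np.vstack([founders.dosages, children.dosages])
    genotypes = GenotypeSet(dosages, founders.sample_ids + children.sample_ids,
                            founders.snps.copy())
    genotypes = inject_mendel_errors(config, genotypes, pedigree)
    truth = {
        "weights_ea": simulate_true_weights(config, genotypes.snps, 0),
        "weights_adhd": simulate_true_weights(config, genotypes.snps, 1),
    }
    cohort = Cohort(genotypes, pedigree, pd.DataFrame(), truth)
    return simulate_phenotypes(config, cohort)
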