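"""End-to-end orchestration: simulate -> QC -> split -> score -> associate -> power."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, io, pgs, power, qc, transmission
from .synthetic import Cohort, SimulationConfig, simulate_cohort, \
    simulate_gwas_weights
from .types import GenotypeSet, Pedigree

log = logging.getLogger("trionurture")


@dataclass
class PipelineConfig:
    """Run configuration: either an embedded simulation or input paths."""

    simulation: SimulationConfig | None = None
    genotypes_vcf: str | None = None
    pedigree_tsv: str | None = None
    phenotypes_tsv: str | None = None
    weights_ea_tsv: str | None = None
    weights_adhd_tsv: str | None = None
    h2_ea: float = 0.2
    h2_adhd: float = 0.25
    window_bp: int = pgs.DEFAULT_WINDOW_BP
    causal_fraction_grid: tuple[float, ...] = (1.0,)
    n_pcs: int = 10
    alpha: float = 0.01
    power_iccs: dict = field(default_factory=lambda: {
        "achievement": {"mz": 0.8, "dz": 0.4},
        "adhd_home": {"mz": 0.8, "dz": 0.3},
        "adhd_school": {"mz": 0.8, "dz": 0.3},
    })
    out_dir: str = "trionurture_out"

    def __post_init__(self) -> None:
        has_paths = self.genotypes_vcf is not None
        if (self.simulation is None) == (not has_paths):
            raise ValueError("set exactly one of simulation or input paths")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "family_type_probs" in sim:
                sim["family_type_probs"] = dict(sim["family_type_probs"])
            for key in ("maf_range", "ea_thresholds"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        if "causal_fraction_grid" in raw:
            raw["causal_fraction_grid"] = tuple(raw["causal_fraction_grid"])
        return cls(simulation=sim, **raw)


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation)
        snps = cohort.genotypes.snps
        gwas = {
            "EA": simulate_gwas_weights(config.simulation,
                                        cohort.truth["weights_ea"], snps, 0),
            "ADHD": simulate_gwas_weights(config.simulation,
                                          cohort.truth["weights_adhd"], snps, 1),
        }
        multi = np.zeros(cohort.genotypes.n_snps, dtype=bool)
        return cohort, gwas, multi
    genotypes, multi = io.read_vcf(config.genotypes_vcf)
    pedigree = io.read_pedigree(config.pedigree_tsv)
    phenotypes = io.read_phenotypes(config.phenotypes_tsv)
    cohort = Cohort(genotypes, pedigree, phenotypes, truth={})
    gwas = {"EA": io.read_weights(config.weights_ea_tsv)}
    if config.weights_adhd_tsv:
        gwas["ADHD"] = io.read_weights(config.weights_adhd_tsv)
    return cohort, gwas, multi


def _family_blocks(pedigree: Pedigree, icc: dict) -> list[power.FamilyBlock]:
    """Summarize the pedigree into MZ / non-MZ strata for the power model."""
    offspring = pedigree.offspring()
    blocks = []
    sizes = offspring.groupby("family_id").agg(
        n=("individual_id", "size"),
        mz=("zygosity", lambda z: (z == "MZ").any()))
    for is_mz, key in [(True, "mz"), (False, "dz")]:
        sub = sizes[sizes["mz"] == is_mz]
        for size, count in sub["n"].value_counts().items():
            blocks.append(power.FamilyBlock(int(count), int(size), icc[key]))
    return blocks


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}}
    if config.simulation is not None:
        manifest["seed"] = config.simulation.seed

    cohort, gwas, multi = _load_inputs(config)
    log.info("cohort: %d samples x %d SNPs, %d offspring",
             cohort.genotypes.n_samples, cohort.genotypes.n_snps,
             len(cohort.pedigree.offspring()))

    # --- QC ---------------------------------------------------------------
    sample_report = qc.sample_qc(cohort.genotypes)
    filtered, snp_log = transmission.trio_snp_filter(
        cohort.genotypes, extra_alleles=pd.Series(multi))
    keep = [s for s, f in zip(sample_report["sample_id"],
                              sample_report["flags"]) if not f]
    filtered = filtered.subset_samples(
        [s for s in filtered.sample_ids if s in set(keep)])
    sample_report.to_csv(out / "sample_qc.tsv", sep="\t", index=False,
                         lineterminator="\n")
    snp_log.to_csv(out / "snp_filter_log.tsv", sep="\t", index=False,
                   lineterminator="\n")
    manifest["stages"]["qc"] = {
        "samples_in": cohort.genotypes.n_samples,
        "samples_passing": len(filtered.sample_ids),
        "samples_excluded": cohort.genotypes.n_samples - len(filtered.sample_ids),
        "snps_in": cohort.genotypes.n_snps,
        "snps_passing": filtered.n_snps,
        "snps_excluded": cohort.genotypes.n_snps - filtered.n_snps,
    }

    pcs = qc.genotype_pca(filtered, min(config.n_pcs, filtered.n_snps - 1),
                          pedigree=cohort.pedigree)

    # --- transmission split ----------------------------------------------
    split = transmission.split_transmission(filtered, cohort.pedigree)
    manifest["stages"]["split"] = {
        "offspring": len(split.offspring_ids),
        "excluded_samples": len(split.excluded_samples),
        "mendel_flagged_snps": len(split.excluded_snps),
    }

    # --- scoring ----------------------------------------------------------
    scores: dict[str, pd.DataFrame] = {}
    h2 = {"EA": config.h2_ea, "ADHD": config.h2_adhd}
    founders = filtered.subset_samples(
        [s for s in cohort.pedigree.founders()["individual_id"]
         if s in set(filtered.sample_ids)])
    for trait, table in gwas.items():
        aligned, align_log = pgs.align_alleles(table, filtered)
        best = None
        for frac in config.causal_fraction_grid:
            screened = pgs.causal_fraction_weights(aligned, frac)
            shrunk = pgs.shrink_weights_inf(screened, founders, h2[trait],
                                            config.window_bp)
            best = shrunk  # last grid point (fraction 1.0 by default)
        scores[trait] = pgs.score(split, best)
        manifest["stages"][f"score_{trait}"] = {
            "snps_scored": int((best["beta_adjusted"] != 0).sum()), **align_log}
        io.write_scores(scores[trait], out / f"scores_{trait}.tsv")

    # --- association ------------------------------------------------------
    phenotypes = cohort.phenotypes
    report = association.run_table1(phenotypes, scores, pcs, alpha=config.alpha)
    report.to_csv(out / "association_report.tsv", sep="\t", index=False,
                  lineterminator="\n", float_format="%.6g")
    manifest["stages"]["association"] = {"models_fit": int(len(report))}

    # --- power ------------------------------------------------------------
    grid = np.round(np.arange(0.001, 0.0501, 0.001), 4)
    power_rows = []
    for outcome, icc in config.power_iccs.items():
        blocks = _family_blocks(cohort.pedigree, icc)
        query = power.PowerQuery(blocks=blocks, alpha=config.alpha,
                                 target_power=0.80)
        ne = power.effective_n(blocks)
        curve = power.power_curve(
            power.PowerQuery(blocks=blocks, alpha=config.alpha, r2=0.01), grid)
        curve.insert(0, "outcome", outcome)
        power_rows.append(curve)
        manifest["stages"].setdefault("power", {})[outcome] = {
            "effective_n": ne,
            "detectable_r2_pct": round(
                100 * power.detectable_r2(ne, config.alpha,
                                          query.target_power), 2),
        }
    pd.concat(power_rows).to_csv(out / "power_curves.tsv", sep="\t",
                                 index=False, lineterminator="\n",
                                 float_format="%.6g")

    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
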