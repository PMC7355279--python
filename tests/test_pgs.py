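"""Scoring: allele alignment, infinitesimal LD shrinkage, causal-fraction
screens and the dosage-weighted sum itself."""

import numpy as np
import pandas as pd
import pytest

from trionurture.pgs import (align_alleles, causal_fraction_weights, score,
                             shrink_weights_inf)
from trionurture.synthetic import (SimulationConfig, simulate_cohort,
                                   simulate_gwas_weights)
from trionurture.transmission import split_transmission
from conftest import make_genotypes


def weight_table(snp_ids, betas, effect="A", other="G", n_gwas=1000,
                 p=None) -> pd.DataFrame:
    m = len(snp_ids)
    return pd.DataFrame({
        "snp_id": snp_ids,
        "effect_allele": [effect] * m if isinstance(effect, str) else effect,
        "other_allele": [other] * m if isinstance(other, str) else other,
        "beta_marginal": betas,
        "se": 0.1, "p": p if p is not None else 0.5, "n_gwas": n_gwas,
        "beta_adjusted": betas,
    })


class TestAlignAlleles:
    def test_identical_orientation_unchanged(self):
        gs = make_genotypes(np.zeros((2, 2)))
        w = weight_table(["snp0", "snp1"], [0.2, -0.1])
        aligned, log = align_alleles(w, gs)
        np.testing.assert_allclose(aligned["beta_marginal"], [0.2, -0.1])
        assert log["matched"] == 2

    def test_allele_swap_flips_sign(self):
        gs = make_genotypes(np.zeros((2, 1)))
        w = weight_table(["snp0"], [0.2], effect=["G"], other=["A"])
        aligned, log = align_alleles(w, gs)
        assert aligned["beta_marginal"].iloc[0] == pytest.approx(-0.2)
        assert log["sign_flipped"] == 1

    def test_strand_flip_resolved(self):
        # weights on the other strand: T/C vs genotype A/G
        gs = make_genotypes(np.zeros((2, 1)))
        w = weight_table(["snp0"], [0.3], effect=["T"], other=["C"])
        aligned, log = align_alleles(w, gs)
        assert aligned["beta_marginal"].iloc[0] == pytest.approx(0.3)
        assert log["strand_flipped"] == 1

    def test_palindromic_swap_dropped(self):
        meta = pd.DataFrame({
            "snp_id": ["snp0"], "chrom": ["1"], "pos": [1],
            "effect_allele": ["C"], "other_allele": ["G"]})
        gs = make_genotypes(np.zeros((2, 1)), snp_meta=meta)
        w = weight_table(["snp0"], [0.3], effect=["G"], other=["C"])
        with pytest.raises(ValueError):
            # the only overlapping SNP is unresolvable
            align_alleles(w, gs)

    def test_no_overlap_is_error(self):
        gs = make_genotypes(np.zeros((2, 1)))
        w = weight_table(["absent"], [0.1])
        with pytest.raises(ValueError):
            align_alleles(w, gs)


class TestShrinkage:
    def test_identity_ld_closed_form(self):
        # with D = I every SNP shrinks by 1 / (1 + M/(N h2))
        rng = np.random.default_rng(0)
        m, n_ref = 8, 4000
        d = rng.binomial(2, 0.4, size=(n_ref, m)).astype(float)
        gs = make_genotypes(
            d, snp_meta=pd.DataFrame({
                "snp_id": [f"snp{j}" for j in range(m)], "chrom": "1",
                # one SNP per 250 kb window: no LD is even estimated
                "pos": 300_000 * (np.arange(m) + 1),
                "effect_allele": "A", "other_allele": "G"}))
        betas = rng.normal(size=m)
        w = weight_table([f"snp{j}" for j in range(m)], betas, n_gwas=1000)
        shrunk = shrink_weights_inf(w, gs, h2=0.5)
        factor = 1.0 / (1.0 + m / (1000 * 0.5))
        np.testing.assert_allclose(shrunk["beta_adjusted"], betas * factor,
                                   rtol=1e-10)
        # shrinkage shrinks
        assert (shrunk["beta_adjusted"].abs()
                <= shrunk["beta_marginal"].abs() + 1e-12).all()

    def test_large_h2_limit_recovers_marginals(self):
        rng = np.random.default_rng(1)
        m = 5
        d = rng.binomial(2, 0.4, size=(500, m)).astype(float)
        gs = make_genotypes(
            d, snp_meta=pd.DataFrame({
                "snp_id": [f"snp{j}" for j in range(m)], "chrom": "1",
                "pos": 300_000 * (np.arange(m) + 1),
                "effect_allele": "A", "other_allele": "G"}))
        betas = rng.normal(size=m)
        w = weight_table([f"snp{j}" for j in range(m)], betas, n_gwas=10 ** 8)
        shrunk = shrink_weights_inf(w, gs, h2=1.0)
        np.testing.assert_allclose(shrunk["beta_adjusted"], betas, rtol=1e-4)

    def test_three_snp_window_matches_direct_solve(self):
        # independent linear-algebra oracle on one correlated window
        rng = np.random.default_rng(2)
        n_ref, m = 2000, 3
        base = rng.binomial(2, 0.5, size=(n_ref, 1)).astype(float)
        noise = rng.binomial(2, 0.5, size=(n_ref, m)).astype(float)
        d = np.where(rng.random((n_ref, m)) < 0.6, base, noise)
        gs = make_genotypes(
            d, snp_meta=pd.DataFrame({
                "snp_id": ["a", "b", "c"], "chrom": "1",
                "pos": [1000, 2000, 3000],  # one shared window
                "effect_allele": "A", "other_allele": "G"}))
        betas = np.array([0.2, -0.1, 0.05])
        w = weight_table(["a", "b", "c"], betas, n_gwas=500)
        shrunk = shrink_weights_inf(w, gs, h2=0.3)

        xs = (d - d.mean(0)) / d.std(0)
        corr = xs.T @ xs / n_ref
        expected = np.linalg.solve(corr + (m / (500 * 0.3)) * np.eye(m), betas)
        np.testing.assert_allclose(shrunk["beta_adjusted"], expected,
                                   rtol=1e-10)


class TestCausalFraction:
    def test_fraction_one_is_identity(self):
        w = weight_table([f"s{i}" for i in range(10)], np.ones(10))
        out = causal_fraction_weights(w, 1.0)
        pd.testing.assert_frame_equal(out, w)

    def test_half_fraction_keeps_best_half(self):
        p = np.linspace(0.01, 0.9, 10)
        w = weight_table([f"s{i}" for i in range(10)], np.ones(10), p=p)
        out = causal_fraction_weights(w, 0.5)
        assert int((out["beta_adjusted"] != 0).sum()) == 5
        kept = out[out["beta_adjusted"] != 0]["snp_id"].tolist()
        assert kept == [f"s{i}" for i in range(5)]  # smallest p-values

    def test_grid_r2_peaks_near_true_sparsity(self):
        # sparse architecture: a fraction screen near the true causal
        # fraction predicts no worse than scoring every null SNP
        cfg = SimulationConfig(n_families=800, n_snps=300,
                               causal_fraction=0.05, delta=0.5, eta=0.0,
                               var_family=0.0, var_resid=0.3,
                               gwas_n=2000, seed=40)
        cohort = simulate_cohort(cfg)
        gwas = simulate_gwas_weights(cfg, cohort.truth["weights_ea"],
                                     cohort.genotypes.snps)
        split = split_transmission(cohort.genotypes, cohort.pedigree)
        y = cohort.phenotypes.set_index("individual_id").loc[
            split.offspring_ids, "achievement"].to_numpy()
        r2 = {}
        for frac in (0.05, 1.0):
            screened = causal_fraction_weights(gwas, frac)
            s = score(split, screened)["pgs_t"].to_numpy()
            r2[frac] = np.corrcoef(s, y)[0, 1] ** 2
        assert r2[0.05] > r2[1.0] * 0.9

    def test_invalid_fraction(self):
        w = weight_table(["s0"], [1.0])
        with pytest.raises(ValueError):
            causal_fraction_weights(w, 0.0)


class TestScore:
    def _split(self, cohort):
        return split_transmission(cohort.genotypes, cohort.pedigree)

    def test_single_snp_example(self):
        from trionurture.types import SplitGenotypes
        t = make_genotypes([[2.0]])
        nt = make_genotypes([[0.0]])
        split = SplitGenotypes(t, nt, np.zeros((1, 1), dtype=np.int8),
                               None, None)
        w = weight_table(["snp0"], [0.5])
        out = score(split, w)
        assert out["pgs_t"].iloc[0] == pytest.approx(1.0)
        assert out["pgs_nt"].iloc[0] == pytest.approx(0.0)

    def test_matches_double_loop_oracle(self, small_cohort):
        split = self._split(small_cohort)
        rng = np.random.default_rng(3)
        m = split.transmitted.n_snps
        w = weight_table(split.transmitted.snps["snp_id"].tolist(),
                         rng.normal(size=m))
        out = score(split, w)
        i = rng.integers(0, len(out))
        brute = sum(split.transmitted.dosages[i, j]
                    * w["beta_adjusted"].iloc[j] for j in range(m))
        assert out["pgs_t"].iloc[i] == pytest.approx(brute)

    def test_linearity(self, small_cohort):
        split = self._split(small_cohort)
        rng = np.random.default_rng(4)
        ids = split.transmitted.snps["snp_id"].tolist()
        w1 = weight_table(ids, rng.normal(size=len(ids)))
        w2 = weight_table(ids, rng.normal(size=len(ids)))
        w12 = w1.copy()
        w12["beta_adjusted"] = w1["beta_adjusted"] + w2["beta_adjusted"]
        s1, s2, s12 = (score(split, w)["pgs_t"] for w in (w1, w2, w12))
        np.testing.assert_allclose(s12, s1 + s2, rtol=1e-10, atol=1e-10)

    def test_t_nt_swap_symmetry(self, small_cohort):
        from trionurture.types import SplitGenotypes
        split = self._split(small_cohort)
        swapped = SplitGenotypes(split.nontransmitted, split.transmitted,
                                 split.status, split.excluded_samples,
                                 split.excluded_snps)
        rng = np.random.default_rng(5)
        ids = split.transmitted.snps["snp_id"].tolist()
        w = weight_table(ids, rng.normal(size=len(ids)))
        a, b = score(split, w), score(swapped, w)
        np.testing.assert_allclose(a["pgs_t"], b["pgs_nt"])
        np.testing.assert_allclose(a["pgs_nt"], b["pgs_t"])

    def test_child_plus_pseudocontrol_equals_parent_sum(self, small_cohort):
        split = self._split(small_cohort)
        rng = np.random.default_rng(6)
        ids = split.transmitted.snps["snp_id"].tolist()
        w = weight_table(ids, rng.normal(size=len(ids)))
        out = score(split, w)
        ped = small_cohort.pedigree.offspring().set_index("individual_id")
        geno = small_cohort.genotypes
        wv = w["beta_adjusted"].to_numpy()
        fathers = geno.dosages[geno.sample_index(
            ped.loc[out["person_id"], "father_id"])] @ wv
        mothers = geno.dosages[geno.sample_index(
            ped.loc[out["person_id"], "mother_id"])] @ wv
        np.testing.assert_allclose(out["pgs_t"] + out["pgs_nt"],
                                   fathers + mothers, rtol=1e-10)

    def test_missing_dosages_mean_imputed(self):
        from trionurture.types import SplitGenotypes
        t = make_genotypes([[2.0, 0.0], [np.nan, 2.0], [1.0, 1.0]])
        nt = make_genotypes(np.zeros((3, 2)))
        split = SplitGenotypes(t, nt, np.zeros((3, 2), dtype=np.int8),
                               None, None)
        w = weight_table(["snp0", "snp1"], [1.0, 0.0])
        out = score(split, w)
        # cohort frequency of snp0 over non-missing = (2+1)/4 -> fill 1.5
        assert out["pgs_t"].iloc[1] == pytest.approx(1.5)

    def test_all_missing_sample_scores_missing(self):
        from trionurture.types import SplitGenotypes
        t = make_genotypes([[np.nan, np.nan], [1.0, 1.0]])
        nt = make_genotypes(np.zeros((2, 2)))
        split = SplitGenotypes(t, nt, np.zeros((2, 2), dtype=np.int8),
                               None, None)
        w = weight_table(["snp0", "snp1"], [1.0, 1.0])
        out = score(split, w)
        assert np.isnan(out["pgs_t"].iloc[0])
        assert np.isfinite(out["pgs_t"].iloc[1])
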