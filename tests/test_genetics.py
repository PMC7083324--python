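"""Trait collapsing, inverse-normal transform, genotype coding and the
covariate-adjusted association scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from ehrssm import (
    GenotypeTable,
    SNPPlantConfig,
    TruthConfig,
    association_scan,
    bonferroni_threshold,
    collapse_repeats,
    encode_genotype,
    generate_truth,
    inject_genetic_effects,
    inverse_normal_transform,
    prediction_errors,
    simulate_cohort,
)


def covariates_for(ds):
    rows = {s.pid: {"age": s.age_at_first, "bmi": float(np.nanmean(s.z[:, 0]))}
            for s in ds.participants}
    return pd.DataFrame.from_dict(rows, orient="index")


class TestCollapse:
    def test_mean_single_and_masked(self):
        df = pd.DataFrame({
            "pid": ["a", "a", "b", "c", "c", "c"],
            "trait": ["x"] * 6,
            "error": [1.0, 3.0, 5.0, 1.0, np.nan, 2.0],
        })
        out = collapse_repeats(df)
        assert out.loc["a", "x"] == pytest.approx(2.0)
        assert out.loc["b", "x"] == pytest.approx(5.0)
        assert out.loc["c", "x"] == pytest.approx(1.5)


class TestInverseNormal:
    def test_blom_formula_n3(self):
        out = inverse_normal_transform([10.0, -5.0, 3.0])
        expected = sstats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out[2] == pytest.approx(0.0, abs=1e-12)  # middle value -> 0

    def test_monotone(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 3, 50)
        out = inverse_normal_transform(x)
        assert (np.argsort(out) == np.argsort(x)).all()

    def test_large_sample_standard_moments(self):
        rng = np.random.default_rng(1)
        out = inverse_normal_transform(rng.exponential(2.0, 10_000))
        assert abs(out.mean()) < 0.02
        assert abs(out.var() - 1.0) < 0.02

    def test_identical_values_raise(self):
        with pytest.raises(ValueError, match="identical"):
            inverse_normal_transform([1.0, 1.0, 1.0])

    def test_missing_preserved(self):
        out = inverse_normal_transform([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()


@pytest.mark.parametrize(
    "g,model,expected",
    [(0, "additive", 0), (1, "additive", 1), (2, "additive", 2),
     (0, "dominant", 0), (1, "dominant", 1), (2, "dominant", 1),
     (0, "recessive", 0), (1, "recessive", 0), (2, "recessive", 1)],
)
def test_genotype_coding_table(g, model, expected):
    assert encode_genotype(g, model) == expected


def test_invalid_genotype_rejected():
    with pytest.raises(ValueError):
        encode_genotype(3, "additive")
    with pytest.raises(ValueError):
        encode_genotype(1, "codominant")


class TestAssociationScan:
    def test_bonferroni_threshold_published_panel(self):
        # 915 array SNPs at alpha 0.05
        assert bonferroni_threshold(0.05, 915) == pytest.approx(5.46e-5, rel=5e-3)

    def test_dose_coefficient_matches_normal_equations(self):
        # 12-row hand computation: OLS via explicit normal equations + t p-value
        rng = np.random.default_rng(7)
        n = 12
        g = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2], dtype=float)
        age = rng.uniform(55, 75, n)
        bmi = rng.uniform(19, 30, n)
        y = 0.5 * g + 0.01 * age - 0.02 * bmi + rng.normal(0, 1, n)
        traits = pd.DataFrame({"t1": y}, index=[f"p{i}" for i in range(n)])
        geno = GenotypeTable(["rs1"], list(traits.index), g.reshape(1, -1))
        cov = pd.DataFrame({"age": age, "bmi": bmi}, index=traits.index)
        res = association_scan(traits, geno, cov, models=("additive",))
        X = np.column_stack([np.ones(n), g, age, bmi])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 4)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        tstat = beta[1] / se
        p = 2 * sstats.t.sf(abs(tstat), n - 4)
        row = res.iloc[0]
        assert row["beta"] == pytest.approx(beta[1], rel=1e-10)
        assert row["se"] == pytest.approx(se, rel=1e-10)
        assert row["p_value"] == pytest.approx(p, rel=1e-10)

    def test_monomorphic_dose_undefined(self):
        n = 20
        rng = np.random.default_rng(8)
        traits = pd.DataFrame({"t1": rng.normal(0, 1, n)},
                              index=[f"p{i}" for i in range(n)])
        geno = GenotypeTable(["rs1"], list(traits.index),
                             np.full((1, n), 2.0))
        cov = pd.DataFrame({"age": rng.uniform(55, 75, n),
                            "bmi": rng.uniform(20, 28, n)}, index=traits.index)
        res = association_scan(traits, geno, cov, models=("recessive",))
        assert np.isnan(res["p_value"].iloc[0])
        assert not res["significant"].iloc[0]

    def test_invariant_to_participant_order_and_covariate_scaling(self):
        rng = np.random.default_rng(9)
        n = 60
        idx = [f"p{i}" for i in range(n)]
        g = rng.binomial(2, 0.3, n).astype(float)
        traits = pd.DataFrame({"t1": rng.normal(0, 1, n) + 0.3 * g}, index=idx)
        cov = pd.DataFrame({"age": rng.uniform(55, 75, n),
                            "bmi": rng.uniform(20, 28, n)}, index=idx)
        geno = GenotypeTable(["rs1"], idx, g.reshape(1, -1))
        res1 = association_scan(traits, geno, cov, models=("additive",))
        perm = rng.permutation(n)
        res2 = association_scan(traits.iloc[perm], geno, cov, models=("additive",))
        cov_scaled = cov.copy()
        cov_scaled["age"] = 3.0 * cov_scaled["age"] - 10
        res3 = association_scan(traits, geno, cov_scaled, models=("additive",))
        assert res1["p_value"].iloc[0] == pytest.approx(res2["p_value"].iloc[0], rel=1e-9)
        assert res1["p_value"].iloc[0] == pytest.approx(res3["p_value"].iloc[0], rel=1e-9)
        assert res1["beta"].iloc[0] == pytest.approx(res3["beta"].iloc[0], rel=1e-9)

    def test_null_pvalues_uniform_after_genotype_permutation(self):
        # permuting genotypes breaks any association: p-values ~ U(0, 1)
        cfg = TruthConfig(seed=15, K=300, T_max=8)
        truth = generate_truth(cfg)
        ds, _ = simulate_cohort(truth, cfg, seed=16)
        plant = SNPPlantConfig(n_snps=500, mafs=0.3, causal={}, seed=17)
        ds2, geno = inject_genetic_effects(ds, plant)
        rng = np.random.default_rng(18)
        perm = rng.permutation(geno.genotypes.shape[1])
        geno_perm = GenotypeTable(geno.snp_ids, geno.participants,
                                  geno.genotypes[:, perm])
        errs = prediction_errors(truth, ds2)
        coll = collapse_repeats(errs[["pid", "trait", "error"]])
        tr = coll.apply(lambda c: inverse_normal_transform(c.to_numpy()),
                        axis=0, result_type="broadcast")
        res = association_scan(tr[["trait_1"]], geno_perm, covariates_for(ds2),
                               models=("additive",))
        ks = sstats.kstest(res["p_value"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_errors_beat_raw_observations_for_planted_residual_effect(self):
        # a SNP effect planted on the residual of a covariate-driven trait is
        # detected more powerfully in prediction errors than in raw values
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = TruthConfig(seed=500 + seed, K=300, T_max=8,
                              g_density=0.6, g_effect_range=(0.8, 1.2))
            truth = generate_truth(cfg)
            ds, _ = simulate_cohort(truth, cfg, seed=600 + seed)
            plant = SNPPlantConfig(n_snps=1, mafs=0.3,
                                   causal={0: (0, 0.5, 0.3, "additive")},
                                   seed=700 + seed)
            ds2, geno = inject_genetic_effects(ds, plant)
            errs = prediction_errors(truth, ds2)
            cov = covariates_for(ds2)
            p_vals = {}
            for col in ("error", "observed"):
                coll = collapse_repeats(errs[["pid", "trait", col]])
                tr = coll.apply(lambda c: inverse_normal_transform(c.to_numpy()),
                                axis=0, result_type="broadcast")
                res = association_scan(tr[["trait_1"]], geno, cov,
                                       models=("additive",))
                p_vals[col] = res["p_value"].iloc[0]
            if p_vals["error"] < p_vals["observed"]:
                wins += 1
        assert wins > n_seeds / 2


def test_genotype_table_tsv_and_vcf_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    g = rng.binomial(2, 0.4, (4, 6)).astype(float)
    g[0, 0] = np.nan
    table = GenotypeTable([f"rs{i}" for i in range(4)],
                          [f"p{i}" for i in range(6)], g)
    tsv = tmp_path / "geno.tsv"
    table.to_frame().to_csv(tsv, sep="\t")
    back = GenotypeTable.from_tsv(tsv)
    np.testing.assert_allclose(np.nan_to_num(back.genotypes, nan=-1),
                               np.nan_to_num(g, nan=-1))
    vcf = tmp_path / "geno.vcf"
    table.to_vcf(vcf)
    back2 = GenotypeTable.from_vcf(vcf)
    assert back2.snp_ids == table.snp_ids
    np.testing.assert_allclose(np.nan_to_num(back2.genotypes, nan=-1),
                               np.nan_to_num(g, nan=-1))
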