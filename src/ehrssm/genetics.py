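"""Genetic association of prediction errors (or raw values) with SNPs.

Per-participant trait values (repeat visits collapsed to means, then
rank-based inverse-normal transformed) are regressed on a genotype dose
under additive / dominant / recessive encodings, adjusting for age and
BMI, with Bonferroni control at alpha / n_snps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

__all__ = [
    "GenotypeTable",
    "collapse_repeats",
    "inverse_normal_transform",
    "encode_genotype",
    "association_scan",
    "bonferroni_threshold",
]

GENETIC_MODELS = ("additive", "dominant", "recessive")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class GenotypeTable:
    """Minor-allele counts per (SNP, participant); NaN = missing call."""

    snp_ids: list
    participants: list
    genotypes: np.ndarray  # (n_snps, n_participants) float with NaN

    def __post_init__(self):
        g = self.genotypes
        valid = np.isin(g[np.isfinite(g)], (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotypes must be 0, 1, 2 or missing")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def row(self, snp: str) -> np.ndarray:
        return self.genotypes[self.snp_ids.index(snp)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.genotypes, index=self.snp_ids, columns=self.participants)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))

    @classmethod
    def from_vcf(cls, path) -> "GenotypeTable":
        """Read a biallelic unphased VCF (GT field only) via cyvcf2."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        participants = list(vcf.samples)
        snp_ids, rows = [], []
        for variant in vcf:
            snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
            g = variant.gt_types.astype(float)  # 0/1/2, 3 = unknown
            g[g == 3] = np.nan
            rows.append(g)
        return cls(snp_ids, participants, np.array(rows, dtype=float))

    def to_vcf(self, path) -> None:
        """Write a minimal biallelic unphased VCF (GT only)."""
        header = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=1>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.participants),
        ]
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        lines = []
        for i, snp in enumerate(self.snp_ids):
            calls = [
                gt_codes.get(g, "./.") if np.isfinite(g) else "./."
                for g in self.genotypes[i]
            ]
            lines.append(f"1\t{i + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls))
        with open(path, "w") as fh:
            fh.write("\n".join(header + lines) + "\n")


def collapse_repeats(values: pd.DataFrame) -> pd.DataFrame:
    """Mean per participant over observed visits, per trait.

    Input is the long prediction-error frame (pid, trait, plus a value
    column named ``error`` or ``observed``) or any long frame with exactly
    one numeric value column; repeat check-ups of the same participant are
    averaged so they do not inflate the association sample.
    """
    value_col = "error" if "error" in values.columns else (
        "observed" if "observed" in values.columns else None
    )
    if value_col is None:
        numeric = [c for c in values.columns if c not in ("pid", "trait", "t")
                   and pd.api.types.is_numeric_dtype(values[c])]
        if len(numeric) != 1:
            raise ValueError("cannot identify the value column to collapse")
        value_col = numeric[0]
    return values.pivot_table(index="pid", columns="trait", values=value_col,
                              aggfunc="mean")


def inverse_normal_transform(values, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transform, Blom offset by default:
    Φ⁻¹((rank − c) / (n − 2c + 1)); ties get average ranks, missing values
    are preserved."""
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.ptp(x[ok]) == 0:
        raise ValueError("all values identical: ranks undefined")
    ranks = sstats.rankdata(x[ok], method="average")
    out[ok] = sstats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


def encode_genotype(g, model: str):
    """Code a 0/1/2 minor-allele count under an inheritance model."""
    g_arr = np.asarray(g, dtype=float)
    finite = g_arr[np.isfinite(g_arr)]
    if not np.isin(finite, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype must be 0, 1 or 2")
    if model == "additive":
        coded = g_arr
    elif model == "dominant":
        coded = np.where(np.isfinite(g_arr), (g_arr >= 1).astype(float), np.nan)
    elif model == "recessive":
        coded = np.where(np.isfinite(g_arr), (g_arr == 2).astype(float), np.nan)
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    return coded if coded.ndim else float(coded)


def association_scan(
    traits: pd.DataFrame,
    geno: GenotypeTable,
    covariates: pd.DataFrame,
    models=GENETIC_MODELS,
    alpha: float = 0.05,
    strict_family: bool = False,
) -> pd.DataFrame:
    """OLS of each (collapsed, transformed) trait on genotype dose + age +
    BMI + intercept, per SNP and inheritance model.

    ``traits`` is participants × traits; ``covariates`` has columns ``age``
    and ``bmi`` indexed by participant.  Complete cases only.  The
    significance threshold is alpha / n_snps (the printed convention);
    ``strict_family`` divides additionally by n_traits × n_models.
    Monomorphic doses and undersized samples give NaN p-values flagged
    undefined.
    """
    n_tests = geno.n_snps
    if strict_family:
        n_tests *= traits.shape[1] * len(models)
    threshold = bonferroni_threshold(alpha, n_tests)
    cov = covariates.loc[:, ["age", "bmi"]]
    results = []
    geno_df = geno.to_frame()
    common = [p for p in traits.index if p in geno_df.columns and p in cov.index]
    geno_mat = geno_df[common].to_numpy()
    cov_mat = cov.loc[common].to_numpy(dtype=float)
    for trait in traits.columns:
        tvals = traits.loc[common, trait].to_numpy(dtype=float)
        for si, snp in enumerate(geno.snp_ids):
            g = geno_mat[si]
            for model in models:
                dose = encode_genotype(g, model)
                X = np.column_stack([dose, cov_mat])
                rows_ok = np.isfinite(X).all(axis=1) & np.isfinite(tvals)
                n_used = int(rows_ok.sum())
                beta = se = pval = np.nan
                if n_used >= X.shape[1] + 3 and np.ptp(dose[rows_ok]) > 0:
                    design = sm.add_constant(X[rows_ok], has_constant="add")
                    ols = sm.OLS(tvals[rows_ok], design).fit()
                    beta, se, pval = ols.params[1], ols.bse[1], ols.pvalues[1]
                results.append(
                    (snp, trait, model, beta, se, pval, n_used,
                     bool(np.isfinite(pval) and pval < threshold))
                )
    out = pd.DataFrame(
        results,
        columns=["snp", "trait", "model", "beta", "se", "p_value", "n", "significant"],
    )
    out.attrs["bonferroni_threshold"] = threshold
    return out
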