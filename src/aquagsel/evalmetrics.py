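"""Imputation-accuracy statistics.

Accuracy is judged against the simulation truth (or a held-out set) on the
masked sites only: the per-individual Pearson correlation between true and
imputed dosages, the per-SNP percentage of exactly recovered genotypes,
and per-SNP correlations grouped into five MAF bins
(0-0.1], (0.1-0.2], (0.2-0.3], (0.3-0.4], (0.4-0.5].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

MAF_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
MAF_BIN_LABELS = ("(0-0.1]", "(0.1-0.2]", "(0.2-0.3]", "(0.3-0.4]", "(0.4-0.5]")


@dataclass
class AccuracyReport:
    per_individual: pd.DataFrame = field(default_factory=pd.DataFrame)
    mean_r: float = np.nan
    sd_r: float = np.nan
    n_undefined: int = 0
    per_snp: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_bin: pd.DataFrame = field(default_factory=pd.DataFrame)


def _aligned(truth: GenotypeMatrix, imputed: GenotypeMatrix, mask: np.ndarray):
    if truth.ids != imputed.ids or truth.snps != imputed.snps:
        raise ValueError("truth and imputed matrices must be congruent")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != truth.dosages.shape:
        raise ValueError("mask shape must match the genotype matrices")
    return mask


def per_individual_accuracy(
    truth: GenotypeMatrix, imputed: GenotypeMatrix, mask: np.ndarray
) -> AccuracyReport:
    """Pearson r of true vs imputed dosages per individual over masked sites.

    Individuals whose true or imputed vector has zero variance (Pearson
    undefined) are recorded as NaN and excluded from the mean, with the
    count reported.
    """
    mask = _aligned(truth, imputed, mask)
    rows = []
    for i, ind in enumerate(truth.ids):
        sel = mask[i]
        n = int(sel.sum())
        if n == 0:
            continue
        t = truth.dosages[i, sel].astype(float)
        x = imputed.dosages[i, sel].astype(float)
        if n < 2 or t.std() == 0 or x.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(t, x)[0, 1])
        rows.append({"id": ind, "r": r, "n_masked": n})
    per_ind = pd.DataFrame(rows, columns=["id", "r", "n_masked"])
    defined = per_ind["r"].dropna()
    return AccuracyReport(
        per_individual=per_ind,
        mean_r=float(defined.mean()) if len(defined) else np.nan,
        sd_r=float(defined.std(ddof=1)) if len(defined) > 1 else 0.0,
        n_undefined=int(per_ind["r"].isna().sum()),
    )


def per_snp_concordance(
    truth: GenotypeMatrix,
    imputed: GenotypeMatrix,
    mask: np.ndarray,
    panel_snps: list[str] | None = None,
) -> pd.DataFrame:
    """Percent of masked genotypes exactly recovered, per SNP.

    Panel SNPs (observed on the LD panel, concordance 100 by construction)
    are flagged so reports can keep them separate.
    """
    mask = _aligned(truth, imputed, mask)
    agree = (truth.dosages == imputed.dosages) & mask
    n_masked = mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        pct = np.where(n_masked > 0, 100.0 * agree.sum(axis=0) / np.maximum(n_masked, 1), np.nan)
    on_panel = np.zeros(truth.n_snps, dtype=bool)
    if panel_snps is not None:
        on_panel[truth.snp_indices(panel_snps)] = True
    return pd.DataFrame(
        {
            "snp": truth.snps,
            "pct_correct": pct,
            "n_masked": n_masked,
            "on_panel": on_panel,
        }
    )


def _per_snp_correlation(truth, imputed, mask) -> np.ndarray:
    t = truth.dosages.astype(float)
    x = imputed.dosages.astype(float)
    out = np.full(truth.n_snps, np.nan)
    for j in range(truth.n_snps):
        sel = mask[:, j]
        if sel.sum() < 2:
            continue
        tv, xv = t[sel, j], x[sel, j]
        if tv.std() == 0 or xv.std() == 0:
            continue
        out[j] = np.corrcoef(tv, xv)[0, 1]
    return out


def maf_binned_accuracy(
    truth: GenotypeMatrix,
    imputed: GenotypeMatrix,
    mask: np.ndarray,
    maf: np.ndarray,
) -> pd.DataFrame:
    """Per-SNP truth-vs-imputed correlation grouped into the five MAF bins.

    Bins are half-open on the left, closed on the right (MAF 0.1 falls in
    (0-0.1]).  Monomorphic SNPs (MAF 0) are excluded with a warning.
    """
    mask = _aligned(truth, imputed, mask)
    maf = np.asarray(maf, dtype=float)
    if len(maf) != truth.n_snps:
        raise ValueError("need one MAF per SNP")
    if (maf > 0.5 + 1e-12).any():
        raise ValueError("MAF cannot exceed 0.5")
    zero = maf <= 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} monomorphic (MAF=0) SNPs")
    r = _per_snp_correlation(truth, imputed, mask)
    bins = pd.cut(maf, bins=list(MAF_BIN_EDGES), labels=list(MAF_BIN_LABELS), right=True)
    df = pd.DataFrame({"snp": truth.snps, "maf": maf, "bin": bins, "r": r})
    df = df[~zero]
    summary = (
        df.dropna(subset=["r"])
        .groupby("bin", observed=False)["r"]
        .agg(["count", "mean", "std", lambda s: s.quantile(0.75) - s.quantile(0.25)])
        .rename(columns={"<lambda_0>": "iqr"})
        .reset_index()
    )
    summary.columns = ["bin", "n_snps", "mean_r", "sd_r", "iqr_r"]
    summary.attrs["per_snp"] = df
    return summary


def evaluate(
    truth: GenotypeMatrix,
    imputed: GenotypeMatrix,
    mask: np.ndarray,
    panel_snps: list[str] | None = None,
) -> AccuracyReport:
    """Full accuracy report: per-individual, per-SNP, per-MAF-bin."""
    rep = per_individual_accuracy(truth, imputed, mask)
    rep.per_snp = per_snp_concordance(truth, imputed, mask, panel_snps)
    maf = truth.maf()
    rep.per_bin = maf_binned_accuracy(truth, imputed, mask, np.nan_to_num(maf))
    return rep
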