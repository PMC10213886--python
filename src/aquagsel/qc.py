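"""Quality control on individuals and SNPs.

Individuals are dropped for high missingness or for having exactly one of
their two parents genotyped.  SNPs are screened on missingness, exact
Hardy-Weinberg deviation, minor allele frequency and trio Mendelian-error
rate; every criterion is computed on the raw input matrix and the report
records the first-failing reason in the fixed order
missingness -> HWE -> MAF -> Mendelian.  Mendelian-inconsistent genotypes
are reported, never altered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import MISSING, GenotypeMatrix, MarkerMap, Pedigree

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    ind_missing_max: float = 0.20
    snp_missing_max: float = 0.10
    hwe_p_min: float = 1e-6
    maf_min: float = 0.05
    mendel_rate_max: float = 0.10

    def __post_init__(self):
        for name in ("ind_missing_max", "snp_missing_max", "maf_min", "mendel_rate_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if not 0 < self.hwe_p_min < 1:
            raise ValueError("hwe_p_min must be in (0,1)")


@dataclass
class QCReport:
    kept_individuals: list[str] = field(default_factory=list)
    removed_individuals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason"])
    )
    kept_snps: list[str] = field(default_factory=list)
    removed_snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )
    snp_stats: pd.DataFrame | None = None

    def write_tsv(self, prefix) -> None:
        self.removed_individuals.to_csv(f"{prefix}.removed_individuals.tsv", sep="\t", index=False)
        self.removed_snps.to_csv(f"{prefix}.removed_snps.tsv", sep="\t", index=False)
        if self.snp_stats is not None:
            self.snp_stats.to_csv(f"{prefix}.snp_stats.tsv", sep="\t", index=False)


# ----------------------------------------------------------- individuals


def filter_individuals(
    geno: GenotypeMatrix, ped: Pedigree, th: QCThresholds = QCThresholds()
) -> tuple[QCReport, GenotypeMatrix]:
    """Drop high-missingness individuals and one-genotyped-parent offspring.

    Offspring with exactly one parent present among the genotyped ids are
    removed (pedigree-based imputation needs both or can fall back to
    population rules with neither); parents are never removed by that rule.
    """
    if geno.n_individuals == 0 or geno.n_snps == 0:
        raise ValueError("empty genotype matrix")
    genotyped = set(geno.ids)
    parents = {p for r in ped.table.itertuples(index=False) for p in (r[1], r[2]) if p != "0"}
    miss = geno.ind_missing_rate()
    removed = []
    for i, ind in enumerate(geno.ids):
        if miss[i] > th.ind_missing_max:
            removed.append({"id": ind, "reason": "missingness"})
            continue
        if ind in parents:
            continue
        try:
            sire, dam = ped.parents_of(ind)
        except KeyError:
            continue
        if sire == "0" and dam == "0":
            continue
        n_geno_parents = (sire in genotyped) + (dam in genotyped)
        if n_geno_parents == 1:
            removed.append({"id": ind, "reason": "one-parent"})
    removed_df = pd.DataFrame(removed, columns=["id", "reason"])
    kept = [i for i in geno.ids if i not in set(removed_df["id"])]
    report = QCReport(kept_individuals=kept, removed_individuals=removed_df)
    return report, geno.subset(ids=kept)


# ------------------------------------------------------------------- HWE


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton-style).

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts no more probable than the observed one.  Monomorphic
    sites return 1 by convention.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped individuals")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # log P(n_het | allele counts) over all feasible het counts (same parity)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[(n_rare - hets) % 2 == 0]
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    valid = hom_common >= 0
    hets, hom_rare, hom_common = hets[valid], hom_rare[valid], hom_common[valid]
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    logp = logp - logp.max()
    probs = np.exp(logp)
    probs = probs / probs.sum()
    p_obs = probs[hets == n_het][0]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p per SNP over non-missing genotypes."""
    d = geno.dosages
    n2 = (d == 2).sum(axis=0)  # hom ref
    n1 = (d == 1).sum(axis=0)
    n0 = (d == 0).sum(axis=0)
    out = np.ones(geno.n_snps)
    cache: dict[tuple[int, int, int], float] = {}
    for j in range(geno.n_snps):
        key = (int(n2[j]), int(n1[j]), int(n0[j]))
        if key not in cache:
            if sum(key) == 0:
                cache[key] = 1.0
            else:
                cache[key] = hwe_exact_test(*key)
        out[j] = cache[key]
    return out


# -------------------------------------------------------------- Mendelian


def mendelian_error_rate(
    geno: GenotypeMatrix, ped: Pedigree
) -> tuple[np.ndarray, pd.DataFrame]:
    """Trio Mendelian-error rates per SNP and per trio.

    An error is an offspring dosage impossible under any transmission from
    the parent pair; missing genotypes are skipped.  Rates divide errors by
    informative (complete) comparisons.
    """
    genotyped = set(geno.ids)
    trios = [
        (o, s, d)
        for o, s, d in ped.trios()
        if o in genotyped and s in genotyped and d in genotyped
    ]
    if not trios:
        warnings.warn("no complete genotyped trios; Mendelian rates undefined")
        return np.full(geno.n_snps, np.nan), pd.DataFrame(
            columns=["id", "errors", "informative", "rate"]
        )
    d = geno.dosages
    err_per_snp = np.zeros(geno.n_snps, dtype=np.int64)
    inf_per_snp = np.zeros(geno.n_snps, dtype=np.int64)
    trio_rows = []
    for o, s, dd in trios:
        go = d[geno.id_indices([o])[0]]
        gs = d[geno.id_indices([s])[0]]
        gd = d[geno.id_indices([dd])[0]]
        ok = (go != MISSING) & (gs != MISSING) & (gd != MISSING)
        lo = (gs == 2).astype(np.int8) + (gd == 2).astype(np.int8)
        hi = (gs >= 1).astype(np.int8) + (gd >= 1).astype(np.int8)
        err = ok & ((go < lo) | (go > hi))
        err_per_snp += err
        inf_per_snp += ok
        trio_rows.append(
            {
                "id": o,
                "errors": int(err.sum()),
                "informative": int(ok.sum()),
                "rate": err.sum() / ok.sum() if ok.sum() else np.nan,
            }
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        snp_rate = np.where(inf_per_snp > 0, err_per_snp / np.maximum(inf_per_snp, 1), np.nan)
    return snp_rate, pd.DataFrame(trio_rows)


# ------------------------------------------------------------------- SNPs


def filter_snps(
    geno: GenotypeMatrix,
    marker_map: MarkerMap,
    ped: Pedigree | None = None,
    th: QCThresholds = QCThresholds(),
) -> tuple[QCReport, GenotypeMatrix]:
    """Screen SNPs on missingness, HWE, MAF and Mendelian-error rate.

    All four statistics are computed on the input matrix; the kept set is
    the intersection of the four criteria and the recorded reason is the
    first failure in the fixed order.  Thresholds are strict as printed
    (missingness > max removes, MAF < min removes), so boundary values stay.
    """
    if set(geno.snps) - set(marker_map.snps):
        raise ValueError("marker map does not cover all genotype SNPs")
    miss = geno.snp_missing_rate()
    hwe_p = hwe_pvalues(geno)
    maf = geno.maf()
    if ped is not None:
        mendel, _ = mendelian_error_rate(geno, ped)
    else:
        mendel = np.full(geno.n_snps, np.nan)
    removed = []
    for j, snp in enumerate(geno.snps):
        if miss[j] > th.snp_missing_max:
            removed.append({"snp": snp, "reason": "missingness"})
        elif hwe_p[j] < th.hwe_p_min:
            removed.append({"snp": snp, "reason": "hwe"})
        elif np.isfinite(maf[j]) and maf[j] < th.maf_min:
            removed.append({"snp": snp, "reason": "maf"})
        elif not np.isfinite(maf[j]):
            removed.append({"snp": snp, "reason": "maf"})  # no calls at all
        elif np.isfinite(mendel[j]) and mendel[j] > th.mendel_rate_max:
            removed.append({"snp": snp, "reason": "mendel"})
    removed_df = pd.DataFrame(removed, columns=["snp", "reason"])
    dropped = set(removed_df["snp"])
    kept = [s for s in geno.snps if s not in dropped]
    stats = pd.DataFrame(
        {"snp": geno.snps, "maf": maf, "missing": miss, "hwe_p": hwe_p, "mendel_rate": mendel}
    )
    report = QCReport(
        kept_individuals=list(geno.ids),
        kept_snps=kept,
        removed_snps=removed_df,
        snp_stats=stats,
    )
    log.info("filter_snps: kept %d of %d SNPs", len(kept), geno.n_snps)
    return report, geno.subset(snps=kept)


def post_imputation_maf_filter(
    geno: GenotypeMatrix, maf_min: float = 0.05
) -> tuple[GenotypeMatrix, list[str]]:
    """Re-filter on MAF after imputation (random fill can drain rare SNPs)."""
    if geno.missing_mask().any():
        raise ValueError("post-imputation filter expects complete genotypes")
    maf = geno.maf()
    kept = [s for j, s in enumerate(geno.snps) if maf[j] >= maf_min]
    removed = [s for s in geno.snps if s not in set(kept)]
    if not kept:
        raise ValueError("no SNPs left after post-imputation MAF filter")
    return geno.subset(snps=kept), removed
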