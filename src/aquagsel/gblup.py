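"""Genomic evaluation: GRM, REML variance components, GBLUP, cross-validation.

The genomic relationship matrix follows the marker-based estimator

    g_jk = (1/N) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with reference-allele frequencies estimated from the supplied genotypes.
The mixed model y = X b + a + e with a ~ N(0, G sigma_a^2) is fitted by
REML via one eigendecomposition of G and a bounded scalar optimisation over
the heritability ratio; breeding values are the BLUP solutions at the REML
estimates.  Prediction accuracy for cross-validation is
cor(EBV, y) / sqrt(h2), with h2 estimated once from the full data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class GRM:
    matrix: np.ndarray
    ids: list[str]
    allele_freqs: np.ndarray
    n_snps: int

    def submatrix(self, rows: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
        cols = rows if cols is None else cols
        return self.matrix[np.ix_(rows, cols)]

    def write_tsv(self, prefix) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(
            f"{prefix}.grm.tsv", sep="\t", float_format="%.6g"
        )
        with open(f"{prefix}.grm.ids", "w") as fh:
            fh.write("\n".join(self.ids) + "\n")


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    h2: float
    loglik: float
    converged: bool


@dataclass
class CVResult:
    accuracies: pd.DataFrame  # replicate, fold, accuracy, n_validation
    mean: float
    sd: float
    fold_assignments: pd.DataFrame
    seed: int
    pooled_mean: float | None = None


# ------------------------------------------------------------------- GRM


def compute_grm(geno: GenotypeMatrix, allele_freqs: np.ndarray | None = None) -> GRM:
    """Marker-based genomic relationship matrix.

    Residual missing genotypes are imputed to the mean dosage (2p, logged);
    monomorphic SNPs are excluded with a warning since their standardised
    contribution is undefined.
    """
    x = geno.dosages.astype(float)
    miss = x == MISSING
    if allele_freqs is None:
        p = geno.allele_freq()
    else:
        p = np.asarray(allele_freqs, dtype=float)
        if len(p) != geno.n_snps:
            raise ValueError("need one allele frequency per SNP")
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs for the GRM")
    if (~poly).sum():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic SNPs from the GRM")
    if miss.any():
        log.info("GRM: imputing %d residual missing genotypes to 2p", int(miss.sum()))
        x = np.where(miss, 2 * p[None, :], x)
    x = x[:, poly]
    pp = p[poly]
    w = (x - 2 * pp[None, :]) / np.sqrt(2 * pp * (1 - pp))[None, :]
    n = poly.sum()
    return GRM(matrix=w @ w.T / n, ids=list(geno.ids), allele_freqs=p, n_snps=int(n))


# ------------------------------------------------------------------ REML


def _check_design(x: np.ndarray, names: list[str] | None):
    if np.linalg.matrix_rank(x) < x.shape[1]:
        _, r = np.linalg.qr(x)
        dep = [i for i in range(x.shape[1]) if abs(r[i, i]) < 1e-8]
        labels = [names[i] if names else f"column {i}" for i in dep]
        raise ValueError(f"singular fixed-effects design; collinear: {labels}")


def reml_fit(
    y: np.ndarray,
    fixed: np.ndarray | None,
    grm: GRM | np.ndarray,
    fixed_names: list[str] | None = None,
    h2_bounds: tuple[float, float] = (1e-6, 1 - 1e-6),
) -> VarianceComponents:
    """REML for the one-random-effect animal model.

    Eigendecomposes G once and profiles the phenotypic variance, leaving a
    one-dimensional restricted likelihood in the heritability ratio
    h = sigma_a^2 / (sigma_a^2 + sigma_e^2), optimised on ``h2_bounds``.
    """
    g = grm.matrix if isinstance(grm, GRM) else np.asarray(grm, float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if g.shape != (n, n):
        raise ValueError("G dimension does not match phenotypes")
    if fixed is None:
        x = np.ones((n, 1))
    else:
        x = np.asarray(fixed, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
    _check_design(x, fixed_names)
    p_rank = x.shape[1]
    # clamping the spectrum at 0 enforces PSD directly in the eigenbasis
    d, u = np.linalg.eigh(g)
    d = np.maximum(d, 0.0)
    yt = u.T @ y
    xt = u.T @ x

    def neg_restricted_ll(h: float) -> float:
        lam = h * d + (1.0 - h)
        inv = 1.0 / lam
        xtx = xt.T @ (xt * inv[:, None])
        xty = xt.T @ (yt * inv)
        beta = np.linalg.solve(xtx, xty)
        resid = yt - xt @ beta
        rss = float(resid @ (resid * inv))
        sigma_p = rss / (n - p_rank)
        _, logdet_xtx = np.linalg.slogdet(xtx)
        ll = -0.5 * (
            (n - p_rank) * np.log(sigma_p)
            + np.log(lam).sum()
            + logdet_xtx
            + (n - p_rank)
        )
        return -ll

    res = minimize_scalar(
        neg_restricted_ll, bounds=h2_bounds, method="bounded",
        options={"xatol": 1e-8},
    )
    h = float(res.x)
    lam = h * d + (1.0 - h)
    inv = 1.0 / lam
    xtx = xt.T @ (xt * inv[:, None])
    beta = np.linalg.solve(xtx, xt.T @ (yt * inv))
    resid = yt - xt @ beta
    sigma_p = float(resid @ (resid * inv)) / (n - p_rank)
    return VarianceComponents(
        sigma2_a=h * sigma_p,
        sigma2_e=(1.0 - h) * sigma_p,
        h2=h,
        loglik=-float(res.fun),
        converged=bool(res.success),
    )


# ----------------------------------------------------------------- GBLUP


def gblup_predict(
    y_train: np.ndarray,
    fixed_train: np.ndarray | None,
    grm: GRM,
    train_idx: np.ndarray,
    predict_idx: np.ndarray,
    vc: VarianceComponents | None = None,
    fixed_names: list[str] | None = None,
) -> np.ndarray:
    """BLUP breeding values for ``predict_idx`` given training phenotypes.

    Solves the mixed model at the (supplied or REML-estimated) variance
    components:  a_hat = sigma_a^2 G[p,t] V_t^{-1} (y_t - X_t b_hat),
    the direct equivalent of the mixed-model equations without inverting G.
    """
    y_train = np.asarray(y_train, dtype=float)
    train_idx = np.asarray(train_idx, dtype=int)
    predict_idx = np.asarray(predict_idx, dtype=int)
    # V = sigma_a^2 G + sigma_e^2 I is well conditioned for sigma_e^2 > 0;
    # REML handles PSD by clamping the spectrum, no extra jitter needed here
    g_tt = grm.submatrix(train_idx)
    if vc is None:
        vc = reml_fit(y_train, fixed_train, g_tt, fixed_names=fixed_names)
    if fixed_train is None:
        x = np.ones((len(y_train), 1))
    else:
        x = np.asarray(fixed_train, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
    _check_design(x, fixed_names)
    v = vc.sigma2_a * g_tt + vc.sigma2_e * np.eye(len(train_idx))
    vinv_x = np.linalg.solve(v, x)
    vinv_y = np.linalg.solve(v, y_train)
    beta = np.linalg.solve(x.T @ vinv_x, x.T @ vinv_y)
    resid_proj = vinv_y - vinv_x @ beta
    g_pt = grm.submatrix(predict_idx, train_idx)
    return vc.sigma2_a * (g_pt @ resid_proj)


def prediction_accuracy(ebv_val: np.ndarray, y_val: np.ndarray, h2_full: float) -> float:
    """cor(EBV, phenotype) / sqrt(h2 from the full data)."""
    if not h2_full > 0:
        raise ValueError("h2_full must be positive")
    ebv_val = np.asarray(ebv_val, float)
    y_val = np.asarray(y_val, float)
    if len(ebv_val) < 2 or ebv_val.std() == 0 or y_val.std() == 0:
        return np.nan
    return float(np.corrcoef(ebv_val, y_val)[0, 1] / np.sqrt(h2_full))


# ------------------------------------------------------- cross-validation


def cross_validate(
    grm: GRM,
    phenotypes: pd.DataFrame,
    h2_full: float,
    k: int = 5,
    reps: int = 20,
    seed: int = 0,
    fixed_cols: list[str] | None = None,
    trait_col: str = "trait",
) -> CVResult:
    """Replicated k-fold cross-validation of GBLUP prediction accuracy.

    Each replicate partitions the phenotyped individuals into k random
    folds (about 1/k each); per fold the validation phenotypes are masked,
    variance components are re-estimated on the training set, breeding
    values predicted, and the accuracy statistic computed.  Fold-level
    accuracies are averaged, except for singleton folds whose predictions
    are pooled per replicate.
    """
    ids = phenotypes["id"].astype(str).tolist()
    pos = {s: j for j, s in enumerate(grm.ids)}
    rows = np.array([pos[i] for i in ids])
    y = phenotypes[trait_col].to_numpy(dtype=float)
    n = len(y)
    if n < k:
        raise ValueError("need at least k phenotyped individuals")
    x_all, names = build_design(phenotypes, fixed_cols)
    rng = np.random.default_rng(seed)
    fold_records, acc_records = [], []
    pooled_acc = []
    for rep in range(reps):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        pooled_pred = np.full(n, np.nan)
        for f, val in enumerate(folds):
            train = np.setdiff1d(perm, val)
            for ind, pos in zip(np.array(ids)[val], val):
                fold_records.append({"replicate": rep, "fold": f, "id": ind})
            if y[train].std() == 0 or y[val].std() == 0:
                warnings.warn(f"replicate {rep} fold {f}: zero phenotype variance, skipped")
                continue
            ebv = gblup_predict(
                y[train], x_all[train], grm, rows[train], rows[val], fixed_names=names
            )
            pooled_pred[val] = ebv
            if len(val) > 1:
                acc_records.append(
                    {
                        "replicate": rep,
                        "fold": f,
                        "accuracy": prediction_accuracy(ebv, y[val], h2_full),
                        "n_validation": len(val),
                    }
                )
        if np.isfinite(pooled_pred).all():
            pooled_acc.append(prediction_accuracy(pooled_pred, y, h2_full))
        if any(len(v) == 1 for v in folds):
            # singleton folds: pool predictions over the replicate
            ok = np.isfinite(pooled_pred)
            acc_records.append(
                {
                    "replicate": rep,
                    "fold": -1,
                    "accuracy": prediction_accuracy(pooled_pred[ok], y[ok], h2_full),
                    "n_validation": int(ok.sum()),
                }
            )
    acc = pd.DataFrame(acc_records, columns=["replicate", "fold", "accuracy", "n_validation"])
    vals = acc.loc[acc["fold"] >= 0, "accuracy"].dropna()
    if not len(vals):
        vals = acc["accuracy"].dropna()
    return CVResult(
        accuracies=acc,
        mean=float(vals.mean()) if len(vals) else np.nan,
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        fold_assignments=pd.DataFrame(fold_records),
        seed=seed,
        pooled_mean=float(np.mean(pooled_acc)) if pooled_acc else None,
    )


def build_design(
    phenotypes: pd.DataFrame, fixed_cols: list[str] | None
) -> tuple[np.ndarray, list[str]]:
    """Intercept plus treatment-coded categorical fixed effects."""
    n = len(phenotypes)
    cols = [np.ones(n)]
    names = ["intercept"]
    for c in fixed_cols or []:
        dummies = pd.get_dummies(phenotypes[c].astype(str), prefix=c, drop_first=True)
        for name in dummies.columns:
            cols.append(dummies[name].to_numpy(dtype=float))
            names.append(name)
    return np.column_stack(cols), names


def estimate_h2(
    geno: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    fixed_cols: list[str] | None = None,
    trait_col: str = "trait",
) -> tuple[VarianceComponents, GRM]:
    """Convenience: GRM on the supplied genotypes + REML h2 on the full data."""
    grm = compute_grm(geno)
    ids = phenotypes["id"].astype(str).tolist()
    pos = {s: j for j, s in enumerate(grm.ids)}
    rows = np.array([pos[i] for i in ids])
    sub = GRM(grm.submatrix(rows), ids, grm.allele_freqs, grm.n_snps)
    x, names = build_design(phenotypes, fixed_cols)
    vc = reml_fit(
        phenotypes[trait_col].to_numpy(float), x, sub, fixed_names=names
    )
    return vc, grm
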