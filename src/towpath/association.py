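"""Gene-level association statistics for rare and common variants.

The test for the effect of an optimally weighted combination of variants
(TOW) scores a gene by

    T = sum_i (y_i - ybar)(x_i0 - xbar_0),   x_i0 = sum_m w_m x_im,

with per-variant weights w_m = cov(y, x_m) / var*(x_m) chosen to maximize the
score; algebraically T equals sum_m cov(y, x_m)^2 / var*(x_m) and is therefore
non-negative (var* denotes the centered sum of squares, not divided by n).

The variable-weight extension (VW-TOW) applies TOW separately to rare
(MAF < 1%) and common variants, combines the variance-standardized pair as
T_lambda = lambda T_r / var(T_r) + (1 - lambda) T_c / var(T_c), and takes the
minimum permutation p-value over a grid of lambda in [0, 1]; the final
p-value of that minimum is itself calibrated against the permutation
distribution of per-permutation minima (a standard min-p construction with
one shared permutation set and leave-one-out ranking).

Covariates enter by residualization: phenotype and every variant column are
replaced by their OLS residuals on (intercept, covariates) before any
statistic is computed, and permutations act on the phenotype residuals with
genotype residuals fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import PHENOTYPE_COLUMNS, DEFAULT_COVARIATES, default_lambda_grid
from .datatypes import GeneVariantMap, GenotypeMatrix
from .mapping import impute_missing_mean
from .phenotypes import derive_phenotypes
from .simulate import gene_seed

log = logging.getLogger(__name__)


class DegenerateVarianceError(ValueError):
    """Permutation variance of a class statistic is zero."""

    def __init__(self, message: str, var_rare: float = 0.0, var_common: float = 0.0):
        super().__init__(message)
        self.var_rare = var_rare
        self.var_common = var_common


# ---------------------------------------------------------------------------
# residualization


@dataclass
class ResidualizedData:
    y_res: np.ndarray
    X_res: np.ndarray
    coef_y: np.ndarray
    coef_X: np.ndarray
    design_columns: list[str] = field(default_factory=list)


def residualize(y: np.ndarray, X: np.ndarray, Z: np.ndarray | None,
                covariate_names: list[str] | None = None) -> ResidualizedData:
    """OLS residuals of the phenotype and of every variant column on
    (intercept, covariates).

    With no covariates this reduces to centering. Raises on a rank-deficient
    design, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n = y.shape[0]
    if Z is None or (hasattr(Z, "size") and np.asarray(Z).size == 0):
        D = np.ones((n, 1))
        names = ["intercept"]
    else:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        D = np.column_stack([np.ones(n), Z])
        names = ["intercept"] + (
            list(covariate_names) if covariate_names else
            [f"z{j}" for j in range(Z.shape[1])]
        )
    if np.isnan(y).any() or np.isnan(D).any() or np.isnan(X).any():
        raise ValueError("residualize requires complete data; impute or drop upstream")
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(D, mode="economic", pivoting=True)
        dropped = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"covariate design is rank-deficient; collinear columns: {dropped}")
    Q, _ = np.linalg.qr(D)
    coef_y, *_ = np.linalg.lstsq(D, y, rcond=None)
    coef_X, *_ = np.linalg.lstsq(D, X, rcond=None)
    y_res = y - Q @ (Q.T @ y)
    X_res = X - Q @ (Q.T @ X)
    return ResidualizedData(y_res=y_res, X_res=X_res, coef_y=coef_y,
                            coef_X=coef_X, design_columns=names)


# ---------------------------------------------------------------------------
# TOW statistic


@dataclass
class TOWResult:
    gene_id: str
    statistic: float
    weights: np.ndarray
    n_variants_used: int
    p: float | None = None
    n_permutations: int | None = None


def tow_statistic(y_res: np.ndarray, X_res: np.ndarray,
                  gene_id: str = "") -> TOWResult:
    """Optimally weighted combination score via the explicit weighted form.

    Computes w_m = sum_i (y_i - ybar)(x_im - xbar_m) / sum_i (x_im - xbar_m)^2,
    the combined column x_0 = X w, and T = sum_i (y_i - ybar)(x_i0 - xbar_0).
    """
    y = np.asarray(y_res, dtype=float)
    X = np.atleast_2d(np.asarray(X_res, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n = y.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 individuals, got {n}")
    Xc = X - X.mean(axis=0, keepdims=True)
    denom = (Xc**2).sum(axis=0)
    if np.any(denom <= 0):
        bad = np.flatnonzero(denom <= 0)
        raise ValueError(
            f"zero-variance variant column(s) {bad.tolist()}; filter monomorphic upstream"
        )
    yc = y - y.mean()
    num = Xc.T @ yc
    w = num / denom
    x0 = X @ w
    T = float(yc @ (x0 - x0.mean()))
    return TOWResult(gene_id=gene_id, statistic=T, weights=w, n_variants_used=X.shape[1])


def _batch_tow(Yc: np.ndarray, Xc: np.ndarray, denom: np.ndarray) -> np.ndarray:
    """TOW statistics for many (permuted) centered phenotype rows at once.

    Uses the closed form T = sum_m cov_m^2 / ss_m, which recomputes the
    optimal weights inside every permutation implicitly.
    """
    num = Yc @ Xc  # (B+1, M)
    return (num * num / denom).sum(axis=1)


def _permutation_matrix(y: np.ndarray, B: int,
                        rng: np.random.Generator | None,
                        permutations: np.ndarray | None) -> np.ndarray:
    """Rows: observed y first, then B permutations of it."""
    if permutations is not None:
        perms = np.asarray(permutations)
        return np.vstack([y[None, :], y[perms]])
    if B < 100:
        raise ValueError("need at least 100 permutations")
    if rng is None:
        raise ValueError("an rng (or explicit permutations) is required")
    idx = np.array([rng.permutation(y.size) for _ in range(B)])
    return np.vstack([y[None, :], y[idx]])


def tow_permutation_p(y_res: np.ndarray, X_res: np.ndarray, B: int = 1000,
                      rng: np.random.Generator | int | None = None,
                      permutations: np.ndarray | None = None,
                      gene_id: str = "") -> TOWResult:
    """TOW with an add-one permutation p-value.

    p = (1 + #{b : T^(b) >= T^(0)}) / (B + 1); permutations act on the
    phenotype residuals, and weights are recomputed within each permutation.
    """
    res = tow_statistic(y_res, X_res, gene_id=gene_id)
    y = np.asarray(y_res, dtype=float)
    X = np.atleast_2d(np.asarray(X_res, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    Y = _permutation_matrix(y, B, rng, permutations)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Xc = X - X.mean(axis=0, keepdims=True)
    denom = (Xc**2).sum(axis=0)
    T = _batch_tow(Yc, Xc, denom)
    B_eff = Y.shape[0] - 1
    p = (1.0 + np.count_nonzero(T[1:] >= T[0])) / (B_eff + 1.0)
    res.p = float(p)
    res.n_permutations = B_eff
    return res


# ---------------------------------------------------------------------------
# VW-TOW


@dataclass
class VWTOWResult:
    gene_id: str
    T_rare: float
    T_common: float
    var_T_rare: float
    var_T_common: float
    lambda_grid: np.ndarray
    p_lambda_observed: np.ndarray
    min_p_observed: float
    best_lambda: float
    p: float
    n_rare: int
    n_common: int
    n_permutations: int


def vw_tow(y_res: np.ndarray, X_rare: np.ndarray, X_common: np.ndarray,
           B: int = 1000, lambda_grid=None,
           rng: np.random.Generator | int | None = None,
           permutations: np.ndarray | None = None,
           gene_id: str = "") -> VWTOWResult:
    """Variable-weight TOW over rare and common variant classes.

    One shared permutation set serves both classes and every lambda. For each
    permutation b (b = 0 is the observed data) the mixed statistic is ranked
    against the *other* permutations (leave-one-out for b >= 1), giving
    per-lambda p-values; the observed statistic is min_lambda p_lambda^(0)
    and its final p-value is the add-one fraction of permutations whose own
    min-p is at least as extreme.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.size == 0 or lam.min() < 0.0 or lam.max() > 1.0:
        raise ValueError("lambda grid must be a non-empty subset of [0, 1]")
    y = np.asarray(y_res, dtype=float)
    Xr = np.atleast_2d(np.asarray(X_rare, dtype=float))
    Xc_ = np.atleast_2d(np.asarray(X_common, dtype=float))
    if Xr.shape[0] != y.shape[0]:
        Xr = Xr.T
    if Xc_.shape[0] != y.shape[0]:
        Xc_ = Xc_.T
    if Xr.shape[1] == 0 or Xc_.shape[1] == 0:
        raise ValueError("both variant classes must be non-empty; use tow_permutation_p")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    Y = _permutation_matrix(y, B, rng, permutations)
    B_eff = Y.shape[0] - 1
    Yc = Y - Y.mean(axis=1, keepdims=True)

    def stats_for(X: np.ndarray) -> np.ndarray:
        Xcen = X - X.mean(axis=0, keepdims=True)
        denom = (Xcen**2).sum(axis=0)
        if np.any(denom <= 0):
            raise ValueError("zero-variance variant column; filter monomorphic upstream")
        return _batch_tow(Yc, Xcen, denom)

    Tr = stats_for(Xr)
    Tc = stats_for(Xc_)
    var_r = float(np.var(Tr[1:], ddof=1))
    var_c = float(np.var(Tc[1:], ddof=1))
    if var_r <= 0 or var_c <= 0:
        raise DegenerateVarianceError(
            f"gene {gene_id or '?'}: permutation variance is zero "
            f"(var_r={var_r}, var_c={var_c})",
            var_rare=var_r, var_common=var_c,
        )

    # (L, B+1) mixed statistics
    Tlam = lam[:, None] * (Tr / var_r)[None, :] + (1.0 - lam[:, None]) * (Tc / var_c)[None, :]
    obs = Tlam[:, 0]
    perm = Tlam[:, 1:]

    # observed p per lambda: add-one over all B permutations
    p_obs = (1.0 + (perm >= obs[:, None]).sum(axis=1)) / (B_eff + 1.0)
    # permuted p per lambda: rank among the other permutations (leave-one-out)
    r_min = rankdata(perm, method="min", axis=1)
    count_ge = B_eff - r_min  # #{b' != b : T_(b') >= T_(b)}
    p_perm = (1.0 + count_ge) / B_eff

    min_p_obs = float(p_obs.min())
    best_lambda = float(lam[int(np.argmin(p_obs))])
    min_p_perm = p_perm.min(axis=0)
    p_final = (1.0 + np.count_nonzero(min_p_perm <= min_p_obs)) / (B_eff + 1.0)

    return VWTOWResult(
        gene_id=gene_id,
        T_rare=float(Tr[0]), T_common=float(Tc[0]),
        var_T_rare=var_r, var_T_common=var_c,
        lambda_grid=lam, p_lambda_observed=p_obs,
        min_p_observed=min_p_obs, best_lambda=best_lambda,
        p=float(p_final),
        n_rare=Xr.shape[1], n_common=Xc_.shape[1],
        n_permutations=B_eff,
    )


# ---------------------------------------------------------------------------
# per-gene driver


def score_all_genes(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    gene_map: GeneVariantMap,
    classification: pd.DataFrame,
    phenotype: str,
    covariates=DEFAULT_COVARIATES,
    B: int = 1000,
    lambda_grid=None,
    seed: int = 0,
    maf_threshold: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every gene with at least one polymorphic variant.

    Genes with both rare and common variants get the variable-weight
    statistic; single-class genes fall back to plain TOW on that class. The
    per-gene RNG stream is derived from (seed, gene id), so results do not
    depend on iteration order. Returns (score table, drop log).
    """
    if phenotype not in PHENOTYPE_COLUMNS:
        raise ValueError(
            f"phenotype must be one of {sorted(PHENOTYPE_COLUMNS)}, got {phenotype!r}"
        )
    col = PHENOTYPE_COLUMNS[phenotype]
    cohort = cohort.set_index("individual_id", drop=False)
    missing_ids = [i for i in genotypes.individual_ids if i not in cohort.index]
    if missing_ids:
        raise ValueError(f"genotyped individuals missing from cohort: {missing_ids[:5]}")
    rows = cohort.loc[genotypes.individual_ids]
    if col not in rows.columns:
        rows = derive_phenotypes(rows)
    y = rows[col].to_numpy(dtype=float)
    Z = rows[list(covariates)].to_numpy(dtype=float) if covariates else None

    X = impute_missing_mean(genotypes)
    # individuals with a missing/flagged phenotype or covariate are excluded
    keep = np.isfinite(y)
    if Z is not None:
        keep &= np.isfinite(Z).all(axis=1)
    if not keep.all():
        log.warning("excluding %d individuals with missing phenotype/covariates",
                    int((~keep).sum()))
        y = y[keep]
        Z = Z[keep] if Z is not None else None
        X = X[keep]
    vclass = classification["vclass"].to_numpy()
    poly = vclass != "monomorphic"

    resid = residualize(y, X[:, poly], Z, covariate_names=list(covariates or []))
    y_res = resid.y_res
    # map original variant index -> column in the residualized polymorphic block
    col_of = -np.ones(X.shape[1], dtype=int)
    col_of[np.flatnonzero(poly)] = np.arange(int(poly.sum()))

    records, drops = [], []
    for gene_id in sorted(gene_map):
        idx = np.asarray(gene_map[gene_id])
        idx_poly = idx[poly[idx]] if idx.size else idx
        if idx_poly.size == 0:
            drops.append({"gene_id": gene_id,
                          "reason": "no polymorphic variants" if idx.size else "no variants"})
            continue
        rare_idx = idx_poly[vclass[idx_poly] == "rare"]
        common_idx = idx_poly[vclass[idx_poly] == "common"]
        rng = np.random.default_rng(gene_seed(seed, gene_id))
        Xr = resid.X_res[:, col_of[rare_idx]]
        Xc = resid.X_res[:, col_of[common_idx]]

        def record_tow(Xs: np.ndarray, kind: str) -> None:
            r = tow_permutation_p(y_res, Xs, B=B, rng=rng, gene_id=gene_id)
            records.append({
                "gene_id": gene_id, "kind": kind,
                "statistic": r.statistic, "p": r.p,
                "n_rare": int(rare_idx.size), "n_common": int(common_idx.size),
            })

        try:
            if rare_idx.size and common_idx.size:
                try:
                    r = vw_tow(y_res, Xr, Xc, B=B, lambda_grid=lambda_grid,
                               rng=rng, gene_id=gene_id)
                    records.append({
                        "gene_id": gene_id, "kind": "VW-TOW",
                        "statistic": r.min_p_observed, "p": r.p,
                        "n_rare": r.n_rare, "n_common": r.n_common,
                    })
                except DegenerateVarianceError as exc:
                    # fall back to the class whose statistic still varies
                    drops.append({"gene_id": gene_id,
                                  "reason": "degenerate permutation variance; "
                                            "fell back to single-class TOW"})
                    if exc.var_rare > 0:
                        record_tow(Xr, "TOW-rare-only")
                    elif exc.var_common > 0:
                        record_tow(Xc, "TOW-common-only")
                    else:
                        drops.append({"gene_id": gene_id,
                                      "reason": "both class statistics degenerate"})
            elif rare_idx.size:
                record_tow(Xr, "TOW-rare-only")
            else:
                record_tow(Xc, "TOW-common-only")
        except ValueError as exc:
            drops.append({"gene_id": gene_id, "reason": str(exc)})
    scores = pd.DataFrame(records, columns=["gene_id", "kind", "statistic", "p",
                                            "n_rare", "n_common"])
    drop_log = pd.DataFrame(drops, columns=["gene_id", "reason"])
    log.info("scored %d genes for %s (%d dropped)", len(scores), phenotype, len(drop_log))
    return scores, drop_log
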