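"""Partial least squares correlation between two variable blocks.

The model is the SVD of the p x q cross-covariance of column-centered
(and by default unit-variance-scaled) blocks: paired singular vectors
(loadings) maximize the covariance between block projections.
Inference: per-component permutation p-values (row-shuffling one
block), bootstrap ratios for block-X loadings and percentile CIs for
block-Y loadings, plus subject-level scores and their (cross-validated)
rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from brainaging.prep import fdr_bh, residualize

__all__ = [
    "PLSModel",
    "PermutationResult",
    "BootstrapResult",
    "fit_pls",
    "permutation_test",
    "bootstrap_stability",
    "score_correlation",
    "crossval_score_correlation",
    "per_marker_regressions",
]


@dataclass
class PLSModel:
    """Fitted PLS correlation solution.

    ``U`` (p x L) and ``V`` (q x L) are unit-norm singular vectors;
    ``covariance_explained`` is ``s_l^2 / sum s^2``.  Scores are the
    projections of the preprocessed blocks onto the loadings.
    """

    U: np.ndarray
    V: np.ndarray
    singular_values: np.ndarray
    covariance_explained: np.ndarray
    imaging_scores: np.ndarray
    clinical_scores: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    sign_convention: str = "first_x_positive"
    x_names: list[str] | None = None
    y_names: list[str] | None = None

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def transform(self, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project new rows using the training preprocessing and loadings."""
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_scale
        Ys = (np.asarray(Y, float) - self.y_mean) / self.y_scale
        return Xs @ self.U, Ys @ self.V


@dataclass
class PermutationResult:
    singular_values: np.ndarray
    null_mean: np.ndarray
    null_p95: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    n_permutations: int


@dataclass
class BootstrapResult:
    bootstrap_ratios: np.ndarray  # p x L
    clinical_ci_lo: np.ndarray  # q x L
    clinical_ci_hi: np.ndarray  # q x L
    n_bootstrap: int
    n_resampled: int = 0
    x_significant: np.ndarray = field(init=False)
    y_significant: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.x_significant = np.abs(self.bootstrap_ratios) > 1.96
        self.y_significant = (self.clinical_ci_lo > 0) | (self.clinical_ci_hi < 0)


def _preprocess(M: np.ndarray, scale: bool, names=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    M = np.asarray(M, float)
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=0)
    # relative tolerance: a column constant up to float roundoff is constant
    flat = sd <= 1e-12 * np.maximum(np.abs(mean), 1.0)
    if np.any(flat):
        bad = np.flatnonzero(flat)
        labels = [names[j] if names else f"col{j}" for j in bad]
        raise ValueError(f"constant column(s): {labels}")
    scl = sd if scale else np.ones_like(sd)
    return (M - mean) / scl, mean, scl


def _cross_cov(Xs: np.ndarray, Ys: np.ndarray) -> np.ndarray:
    return Xs.T @ Ys / (len(Xs) - 1)


def _svd_lv(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    return U, s, Vt.T


def _apply_sign(U: np.ndarray, V: np.ndarray, anchor: int = 0) -> tuple[np.ndarray, np.ndarray]:
    # orient each component so the anchor X-variable loads positively;
    # fall back to the largest-|u| entry when the anchor loading is ~0
    U, V = U.copy(), V.copy()
    for l in range(U.shape[1]):
        ref = U[anchor, l]
        if abs(ref) < 1e-12:
            ref = U[np.argmax(np.abs(U[:, l])), l]
        if ref < 0:
            U[:, l] *= -1
            V[:, l] *= -1
    return U, V


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    scale: bool = True,
    sign_anchor: int = 0,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> PLSModel:
    """SVD of the cross-covariance of the centered (scaled) blocks.

    With unit-variance scaling (the default, matching the pipeline's
    z-scored residual inputs) covariance and correlation coincide.
    Returns all ``L = min(p, q)`` components with scores ``X @ U`` and
    ``Y @ V``; each component is oriented so the ``sign_anchor``-th
    X-variable loads positively.
    """
    Xs, x_mean, x_scale = _preprocess(X, scale, x_names)
    Ys, y_mean, y_scale = _preprocess(Y, scale, y_names)
    if len(Xs) != len(Ys):
        raise ValueError("X and Y must have the same number of rows")
    if len(Xs) <= max(Xs.shape[1], Ys.shape[1]):
        raise ValueError("need n > max(p, q)")
    U, s, V = _svd_lv(_cross_cov(Xs, Ys))
    U, V = _apply_sign(U, V, sign_anchor)
    total = float(np.sum(s**2))
    return PLSModel(
        U=U,
        V=V,
        singular_values=s,
        covariance_explained=s**2 / total if total > 0 else np.zeros_like(s),
        imaging_scores=Xs @ U,
        clinical_scores=Ys @ V,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        x_names=x_names,
        y_names=y_names,
    )


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 5000,
    seed: int | None = 0,
    scale: bool = True,
    rotate: bool = False,
) -> PermutationResult:
    """Permutation significance of each latent variable.

    Each permutation row-shuffles the X block only (breaking the
    subject pairing), refits the SVD and records same-index singular
    values; ``p_l = (1 + #{s_perm >= s_emp}) / (1 + n_perm)``, then
    FDR-adjusted across components.  ``rotate=True`` instead measures
    permuted singular values in the original clinical singular basis
    (column norms of ``R_perm @ V0``), aligning components across
    permutations.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse p-value resolution", stacklevel=2)
    rng = np.random.default_rng(seed)
    Xs, *_ = _preprocess(X, scale)
    Ys, *_ = _preprocess(Y, scale)
    _, s_emp, V0 = _svd_lv(_cross_cov(Xs, Ys))
    L = len(s_emp)
    null = np.empty((n_perm, L))
    for b in range(n_perm):
        Xp = Xs[rng.permutation(len(Xs))]
        Rp = _cross_cov(Xp, Ys)
        if rotate:
            null[b] = np.linalg.norm(Rp @ V0, axis=0)[:L]
        else:
            null[b] = np.linalg.svd(Rp, compute_uv=False)[:L]
    exceed = (null >= s_emp[None, :]).sum(axis=0)
    p_raw = (1.0 + exceed) / (1.0 + n_perm)
    return PermutationResult(
        singular_values=s_emp,
        null_mean=null.mean(axis=0),
        null_p95=np.percentile(null, 95, axis=0),
        p_raw=p_raw,
        p_fdr=fdr_bh(p_raw),
        n_permutations=n_perm,
    )


def bootstrap_stability(
    X: np.ndarray,
    Y: np.ndarray,
    n_boot: int = 5000,
    seed: int | None = 0,
    scale: bool = True,
) -> BootstrapResult:
    """Bootstrap stability of the loadings.

    Subjects are resampled with replacement (paired rows); each
    bootstrap solution is aligned to the original by a per-component
    sign flip maximizing congruence with the original singular
    vectors.  Reports ``BSR = original X-loading / bootstrap SE`` and
    percentile 95% CIs for the Y-loadings.  Replicates that produce a
    constant column are redrawn (count logged).
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(seed)
    model = fit_pls(X, Y, scale=scale)
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, L = len(X), model.n_components
    boot_U = np.empty((n_boot, *model.U.shape))
    boot_V = np.empty((n_boot, *model.V.shape))
    n_resampled = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        Xb, Yb = X[idx], Y[idx]
        if np.any(Xb.std(axis=0) == 0) or np.any(Yb.std(axis=0) == 0):
            n_resampled += 1
            continue
        Xbs, *_ = _preprocess(Xb, scale)
        Ybs, *_ = _preprocess(Yb, scale)
        Ub, _, Vb = _svd_lv(_cross_cov(Xbs, Ybs))
        # per-component sign alignment to the original solution
        flip = np.sign(
            np.einsum("pl,pl->l", Ub[:, :L], model.U) + np.einsum("ql,ql->l", Vb[:, :L], model.V)
        )
        flip[flip == 0] = 1.0
        boot_U[b] = Ub[:, :L] * flip
        boot_V[b] = Vb[:, :L] * flip
        b += 1
    se_U = boot_U.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(se_U > 0, model.U / se_U, np.inf * np.sign(model.U))
    ci_lo = np.percentile(boot_V, 2.5, axis=0)
    ci_hi = np.percentile(boot_V, 97.5, axis=0)
    return BootstrapResult(
        bootstrap_ratios=bsr,
        clinical_ci_lo=ci_lo,
        clinical_ci_hi=ci_hi,
        n_bootstrap=n_boot,
        n_resampled=n_resampled,
    )


def score_correlation(model: PLSModel, lv: int = 0, method: str = "spearman") -> float:
    """Rank (or Pearson) correlation of paired subject scores for one LV."""
    if not 0 <= lv < model.n_components:
        raise IndexError(f"lv {lv} out of range (0..{model.n_components - 1})")
    x = model.imaging_scores[:, lv]
    y = model.clinical_scores[:, lv]
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def crossval_score_correlation(
    X: np.ndarray,
    Y: np.ndarray,
    k: int = 10,
    seed: int | None = 0,
    lv: int = 0,
    scale: bool = True,
) -> float:
    """Mean out-of-fold Spearman correlation of held-out LV scores.

    For each fold, PLS is fit on the training rows (training
    preprocessing) and the held-out rows are projected with the
    training loadings.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    rs = []
    for train, test in kf.split(X):
        model = fit_pls(X[train], Y[train], scale=scale)
        xs, ys = model.transform(X[test], Y[test])
        rs.append(stats.spearmanr(xs[:, lv], ys[:, lv]).statistic)
    return float(np.mean(rs))


def per_marker_regressions(
    markers: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """One adjusted OLS per (marker, outcome) pair with standardized betas.

    Marker and outcome are z-scored; covariates enter unstandardized
    alongside an intercept.  p-values are FDR-adjusted across the full
    marker x outcome grid.
    """
    import statsmodels.api as sm

    cov = None if covariates is None else np.asarray(covariates, float)
    rows = []
    for marker in markers.columns:
        x = stats.zscore(markers[marker].to_numpy(float))
        for outcome in clinical.columns:
            y = stats.zscore(clinical[outcome].to_numpy(float))
            design = x[:, None] if cov is None else np.column_stack([x, cov])
            fit = sm.OLS(y, sm.add_constant(design)).fit()
            rows.append(
                {
                    "marker": marker,
                    "outcome": outcome,
                    "beta": float(fit.params[1]),
                    "se": float(fit.bse[1]),
                    "p_raw": float(fit.pvalues[1]),
                }
            )
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_bh(table["p_raw"].to_numpy())
    return table


def deconfound_blocks(
    X: np.ndarray, Y: np.ndarray, confounds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residualize both blocks against the shared confound matrix."""
    return residualize(X, confounds), residualize(Y, confounds)
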