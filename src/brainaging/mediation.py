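"""Single-mediator mediation with covariate adjustment and bootstrap CIs.

Decomposes the total effect ``c`` of an exposure on an outcome into a
direct effect ``c'`` and an indirect effect ``ab`` through one
mediator, via three same-sample OLS fits:

* ``m ~ x + covariates``       -> a
* ``y ~ x + m + covariates``   -> b, c'
* ``y ~ x + covariates``       -> c

For linear models fit on the same sample, ``c = c' + a*b`` holds as an
algebraic identity.  The indirect effect's CI and p-value come from a
percentile bootstrap over subject resamples; inputs are z-scored by
default so all paths are standardized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from brainaging.prep import fdr_bh, zscore

PATH_FAMILIES = ("a", "b", "c", "c_prime", "ab")


@dataclass
class MediationResult:
    """Standardized paths, bootstrap CI for the indirect effect, p-values."""

    risk_factor: str
    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    ab_ci: tuple[float, float]
    se: dict[str, float]
    p_raw: dict[str, float]
    p_fdr: dict[str, float] = field(default_factory=dict)
    n_boot: int = 0
    proportion_mediated: float | None = None
    proportion_mediated_stable: bool = True
    classification: str = "none"

    def significant(self, path: str, alpha: float = 0.05) -> bool:
        p = self.p_fdr.get(path, self.p_raw[path])
        return p < alpha


def proportion_mediated(ab: float, c: float) -> float:
    """Indirect share of the total effect, in percent: ``100 * ab / c``."""
    if c == 0:
        raise ZeroDivisionError("total effect c is zero")
    return 100.0 * ab / c


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and their classical SEs for one OLS fit."""
    n, k = design.shape
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < k:
        raise ValueError("degenerate design matrix in mediation fit")
    resid = y - design @ coef
    sigma2 = resid @ resid / (n - k)
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return coef, np.sqrt(np.diag(cov))


def _ols_p(coef: float, se: float, dof: int) -> float:
    return float(2 * stats.t.sf(abs(coef) / se, dof))


def _batched_coef(design: np.ndarray, y: np.ndarray, idx: np.ndarray, col: np.ndarray):
    """OLS coefficients for many bootstrap resamples at once.

    ``idx`` is (n_boot, n); solves the normal equations per replicate
    and returns the coefficients for the requested columns.
    """
    Db = design[idx]  # (B, n, k)
    yb = y[idx]  # (B, n)
    G = np.einsum("bni,bnj->bij", Db, Db)
    h = np.einsum("bni,bn->bi", Db, yb)
    coefs = np.linalg.solve(G, h[..., None])[..., 0]
    return coefs[:, col]


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 5000,
    seed: int | None = 0,
    zscore_inputs: bool = True,
    name: str = "x",
    alpha: float = 0.05,
) -> MediationResult:
    """Fit the three-model mediation and bootstrap the indirect effect.

    The ``ab`` CI is the 2.5/97.5 percentile interval of ``a*b`` over
    seeded subject resamples; its p-value is ``2 * min(P(ab* <= 0),
    P(ab* >= 0))`` clipped to ``[2/n_boot, 1]``.  The a, b, c, c' paths
    carry classical OLS t-test p-values.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable CIs", stacklevel=2)
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    if zscore_inputs:
        x, m, y = zscore(x), zscore(m), zscore(y)
    n = len(x)
    cov = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    if cov.ndim == 1:
        cov = cov[:, None]
    ones = np.ones((n, 1))

    design_m = np.column_stack([ones, x, cov])  # m ~ x + cov
    design_y2 = np.column_stack([ones, x, m, cov])  # y ~ x + m + cov
    design_y1 = np.column_stack([ones, x, cov])  # y ~ x + cov

    coef_a, se_a = _ols(design_m, m)
    coef_f, se_f = _ols(design_y2, y)
    coef_t, se_t = _ols(design_y1, y)
    a, b, c_prime, c = coef_a[1], coef_f[2], coef_f[1], coef_t[1]
    ab = a * b

    se = {
        "a": float(se_a[1]),
        "b": float(se_f[2]),
        "c_prime": float(se_f[1]),
        "c": float(se_t[1]),
    }
    p_raw = {
        "a": _ols_p(a, se_a[1], n - design_m.shape[1]),
        "b": _ols_p(b, se_f[2], n - design_y2.shape[1]),
        "c_prime": _ols_p(c_prime, se_f[1], n - design_y2.shape[1]),
        "c": _ols_p(c, se_t[1], n - design_y1.shape[1]),
    }

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_a = _batched_coef(design_m, m, idx, 1)
    boot_b = _batched_coef(design_y2, y, idx, 2)
    boot_ab = boot_a * boot_b
    ci = (float(np.percentile(boot_ab, 2.5)), float(np.percentile(boot_ab, 97.5)))
    frac_le = np.mean(boot_ab <= 0)
    frac_ge = np.mean(boot_ab >= 0)
    p_ab = float(np.clip(2 * min(frac_le, frac_ge), 2.0 / n_boot, 1.0))
    p_raw["ab"] = p_ab
    se["ab"] = float(boot_ab.std(ddof=1))

    c_se = se["c"]
    stable = abs(c) > 10 * c_se
    prop = proportion_mediated(ab, c) if c != 0 else None

    result = MediationResult(
        risk_factor=name,
        a=float(a),
        b=float(b),
        c=float(c),
        c_prime=float(c_prime),
        ab=float(ab),
        ab_ci=ci,
        se=se,
        p_raw=p_raw,
        n_boot=n_boot,
        proportion_mediated=prop,
        proportion_mediated_stable=stable,
    )
    result.classification = classify(result, alpha=alpha)
    return result


def classify(result: MediationResult, alpha: float = 0.05) -> str:
    """Partial/full/none per the attenuation rule.

    Mediation requires a, b and ab all significant; it is *full* when
    the direct effect c' loses significance and *partial* when c' stays
    significant but is attenuated relative to the total effect.
    """
    sig = lambda path: result.significant(path, alpha)  # noqa: E731
    if not (sig("a") and sig("b") and sig("ab")):
        return "none"
    if not sig("c_prime"):
        return "full"
    if abs(result.c_prime) < abs(result.c):
        return "partial"
    return "none"


def run_mediation_suite(
    risk: pd.DataFrame,
    imaging_score: np.ndarray,
    clinical_score: np.ndarray,
    covariates: np.ndarray | None = None,
    risk_factors: list[str] | None = None,
    n_boot: int = 5000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> list[MediationResult]:
    """One mediation model per risk factor, FDR-corrected per path family.

    p-values are adjusted across risk factors separately within each
    effect family (all a's together, all b's together, ...), then each
    result is (re)classified with the adjusted values.
    """
    factors = risk_factors if risk_factors is not None else list(risk.columns)
    results = []
    rng = np.random.default_rng(seed)
    for factor in factors:
        if factor not in risk.columns:
            warnings.warn(f"risk factor {factor!r} missing, skipped", stacklevel=2)
            continue
        results.append(
            mediate(
                risk[factor].to_numpy(float),
                imaging_score,
                clinical_score,
                covariates=covariates,
                n_boot=n_boot,
                seed=int(rng.integers(0, 2**31 - 1)),
                name=factor,
                alpha=alpha,
            )
        )
    for family in PATH_FAMILIES:
        adj = fdr_bh([r.p_raw[family] for r in results])
        for r, p in zip(results, adj):
            r.p_fdr[family] = float(p)
    for r in results:
        r.classification = classify(r, alpha=alpha)
    return results


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    """Tabular summary: one row per risk factor with all paths and p-values."""
    rows = []
    for r in results:
        row = {
            "risk_factor": r.risk_factor,
            "a": r.a,
            "b": r.b,
            "ab": r.ab,
            "ab_ci_lo": r.ab_ci[0],
            "ab_ci_hi": r.ab_ci[1],
            "c": r.c,
            "c_prime": r.c_prime,
            "proportion_mediated_pct": r.proportion_mediated,
            "proportion_mediated_stable": r.proportion_mediated_stable,
            "classification": r.classification,
        }
        for family in PATH_FAMILIES:
            row[f"p_raw_{family}"] = r.p_raw[family]
            row[f"p_fdr_{family}"] = r.p_fdr.get(family, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
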