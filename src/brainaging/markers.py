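"""Brain-aging markers: relative brain age, log WMH load, PSMD.

Relative brain age is the two-stage, bias-corrected brain-age gap:
chronological age is predicted from region-level morphometry with
sex-stratified 5-fold out-of-fold OLS, an expected age is then fitted
per stratum as the OLS of predicted on chronological age, and the
marker is the difference ``predicted - expected`` — orthogonal to
chronological age within each stratum by construction.  The same
two-stage pipeline applied to a single marker (log WMH load or PSMD)
yields the gap-variant markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import KFold

from brainaging.cohort import CohortTable


@dataclass
class BrainAgeResult:
    """Out-of-fold brain-age predictions and the derived relative brain age."""

    predicted_age: np.ndarray
    expected_age: np.ndarray
    relative_brain_age: np.ndarray
    fold_id: np.ndarray
    sex_stratum: np.ndarray
    cv_metrics: dict[str, dict[str, float]] = field(default_factory=dict)
    expected_age_coefficients: dict[str, tuple[float, float]] = field(default_factory=dict)


class CollinearityError(ValueError):
    """Feature matrix is rank deficient."""


def _check_rank(X: np.ndarray, names: list[str] | None) -> None:
    Xc = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # QR with pivoting: columns pivoted beyond the numerical rank
        _, _, piv = qr(Xc, pivoting=True, mode="economic")
        bad = sorted(piv[rank:] - 1)  # drop intercept offset
        labels = [names[j] if names and 0 <= j < len(names) else f"col{j}" for j in bad]
        raise CollinearityError(f"rank-deficient feature matrix; collinear columns: {labels}")


def fit_predict_age(
    features: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    n_folds: int = 5,
    seed: int | None = 0,
    feature_names: list[str] | None = None,
    ridge: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Sex-stratified out-of-fold OLS age prediction.

    Within each sex stratum, subjects are partitioned into ``n_folds``
    seeded random folds; each subject's predicted age comes from the
    least-squares model (with intercept) fit on the remaining folds.

    Returns the out-of-fold predicted-age vector plus diagnostics
    (per-stratum MAE / out-of-fold R^2 and fold assignments).

    A rank-deficient feature matrix raises :class:`CollinearityError`
    naming the collinear columns; pass ``ridge > 0`` to fall back to a
    (logged) minimally regularized fit instead.
    """
    features = np.asarray(features, float)
    if features.ndim == 1:
        features = features[:, None]
    age = np.asarray(age, float)
    sex = np.asarray(sex)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")

    predicted = np.full(len(age), np.nan)
    fold_id = np.full(len(age), -1, dtype=int)
    metrics: dict[str, dict[str, float]] = {}
    for stratum in np.unique(sex):
        idx = np.flatnonzero(sex == stratum)
        Xs, ys = features[idx], age[idx]
        if len(idx) <= features.shape[1] + 1:
            raise ValueError(
                f"stratum {stratum!r}: need n > n_features + 1 ({len(idx)} subjects, "
                f"{features.shape[1]} features)"
            )
        if ridge > 0:
            scale = ridge * np.trace(Xs.T @ Xs) / max(Xs.shape[1], 1)
            warnings.warn(f"using ridge fallback (alpha={scale:.3g})", stacklevel=2)
            model_factory = lambda: Ridge(alpha=scale)  # noqa: E731
        else:
            _check_rank(Xs, feature_names)
            model_factory = LinearRegression
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fold, (train, test) in enumerate(kf.split(Xs)):
            model = model_factory().fit(Xs[train], ys[train])
            predicted[idx[test]] = model.predict(Xs[test])
            fold_id[idx[test]] = fold
        resid = ys - predicted[idx]
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((ys - ys.mean()) ** 2))
        metrics[str(stratum)] = {
            "n": int(len(idx)),
            "mae": float(np.mean(np.abs(resid))),
            "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        }
    return predicted, {"metrics": metrics, "fold_id": fold_id}


def relative_brain_age(
    predicted_age: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Second-stage bias correction: ``predicted - expected`` per sex stratum.

    Expected age is the per-stratum OLS of predicted on chronological
    age, fit on the pooled out-of-fold predictions; the result is
    orthogonal to chronological age within each stratum.
    """
    predicted_age = np.asarray(predicted_age, float)
    age = np.asarray(age, float)
    sex = np.asarray(sex)
    strata = np.unique(sex)
    if len(strata) == 1:
        warnings.warn("single sex level present; fitting one stratum", stacklevel=2)
    rba = np.full(len(age), np.nan)
    coefs: dict[str, tuple[float, float]] = {}
    for stratum in strata:
        idx = sex == stratum
        if idx.sum() < 3:
            raise ValueError(f"stratum {stratum!r}: need >= 3 subjects")
        slope, intercept = np.polyfit(age[idx], predicted_age[idx], 1)
        expected = intercept + slope * age[idx]
        rba[idx] = predicted_age[idx] - expected
        coefs[str(stratum)] = (float(intercept), float(slope))
    return rba, coefs


def compute_wmh_load(
    wmh_volume: np.ndarray, icv: np.ndarray, floor: float = 1e-3
) -> np.ndarray:
    """Natural log of WMH volume as a percentage of intracranial volume.

    ``load% = 100 * wmh / icv``; a configurable floor (default 1e-3 %)
    is added before the log so zero-WMH subjects stay finite.
    """
    wmh_volume = np.asarray(wmh_volume, float)
    icv = np.asarray(icv, float)
    if np.any(icv <= 0):
        raise ValueError("icv must be > 0")
    if np.any(wmh_volume < 0):
        raise ValueError("wmh_volume must be >= 0")
    load_pct = 100.0 * wmh_volume / icv
    if np.any(load_pct == 0):
        warnings.warn("zero WMH volume present; floored before log", stacklevel=2)
    return np.log(load_pct + floor)


def compute_psmd(md_values: np.ndarray) -> float | np.ndarray:
    """Peak width of skeletonized MD: p95 - p5 of the voxel values.

    Percentiles use linear interpolation between order statistics.
    Accepts a vector (one subject) or an ``(n, voxels)`` matrix.
    """
    md_values = np.asarray(md_values, float)
    if not np.all(np.isfinite(md_values)):
        raise ValueError("md values must be finite")
    n_vox = md_values.shape[-1]
    if n_vox < 20:
        raise ValueError(f"need >= 20 MD values for stable percentiles, got {n_vox}")
    p5, p95 = np.percentile(md_values, [5, 95], axis=-1, method="linear")
    return p95 - p5


def marker_gap(
    marker: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    n_folds: int = 5,
    seed: int | None = 0,
) -> np.ndarray:
    """Gap variant of a scalar marker via the two-stage brain-age pipeline.

    Runs the identical CV age prediction (single feature) followed by
    the expected-age regression; used to derive WMH brain age and
    microstructural brain age.
    """
    predicted, _ = fit_predict_age(
        np.asarray(marker, float)[:, None], age, sex, n_folds=n_folds, seed=seed
    )
    gap, _ = relative_brain_age(predicted, age, sex)
    return gap


def compute_marker_panel(
    cohort: CohortTable,
    n_folds: int = 5,
    seed: int | None = 0,
    gap_variants: bool = False,
    wmh_floor: float = 1e-3,
) -> tuple[pd.DataFrame, BrainAgeResult]:
    """All three markers (plus optional gap variants) for one cohort.

    Returns a panel keyed by ``subject_id`` with columns
    ``relative_brain_age``, ``log_wmh_load``, ``psmd`` and, when
    requested, ``wmh_brain_age`` / ``microstructural_brain_age``.
    """
    df = cohort.data
    age = df["age"].to_numpy(float)
    sex = df["sex"].to_numpy()

    predicted, diag = fit_predict_age(
        cohort.morphometry_matrix(),
        age,
        sex,
        n_folds=n_folds,
        seed=seed,
        feature_names=list(cohort.morphometry),
    )
    rba, coefs = relative_brain_age(predicted, age, sex)
    result = BrainAgeResult(
        predicted_age=predicted,
        expected_age=predicted - rba,
        relative_brain_age=rba,
        fold_id=diag["fold_id"],
        sex_stratum=sex,
        cv_metrics=diag["metrics"],
        expected_age_coefficients=coefs,
    )

    log_wmh = compute_wmh_load(
        df["wmh_volume"].to_numpy(float), df["icv"].to_numpy(float), floor=wmh_floor
    )
    if cohort.md_value_columns:
        psmd = compute_psmd(cohort.md_matrix())
    else:
        psmd = df["psmd"].to_numpy(float)

    panel = pd.DataFrame(
        {
            "subject_id": df["subject_id"].to_numpy(),
            "relative_brain_age": rba,
            "log_wmh_load": log_wmh,
            "psmd": psmd,
        }
    )
    if gap_variants:
        panel["wmh_brain_age"] = marker_gap(log_wmh, age, sex, n_folds=n_folds, seed=seed)
        panel["microstructural_brain_age"] = marker_gap(
            psmd, age, sex, n_folds=n_folds, seed=seed
        )
    return panel, result
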