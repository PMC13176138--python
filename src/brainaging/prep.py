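"""Clinical score harmonization and shared statistics utilities.

Raw cognitive tests are transformed (timed tests inverted and
log-transformed so higher is always better), z-scored within the
analysis sample and averaged into domain scores; grip strength is
normalized by squared height.  Also provides column-wise confound
residualization and step-up Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRANSFORMS = ("identity", "invert_log")


@dataclass
class DomainMap:
    """Test -> cognitive-domain assignment and per-test transform tags."""

    domains: dict[str, str]
    transforms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for test, tag in self.transforms.items():
            if tag not in TRANSFORMS:
                raise ValueError(f"unknown transform {tag!r} for test {test!r}")
        for test in self.transforms:
            if test not in self.domains:
                raise ValueError(f"transform declared for unmapped test {test!r}")

    def transform_for(self, test: str) -> str:
        return self.transforms.get(test, "identity")


#: Editable default domain assignments for the two cohort dialects.
UKB_DOMAIN_MAP = DomainMap(
    domains={
        "numeric_memory": "memory",
        "paired_associate": "memory",
        "tmt_b": "executive_function",
        "tower_rearranging": "executive_function",
        "tmt_a": "processing_speed",
        "reaction_time": "processing_speed",
        "symbol_digit": "processing_speed",
        "fluid_intelligence": "reasoning",
        "matrix_completion": "reasoning",
    },
    transforms={"tmt_a": "invert_log", "tmt_b": "invert_log", "reaction_time": "invert_log"},
)

HCHS_DOMAIN_MAP = DomainMap(
    domains={
        "word_list_recall": "memory",
        "tmt_b": "executive_function",
        "animal_naming": "executive_function",
        "tmt_a": "processing_speed",
        "vocabulary": "reasoning",
    },
    transforms={"tmt_a": "invert_log", "tmt_b": "invert_log"},
)


def invert_log_transform(raw):
    """``-ln(raw)``: invert-and-log for timed scores (higher = better)."""
    raw = np.asarray(raw, float)
    if np.any(raw <= 0):
        raise ValueError("invert_log_transform requires strictly positive values")
    return -np.log(raw)


def zscore(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Center and scale to unit variance within the analysis sample."""
    values = np.asarray(values, float)
    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("cannot z-score a constant column")
    return (values - mean) / sd


def build_domain_scores(
    tests: pd.DataFrame, domain_map: DomainMap, rescale: bool = False
) -> pd.DataFrame:
    """Transform, z-score and average raw tests into domain scores.

    Per test: apply its declared transform, z-score within the sample,
    then average available tests within each domain (requiring at least
    one non-missing test per subject).  Domain scores are not re-z-scored
    unless ``rescale`` is set.
    """
    available = [t for t in domain_map.domains if t in tests.columns]
    missing = [t for t in domain_map.domains if t not in tests.columns]
    if missing:
        warnings.warn(f"tests not present, skipped: {missing}", stacklevel=2)
    z_cols = {}
    for test in available:
        vals = tests[test].to_numpy(float)
        if domain_map.transform_for(test) == "invert_log":
            vals = invert_log_transform(vals)
        z_cols[test] = zscore(vals)
    domains = sorted({domain_map.domains[t] for t in available})
    out = {}
    for domain in domains:
        members = [t for t in available if domain_map.domains[t] == domain]
        stacked = np.column_stack([z_cols[t] for t in members])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[domain] = np.nanmean(stacked, axis=1)
    result = pd.DataFrame(out, index=tests.index)
    if rescale:
        result = result.apply(zscore)
    return result


def normalize_grip(left, right, height):
    """Mean grip strength divided by squared height (kg / m^2)."""
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    height = np.asarray(height, float)
    if np.any(height <= 0):
        raise ValueError("height must be > 0")
    if np.any(left < 0) or np.any(right < 0):
        raise ValueError("grip strength must be >= 0")
    return (left + right) / 2.0 / height**2


def residualize(values: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Column-wise OLS residuals against the confound matrix (+ intercept).

    Each residual column has mean 0 and zero correlation with every
    confound column.
    """
    values = np.asarray(values, float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    confounds = np.asarray(confounds, float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    design = np.column_stack([np.ones(len(confounds)), confounds])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient confound matrix")
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ beta
    return resid[:, 0] if squeeze else resid


def fdr_bh(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values.

    ``p_(i) * m / i`` with enforced monotonicity from the largest rank
    down, clipped at 1; adjusted values never fall below the raw ones.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0, 1)
    return out
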