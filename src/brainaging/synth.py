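"""Synthetic population-cohort generator with planted effects.

Generates wide cohort tables whose marginals match published
population moments and which carry, by construction, (a) a single
latent brain-aging deviation ``delta`` (years) coupling the imaging
markers to cognitive-motor performance and (b) risk -> delta ->
performance mediation paths.  The realized latents are returned as a
:class:`GroundTruth` so downstream stages can be tested as
parameter-recovery problems.

Generative model (in order):

1. ``age ~ TruncNormal(mean, sd, [45, 80])``; ``sex ~ Bernoulli``;
   education ordinal from a declared categorical distribution.
2. Risk factors from moment-matched normals; pack-years and
   triglycerides log-normal to respect non-negativity.
3. ``delta_i = sum_k a_k * z(risk_k) + eps``, ``eps ~ N(0, delta_sd)``
   — ``a_k`` in years per risk-factor SD.
4. Morphometric feature f: ``x_f = mu_f - slope_f * (age_i + delta_i)
   + noise``.
5. ``log WMH%`` and a PSMD target linear in ``age + delta`` plus
   marker noise; MD voxel values drawn so their p95 - p5 equals the
   PSMD target in expectation.
6. Behavioral latent ``eta_i = -b * z(delta) + sum_k c_prime_k *
   z(risk_k) - s_age * z(age) + eps_eta``; each raw test is a loading
   on ``eta`` mapped to its native scale (timed tests via the
   exponential inverse of the -log harmonization transform).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from brainaging.cohort import RISK_FACTORS, CohortTable

# z(p95) - z(p5) for a standard normal; MD voxel sd is chosen so the
# per-subject percentile width hits the PSMD target in expectation.
_NORMAL_P95_P5 = 2 * stats.norm.ppf(0.95)

#: Published population moments used as marginal defaults (mean, sd).
DEFAULT_MOMENTS: dict[str, tuple[float, float]] = {
    "age": (63.7, 7.6),
    "bp_systolic": (138.6, 18.6),
    "bp_diastolic": (78.7, 10.0),
    "cholesterol_total": (5.7, 1.1),
    "cholesterol_ldl": (3.6, 0.8),
    "cholesterol_hdl": (1.5, 0.4),
    "triglycerides": (1.6, 1.0),
    "glucose": (5.0, 1.0),
    "waist_hip_ratio": (0.9, 0.1),
    "pack_years": (18.8, 15.7),
    "height": (1.7, 0.09),
    "icv": (1500.0, 130.0),
}

_LOGNORMAL_FACTORS = ("pack_years", "triglycerides")

# P(education level = 1..6): mean 4.52, sd 1.29 (ISCED-like ordinal).
_EDUCATION_PROBS = (0.02, 0.07, 0.13, 0.18, 0.35, 0.25)

# (mean, sd, loading on the behavioral latent, transform tag)
# "timed" tests are generated in -log space and exponentiated back, so
# larger raw values mean worse performance.
UKB_TESTS: dict[str, tuple[float, float, float, str]] = {
    "numeric_memory": (6.79, 1.3, 0.45, "identity"),
    "tmt_a": (22.45, 8.1, 0.50, "timed"),
    "tmt_b": (57.13, 25.7, 0.55, "timed"),
    "matrix_completion": (8.03, 2.1, 0.45, "identity"),
    "fluid_intelligence": (6.66, 2.1, 0.45, "identity"),
    "reaction_time": (0.59, 0.1, 0.50, "timed"),
    "paired_associate": (6.98, 2.6, 0.45, "identity"),
    "tower_rearranging": (9.97, 3.2, 0.50, "identity"),
    "symbol_digit": (19.06, 5.2, 0.55, "identity"),
    "accelerometry": (28.5, 7.8, 0.40, "identity"),
}

_DEFAULT_A = {
    "bp_systolic": 0.7,
    "bp_diastolic": 0.6,
    "cholesterol_total": 0.0,
    "cholesterol_ldl": 0.0,
    "cholesterol_hdl": 0.0,
    "triglycerides": 0.5,
    "glucose": 0.6,
    "waist_hip_ratio": 0.8,
    "pack_years": 0.7,
}

_DEFAULT_C_PRIME = {
    "bp_systolic": -0.05,
    "bp_diastolic": -0.06,
    "cholesterol_total": 0.0,
    "cholesterol_ldl": 0.0,
    "cholesterol_hdl": 0.08,
    "triglycerides": -0.08,
    "glucose": -0.04,
    "waist_hip_ratio": -0.12,
    "pack_years": -0.08,
}


@dataclass
class SyntheticConfig:
    """Knobs of the generative model; defaults plant a recoverable signal."""

    n_subjects: int = 2000
    seed: int = 0
    moments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOMENTS)
    )
    p_female: float = 0.502
    education_probs: tuple[float, ...] = _EDUCATION_PROBS
    n_cortical_features: int = 68
    n_subcortical_features: int = 16
    #: mm of thickness lost per year of (age + delta)
    cortical_slope: float = 0.004
    cortical_noise: float = 0.10
    #: mm^3 of volume lost per year of (age + delta)
    subcortical_slope: float = 8.0
    subcortical_noise: float = 300.0
    delta_sd: float = 3.0
    #: years of brain-aging deviation per SD of each risk factor
    a_k: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_A))
    b: float = 0.35
    c_prime_k: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_C_PRIME))
    s_age: float = 0.30
    #: log WMH%% slope per year of (age + delta) and residual SD
    wmh_slope: float = 0.035
    wmh_noise: float = 0.28
    #: PSMD slope per year of (age + delta) in mm^2/s, and residual SD
    psmd_slope: float = 2.2e-6
    psmd_noise: float = 1.6e-5
    md_voxels_per_subject: int = 0
    behavior_noise: float = 1.0
    grip_loading: float = 0.40

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name, (_, sd) in self.moments.items():
            if sd <= 0:
                raise ValueError(f"SD for {name!r} must be > 0")
        if self.delta_sd <= 0 or self.behavior_noise <= 0:
            raise ValueError("noise SDs must be > 0")
        for coefs in (self.a_k, self.b, self.c_prime_k, self.s_age):
            if not np.all(np.isfinite(list(coefs.values()) if isinstance(coefs, dict) else [coefs])):
                raise ValueError("effect sizes must be finite")
        if abs(sum(self.education_probs) - 1) > 1e-9:
            raise ValueError("education_probs must sum to 1")

    def to_dict(self) -> dict[str, Any]:
        out = {}
        for key, val in self.__dict__.items():
            if isinstance(val, dict):
                out[key] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in val.items()}
            elif isinstance(val, tuple):
                out[key] = list(val)
            else:
                out[key] = val
        return out


@dataclass
class GroundTruth:
    """Realized latents, aligned row-for-row with the generated cohort."""

    delta: np.ndarray
    eta: np.ndarray
    a_k: dict[str, float]
    b: float
    c_prime_k: dict[str, float]
    psmd_target: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"delta": self.delta, "eta": self.eta}
        if self.psmd_target is not None:
            cols["psmd_target"] = self.psmd_target
        return pd.DataFrame(cols)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def generate_cohort(config: SyntheticConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort and its ground truth; identical config+seed → identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    mom = config.moments

    # (1) demographics
    age_mu, age_sd = mom["age"]
    lo, hi = (45 - age_mu) / age_sd, (80 - age_mu) / age_sd
    age = stats.truncnorm.rvs(lo, hi, loc=age_mu, scale=age_sd, size=n, random_state=rng)
    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    education = rng.choice(
        np.arange(1, len(config.education_probs) + 1), size=n, p=config.education_probs
    ).astype(float)

    # (2) risk factors
    risk = {}
    for name in RISK_FACTORS:
        mean, sd = mom[name]
        if name in _LOGNORMAL_FACTORS:
            mu, sigma = _lognormal_params(mean, sd)
            risk[name] = rng.lognormal(mu, sigma, size=n)
        else:
            risk[name] = rng.normal(mean, sd, size=n)
    risk_z = {k: _zscore(v) for k, v in risk.items()}

    # (3) latent brain-aging deviation (years)
    delta = rng.normal(0.0, config.delta_sd, size=n)
    for name, a in config.a_k.items():
        delta = delta + a * risk_z[name]
    brain_age = age + delta

    # (4) morphometry
    morph = {}
    for j in range(config.n_cortical_features):
        mu_f = 2.0 + 1.0 * (j / max(config.n_cortical_features - 1, 1))
        morph[f"morph_ct_{j:03d}"] = (
            mu_f
            - config.cortical_slope * brain_age
            + rng.normal(0, config.cortical_noise, size=n)
        )
    for j in range(config.n_subcortical_features):
        mu_f = 3000.0 + 400.0 * j
        morph[f"morph_vol_{j:03d}"] = (
            mu_f
            - config.subcortical_slope * brain_age
            + rng.normal(0, config.subcortical_noise, size=n)
        )

    # (5) white-matter markers
    icv = rng.normal(*mom["icv"], size=n).clip(min=1000.0)
    log_wmh_pct = (
        np.log(0.29)
        + config.wmh_slope * (brain_age - age_mu)
        + rng.normal(0, config.wmh_noise, size=n)
    )
    wmh_volume = np.exp(log_wmh_pct) / 100.0 * icv
    psmd_target = (
        2.29e-4
        + config.psmd_slope * (brain_age - age_mu)
        + rng.normal(0, config.psmd_noise, size=n)
    ).clip(min=1e-5)

    md_cols: dict[str, np.ndarray] = {}
    if config.md_voxels_per_subject > 0:
        voxel_sd = psmd_target / _NORMAL_P95_P5
        voxels = rng.normal(
            7e-4, voxel_sd[:, None], size=(n, config.md_voxels_per_subject)
        )
        md_cols = {
            f"md_{j:05d}": voxels[:, j] for j in range(config.md_voxels_per_subject)
        }

    # (6) behavior
    eta = (
        -config.b * _zscore(delta)
        - config.s_age * _zscore(age)
        + rng.normal(0, config.behavior_noise, size=n)
    )
    for name, c in config.c_prime_k.items():
        eta = eta + c * risk_z[name]
    eta_z = _zscore(eta)

    tests = {}
    for name, (mean, sd, loading, kind) in UKB_TESTS.items():
        std = loading * eta_z + np.sqrt(1 - loading**2) * rng.standard_normal(n)
        if kind == "timed":
            # generate in -log(seconds) space (higher = better), map back
            t_mean, t_sd = -np.log(mean), sd / mean
            tests[name] = np.exp(-(t_mean + t_sd * std))
        else:
            tests[name] = mean + sd * std

    height = rng.normal(*mom["height"], size=n).clip(min=1.4)
    grip_mu, grip_sd = 30.3, 10.3
    grip_std = config.grip_loading * eta_z + np.sqrt(
        1 - config.grip_loading**2
    ) * rng.standard_normal(n)
    grip_mean = (grip_mu + grip_sd * grip_std).clip(min=1.0)
    grip_split = rng.normal(0, 1.5, size=n)
    tests["grip_left"] = (grip_mean - grip_split).clip(min=0.0)
    tests["grip_right"] = (grip_mean + grip_split).clip(min=0.0)

    frame = {
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "education": education,
        **risk,
        "height": height,
        "icv": icv,
        "wmh_volume": wmh_volume,
        **morph,
        **tests,
        **md_cols,
    }
    if not md_cols:
        frame["psmd"] = psmd_target
    cohort = CohortTable(
        pd.DataFrame(frame),
        morphometry=list(morph),
        md_value_columns=list(md_cols),
        test_columns=list(tests),
    )
    truth = GroundTruth(
        delta=delta,
        eta=eta,
        a_k=dict(config.a_k),
        b=config.b,
        c_prime_k=dict(config.c_prime_k),
        psmd_target=psmd_target,
    )
    return cohort, truth


def make_null_pair(
    n: int, p: int, q: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent standard-normal matrices (zero population cross-covariance)."""
    if n <= max(p, q):
        raise ValueError("need n > max(p, q)")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, p)), rng.standard_normal((n, q))
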