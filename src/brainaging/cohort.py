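"""Cohort data model, tabular I/O and subject-exclusion rules.

A cohort is a wide per-subject table: demographics, vascular risk
factors, region-level morphometry, white-matter markers and raw
clinical test scores.  Files are plain CSV/TSV (UTF-8, header row,
``.`` decimal); sex is stored as the labels ``female``/``male`` and
encoded 0 = female, 1 = male for modeling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RISK_FACTORS = [
    "bp_systolic",
    "bp_diastolic",
    "cholesterol_total",
    "cholesterol_hdl",
    "cholesterol_ldl",
    "triglycerides",
    "glucose",
    "waist_hip_ratio",
    "pack_years",
]

#: Columns every cohort table must carry.  Morphometry, MD values /
#: PSMD and clinical tests are declared per-table, not hard-coded.
MANDATORY_COLUMNS = ["subject_id", "age", "sex", "education", "wmh_volume", "icv"]

SEX_LEVELS = ("female", "male")


class SchemaError(ValueError):
    """A mandatory column is missing or mis-declared."""


class CohortParseError(ValueError):
    """A numeric column contains an unparseable value."""


@dataclass
class CohortTable:
    """Validated per-subject wide table plus column-role metadata.

    Parameters
    ----------
    data:
        The underlying table, one row per subject.
    morphometry:
        Ordered names of region-level morphometric feature columns
        (cortical thickness, subcortical volumes).
    md_value_columns:
        Columns holding the per-subject skeletonized-MD voxel sample,
        empty if a precomputed ``psmd`` column is present instead.
    test_columns:
        Raw cognitive/motor test score columns.
    """

    data: pd.DataFrame
    morphometry: list[str] = field(default_factory=list)
    md_value_columns: list[str] = field(default_factory=list)
    test_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        df = self.data
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"mandatory column missing: {col!r}")
        for cols, role in [
            (self.morphometry, "morphometry"),
            (self.md_value_columns, "md_value"),
            (self.test_columns, "test"),
        ]:
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"declared {role} columns missing: {missing}")
        if not self.md_value_columns and "psmd" not in df.columns:
            raise SchemaError(
                "cohort must carry either md_value_columns or a precomputed 'psmd' column"
            )
        if len(df):
            if (df["age"] <= 0).any():
                raise ValueError("age must be > 0")
            if (df["icv"] <= 0).any():
                raise ValueError("icv must be > 0")
            if (df["wmh_volume"] < 0).any():
                raise ValueError("wmh_volume must be >= 0")
            bad_sex = set(df["sex"].unique()) - set(SEX_LEVELS)
            if bad_sex:
                raise ValueError(f"sex must be one of {SEX_LEVELS}, got {sorted(bad_sex)}")

    # -- convenience ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> pd.Series:
        return self.data["subject_id"]

    def sex_codes(self) -> np.ndarray:
        """0 = female, 1 = male."""
        return (self.data["sex"].to_numpy() == "male").astype(int)

    def morphometry_matrix(self) -> np.ndarray:
        return self.data[self.morphometry].to_numpy(float)

    def md_matrix(self) -> np.ndarray:
        if not self.md_value_columns:
            raise ValueError("cohort carries precomputed psmd, no raw MD values")
        return self.data[self.md_value_columns].to_numpy(float)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(
            self.data.loc[mask].reset_index(drop=True),
            morphometry=list(self.morphometry),
            md_value_columns=list(self.md_value_columns),
            test_columns=list(self.test_columns),
        )


@dataclass
class ExclusionReport:
    """Bookkeeping for one pass of subject exclusion."""

    n_input: int
    n_excluded_by_rule: dict[str, int]
    n_retained: int
    excluded_ids: list[str]

    def __post_init__(self) -> None:
        if self.n_input < 0 or self.n_retained < 0:
            raise ValueError("counts must be non-negative")
        if self.n_retained != self.n_input - len(set(self.excluded_ids)):
            raise ValueError("retained count does not reconcile with excluded ids")

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_input": self.n_input,
                "n_excluded_by_rule": self.n_excluded_by_rule,
                "n_excluded": self.n_excluded,
                "n_retained": self.n_retained,
                "excluded_ids": list(self.excluded_ids),
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


@dataclass
class ExclusionRule:
    """One exclusion rule.

    ``kind='sd_outlier'`` drops subjects whose value on ``column`` lies
    more than ``k`` full-sample standard deviations from the full-sample
    mean.  ``kind='flag'`` drops subjects where the boolean ``column``
    is true (generic hook for cohort-specific metadata such as illness
    codes).
    """

    name: str
    column: str
    kind: str = "sd_outlier"
    k: float = 3.0

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        if self.column not in df.columns:
            raise KeyError(f"exclusion rule {self.name!r}: column {self.column!r} not in cohort")
        if self.kind == "sd_outlier":
            return exclude_outliers(df[self.column].to_numpy(float), k=self.k)
        if self.kind == "flag":
            return ~df[self.column].astype(bool).to_numpy()
        raise ValueError(f"unknown rule kind {self.kind!r}")


def exclude_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Keep-mask that is false where ``|x - mean| > k * sd``.

    Mean and SD are computed once on the full input vector (single
    pass, no iterative re-screening).  A constant vector keeps all
    entries with a warning.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("cannot screen an empty vector")
    if values.size < 2:
        raise ValueError("need at least 2 values to estimate an SD")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("constant vector: SD is 0, keeping all subjects", stacklevel=2)
        return np.ones(values.shape, dtype=bool)
    return np.abs(values - values.mean()) <= k * sd


def apply_exclusions(
    cohort: CohortTable, rules: list[ExclusionRule]
) -> tuple[CohortTable, ExclusionReport]:
    """Apply exclusion rules in order, each on the original sample.

    Per-rule masks are computed from the *input* cohort's statistics
    (one removal step, not sequential re-screening); subjects failing
    any rule are removed and the union is reported.
    """
    df = cohort.data
    keep = np.ones(len(df), dtype=bool)
    per_rule: dict[str, int] = {}
    for rule in rules:
        rule_keep = rule.mask(df)
        per_rule[rule.name] = int((~rule_keep).sum())
        keep &= rule_keep
    excluded_ids = df.loc[~keep, "subject_id"].astype(str).tolist()
    report = ExclusionReport(
        n_input=len(df),
        n_excluded_by_rule=per_rule,
        n_retained=int(keep.sum()),
        excluded_ids=excluded_ids,
    )
    return cohort.subset(keep), report


def _detect_sep(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cohort(
    path,
    schema: dict[str, str] | None = None,
    morphometry_prefix: str = "morph_",
    md_prefix: str = "md_",
    test_columns: list[str] | None = None,
) -> CohortTable:
    """Read a cohort CSV/TSV.

    ``schema`` maps canonical column names to the file's column names
    (``{"icv": "EstimatedTotalIntraCranialVol"}``); unmapped extra
    columns are preserved as passthrough.  Morphometry and MD-value
    columns are recognized by prefix.
    """
    df = pd.read_csv(path, sep=_detect_sep(path))
    if schema:
        rename = {src: dst for dst, src in schema.items() if src in df.columns}
        missing = [dst for dst, src in schema.items() if src not in df.columns]
        if missing:
            raise SchemaError(f"schema maps absent columns: {missing}")
        df = df.rename(columns=rename)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column missing: {col!r}")
    morph = [c for c in df.columns if c.startswith(morphometry_prefix)]
    md_cols = [c for c in df.columns if c.startswith(md_prefix)]
    numeric = [c for c in df.columns if c not in ("subject_id", "sex")]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[bad.isna() & df[col].notna()].tolist()
            raise CohortParseError(
                f"non-numeric value in column {col!r} at row(s) {rows[:5]}"
            ) from exc
    # complete-case on mandatory imaging fields, logged via warning
    mand_numeric = [c for c in MANDATORY_COLUMNS if c not in ("subject_id", "sex")]
    incomplete = df[mand_numeric].isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"dropping {int(incomplete.sum())} rows with missing mandatory fields",
            stacklevel=2,
        )
        df = df.loc[~incomplete].reset_index(drop=True)
    df["subject_id"] = df["subject_id"].astype(str)
    return CohortTable(
        df,
        morphometry=morph,
        md_value_columns=md_cols,
        test_columns=test_columns or [],
    )


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, sep=_detect_sep(path), index=False)
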