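"""Patient-record data model, CSV serialization, validation, and the
clinical-benefit endpoint.

A cohort is an ordered :class:`pandas.DataFrame` with one row per patient and
the fixed column schema below.  Clinical benefit (CB) is a *derived* endpoint:
a patient has CB iff neither death nor disease progression occurred between
diagnosis and last follow-up.  It is recomputed from the ``death`` and
``progression`` flags whenever a cohort is loaded; a stored ``cb`` column is
cross-checked, never trusted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA",
    "CATEGORICAL_LEVELS",
    "Violation",
    "CohortValidationError",
    "derive_cb",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
]

#: column -> kind ("str", "float", "int", "cat")
SCHEMA: dict[str, str] = {
    "patient_id": "str",
    "age": "float",
    "bmi": "float",
    "blood_glucose": "float",
    "injected_activity": "float",
    "dlp": "float",
    "site": "cat",
    "quadrant": "cat",
    "histology": "cat",
    "ki67": "float",
    "subtype": "cat",
    "t_stage": "int",
    "n_stage": "int",
    "m_stage": "int",
    "pt_volume": "float",
    "suv_max": "float",
    "suv_mean": "float",
    "mtv": "float",
    "tlg": "float",
    "margin": "cat",
    "morphology": "cat",
    "scanner": "str",
    "follow_up": "float",
    "os": "float",
    "pfs": "float",
    "death": "int",
    "progression": "int",
}

CATEGORICAL_LEVELS: dict[str, list] = {
    "site": ["right", "left"],
    "quadrant": [
        "central",
        "upper-inner",
        "lower-inner",
        "upper-outer",
        "lower-outer",
        "unspecified",
    ],
    "histology": ["ductal", "lobular", "papillary", "mucinous", "apocrine"],
    "subtype": ["A", "B", "H", "N"],
    "t_stage": [1, 2, 3, 4],
    "n_stage": [0, 1, 2, 3],
    "m_stage": [0, 1],
    "margin": ["sharp", "irregular", "spiculated"],
    "morphology": ["solid", "inflammatory"],
    "death": [0, 1],
    "progression": [0, 1],
}

#: PET semiquantitative primary-tumor features (scanner-comparability checks)
SEMIQUANTITATIVE = ["suv_max", "suv_mean", "mtv", "tlg", "pt_volume"]

_TOL = 1e-9


@dataclass(frozen=True)
class Violation:
    """One validation failure: which record, which field, which rule."""

    record: str  # patient_id, or "<cohort>" for cohort-level rules
    field: str
    rule: str
    message: str


class CohortValidationError(ValueError):
    """Raised when a cohort fails schema or invariant validation."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        lines = [f"{v.record} / {v.field}: {v.message}" for v in violations[:20]]
        if len(violations) > 20:
            lines.append(f"... and {len(violations) - 20} more")
        super().__init__(
            f"cohort validation failed with {len(violations)} violation(s):\n"
            + "\n".join(lines)
        )


def derive_cb(death, progression):
    """Clinical benefit: no death and no progression up to last follow-up.

    Accepts scalars or arrays of 0/1 flags; returns int 0/1 of the same shape.
    """
    death = np.asarray(death)
    progression = np.asarray(progression)
    if death.shape != progression.shape:
        raise ValueError("death and progression must have the same shape")
    for name, arr in (("death", death), ("progression", progression)):
        vals = np.unique(arr[~pd.isna(arr)]) if arr.size else np.array([])
        if pd.isna(arr).any():
            raise CohortValidationError(
                [Violation("<cohort>", name, "missing-flag", f"{name} contains missing values")]
            )
        if not np.isin(vals, [0, 1]).all():
            raise ValueError(f"{name} must be binary 0/1, got values {vals}")
    cb = ((death == 0) & (progression == 0)).astype(int)
    return cb if cb.ndim else int(cb)


def _check_record_invariants(df: pd.DataFrame) -> list[Violation]:
    out: list[Violation] = []

    def add(mask, field, rule, fmt):
        for pid in df.loc[np.asarray(mask, dtype=bool), "patient_id"]:
            out.append(Violation(str(pid), field, rule, fmt))

    for col in ["pt_volume", "mtv", "tlg", "suv_max", "suv_mean"]:
        add(df[col] < -_TOL, col, "non-negative", f"{col} must be >= 0")
    add(df["suv_mean"] > df["suv_max"] + _TOL, "suv_mean", "suv_mean<=suv_max",
        "suv_mean exceeds suv_max")
    add((df["ki67"] < -_TOL) | (df["ki67"] > 100 + _TOL), "ki67", "range",
        "ki67 must lie in [0, 100]")
    add(df["pfs"] > df["os"] + _TOL, "pfs", "pfs<=os", "pfs exceeds os")
    add(df["os"] > df["follow_up"] + _TOL, "os", "os<=follow_up",
        "os exceeds follow-up")
    for col, levels in CATEGORICAL_LEVELS.items():
        bad = ~df[col].isin(levels)
        add(bad, col, "enumeration",
            f"value outside allowed levels {levels}")
    return out


def validate_cohort(df: pd.DataFrame) -> list[Violation]:
    """Return every invariant violation in the cohort (empty list = valid).

    Violations are data, not exceptions: callers decide whether to raise.
    """
    out: list[Violation] = []
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        return [
            Violation("<cohort>", c, "missing-column", f"required column {c!r} absent")
            for c in missing
        ]
    if len(df) == 0:
        return [Violation("<cohort>", "<cohort>", "non-empty", "cohort is empty")]
    dup = df["patient_id"].duplicated()
    if dup.any():
        dups = sorted(set(df.loc[dup, "patient_id"].astype(str)))
        out.append(
            Violation("<cohort>", "patient_id", "unique",
                      f"duplicate patient_id(s): {dups}")
        )
    out.extend(_check_record_invariants(df))
    if "cb" in df.columns:
        expected = derive_cb(df["death"].to_numpy(), df["progression"].to_numpy())
        bad = df["cb"].to_numpy() != expected
        for pid in df.loc[bad, "patient_id"]:
            out.append(
                Violation(str(pid), "cb", "cb-derivation",
                          "stored cb disagrees with (not death and not progression)")
            )
    return out


def attach_cb(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the derived ``cb`` column (recomputed, never trusted)."""
    df = df.copy()
    df["cb"] = derive_cb(df["death"].to_numpy(), df["progression"].to_numpy())
    return df


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises :class:`CohortValidationError`.

    The returned frame carries the derived ``cb`` column and a provenance note
    in ``df.attrs``.
    """
    raw = pd.read_csv(path, dtype={"patient_id": str, "scanner": str})
    missing = [c for c in SCHEMA if c not in raw.columns]
    if missing:
        raise CohortValidationError(
            [Violation("<cohort>", c, "missing-column",
                       f"required column {c!r} absent") for c in missing]
        )
    violations: list[Violation] = []
    for col, kind in SCHEMA.items():
        if kind in ("float", "int"):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            for pid in raw.loc[bad, "patient_id"]:
                violations.append(
                    Violation(str(pid), col, "parse", f"unparseable value in {col}")
                )
            if coerced.isna().any() and not bad.any():
                for pid in raw.loc[coerced.isna(), "patient_id"]:
                    violations.append(
                        Violation(str(pid), col, "missing", f"missing value in {col}")
                    )
            raw[col] = coerced.astype(float if kind == "float" else "Int64")
    if violations:
        raise CohortValidationError(violations)
    for col, kind in SCHEMA.items():
        if kind == "int":
            raw[col] = raw[col].astype(int)
    violations = validate_cohort(raw)
    if violations:
        raise CohortValidationError(violations)
    df = attach_cb(raw)
    df.attrs["provenance"] = f"file:{path}"
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV (12 significant digits; includes the derived cb)."""
    out = attach_cb(df)
    cols = list(SCHEMA) + ["cb"]
    out[cols].to_csv(path, index=False, float_format="%.12g")


def violations_to_json(violations: list[Violation], path=None) -> str:
    doc = json.dumps([asdict(v) for v in violations], indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(doc)
    return doc
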