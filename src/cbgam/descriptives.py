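"""Descriptive-statistics machinery: CB vs no-CB group comparisons,
categorical distribution tests, the scanner-comparability ANOVA, and
publication-style summary tables.

Continuous variables are compared with Welch's t-test (unequal variances),
categorical distributions with Pearson's chi-squared test without continuity
correction, and scanner influence on the PET semiquantitative features with
one-way ANOVA.  Percentages are rounded half away from zero to one decimal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CATEGORICAL_LEVELS, SEMIQUANTITATIVE, attach_cb

__all__ = [
    "welch_t_test",
    "chi_squared_test",
    "scanner_anova",
    "build_descriptives",
    "percentages_from_counts",
    "load_count_fixture",
    "round_half_away",
    "DescriptivesReport",
]

CONTINUOUS_VARS = [
    "age", "bmi", "blood_glucose", "injected_activity", "dlp",
    "pt_volume", "suv_max", "suv_mean", "mtv", "tlg", "ki67",
    "follow_up", "os", "pfs",
]
CATEGORICAL_VARS = [
    "site", "quadrant", "histology", "subtype",
    "t_stage", "n_stage", "m_stage", "margin", "morphology", "death",
]

ALPHA = 0.05


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (68.75 -> 68.8, -2.5 -> -2.5 at 0 digits -3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def welch_t_test(x, y) -> tuple[float, float]:
    """Two-sided Welch t-test; returns (statistic, p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("both groups are degenerate (zero variance)")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def chi_squared_test(table) -> tuple[float, int, float]:
    """Pearson chi-squared without continuity correction.

    ``table`` is an r x c array of counts (rows: categories, columns:
    groups).  Returns (statistic, dof, p-value).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be >= 0")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin")
    expected = stats.contingency.expected_freq(t)
    if (expected < 5).any():
        warnings.warn(
            "chi-squared approximation: some expected cell counts < 5",
            stacklevel=2,
        )
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(dof), float(p)


def scanner_anova(df: pd.DataFrame, variables=None) -> pd.DataFrame:
    """One-way ANOVA of each PET semiquantitative feature across scanners."""
    variables = list(variables) if variables is not None else list(SEMIQUANTITATIVE)
    groups = {k: g for k, g in df.groupby("scanner")}
    if len(groups) < 2:
        raise ValueError("need >= 2 scanner groups")
    if any(len(g) < 2 for g in groups.values()):
        raise ValueError("each scanner group needs n >= 2")
    rows = []
    for var in variables:
        samples = [g[var].to_numpy(dtype=float) for g in groups.values()]
        f, p = stats.f_oneway(*samples)
        rows.append({"variable": var, "F": float(f), "p_value": float(p)})
    return pd.DataFrame(rows)


@dataclass
class DescriptivesReport:
    """Publication-style summary: continuous and categorical tables."""

    continuous: pd.DataFrame   # variable, mean/sd for all/cb/no_cb, t, p
    categorical: pd.DataFrame  # variable, category, counts & percentages, chi2 p
    n_all: int
    n_cb: int
    n_no_cb: int
    warnings: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {
                "n": {"all": self.n_all, "cb": self.n_cb, "no_cb": self.n_no_cb},
                "continuous": self.continuous.to_dict(orient="records"),
                "categorical": self.categorical.to_dict(orient="records"),
                "warnings": self.warnings,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    def to_csv(self, continuous_path, categorical_path) -> None:
        self.continuous.to_csv(continuous_path, index=False)
        self.categorical.to_csv(categorical_path, index=False)


def build_descriptives(df: pd.DataFrame) -> DescriptivesReport:
    """Cohort summary with All / CB / no-CB columns and group-difference tests."""
    if "cb" not in df.columns:
        df = attach_cb(df)
    cb_mask = df["cb"] == 1
    g_cb, g_no = df[cb_mask], df[~cb_mask]
    report_warnings: list[str] = []
    if len(g_cb) == 0 or len(g_no) == 0:
        report_warnings.append("one CB group is empty; group tests skipped")

    cont_rows = []
    for var in CONTINUOUS_VARS:
        row = {"variable": var}
        for label, g in (("all", df), ("cb", g_cb), ("no_cb", g_no)):
            row[f"mean_{label}"] = float(g[var].mean()) if len(g) else np.nan
            row[f"sd_{label}"] = float(g[var].std(ddof=1)) if len(g) > 1 else np.nan
        try:
            t, p = welch_t_test(g_cb[var], g_no[var])
        except ValueError as exc:
            t, p = np.nan, np.nan
            report_warnings.append(f"{var}: t-test skipped ({exc})")
        row["t_statistic"], row["p_value"] = t, p
        cont_rows.append(row)

    cat_rows = []
    for var in CATEGORICAL_VARS:
        levels = CATEGORICAL_LEVELS.get(var, sorted(df[var].unique()))
        counts = {
            label: g[var].value_counts().reindex(levels).fillna(0).astype(int)
            for label, g in (("all", df), ("cb", g_cb), ("no_cb", g_no))
        }
        observed = [lv for lv in levels if counts["all"][lv] > 0]
        p_chi = np.nan
        if len(observed) >= 2 and len(g_cb) and len(g_no) and var != "death":
            tab = np.array(
                [[counts["cb"][lv], counts["no_cb"][lv]] for lv in observed]
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                _, _, p_chi = chi_squared_test(tab)
                for w in caught:
                    report_warnings.append(f"{var}: {w.message}")
        elif var == "death" and len(g_cb) and len(g_no):
            tab = np.array(
                [[counts["cb"][lv], counts["no_cb"][lv]] for lv in [0, 1]]
            )
            if (tab.sum(axis=1) > 0).all():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, _, p_chi = chi_squared_test(tab)
        for lv in levels:
            row = {"variable": var, "category": str(lv)}
            for label in ("all", "cb", "no_cb"):
                n_grp = {"all": len(df), "cb": len(g_cb), "no_cb": len(g_no)}[label]
                c = int(counts[label][lv])
                row[f"count_{label}"] = c
                row[f"pct_{label}"] = (
                    round_half_away(100.0 * c / n_grp) if n_grp else np.nan
                )
            row["p_value"] = p_chi
            cat_rows.append(row)

    return DescriptivesReport(
        continuous=pd.DataFrame(cont_rows),
        categorical=pd.DataFrame(cat_rows),
        n_all=len(df),
        n_cb=int(cb_mask.sum()),
        n_no_cb=int((~cb_mask).sum()),
        warnings=report_warnings,
    )


def percentages_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """One-decimal percentages from a variable/category count table.

    Expects columns ``variable, category, all, cb, no_cb``; percentages are
    taken within each column's own total per variable.
    """
    out = counts.copy()
    for col in ("all", "cb", "no_cb"):
        pct = []
        for _, grp in counts.groupby("variable", sort=False):
            total = grp[col].sum()
            pct.extend(
                round_half_away(100.0 * c / total) if total else np.nan
                for c in grp[col]
            )
        out[f"pct_{col}"] = pct
    return out


def load_count_fixture() -> pd.DataFrame:
    """Packaged categorical count table of the published 70-patient cohort."""
    with resources.files("cbgam.data").joinpath("table2_counts.csv").open() as fh:
        return pd.read_csv(fh)
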