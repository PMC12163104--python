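"""Angle-table summaries and the two-way mixed-effects (split-plot) ANOVA.

The design has one within-subject factor (side: left/right) and two
between-subject factors (sex, hip dysplasia) with side x sex and
side x dysplasia interactions and no between-factor interaction. The
split-plot decomposition is computed on two orthogonal strata:

* between-subject stratum: ordinary Type-II F tests of sex and dysplasia in
  an additive linear model on the subject side-averages;
* within-subject stratum: on the side differences (right - left), the
  intercept of a sum-coded additive model tests the side main effect and
  Type-II F tests of the factors test the side x factor interactions.

For a balanced two-level within factor these are the classical exact F
tests. Subjects missing one side are excluded (with a recorded count),
mirroring how incomplete angle measurements are handled in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ANGLE_NAMES

__all__ = ["AnovaResult", "summarize_angles", "mixed_anova"]

ANOVA_TERMS = ("sex", "dysplasia", "side", "side_sex", "side_dysplasia")


@dataclass
class AnovaResult:
    """Per-term F statistics, degrees of freedom and p-values."""

    terms: dict = field(default_factory=dict)  # term -> {"F", "df1", "df2", "p"}
    n_subjects: int = 0
    n_excluded: int = 0

    def p(self, term: str) -> float:
        return self.terms[term]["p"]

    def F(self, term: str) -> float:
        return self.terms[term]["F"]


def summarize_angles(table: pd.DataFrame) -> pd.DataFrame:
    """Summary statistics (mean, sd; n-1 convention) per angle, total and by
    sex, combining left and right sides. Empty groups yield missing values."""
    angles = [a for a in ANGLE_NAMES if a in table.columns]
    if not angles:
        raise ValueError(f"table has none of the angle columns {ANGLE_NAMES}")
    rows = {}
    groups = {"total": table}
    if "sex" in table.columns:
        groups["male"] = table[table["sex"] == "M"]
        groups["female"] = table[table["sex"] == "F"]
    for angle in angles:
        row = {}
        for gname, g in groups.items():
            vals = g[angle].dropna()
            row[f"{gname}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{gname}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[f"{gname}_n"] = len(vals)
        rows[angle.upper()] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def _nested_f(y: np.ndarray, X_full: np.ndarray, drop: int):
    """Type-II F test of one column of an additive linear model."""
    n, p = X_full.shape
    rss_full = float(np.sum((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2))
    X_red = np.delete(X_full, drop, axis=1)
    rss_red = float(np.sum((y - X_red @ np.linalg.lstsq(X_red, y, rcond=None)[0]) ** 2))
    df2 = n - p
    if df2 <= 0:
        raise ValueError("not enough subjects for the requested model")
    F = max(0.0, (rss_red - rss_full)) / (rss_full / df2)
    return F, 1, df2, float(sps.f.sf(F, 1, df2))


def mixed_anova(
    table: pd.DataFrame,
    value: str = "value",
    dysplasia_coding: str = "either",
    between: tuple = ("sex", "dysplasia"),
) -> AnovaResult:
    """Two-way mixed ANOVA of one angle from a long table.

    ``table`` needs columns subject_id, side ('L'/'R'), the ``between``
    factor columns (by default sex 'F'/'M' and per-hip boolean dysplasia)
    and the ``value`` column. Dysplasia is coded per subject for the
    between-subject term: dysplastic if ``either`` hip is (default) or only
    if ``both`` are.

    Every subject must contribute both sides; incomplete subjects are
    excluded and counted in ``n_excluded``.
    """
    if dysplasia_coding not in ("either", "both"):
        raise ValueError(f"dysplasia_coding must be 'either' or 'both', got {dysplasia_coding!r}")
    req = {"subject_id", "side", value, *between}
    if not req <= set(table.columns):
        raise ValueError(f"table missing columns {sorted(req - set(table.columns))}")

    df = table.dropna(subset=[value])
    wide = df.pivot_table(index="subject_id", columns="side", values=value, aggfunc="first")
    complete = wide.dropna(subset=["L", "R"]).index if {"L", "R"} <= set(wide.columns) else wide.index[:0]
    n_total = wide.shape[0]
    n = len(complete)
    if n < 4:
        raise ValueError(f"need at least 4 complete subjects, got {n}")

    meta = df.drop_duplicates("subject_id").set_index("subject_id")
    sub = complete
    m = ((wide.loc[sub, "L"] + wide.loc[sub, "R"]) / 2.0).to_numpy(float)
    d = (wide.loc[sub, "R"] - wide.loc[sub, "L"]).to_numpy(float)

    columns = {}
    for name in between:
        if name == "dysplasia":
            agg = any if dysplasia_coding == "either" else all
            per_subj = df.groupby("subject_id")["dysplasia"].agg(
                lambda v: agg(bool(x) for x in v)
            )
            x = np.where(per_subj.loc[sub].to_numpy(), 1.0, -1.0)
        else:
            levels = meta.loc[sub, name].to_numpy()
            uniq = np.unique(levels)
            if uniq.size != 2:
                raise ValueError(f"between-subject factor {name!r} must have 2 levels, has {uniq.size}")
            x = np.where(levels == uniq[0], 1.0, -1.0)
        if np.unique(x).size < 2:
            raise ValueError(f"between-subject factor {name!r} has a single level")
        columns[name] = x

    X = np.column_stack([np.ones(n)] + [columns[name] for name in between])
    terms = {}
    # between-subject stratum: side-averages
    for col, name in enumerate(between, start=1):
        F, df1, df2, p = _nested_f(m, X, col)
        terms[name] = {"F": F, "df1": df1, "df2": df2, "p": p}
    # within-subject stratum: side differences
    F, df1, df2, p = _nested_f(d, X, 0)  # sum-coded intercept = side main effect
    terms["side"] = {"F": F, "df1": df1, "df2": df2, "p": p}
    for col, name in enumerate(between, start=1):
        F, df1, df2, p = _nested_f(d, X, col)
        terms[f"side_{name}"] = {"F": F, "df1": df1, "df2": df2, "p": p}

    return AnovaResult(terms=terms, n_subjects=n, n_excluded=n_total - n)
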