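"""Summary statistics and test conventions for the derived tables.

Measurements are kept in long format — one value per (embryo, genotype, age,
rudiment, compartment, quantity) — and summarised as mean +- sample SD with
group size ``n``.  Comparisons use two-sided Student's t-tests: paired when
the BrdU-exposure conditions match (littermates, tissues within a specimen),
unpaired otherwise; differences among the five rudiments are tested with
one-way ANOVA.  Significance is marked with an asterisk at p < 0.05, and no
multiple-testing correction is applied — the convention these tables follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from mamrud.errors import ValidationError

__all__ = [
    "MEASUREMENT_COLUMNS",
    "make_table",
    "summarize",
    "fold_change",
    "group_ratio_means",
    "CompareResult",
    "compare",
    "anova_across_rudiments",
    "render_markdown",
    "load_printed_volume_table",
    "load_printed_ratio_table",
]


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("mamrud.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_printed_volume_table() -> pd.DataFrame:
    """Bundled per-rudiment mean volumes (x1e4 um^3) by embryonic age."""
    return _load_csv("table1_volumes.csv")


def load_printed_ratio_table() -> pd.DataFrame:
    """Bundled per-rudiment ectoderm/MR labelling-fraction fold ratios."""
    return _load_csv("table2_ratios.csv")

MEASUREMENT_COLUMNS = ["embryo", "genotype", "age", "rudiment", "compartment", "quantity", "value"]

ALPHA = 0.05


def make_table(records) -> pd.DataFrame:
    """Validate and assemble a long-format measurement table."""
    table = pd.DataFrame(records)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing columns {missing}", field="records")
    keys = [c for c in MEASUREMENT_COLUMNS if c != "value"]
    if table.duplicated(subset=keys).any():
        raise ValidationError("duplicate (embryo, rudiment, compartment, quantity) records", field="records")
    return table[MEASUREMENT_COLUMNS]


def summarize(table: pd.DataFrame, by) -> pd.DataFrame:
    """Mean +- sample SD and n per group (``by`` = grouping column names)."""
    if len(table) == 0:
        raise ValidationError("empty table", field="table")
    grouped = table.groupby(list(by))["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
    return out.reset_index()


def fold_change(summary: pd.DataFrame, by: str, numerator, denominator, value_col: str = "mean") -> pd.DataFrame:
    """Ratio of group means between two levels of ``by`` (e.g. two ages).

    Returns one row per remaining grouping with the ``fold`` column
    ``mean[numerator] / mean[denominator]`` — the day-to-day volume growth
    folds of a rudiment, for example.
    """
    rest = [c for c in summary.columns if c not in (by, value_col, "sd", "n")]
    num = summary[summary[by] == numerator].set_index(rest)[value_col]
    den = summary[summary[by] == denominator].set_index(rest)[value_col]
    common = num.index.intersection(den.index)
    out = (num.loc[common] / den.loc[common]).rename("fold").reset_index()
    out.insert(len(rest), "comparison", f"{numerator}/{denominator}")
    return out


def group_ratio_means(ratios: pd.DataFrame, by: str = "age", value_col: str = "ect_over_mr_ratio") -> pd.Series:
    """Mean of per-rudiment ratios per group (e.g. mean ectoderm/MR fold)."""
    return ratios.groupby(by)[value_col].mean()


@dataclass(frozen=True)
class CompareResult:
    statistic: float
    p_value: float
    paired: bool
    significant: bool

    @property
    def mark(self) -> str:
        return "*" if self.significant else ""


def compare(a, b, paired: bool = False, equal_var: bool = True) -> CompareResult:
    """Two-sided Student's t-test between two samples.

    ``paired=True`` requires equal-length matched samples (same BrdU
    exposure conditions); otherwise an independent two-sample test is used,
    with classic equal-variance pooling by default (``equal_var=False`` for
    Welch).  Significance is marked at p < 0.05.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least two values per sample", field="a")
    if paired:
        if a.size != b.size:
            raise ValidationError("paired samples must be matched in length", field="b")
        stat, p = sps.ttest_rel(a, b)
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
    stat, p = float(stat), float(p)
    if np.isnan(p):  # identical constant samples: no evidence of difference
        p = 1.0
        stat = 0.0
    return CompareResult(statistic=stat, p_value=p, paired=paired, significant=p < ALPHA)


def anova_across_rudiments(table: pd.DataFrame, group_col: str = "rudiment") -> tuple[float, float]:
    """One-way ANOVA of ``value`` across rudiments; returns (F, p)."""
    groups = [g["value"].to_numpy(dtype=float) for _, g in table.groupby(group_col)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 values each", field="table")
    if all(np.allclose(g, groups[0].mean()) for g in groups):
        return 0.0, 1.0
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def render_markdown(summary: pd.DataFrame, title: str = "") -> str:
    """Markdown rendering with the ``mean +- SD (n)`` cell convention."""
    lines = [f"### {title}", ""] if title else []
    cols = [c for c in summary.columns if c not in ("mean", "sd", "n")]
    header = cols + ["mean ± SD (n)"]
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    for _, row in summary.iterrows():
        cells = [str(row[c]) for c in cols]
        cells.append(f"{row['mean']:.1f} ± {row['sd']:.1f} ({int(row['n'])})")
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
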