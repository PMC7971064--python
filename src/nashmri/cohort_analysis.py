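"""Cohort statistics and the multiparametric study report.

Two-group contrasts use the unpaired t-test in its Welch (unequal
variance) form by default, since group variances differ visibly across the
study arms; the pooled-variance form is available via ``equal_var=True``.
Multi-group contrasts use one-way ANOVA with Tukey's HSD post-hoc
adjustment.  Correlations are Pearson r with a Fisher-z 95 % confidence
interval.  No correction across metrics is applied beyond Tukey within
each ANOVA family.

The report reproduces the study's comparison structure: per metric, the
control-vs-CDAHFD contrast at each week, the withdrawal-vs-week-14-CDAHFD
contrast, and the cross-metric correlation matrix (fat↔LV, CPA↔T1,
CPA↔T2*, CPA↔enhancement AUC).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .phantom.trajectory import Diet

__all__ = ["GroupComparison", "CorrelationResult", "welch_t", "anova_tukey",
           "pearson_r", "build_report", "REQUIRED_COLUMNS", "CohortReport"]

ALPHA = 0.05

REQUIRED_COLUMNS = ("animal_id", "diet", "week", "t1_ms", "t2star_ms",
                    "fat_pct", "lv_pct", "cpa_pct", "auc_pct_dsnr",
                    "auc_delta_lmr")

REPORT_METRICS = ("t1_ms", "t2star_ms", "fat_pct", "lv_pct", "cpa_pct",
                  "auc_pct_dsnr", "auc_delta_lmr")

CORRELATION_PAIRS = (("fat_pct", "lv_pct"), ("cpa_pct", "t1_ms"),
                     ("cpa_pct", "t2star_ms"), ("cpa_pct", "auc_pct_dsnr"))


@dataclass
class GroupComparison:
    name_a: str
    name_b: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    test: str                   # welch_t | student_t | anova_tukey
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def welch_t(group_a, group_b, equal_var: bool = False,
            name_a: str = "a", name_b: str = "b") -> GroupComparison:
    """Two-sided unpaired t-test (Welch by default).

    Degenerate zero-variance inputs are resolved deterministically: equal
    constant groups give t = 0, p = 1; unequal constant groups give
    t = ±inf, p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        name_a, name_b, float(a.mean()), _sem(a), len(a),
        float(b.mean()), _sem(b), len(b),
        "student_t" if equal_var else "welch_t", float(t), float(p))


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise: list[GroupComparison] = field(default_factory=list)


def anova_tukey(groups, labels=None) -> AnovaResult:
    """One-way ANOVA followed by all pairwise Tukey HSD comparisons."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups; use welch_t for two")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    labels = list(labels) if labels is not None else [
        f"group{i}" for i in range(len(groups))]

    if all(np.var(g) == 0 for g in groups) and \
            len({float(g.mean()) for g in groups}) == 1:
        f, p = 0.0, 1.0
        tukey_p = np.ones((len(groups), len(groups)))
        tukey_stat = np.zeros((len(groups), len(groups)))
    else:
        f, p = stats.f_oneway(*groups)
        hsd = stats.tukey_hsd(*groups)
        tukey_p = hsd.pvalue
        tukey_stat = hsd.statistic

    pairwise = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            pairwise.append(GroupComparison(
                labels[i], labels[j], float(a.mean()), _sem(a), len(a),
                float(b.mean()), _sem(b), len(b), "anova_tukey",
                float(tukey_stat[i, j]), float(tukey_p[i, j])))
    return AnovaResult(float(f), float(p), pairwise)


def pearson_r(x, y, confidence: float = 0.95) -> CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched vectors of length ≥ 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs contain non-finite values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    if abs(r) >= 1.0 or n <= 3:
        lo, hi = r, r
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        crit = stats.norm.ppf(0.5 + confidence / 2)
        lo, hi = np.tanh(z - crit * se), np.tanh(z + crit * se)
    return CorrelationResult(float(r), float(p), float(lo), float(hi), n)


@dataclass
class CohortReport:
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    markdown: str


def _check_columns(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")


def build_report(table: pd.DataFrame, out_dir: str | Path | None = None) -> CohortReport:
    """Emit the study-structured comparison and correlation report.

    Rows are one animal × timepoint; the report contains, per metric, the
    control-vs-CDAHFD Welch test at each common week, the withdrawal vs
    14-week-CDAHFD test, and the cross-metric Pearson correlations.  If
    ``out_dir`` is given, ``report_comparisons.csv``,
    ``report_correlations.csv`` and ``report.md`` are written there.
    """
    if len(table) == 0:
        raise ValueError("cohort table is empty")
    _check_columns(table)
    nc, cd, wd = Diet.NORMAL_CHOW.value, Diet.CDAHFD.value, Diet.WITHDRAWAL.value

    rows = []
    for metric in REPORT_METRICS:
        for week in sorted(table["week"].unique()):
            a = table.query("diet == @nc and week == @week")[metric].to_numpy()
            b = table.query("diet == @cd and week == @week")[metric].to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                c = welch_t(a, b, name_a=f"{nc}_w{week}", name_b=f"{cd}_w{week}")
                rows.append((metric, *_comparison_row(c)))
        a = table.query("diet == @wd and week == 14")[metric].to_numpy()
        b = table.query("diet == @cd and week == 14")[metric].to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            c = welch_t(a, b, name_a=f"{wd}_w14", name_b=f"{cd}_w14")
            rows.append((metric, *_comparison_row(c)))
    comparisons = pd.DataFrame(rows, columns=[
        "metric", "group_a", "group_b", "mean_a", "sem_a", "n_a",
        "mean_b", "sem_b", "n_b", "test", "statistic", "p_value",
        "significant"])

    crows = []
    for x_col, y_col in CORRELATION_PAIRS:
        sub = table[[x_col, y_col]].dropna()
        if len(sub) >= 3 and sub[x_col].var() > 0 and sub[y_col].var() > 0:
            res = pearson_r(sub[x_col], sub[y_col])
            crows.append((x_col, y_col, res.r, res.p_value,
                          res.ci_low, res.ci_high, res.n))
    correlations = pd.DataFrame(crows, columns=[
        "x", "y", "r", "p_value", "ci_low", "ci_high", "n"])

    md = _render_markdown(comparisons, correlations)
    report = CohortReport(comparisons, correlations, md)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        comparisons.to_csv(out / "report_comparisons.csv", index=False,
                           float_format="%.10g")
        correlations.to_csv(out / "report_correlations.csv", index=False,
                            float_format="%.10g")
        (out / "report.md").write_text(md)
    return report


def _comparison_row(c: GroupComparison) -> tuple:
    return (c.name_a, c.name_b, c.mean_a, c.sem_a, c.n_a,
            c.mean_b, c.sem_b, c.n_b, c.test, c.statistic, c.p_value,
            c.significant)


def _render_markdown(comparisons: pd.DataFrame,
                     correlations: pd.DataFrame) -> str:
    buf = io.StringIO()
    buf.write("# Cohort report\n\n## Group comparisons (Welch t)\n\n")
    buf.write("| metric | A | B | mean A ± SEM | mean B ± SEM | p | sig |\n")
    buf.write("|---|---|---|---|---|---|---|\n")
    for _, r in comparisons.iterrows():
        buf.write(
            f"| {r.metric} | {r.group_a} | {r.group_b} "
            f"| {r.mean_a:.3g} ± {r.sem_a:.2g} | {r.mean_b:.3g} ± {r.sem_b:.2g} "
            f"| {r.p_value:.3g} | {'*' if r.significant else ''} |\n")
    buf.write("\n## Cross-metric correlations (Pearson)\n\n")
    buf.write("| x | y | r | 95% CI | p | n |\n|---|---|---|---|---|---|\n")
    for _, r in correlations.iterrows():
        buf.write(f"| {r.x} | {r.y} | {r.r:.3f} "
                  f"| [{r.ci_low:.3f}, {r.ci_high:.3f}] | {r.p_value:.3g} "
                  f"| {r.n:.0f} |\n")
    return buf.getvalue()
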