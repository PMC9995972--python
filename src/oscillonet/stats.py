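"""Nonparametric inferential layer: Shapiro–Wilk normality gate, Friedman
with Conover–Iman post hoc, Kruskal–Wallis, Mann–Whitney with Bonferroni,
and tidy result tables.

Repeated-measures metrics (e.g. relative power per protocol epoch) enter as
a subjects × conditions table.  All tests are rank-based with mid-ranks for
ties; significance is decided at α = 0.05 and summaries are reported as
mean ± SEM with the usual star convention (*, **, *** at 0.05/0.01/0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass
class RepeatedMeasuresTable:
    """Subjects × conditions matrix of one metric."""

    values: np.ndarray
    subject_ids: list = field(default_factory=list)
    condition_names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x conditions)")
        n, k = self.values.shape
        self.subject_ids = list(self.subject_ids) or [f"s{i}" for i in range(n)]
        self.condition_names = list(self.condition_names) or [f"c{j}" for j in range(k)]
        if np.isnan(self.values).any():
            keep = ~np.isnan(self.values).any(axis=1)
            import logging
            logging.getLogger(__name__).warning(
                "dropping %d subjects with missing cells", (~keep).sum())
            self.values = self.values[keep]
            self.subject_ids = [s for s, k_ in zip(self.subject_ids, keep) if k_]


@dataclass
class TestResult:
    test: str
    statistic: float
    df: float | None
    p: float
    posthoc: pd.DataFrame | None = None
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def shapiro_gate(samples) -> bool:
    """True when any group fails Shapiro–Wilk normality at α = 0.05.

    Informational: the pipeline always runs nonparametric tests, this flag
    just documents that the choice is warranted.
    """
    flag = False
    for g in samples:
        g = np.asarray(g, float)
        if g.size < 3:
            raise ValueError("Shapiro-Wilk needs at least 3 observations")
        if np.ptp(g) == 0:
            raise ValueError("constant sample: normality test degenerate")
        if ss.shapiro(g).pvalue < ALPHA:
            flag = True
    return flag


def friedman_conover(tbl: RepeatedMeasuresTable) -> TestResult:
    """Friedman chi-square plus Conover–Iman all-pairs post hoc.

    Post hoc t statistics compare condition rank sums using the residual
    rank variance (Conover 1999), df = (n−1)(k−1); two-sided p-values are
    Holm-adjusted (raw values retained alongside).
    """
    x = tbl.values
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if k >= 3:
        stat, p = ss.friedmanchisquare(*(x[:, j] for j in range(k)))
    else:
        # scipy requires k >= 3; same statistic (tie-corrected) by hand
        rr = np.apply_along_axis(ss.rankdata, 1, x)
        rsum2 = rr.sum(axis=0)
        stat = 12.0 / (n * k * (k + 1)) * float((rsum2 ** 2).sum()) \
            - 3.0 * n * (k + 1)
        ties = 0.0
        for row in x:
            _, counts = np.unique(row, return_counts=True)
            ties += float((counts ** 3 - counts).sum())
        c = 1.0 - ties / (n * k * (k * k - 1))
        stat = stat / c if c > 0 else 0.0
        p = float(ss.chi2.sf(stat, k - 1))

    r = np.apply_along_axis(ss.rankdata, 1, x)        # within-subject ranks
    rsum = r.sum(axis=0)
    a1 = float((r ** 2).sum())
    b1 = float((rsum ** 2).sum()) / n
    df = (n - 1) * (k - 1)
    rows = []
    denom2 = 2.0 * n * (a1 - b1) / df
    for i in range(k):
        for j in range(i + 1, k):
            d = rsum[i] - rsum[j]
            if denom2 <= 0:
                t = np.inf if d != 0 else 0.0
            else:
                t = d / np.sqrt(denom2)
            praw = 2.0 * ss.t.sf(abs(t), df) if np.isfinite(t) else (0.0 if d else 1.0)
            rows.append((f"{tbl.condition_names[i]} vs {tbl.condition_names[j]}",
                         float(t), min(praw, 1.0)))
    ph = pd.DataFrame(rows, columns=["comparison", "statistic", "p_raw"])
    ph["p_adj"] = multipletests(ph["p_raw"], method="holm")[1]
    ph["method"] = "conover-holm"
    return TestResult("friedman", float(stat), k - 1, float(p), posthoc=ph)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H (tie-corrected), chi-square p with k−1 df."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if np.ptp(np.concatenate(groups)) == 0:  # all observations equal: H = 0
        return TestResult("kruskal-wallis", 0.0, len(groups) - 1, 1.0)
    stat, p = ss.kruskal(*groups)
    return TestResult("kruskal-wallis", float(stat), len(groups) - 1, float(p))


def mann_whitney_bonferroni(pairs, m: int | None = None) -> list:
    """Two-sided Mann–Whitney U per (group1, group2) pair, Bonferroni-adjusted.

    Exact null distribution when min(n1, n2) ≤ 8 and the data are tie-free
    (the study's group sizes sit in this regime); normal approximation with
    tie correction otherwise.  ``m`` is the number of comparisons charged to
    the correction (defaults to ``len(pairs)``).
    """
    pairs = list(pairs)
    m = len(pairs) if m is None else m
    if m < len(pairs):
        raise ValueError("m must cover all comparisons")
    out = []
    for g1, g2 in pairs:
        g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
        if g1.size == 0 or g2.size == 0:
            raise ValueError("empty group in Mann-Whitney comparison")
        pooled = np.concatenate([g1, g2])
        ties = len(np.unique(pooled)) < pooled.size
        method = "exact" if (min(g1.size, g2.size) <= 8 and not ties) else "asymptotic"
        res = ss.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
        tr = TestResult("mann-whitney", float(res.statistic), None, float(res.pvalue))
        tr.posthoc = pd.DataFrame([{
            "comparison": "g1 vs g2", "statistic": float(res.statistic),
            "p_raw": float(res.pvalue),
            "p_adj": min(1.0, m * float(res.pvalue)), "method": f"bonferroni(m={m})",
        }])
        out.append(tr)
    return out


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < ALPHA:
        return "*"
    return ""


def format_mean_sem(values) -> str:
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("empty cell")
    sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
    return f"{v.mean():.3f}±{sem:.3f}"


def summarize_results(cells: dict, tests: dict | None = None) -> pd.DataFrame:
    """Tidy summary: one row per named cell, mean ± SEM and stars.

    ``cells`` maps a label to its observations; ``tests`` optionally maps
    the same labels to a p-value to annotate.
    """
    if not cells:
        raise ValueError("no cells to summarize")
    tests = tests or {}
    rows = []
    for name, values in cells.items():
        p = tests.get(name)
        rows.append({
            "cell": name,
            "mean_sem": format_mean_sem(values),
            "n": len(np.asarray(values).ravel()),
            "p": p,
            "stars": significance_stars(p) if p is not None else "",
        })
    return pd.DataFrame(rows)
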