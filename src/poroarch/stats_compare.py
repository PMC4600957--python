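"""Rank-based group comparisons and study-table reporting.

Group differences in morphometric, fractal and biomechanical parameters
are assessed non-parametrically: the Kruskal–Wallis rank ANOVA (tie
corrected, chi-square approximation) across all groups, followed by the
Conover–Inman pairwise test on the pooled ranks (Conover's t-form with
the pooled-variance formula, df = N − k), and the Mann–Whitney U test for
two-group designs (exact enumeration for small tie-free samples, normal
approximation with tie correction otherwise).  A difference is flagged
as significant at α = 0.05 by default.  Mid-ranks are assigned to ties
throughout, and no multiplicity adjustment is applied beyond the
Conover–Inman procedure itself unless Holm adjustment is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .volume import UndefinedResultError


@dataclass
class GroupData:
    """Per-group numeric observations of one parameter."""

    labels: list[str]
    values: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values must align")
        if len(self.labels) < 2:
            raise ValueError("need at least 2 groups")
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        for lab, v in zip(self.labels, self.values):
            if v.size < 2:
                raise ValueError(f"group {lab!r} has fewer than 2 "
                                 "observations")


@dataclass
class ComparisonReport:
    table: pd.DataFrame             # one row per parameter × group summary
    omnibus: dict                   # parameter -> (H, p)
    pairwise: dict                  # parameter -> DataFrame of p values
    alpha: float = 0.05
    warnings: list[str] = field(default_factory=list)

    def significant(self, parameter: str) -> pd.DataFrame:
        return self.pairwise[parameter] < self.alpha


def kruskal_wallis(data: GroupData) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p (df = k − 1)."""
    pooled = np.concatenate(data.values)
    if np.all(pooled == pooled[0]):
        raise UndefinedResultError("all observations identical: "
                                   "rank test degenerate")
    h, p = stats.kruskal(*data.values)
    return float(h), float(p)


def conover_inman_pairwise(data: GroupData,
                           holm: bool = False) -> pd.DataFrame:
    """All-pairs Conover–Inman test on the pooled ranks.

    Uses Conover's t statistic t = (R̄_i − R̄_j) / sqrt(S² (N−1−H)/(N−k)
    (1/n_i + 1/n_j)), where R̄ are mean group ranks, S² the variance of
    the pooled (mid-)ranks and H the tie-corrected Kruskal–Wallis
    statistic; two-sided p values come from the t distribution with
    df = N − k.  Returns a symmetric DataFrame with NaN on the diagonal.
    """
    pooled = np.concatenate(data.values)
    if np.all(pooled == pooled[0]):
        raise UndefinedResultError("all observations identical: "
                                   "rank test degenerate")
    k = len(data.labels)
    n_i = np.array([v.size for v in data.values])
    N = int(n_i.sum())
    ranks = stats.rankdata(pooled)                 # mid-ranks for ties
    bounds = np.concatenate([[0], np.cumsum(n_i)])
    mean_ranks = np.array([ranks[bounds[g]:bounds[g + 1]].mean()
                           for g in range(k)])
    h, _ = stats.kruskal(*data.values)
    s2 = ranks.var(ddof=1)                          # = N(N+1)/12 without ties
    df = N - k
    scale2 = s2 * (N - 1 - h) / df
    pmat = np.full((k, k), np.nan)
    pvals = []
    pairs = list(combinations(range(k), 2))
    for i, j in pairs:
        se = np.sqrt(scale2 * (1.0 / n_i[i] + 1.0 / n_i[j]))
        t = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(t), df)
        pvals.append(min(p, 1.0))
    if holm:
        order = np.argsort(pvals)
        adj = np.empty(len(pvals))
        running = 0.0
        for rank_pos, idx in enumerate(order):
            running = max(running,
                          (len(pvals) - rank_pos) * pvals[idx])
            adj[idx] = min(1.0, running)
        pvals = list(adj)
    for (i, j), p in zip(pairs, pvals):
        pmat[i, j] = pmat[j, i] = p
    return pd.DataFrame(pmat, index=data.labels, columns=data.labels)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann–Whitney U with two-sided p.

    Exact enumeration (via the exact null distribution of U) when both
    samples have ≤ 8 observations and the data are tie-free; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise UndefinedResultError("all observations identical: "
                                   "rank test degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    small = max(a.size, b.size) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def percent_change(reference_mean: float, new_mean: float) -> float:
    """Relative change in percent: 100 × (new − reference)/reference."""
    if reference_mean == 0:
        raise UndefinedResultError("percent change undefined for a zero "
                                   "reference mean")
    return 100.0 * (new_mean - reference_mean) / reference_mean


def build_table(df: pd.DataFrame, alpha: float = 0.05,
                holm: bool = False) -> ComparisonReport:
    """Study-level comparison table from long-format per-sample results.

    ``df`` must have columns (sample_id, group, parameter, value).  For
    each parameter, groups are summarized as mean ± SD with n, compared
    with Kruskal–Wallis, and followed up with all-pairs Conover–Inman p
    values.  Groups with n < 2 are reported without SD and excluded from
    the tests, with a warning.
    """
    required = {"sample_id", "group", "parameter", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"input needs columns {sorted(required)}")
    warnings: list[str] = []
    rows = []
    omnibus: dict = {}
    pairwise: dict = {}
    for param, sub in df.groupby("parameter", sort=False):
        groups = {g: s["value"].to_numpy(dtype=float)
                  for g, s in sub.groupby("group", sort=False)}
        row = {"parameter": param}
        for g, v in groups.items():
            row[f"{g}_mean"] = float(np.mean(v))
            row[f"{g}_sd"] = float(np.std(v, ddof=1)) if v.size > 1 \
                else float("nan")
            row[f"{g}_n"] = int(v.size)
            if v.size < 2:
                warnings.append(f"group {g!r} for {param!r} has n < 2: "
                                "excluded from tests")
        testable = {g: v for g, v in groups.items() if v.size >= 2}
        if len(testable) >= 2:
            gd = GroupData(list(testable.keys()), list(testable.values()))
            try:
                omnibus[param] = kruskal_wallis(gd)
                pairwise[param] = conover_inman_pairwise(gd, holm=holm)
            except UndefinedResultError:
                omnibus[param] = (0.0, 1.0)
                labs = list(testable.keys())
                pairwise[param] = pd.DataFrame(
                    np.where(np.eye(len(labs)), np.nan, 1.0),
                    index=labs, columns=labs)
        else:
            warnings.append(f"{param!r}: fewer than 2 testable groups, "
                            "no statistics computed")
        rows.append(row)
    return ComparisonReport(table=pd.DataFrame(rows), omnibus=omnibus,
                            pairwise=pairwise, alpha=alpha,
                            warnings=warnings)


def report_markdown(report: ComparisonReport) -> str:
    """Render a comparison report as a compact Markdown table."""
    lines = []
    t = report.table
    group_names = sorted({c[:-5] for c in t.columns if c.endswith("_mean")})
    header = "| parameter | " + " | ".join(group_names) + " | H | p |"
    lines.append(header)
    lines.append("|" + "---|" * (len(group_names) + 3))
    for _, row in t.iterrows():
        cells = [str(row["parameter"])]
        for g in group_names:
            m, s = row.get(f"{g}_mean"), row.get(f"{g}_sd")
            cells.append("—" if pd.isna(m) else f"{m:.3g} ± {s:.2g}")
        h, p = report.omnibus.get(row["parameter"], (float("nan"),) * 2)
        cells += [f"{h:.3g}", f"{p:.3g}"]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
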