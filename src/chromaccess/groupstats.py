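"""Multi-group comparison statistics for the assay's readouts.

Two families are used, matching how plate data are reported:

* pooled per-object values (mean nuclear fluorescence of every nucleus from
  all replicate wells of a condition) are compared with the Kruskal-Wallis
  rank test followed by Dunn's post hoc z tests with Holm step-down
  adjustment — distributions are skewed and n is in the thousands;
* per-well quantities (object counts, well averages) are compared with
  one-way ANOVA followed by Tukey's HSD — a handful of replicate wells per
  condition, approximately normal.

Dunn's test is implemented here directly (tie-corrected pooled-rank z
statistics); the Kruskal-Wallis H, ANOVA F, Tukey HSD and Holm adjustment are
delegated to scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "kruskal_dunn_holm",
    "dunn_test",
    "anova_tukey",
    "fold_change_per_well",
    "distribution_summary",
    "format_p",
]


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame  # columns: group1, group2, statistic, p_raw, p_adj, method
    degenerate: bool = False

    def formatted(self) -> pd.DataFrame:
        """Pairwise table with the reporting convention applied."""
        out = self.pairwise.copy()
        out["p_report"] = out["p_adj"].map(format_p)
        return out


def format_p(p: float, alpha: float = 0.05, decimals: int = 3) -> str:
    """Figure-legend convention: 3 decimals, 'ns' above alpha."""
    if not np.isfinite(p):
        return "ns"
    return "ns" if p > alpha else f"{round(p, decimals):.{decimals}f}"


def _check_groups(groups: dict, min_size: int = 1) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < min_size:
            raise ValueError(f"group '{name}' has fewer than {min_size} values")
        out[str(name)] = arr
    return out


def dunn_test(
    groups: dict,
    control: str | None = None,
    mode: str = "control",
) -> pd.DataFrame:
    """Dunn's post hoc test on pooled ranks with tie-corrected variance.

    For groups i, j the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))`` with the
    tie term ``T = sum(t^3 - t) / (12 (N - 1))``; p-values are two-sided
    normal.  ``mode='control'`` compares every group against the control (the
    first group by default), ``mode='all'`` reports all pairs.
    """
    g = _check_groups(groups)
    names = list(g)
    if mode not in ("control", "all"):
        raise ValueError("mode must be 'control' or 'all'")
    if control is None:
        control = names[0]
    if control not in g:
        raise ValueError(f"control group '{control}' not found")

    pooled = np.concatenate([g[n] for n in names])
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank, sizes = {}, {}
    start = 0
    for n in names:
        k = g[n].size
        mean_rank[n] = ranks[start : start + k].mean()
        sizes[n] = k
        start += k

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_unit = N * (N + 1) / 12.0 - tie_term

    if mode == "control":
        pairs = [(control, n) for n in names if n != control]
    else:
        pairs = list(combinations(names, 2))

    rows = []
    for a, b in pairs:
        se2 = var_unit * (1.0 / sizes[a] + 1.0 / sizes[b])
        if se2 <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / np.sqrt(se2)
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append(dict(group1=a, group2=b, statistic=float(z), p_raw=float(min(p, 1.0))))
    return pd.DataFrame(rows)


def kruskal_dunn_holm(
    groups: dict,
    control: str | None = None,
    mode: str = "control",
) -> ComparisonResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn post hoc and Holm adjustment.

    With all values identical across groups the test is degenerate and
    reported as H = 0, p = 1 with unit pairwise p-values.
    """
    g = _check_groups(groups)
    pooled = np.concatenate(list(g.values()))
    if np.all(pooled == pooled[0]):
        pw = dunn_test(g, control=control, mode=mode)
        pw["p_raw"] = 1.0
        pw["p_adj"] = 1.0
        pw["method"] = "holm"
        return ComparisonResult("kruskal-wallis", 0.0, 1.0, pw, degenerate=True)

    H, p = stats.kruskal(*g.values())
    pw = dunn_test(g, control=control, mode=mode)
    pw["p_adj"] = multipletests(pw["p_raw"].to_numpy(), method="holm")[1]
    pw["method"] = "holm"
    return ComparisonResult("kruskal-wallis", float(H), float(p), pw)


def anova_tukey(groups: dict) -> ComparisonResult:
    """One-way ANOVA with Tukey HSD post hoc on per-well values.

    Every group needs at least two wells.  Zero within-group variance
    everywhere is a degenerate design and is flagged rather than tested.
    """
    g = _check_groups(groups, min_size=2)
    within_var = sum(np.var(v, ddof=1) for v in g.values())
    names = list(g)
    if within_var == 0:
        pairs = list(combinations(names, 2))
        pw = pd.DataFrame(
            [dict(group1=a, group2=b, statistic=np.nan, p_raw=1.0, p_adj=1.0, method="tukey") for a, b in pairs]
        )
        return ComparisonResult("anova", 0.0, 1.0, pw, degenerate=True)

    F, p = stats.f_oneway(*g.values())
    values = np.concatenate(list(g.values()))
    labels = np.concatenate([[n] * g[n].size for n in names])
    tk = pairwise_tukeyhsd(values, labels)
    res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    pw = pd.DataFrame(
        dict(
            group1=res["group1"].astype(str),
            group2=res["group2"].astype(str),
            statistic=res["meandiff"].astype(float),
            p_raw=np.asarray(tk.pvalues, dtype=float),
            p_adj=np.asarray(tk.pvalues, dtype=float),
            method="tukey",
        )
    )
    return ComparisonResult("anova", float(F), float(p), pw)


def fold_change_per_well(
    well_summary: pd.DataFrame,
    reference: str,
    value_column: str = "well_mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well fold change of a well-average readout vs a reference condition.

    Each well's average is divided by the mean of the reference wells'
    averages.  Returns ``(per_well, per_condition)`` where the condition table
    carries the mean fold change and the sample SD across replicate wells.
    """
    req = {"well", "condition", value_column}
    if not req.issubset(well_summary.columns):
        raise ValueError(f"well summary must have columns {sorted(req)}")
    ref = well_summary.loc[well_summary["condition"] == reference, value_column]
    ref = ref.dropna()
    if ref.empty:
        raise ValueError(f"reference condition '{reference}' has no wells")
    ref_mean = float(ref.mean())
    if ref_mean == 0:
        raise ValueError("reference mean is zero; fold change undefined")

    per_well = well_summary[["well", "condition"]].copy()
    per_well["fold_change"] = well_summary[value_column] / ref_mean
    agg = (
        per_well.dropna(subset=["fold_change"])
        .groupby("condition", sort=False)["fold_change"]
        .agg(fold_change="mean", sd=lambda v: v.std(ddof=1), n_wells="count")
        .reset_index()
    )
    return per_well, agg


def distribution_summary(values) -> dict:
    """Quartiles (0.25/0.5/0.75, linear interpolation) and count, for violins."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("no values supplied")
    q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    return dict(q25=float(q25), q50=float(q50), q75=float(q75), n=int(x.size))
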