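"""Edge-wise group statistics: t-tests, correlations, FDR, path-length tests.

Inputs are tidy pandas objects: a *z table* is a subjects x edges DataFrame
of Fisher-transformed correlations whose columns are canonical edge keys
(``"A|B"`` with A < B lexicographically). All result tables carry node-name
keys, never positional indices, plus an ``analysis`` tag.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "edge_key",
    "split_edge_key",
    "edge_z_table",
    "edgewise_group_ttest",
    "edge_activity_correlation",
    "edge_rt_correlation",
    "pathlength_group_comparison",
    "wilcoxon_rank_sum",
    "bh_fdr",
]


def edge_key(a: str, b: str) -> str:
    """Canonical unordered edge key: names sorted, joined with '|'."""
    if a == b:
        raise ValueError("self-edges are not allowed")
    return "|".join(sorted((a, b)))


def split_edge_key(key: str) -> tuple[str, str]:
    a, b = key.split("|")
    return a, b


def edge_z_table(z_by_subject: dict, pairs) -> pd.DataFrame:
    """Assemble a subjects x edges table of Fisher-z values.

    ``z_by_subject`` maps subject id -> CorrelationMatrix; ``pairs`` is an
    iterable of (nodeA, nodeB) name tuples.
    """
    keys = [edge_key(a, b) for a, b in pairs]
    rows = {}
    for subject, corr in z_by_subject.items():
        z = corr.fisher_z()
        idx = {name: i for i, name in enumerate(corr.names)}
        rows[subject] = [
            z[idx[a], idx[b]] for a, b in (split_edge_key(k) for k in keys)
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=keys)


def _pooled_ttest(x: np.ndarray, y: np.ndarray, equal_var: bool):
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0, False  # no signal at all, not degenerate
        return np.nan, np.nan, True
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue), False


def edgewise_group_ttest(
    z_group1: pd.DataFrame,
    z_group2: pd.DataFrame,
    edges=None,
    alpha: float = 0.05,
    equal_var: bool = True,
    group_labels: tuple[str, str] = ("group1", "group2"),
) -> pd.DataFrame:
    """Two-sample t-test per edge on Fisher-z values (uncorrected).

    Pooled-variance Student's t by default (``equal_var=False`` switches to
    Welch's form for sensitivity checks). Rows are flagged significant at
    ``alpha`` uncorrected and labelled with the direction of the difference.
    """
    if len(z_group1) < 2 or len(z_group2) < 2:
        raise ValueError("need at least 2 subjects per group")
    if edges is None:
        edges = [c for c in z_group1.columns if c in z_group2.columns]
    g1, g2 = group_labels
    rows = []
    for key in edges:
        x = z_group1[key].to_numpy(dtype=float)
        y = z_group2[key].to_numpy(dtype=float)
        t, p, degenerate = _pooled_ttest(x, y, equal_var)
        a, b = split_edge_key(key)
        direction = ""
        if not degenerate and x.mean() != y.mean():
            direction = f"{g1}>{g2}" if x.mean() > y.mean() else f"{g2}>{g1}"
        rows.append(
            {
                "node_a": a,
                "node_b": b,
                f"mean_z_{g1}": x.mean(),
                f"mean_z_{g2}": y.mean(),
                "t": t,
                "p": p,
                "direction": direction,
                "significant": bool(p < alpha) if not degenerate else False,
                "degenerate": degenerate,
                "analysis": "group-diff",
            }
        )
    return pd.DataFrame(rows)


def _pearson(x: np.ndarray, y: np.ndarray):
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        return np.nan, np.nan, True
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), False


def edge_activity_correlation(
    z: pd.DataFrame, activity: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of each edge's z with each subcortical activity.

    ``activity`` is subjects x subcortical-ROIs; either the mean-signal
    activity index or surrogate t-values of a task contrast may be supplied.
    Rows are flagged significant at ``alpha`` uncorrected.
    """
    common = z.index.intersection(activity.index)
    if len(common) != len(z) or len(common) != len(activity):
        raise ValueError("z and activity tables must cover the same subjects")
    z = z.loc[common]
    activity = activity.loc[common]
    rows = []
    for key in z.columns:
        a, b = split_edge_key(key)
        for roi in activity.columns:
            r, p, degenerate = _pearson(
                z[key].to_numpy(dtype=float), activity[roi].to_numpy(dtype=float)
            )
            rows.append(
                {
                    "node_a": a,
                    "node_b": b,
                    "subcortical_roi": roi,
                    "r": r,
                    "p": p,
                    "significant": bool(p < alpha) if not degenerate else False,
                    "degenerate": degenerate,
                    "analysis": "activity-corr",
                }
            )
    return pd.DataFrame(rows)


def edge_rt_correlation(
    z: pd.DataFrame,
    rt: pd.Series,
    dlpfc_nodes,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate cortico-subcortical edge strength with mean response time.

    Pairs whose cortical node belongs to ``dlpfc_nodes`` (the a-priori
    hypothesis that stronger DLPFC-striatum coupling means faster responses)
    are tested at ``alpha`` uncorrected; all remaining pairs are
    Benjamini-Hochberg adjusted and judged on the adjusted p.
    """
    common = z.index.intersection(rt.index)
    if len(common) != len(z) or len(common) != len(rt):
        raise ValueError("z table and RT series must cover the same subjects")
    z = z.loc[common]
    rt_values = rt.loc[common].to_numpy(dtype=float)
    dlpfc_nodes = set(dlpfc_nodes)
    rows = []
    for key in z.columns:
        a, b = split_edge_key(key)
        r, p, degenerate = _pearson(z[key].to_numpy(dtype=float), rt_values)
        rows.append(
            {
                "node_a": a,
                "node_b": b,
                "r": r,
                "p": p,
                "a_priori": bool(dlpfc_nodes & {a, b}),
                "degenerate": degenerate,
                "analysis": "rt-corr",
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    rest = table.index[~table["a_priori"] & ~table["degenerate"]]
    if len(rest):
        table.loc[rest, "p_adjusted"] = bh_fdr(table.loc[rest, "p"].to_numpy())
    crit = np.where(table["a_priori"], table["p"], table["p_adjusted"])
    table["significant"] = pd.Series(crit < alpha, index=table.index).fillna(
        False
    ) & ~table["degenerate"]
    return table


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum statistic, p).

    Exact: for combined n <= 20 the null distribution of the rank sum is
    enumerated over all group assignments (ties handled via midranks).
    Larger samples use the tie-corrected normal approximation of the
    Mann-Whitney U (no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    t_obs = ranks[:n1].sum()
    if n1 + n2 <= 20:
        sums = np.array(
            [ranks[list(c)].sum() for c in combinations(range(n1 + n2), n1)]
        )
        p_lo = np.mean(sums <= t_obs + 1e-12)
        p_hi = np.mean(sums >= t_obs - 1e-12)
        p = min(1.0, 2 * min(p_lo, p_hi))
        return float(t_obs), float(p)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", use_continuity=False)
    # all-tied samples: scipy returns NaN; no evidence against the null
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return float(t_obs), p


def pathlength_group_comparison(
    dists_group1: list[pd.DataFrame],
    dists_group2: list[pd.DataFrame],
    source_nodes,
    alpha: float = 0.05,
    group_labels: tuple[str, str] = ("group1", "group2"),
) -> pd.DataFrame:
    """Compare per-subject shortest path lengths from source nodes between groups.

    For each (source, target) pair the finite path lengths of the two groups
    are compared with the two-sided Wilcoxon rank-sum test. Subjects for
    whom the target is unreachable are excluded from that pair's test and
    counted; a pair with fewer than 2 finite values in either group is
    flagged untestable.
    """
    g1, g2 = group_labels
    nodes = list(dists_group1[0].columns)
    rows = []
    for source in source_nodes:
        for target in nodes:
            if target == source:
                continue
            v1 = np.array([d.loc[source, target] for d in dists_group1])
            v2 = np.array([d.loc[source, target] for d in dists_group2])
            f1, f2 = v1[np.isfinite(v1)], v2[np.isfinite(v2)]
            row = {
                "source": source,
                "target": target,
                f"mean_{g1}": f1.mean() if f1.size else np.nan,
                f"sd_{g1}": f1.std(ddof=1) if f1.size > 1 else np.nan,
                f"mean_{g2}": f2.mean() if f2.size else np.nan,
                f"sd_{g2}": f2.std(ddof=1) if f2.size > 1 else np.nan,
                f"n_excluded_{g1}": int(v1.size - f1.size),
                f"n_excluded_{g2}": int(v2.size - f2.size),
                "analysis": "path-length",
            }
            if f1.size < 2 or f2.size < 2:
                row.update({"p": np.nan, "significant": False, "untestable": True})
            else:
                _, p = wilcoxon_rank_sum(f1, f2)
                row.update(
                    {"p": p, "significant": bool(p < alpha), "untestable": False}
                )
            rows.append(row)
    return pd.DataFrame(rows)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")
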