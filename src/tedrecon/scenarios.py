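"""Evacuation-scenario analysis: key-segment selection, Ward clustering, group tests.

A handful of six-hour segments (plume passages) carry most of the total
dose, so subjects are clustered on their doses in those segments —
optionally augmented with visited-landmark indicators — by Ward's
minimum-variance hierarchical method.  Dose differences between the
resulting scenarios are tested with Kruskal-Wallis and the Steel-Dwass
all-pairs post-hoc procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy


@dataclass
class FeatureMatrix:
    """Subjects x features, feature names kept for reporting."""

    subject_ids: list[str]
    X: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("feature matrix has missing values")


@dataclass
class ScenarioAssignment:
    labels: dict[str, int]  # subject_id -> 1-based cluster label, by descending size
    linkage: np.ndarray  # scipy linkage matrix, for dendrogram export

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def usage_rates(self) -> dict[int, float]:
        """Percent of subjects following each scenario."""
        n = len(self.labels)
        counts = pd.Series(list(self.labels.values())).value_counts()
        return {int(c): 100.0 * k / n for c, k in counts.items()}


def select_key_segments(
    per_segment: np.ndarray,
    max_k: int = 5,
    r2_stop: float = 0.95,
) -> list[int]:
    """Forward stepwise selection of dose-dominant segments.

    Regresses total dose on segment-dose columns, greedily adding the
    column with the largest R^2 gain (ties to the earlier segment) until
    cumulative R^2 >= ``r2_stop`` or ``max_k`` segments.  Returns 0-based
    column indices in selection order; empty if the total dose is constant.
    """
    X = np.asarray(per_segment, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a subjects x segments matrix with >= 2 subjects")
    y = X.sum(axis=1)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        return []
    selected: list[int] = []
    remaining = list(range(X.shape[1]))
    best_r2 = 0.0
    ones = np.ones((X.shape[0], 1))
    while remaining and len(selected) < max_k and best_r2 < r2_stop:
        gains = []
        for j in remaining:
            design = np.hstack([ones, X[:, selected + [j]]])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            rss = float(((y - design @ beta) ** 2).sum())
            gains.append((1.0 - rss / tss, -j))  # -j: earlier segment wins ties
        r2, neg_j = max(gains)
        if r2 <= best_r2 + 1e-12:
            break  # no remaining column explains anything further
        selected.append(-neg_j)
        remaining.remove(-neg_j)
        best_r2 = r2
    return selected


def zscore_columns(X: np.ndarray) -> np.ndarray:
    """Column z-standardization; constant columns map to zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def ward_cluster(fm: FeatureMatrix, k: int, standardize: bool = True) -> ScenarioAssignment:
    """Ward minimum-variance agglomeration cut at ``k`` clusters.

    Labels are renumbered 1..k by descending cluster size (ties by the
    smallest original dendrogram label).
    """
    n = len(fm.subject_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} subjects")
    if k < 1:
        raise ValueError("k must be >= 1")
    X = zscore_columns(fm.X) if standardize else fm.X
    Z = hierarchy.linkage(X, method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = sorted(set(raw), key=lambda c: (-(raw == c).sum(), c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = {sid: relabel[c] for sid, c in zip(fm.subject_ids, raw)}
    return ScenarioAssignment(labels, Z)


def dendrogram_text(assign: ScenarioAssignment, leaf_names: list[str]) -> str:
    """Newick-style nested-parenthesis export of the Ward dendrogram."""
    tree = hierarchy.to_tree(assign.linkage)

    def render(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        return f"({render(node.left)},{render(node.right)}):{node.dist:.6g}"

    return render(tree) + ";"


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All observations identical across groups is a degenerate, perfectly
    null case: H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _rank_sum_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized two-sample rank-sum statistic with tie-corrected variance."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    expect = n1 * (n + 1) / 2.0
    # tie-corrected variance of the rank sum
    var = n1 * n2 / (n * (n - 1.0)) * (float(np.sum(ranks**2)) - n * (n + 1.0) ** 2 / 4.0)
    if var <= 0:
        return 0.0
    return (w - expect) / np.sqrt(var)


def steel_dwass(groups: list[np.ndarray]) -> pd.DataFrame:
    """All-pairs Steel-Dwass comparisons.

    For every pair of groups the two-sample rank-sum statistic (recomputed
    on that pair alone, tie-corrected) is referred to the studentized-range
    distribution: p = P(q(k, inf) > |t| * sqrt(2)), k the number of groups.
    At k = 2 this reduces to the normal-approximation Wilcoxon rank-sum
    test.  Returns a DataFrame with columns group_i, group_j, statistic, p.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    k = len(groups)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            t = _rank_sum_statistic(groups[i], groups[j])
            p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, np.inf))
            rows.append({"group_i": i, "group_j": j, "statistic": t, "p": min(p, 1.0)})
    return pd.DataFrame(rows)


def significance_marker(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def scenario_summary(assign: ScenarioAssignment, doses: dict[str, float]) -> pd.DataFrame:
    """Per-scenario n, usage rate, dose quartiles, and pairwise significance.

    ``doses`` maps subject_id -> total dose (mSv); every assigned subject
    must be dosed.
    """
    labels = assign.labels
    df = pd.DataFrame(
        {"cluster": [labels[s] for s in labels], "dose": [doses[s] for s in labels]}
    )
    n_total = len(df)
    out = (
        df.groupby("cluster", sort=True)["dose"]
        .agg(
            n="size",
            median="median",
            q25=lambda s: float(np.quantile(s, 0.25)),
            q75=lambda s: float(np.quantile(s, 0.75)),
        )
        .reset_index()
    )
    out["usage_rate_pct"] = 100.0 * out["n"] / n_total
    clusters = list(out["cluster"])
    if len(clusters) > 1:
        groups = [df.loc[df["cluster"] == c, "dose"].to_numpy() for c in clusters]
        pairs = steel_dwass(groups)
        min_p = np.ones(len(clusters))
        for _, r in pairs.iterrows():
            for idx in (int(r["group_i"]), int(r["group_j"])):
                min_p[idx] = min(min_p[idx], r["p"])
        out["significance"] = [significance_marker(p) for p in min_p]
    else:
        out["significance"] = ""
    return out[["cluster", "n", "usage_rate_pct", "median", "q25", "q75", "significance"]]
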