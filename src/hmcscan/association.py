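"""Correlation, clustering and hypothesis-test analytics.

Covers the study's statistical toolkit: Spearman sample-similarity of
intragenic coverage, Wilcoxon rank-sum comparisons of marked vs unmarked
genes, hierarchical (Ward) clustering of gene-body enrichment profiles into
C1..C5 ordered by mean coverage, per-cluster expression summaries, gene-set
membership counts, ANOVA (one- and two-way with Tukey HSD) and Welch
t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "sample_similarity",
    "marked_vs_unmarked_test",
    "ClusterAssignment",
    "cluster_genes",
    "cluster_expression_summary",
    "GeneSetStats",
    "set_membership",
    "one_way_anova",
    "two_way_anova_tukey",
    "group_ttest",
]


def sample_similarity(coverage: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Spearman rank correlation of coverage vectors.

    Mid-rank ties; computed pairwise over all genes. Symmetric with unit
    diagonal.
    """
    if coverage.shape[1] < 2 or coverage.shape[0] < 3:
        raise ValueError("need >= 2 samples and >= 3 genes")
    rho, _ = stats.spearmanr(coverage.to_numpy())
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=coverage.columns, columns=coverage.columns)


def marked_vs_unmarked_test(values: pd.Series, marked: pd.Series,
                            groups: pd.Series | None = None,
                            exact_max_n: int = 12) -> pd.DataFrame:
    """Wilcoxon rank-sum test of marked vs unmarked genes, per group.

    ``values`` are per-gene expression values, ``marked`` a boolean per
    gene, ``groups`` an optional per-gene label (e.g. biotype). Small
    comparisons (n1 + n2 <= ``exact_max_n``) use the exact permutation null;
    larger ones the tie-corrected normal approximation with continuity
    correction. Groups in which either side has < 2 members are reported as
    untestable (NaN statistic/p).
    """
    if groups is None:
        groups = pd.Series("all", index=values.index)
    rows = []
    for label, idx in values.groupby(groups).groups.items():
        v = values.loc[idx]
        m = marked.loc[idx].astype(bool)
        x, y = v[m].to_numpy(), v[~m].to_numpy()
        row = {"group": label, "n_marked": len(x), "n_unmarked": len(y)}
        if len(x) < 2 or len(y) < 2:
            row.update(statistic=np.nan, p_value=np.nan, testable=False)
        else:
            method = "exact" if len(x) + len(y) <= exact_max_n else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method=method)
            row.update(statistic=float(res.statistic),
                       p_value=float(res.pvalue), testable=True)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def coverage_expression_correlation(coverage: pd.DataFrame,
                                    log2cpm: pd.DataFrame,
                                    sample_map: Mapping[str, Sequence[str]],
                                    genes: Sequence[str] | None = None
                                    ) -> pd.Series:
    """Within-sample Spearman between coverage and expression, per sample.

    For each coverage sample, gene coverage fractions are paired with the
    replicate-averaged log2 CPM of the matching expression libraries
    (``sample_map``: coverage sample -> its expression sample names) and the
    Spearman correlation is computed across genes. Computing the statistic
    within each sample avoids the compositional between-sample confound of
    CPM scaling; the cross-sample mean is the summary correlation.
    """
    idx = coverage.index if genes is None else pd.Index(genes)
    rhos = {}
    for cov_sample, expr_samples in sample_map.items():
        e = log2cpm.loc[idx, list(expr_samples)].mean(axis=1)
        rho, _ = stats.spearmanr(coverage.loc[idx, cov_sample], e)
        rhos[cov_sample] = float(rho)
    return pd.Series(rhos, name="spearman_rho")


@dataclass
class ClusterAssignment:
    """Gene -> C1..Ck labels ordered by ascending mean coverage."""

    labels: pd.Series            # gene_id -> "C1".."Ck"
    sizes: pd.Series             # label -> gene count
    mean_coverage: pd.Series     # label -> mean profile value
    mean_profiles: pd.DataFrame  # label x bin mean profile

    @property
    def k(self) -> int:
        return len(self.sizes)


def cluster_genes(profiles: pd.DataFrame, k: int = 5,
                  method: str = "ward") -> ClusterAssignment:
    """Hierarchical clustering of gene-body enrichment profiles.

    Euclidean distance with Ward linkage (configurable to complete/average),
    tree cut at ``k`` clusters, then relabelled C1..Ck so mean profile
    coverage increases strictly with the cluster index. Deterministic for a
    fixed input order.
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of genes ({len(profiles)})")
    X = profiles.to_numpy(dtype=float)
    Z = linkage(X, method=method, metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    means = pd.Series(X.mean(axis=1)).groupby(raw).mean()
    # order raw labels by ascending mean coverage -> C1..Ck
    order = means.sort_values(kind="stable").index
    relabel = {old: f"C{i + 1}" for i, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=profiles.index,
                       name="cluster")
    sizes = labels.value_counts().sort_index()
    mean_profiles = profiles.groupby(labels).mean()
    mean_cov = mean_profiles.mean(axis=1)
    return ClusterAssignment(labels, sizes, mean_cov, mean_profiles)


def cluster_expression_summary(assignment: ClusterAssignment,
                               log2cpm: pd.DataFrame) -> Dict:
    """Per-cluster expression summaries plus the monotone-trend statistic.

    Returns per-cluster median and IQR of log2 CPM per sample, and the
    Spearman correlation between cluster index (1..k) and per-gene mean
    expression across samples.
    """
    common = assignment.labels.index.intersection(log2cpm.index)
    missing = assignment.labels.index.difference(log2cpm.index)
    if len(missing):
        raise ValueError(f"clustered genes absent from expression: "
                         f"{sorted(missing)[:5]}...")
    labels = assignment.labels.loc[common]
    expr = log2cpm.loc[common]
    med = expr.groupby(labels).median()
    q1 = expr.groupby(labels).quantile(0.25)
    q3 = expr.groupby(labels).quantile(0.75)
    cluster_index = labels.str.lstrip("C").astype(int)
    gene_mean = expr.mean(axis=1)
    if gene_mean.nunique() <= 1 or cluster_index.nunique() <= 1:
        rho, p = 0.0, 1.0  # no trend is measurable on constant input
    else:
        rho, p = stats.spearmanr(cluster_index, gene_mean)
    return {
        "median": med,
        "iqr_low": q1,
        "iqr_high": q3,
        "trend_rho": float(rho),
        "trend_p": float(p),
    }


@dataclass(frozen=True)
class GeneSetStats:
    """Membership of a named gene set within a subset of clusters."""

    set_name: str
    clusters: Tuple[str, ...]
    count: int
    size: int
    percentage: int  # rounded half-away-from-zero to integer


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def set_membership(labels: pd.Series | Mapping[str, str],
                   gene_set: Iterable[str],
                   clusters: Iterable[str],
                   set_name: str = "gene_set") -> GeneSetStats:
    """Count gene-set members assigned to the given clusters.

    ``percentage`` = round(100 * count / size), half away from zero, to
    match integer-percent reporting. An empty set yields count 0, pct 0.
    """
    lab = labels if isinstance(labels, Mapping) else labels.to_dict()
    gene_set = list(gene_set)
    wanted = set(clusters)
    count = sum(1 for g in gene_set if lab.get(g) in wanted)
    size = len(gene_set)
    pct = _round_half_away(100.0 * count / size) if size else 0
    return GeneSetStats(set_name, tuple(sorted(wanted)), count, size, pct)


def one_way_anova(*groups: Sequence[float]) -> Tuple[float, float]:
    """One-way ANOVA F and p across >= 2 groups of >= 2 observations."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    res = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def two_way_anova_tukey(values: Sequence[float], factor_a: Sequence,
                        factor_b: Sequence) -> Dict:
    """Two-way ANOVA (with interaction) plus Tukey HSD on the cell means.

    Returns the ANOVA table and the pairwise Tukey comparisons over the
    (A, B) cells; an interval excluding 0 is flagged significant.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "A": pd.Categorical(factor_a),
        "B": pd.Categorical(factor_b),
    })
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    cells = df["A"].astype(str) + ":" + df["B"].astype(str)
    tukey = pairwise_tukeyhsd(df["y"].to_numpy(), cells.to_numpy())
    tk = pd.DataFrame(tukey.summary().data[1:],
                      columns=tukey.summary().data[0])
    return {"anova": table, "tukey": tk}


def group_ttest(x: Sequence[float], y: Sequence[float],
                eps: float = 1e-300) -> Dict:
    """Two-sided Welch t-test with a degenerate-variance guard.

    When both groups have (near-)zero variance the statistic is undefined;
    the result then reports p < 1e-12 if the means differ (flagged
    ``degenerate=True``) or t=0, p=1 if they coincide.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx <= eps and vy <= eps:
        if np.isclose(x.mean(), y.mean()):
            return {"t": 0.0, "p_value": 1.0, "degenerate": True}
        return {"t": np.inf if x.mean() > y.mean() else -np.inf,
                "p_value": 1e-12, "degenerate": True}
    res = stats.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "p_value": float(res.pvalue),
            "degenerate": False}
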