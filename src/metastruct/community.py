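"""Community-level statistics on edge and pathway abundance matrices.

Normalisations, Bray-Curtis/Ward sample clustering, PCA loading ranks,
Chao1 richness, Mann-Whitney group tests, the group anomaly statistic
(mean_A − mean_B)/(mean_A + mean_B), and OLS agreement between two sample
distance matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    feature_id: str
    mean_a: float
    mean_b: float
    anomaly: float
    u_statistic: float
    p_value: float
    p_bh: float  # Benjamini-Hochberg adjusted (extension, not used upstream)


@dataclass
class SampleClustering:
    labels: list[str]
    linkage: np.ndarray
    distances: np.ndarray  # condensed Bray-Curtis

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(x) for x in flat)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return f"{self.labels[node.id]}:{node.dist:g}"
            return f"({render(node.left)},{render(node.right)}):{node.dist:g}"

        return f"({render(tree.left)},{render(tree.right)});"


def normalize_matrix(m: pd.DataFrame, mode: str) -> pd.DataFrame:
    """``per_feature_max`` divides each column by its maximum;
    ``per_sample_total`` divides each row by its sum."""
    values = m.astype(float)
    if (values.values < 0).any():
        raise ValueError("abundance matrix must be nonnegative")
    if mode == "per_feature_max":
        maxes = values.max(axis=0)
        zero = list(maxes.index[maxes == 0])
        if zero:
            raise ValueError(f"features with zero maximum: {zero}")
        return values / maxes
    if mode == "per_sample_total":
        totals = values.sum(axis=1)
        zero = list(totals.index[totals == 0])
        if zero:
            raise ValueError(f"samples with zero total: {zero}")
        return values.div(totals, axis=0)
    raise ValueError(f"unknown normalization mode {mode!r}")


def bray_curtis_condensed(m: pd.DataFrame) -> np.ndarray:
    """Condensed Bray-Curtis distances between sample rows."""
    return pdist(m.to_numpy(dtype=float), metric="braycurtis")


def cluster_samples(m: pd.DataFrame) -> SampleClustering:
    """Ward linkage on Bray-Curtis distances between sample rows.

    Leaf order is scipy's deterministic dendrogram convention (ties broken
    by cluster formation order).
    """
    if len(m) < 2:
        raise ValueError("clustering requires at least 2 samples")
    d = bray_curtis_condensed(m)
    link = hierarchy.linkage(d, method="ward")
    return SampleClustering(list(m.index), link, d)


def pca_loadings(
    m: pd.DataFrame, n_top: int = 20, weighted: bool = True
) -> pd.DataFrame:
    """Features ranked by loading magnitude in the first two components.

    With ``weighted=True`` (biplot convention) each component's loadings are
    scaled by the square root of its explained variance before taking the
    Euclidean norm, so arrow lengths match standard biplots.
    """
    values = m.to_numpy(dtype=float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    if np.allclose(values.var(axis=0), 0):
        raise ValueError("constant matrix: no variance to decompose")
    pca = PCA(n_components=2)
    pca.fit(values)
    load = pca.components_.T  # features × 2
    if weighted:
        load = load * np.sqrt(pca.explained_variance_)
    magnitude = np.linalg.norm(load, axis=1)
    frame = pd.DataFrame(
        {"pc1": load[:, 0], "pc2": load[:, 1], "magnitude": magnitude},
        index=m.columns,
    )
    frame = frame.iloc[np.lexsort((frame.index, -frame["magnitude"]))]
    return frame.head(n_top)


def chao1(counts) -> float:
    """Chao1 richness: S_obs + F1²/(2·F2), or the bias-corrected form
    S_obs + F1(F1−1)/(2(F2+1)) when no doubletons are observed."""
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("empty count vector")
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def mann_whitney(a, b, exact_threshold: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (rank-sum) test.

    Exact p when the smaller group has at most ``exact_threshold``
    observations and the data carry no ties; normal approximation with tie
    correction otherwise.  Fully tied data give p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        log.warning("all observations tied; p = 1")
        return float(a.size * b.size / 2), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(a.size, b.size) <= exact_threshold and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_anomaly(
    m: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> list[GroupComparison]:
    """Per-feature anomaly (mean_a − mean_b)/(mean_a + mean_b) with a
    Mann-Whitney p-value between the two sample groups.

    Features with zero mean in both groups are skipped.  Raw p-values are
    reported (matching the figure convention); a Benjamini-Hochberg column
    is attached for convenience.
    """
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    sub_a, sub_b = m.loc[group_a], m.loc[group_b]
    rows = []
    for feature in m.columns:
        ma, mb = float(sub_a[feature].mean()), float(sub_b[feature].mean())
        if ma + mb == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u, p = mann_whitney(sub_a[feature].to_numpy(), sub_b[feature].to_numpy())
        rows.append((feature, ma, mb, (ma - mb) / (ma + mb), u, p))
    if not rows:
        return []
    p_bh = multipletests([r[5] for r in rows], method="fdr_bh")[1]
    return [
        GroupComparison(*row, float(adj)) for row, adj in zip(rows, p_bh)
    ]


def distance_agreement(d1, d2) -> tuple[float, float, float]:
    """OLS of d1 on d2 over all sample pairs: (slope, intercept, r²)."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("condensed distance vectors differ in length")
    if d1.size < 3:
        raise ValueError("need at least 3 sample pairs")
    fit = stats.linregress(d2, d1)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
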