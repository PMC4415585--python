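"""Community-level statistics and genome-function networks.

Covers the downstream comparisons of an enrichment-microcosm experiment:
per-sample normalisation of taxon/function tables to 100%, Kruskal-Wallis
tests for shifts between conditions, unique/core function accounting,
bipartite genome-function presence networks, and classification of samples
by their recruitment profiles (Ward linkage on Euclidean distances).

The Kruskal-Wallis statistic is computed from the rank formula with tie
correction; p-values use the chi-square approximation with (groups - 1)
degrees of freedom. No multiple-testing correction is applied by default
(raw p < 0.05 is the conventional readout here); a Benjamini-Hochberg
option is available and flagged in output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2, rankdata
from sklearn.metrics import adjusted_rand_score

from .binning import ClusterTree
from .markers import FunctionCatalog


@dataclass
class AbundanceTable:
    """Samples x features matrix of non-negative values."""

    data: pd.DataFrame  # index: sample ids, columns: feature ids
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")


@dataclass
class KWResult:
    feature_id: str
    H: float
    df: int
    p_value: float


@dataclass
class BiomeClassification:
    sample_ids: list[str]
    tree: ClusterTree
    labels: dict[str, int] | None = None
    ari: float | None = None


def normalize_to_percent(table: AbundanceTable) -> AbundanceTable:
    """Scale every sample (row) to sum to 100."""
    sums = table.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero samples cannot be normalized: {list(zero.index)[:3]}")
    return AbundanceTable(data=table.data.div(sums, axis=0) * 100.0, normalized=True)


def kruskal_wallis(
    values: Sequence[float], groups: Sequence[str], feature_id: str = ""
) -> KWResult:
    """Kruskal-Wallis H with tie correction and chi-square p-value.

    H = 12/(N(N+1)) * sum_j n_j (rbar_j - (N+1)/2)^2, divided by
    1 - sum(t^3 - t)/(N^3 - N) over tie groups. All values identical gives
    H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if any((groups == g).sum() == 0 for g in labels):  # pragma: no cover
        raise ValueError("empty group")
    N = values.size
    ranks = rankdata(values)
    H = 0.0
    for g in labels:
        r = ranks[groups == g]
        H += r.size * (r.mean() - (N + 1) / 2.0) ** 2
    H *= 12.0 / (N * (N + 1))
    _, tie_counts = np.unique(values, return_counts=True)
    denom = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (N**3 - N)
    if denom <= 0:  # every value identical
        return KWResult(feature_id, 0.0, len(labels) - 1, 1.0)
    H /= denom
    df = len(labels) - 1
    p = float(chi2.sf(H, df))
    return KWResult(feature_id, float(H), df, max(min(p, 1.0), np.nextafter(0, 1)))


def kruskal_wallis_table(
    table: AbundanceTable, groups: dict[str, str], bh_correct: bool = False
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis across condition groups.

    ``groups`` maps sample id -> condition label. Returns a DataFrame with
    H, df, p_value (and q_value when ``bh_correct``), sorted by p.
    """
    gvec = [groups[s] for s in table.data.index]
    rows = []
    for feat in table.data.columns:
        r = kruskal_wallis(table.data[feat].to_numpy(), gvec, feature_id=feat)
        rows.append((feat, r.H, r.df, r.p_value))
    out = pd.DataFrame(rows, columns=["feature_id", "H", "df", "p_value"])
    if bh_correct:
        p = out["p_value"].to_numpy()
        order = np.argsort(p)
        q = np.empty_like(p)
        m = len(p)
        prev = 1.0
        for rank_i, idx in list(enumerate(order))[::-1]:
            prev = min(prev, p[idx] * m / (rank_i + 1))
            q[idx] = prev
        out["q_value"] = q
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def unique_functions(catalogs: list[FunctionCatalog]) -> dict[str, int]:
    """Per-owner count of labels found in exactly one owner's catalog."""
    if len(catalogs) < 2:
        raise ValueError("need at least two catalogs")
    count: dict[str, int] = {}
    for c in catalogs:
        others = frozenset().union(*(o.labels for o in catalogs if o is not c))
        count[c.owner_id] = len(c.labels - others)
    return count


def fold_increase(count_a: float, count_b: float) -> float:
    """Ratio of unique-function counts; rounded to an integer when >= 10."""
    if count_b == 0:
        raise ZeroDivisionError("reference count is zero")
    ratio = count_a / count_b
    return float(round(ratio)) if ratio >= 10 else ratio


def core_functions(catalogs: list[FunctionCatalog]) -> int:
    """Size of the intersection of all catalogs (the group's core)."""
    if not catalogs:
        raise ValueError("need at least one catalog")
    core = catalogs[0].labels
    for c in catalogs[1:]:
        core = core & c.labels
    return len(core)


def build_bipartite(catalogs: list[FunctionCatalog]) -> nx.Graph:
    """Bipartite owner-function presence network.

    Owner nodes carry ``bipartite=0``, function nodes ``bipartite=1``; an
    edge means the owner's catalog contains the function. Function-node
    degree is the number of owners carrying that function.
    """
    if not catalogs:
        raise ValueError("need at least one catalog")
    G = nx.Graph()
    for c in catalogs:
        G.add_node(c.owner_id, bipartite=0)
    for c in catalogs:
        for lab in c.labels:
            if lab not in G:
                G.add_node(lab, bipartite=1)
            G.add_edge(c.owner_id, lab)
    return G


def _linkage_to_tree(Z: np.ndarray, leaf_ids: list[str]) -> ClusterTree:
    merges = [(int(a), int(b), float(h), int(s)) for a, b, h, s in Z]
    return ClusterTree(leaf_ids=leaf_ids, merges=merges)


def classify_biomes(
    profiles: AbundanceTable,
    planted_groups: dict[str, int] | None = None,
) -> BiomeClassification:
    """Cluster samples by recruitment profile: Ward linkage, Euclidean.

    With planted group labels, cuts the dendrogram at k = number of groups
    and reports the adjusted Rand index of the recovered partition.
    """
    samples = list(profiles.data.index)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    X = profiles.data.to_numpy(dtype=float)
    Z = linkage(pdist(X, metric="euclidean"), method="ward")
    tree = _linkage_to_tree(Z, samples)
    ari = None
    if planted_groups is not None:
        k = len(set(planted_groups.values()))
        clusters = tree.cut(n_clusters=k)
        pred = {}
        for ci, members in enumerate(clusters):
            for s in members:
                pred[s] = ci
        ari = float(
            adjusted_rand_score(
                [planted_groups[s] for s in samples], [pred[s] for s in samples]
            )
        )
    return BiomeClassification(
        sample_ids=samples, tree=tree, labels=planted_groups, ari=ari
    )
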