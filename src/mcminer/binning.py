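"""Composition-based binning of contig fragments into draft genomes.

Fragments (10-20 kb sections of contigs/scaffolds) are compared by Euclidean
distance between their canonical tetranucleotide profiles, organised into a
dendrogram by agglomerative clustering, and cut into bins. Coverage and GC
are used afterwards as coherence checks — a clean bin has stable coverage and
a narrow GC range — not as clustering features (an opt-in combined feature
space is available).

The agglomeration is implemented as an explicit rescan over all cluster
pairs each step with a deterministic tie-break: among pairs at equal
distance, merge the one with the lexicographically smallest (min leaf id,
max leaf id). This makes the merge sequence reproducible and directly
comparable to a brute-force oracle; scipy's nearest-neighbour-chain linkage
produces the same dendrogram for monotone linkages but not a guaranteed
merge order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import TetraProfile

LINKAGES = ("average", "complete", "ward")


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.matrix < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass
class ClusterTree:
    """Dendrogram as a merge list.

    ``merges[i] = (node_a, node_b, height, size)``: nodes 0..n-1 are leaves
    (in ``leaf_ids`` order), node n+i is the cluster created by merge i.
    Compatible with scipy's linkage matrix layout.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def as_linkage(self) -> np.ndarray:
        return np.array(self.merges, dtype=float).reshape(-1, 4)

    def cut(self, n_clusters: int | None = None, height: float | None = None) -> list[list[str]]:
        """Cut into flat clusters by count or by merge height."""
        n = self.n_leaves
        if n_clusters is not None:
            if not 1 <= n_clusters <= n:
                raise ValueError("n_clusters out of range")
            n_merges = n - n_clusters
        elif height is not None:
            n_merges = sum(1 for m in self.merges if m[2] <= height)
        else:
            raise ValueError("give n_clusters or height")
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for i, (a, b, _h, _s) in enumerate(self.merges[:n_merges]):
            members[n + i] = members.pop(int(a)) + members.pop(int(b))
        return [
            sorted(self.leaf_ids[j] for j in leaves)
            for leaves in sorted(members.values(), key=min)
        ]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: self.leaf_ids[i] for i in range(n)}
        for i, (a, b, h, _s) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + i] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return nodes[root] + ";"


@dataclass
class Bin:
    bin_id: str
    fragment_ids: list[str]
    contig_ids: list[str] = field(default_factory=list)
    coverage_mean: float = float("nan")
    coverage_cv: float = float("nan")
    gc_mean: float = float("nan")
    gc_range: float = float("nan")
    total_length: int = 0
    flagged_incoherent: bool = False


@dataclass
class BinEvaluation:
    purity: dict[str, float]
    recall: dict[str, float]
    accuracy: float


def pairwise_distance(profiles: list[TetraProfile], ids: list[str] | None = None) -> DistanceMatrix:
    """Euclidean distance matrix between tetranucleotide profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    X = np.stack([p.vector for p in profiles])
    if ids is None:
        ids = [f"item{i}" for i in range(len(profiles))]
    if len(ids) != len(profiles):
        raise ValueError("ids length mismatch")
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    D = np.sqrt(d2)
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(ids=list(ids), matrix=D)


def _cluster_distance(
    D: np.ndarray, a: list[int], b: list[int], linkage: str, centroids=None, sizes=None
) -> float:
    block = D[np.ix_(a, b)]
    if linkage == "average":
        return float(block.mean())
    if linkage == "complete":
        return float(block.max())
    raise ValueError(f"unknown linkage {linkage!r}")


def build_tree(dist: DistanceMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering by explicit rescan of all pairs each step.

    Average and complete linkage recompute cluster-cluster distances from the
    original matrix; Ward recomputes the merge cost from squared Euclidean
    distances via the centroid identity. Ties are broken on the lexicographically smallest
    (min leaf id, max leaf id) pair, making the merge sequence deterministic.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    n = len(dist.ids)
    D0 = dist.matrix
    # active clusters: node id -> member leaf indices
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    # current inter-cluster distances, keyed frozenset({u, v})
    cur: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            cur[frozenset((i, j))] = float(D0[i, j])
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(members) > 1:
        # pick min-distance pair; tie-break on sorted leaf-id signature
        best_key, best_d, best_sig = None, np.inf, None
        for key, d in cur.items():
            u, v = sorted(key)
            sig = (min(min(members[u]), min(members[v])),
                   max(min(members[u]), min(members[v])))
            if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and sig < best_sig):
                best_key, best_d, best_sig = key, d, sig
        u, v = sorted(best_key)
        mu, mv = members.pop(u), members.pop(v)
        merged = mu + mv
        merges.append((u, v, best_d, len(merged)))
        # drop stale distances, compute distances to the new cluster
        for w in list(members):
            cur.pop(frozenset((u, w)), None)
            cur.pop(frozenset((v, w)), None)
        cur.pop(frozenset((u, v)))
        for w, mw in members.items():
            if linkage in ("average", "complete"):
                d = _cluster_distance(D0, merged, mw, linkage)
            else:
                d = np.sqrt(_ward_d2(D0, merged, mw))
            cur[frozenset((next_id, w))] = d
        members[next_id] = merged
        next_id += 1
    return ClusterTree(leaf_ids=list(dist.ids), merges=merges)


def _ward_d2(D0: np.ndarray, a: list[int], b: list[int]) -> float:
    """Ward merge cost from the original Euclidean matrix (centroid form)."""
    na, nb = len(a), len(b)
    # squared centroid distance via the identity on pairwise squared distances
    dab = np.mean(D0[np.ix_(a, b)] ** 2)
    daa = np.mean(D0[np.ix_(a, a)] ** 2) if na > 1 else 0.0
    dbb = np.mean(D0[np.ix_(b, b)] ** 2) if nb > 1 else 0.0
    cent2 = dab - 0.5 * daa - 0.5 * dbb
    return max(2.0 * na * nb / (na + nb) * cent2, 0.0)


def extract_bins(
    tree: ClusterTree,
    n_bins: int | None = None,
    height: float | None = None,
    manual: list[list[str]] | None = None,
) -> list[Bin]:
    """Cut the dendrogram into bins (automatic) or honour supervised lists.

    Manual mode emulates human-curated binning: explicit leaf-id lists become
    bins; leaves in no list fall into a trailing ``unbinned`` bin. Lists may
    not overlap.
    """
    if manual is not None:
        seen: set[str] = set()
        for lst in manual:
            dup = seen & set(lst)
            if dup:
                raise ValueError(f"manual bins overlap on {sorted(dup)}")
            unknown = set(lst) - set(tree.leaf_ids)
            if unknown:
                raise ValueError(f"unknown fragment ids {sorted(unknown)}")
            seen |= set(lst)
        groups = [sorted(lst) for lst in manual]
        rest = sorted(set(tree.leaf_ids) - seen)
        bins = [
            Bin(bin_id=f"bin{i:03d}", fragment_ids=g) for i, g in enumerate(groups)
        ]
        if rest:
            bins.append(Bin(bin_id="unbinned", fragment_ids=rest))
        return bins
    groups = tree.cut(n_clusters=n_bins, height=height)
    return [Bin(bin_id=f"bin{i:03d}", fragment_ids=g) for i, g in enumerate(groups)]


def bin_coherence(
    b: Bin,
    fragment_meta: pd.DataFrame,
    cv_threshold: float = 0.5,
) -> Bin:
    """Fill coverage/GC coherence statistics of a bin in place.

    ``fragment_meta`` is indexed by fragment id with columns
    ``contig_id, coverage, gc, length``. Coverage CV is sd/mean (ddof=1;
    0 for a single member); bins above ``cv_threshold`` are flagged as
    incoherent — the composition cluster mixes structures at different
    abundances.
    """
    missing = [f for f in b.fragment_ids if f not in fragment_meta.index]
    if missing:
        raise KeyError(f"no metadata for fragments {missing[:3]}...")
    sub = fragment_meta.loc[b.fragment_ids]
    cov = sub["coverage"].to_numpy(dtype=float)
    gc = sub["gc"].to_numpy(dtype=float)
    b.contig_ids = sorted(set(sub["contig_id"]))
    b.coverage_mean = float(cov.mean())
    b.coverage_cv = 0.0 if len(cov) < 2 else float(cov.std(ddof=1) / cov.mean())
    b.gc_mean = float(gc.mean())
    b.gc_range = float(gc.max() - gc.min())
    b.total_length = int(sub["length"].sum())
    b.flagged_incoherent = b.coverage_cv > cv_threshold
    return b


def evaluate_binning(bins: list[Bin], truth: dict[str, str]) -> BinEvaluation:
    """Score bins against known fragment origins.

    Purity: per bin, the largest fraction of members from one source.
    Recall: per source, the largest fraction captured in one bin.
    Accuracy: bins matched to sources by greedy maximum overlap; accuracy is
    the fraction of fragments landing in the bin matched to their source.
    """
    missing = [f for b in bins for f in b.fragment_ids if f not in truth]
    if missing:
        raise KeyError(f"truth missing for {missing[:3]}...")
    sources = sorted(set(truth.values()))
    counts = pd.DataFrame(0, index=[b.bin_id for b in bins], columns=sources)
    for b in bins:
        for f in b.fragment_ids:
            counts.loc[b.bin_id, truth[f]] += 1
    purity = {
        b.bin_id: (counts.loc[b.bin_id].max() / max(len(b.fragment_ids), 1))
        if b.fragment_ids
        else 0.0
        for b in bins
    }
    src_tot = counts.sum(axis=0)
    recall = {
        s: float(counts[s].max() / src_tot[s]) if src_tot[s] else 0.0 for s in sources
    }
    # greedy max-overlap matching
    pool = counts.copy()
    correct = 0
    while pool.size and pool.to_numpy().max() > 0:
        idx = np.unravel_index(np.argmax(pool.to_numpy()), pool.shape)
        correct += int(pool.iloc[idx])
        pool = pool.drop(index=pool.index[idx[0]], columns=pool.columns[idx[1]])
    total = int(counts.to_numpy().sum())
    return BinEvaluation(
        purity={k: float(v) for k, v in purity.items()},
        recall=recall,
        accuracy=correct / total if total else 0.0,
    )
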