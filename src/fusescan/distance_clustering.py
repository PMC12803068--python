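"""Multimodality detection on per-gene difference distributions.

Per gene, the signed prefix-suffix differences observed across a genome
collection form a 1D distribution (each genome contributes one point).
Recurrent structural variation shows up as distinct density peaks, found
with a 1D DBSCAN (eps = 800 bp, min_samples = 25 by default). A gene is
*multimodal* when at least two non-noise clusters exist; the fusion-gene
cascade additionally requires one cluster centered near zero (the intact
allele) and at least one cluster centered above 800 bp (a substantial
intervening segment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_EPS = 800.0
DEFAULT_MIN_SAMPLES = 25
POSITIVE_PEAK_MIN = 800.0  # bp; minimum mean for a "split" cluster


@dataclass
class DifferenceDistribution:
    """Unique difference values with genome multiplicities for one gene."""

    gene_id: str
    values: list[tuple[float, int]]  # (difference, multiplicity >= 1)

    @classmethod
    def from_measurements(cls, meas: pd.DataFrame,
                          gene_id: str) -> "DifferenceDistribution":
        sub = meas[(meas.gene_id == gene_id) & (meas.status == "ok")]
        counts = sub["difference"].value_counts().sort_index()
        return cls(gene_id, [(float(v), int(c)) for v, c in counts.items()])

    def expand(self) -> np.ndarray:
        """One point per genome (multiplicity expansion), ascending."""
        return np.repeat([v for v, _ in self.values],
                         [m for _, m in self.values]).astype(float)


@dataclass
class ClusterSet:
    gene_id: str
    eps: float
    min_samples: int
    clusters: list[tuple[int, float, int]]  # (cluster_id, mean, size)
    noise_count: int
    assignment: dict[float, int]  # difference value -> cluster_id (-1 noise)

    def cluster_ids(self) -> list[int]:
        return [cid for cid, _, _ in self.clusters]

    def mean_of(self, cluster_id: int) -> float:
        for cid, mean, _ in self.clusters:
            if cid == cluster_id:
                return mean
        raise KeyError(cluster_id)

    def size_of(self, cluster_id: int) -> int:
        for cid, _, size in self.clusters:
            if cid == cluster_id:
                return size
        raise KeyError(cluster_id)


@dataclass
class GeneScreenCall:
    gene_id: str
    multimodal: bool
    zero_cluster_id: int | None
    positive_cluster_ids: list[int] = field(default_factory=list)
    stage_passed: int = 0


def dbscan_1d(points: np.ndarray, eps: float,
              min_samples: int) -> np.ndarray:
    """DBSCAN on sorted-scan 1D points; returns labels (-1 = noise).

    Core points have >= min_samples neighbours (self included) within eps.
    Clusters are eps-chains of core points plus border points; a border
    point reachable from two clusters is assigned to the lower-valued
    (left) one, deterministically. Labels are provisional scan order; the
    caller relabels.
    """
    n = len(points)
    order = np.argsort(points, kind="stable")
    x = points[order]
    # neighbour counts within eps via two binary searches
    left = np.searchsorted(x, x - eps, side="left")
    right = np.searchsorted(x, x + eps, side="right")
    is_core = (right - left) >= min_samples

    labels_sorted = np.full(n, -1, dtype=int)
    cid = -1
    prev_core_idx = -1
    for i in range(n):
        if not is_core[i]:
            continue
        if prev_core_idx >= 0 and x[i] - x[prev_core_idx] <= eps:
            labels_sorted[i] = labels_sorted[prev_core_idx]
        else:
            cid += 1
            labels_sorted[i] = cid
        prev_core_idx = i
    # border points: within eps of some core point; ties go left
    core_positions = np.flatnonzero(is_core)
    if core_positions.size:
        core_x = x[core_positions]
        for i in range(n):
            if labels_sorted[i] != -1:
                continue
            j = np.searchsorted(core_x, x[i])
            # nearest core on the left, then right; prefer left on tie
            best = -1
            if j > 0 and x[i] - core_x[j - 1] <= eps:
                best = core_positions[j - 1]
            elif j < core_x.size and core_x[j] - x[i] <= eps:
                best = core_positions[j]
            if best >= 0:
                labels_sorted[i] = labels_sorted[best]
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def cluster_differences(dist: DifferenceDistribution,
                        eps: float = DEFAULT_EPS,
                        min_samples: int = DEFAULT_MIN_SAMPLES) -> ClusterSet:
    """Density-cluster a gene's difference distribution.

    Each genome contributes one point, so min_samples counts genomes.
    Noise points are excluded from cluster statistics. Cluster ids are
    assigned by ascending |mean|, so cluster 0 is the intact-most cluster.
    """
    if not dist.values:
        raise ValueError(f"gene {dist.gene_id!r}: empty distribution")
    points = dist.expand()
    labels = dbscan_1d(points, eps, min_samples)

    raw_ids = sorted(set(labels) - {-1})
    stats = []
    for rid in raw_ids:
        members = points[labels == rid]
        stats.append((rid, float(members.mean()), int(members.size)))
    # relabel by ascending |mean| (ties by mean) so cluster 0 is intact-most
    stats.sort(key=lambda t: (abs(t[1]), t[1]))
    relabel = {rid: new for new, (rid, _, _) in enumerate(stats)}
    clusters = [(relabel[rid], mean, size) for rid, mean, size in stats]
    clusters.sort(key=lambda t: t[0])

    assignment: dict[float, int] = {}
    for v, _ in dist.values:
        idx = np.flatnonzero(points == v)[0]
        lab = labels[idx]
        assignment[v] = relabel[lab] if lab != -1 else -1
    noise = int((labels == -1).sum())
    return ClusterSet(dist.gene_id, eps, min_samples, clusters, noise,
                      assignment)


def screen_gene(clusters: ClusterSet,
                zero_tolerance: float | None = None,
                positive_peak_min: float = POSITIVE_PEAK_MIN,
                ) -> GeneScreenCall:
    """Apply cascade stages 1-2 to a gene's cluster structure.

    Stage 1 (multimodal): >= 2 non-noise clusters. Stage 2 (peak shape):
    additionally one cluster mean within ``zero_tolerance`` of 0 (default:
    eps) and >= 1 cluster mean > ``positive_peak_min``. Genes whose only
    extra peaks are small positive shifts (internal-deletion scale) stop at
    stage 1.
    """
    tol = clusters.eps if zero_tolerance is None else zero_tolerance
    multimodal = len(clusters.clusters) >= 2
    zero_id = None
    positive_ids = []
    for cid, mean, _ in clusters.clusters:
        if abs(mean) <= tol and zero_id is None:
            zero_id = cid
        if mean > positive_peak_min:
            positive_ids.append(cid)
    stage = 0
    if multimodal:
        stage = 1
        if zero_id is not None and positive_ids:
            stage = 2
    return GeneScreenCall(clusters.gene_id, multimodal, zero_id,
                          positive_ids, stage)


def cluster_all_genes(meas: pd.DataFrame, eps: float = DEFAULT_EPS,
                      min_samples: int = DEFAULT_MIN_SAMPLES,
                      ) -> tuple[pd.DataFrame, pd.DataFrame,
                                 dict[str, ClusterSet]]:
    """Cluster every gene in a measurements table.

    Returns (clusters_df, calls_df, cluster_sets) in the TSV schema.
    """
    cluster_rows = []
    call_rows = []
    sets: dict[str, ClusterSet] = {}
    for gene_id in sorted(meas.gene_id.unique()):
        dist = DifferenceDistribution.from_measurements(meas, gene_id)
        if not dist.values:
            continue
        cs = cluster_differences(dist, eps=eps, min_samples=min_samples)
        sets[gene_id] = cs
        for cid, mean, size in cs.clusters:
            cluster_rows.append((gene_id, cid, mean, size))
        call = screen_gene(cs)
        call_rows.append((gene_id, call.stage_passed, call.multimodal,
                          call.zero_cluster_id,
                          ",".join(map(str, call.positive_cluster_ids))))
    clusters_df = pd.DataFrame(
        cluster_rows, columns=["gene_id", "cluster_id", "mean_difference",
                               "size"])
    calls_df = pd.DataFrame(
        call_rows, columns=["gene_id", "stage_passed", "multimodal",
                            "zero_cluster_id", "positive_cluster_ids"])
    return clusters_df, calls_df, sets
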