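"""Phylogenetic filtering: is the split or the intact state ancestral?

For a gene passing the multimodality filters, genomes are sampled evenly
across distance clusters, the locus (anchor to anchor) is extracted and
masked out of each genome, pairwise distances between masked genomes are
estimated from fixed-size bottom min-hash sketches via the Mash distance
transform, a neighbor-joining tree is built and rooted on the more distant
of two outgroup genomes, and the cluster label of the ingroup MRCA is
inferred by multi-state Fitch parsimony. A gene is consistent with a
deletion-born fusion when the MRCA state is a split (positive-difference)
cluster and at least one descendant carries the intact (zero) cluster;
an intact MRCA instead indicates disruption of an ancestral gene, usually
by insertion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .kmer_screen import LocusMeasurement, QueryGene, reverse_complement
from .distance_clustering import ClusterSet

DEFAULT_QUOTA = 300
DEFAULT_SKETCH_SIZE = 1000
DEFAULT_SKETCH_K = 21


@dataclass
class LocusExtraction:
    genome_id: str
    locus_seq: str
    masked_genome: list[tuple[str, str]]  # contigs with the span N-masked


@dataclass
class RootedStateTree:
    topology: TreeNode
    leaf_states: dict[str, int]
    outgroup_ids: tuple[str, str]
    rooted_on: str

    def newick(self) -> str:
        return str(self.topology).strip()


@dataclass
class AncestralCall:
    gene_id: str
    mrca_state_set: frozenset[int]
    parsimony_score: int
    classification: str  # "split_ancestor" | "intact_ancestor" | "ambiguous"


# ---------------------------------------------------------------------------
# Cluster-stratified genome sampling
# ---------------------------------------------------------------------------

def sample_by_cluster(cluster_members: dict[int, list[str]], quota: int,
                      seed: int) -> list[str]:
    """Draw ``quota`` genomes split evenly across clusters.

    Clusters smaller than their even share contribute all members; the
    shortfall is redistributed proportionally to remaining cluster sizes.
    Deterministic for a fixed seed.
    """
    total = sum(len(v) for v in cluster_members.values())
    if total < 2:
        raise ValueError("need at least 2 genomes to sample")
    quota = min(quota, total)
    rng = np.random.default_rng(seed)
    cids = sorted(cluster_members)
    sizes = {cid: len(cluster_members[cid]) for cid in cids}
    # even split, capped by availability
    base = quota // len(cids)
    extra = quota - base * len(cids)
    take = {}
    for i, cid in enumerate(cids):
        want = base + (1 if i < extra else 0)
        take[cid] = min(want, sizes[cid])
    # redistribute shortfall proportionally to remaining cluster capacity
    left = quota - sum(take.values())
    while left > 0:
        capacity = {cid: sizes[cid] - take[cid] for cid in cids}
        total_cap = sum(capacity.values())
        if total_cap == 0:
            break
        shares = {cid: left * capacity[cid] / total_cap for cid in cids}
        added = 0
        for cid in cids:
            add = min(int(shares[cid]), capacity[cid])
            take[cid] += add
            added += add
        if added == 0:  # largest-remainder top-up, deterministic order
            for cid in sorted(cids, key=lambda c: -(shares[c] % 1)):
                if left - added > 0 and capacity[cid] - 0 > 0 and \
                        take[cid] < sizes[cid]:
                    take[cid] += 1
                    added += 1
        left -= added
    sampled: list[str] = []
    for cid in cids:
        members = sorted(cluster_members[cid])
        idx = rng.choice(len(members), size=take[cid], replace=False)
        sampled.extend(members[i] for i in sorted(idx))
    return sampled


def cluster_members_from_assignment(
        clusters: ClusterSet,
        genome_values: dict[str, float]) -> dict[int, list[str]]:
    """Map cluster_id -> genome ids using the value->cluster assignment."""
    out: dict[int, list[str]] = {}
    for gid, v in genome_values.items():
        cid = clusters.assignment.get(float(v), -1)
        if cid != -1:
            out.setdefault(cid, []).append(gid)
    return out


# ---------------------------------------------------------------------------
# Locus extraction and masking
# ---------------------------------------------------------------------------

def extract_and_mask(contigs: list[tuple[str, str]],
                     measurement: LocusMeasurement,
                     query: QueryGene) -> LocusExtraction:
    """Cut out the anchored locus and N-mask it in the genome.

    The locus runs from the prefix-window start through the suffix-window
    end (inclusive of both anchors). For a reverse-complement placement the
    extracted sequence is reverse-complemented into gene orientation.
    """
    if measurement.status != "ok":
        raise ValueError("measurement must have status ok")
    k = query.k
    if measurement.orientation == "forward":
        lo = measurement.prefix_start
        hi = measurement.suffix_start + k
    else:
        lo = measurement.suffix_start
        hi = measurement.prefix_start + k
    masked = []
    locus_seq = None
    for contig_id, seq in contigs:
        if contig_id == measurement.contig_id:
            if lo < 0 or hi > len(seq):
                raise ValueError("locus coordinates out of contig bounds")
            region = seq[lo:hi]
            locus_seq = (region if measurement.orientation == "forward"
                         else reverse_complement(region))
            seq = seq[:lo] + "N" * (hi - lo) + seq[hi:]
        masked.append((contig_id, seq))
    if locus_seq is None:
        raise ValueError(f"contig {measurement.contig_id!r} not in genome")
    return LocusExtraction(measurement.genome_id, locus_seq, masked)


# ---------------------------------------------------------------------------
# Bottom-sketch Mash distances
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _c
_RC_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"TGCA", range(4)):
    _RC_CODE[_b] = _c


def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer; decorrelates lexicographic k-mer codes."""
    x = x.astype(np.uint64, copy=True)
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


def genome_kmer_hashes(contigs: list[tuple[str, str]],
                       k: int = DEFAULT_SKETCH_K,
                       ) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Per-contig canonical k-mer hashes and validity flags by position.

    Returns [(contig_id, hashes, ok)] where hashes[i] is the canonical
    hash of the k-mer starting at position i and ok[i] is False when that
    window contains a non-ACGT character. Strand symmetry comes from
    hashing both orientations and keeping the elementwise minimum.
    """
    assert 2 * k <= 64
    out = []
    shift = np.uint64(2 * (k - 1))
    for contig_id, seq in contigs:
        raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        codes = _BASE_CODE[raw]
        rc_codes = _RC_CODE[raw]
        n = len(codes) - k + 1
        if n <= 0:
            continue
        valid = codes != 255
        # rolling 2-bit pack, vectorized over positions
        fwd = np.zeros(len(codes), dtype=np.uint64)
        rev = np.zeros(len(codes), dtype=np.uint64)
        ok = np.ones(n, dtype=bool)
        for j in range(k):
            c = codes[j:j + n]
            r = rc_codes[j:j + n]
            ok &= valid[j:j + n]
            fwd[:n] = (fwd[:n] << np.uint64(2)) | c.astype(np.uint64)
            rev[:n] = (rev[:n] >> np.uint64(2)) | (
                r.astype(np.uint64) << shift)
        mask = np.uint64((1 << (2 * k)) - 1)
        f = _mix64(fwd[:n] & mask)
        r = _mix64(rev[:n] & mask)
        out.append((contig_id, np.minimum(f, r), ok))
    return out


def sketch_from_hashes(hash_arrays: list[tuple[str, np.ndarray, np.ndarray]],
                       sketch_size: int = DEFAULT_SKETCH_SIZE,
                       k: int = DEFAULT_SKETCH_K,
                       exclude: dict[str, tuple[int, int]] | None = None,
                       _sorted_counts: tuple[np.ndarray, np.ndarray]
                       | None = None) -> np.ndarray:
    """Bottom-s sketch from precomputed hashes, optionally excluding every
    k-mer overlapping an interval per contig (equivalent to N-masking that
    interval before sketching).

    ``_sorted_counts`` is an optional cache of the genome-wide
    (sorted unique hashes, counts) pair; with it, exclusion only hashes
    the window and removes values whose occurrences all fall inside it.
    """
    if _sorted_counts is not None:
        uniq, counts = _sorted_counts
        if not exclude:
            return uniq[:sketch_size]
        win_parts = []
        for contig_id, h, ok in hash_arrays:
            if contig_id in exclude:
                lo, hi = exclude[contig_id]
                a = max(0, lo - k + 1)
                win_parts.append(h[a:hi][ok[a:hi]])
        if not win_parts:
            return uniq[:sketch_size]
        wu, wc = np.unique(np.concatenate(win_parts), return_counts=True)
        idx = np.searchsorted(uniq, wu)
        gone = wu[wc == counts[idx]]
        head = uniq[:sketch_size + gone.size]
        head = head[~np.isin(head, gone, assume_unique=True)]
        return head[:sketch_size]
    parts = []
    for contig_id, h, ok in hash_arrays:
        use = ok
        if exclude and contig_id in exclude:
            lo, hi = exclude[contig_id]
            use = ok.copy()
            a = max(0, lo - k + 1)
            use[a:hi] = False
        sel = h[use]
        if sel.size:
            parts.append(sel)
    if not parts:
        return np.empty(0, dtype=np.uint64)
    uniq = np.unique(np.concatenate(parts))
    return uniq[:sketch_size]


def sorted_hash_counts(hash_arrays: list[tuple[str, np.ndarray, np.ndarray]],
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Genome-wide (sorted unique hashes, counts) for sketch caching."""
    parts = [h[ok] for _, h, ok in hash_arrays if h[ok].size]
    if not parts:
        e = np.empty(0, dtype=np.uint64)
        return e, e.astype(np.int64)
    return np.unique(np.concatenate(parts), return_counts=True)


def sketch_genome(contigs: list[tuple[str, str]],
                  sketch_size: int = DEFAULT_SKETCH_SIZE,
                  k: int = DEFAULT_SKETCH_K) -> np.ndarray:
    """Bottom-s min-hash sketch over canonical k-mer hashes.

    k-mers containing non-ACGT characters (including masked N runs) are
    skipped.
    """
    return sketch_from_hashes(genome_kmer_hashes(contigs, k), sketch_size, k)


def mash_distance(sketch_a: np.ndarray, sketch_b: np.ndarray,
                  sketch_size: int = DEFAULT_SKETCH_SIZE,
                  k: int = DEFAULT_SKETCH_K) -> float:
    """Mash distance d = -ln(2j/(1+j))/k from merged bottom sketches.

    j is estimated as the fraction of the s smallest hashes of the union
    that occur in both sketches. Identical sketches give d = 0; disjoint
    sketches give +inf (capped at 1.0 for tree building).
    """
    if sketch_a.size == 0 or sketch_b.size == 0:
        return 1.0
    # sketches are sorted unique; a duplicate in the merged array marks a
    # value present in both
    merged = np.concatenate([sketch_a, sketch_b])
    merged.sort(kind="mergesort")
    is_first = np.empty(merged.size, dtype=bool)
    is_first[0] = True
    np.not_equal(merged[1:], merged[:-1], out=is_first[1:])
    first_idx = np.flatnonzero(is_first)[:sketch_size]  # bottom-s of union
    denom = first_idx.size
    # a union value is shared when its first occurrence is followed by a
    # duplicate (each input sketch is unique, so a repeat means "in both")
    shared_next = np.zeros(merged.size, dtype=bool)
    shared_next[:-1] = merged[:-1] == merged[1:]
    common = int(shared_next[first_idx].sum())
    j = common / denom
    if j <= 0:
        return 1.0
    if j >= 1:
        return 0.0
    d = -np.log(2 * j / (1 + j)) / k
    return float(min(d, 1.0))


def sketch_distance_matrix(genome_sketches: dict[str, np.ndarray],
                           sketch_size: int = DEFAULT_SKETCH_SIZE,
                           k: int = DEFAULT_SKETCH_K) -> DistanceMatrix:
    ids = sorted(genome_sketches)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = mash_distance(genome_sketches[ids[i]],
                              genome_sketches[ids[j]], sketch_size, k)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


# ---------------------------------------------------------------------------
# Tree building and rooting
# ---------------------------------------------------------------------------

def build_rooted_tree(masked_genomes: dict[str, list[tuple[str, str]]],
                      outgroup_genomes: dict[str, list[tuple[str, str]]],
                      leaf_states: dict[str, int],
                      sketch_size: int = DEFAULT_SKETCH_SIZE,
                      sketch_k: int = DEFAULT_SKETCH_K,
                      sketches: dict[str, np.ndarray] | None = None,
                      ) -> RootedStateTree:
    """Sketch -> NJ -> root on the more distant of the two outgroups.

    Negative NJ branch lengths are clamped to zero. The outgroup used for
    rooting is the candidate with the largest mean distance to all other
    leaves. Precomputed ``sketches`` (one per leaf) may be supplied to skip
    the sketching step.
    """
    if len(outgroup_genomes) != 2:
        raise ValueError("exactly two outgroup genomes are required")
    if len(masked_genomes) < 3:
        raise ValueError("need at least 3 ingroup genomes")
    if sketches is None:
        sketches = {gid: sketch_genome(c, sketch_size, sketch_k)
                    for gid, c in {**masked_genomes,
                                   **outgroup_genomes}.items()}
    dm = sketch_distance_matrix(sketches, sketch_size, sketch_k)
    if np.allclose(dm.data, 0):
        raise ValueError("all sketches identical: star tree, cannot resolve")
    tree = nj(dm)
    og_ids = sorted(outgroup_genomes)
    mean_dist = {og: float(np.mean([dm[og, other] for other in dm.ids
                                    if other != og]))
                 for og in og_ids}
    chosen = max(og_ids, key=lambda og: mean_dist[og])
    rooted = tree.root_by_outgroup([chosen])
    return RootedStateTree(rooted, dict(leaf_states),
                           (og_ids[0], og_ids[1]), chosen)


# ---------------------------------------------------------------------------
# Fitch parsimony at the ingroup MRCA
# ---------------------------------------------------------------------------

def _fitch_sets(node: TreeNode, states: dict[str, frozenset[int]],
                sets: dict[int, frozenset[int]], score: list[int]) -> None:
    if node.is_tip():
        sets[id(node)] = states[node.name]
        return
    child_sets = []
    for child in node.children:
        _fitch_sets(child, states, sets, score)
        child_sets.append(sets[id(child)])
    acc = child_sets[0]
    for cs in child_sets[1:]:
        inter = acc & cs
        if inter:
            acc = inter
        else:
            acc = acc | cs
            score[0] += 1
    sets[id(node)] = acc


def fitch_mrca(tree: RootedStateTree, gene_id: str,
               zero_cluster_id: int,
               positive_cluster_ids: list[int]) -> AncestralCall:
    """Multi-state Fitch parsimony; classify the ingroup MRCA.

    Outgroup leaves carry no state and are pruned before the pass; the
    ingroup MRCA is the MRCA of all state-labeled leaves in the rooted
    tree. split_ancestor requires the MRCA set to be a single positive
    cluster with at least one zero-cluster descendant; intact_ancestor
    requires the MRCA set to be exactly the zero cluster; anything else
    (including multi-state MRCA sets) is ambiguous.
    """
    work = tree.topology.copy()
    og = set(tree.outgroup_ids)
    tips = [t for t in work.tips()]
    for t in tips:
        if t.name in og:
            t.parent.remove(t)
    work.prune()  # suppress unifurcations left by outgroup removal
    ingroup_tips = [t.name for t in work.tips()]
    missing = [n for n in ingroup_tips if n not in tree.leaf_states]
    if missing:
        raise ValueError(f"unlabeled ingroup leaves: {missing[:5]}")
    states = {n: frozenset([tree.leaf_states[n]]) for n in ingroup_tips}
    # the root of the pruned tree is the ingroup MRCA (the tree was rooted
    # on the outgroup branch); collapse any residual single-child root
    root = work
    while len(root.children) == 1:
        root = root.children[0]
    sets: dict[int, frozenset[int]] = {}
    score = [0]
    _fitch_sets(root, states, sets, score)
    mrca_set = sets[id(root)]
    observed = set(tree.leaf_states[n] for n in ingroup_tips)
    classification = "ambiguous"
    if len(mrca_set) == 1:
        (state,) = mrca_set
        if state in positive_cluster_ids and zero_cluster_id in observed:
            classification = "split_ancestor"
        elif state == zero_cluster_id:
            classification = "intact_ancestor"
    return AncestralCall(gene_id, frozenset(mrca_set), score[0],
                         classification)
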