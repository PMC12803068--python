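"""MGE/prophage coverage, the fragmented-alignment fusion filter, and
protein-family sampling statistics.

The intervening sequence between the matched anchors is aligned to a
mobile-genetic-element / prophage nucleotide database; overlapping hit
intervals are merged along the query and the covered fraction computed.
Per-locus fractions are compared between split-ancestor and
intact-ancestor loci with a two-sided Mann-Whitney U test: loci whose
positive-distance cluster reflects an insertion should be largely covered
by MGE sequence, whereas true pre-deletion (split) loci should not.

The fragmented-alignment filter flags a gene as a putative deletion-born
fusion in a target genome when its merged hit coverage is high but no
single hit explains the gene and the hits are well separated on the
genome — the signature of a gene stitched together from two distant
fragments.

Family sampling implements the three database-sampling strategies (all
families, non-singletons, families with more than 20 members) and the
sampling depth score: genomes containing a family divided by the unique
species represented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MATCH_SCORE = 2
MISMATCH_SCORE = -3
SEED_K = 13
XDROP = 20  # ungapped extension stops when score drops this far below max


@dataclass(frozen=True)
class HitInterval:
    """A local-alignment hit with coordinates on query and subject."""

    query_start: int
    query_end: int  # half-open
    subject_id: str
    score: float
    subject_start: int = 0
    subject_end: int = 0


@dataclass(frozen=True)
class CoverageFraction:
    covered_bases: int
    query_len: int

    @property
    def fraction(self) -> float:
        return self.covered_bases / self.query_len


@dataclass(frozen=True)
class FamilyRecord:
    family_id: str
    members: tuple[tuple[str, str], ...]  # (genome_id, species_id)


@dataclass(frozen=True)
class DepthScore:
    family_id: str
    n_genomes: int
    n_species: int

    @property
    def score(self) -> float:
        return self.n_genomes / self.n_species


# ---------------------------------------------------------------------------
# Seeded gapless local alignment (internal hit finder)
# ---------------------------------------------------------------------------

def _ungapped_extend(query: str, subject: str, qpos: int, spos: int,
                     length: int) -> tuple[int, int, float]:
    """X-drop ungapped extension of an exact seed in both directions.

    Returns (query_start, query_end, score) of the retained segment.
    """
    def step_score(a: str, b: str) -> int:
        return MATCH_SCORE if a == b and a in "ACGT" else MISMATCH_SCORE

    score = MATCH_SCORE * length
    # extend right
    best = score
    best_right = qpos + length
    cur = score
    i, j = qpos + length, spos + length
    while i < len(query) and j < len(subject):
        cur += step_score(query[i], subject[j])
        i += 1
        j += 1
        if cur > best:
            best, best_right = cur, i
        elif best - cur > XDROP:
            break
    # extend left
    score = best
    best_left = qpos
    cur = best
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        cur += step_score(query[i], subject[j])
        if cur > score:
            score, best_left = cur, i
        elif score - cur > XDROP:
            break
        i -= 1
        j -= 1
    return best_left, best_right, float(score)


def find_local_hits(query: str, subject: str, subject_id: str = "subject",
                    seed_k: int = SEED_K, min_score: float = 0.0,
                    both_strands: bool = True) -> list[HitInterval]:
    """Gapless local hits of query vs subject via exact seeds + extension.

    Exact ``seed_k``-mers shared between the sequences are grouped by
    alignment diagonal and extended without gaps under an X-drop rule with
    match +2 / mismatch -3 scoring. Overlapping extensions on the same
    diagonal are reported once. Reverse-strand hits (query matching the
    subject's reverse complement) carry subject coordinates on the forward
    subject strand.
    """
    from .kmer_screen import reverse_complement

    query = query.upper()
    hits: list[HitInterval] = []
    for strand, subj in ((1, subject.upper()),
                         *(((-1, reverse_complement(subject.upper())),)
                           if both_strands else ())):
        index: dict[str, list[int]] = {}
        for i in range(len(subj) - seed_k + 1):
            kmer = subj[i:i + seed_k]
            if "N" not in kmer:
                index.setdefault(kmer, []).append(i)
        seen: set[tuple[int, int, int]] = set()
        # per-diagonal extents already covered by an extension; seeds inside
        # a covered extent would re-derive the same segment
        extents: dict[int, list[tuple[int, int]]] = {}
        for qpos in range(len(query) - seed_k + 1):
            kmer = query[qpos:qpos + seed_k]
            for spos in index.get(kmer, ()):
                diag = qpos - spos
                if any(lo <= qpos < hi for lo, hi in extents.get(diag, ())):
                    continue
                qs, qe, score = _ungapped_extend(query, subj, qpos, spos,
                                                 seed_k)
                extents.setdefault(diag, []).append((qs, qe))
                key = (diag, qs, qe)
                if key in seen or score < min_score:
                    continue
                seen.add(key)
                ss = qs - diag
                se = qe - diag
                if strand == -1:
                    ss, se = len(subj) - se, len(subj) - ss
                hits.append(HitInterval(qs, qe, subject_id, score, ss, se))
    # drop hits wholly contained in a higher-scoring hit on the query
    hits.sort(key=lambda h: (-h.score, h.query_start))
    kept: list[HitInterval] = []
    for h in hits:
        if not any(k.query_start <= h.query_start and
                   h.query_end <= k.query_end and k.score >= h.score
                   for k in kept):
            kept.append(h)
    return kept


def read_tabular_hits(path: str | Path) -> dict[str, list[HitInterval]]:
    """Import 12-column tabular local-alignment hits (qseqid sseqid pident
    length mismatch gapopen qstart qend sstart send evalue bitscore).

    Query coordinates are converted from 1-based inclusive to 0-based
    half-open. Returns hits grouped by query id.
    """
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    out: dict[str, list[HitInterval]] = {}
    for _, r in df.iterrows():
        qs, qe = int(r.qstart) - 1, int(r.qend)
        ss, se = int(r.sstart), int(r.send)
        if ss <= se:
            ss, se = ss - 1, se
        else:
            ss, se = se - 1, ss
        out.setdefault(str(r.qseqid), []).append(
            HitInterval(qs, qe, str(r.sseqid), float(r.bitscore), ss, se))
    return out


# ---------------------------------------------------------------------------
# Interval merging and coverage
# ---------------------------------------------------------------------------

def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for lo, hi in ivs[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def merged_coverage_fraction(hits: list[HitInterval],
                             query_len: int) -> CoverageFraction:
    """Union length of hit intervals on the query over the query length."""
    for h in hits:
        if not (0 <= h.query_start < h.query_end <= query_len):
            raise ValueError(
                f"hit interval [{h.query_start},{h.query_end}) out of "
                f"bounds for query of length {query_len}")
    covered = sum(hi - lo for lo, hi in merge_intervals(
        [(h.query_start, h.query_end) for h in hits]))
    return CoverageFraction(covered, query_len)


def mge_coverage(intervening_seq: str,
                 mge_db: list[tuple[str, str]],
                 min_score: float = 0.0) -> CoverageFraction:
    """Fraction of an intervening sequence explained by MGE/prophage hits."""
    hits: list[HitInterval] = []
    for sid, sseq in mge_db:
        hits.extend(find_local_hits(intervening_seq, sseq, subject_id=sid,
                                    min_score=min_score))
    return merged_coverage_fraction(hits, len(intervening_seq))


def compare_coverage_groups(split_fracs: list[float],
                            intact_fracs: list[float],
                            ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between split- and intact-ancestor loci.

    Exact null enumeration for group sizes up to 20 each, tie-corrected
    normal approximation otherwise. Returns (U, p).
    """
    if not split_fracs or not intact_fracs:
        raise ValueError("both groups must be non-empty")
    method = ("exact" if max(len(split_fracs), len(intact_fracs)) <= 20
              else "asymptotic")
    res = stats.mannwhitneyu(split_fracs, intact_fracs,
                             alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Fragmented-alignment fusion filter (reference-genome screen)
# ---------------------------------------------------------------------------

def split_alignment_filter(hits: list[HitInterval], gene_len: int,
                           min_total_cov: float = 0.8,
                           max_single_frac: float = 0.8,
                           min_separation: int = 1000) -> bool:
    """Flag a putative deletion-born fusion from fragmented genome hits.

    True iff merged query coverage >= min_total_cov, no single hit spans
    more than max_single_frac of the gene, and at least two hits are
    separated by >= min_separation bp in genome coordinates.
    """
    if not hits:
        return False
    cov = merged_coverage_fraction(hits, gene_len).fraction
    if cov < min_total_cov:
        return False
    if max(h.query_end - h.query_start for h in hits) > \
            max_single_frac * gene_len:
        return False
    spans = sorted((h.subject_start, h.subject_end) for h in hits)
    for a, b in zip(spans, spans[1:]):
        if b[0] - a[1] >= min_separation:
            return True
    return False


# ---------------------------------------------------------------------------
# Protein-family sampling strategies and the depth score
# ---------------------------------------------------------------------------

def read_family_table(path: str | Path) -> list[FamilyRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"family_id", "genome_id", "species_id"}
    if not need <= set(df.columns):
        raise ValueError(f"family table must have columns {sorted(need)}")
    out = []
    for fid, sub in df.groupby("family_id", sort=True):
        out.append(FamilyRecord(
            str(fid), tuple(zip(sub.genome_id, sub.species_id))))
    return out


def sample_families(families: list[FamilyRecord], strategy: str, n: int,
                    seed: int) -> list[str]:
    """Uniform sample of family ids under a sampling strategy.

    Strategies: "all" (every family), "non_singleton" (>= 2 members),
    "large" (> 20 members). Member count is the raw row count (one row per
    protein).
    """
    if strategy == "all":
        eligible = [f.family_id for f in families]
    elif strategy == "non_singleton":
        eligible = [f.family_id for f in families if len(f.members) >= 2]
    elif strategy == "large":
        eligible = [f.family_id for f in families if len(f.members) > 20]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if len(eligible) < n:
        raise ValueError(
            f"strategy {strategy!r}: only {len(eligible)} eligible "
            f"families, {n} requested (short by {n - len(eligible)})")
    rng = np.random.default_rng(seed)
    eligible = sorted(eligible)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]


def sampling_depth_score(family: FamilyRecord) -> DepthScore:
    """Genomes containing the family divided by unique species represented.

    Duplicate proteins from one genome count that genome once; a score of
    1 means every genome is a distinct species.
    """
    if not family.members:
        raise ValueError("family has no members")
    genomes = {g for g, _ in family.members}
    species = {s for _, s in family.members}
    return DepthScore(family.family_id, len(genomes), len(species))
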