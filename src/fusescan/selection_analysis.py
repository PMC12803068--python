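"""Selection signatures on candidate fusion genes.

Two dN/dS-style axes are computed for each candidate. First, locus
sequences from genomes in the intact (zero-difference) cluster are
deduplicated, codon-aligned to the canonical query CDS, and synonymous /
nonsynonymous differences are counted per codon and pooled with each
unique sequence weighted by the number of genomes carrying it. Second, a
"surrogate" pre-deletion gene is reconstructed from a split-state genome
by tiling the query against the split locus with local alignment hits,
mapping each accepted segment onto predicted ORFs in the flanking context,
and stitching the ORF sequences in query order with NNN joints; the
surrogate is then scored on the same weighted dN/dS axis. Codons that
overlap gaps or ambiguous bases (including the NNN joints) are skipped.
Multi-site codons are resolved by averaging over all orderings of
single-site mutational paths; changes that create a stop codon are tallied
separately and excluded from the syn/nonsyn counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

from .kmer_screen import reverse_complement

_BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]
_STOP_CODONS = set(_BACTERIAL_TABLE.stop_codons)
_ORF_STARTS = ("ATG", "GTG", "TTG")
MIN_ORF_LEN = 90  # bp, incl. stop


def _translate_codon(codon: str) -> str:
    if codon in _STOP_CODONS:
        return "*"
    return _BACTERIAL_TABLE.forward_table.get(codon, "X")


@dataclass
class WeightedSequenceSet:
    """Unique sequences with genome-count weights."""

    unique_seqs: list[tuple[str, int]]

    @classmethod
    def from_sequences(cls, seqs: list[str]) -> "WeightedSequenceSet":
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s.upper()] = counts.get(s.upper(), 0) + 1
        return cls(sorted(counts.items()))

    @property
    def n_genomes(self) -> int:
        return sum(w for _, w in self.unique_seqs)


@dataclass
class CodonDiffCount:
    syn: float = 0.0
    nonsyn: float = 0.0
    stop_gains: int = 0
    codons_skipped: int = 0


@dataclass
class SelectionEstimate:
    weighted_dN: float
    weighted_dS: float
    ratio: float | None
    n_unique: int
    n_genomes: int
    stop_gains: float = 0.0


@dataclass
class SurrogateGene:
    stitched_seq: str
    segments: list[tuple[tuple[int, int], tuple[int, int], int]] = \
        field(default_factory=list)  # (query iv, locus iv, orf index)


# ---------------------------------------------------------------------------
# Codon-aware pairwise alignment (translate -> align -> back-map)
# ---------------------------------------------------------------------------

_PROT_ALIGNER = PairwiseAligner()
_PROT_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
_PROT_ALIGNER.open_gap_score = -11
_PROT_ALIGNER.extend_gap_score = -1
_PROT_ALIGNER.mode = "global"


def _translate_frame(seq: str) -> str:
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa.append(_translate_codon(seq[i:i + 3]))
    return "".join(aa)


def codon_align(ref_cds: str, alt_seq: str) -> tuple[str, str]:
    """Frame-preserving pairwise codon alignment of alt against ref.

    Both sequences are translated (trailing partial codons of alt dropped;
    a terminal ref stop is aligned too), proteins are globally aligned, and
    the alignment is back-mapped to nucleotide triplets, producing two
    gapped strings of equal length that is a multiple of 3. Internal stops
    and ambiguous codons translate to '*'/'X' and stay in frame.
    """
    ref = ref_cds.upper()
    alt = alt_seq.upper()
    ref_aa = _translate_frame(ref)
    alt_aa = _translate_frame(alt)
    if not ref_aa or not alt_aa:
        raise ValueError("empty translation; frame-incompatible input")
    aln = _PROT_ALIGNER.align(ref_aa, alt_aa)[0]
    ref_out, alt_out = [], []
    ri = ai = 0
    for (rs, re_), (as_, ae) in zip(*aln.aligned):
        while ri < rs:
            ref_out.append(ref[ri * 3:ri * 3 + 3])
            alt_out.append("---")
            ri += 1
        while ai < as_:
            ref_out.append("---")
            alt_out.append(alt[ai * 3:ai * 3 + 3])
            ai += 1
        for _ in range(re_ - rs):
            ref_out.append(ref[ri * 3:ri * 3 + 3])
            alt_out.append(alt[ai * 3:ai * 3 + 3])
            ri += 1
            ai += 1
    while ri < len(ref_aa):
        ref_out.append(ref[ri * 3:ri * 3 + 3])
        alt_out.append("---")
        ri += 1
    while ai < len(alt_aa):
        ref_out.append("---")
        alt_out.append(alt[ai * 3:ai * 3 + 3])
        ai += 1
    return "".join(ref_out), "".join(alt_out)


# ---------------------------------------------------------------------------
# Path-averaged synonymous / nonsynonymous counting
# ---------------------------------------------------------------------------

def _codon_path_counts(c1: str, c2: str) -> tuple[float, float, bool]:
    """Average (syn, nonsyn) over all orderings of single-site paths.

    Paths passing through a stop codon are excluded; if every path passes
    through a stop (or the end state is a stop), the change is a stop gain:
    returns (0, 0, True).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0, False
    if c2 in _STOP_CODONS:
        return 0.0, 0.0, True
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOP_CODONS and nxt != c2:
                ok = False
                break
            if _translate_codon(cur) == _translate_codon(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            paths.append((syn, nonsyn))
    if not paths:
        return 0.0, 0.0, True
    s = float(np.mean([p[0] for p in paths]))
    n = float(np.mean([p[1] for p in paths]))
    return s, n, False


def count_codon_diffs(ref_aligned: str, alt_aligned: str) -> CodonDiffCount:
    """Count syn/nonsyn differences over an aligned codon pair of strings.

    Input strings must be equal length, a multiple of 3, with gaps only in
    whole-codon units ('-'). Codons overlapping gaps or ambiguous bases on
    either side contribute only to codons_skipped.
    """
    if len(ref_aligned) != len(alt_aligned) or len(ref_aligned) % 3:
        raise ValueError("frame-incompatible alignment")
    out = CodonDiffCount()
    for i in range(0, len(ref_aligned), 3):
        c1 = ref_aligned[i:i + 3]
        c2 = alt_aligned[i:i + 3]
        if set(c1 + c2) - set("ACGT"):
            out.codons_skipped += 1
            continue
        syn, nonsyn, stop = _codon_path_counts(c1, c2)
        if stop:
            out.stop_gains += 1
        else:
            out.syn += syn
            out.nonsyn += nonsyn
    return out


def weighted_dnds(counts: list[CodonDiffCount],
                  weights: list[int]) -> SelectionEstimate:
    """Pool per-sequence counts with genome-count weights.

    weighted_dN = sum w_i * nonsyn_i, weighted_dS = sum w_i * syn_i; the
    ratio is undefined (None) when weighted_dS is 0, with counts still
    reported.
    """
    if len(counts) != len(weights):
        raise ValueError("counts and weights must align")
    dN = float(sum(w * c.nonsyn for c, w in zip(counts, weights)))
    dS = float(sum(w * c.syn for c, w in zip(counts, weights)))
    sg = float(sum(w * c.stop_gains for c, w in zip(counts, weights)))
    ratio = dN / dS if dS > 0 else None
    return SelectionEstimate(dN, dS, ratio, len(counts),
                             int(sum(weights)), sg)


def selection_for_cluster(ref_cds: str, locus_seqs: list[str],
                          ) -> SelectionEstimate:
    """Weighted dN/dS of a set of locus sequences against the query CDS."""
    wss = WeightedSequenceSet.from_sequences(locus_seqs)
    counts = []
    weights = []
    for seq, w in wss.unique_seqs:
        ra, aa = codon_align(ref_cds, seq)
        counts.append(count_codon_diffs(ra, aa))
        weights.append(w)
    return weighted_dnds(counts, weights)


# ---------------------------------------------------------------------------
# ORF prediction and surrogate pre-deletion gene construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Orf:
    start: int  # 0-based on the forward strand of the input sequence
    end: int    # half-open
    strand: str  # "+" | "-"

    def extract(self, seq: str) -> str:
        sub = seq[self.start:self.end]
        return sub if self.strand == "+" else reverse_complement(sub)


def find_orfs(seq: str, min_len: int = MIN_ORF_LEN) -> list[Orf]:
    """Exhaustive ORFs on both strands: ATG/GTG/TTG start to in-frame stop.

    Per (frame, stop) only the longest ORF (first upstream start) is kept.
    Coordinates are on the forward strand, half-open, stop codon included.
    """
    seq = seq.upper()
    n = len(seq)
    orfs: list[Orf] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            start_pending: int | None = None
            for i in range(frame, n - 2, 3):
                codon = s[i:i + 3]
                if codon in _STOP_CODONS:
                    if start_pending is not None:
                        length = i + 3 - start_pending
                        if length >= min_len:
                            if strand == "+":
                                orfs.append(Orf(start_pending, i + 3, "+"))
                            else:
                                orfs.append(Orf(n - (i + 3),
                                                n - start_pending, "-"))
                        start_pending = None
                elif codon in _ORF_STARTS and start_pending is None:
                    start_pending = i
    return sorted(orfs, key=lambda o: (o.start, o.end, o.strand))


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def build_surrogate(query_cds: str, locus_seq: str, flank_seq: str,
                    max_overlap_frac: float = 0.2,
                    min_orf_len: int = MIN_ORF_LEN) -> SurrogateGene | None:
    """Reconstruct a pre-deletion surrogate gene from a split-state locus.

    Local-alignment hits of the query against the locus are accepted
    greedily by descending score, rejecting hits overlapping accepted ones
    by more than ``max_overlap_frac`` of the query length. Each accepted
    segment is projected onto the flanking context (the locus must occur
    in the flank, either strand) and intersected with predicted ORFs; the
    maximal-overlap ORF's nucleotide sequence is taken per segment, and
    segments are concatenated in query order with "NNN" joints. Returns
    None when no alignment segment is found.
    """
    from .annotation_stats import find_local_hits

    query = query_cds.upper()
    locus = locus_seq.upper()
    flank = flank_seq.upper()
    hits = find_local_hits(query, locus)
    if not hits:
        return None
    max_ov = max_overlap_frac * len(query)
    accepted = []
    for h in sorted(hits, key=lambda h: (-h.score, h.query_start)):
        if all(_overlap((h.query_start, h.query_end),
                        (a.query_start, a.query_end)) <= max_ov
               for a in accepted):
            accepted.append(h)
    if not accepted:
        return None
    # project locus coordinates into the flank context
    offset = flank.find(locus)
    rc = False
    if offset == -1:
        offset = flank.find(reverse_complement(locus))
        rc = offset != -1
        if not rc:
            raise ValueError("locus sequence not found in flank context")
    orfs = find_orfs(flank, min_len=min_orf_len)
    segments = []
    pieces = []
    for h in sorted(accepted, key=lambda h: h.query_start):
        if rc:
            flo = offset + (len(locus) - h.subject_end)
            fhi = offset + (len(locus) - h.subject_start)
        else:
            flo = offset + h.subject_start
            fhi = offset + h.subject_end
        best_i, best_ov = -1, 0
        for i, orf in enumerate(orfs):
            ov = _overlap((flo, fhi), (orf.start, orf.end))
            if ov > best_ov:
                best_i, best_ov = i, ov
        if best_i < 0:
            continue
        segments.append(((h.query_start, h.query_end), (flo, fhi), best_i))
        pieces.append(orfs[best_i].extract(flank))
    if not pieces:
        return None
    return SurrogateGene("NNN".join(pieces), segments)
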