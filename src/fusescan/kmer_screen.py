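"""Prefix-suffix k-mer screen.

A query gene is reduced to two exact anchors: a *prefix* k-mer taken just
inside the 5' end and a *suffix* k-mer just inside the 3' end, each offset
from the terminus by a small gap ``g`` so that the anchors avoid start/stop
codons and sit out of frame relative to the CDS. Every exact occurrence of
either anchor in a genome collection is located on both strands; whenever a
prefix and a suffix match land on the same contig in the same orientation,
the spanned distance is compared with the span expected for the intact gene.
The signed difference (observed span minus expected span) is 0 for an intact
allele and large positive for a split (pre-deletion or insertion-disrupted)
configuration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

DEFAULT_K = 27
DEFAULT_GAP = 4

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

_ACGT_RE = re.compile(r"^[ACGT]+$")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GeneTooShortError(ValueError):
    """Gene shorter than 2(k+g); no disjoint anchor windows exist."""

    def __init__(self, gene_id: str, length: int, k: int, g: int):
        self.gene_id = gene_id
        super().__init__(
            f"gene {gene_id!r}: length {length} < 2(k+g) = {2 * (k + g)}"
        )


class AmbiguousWindowError(ValueError):
    """An anchor window contains a non-ACGT character."""

    def __init__(self, gene_id: str, window: str, role: str):
        self.gene_id = gene_id
        self.role = role
        super().__init__(
            f"gene {gene_id!r}: {role} k-mer window contains ambiguous bases: {window}"
        )


@dataclass(frozen=True)
class QueryGene:
    """A query gene with its extracted anchor k-mers.

    ``expected_span`` is the distance from the prefix-window start to the
    suffix-window end on the intact gene: L - 2g.
    """

    gene_id: str
    sequence: str
    k: int = DEFAULT_K
    g: int = DEFAULT_GAP
    prefix_kmer: str = field(default="", compare=False)
    suffix_kmer: str = field(default="", compare=False)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def expected_span(self) -> int:
        return self.length - 2 * self.g


@dataclass(frozen=True)
class KmerMatch:
    genome_id: str
    contig_id: str
    role: str  # "prefix" | "suffix"
    start: int  # 0-based contig coordinate of the match window
    strand: str  # "forward" | "reverse_complement"


@dataclass(frozen=True)
class LocusMeasurement:
    gene_id: str
    genome_id: str
    contig_id: str | None
    prefix_start: int | None
    suffix_start: int | None
    orientation: str | None  # "forward" | "reverse_complement"
    span: int | None
    difference: int | None
    status: str  # "ok" | "missing" | "discordant"


def extract_query_kmers(gene_id: str, sequence: str, k: int = DEFAULT_K,
                        g: int = DEFAULT_GAP) -> QueryGene:
    """Extract prefix/suffix anchor k-mers from a coding sequence.

    The prefix window is [g, g+k) and the suffix window [L-g-k, L-g),
    0-based half-open. With the default g=4 the windows are shifted out of
    frame relative to the CDS.
    """
    seq = str(sequence).upper()
    L = len(seq)
    if L < 2 * (k + g):
        raise GeneTooShortError(gene_id, L, k, g)
    prefix = seq[g:g + k]
    suffix = seq[L - g - k:L - g]
    if not _ACGT_RE.match(prefix):
        raise AmbiguousWindowError(gene_id, prefix, "prefix")
    if not _ACGT_RE.match(suffix):
        raise AmbiguousWindowError(gene_id, suffix, "suffix")
    return QueryGene(gene_id=gene_id, sequence=seq, k=k, g=g,
                     prefix_kmer=prefix, suffix_kmer=suffix)


def load_query_genes(path: str | Path, k: int = DEFAULT_K,
                     g: int = DEFAULT_GAP) -> list[QueryGene]:
    """Read a coding-nucleotide FASTA and extract anchors for every entry.

    Rejected entries (too short, ambiguous windows) raise; callers that want
    to continue past bad genes should catch per-record.
    """
    return [extract_query_kmers(rec.id, str(rec.seq), k=k, g=g)
            for rec in SeqIO.parse(str(path), "fasta")]


def _find_all(haystack: str, needle: str) -> Iterator[int]:
    """All (possibly overlapping) exact occurrence starts of needle."""
    start = haystack.find(needle)
    while start != -1:
        yield start
        start = haystack.find(needle, start + 1)


def find_matches_in_contig(contig_seq: str, query: QueryGene,
                           genome_id: str, contig_id: str) -> list[KmerMatch]:
    """Exact matches of both anchors on both strands of one contig.

    A reverse_complement match at ``start`` means the contig window
    [start, start+k) equals the reverse complement of the anchor. Positions
    containing ambiguous bases never match (anchors are pure ACGT, so any
    window containing non-ACGT differs from them).
    """
    seq = contig_seq.upper()
    out: list[KmerMatch] = []
    for role, kmer in (("prefix", query.prefix_kmer),
                       ("suffix", query.suffix_kmer)):
        rc = reverse_complement(kmer)
        for s in _find_all(seq, kmer):
            out.append(KmerMatch(genome_id, contig_id, role, s, "forward"))
        if rc != kmer:
            for s in _find_all(seq, rc):
                out.append(KmerMatch(genome_id, contig_id, role, s,
                                     "reverse_complement"))
        else:  # palindromic anchor: single placement, both strands collapse
            pass
    return out


def find_exact_matches(queries: Iterable[QueryGene],
                       genomes: Iterable[tuple[str, list[tuple[str, str]]]],
                       ) -> dict[str, dict[str, list[KmerMatch]]]:
    """Locate every exact anchor occurrence in a genome collection.

    Parameters
    ----------
    queries:
        Query genes with extracted anchors.
    genomes:
        Iterable of (genome_id, [(contig_id, contig_seq), ...]).

    Returns
    -------
    Nested dict: matches[gene_id][genome_id] -> list of KmerMatch. Results
    are independent of iteration order; every occurrence is reported once.
    """
    queries = list(queries)
    matches: dict[str, dict[str, list[KmerMatch]]] = {
        q.gene_id: {} for q in queries
    }
    for genome_id, contigs in genomes:
        for contig_id, contig_seq in contigs:
            for q in queries:
                found = find_matches_in_contig(contig_seq, q, genome_id,
                                               contig_id)
                if found:
                    matches[q.gene_id].setdefault(genome_id, []).extend(found)
    return matches


def measure_locus(matches: Iterable[KmerMatch], query: QueryGene,
                  genome_id: str,
                  allow_reverse: bool = True) -> LocusMeasurement:
    """Reduce one (gene, genome) match set to a single locus measurement.

    Only same-contig, same-orientation prefix/suffix pairs with positive
    span are considered. Forward span = (suffix_start + k) - prefix_start;
    reverse-complement span = (prefix_start + k) - suffix_start (the gene
    reads right-to-left on the contig). Among valid pairs the one minimizing
    |difference| is kept, ties broken by smaller prefix_start; an intact
    gene therefore always measures difference 0. No valid pair with at
    least one prefix and one suffix on some contig in opposite orientations
    -> "discordant"; otherwise no pair -> "missing".
    """
    k = query.k
    by_contig: dict[str, list[KmerMatch]] = {}
    for m in matches:
        by_contig.setdefault(m.contig_id, []).append(m)

    best: tuple[int, int, KmerMatch, KmerMatch, int] | None = None
    saw_discordant = False
    for contig_id, ms in by_contig.items():
        prefixes = [m for m in ms if m.role == "prefix"]
        suffixes = [m for m in ms if m.role == "suffix"]
        if not prefixes or not suffixes:
            continue
        found_pair = False
        for p in prefixes:
            for s in suffixes:
                if p.strand != s.strand:
                    continue
                if p.strand == "reverse_complement" and not allow_reverse:
                    continue
                if p.strand == "forward":
                    span = (s.start + k) - p.start
                else:
                    span = (p.start + k) - s.start
                if span <= 0:
                    continue
                found_pair = True
                diff = span - query.expected_span
                key = (abs(diff), p.start)
                if best is None or key < (best[0], best[1]):
                    best = (abs(diff), p.start, p, s, span)
        if not found_pair:
            saw_discordant = True
    if best is not None:
        _, _, p, s, span = best
        return LocusMeasurement(
            gene_id=query.gene_id, genome_id=genome_id,
            contig_id=p.contig_id, prefix_start=p.start, suffix_start=s.start,
            orientation=p.strand, span=span,
            difference=span - query.expected_span, status="ok")
    status = "discordant" if saw_discordant else "missing"
    return LocusMeasurement(query.gene_id, genome_id, None, None, None, None,
                            None, None, status)


# ---------------------------------------------------------------------------
# Collection IO and the end-to-end screen runner
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def load_collection(collection: str | Path,
                    ) -> list[tuple[str, str | Path]]:
    """Resolve a collection spec to [(genome_id, fasta_path), ...].

    ``collection`` is either a directory of FASTA files (genome_id = stem)
    or a manifest TSV with columns genome_id, path (paths relative to the
    manifest's directory are resolved against it).
    """
    collection = Path(collection)
    if collection.is_dir():
        entries = sorted(
            p for p in collection.iterdir()
            if p.suffix.lower() in {".fa", ".fasta", ".fna"})
        return [(p.stem, p) for p in entries]
    df = pd.read_csv(collection, sep="\t", dtype=str)
    if not {"genome_id", "path"} <= set(df.columns):
        raise ValueError("manifest must have columns genome_id, path")
    base = collection.parent
    out = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        out.append((row["genome_id"], p if p.is_absolute() else base / p))
    return out


def run_screen(queries: list[QueryGene],
               genome_entries: Iterable[tuple[str, list[tuple[str, str]]]],
               allow_reverse: bool = True,
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match anchors and measure loci across a whole in-memory collection.

    Returns (matches_df, measurements_df) in the screen's TSV schema. One
    measurement row is emitted per (gene, genome), including genomes with no
    match at all (status "missing").
    """
    genome_entries = list(genome_entries)
    genome_ids = [gid for gid, _ in genome_entries]
    all_matches = find_exact_matches(queries, genome_entries)

    match_rows = []
    meas_rows = []
    for q in queries:
        per_genome = all_matches.get(q.gene_id, {})
        for gid in genome_ids:
            ms = per_genome.get(gid, [])
            for m in ms:
                match_rows.append((q.gene_id, m.genome_id, m.contig_id,
                                   m.role, m.start, m.strand))
            meas = measure_locus(ms, q, gid, allow_reverse=allow_reverse)
            meas_rows.append((meas.gene_id, meas.genome_id, meas.contig_id,
                              meas.prefix_start, meas.suffix_start,
                              meas.orientation, meas.span, meas.difference,
                              meas.status))
    matches_df = pd.DataFrame(
        match_rows, columns=["gene_id", "genome_id", "contig_id", "role",
                             "start", "strand"])
    meas_df = pd.DataFrame(
        meas_rows, columns=["gene_id", "genome_id", "contig_id",
                            "prefix_start", "suffix_start", "orientation",
                            "span", "difference", "status"])
    return matches_df, meas_df


def run_screen_on_paths(genes_fasta: str | Path, collection: str | Path,
                        k: int = DEFAULT_K, g: int = DEFAULT_GAP,
                        allow_reverse: bool = True,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """File-based front end: returns (matches, measurements, failed_genomes).

    Unreadable genome FASTAs are recorded in failed_genomes and skipped; the
    run continues.
    """
    queries = load_query_genes(genes_fasta, k=k, g=g)
    entries = load_collection(collection)
    loaded = []
    failed = []
    for gid, path in entries:
        try:
            loaded.append((gid, read_genome_fasta(path)))
        except (OSError, ValueError):
            failed.append(gid)
    matches_df, meas_df = run_screen(queries, loaded,
                                     allow_reverse=allow_reverse)
    return matches_df, meas_df, failed
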