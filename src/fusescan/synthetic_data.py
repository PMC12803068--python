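"""Synthetic genome collections with planted structural events.

A random ancestral genome (GC ~ 0.5) evolves along a random birth-death
tree under Jukes-Cantor point substitutions; indels enter only through
planted events, so the expected prefix-suffix difference of every genome
is known exactly. Two event types emulate the two scenarios the screen
must distinguish:

* ``deletion_fusion`` — the ancestor carries the *split* configuration
  (5' gene fragment, an intervening segment, 3' gene fragment); genomes in
  a derived clade carry the deletion that removes the intervening segment
  and fuses the fragments into the query gene. Clade genomes measure
  difference 0, all others +size, and the split state is ancestral.
* ``cargo_insertion`` — the ancestor carries the intact query gene; clade
  genomes carry an MGE-fixture cargo inserted between the anchor windows.
  Clade genomes measure +size, others 0, and the intact state is
  ancestral.

Substitutions are suppressed inside a protected zone around each anchor
k-mer window, so both anchors survive at any substitution rate and the
truth table is exact. The MGE fixture is a fixed set of ~20 pseudo-random
1-10 kb cargo sequences regenerated deterministically from an internal
seed (a synthetic stand-in for a curated MGE/prophage database).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .kmer_screen import DEFAULT_GAP, DEFAULT_K

_BASES = np.array(list("ACGT"))
_MGE_FIXTURE_SEED = 20240901  # fixed: the fixture is part of the conditions
MGE_FIXTURE_COUNT = 20
DEFAULT_GENOME_LEN = 200_000
DEFAULT_SUB_RATE = 0.005  # subs/site per unit branch length (~within-species)


@dataclass
class PlantedEvent:
    event_type: str  # "deletion_fusion" | "cargo_insertion"
    clade_size: int  # target number of genomes carrying the derived state
    size: int  # deletion / insertion length in bp
    gene_len: int = 1000
    cargo_source: int | None = None  # MGE fixture index for insertions
    # filled in during generation:
    gene_id: str = ""
    clade: frozenset[str] = frozenset()
    locus: tuple[int, int] = (0, 0)  # ancestral genome coordinates


@dataclass
class SyntheticCollection:
    genomes: dict[str, list[tuple[str, str]]]
    tree: dendropy.Tree
    query_genes: list[tuple[str, str]]  # (gene_id, fused/intact CDS)
    events: list[PlantedEvent]
    truth: pd.DataFrame  # gene_id, genome_id, expected_difference, in_clade
    outgroups: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def mge_fixture(count: int = MGE_FIXTURE_COUNT,
                min_len: int = 1000, max_len: int = 10_000,
                ) -> list[tuple[str, str]]:
    """The fixed synthetic MGE/prophage cargo database."""
    rng = np.random.default_rng(_MGE_FIXTURE_SEED)
    out = []
    for i in range(count):
        n = int(rng.integers(min_len, max_len + 1))
        out.append((f"MGE_{i:02d}", random_dna(rng, n)))
    return out


def _random_coding_gene(rng: np.random.Generator, length: int) -> str:
    """Random in-frame CDS: ATG, non-stop codons, TAA; length % 3 == 0."""
    length -= length % 3
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < length // 3 - 1:
        c = random_dna(rng, 3)
        if c not in stops:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _pick_clade(tree: dendropy.Tree, target: int,
                rng: np.random.Generator) -> frozenset[str]:
    """Strictly nested ingroup clade whose leaf count is closest to target;
    ties broken uniformly at random (distinct events may share a clade).

    Children of the root are excluded: a derived event on a basal lineage
    would leave the ingroup-MRCA state genuinely ambiguous under parsimony,
    which is not the scenario the generator is meant to plant.
    """
    candidates: list[frozenset[str]] = []
    best_err: int | None = None
    n_total = len(tree.leaf_nodes())
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node or \
                node.parent_node is tree.seed_node:
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(leaves) >= n_total:
            continue
        err = abs(len(leaves) - target)
        if best_err is None or err < best_err:
            candidates, best_err = [leaves], err
        elif err == best_err:
            candidates.append(leaves)
    if not candidates:
        raise ValueError("no clade available for event placement")
    return candidates[int(rng.integers(len(candidates)))]


def _apply_substitutions(seq: np.ndarray, rng: np.random.Generator,
                         n_subs: int, protected: np.ndarray) -> None:
    """In-place Jukes-Cantor substitutions avoiding protected positions."""
    allowed = np.flatnonzero(~protected)
    if allowed.size == 0 or n_subs == 0:
        return
    n_subs = min(n_subs, allowed.size)
    pos = rng.choice(allowed, size=n_subs, replace=False)
    shift = rng.integers(1, 4, size=n_subs)
    seq[pos] = (seq[pos] + shift) % 4


def generate_collection(n_genomes: int,
                        events: list[PlantedEvent],
                        genome_len: int = DEFAULT_GENOME_LEN,
                        sub_rate: float = DEFAULT_SUB_RATE,
                        seed: int = 0,
                        k: int = DEFAULT_K,
                        g: int = DEFAULT_GAP,
                        n_outgroups: int = 2,
                        outgroup_extra_rate: float = 3.0,
                        ) -> SyntheticCollection:
    """Simulate a genome collection with planted structural events.

    Each event occupies its own locus, evenly spaced along the single
    ancestral contig, and defines one query gene. Outgroup genomes are
    evolved from the ancestral (root) state with ``outgroup_extra_rate``
    times the root-to-tip substitution load and always carry the ancestral
    configuration at every locus.
    """
    rng = np.random.default_rng(seed)
    base_to_int = {b: i for i, b in enumerate("ACGT")}

    # --- tree -------------------------------------------------------------
    taxa = dendropy.TaxonNamespace([f"g{i:03d}" for i in range(n_genomes)])
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_genomes,
        taxon_namespace=taxa,
        rng=random.Random(int(rng.integers(2**31))))
    # normalize depth to 1 so sub_rate is per site root-to-tip on average
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    scale = 1.0 / max(depths)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale

    # --- ancestral genome and loci ----------------------------------------
    ancestor = rng.integers(0, 4, size=genome_len).astype(np.int8)
    protected = np.zeros(genome_len, dtype=bool)
    mge = mge_fixture()
    spacing = genome_len // (len(events) + 1)
    genes: list[tuple[str, str]] = []
    pad = 50  # protected padding around each anchor window

    for ei, ev in enumerate(events):
        ev.gene_id = ev.gene_id or f"gene{ei:02d}"
        gene = _random_coding_gene(rng, ev.gene_len)
        L = len(gene)
        if L < 2 * (k + g):
            raise ValueError("gene_len too short for anchor extraction")
        start = spacing * (ei + 1)
        if ev.event_type == "deletion_fusion":
            # ancestor holds: [5' fragment][intervening][3' fragment]
            half = L // 2
            anc_block = gene[:half] + random_dna(rng, ev.size) + gene[half:]
            if not (g + k <= half <= L - g - k):
                raise ValueError("anchor window would straddle the junction")
        elif ev.event_type == "cargo_insertion":
            anc_block = gene
            src = ev.cargo_source
            if src is None:
                eligible = [i for i, (_, s) in enumerate(mge)
                            if len(s) >= ev.size]
                if not eligible:
                    raise ValueError(
                        f"no cargo fixture of length >= {ev.size}")
                src = eligible[int(rng.integers(len(eligible)))]
                ev.cargo_source = src
            cargo = mge[src][1]
            if ev.size > len(cargo):
                raise ValueError(
                    f"cargo fixture {src} shorter than event size {ev.size}")
        else:
            raise ValueError(f"unknown event type {ev.event_type!r}")
        end = start + len(anc_block)
        if end + pad >= genome_len or start < pad:
            raise ValueError("genome too short for requested events")
        ancestor[start:end] = [base_to_int[b] for b in anc_block]
        ev.locus = (start, end)
        genes.append((ev.gene_id, gene))
        # protect anchor windows (+pad) in ancestral coordinates
        if ev.event_type == "deletion_fusion":
            half = L // 2
            p_lo = start + g - pad
            p_hi = start + g + k + pad
            s_lo = start + ev.size + L - g - k - pad
            s_hi = start + ev.size + L - g + pad
        else:
            p_lo = start + g - pad
            p_hi = start + g + k + pad
            s_lo = start + L - g - k - pad
            s_hi = start + L - g + pad
        protected[max(0, p_lo):p_hi] = True
        protected[max(0, s_lo):s_hi] = True
        ev.clade = _pick_clade(tree, ev.clade_size, rng)

    # --- evolve along the tree ---------------------------------------------
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): ancestor}
    leaf_seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        child = parent_seq.copy()
        blen = node.edge.length or 0.0
        n_subs = rng.poisson(sub_rate * blen * genome_len)
        _apply_substitutions(child, rng, n_subs, protected)
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = child
        else:
            seqs[id(node)] = child

    # --- apply events per leaf, build truth --------------------------------
    int_to_base = np.array(list("ACGT"))
    genomes: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for gid in sorted(leaf_seqs):
        seq = "".join(int_to_base[leaf_seqs[gid]])
        # apply events right-to-left so earlier loci keep their coordinates
        for ev in sorted(events, key=lambda e: -e.locus[0]):
            start, end = ev.locus
            in_clade = gid in ev.clade
            if ev.event_type == "deletion_fusion" and in_clade:
                half = len(dict(genes)[ev.gene_id]) // 2
                del_lo = start + half
                del_hi = start + half + ev.size
                seq = seq[:del_lo] + seq[del_hi:]
            elif ev.event_type == "cargo_insertion" and in_clade:
                L = len(dict(genes)[ev.gene_id])
                cargo = mge[ev.cargo_source][1][:ev.size]
                ins_at = start + L // 2
                seq = seq[:ins_at] + cargo + seq[ins_at:]
        genomes[gid] = [("contig0", seq)]
        for ev in events:
            in_clade = gid in ev.clade
            if ev.event_type == "deletion_fusion":
                expected = 0 if in_clade else ev.size
            else:
                expected = ev.size if in_clade else 0
            truth_rows.append((ev.gene_id, gid, expected, in_clade))

    # --- outgroups: ancestral configuration, extra divergence ---------------
    outgroups: dict[str, list[tuple[str, str]]] = {}
    for i in range(n_outgroups):
        og = ancestor.copy()
        n_subs = rng.poisson(sub_rate * outgroup_extra_rate * (i + 1)
                             * genome_len)
        _apply_substitutions(og, rng, n_subs, protected)
        outgroups[f"outgroup{i}"] = [("contig0",
                                      "".join(int_to_base[og]))]

    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "genome_id", "expected_difference", "in_clade"])
    return SyntheticCollection(genomes, tree, genes, events, truth,
                               outgroups)


def write_collection(coll: SyntheticCollection, out_dir: str | Path) -> None:
    """Write genomes/, genes.fa, tree.nwk, truth.tsv, mge_fixture.fa."""
    out = Path(out_dir)
    gdir = out / "genomes"
    gdir.mkdir(parents=True, exist_ok=True)
    for gid, contigs in {**coll.genomes, **coll.outgroups}.items():
        with open(gdir / f"{gid}.fa", "w") as fh:
            for cid, seq in contigs:
                fh.write(f">{cid}\n{seq}\n")
    with open(out / "genes.fa", "w") as fh:
        for gene_id, seq in coll.query_genes:
            fh.write(f">{gene_id}\n{seq}\n")
    with open(out / "tree.nwk", "w") as fh:
        fh.write(coll.newick() + "\n")
    coll.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "mge_fixture.fa", "w") as fh:
        for mid, seq in mge_fixture():
            fh.write(f">{mid}\n{seq}\n")
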