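"""End-to-end orchestration of the screen on an in-memory collection.

Glues the stages together in cascade order: anchor extraction and exact
matching, per-genome locus measurement, difference clustering and
multimodality calls, cluster-stratified sampling, locus extraction and
masking, sketch-distance tree building, and Fitch ancestral-state
inference — returning one consolidated result per query gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation_stats import mge_coverage
from .distance_clustering import (ClusterSet, GeneScreenCall,
                                  cluster_all_genes, screen_gene)
from .kmer_screen import (LocusMeasurement, extract_query_kmers,
                          run_screen)
from .locus_ancestry import (AncestralCall, build_rooted_tree,
                             cluster_members_from_assignment,
                             extract_and_mask, fitch_mrca, genome_kmer_hashes,
                             sample_by_cluster, sketch_from_hashes,
                             sorted_hash_counts)


@dataclass
class GeneResult:
    gene_id: str
    call: GeneScreenCall
    clusters: ClusterSet
    ancestry: AncestralCall | None
    stage_passed: int
    intervening_by_genome: dict[str, str]  # positive-cluster locus seqs
    locus_by_genome: dict[str, str]  # all sampled locus seqs


def analyze_collection(genomes: dict[str, list[tuple[str, str]]],
                       query_genes: list[tuple[str, str]],
                       outgroups: dict[str, list[tuple[str, str]]],
                       k: int = 27, g: int = 4,
                       eps: float = 800.0, min_samples: int = 25,
                       quota: int = 300, seed: int = 0,
                       sketch_size: int = 1000, sketch_k: int = 21,
                       ) -> tuple[pd.DataFrame, dict[str, GeneResult]]:
    """Run the full cascade; returns (measurements, per-gene results).

    Stage 3 (ancestry) runs only for genes that pass stage 2. The final
    ``stage_passed`` is 3 when the ancestral state is a split cluster with
    an intact descendant.
    """
    queries = [extract_query_kmers(gid, seq, k=k, g=g)
               for gid, seq in query_genes]
    qmap = {q.gene_id: q for q in queries}
    entries = sorted(genomes.items())
    _, meas = run_screen(queries, entries)
    _, _, cluster_sets = cluster_all_genes(meas, eps=eps,
                                           min_samples=min_samples)
    # k-mer hashes are gene-independent; cache them and derive per-gene
    # masked sketches by window exclusion (equivalent to N-masking)
    hash_cache: dict[str, tuple] = {}

    def cached_hashes(gid2: str, contigs) -> tuple:
        if gid2 not in hash_cache:
            arrays = genome_kmer_hashes(contigs, sketch_k)
            hash_cache[gid2] = (arrays, sorted_hash_counts(arrays))
        return hash_cache[gid2]
    results: dict[str, GeneResult] = {}
    for gene_id, cs in cluster_sets.items():
        call = screen_gene(cs)
        ancestry = None
        stage = call.stage_passed
        intervening: dict[str, str] = {}
        locus_seqs: dict[str, str] = {}
        if call.stage_passed >= 2:
            sub = meas[(meas.gene_id == gene_id) & (meas.status == "ok")]
            genome_values = dict(zip(sub.genome_id, sub.difference))
            members = cluster_members_from_assignment(cs, genome_values)
            sampled = sample_by_cluster(members, quota, seed)
            meas_by_genome = {
                r.genome_id: r for r in sub.itertuples()}
            masked = {}
            states = {}
            sketches = {}
            by_cluster = {gid2: cid for cid, gids in members.items()
                          for gid2 in gids}
            for gid2 in sampled:
                row = meas_by_genome[gid2]
                lm = LocusMeasurement(gene_id, gid2, row.contig_id,
                                      row.prefix_start, row.suffix_start,
                                      row.orientation, row.span,
                                      row.difference, row.status)
                ext = extract_and_mask(genomes[gid2], lm, qmap[gene_id])
                masked[gid2] = ext.masked_genome
                locus_seqs[gid2] = ext.locus_seq
                states[gid2] = by_cluster[gid2]
                if by_cluster[gid2] in call.positive_cluster_ids:
                    intervening[gid2] = ext.locus_seq
                lo = min(row.prefix_start, row.suffix_start)
                hi = max(row.prefix_start, row.suffix_start) + qmap[
                    gene_id].k
                arrays, sc = cached_hashes(gid2, genomes[gid2])
                sketches[gid2] = sketch_from_hashes(
                    arrays, sketch_size, sketch_k,
                    exclude={row.contig_id: (lo, hi)}, _sorted_counts=sc)
            for og_id, og_contigs in outgroups.items():
                arrays, sc = cached_hashes(og_id, og_contigs)
                sketches[og_id] = sketch_from_hashes(
                    arrays, sketch_size, sketch_k, _sorted_counts=sc)
            tree = build_rooted_tree(masked, outgroups, states,
                                     sketch_size=sketch_size,
                                     sketch_k=sketch_k, sketches=sketches)
            ancestry = fitch_mrca(tree, gene_id, call.zero_cluster_id,
                                  call.positive_cluster_ids)
            if ancestry.classification == "split_ancestor":
                stage = 3
        results[gene_id] = GeneResult(gene_id, call, cs, ancestry, stage,
                                      intervening, locus_seqs)
    return meas, results


def coverage_by_ancestry(results: dict[str, GeneResult],
                         mge_db: list[tuple[str, str]],
                         max_per_gene: int = 5,
                         ) -> tuple[list[float], list[float]]:
    """Mean MGE coverage fraction per locus, grouped by MRCA state.

    For each stage >= 2 gene with an unambiguous ancestral call, the
    intervening sequences of up to ``max_per_gene`` positive-cluster
    genomes are aligned to the MGE database and the mean covered fraction
    is recorded, yielding (split_ancestor_fracs, intact_ancestor_fracs).
    """
    split_fracs: list[float] = []
    intact_fracs: list[float] = []
    for gr in results.values():
        if gr.ancestry is None:
            continue
        cls = gr.ancestry.classification
        if cls not in ("split_ancestor", "intact_ancestor"):
            continue
        seqs = sorted(gr.intervening_by_genome.items())[:max_per_gene]
        if not seqs:
            continue
        fracs = [mge_coverage(s, mge_db).fraction for _, s in seqs]
        mean_frac = sum(fracs) / len(fracs)
        (split_fracs if cls == "split_ancestor" else
         intact_fracs).append(mean_frac)
    return split_fracs, intact_fracs
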