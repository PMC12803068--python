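"""Codon-aware dN/dS counting and surrogate pre-deletion genes."""

import numpy as np
import pytest

from fusescan.kmer_screen import reverse_complement
from fusescan.selection_analysis import (CodonDiffCount, build_surrogate,
                                         codon_align, count_codon_diffs,
                                         find_orfs, selection_for_cluster,
                                         weighted_dnds)
from conftest import random_dna

STOPS = {"TAA", "TAG", "TGA"}


def random_cds(rng, n_codons):
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = random_dna(rng, 3)
        if c not in STOPS:
            codons.append(c)
    return "".join(codons) + "TAA"


class TestCodonCounting:
    def test_identical_sequences(self):
        c = count_codon_diffs("AAACCC", "AAACCC")
        assert (c.syn, c.nonsyn, c.stop_gains) == (0, 0, 0)

    def test_manual_codon_table_example(self):
        # AAA->AAG is Lys->Lys (syn); CCC->ACC is Pro->Thr (nonsyn)
        c = count_codon_diffs("AAACCC", "AAGACC")
        assert c.syn == 1 and c.nonsyn == 1
        est = weighted_dnds([c], [1])
        assert est.ratio == 1.0

    def test_gap_and_ambiguous_codons_skipped(self):
        c = count_codon_diffs("AAACCCGGG", "AAA---GNG")
        assert c.codons_skipped == 2
        assert c.syn == 0 and c.nonsyn == 0

    def test_stop_gain_tracked_separately(self):
        # CAA (Gln) -> TAA (stop)
        c = count_codon_diffs("CAA", "TAA")
        assert c.stop_gains == 1 and c.syn == 0 and c.nonsyn == 0

    def test_frame_incompatible_alignment_errors(self):
        with pytest.raises(ValueError):
            count_codon_diffs("AAAA", "AAAA")

    @pytest.mark.parametrize("seed", range(30))
    def test_path_average_totals_match_site_differences(self, seed):
        r = np.random.default_rng(seed)
        bases = "ACGT"
        c1 = "".join(r.choice(list(bases), 3))
        c2 = "".join(r.choice(list(bases), 3))
        if c1 in STOPS or c2 in STOPS:
            return
        cnt = count_codon_diffs(c1, c2)
        ndiff = sum(a != b for a, b in zip(c1, c2))
        if cnt.stop_gains == 0:
            assert cnt.syn + cnt.nonsyn == pytest.approx(ndiff)


class TestWeightedDnds:
    def test_weighted_ratio_example(self):
        x = CodonDiffCount(syn=0, nonsyn=1)  # in 3 genomes
        y = CodonDiffCount(syn=1, nonsyn=0)  # in 1 genome
        est = weighted_dnds([x, y], [3, 1])
        assert est.ratio == 3.0

    def test_all_identical_undefined_ratio(self):
        est = weighted_dnds([CodonDiffCount(), CodonDiffCount()], [5, 2])
        assert est.ratio is None and est.weighted_dN == 0

    def test_weight_scaling_invariance(self):
        counts = [CodonDiffCount(syn=2, nonsyn=3),
                  CodonDiffCount(syn=1, nonsyn=0)]
        a = weighted_dnds(counts, [2, 3])
        b = weighted_dnds(counts, [4, 6])
        assert a.ratio == b.ratio

    def test_order_invariance(self):
        counts = [CodonDiffCount(syn=2, nonsyn=3),
                  CodonDiffCount(syn=1, nonsyn=5)]
        a = weighted_dnds(counts, [2, 3])
        b = weighted_dnds(counts[::-1], [3, 2])
        assert a.ratio == b.ratio

    def test_parameter_recovery_simulation(self):
        """Sequences mutated with known syn:nonsyn ratio recover it."""
        rng = np.random.default_rng(42)
        ref = random_cds(rng, 200)
        # catalogue strictly single-site syn and nonsyn codon changes
        from fusescan.selection_analysis import _translate_codon
        syn_muts, nonsyn_muts = [], []
        for ci in range(1, len(ref) // 3 - 1):
            codon = ref[ci * 3:ci * 3 + 3]
            for pos in range(3):
                for b in "ACGT":
                    if b == codon[pos]:
                        continue
                    alt = codon[:pos] + b + codon[pos + 1:]
                    if alt in STOPS:
                        continue
                    pair = (ci, alt)
                    if _translate_codon(alt) == _translate_codon(codon):
                        syn_muts.append(pair)
                    else:
                        nonsyn_muts.append(pair)
        target = 2.0  # nonsyn:syn ratio
        total_dn = total_ds = 0.0
        for _ in range(200):
            seq = list(ref)
            picks = {}
            for _ in range(6):
                if rng.random() < target / (1 + target):
                    ci, alt = nonsyn_muts[rng.integers(len(nonsyn_muts))]
                else:
                    ci, alt = syn_muts[rng.integers(len(syn_muts))]
                picks[ci] = alt
            for ci, alt in picks.items():
                seq[ci * 3:ci * 3 + 3] = alt
            cnt = count_codon_diffs(ref, "".join(seq))
            total_dn += cnt.nonsyn
            total_ds += cnt.syn
        assert total_dn / total_ds == pytest.approx(target, rel=0.15)


class TestCodonAlign:
    def test_identity_alignment(self, rng):
        cds = random_cds(rng, 50)
        ra, aa = codon_align(cds, cds)
        assert ra == aa == cds

    def test_internal_deletion_backmaps_in_frame(self, rng):
        cds = random_cds(rng, 60)
        alt = cds[:30] + cds[60:]  # drop 10 codons in frame
        ra, aa = codon_align(cds, alt)
        assert len(ra) == len(aa)
        assert len(ra) % 3 == 0
        cnt = count_codon_diffs(ra, aa)
        assert cnt.codons_skipped == 10
        assert cnt.syn == 0 and cnt.nonsyn == 0


class TestOrfsAndSurrogate:
    def test_finds_planted_orf_both_strands(self, rng):
        # the reported ORF may extend to an earlier in-frame start in the
        # random flank, so the planted ORF is a suffix of it
        orf = random_cds(rng, 60)  # 180 bp
        seq = random_dna(rng, 200) + orf + random_dna(rng, 200)
        fwd = [o for o in find_orfs(seq) if o.strand == "+"]
        assert any(o.extract(seq).endswith(orf) for o in fwd)
        rev_seq = reverse_complement(seq)
        rev = [o for o in find_orfs(rev_seq) if o.strand == "-"]
        assert any(o.extract(rev_seq).endswith(orf) for o in rev)

    def test_min_length_enforced(self, rng):
        short = "ATG" + "AAA" * 10 + "TAA"  # 36 bp < 90
        seq = random_dna(rng, 100) + short + random_dna(rng, 100)
        assert not any(o.extract(seq) == short for o in find_orfs(seq))

    def _two_fragment_scenario(self, rng):
        """Locus = [5' ORF][spacer][3' ORF]; query = fused gene."""
        frag5 = random_cds(rng, 100)  # 300 bp, self-contained ORF
        frag3 = random_cds(rng, 120)
        query = frag5[:-3] + frag3[3:]  # fuse, dropping stop and start
        spacer = random_dna(rng, 2000)
        locus = frag5 + spacer + frag3
        flank = random_dna(rng, 300) + locus + random_dna(rng, 300)
        return query, locus, flank, frag5, frag3

    def test_two_fragment_surrogate_recovered_in_order(self, rng):
        query, locus, flank, frag5, frag3 = self._two_fragment_scenario(rng)
        sg = build_surrogate(query, locus, flank)
        assert sg is not None
        assert len(sg.segments) == 2
        assert sg.stitched_seq.count("NNN") >= 1
        parts = sg.stitched_seq.split("NNN")
        # chosen ORFs may extend to an earlier upstream in-frame start
        assert parts[0].endswith(frag5)
        assert parts[-1].endswith(frag3)

    def test_single_orf_query_gives_single_segment(self, rng):
        gene = random_cds(rng, 150)
        locus = random_dna(rng, 500) + gene + random_dna(rng, 500)
        flank = random_dna(rng, 200) + locus + random_dna(rng, 200)
        sg = build_surrogate(gene, locus, flank)
        assert sg is not None
        assert len(sg.segments) == 1
        assert "NNN" not in sg.stitched_seq

    def test_no_alignment_returns_none(self, rng):
        sg = build_surrogate(random_cds(rng, 100), random_dna(rng, 1000),
                             random_dna(rng, 2000))
        assert sg is None

    def test_surrogate_codon_alignment_skips_only_joints(self, rng):
        query, locus, flank, frag5, frag3 = self._two_fragment_scenario(rng)
        sg = build_surrogate(query, locus, flank)
        ra, aa = codon_align(query, sg.stitched_seq)
        cnt = count_codon_diffs(ra, aa)
        assert cnt.codons_skipped > 0
        # skipped codons stem from joints/indel codons, not substitutions
        assert cnt.syn + cnt.nonsyn == 0


class TestSelectionForCluster:
    def test_deduplication_and_weighting(self, rng):
        ref = random_cds(rng, 80)
        # one nonsyn variant shared by 3 genomes, reference in 2
        alt = list(ref)
        # mutate codon 10 first base: ensure nonsyn and no stop
        for b in "ACGT":
            cand = b + ref[31:33]
            from fusescan.selection_analysis import _translate_codon
            if cand not in STOPS and \
                    _translate_codon(cand) != _translate_codon(ref[30:33]):
                alt[30] = b
                break
        alt = "".join(alt)
        est = selection_for_cluster(ref, [alt, alt, alt, ref, ref])
        assert est.n_unique == 2
        assert est.n_genomes == 5
        assert est.weighted_dN == 3.0
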