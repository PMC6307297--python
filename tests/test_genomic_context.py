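"""Context classification: windows, divergence, overlap, census, distances."""

import numpy as np
import pytest

from heartlnc.candidate_filter import LncCandidate, identify_candidates
from heartlnc.genome_model import GenomeAnnotation, point_to_span_distance
from heartlnc.genomic_context import (
    ContextConfig,
    classify_genomic_context,
    compute_nearest_distances,
    orientation_census,
)

from conftest import make_gene, make_matrix, make_transcript


def _candidate(tid="lncA", **kwargs):
    return LncCandidate(transcript=make_transcript(tid, gid=f"{tid}_g", **kwargs))


def _coding(gid, start, strand="+", length=12_000):
    return make_gene(gid, chrom="chr1", start=start, strand=strand,
                     exon_lengths=(length,), intron=0)


class TestBidirectional:
    def test_divergent_tss_within_window(self):
        # coding TSS at 10,000 on '+'; lncRNA on '-' with TSS at 9,500 points left
        coding = _coding("pc1", 10_000)
        lnc_t = make_transcript("lncA", gid="lg", chrom="chr1", start=8_500,
                                strand="-", exon_lengths=(400, 400), intron=200)
        assert lnc_t.tss == 9_500
        cand = LncCandidate(transcript=lnc_t)
        ann = GenomeAnnotation([coding, make_gene("lg", "lncRNA_candidate", (lnc_t,))])
        classify_genomic_context([cand], ann)
        assert cand.context == "bidirectional"
        assert cand.bidirectional_partners == ("pc1",)

    def test_convergent_orientation_not_bidirectional(self):
        # short '+' gene, lncRNA on '-' to its right pointing back at it:
        # TSSs are 2 kb apart but the pair is head-to-head-to-tail (convergent)
        coding = _coding("pc1", 50_000, length=400)
        lnc_t = make_transcript("lncA", gid="lg", chrom="chr1", start=51_200,
                                strand="-", exon_lengths=(300, 300), intron=200)
        assert lnc_t.tss == 52_000
        cand = LncCandidate(transcript=lnc_t)
        ann = GenomeAnnotation([coding, make_gene("lg", "lncRNA_candidate", (lnc_t,))])
        classify_genomic_context([cand], ann)
        assert cand.context == "intergenic"
        assert not cand.same_strand_proximal
        relaxed = ContextConfig(require_divergent=False)
        classify_genomic_context([cand], ann, relaxed)
        assert cand.context == "bidirectional"

    def test_same_strand_proximal_is_diagnostic_only(self):
        coding = _coding("pc1", 50_000)
        lnc_t = make_transcript("lncA", gid="lg", chrom="chr1", start=47_500,
                                strand="+", exon_lengths=(400, 400), intron=200)
        cand = LncCandidate(transcript=lnc_t)
        ann = GenomeAnnotation([coding, make_gene("lg", "lncRNA_candidate", (lnc_t,))])
        classify_genomic_context([cand], ann)
        assert cand.context == "intergenic"
        assert cand.same_strand_proximal

    def test_window_monotonicity(self, sim_data):
        annotation, _, matrix = sim_data
        cands = identify_candidates(annotation.transcripts(), matrix)
        classify_genomic_context(cands, annotation, ContextConfig(bidirectional_window=3000))
        small = {c.transcript_id for c in cands if c.bidirectional_partners}
        classify_genomic_context(cands, annotation, ContextConfig(bidirectional_window=8000))
        large = {c.transcript_id for c in cands if c.bidirectional_partners}
        assert small <= large


class TestAntisense:
    def test_intronic_opposite_strand_overlap_is_antisense_only(self):
        # mirrors the Tbx5ua geometry: lncRNA inside an intron of the host,
        # opposite strand, TSS ~5 kb away from the host promoter
        host_t = make_transcript("pc1.t1", gid="pc1", biotype="protein_coding",
                                 chrom="chr1", start=10_000, strand="+",
                                 exon_lengths=(500, 500), intron=9_000)
        host = make_gene("pc1", transcripts=(host_t,))
        lnc_t = make_transcript("lncA", gid="lg", chrom="chr1", start=14_000,
                                strand="-", exon_lengths=(300, 300), intron=400)
        cand = LncCandidate(transcript=lnc_t)
        ann = GenomeAnnotation([host, make_gene("lg", "lncRNA_candidate", (lnc_t,))])
        classify_genomic_context([cand], ann)
        assert cand.context == "antisense"
        assert cand.antisense_partners == ("pc1",)

    def test_alternative_promoter_gives_both(self):
        # isoform 1 spans the lncRNA (antisense); isoform 2's TSS sits 1 kb
        # downstream of the lncRNA TSS on the opposite strand (bidirectional)
        iso1 = make_transcript("pc1.t1", gid="pc1", biotype="protein_coding",
                               chrom="chr1", start=10_000, strand="+",
                               exon_lengths=(500, 500), intron=9_000)
        iso2 = make_transcript("pc1.t2", gid="pc1", biotype="protein_coding",
                               chrom="chr1", start=16_000, strand="+",
                               exon_lengths=(500, 500), intron=3_000)
        host = make_gene("pc1", transcripts=(iso1, iso2))
        lnc_t = make_transcript("lncA", gid="lg", chrom="chr1", start=13_000,
                                strand="-", exon_lengths=(800, 800), intron=400)
        cand = LncCandidate(transcript=lnc_t)
        ann = GenomeAnnotation([host, make_gene("lg", "lncRNA_candidate", (lnc_t,))])
        classify_genomic_context([cand], ann)
        assert cand.context == "both"


class TestPlantedRecovery:
    def test_all_planted_labels_recovered(self, sim_data):
        annotation, truth, matrix = sim_data
        cands = identify_candidates(annotation.transcripts(), matrix)
        classify_genomic_context(cands, annotation)
        for c in cands:
            assert c.context == truth.lnc_class[c.transcript_id], c.transcript_id

    def test_mirror_image_preserves_every_class_label(self, sim_data):
        """Strand flip combined with coordinate reflection is an exact
        symmetry of the classifier: each candidate keeps its label."""
        annotation, _, matrix = sim_data
        cands = identify_candidates(annotation.transcripts(), matrix)
        classify_genomic_context(cands, annotation)
        original = {c.transcript_id: c.context for c in cands}
        mirrored = annotation.mirror()
        m_cands = identify_candidates(mirrored.transcripts(), matrix)
        classify_genomic_context(m_cands, mirrored)
        assert {c.transcript_id: c.context for c in m_cands} == original


class TestNearestDistances:
    def test_expressed_neighbor_preferred_over_closer_silent_gene(self):
        expressed = _coding("pc_far", 8_000, length=4_000)
        silent = _coding("pc_near", 5_500, length=500)
        lnc_t = make_transcript("lncA", gid="lg", chrom="chr1", start=4_600,
                                strand="+", exon_lengths=(150, 150), intron=100)
        assert lnc_t.tss == 4_600 + 0  # TSS at span start
        cand = LncCandidate(transcript=lnc_t)
        ann = GenomeAnnotation([expressed, silent, make_gene("lg", "lncRNA_candidate", (lnc_t,))])
        matrix = make_matrix({
            "pc_far.t1": (5, 5, 5, 5),
            "pc_near.t1": (0.1, 0.1, 0.1, 0.1),
            "lncA": (3, 3, 3, 0),
        })
        compute_nearest_distances([cand], ann, matrix)
        assert cand.nearest_gene == "pc_far"
        assert cand.nearest_distance == point_to_span_distance(4_600, 8_000, 12_000)

    def test_distances_match_brute_force(self, sim_data, rng):
        annotation, _, matrix = sim_data
        cands = identify_candidates(annotation.transcripts(), matrix)
        compute_nearest_distances(cands, annotation, matrix)
        coding = annotation.genes_of_biotype("protein_coding")
        for c in cands:
            t = c.transcript
            dists = sorted(
                (point_to_span_distance(t.tss, g.span.start, g.span.end), g.gene_id)
                for g in coding if g.chrom == t.chrom
            )
            assert (c.nearest_distance, c.nearest_gene) == dists[0]

    def test_empty_pool_sets_sentinel(self):
        lnc_t = make_transcript("lncA", gid="lg")
        cand = LncCandidate(transcript=lnc_t)
        ann = GenomeAnnotation([make_gene("lg", "lncRNA_candidate", (lnc_t,))])
        compute_nearest_distances([cand], ann, None)
        assert cand.nearest_gene is None and cand.nearest_distance is None


class TestOrientationCensus:
    def test_counts_match_direct_tally(self, sim_data):
        annotation, truth, matrix = sim_data
        cands = identify_candidates(annotation.transcripts(), matrix)
        opposite, same = orientation_census(cands, annotation)
        # direct tally over known genes (everything except lncRNA candidates)
        known = [g for g in annotation.genes.values() if g.biotype != "lncRNA_candidate"]
        exp_opp = exp_same = 0
        for c in cands:
            t = c.transcript
            best = None
            for g in known:
                if g.chrom != t.chrom:
                    continue
                d = point_to_span_distance(t.tss, g.span.start, g.span.end)
                if best is None or (d, g.gene_id) < best[:2]:
                    best = (d, g.gene_id, g.strand)
            if best is None or best[0] > 10_000:
                continue
            if best[2] == t.strand:
                exp_same += 1
            else:
                exp_opp += 1
        assert (opposite, same) == (exp_opp, exp_same)

    def test_gap_beyond_window_excluded(self):
        coding = _coding("pc1", 50_000)
        lnc_t = make_transcript("lncA", gid="lg", chrom="chr1", start=20_000,
                                strand="-", exon_lengths=(300, 300), intron=200)
        cand = LncCandidate(transcript=lnc_t)
        ann = GenomeAnnotation([coding, make_gene("lg", "lncRNA_candidate", (lnc_t,))])
        assert orientation_census([cand], ann) == (0, 0)
        wide = ContextConfig(proximity_window=40_000)
        assert orientation_census([cand], ann, wide) == (1, 0)
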