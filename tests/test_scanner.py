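import numpy as np
import pytest

from metboxscan.iwm import BASES, ScanThresholds, reverse_complement
from metboxscan.scanner import BoxHit, call_sites, scan_boxes, scan_genome
from metboxscan.sequence_io import GeneRecord, UpstreamRegion


def region_of(seq, gene_id="g", strand="+", genomic_start=1):
    return UpstreamRegion(
        gene_id=gene_id,
        sequence=seq,
        genomic_start=genomic_start,
        genomic_end=genomic_start + len(seq) - 1,
        strand=strand,
        contig_id="c",
    )


@pytest.fixture(scope="module")
def thresholds(final_matrix):
    return ScanThresholds.from_matrix(final_matrix)


def naive_scan(sequence, matrix, tau_box):
    """Independent oracle: rescore every window with explicit arithmetic."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    idx = {b: i for i, b in enumerate(BASES)}
    hits = []
    for i in range(len(sequence) - 7):
        window = sequence[i : i + 8]
        score = 0.0
        for j, base in enumerate(window):
            col = j if j < 4 else 7 - j
            if j >= 4:
                base = comp[base]
            if base == "N":
                score += matrix.bits[:, col].min()
            else:
                score += matrix.bits[idx[base], col]
        if score >= tau_box:
            hits.append((i, score))
    return hits


class TestScanBoxes:
    def test_single_consensus_hit(self, final_matrix, thresholds):
        region = region_of("TTTTAGACGTCTTTTT")
        hits = scan_boxes(region, final_matrix, thresholds)
        assert len(hits) == 1
        assert hits[0].region_offset == 4
        assert hits[0].sequence == "AGACGTCT"
        assert hits[0].score == pytest.approx(12.58, abs=0.01)

    def test_poly_a_no_hits(self, final_matrix, thresholds):
        assert scan_boxes(region_of("A" * 50), final_matrix, thresholds) == []

    def test_short_region_empty(self, final_matrix, thresholds):
        assert scan_boxes(region_of("ACGTACG"), final_matrix, thresholds) == []

    def test_hits_in_offset_order(self, final_matrix, thresholds):
        region = region_of("AGACGTCT" * 5)
        hits = scan_boxes(region, final_matrix, thresholds)
        offsets = [h.region_offset for h in hits]
        assert offsets == sorted(offsets)

    def test_matches_naive_oracle(self, final_matrix, thresholds):
        rng = np.random.default_rng(17)
        for _ in range(50):
            seq = "".join(BASES[i] for i in rng.integers(0, 4, 400))
            hits = scan_boxes(region_of(seq), final_matrix, thresholds)
            expected = naive_scan(seq, final_matrix, thresholds.tau_box)
            assert [(h.region_offset, pytest.approx(h.score)) for h in hits] == [
                (o, pytest.approx(s)) for o, s in expected
            ]

    def test_n_never_creates_hit(self, final_matrix, thresholds):
        # N forces the worst weight: a consensus window with N must score lower
        hits = scan_boxes(region_of("TTTTAGNCGTCTTTTT"), final_matrix, thresholds)
        assert hits == []


class TestCallSites:
    def test_tandem_pair(self, final_matrix, thresholds):
        region = region_of("TTTTAGACGTCTAGACGTCTTTTT")
        hits = scan_boxes(region, final_matrix, thresholds)
        (site,) = call_sites(hits, thresholds)
        assert [b.region_offset for b in site.boxes] == [4, 12]
        assert site.total_score == pytest.approx(25.16, abs=0.02)
        assert (site.region_start, site.region_end) == (4, 20)

    def test_single_box_never_a_site(self, thresholds):
        hits = [BoxHit(4, "AGACGTCT", 12.58)]
        assert call_sites(hits, thresholds) == []

    def test_pair_below_site_threshold(self, thresholds):
        hits = [BoxHit(4, "AAAAAAAA", 3.20), BoxHit(12, "AAAAAAAA", 3.30)]
        assert call_sites(hits, thresholds) == []

    def test_triple_run_single_site(self, final_matrix, thresholds):
        region = region_of("TT" + "AGACGTCT" * 3 + "TT")
        hits = scan_boxes(region, final_matrix, thresholds)
        (site,) = call_sites(hits, thresholds)
        assert len(site.boxes) == 3
        assert site.total_score == pytest.approx(3 * 12.584, abs=0.01)

    def test_gap_breaks_run(self, thresholds):
        hits = [BoxHit(0, "AGACGTCT", 12.58), BoxHit(9, "AGACGTCT", 12.58)]
        assert call_sites(hits, thresholds) == []

    def test_spacing_tolerance_bridges_gap(self, thresholds):
        hits = [BoxHit(0, "AGACGTCT", 12.58), BoxHit(9, "AGACGTCT", 12.58)]
        (site,) = call_sites(hits, thresholds, spacing_tolerance=1)
        assert len(site.boxes) == 2

    def test_unsorted_input_rejected(self, thresholds):
        hits = [BoxHit(12, "AGACGTCT", 12.58), BoxHit(4, "AGACGTCT", 12.58)]
        with pytest.raises(ValueError, match="sorted"):
            call_sites(hits, thresholds)

    def test_out_of_phase_overlap_keeps_higher_total(self, thresholds):
        # two 2-box runs overlapping in span; second run scores higher
        low = [BoxHit(0, "X", 7.0), BoxHit(8, "X", 7.0)]
        high = [BoxHit(3, "Y", 8.0), BoxHit(11, "Y", 8.0)]
        hits = sorted(low + high, key=lambda h: h.region_offset)
        (site,) = call_sites(hits, thresholds)
        assert [b.region_offset for b in site.boxes] == [3, 11]

    def test_out_of_phase_tie_keeps_leftmost(self, thresholds):
        a = [BoxHit(0, "X", 7.0), BoxHit(8, "X", 7.0)]
        b = [BoxHit(3, "Y", 7.0), BoxHit(11, "Y", 7.0)]
        hits = sorted(a + b, key=lambda h: h.region_offset)
        (site,) = call_sites(hits, thresholds)
        assert site.region_start == 0

    def test_non_overlapping_runs_both_kept(self, final_matrix, thresholds):
        region = region_of("AGACGTCT" * 2 + "T" * 20 + "AGACGTCT" * 2)
        hits = scan_boxes(region, final_matrix, thresholds)
        sites = call_sites(hits, thresholds)
        assert len(sites) == 2

    def test_monotonicity_in_thresholds(self, final_matrix):
        rng = np.random.default_rng(5)
        seq = "".join(BASES[i] for i in rng.integers(0, 4, 300))
        seq = seq[:40] + "AGACGTCTAGACGTCT" + seq[56:]
        region = region_of(seq)
        base = ScanThresholds.from_matrix(final_matrix)
        n_base = len(call_sites(scan_boxes(region, final_matrix, base), base))
        for factor in (1.1, 1.5, 2.0):
            tighter = ScanThresholds(base.tau_box * factor, base.tau_site * factor)
            n = len(call_sites(scan_boxes(region, final_matrix, tighter), tighter))
            assert n <= n_base
            n_base = n


class TestScanGenome:
    def make_genome(self, upstream, strand="+"):
        """One gene with a controlled upstream window."""
        body = "ATG" + "C" * 27
        if strand == "+":
            contig = upstream + body
            gene = GeneRecord("g1", "c1", "+", len(upstream) + 1, len(contig))
        else:
            contig = body + reverse_complement(upstream)
            gene = GeneRecord("g1", "c1", "-", 1, len(body))
        return {"c1": contig}, [gene]

    def test_planted_site_recovered_plus(self, final_matrix, thresholds):
        upstream = "T" * 40 + "AGACGTCTAGACGTCT" + "T" * 44
        genome, genes = self.make_genome(upstream, "+")
        (site,) = scan_genome(genome, genes, final_matrix, thresholds, window=100)
        assert site.gene_id == "g1"
        assert (site.genomic_start, site.genomic_end) == (41, 56)
        assert site.distance_to_start == 44
        assert not site.shared

    def test_planted_site_recovered_minus(self, final_matrix, thresholds):
        upstream = "T" * 40 + "AGACGTCTAGACGTCT" + "T" * 44
        genome, genes = self.make_genome(upstream, "-")
        (site,) = scan_genome(genome, genes, final_matrix, thresholds, window=100)
        # forward span: region runs 31..130, site at region offsets 40..55
        assert site.genomic_end - site.genomic_start + 1 == 16
        forward = genome["c1"][site.genomic_start - 1 : site.genomic_end]
        assert reverse_complement(forward) == "AGACGTCTAGACGTCT"

    def test_background_false_positive_rate(self, final_matrix, thresholds):
        # uniform background, 50 genes: sites are expected to be rare; the
        # measured count at this seed is the false-positive rate of the
        # default thresholds (~2% of regions)
        rng = np.random.default_rng(23)
        contig = "".join(BASES[i] for i in rng.integers(0, 4, 25500))
        genes = [
            GeneRecord(f"g{i}", "c1", "+", 500 * i + 401, 500 * i + 500)
            for i in range(50)
        ]
        sites = scan_genome({"c1": contig}, genes, final_matrix, thresholds)
        assert len(sites) <= 3

    def test_divergent_pair_shared_flag(self, final_matrix, thresholds):
        # two genes facing away, one planted site in the shared intergenic gap
        left_body = "ATGAAACCC"
        right_body = "ATGTTTGGG"
        gap = "T" * 10 + "AGACGTCTAGACGTCT" + "T" * 10
        contig = reverse_complement(left_body) + gap + right_body
        genes = [
            GeneRecord("gL", "c1", "-", 1, len(left_body)),
            GeneRecord("gR", "c1", "+", len(left_body) + len(gap) + 1, len(contig)),
        ]
        sites = scan_genome({"c1": contig}, genes, final_matrix, thresholds, window=36)
        assert {s.gene_id for s in sites} == {"gL", "gR"}
        spans = {(s.genomic_start, s.genomic_end) for s in sites}
        assert len(spans) == 1
        assert all(s.shared for s in sites)

    def test_reverse_complement_region_same_span(self, final_matrix, thresholds):
        # scanning the revcomp orientation of the same DNA yields the same
        # genomic span (strand symmetry end to end)
        upstream = "T" * 20 + "AGACGTCTAGACGTCT" + "T" * 24
        genome_p, genes_p = self.make_genome(upstream, "+")
        (sp,) = scan_genome(genome_p, genes_p, final_matrix, thresholds, window=60)
        forward = genome_p["c1"][sp.genomic_start - 1 : sp.genomic_end]
        genome_m = {"c1": reverse_complement(genome_p["c1"])}
        L = len(genome_p["c1"])
        gene_m = GeneRecord("g1", "c1", "-", L - genes_p[0].end + 1, L - genes_p[0].start + 1)
        (sm,) = scan_genome(genome_m, [gene_m], final_matrix, thresholds, window=60)
        mirrored = genome_m["c1"][sm.genomic_start - 1 : sm.genomic_end]
        assert mirrored == reverse_complement(forward)
        assert sm.total_score == pytest.approx(sp.total_score)
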