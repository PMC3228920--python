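"""Box scanning and tandem-site assembly under the two-threshold rule.

A single 8-bp box must score at least ``tau_box`` (a quarter of the
consensus score by default); boxes abutting at exactly 8-bp spacing chain
into runs, and a run of two or more boxes becomes a site call when its
summed score reaches ``tau_site`` (the full consensus score by default).
Scanning is forward-strand only: the symmetrized matrix scores a window and
its reverse complement identically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .iwm import BOX_WIDTH, InformationWeightMatrix, ScanThresholds
from .sequence_io import GeneRecord, UpstreamRegion, extract_upstream

__all__ = ["BoxHit", "SiteCall", "GenomicSite", "scan_boxes", "call_sites", "scan_genome"]


@dataclass(frozen=True)
class BoxHit:
    """A scored 8-bp window inside an upstream region."""

    region_offset: int
    sequence: str
    score: float


@dataclass(frozen=True)
class SiteCall:
    """A run of >=2 abutting boxes whose summed score passes the site cutoff."""

    boxes: tuple[BoxHit, ...]
    total_score: float
    region_start: int
    region_end: int  # half-open within the region
    gene_id: str = ""


@dataclass(frozen=True)
class GenomicSite:
    """A site call lifted to forward-strand genomic coordinates (1-based)."""

    gene_id: str
    contig_id: str
    strand: str
    genomic_start: int
    genomic_end: int
    boxes: tuple[BoxHit, ...]
    total_score: float
    distance_to_start: int
    shared: bool = False


def scan_boxes(
    region: UpstreamRegion | str,
    matrix: InformationWeightMatrix,
    thresholds: ScanThresholds,
) -> list[BoxHit]:
    """Score every 8-bp window and keep those at or above ``tau_box``.

    Hits come back in offset order.  Regions shorter than 8 bp yield an
    empty list.
    """
    sequence = region.sequence if isinstance(region, UpstreamRegion) else region
    scores = matrix.score_all_windows(sequence)
    return [
        BoxHit(region_offset=i, sequence=sequence[i : i + BOX_WIDTH], score=float(s))
        for i, s in enumerate(scores)
        if s >= thresholds.tau_box
    ]


def _chain_runs(hits: Sequence[BoxHit], spacing_tolerance: int) -> list[list[BoxHit]]:
    """Partition hits into maximal runs of consecutive in-phase boxes.

    A hit's successor is the nearest hit starting 8 bp (up to
    ``spacing_tolerance`` extra bases) after it; out-of-phase hits in between
    belong to their own chains and never break a run.  Every hit joins
    exactly one chain.
    """
    runs: list[list[BoxHit]] = []
    consumed: set[int] = set()
    by_offset = {h.region_offset: h for h in hits}
    for hit in hits:
        if hit.region_offset in consumed:
            continue
        chain = [hit]
        consumed.add(hit.region_offset)
        cursor = hit
        while True:
            succ = next(
                (
                    by_offset[o]
                    for o in range(
                        cursor.region_offset + BOX_WIDTH,
                        cursor.region_offset + BOX_WIDTH + spacing_tolerance + 1,
                    )
                    if o in by_offset and o not in consumed
                ),
                None,
            )
            if succ is None:
                break
            chain.append(succ)
            consumed.add(succ.region_offset)
            cursor = succ
        runs.append(chain)
    return runs


def call_sites(
    hits: Sequence[BoxHit],
    thresholds: ScanThresholds,
    spacing_tolerance: int = 0,
    gene_id: str = "",
) -> list[SiteCall]:
    """Assemble tandem sites from box hits.

    Maximal runs of abutting boxes with >=2 members and summed score >=
    ``tau_site`` become site calls.  When two passing runs overlap in span
    (out-of-phase boxes), the higher-total run wins; ties go to the leftmost.

    Raises
    ------
    ValueError
        If hits are not sorted by offset.
    """
    offsets = [h.region_offset for h in hits]
    if offsets != sorted(offsets):
        raise ValueError("box hits must be sorted by region offset")

    candidates: list[SiteCall] = []
    for run in _chain_runs(hits, spacing_tolerance):
        if len(run) < 2:
            continue
        total = sum(h.score for h in run)
        if total < thresholds.tau_site:
            continue
        candidates.append(
            SiteCall(
                boxes=tuple(run),
                total_score=total,
                region_start=run[0].region_offset,
                region_end=run[-1].region_offset + BOX_WIDTH,
                gene_id=gene_id,
            )
        )

    # resolve span overlaps between out-of-phase runs: best total first,
    # leftmost on ties
    kept: list[SiteCall] = []
    for site in sorted(candidates, key=lambda s: (-s.total_score, s.region_start)):
        if all(
            site.region_end <= k.region_start or site.region_start >= k.region_end
            for k in kept
        ):
            kept.append(site)
    return sorted(kept, key=lambda s: s.region_start)


def scan_genome(
    genome: Mapping[str, str],
    genes: Sequence[GeneRecord],
    matrix: InformationWeightMatrix,
    thresholds: ScanThresholds,
    window: int = 400,
    spacing_tolerance: int = 0,
) -> list[GenomicSite]:
    """Scan every gene's upstream window and lift calls to genomic coordinates.

    A physically identical genomic span reachable from two genes (divergent
    pair sharing an intergenic region) is reported once per gene with the
    ``shared`` flag set on both.
    """
    sites: list[GenomicSite] = []
    for gene in genes:
        region = extract_upstream(genome, gene, window=window)
        if len(region) < BOX_WIDTH:
            continue
        hits = scan_boxes(region, matrix, thresholds)
        for call in call_sites(hits, thresholds, spacing_tolerance, gene_id=gene.gene_id):
            width = call.region_end - call.region_start
            gstart, gend = region.offset_to_genomic(call.region_start, width)
            distance = len(region) - call.region_end
            sites.append(
                GenomicSite(
                    gene_id=gene.gene_id,
                    contig_id=gene.contig_id,
                    strand=gene.strand,
                    genomic_start=gstart,
                    genomic_end=gend,
                    boxes=call.boxes,
                    total_score=call.total_score,
                    distance_to_start=distance,
                )
            )
    spans: dict[tuple[str, int, int], int] = {}
    for s in sites:
        key = (s.contig_id, s.genomic_start, s.genomic_end)
        spans[key] = spans.get(key, 0) + 1
    return [
        replace(s, shared=spans[(s.contig_id, s.genomic_start, s.genomic_end)] > 1)
        for s in sites
    ]
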