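"""Two-stage bootstrap regulon discovery and per-order regulon summaries.

Stage 1 builds a seed matrix from known operator boxes.  Stage 2 scans the
upstream windows of candidate regulon homologs in one representative
species per genus (de-biasing) with the seed matrix's own consensus-derived
thresholds, and pools the half-sites of every box inside a passing tandem
site.  Stage 3 rebuilds the matrix from that pool; stage 4 scans every
genome with it; stage 5 tallies gene-family presence and site calls per
taxonomic order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .iwm import InformationWeightMatrix, ScanThresholds, build_matrix, symmetrize_boxes
from .scanner import GenomicSite, call_sites, scan_boxes, scan_genome
from .sequence_io import GeneRecord, UpstreamRegion, extract_upstream

__all__ = [
    "SpeciesRecord",
    "RegulonSummary",
    "DiscoveryResult",
    "select_representatives",
    "preliminary_collect",
    "discover",
    "summarize_regulon",
]

logger = logging.getLogger("metboxscan")


@dataclass(frozen=True)
class SpeciesRecord:
    """A species with its genus (for de-biasing) and taxonomic order label."""

    species_id: str
    genus: str
    order_label: str
    genome_path: str = ""
    annotation_path: str = ""

    def __post_init__(self) -> None:
        if not self.genus:
            raise ValueError(f"species {self.species_id}: genus must be nonempty")


@dataclass
class RegulonSummary:
    """Per gene-family, per-order membership counts.

    ``cells[(family, order)] = (species_with_gene, species_with_metboxes)``,
    rendered as "n (m)" in reports.
    """

    cells: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    orders: tuple[str, ...] = ()

    def families(self) -> list[str]:
        return sorted({fam for fam, _ in self.cells})

    def totals(self, family: str) -> tuple[int, int]:
        gene = sum(v[0] for (f, _), v in self.cells.items() if f == family)
        box = sum(v[1] for (f, _), v in self.cells.items() if f == family)
        return gene, box

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in self.families():
            row: dict[str, str] = {"family": fam}
            for order in self.orders:
                n, m = self.cells.get((fam, order), (0, 0))
                row[order] = f"{n} ({m})"
            n, m = self.totals(fam)
            row["total"] = f"{n} ({m})"
            rows.append(row)
        return pd.DataFrame(rows, columns=["family", *self.orders, "total"])


@dataclass
class DiscoveryResult:
    seed_matrix: InformationWeightMatrix
    final_matrix: InformationWeightMatrix
    pooled_half_sites: list[str]
    sites: dict[str, list[GenomicSite]]  # species_id -> calls
    summary: RegulonSummary
    stage_counts: dict[str, int] = field(default_factory=dict)


def select_representatives(
    species: Sequence[SpeciesRecord], policy: str = "lexicographic"
) -> list[SpeciesRecord]:
    """Pick exactly one species per genus, deterministically.

    The default (and only built-in) policy keeps the lexicographically first
    ``species_id`` within each genus.
    """
    if policy != "lexicographic":
        raise ValueError(f"unknown representative policy {policy!r}")
    by_genus: dict[str, SpeciesRecord] = {}
    for sp in sorted(species, key=lambda s: s.species_id):
        by_genus.setdefault(sp.genus, sp)
    return sorted(by_genus.values(), key=lambda s: s.species_id)


def preliminary_collect(
    seed_matrix: InformationWeightMatrix,
    candidate_regions: Iterable[UpstreamRegion],
    thresholds: ScanThresholds | None = None,
    spacing_tolerance: int = 0,
) -> list[str]:
    """Scan candidate upstream regions and pool half-sites of passing boxes.

    Every box inside every tandem site passing both thresholds contributes
    its two half-sites.  Raises if no region yields a passing site (a final
    matrix could not be built).
    """
    if thresholds is None:
        thresholds = ScanThresholds.from_matrix(seed_matrix)
    pooled: list[str] = []
    for region in candidate_regions:
        hits = scan_boxes(region, seed_matrix, thresholds)
        for site in call_sites(hits, thresholds, spacing_tolerance, gene_id=region.gene_id):
            pooled.extend(symmetrize_boxes([b.sequence for b in site.boxes]))
    if not pooled:
        raise RuntimeError(
            "preliminary scan found no passing sites; cannot build a final matrix"
        )
    return pooled


def summarize_regulon(
    site_calls: Mapping[str, Sequence[GenomicSite]],
    ortholog_map: Mapping[tuple[str, str], str],
    species: Sequence[SpeciesRecord],
) -> RegulonSummary:
    """Tally, per gene family and order, how many species carry the gene and
    how many of those carry a called tandem site upstream of it."""
    order_of = {sp.species_id: sp.order_label for sp in species}
    orders = tuple(dict.fromkeys(sp.order_label for sp in species))

    gene_presence: dict[tuple[str, str], set[str]] = {}
    for (sp_id, _gene_id), family in ortholog_map.items():
        if sp_id in order_of:
            gene_presence.setdefault((family, order_of[sp_id]), set()).add(sp_id)

    box_presence: dict[tuple[str, str], set[str]] = {}
    for sp_id, calls in site_calls.items():
        if sp_id not in order_of:
            continue
        for call in calls:
            family = ortholog_map.get((sp_id, call.gene_id))
            if family is None:
                warnings.warn(
                    f"gene {call.gene_id} in {sp_id} has a site but no family; "
                    "tallying as 'unassigned'"
                )
                family = "unassigned"
                gene_presence.setdefault((family, order_of[sp_id]), set()).add(sp_id)
            box_presence.setdefault((family, order_of[sp_id]), set()).add(sp_id)

    cells = {
        key: (len(gene_sp), len(box_presence.get(key, set())))
        for key, gene_sp in gene_presence.items()
    }
    return RegulonSummary(cells=cells, orders=orders)


def discover(
    seed_boxes: Sequence[str],
    species: Sequence[SpeciesRecord],
    genomes: Mapping[str, Mapping[str, str]],
    genes: Mapping[str, Sequence[GeneRecord]],
    ortholog_map: Mapping[tuple[str, str], str],
    candidate_families: set[str] | None = None,
    window: int = 400,
    mu_bits: float = 2.0,
    pseudocount: float = 1.0,
    spacing_tolerance: int = 0,
    tau_box: float | None = None,
    tau_site: float | None = None,
) -> DiscoveryResult:
    """Run the full two-stage bootstrap.

    ``candidate_families`` restricts the stage-2 preliminary scan to genes of
    known-regulon families; the default uses every family in the ortholog
    map.  Thresholds at each stage derive from that stage's own matrix
    unless overridden.  Fully deterministic for identical inputs.
    """
    if not seed_boxes:
        raise ValueError("stage 1 (seed matrix): no seed boxes provided")
    if not species:
        raise ValueError("stage 2 (preliminary scan): no species provided")

    seed_matrix = build_matrix(
        half_sites=symmetrize_boxes(seed_boxes), mu_bits=mu_bits, pseudocount=pseudocount
    )
    logger.info("[stage1] seed matrix from %d boxes", len(seed_boxes))

    if candidate_families is None:
        candidate_families = set(ortholog_map.values())
    reps = select_representatives(species)
    candidate_regions: list[UpstreamRegion] = []
    for sp in reps:
        for gene in genes[sp.species_id]:
            if ortholog_map.get((sp.species_id, gene.gene_id)) in candidate_families:
                region = extract_upstream(genomes[sp.species_id], gene, window=window)
                if len(region) >= 8:
                    candidate_regions.append(region)
    logger.info(
        "[stage2] %d representative species, %d candidate regions",
        len(reps),
        len(candidate_regions),
    )
    pooled = preliminary_collect(
        seed_matrix, candidate_regions, spacing_tolerance=spacing_tolerance
    )
    logger.info("[stage2] pooled %d half-sites", len(pooled))

    final_matrix = build_matrix(half_sites=pooled, mu_bits=mu_bits, pseudocount=pseudocount)
    logger.info(
        "[stage3] final matrix, consensus %.2f bits", final_matrix.consensus_score()
    )

    thresholds = ScanThresholds.from_matrix(final_matrix, tau_box=tau_box, tau_site=tau_site)
    sites: dict[str, list[GenomicSite]] = {}
    for sp in species:
        sites[sp.species_id] = scan_genome(
            genomes[sp.species_id],
            genes[sp.species_id],
            final_matrix,
            thresholds,
            window=window,
            spacing_tolerance=spacing_tolerance,
        )
    n_sites = sum(len(v) for v in sites.values())
    logger.info("[stage4] %d sites across %d species", n_sites, len(species))

    summary = summarize_regulon(sites, ortholog_map, species)
    logger.info("[stage5] %d families summarized", len(summary.families()))

    return DiscoveryResult(
        seed_matrix=seed_matrix,
        final_matrix=final_matrix,
        pooled_half_sites=pooled,
        sites=sites,
        summary=summary,
        stage_counts={
            "seed_boxes": len(seed_boxes),
            "representatives": len(reps),
            "candidate_regions": len(candidate_regions),
            "pooled_half_sites": len(pooled),
            "sites": n_sites,
        },
    )
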