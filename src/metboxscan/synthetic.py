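"""Synthetic cohorts with planted tandem sites and ground-truth bookkeeping.

Generates bacterial-like contigs in which genes are tiled with fixed-length
upstream windows, a chosen fraction of genes carry a planted array of
abutting 8-bp boxes sampled from a source matrix at controlled fidelity,
and every planting is recorded with exact genomic coordinates.  Both
strands are represented (genes alternate orientation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .iwm import BASES, BOX_WIDTH, HALF_WIDTH, InformationWeightMatrix, reverse_complement
from .pipeline import SpeciesRecord
from .sequence_io import GeneRecord

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "Cohort",
    "sample_box",
    "generate_cohort",
    "consensus_planting_matrix",
]

_ORDER_LABELS = ("Ent", "Pas", "Vib", "Aer", "Alt")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for cohort generation.

    ``fidelity`` is the per-base probability of drawing from the matrix's
    frequency model instead of the uniform distribution.  The default site
    placement puts the mode of the site-to-start-codon distance near 75 bp;
    ``site_offset_distribution="uniform"`` spreads it over the window.
    """

    n_species: int = 5
    genes_per_species: int = 50
    upstream_len: int = 400
    gene_len: int = 120
    gc_fraction: float = 0.5
    boxes_per_site: int = 2
    planting_fraction: float = 0.5
    fidelity: float = 1.0
    site_offset_distribution: str = "near_start"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "planting_fraction", "fidelity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.boxes_per_site < 2:
            raise ValueError("boxes_per_site must be >= 2")
        if self.upstream_len < BOX_WIDTH * self.boxes_per_site:
            raise ValueError(
                f"upstream_len {self.upstream_len} cannot hold "
                f"{self.boxes_per_site} boxes of {BOX_WIDTH} bp"
            )


@dataclass(frozen=True)
class TruthRecord:
    """One planted site: where it is and what was written there."""

    species_id: str
    gene_id: str
    contig_id: str
    genomic_start: int  # 1-based inclusive, forward strand
    genomic_end: int
    strand: str
    region_offset: int  # 0-based within the gene-oriented upstream window
    box_sequences: tuple[str, ...]
    expected_score: float


@dataclass
class Cohort:
    """In-memory synthetic dataset plus writers for on-disk fixtures."""

    config: SyntheticConfig
    species: list[SpeciesRecord]
    genomes: dict[str, dict[str, str]]
    genes: dict[str, list[GeneRecord]]
    ortholog_map: dict[tuple[str, str], str]  # (species_id, gene_id) -> family
    truth: list[TruthRecord] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in self.species:
            with open(outdir / f"{sp.species_id}.fasta", "w") as fa:
                for contig, seq in self.genomes[sp.species_id].items():
                    fa.write(f">{contig}\n")
                    for i in range(0, len(seq), 70):
                        fa.write(seq[i : i + 70] + "\n")
            with open(outdir / f"{sp.species_id}.genes.tsv", "w") as gt:
                for g in self.genes[sp.species_id]:
                    gt.write(f"{g.contig_id}\t{g.strand}\t{g.start}\t{g.end}\t{g.gene_id}\t{g.name}\n")
        with open(outdir / "species.tsv", "w") as st:
            st.write("species_id\tgenus\torder_label\n")
            for sp in self.species:
                st.write(f"{sp.species_id}\t{sp.genus}\t{sp.order_label}\n")
        with open(outdir / "orthologs.tsv", "w") as om:
            om.write("species_id\tgene_id\tfamily\n")
            for (sp_id, gene_id), fam in sorted(self.ortholog_map.items()):
                om.write(f"{sp_id}\t{gene_id}\t{fam}\n")
        with open(outdir / "truth.bed", "w") as bed:
            for t in self.truth:
                bed.write(
                    f"{t.contig_id}\t{t.genomic_start - 1}\t{t.genomic_end}\t"
                    f"{t.species_id}:{t.gene_id}\t{round(t.expected_score * 10)}\t{t.strand}\n"
                )
        with open(outdir / "truth.json", "w") as js:
            json.dump(
                {
                    "config": asdict(self.config),
                    "sites": [asdict(t) for t in self.truth],
                },
                js,
                indent=1,
            )


def consensus_planting_matrix(
    consensus_half: str = "AGAC",
    n_observations: int = 832,
    minor_count: int = 1,
) -> InformationWeightMatrix:
    """A sharply peaked matrix for planting benchmarks.

    Frequency models estimated from threshold-passing sites understate the
    positional correlation of real boxes, so independently resampling each
    position from such a matrix yields many boxes that would fail the
    thresholds derived from it.  Recovery benchmarks therefore plant from a
    matrix whose columns put nearly all mass on the consensus base
    (``minor_count`` observations on each of the other three bases).
    """
    from .iwm import _BASE_INDEX, build_matrix  # local import avoids cycle noise

    counts = np.full((4, HALF_WIDTH), minor_count, dtype=np.int64)
    for pos, base in enumerate(consensus_half):
        counts[_BASE_INDEX[base], pos] = n_observations - 3 * minor_count
    return build_matrix(counts=counts)


def _sample_half(
    matrix: InformationWeightMatrix, fidelity: float, rng: np.random.Generator
) -> str:
    freqs = matrix.frequencies
    half = []
    for pos in range(HALF_WIDTH):
        if rng.random() < fidelity:
            p = freqs[:, pos] / freqs[:, pos].sum()
            half.append(BASES[rng.choice(4, p=p)])
        else:
            half.append(BASES[rng.integers(4)])
    return "".join(half)


def sample_box(
    matrix: InformationWeightMatrix, fidelity: float, rng: np.random.Generator
) -> str:
    """Draw one 8-bp box: two independent half-sites, the second mirrored.

    Preserves the palindromic statistics of the source matrix: positions
    5-8 are the reverse complement of a half drawn from the same model.
    """
    first = _sample_half(matrix, fidelity, rng)
    second = _sample_half(matrix, fidelity, rng)
    return first + reverse_complement(second)


def _background(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=p))


def _site_offset(
    config: SyntheticConfig, site_len: int, rng: np.random.Generator
) -> int:
    """0-based site start within the upstream window."""
    max_d = config.upstream_len - site_len
    if config.site_offset_distribution == "uniform" or max_d == 0:
        d = int(rng.integers(0, max_d + 1))
    else:
        # distance from site end to the start codon, mode near 75 bp
        mode = min(75, max_d)
        d = int(rng.triangular(0, mode, max_d))
    return config.upstream_len - site_len - d


def generate_cohort(
    config: SyntheticConfig, matrix: InformationWeightMatrix
) -> Cohort:
    """Generate genomes, annotations, orthologs and planted-site truth.

    Layout per species: one contig of ``genes_per_species`` slots, each an
    upstream window followed (or preceded, for minus-strand genes) by a gene
    body.  Genes alternate strand; gene ``i`` belongs to family ``fam{i}``
    in every species, giving a trivially correct ortholog map.
    """
    rng = np.random.default_rng(config.seed)
    site_len = BOX_WIDTH * config.boxes_per_site
    slot = config.upstream_len + config.gene_len

    species: list[SpeciesRecord] = []
    genomes: dict[str, dict[str, str]] = {}
    genes: dict[str, list[GeneRecord]] = {}
    orthologs: dict[tuple[str, str], str] = {}
    truth: list[TruthRecord] = []

    for s in range(config.n_species):
        sp_id = f"sp{s:02d}"
        contig_id = f"{sp_id}_c1"
        species.append(
            SpeciesRecord(
                species_id=sp_id,
                genus=f"genus{s:02d}",
                order_label=_ORDER_LABELS[s % len(_ORDER_LABELS)],
            )
        )
        n_planted = round(config.planting_fraction * config.genes_per_species)
        planted = set(
            rng.choice(config.genes_per_species, size=n_planted, replace=False).tolist()
        )
        segments: list[str] = []
        gene_list: list[GeneRecord] = []
        for i in range(config.genes_per_species):
            gene_id = f"{sp_id}_g{i:03d}"
            strand = "+" if i % 2 == 0 else "-"
            upstream = _background(config.upstream_len, config.gc_fraction, rng)
            boxes: tuple[str, ...] = ()
            offset = -1
            if i in planted:
                boxes = tuple(
                    sample_box(matrix, config.fidelity, rng)
                    for _ in range(config.boxes_per_site)
                )
                offset = _site_offset(config, site_len, rng)
                upstream = (
                    upstream[:offset] + "".join(boxes) + upstream[offset + site_len :]
                )
            body = _background(config.gene_len, config.gc_fraction, rng)
            slot_start = i * slot  # 0-based forward position of this slot
            if strand == "+":
                segments.append(upstream + body)
                gene_start = slot_start + config.upstream_len + 1
                gene_end = slot_start + slot
                region_fwd_start = slot_start + 1
                site_start = region_fwd_start + offset
                site_end = site_start + site_len - 1
            else:
                segments.append(body + reverse_complement(upstream))
                gene_start = slot_start + 1
                gene_end = slot_start + config.gene_len
                region_fwd_end = slot_start + slot
                site_end = region_fwd_end - offset
                site_start = site_end - site_len + 1
            gene_list.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=contig_id,
                    strand=strand,
                    start=gene_start,
                    end=gene_end,
                    name=f"fam{i:03d}",
                )
            )
            orthologs[(sp_id, gene_id)] = f"fam{i:03d}"
            if i in planted:
                truth.append(
                    TruthRecord(
                        species_id=sp_id,
                        gene_id=gene_id,
                        contig_id=contig_id,
                        genomic_start=site_start,
                        genomic_end=site_end,
                        strand=strand,
                        region_offset=offset,
                        box_sequences=boxes,
                        expected_score=sum(matrix.score_window(b) for b in boxes),
                    )
                )
        genomes[sp_id] = {contig_id: "".join(segments)}
        genes[sp_id] = gene_list

    return Cohort(
        config=config,
        species=species,
        genomes=genomes,
        genes=genes,
        ortholog_map=orthologs,
        truth=truth,
    )
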