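"""Genome/annotation reading and strand-aware upstream-region extraction.

Coordinates follow each format's native convention at the file boundary
(GFF3 and gene tables: 1-based inclusive; BED: 0-based half-open) and are
0-based half-open internally.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

from Bio import SeqIO

from .iwm import reverse_complement

__all__ = [
    "GeneRecord",
    "UpstreamRegion",
    "read_genome",
    "read_annotations",
    "extract_upstream",
    "write_sites_bed",
    "write_sites_tsv",
]

_VALID = re.compile(r"[^ACGT]")


def _normalize(seq: str) -> str:
    """Uppercase and collapse anything outside A/C/G/T to N."""
    return _VALID.sub("N", seq.upper())


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene with 1-based inclusive genomic coordinates."""

    gene_id: str
    contig_id: str
    strand: str
    start: int
    end: int
    name: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: coordinates are 1-based, got start {self.start}")


@dataclass(frozen=True)
class UpstreamRegion:
    """Gene-oriented upstream window mapped back to forward-strand coordinates.

    ``sequence`` reads 5'->3' toward the start codon: its last base is
    immediately adjacent to the first codon base.  For minus-strand genes it
    is the reverse complement of the forward-strand slice
    ``[genomic_start, genomic_end]`` (1-based inclusive).
    """

    gene_id: str
    sequence: str
    genomic_start: int
    genomic_end: int
    strand: str
    contig_id: str = ""

    def __post_init__(self) -> None:
        expected = self.genomic_end - self.genomic_start + 1
        if self.sequence and len(self.sequence) != expected:
            raise ValueError(
                f"region for {self.gene_id}: sequence length {len(self.sequence)} "
                f"!= span {expected}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def offset_to_genomic(self, offset: int, width: int) -> tuple[int, int]:
        """Map a window at ``offset`` (0-based within ``sequence``) to 1-based
        inclusive forward-strand coordinates."""
        if self.strand == "+":
            start = self.genomic_start + offset
            return start, start + width - 1
        end = self.genomic_end - offset
        return end - width + 1, end


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA file into ``{contig_id: sequence}``.

    Sequences are uppercased and non-ACGT characters become N.  Empty files
    and duplicate identifiers are hard errors.
    """
    genome: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in genome:
                raise ValueError(f"{path}: duplicate contig identifier {record.id!r}")
            genome[record.id] = _normalize(str(record.seq))
    if not genome:
        raise ValueError(f"{path}: no FASTA records found")
    return genome


def _parse_gff3(handle: IO[str], path: str) -> Iterable[GeneRecord]:
    wanted = {"CDS", "gene"}
    seen_ids: set[str] = set()
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
        contig, _, ftype, start_s, end_s, _, strand, _, attrs = fields[:9]
        if ftype not in wanted:
            continue
        start, end = int(start_s), int(end_s)
        if start > end:
            raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
        if strand not in "+-":
            raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        gene_id = attr_map.get("ID") or attr_map.get("locus_tag") or f"feat{lineno}"
        if gene_id in seen_ids:
            # a gene and its CDS share an ID lineage; keep the first
            continue
        seen_ids.add(gene_id)
        yield GeneRecord(
            gene_id=gene_id,
            contig_id=contig,
            strand=strand,
            start=start,
            end=end,
            name=attr_map.get("Name", ""),
            product=attr_map.get("product", ""),
        )


def _parse_gene_table(handle: IO[str], path: str) -> Iterable[GeneRecord]:
    """Tab-separated: contig, strand, start, end, locus tag[, gene name]."""
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(f"{path}:{lineno}: expected >=5 columns, got {len(fields)}")
        contig, strand, start_s, end_s, gene_id = fields[:5]
        start, end = int(start_s), int(end_s)
        if start > end:
            raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
        if strand not in "+-":
            raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
        yield GeneRecord(
            gene_id=gene_id,
            contig_id=contig,
            strand=strand,
            start=start,
            end=end,
            name=fields[5] if len(fields) > 5 else "",
        )


def read_annotations(path: str | Path) -> list[GeneRecord]:
    """Read gene annotations from GFF3 (``.gff``/``.gff3``) or a TSV table.

    Records come back sorted by contig then start.  Duplicate gene_ids across
    the file are a hard error (GFF3 gene+CDS pairs sharing an ID collapse to
    one record).
    """
    path = Path(path)
    with _open_text(path) as handle:
        if path.name.replace(".gz", "").endswith((".gff", ".gff3")):
            records = list(_parse_gff3(handle, str(path)))
        else:
            records = list(_parse_gene_table(handle, str(path)))
    ids = [r.gene_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"{path}: duplicate gene identifiers {dupes}")
    return sorted(records, key=lambda r: (r.contig_id, r.start, r.gene_id))


def extract_upstream(
    genome: Mapping[str, str], gene: GeneRecord, window: int = 400
) -> UpstreamRegion:
    """Strand-aware upstream window of ``gene``, truncated at contig edges.

    For a plus-strand gene the window is the forward slice
    ``[start-window, start-1]``; for minus strand the reverse complement of
    ``[end+1, end+window]``.  Windows are never padded, never clipped at
    neighboring genes, and a zero-length result only triggers a warning.
    """
    try:
        contig = genome[gene.contig_id]
    except KeyError:
        raise KeyError(f"gene {gene.gene_id}: contig {gene.contig_id!r} not in genome")
    if gene.strand == "+":
        lo = max(0, gene.start - 1 - window)  # 0-based half-open
        hi = gene.start - 1
        seq = contig[lo:hi]
    else:
        lo = gene.end
        hi = min(len(contig), gene.end + window)
        seq = reverse_complement(contig[lo:hi])
    if not seq:
        warnings.warn(f"gene {gene.gene_id}: zero-length upstream region at contig edge")
        # degenerate coordinates: empty span flagged by genomic_end < genomic_start
        return UpstreamRegion(
            gene_id=gene.gene_id,
            sequence="",
            genomic_start=lo + 1,
            genomic_end=lo,
            strand=gene.strand,
            contig_id=gene.contig_id,
        )
    return UpstreamRegion(
        gene_id=gene.gene_id,
        sequence=seq,
        genomic_start=lo + 1,
        genomic_end=hi,
        strand=gene.strand,
        contig_id=gene.contig_id,
    )


def write_sites_bed(sites, path: str | Path) -> None:
    """Write genomic site calls as BED6 (score = total bits x 10, rounded)."""
    with open(path, "w") as out:
        for s in sites:
            out.write(
                f"{s.contig_id}\t{s.genomic_start - 1}\t{s.genomic_end}\t"
                f"{s.gene_id}\t{round(s.total_score * 10)}\t{s.strand}\n"
            )


def write_sites_tsv(sites, path: str | Path) -> None:
    """Detailed per-site TSV (1-based inclusive coordinates)."""
    header = (
        "gene_id\tcontig\tstart\tend\tstrand\tn_boxes\tbox_sequences\t"
        "box_scores\ttotal_bits\tdistance_to_start\tshared\n"
    )
    with open(path, "w") as out:
        out.write(header)
        for s in sites:
            out.write(
                f"{s.gene_id}\t{s.contig_id}\t{s.genomic_start}\t{s.genomic_end}\t"
                f"{s.strand}\t{len(s.boxes)}\t"
                f"{','.join(b.sequence for b in s.boxes)}\t"
                f"{','.join(f'{b.score:.2f}' for b in s.boxes)}\t"
                f"{s.total_score:.2f}\t{s.distance_to_start}\t"
                f"{int(s.shared)}\n"
            )
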