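"""The published final half-site counts table, shipped with the package.

Counts are per base (rows A, C, G, T) per half-site position 1-4; each
column sums to the 832 half-sites pooled by the original genome-scale scan.
The position-3 zero count for T is pseudocounted to 1 when weights are
formed.
"""

from __future__ import annotations

from importlib import resources

from .iwm import InformationWeightMatrix

__all__ = ["published_counts_tsv", "published_matrix"]


def published_counts_tsv() -> str:
    """Raw TSV text of the shipped counts table."""
    return (
        resources.files("metboxscan")
        .joinpath("data/final_matrix_counts.tsv")
        .read_text()
    )


def published_matrix(
    mu_bits: float = 2.0, pseudocount: float = 1.0
) -> InformationWeightMatrix:
    """Information weight matrix built from the shipped counts."""
    return InformationWeightMatrix.from_counts_tsv(
        published_counts_tsv(), mu_bits=mu_bits, pseudocount=pseudocount
    )
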