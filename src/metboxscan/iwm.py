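"""Palindromic information weight matrix: construction and window scoring.

The matrix models an 8-bp palindromic operator box through its 4-position
half-site.  Weights are information contents in bits,

    R(b, l) = mu + log2(f(b, l)),    f(b, l) = n(b, l) / N,

with ``mu`` an additive constant (2 bits for DNA under a uniform background)
and zero counts replaced by a pseudocount before the frequency is formed
(the denominator N is left unchanged).  An 8-bp window is scored by summing
the half-site weight of the observed base over positions 1-4 and, for
positions 5-8, the weight of the *complemented* base at the mirrored
position.  This makes every score exactly strand-symmetric.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BASES",
    "HALF_WIDTH",
    "BOX_WIDTH",
    "InformationWeightMatrix",
    "ScanThresholds",
    "symmetrize_boxes",
    "build_matrix",
    "reverse_complement",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

HALF_WIDTH = 4
BOX_WIDTH = 8


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0 C=1 G=2 T=3 N=4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def symmetrize_boxes(boxes: Iterable[str]) -> list[str]:
    """Decompose 8-bp boxes into half-sites, folding in the palindrome.

    Each box contributes its first 4 bases and the reverse complement of its
    last 4 bases, so ``len(output) == 2 * len(input)``.

    Raises
    ------
    ValueError
        If any box is not exactly 8 A/C/G/T characters.
    """
    halves: list[str] = []
    for box in boxes:
        if len(box) != BOX_WIDTH:
            raise ValueError(f"box {box!r} is not {BOX_WIDTH} bp")
        if any(c not in _BASE_INDEX for c in box):
            raise ValueError(f"box {box!r} contains a non-ACGT character")
        halves.append(box[:HALF_WIDTH])
        halves.append(reverse_complement(box[HALF_WIDTH:]))
    return halves


@dataclass(frozen=True)
class InformationWeightMatrix:
    """Half-site counts plus derived bit weights.

    Attributes
    ----------
    counts : (4, 4) int array
        Rows are bases A, C, G, T; columns are half-site positions 1-4.
    n_observations : int
        Number of half-sites tallied (every column of ``counts`` sums to it).
    mu_bits : float
        Additive constant of the weight equation.
    pseudocount : float
        Replacement for zero counts before taking the log.
    bits : (4, 4) float array
        Derived weights in bits; never stored independently of the counts.
    """

    counts: np.ndarray
    n_observations: int
    mu_bits: float = 2.0
    pseudocount: float = 1.0
    bits: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (4, HALF_WIDTH):
            raise ValueError(f"counts must be 4x{HALF_WIDTH}, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        colsums = counts.sum(axis=0)
        if not np.all(colsums == self.n_observations):
            raise ValueError(
                f"column sums {colsums.tolist()} != n_observations {self.n_observations}"
            )
        if self.n_observations <= 0:
            raise ValueError("n_observations must be positive")
        adjusted = np.where(counts == 0, self.pseudocount, counts)
        bits = self.mu_bits + np.log2(adjusted / self.n_observations)
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "bits", bits)
        # Full 8-position weight view used by the scanner: positions 5-8 read
        # the complemented base at the mirrored half position.  A 5th base row
        # (N) carries the worst weight of each position — conservative, never
        # a wildcard.
        full = np.empty((BOX_WIDTH, 5))
        full[:HALF_WIDTH, :4] = bits.T
        full[HALF_WIDTH:, :4] = bits.T[::-1][:, _COMPLEMENT_INDEX[:4]]
        full[:, 4] = full[:, :4].min(axis=1)
        object.__setattr__(self, "_full_weights", full)

    # -- frequencies -------------------------------------------------------

    @property
    def frequencies(self) -> np.ndarray:
        """Pseudocount-adjusted base frequencies per half position (4x4)."""
        adjusted = np.where(self.counts == 0, self.pseudocount, self.counts)
        return adjusted / self.n_observations

    # -- scoring -----------------------------------------------------------

    def score_window(self, window: str) -> float:
        """Bit score of one 8-bp window (strand symmetric by construction)."""
        if len(window) != BOX_WIDTH:
            raise ValueError(f"window must be {BOX_WIDTH} bp, got {len(window)}")
        codes = _encode(window.upper())
        return float(self._full_weights[np.arange(BOX_WIDTH), codes].sum())

    def score_all_windows(self, sequence: str) -> np.ndarray:
        """Score every 8-bp window of ``sequence`` (vectorized).

        Returns an array of length ``len(sequence) - 7`` (empty for shorter
        input).
        """
        codes = _encode(sequence.upper())
        n = codes.size - BOX_WIDTH + 1
        if n <= 0:
            return np.empty(0)
        windows = np.lib.stride_tricks.sliding_window_view(codes, BOX_WIDTH)
        return self._full_weights[np.arange(BOX_WIDTH), windows].sum(axis=1)

    def consensus_score(self) -> float:
        """Score of the best possible window: twice the half-site maxima sum."""
        return float(2.0 * self.bits.max(axis=0).sum())

    def consensus_box(self) -> str:
        """Highest-scoring 8-mer (half-site argmax, mirrored)."""
        half = "".join(BASES[i] for i in self.bits.argmax(axis=0))
        return half + reverse_complement(half)

    # -- serialization -----------------------------------------------------

    def to_tsv(self) -> str:
        """Counts-then-bits table, rows A/C/G/T, columns 1(8)..4(5)."""
        cols = ["1 (8)", "2 (7)", "3 (6)", "4 (5)"]
        buf = io.StringIO()
        buf.write("base\t" + "\t".join(f"count {c}" for c in cols))
        buf.write("\t" + "\t".join(f"bits {c}" for c in cols) + "\n")
        for i, b in enumerate(BASES):
            row = [b]
            row += [str(int(c)) for c in self.counts[i]]
            row += [f"{v:.2f}" for v in self.bits[i]]
            buf.write("\t".join(row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_counts_tsv(
        cls, text: str, mu_bits: float = 2.0, pseudocount: float = 1.0
    ) -> "InformationWeightMatrix":
        """Parse a counts table (rows A/C/G/T, first 4 numeric columns)."""
        counts = np.zeros((4, HALF_WIDTH), dtype=np.int64)
        seen = set()
        for line in text.splitlines():
            fields = line.strip().split("\t")
            if not fields or fields[0] not in _BASE_INDEX:
                continue
            base = fields[0]
            values = [int(round(float(x))) for x in fields[1 : 1 + HALF_WIDTH]]
            counts[_BASE_INDEX[base]] = values
            seen.add(base)
        if seen != set(BASES):
            raise ValueError(f"counts table missing rows for {set(BASES) - seen}")
        return build_matrix(counts=counts, mu_bits=mu_bits, pseudocount=pseudocount)


def build_matrix(
    half_sites: Sequence[str] | None = None,
    counts: np.ndarray | None = None,
    mu_bits: float = 2.0,
    pseudocount: float = 1.0,
) -> InformationWeightMatrix:
    """Build an :class:`InformationWeightMatrix` from half-sites or counts.

    Exactly one of ``half_sites`` (4-mers) or ``counts`` (4x4, equal column
    sums) must be given.
    """
    if (half_sites is None) == (counts is None):
        raise ValueError("provide exactly one of half_sites or counts")
    if half_sites is not None:
        if len(half_sites) == 0:
            raise ValueError("no half-sites to tally")
        tally = np.zeros((4, HALF_WIDTH), dtype=np.int64)
        for hs in half_sites:
            if len(hs) != HALF_WIDTH:
                raise ValueError(f"half-site {hs!r} is not {HALF_WIDTH} bp")
            for pos, base in enumerate(hs):
                try:
                    tally[_BASE_INDEX[base], pos] += 1
                except KeyError:
                    raise ValueError(f"half-site {hs!r} contains a non-ACGT character")
        counts = tally
        n_obs = len(half_sites)
    else:
        counts = np.asarray(counts)
        n_obs = int(counts[:, 0].sum())
    return InformationWeightMatrix(
        counts=counts, n_observations=n_obs, mu_bits=mu_bits, pseudocount=pseudocount
    )


@dataclass(frozen=True)
class ScanThresholds:
    """Box- and site-level bit-score cutoffs.

    Defaults derive from a matrix's consensus score: a single box must reach
    a quarter of it and the summed tandem site the full value.
    """

    tau_box: float
    tau_site: float

    @classmethod
    def from_matrix(
        cls,
        matrix: InformationWeightMatrix,
        tau_box: float | None = None,
        tau_site: float | None = None,
    ) -> "ScanThresholds":
        consensus = matrix.consensus_score()
        return cls(
            tau_box=consensus / 4.0 if tau_box is None else tau_box,
            tau_site=consensus if tau_site is None else tau_site,
        )
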