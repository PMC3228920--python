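"""Cross-species conservation of site regions versus a reference species.

A site region is the tandem box span plus 8 bp of flanking DNA on each
side.  Percent identity is an ungapped column-wise comparison; tiers follow
the >=70% (strong) / >=60% (weak) rule, everything below is divergent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .sequence_io import UpstreamRegion
from .scanner import SiteCall

__all__ = [
    "ConservationCall",
    "TIER_STRONG_MIN",
    "TIER_WEAK_MIN",
    "extract_site_context",
    "percent_identity",
    "classify_tier",
    "classify_conservation",
]

TIER_STRONG_MIN = 70.0
TIER_WEAK_MIN = 60.0


@dataclass(frozen=True)
class ConservationCall:
    species_id: str
    family: str
    query_region: str
    reference_region: str
    percent_identity: float | None
    tier: str  # strong | weak | divergent | not-evaluable


def classify_tier(identity: float) -> str:
    if identity >= TIER_STRONG_MIN:
        return "strong"
    if identity >= TIER_WEAK_MIN:
        return "weak"
    return "divergent"


def extract_site_context(
    region: UpstreamRegion | str, site: SiteCall, flank: int = 8
) -> str:
    """Site span extended by ``flank`` bases each side, truncated at edges."""
    sequence = region.sequence if isinstance(region, UpstreamRegion) else region
    lo = max(0, site.region_start - flank)
    hi = min(len(sequence), site.region_end + flank)
    return sequence[lo:hi]


def percent_identity(query: str, reference: str) -> float:
    """Ungapped percent identity between two site regions.

    Equal lengths compare column-wise end to end.  Otherwise the shorter
    sequence slides along the longer at every offset and the best match
    count is taken; the denominator is always the shorter length.
    """
    if not query or not reference:
        raise ValueError("percent_identity requires two nonempty sequences")
    short, long_ = (query, reference) if len(query) <= len(reference) else (reference, query)
    best = 0
    for shift in range(len(long_) - len(short) + 1):
        matches = sum(a == b for a, b in zip(short, long_[shift : shift + len(short)]))
        best = max(best, matches)
    return 100.0 * best / len(short)


def classify_conservation(
    site_regions: Mapping[str, Mapping[str, str]],
    reference_species: str,
) -> list[ConservationCall]:
    """Tier every (species, gene family) site region against the reference.

    ``site_regions`` maps species_id -> {family: context sequence}.  A family
    absent from the reference species yields a ``not-evaluable`` call.
    """
    reference = site_regions.get(reference_species, {})
    calls: list[ConservationCall] = []
    for species_id in sorted(site_regions):
        if species_id == reference_species:
            continue
        for family in sorted(site_regions[species_id]):
            query = site_regions[species_id][family]
            ref = reference.get(family)
            if ref is None:
                calls.append(
                    ConservationCall(species_id, family, query, "", None, "not-evaluable")
                )
                continue
            identity = percent_identity(query, ref)
            calls.append(
                ConservationCall(
                    species_id, family, query, ref, identity, classify_tier(identity)
                )
            )
    return calls


def write_conservation_tsv(calls: list[ConservationCall], path) -> None:
    with open(path, "w") as out:
        out.write("species\tfamily\tpercent_identity\ttier\n")
        for c in calls:
            pid = "" if c.percent_identity is None else f"{c.percent_identity:.3f}"
            out.write(f"{c.species_id}\t{c.family}\t{pid}\t{c.tier}\n")
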