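"""Four-criterion readthrough calling from per-region footprint statistics.

A transcript/dataset is called positive for translational readthrough when
all four of the following hold (thresholds configurable, defaults below):

1. at least 45 P-sites in the coding sequence,
2. at least 1 P-site in the second half of the inter-stop codon region,
3. at least 10% of the ISR covered by footprint spans, and
4. ISR footprint density at least threefold that of the rest of the 3'UTR.

Density is the number of P-sites in a region divided by the region length;
by default both the counts and the denominators omit the 12-nt exclusion
zones (effective lengths), with nominal-length densities also reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .footprint_mapper import Footprint
from .transcript_model import (
    REGION_NAMES,
    RegionMap,
    TranscriptAnnotation,
    partition_regions,
    _merge_intervals,
)

__all__ = [
    "ZeroLengthIsr",
    "RegionStats",
    "ReadthroughThresholds",
    "ReadthroughCall",
    "count_by_region",
    "second_half_count",
    "isr_coverage",
    "compute_region_stats",
    "call_readthrough",
    "analyze_transcript",
]


class ZeroLengthIsr(ValueError):
    """The ISR has zero nominal length; the coverage criterion is undefined."""


@dataclass(frozen=True)
class ReadthroughThresholds:
    """Thresholds of the four readthrough criteria (all compared with >=)."""

    min_cds_reads: int = 45
    min_second_half_reads: int = 1
    min_isr_coverage: float = 0.10
    min_density_ratio: float = 3.0

    def __post_init__(self) -> None:
        if min(
            self.min_cds_reads,
            self.min_second_half_reads,
            self.min_isr_coverage,
            self.min_density_ratio,
        ) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class RegionStats:
    """P-site counts, densities, ISR coverage and second-half count.

    ``counts`` are exclusion-filtered P-site counts per region;
    ``n_excluded`` P-sites fell in exclusion zones. ``isr_coverage_fraction``
    is the fraction of the nominal ISR (stop codons excluded) covered by the
    union of full footprint spans.
    """

    transcript_id: str
    counts: dict[str, int]
    n_excluded: int
    n_isr_second_half: int
    isr_coverage_fraction: float
    effective_lengths: dict[str, int]
    nominal_lengths: dict[str, int]

    @property
    def n_total(self) -> int:
        return sum(self.counts.values()) + self.n_excluded

    def density(self, region: str, adjusted: bool = True) -> float:
        """Reads per nucleotide; over effective length unless ``adjusted=False``."""
        lengths = self.effective_lengths if adjusted else self.nominal_lengths
        if lengths[region] == 0:
            raise ZeroDivisionError(f"region {region!r} has zero length")
        return self.counts[region] / lengths[region]

    def density_ratio(self, adjusted: bool = True) -> float:
        """ISR / distal-3'UTR density; 0 if ISR empty, +inf if only 3'UTR empty."""
        d_isr = self.density("isr", adjusted)
        d_utr3 = self.density("utr3_rest", adjusted)
        if d_isr == 0:
            return 0.0
        if d_utr3 == 0:
            return math.inf
        return d_isr / d_utr3


@dataclass(frozen=True)
class ReadthroughCall:
    """Per-criterion verdicts; positive iff all four criteria hold."""

    transcript_id: str
    enough_cds_reads: bool
    second_half_read: bool
    enough_isr_coverage: bool
    enough_density_ratio: bool
    density_ratio: float

    @property
    def criteria(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.enough_cds_reads,
            self.second_half_read,
            self.enough_isr_coverage,
            self.enough_density_ratio,
        )

    @property
    def verdict(self) -> bool:
        return all(self.criteria)


def _p_sites(footprints: Iterable[Footprint]) -> np.ndarray:
    return np.fromiter((fp.p_site for fp in footprints), dtype=np.int64)


def count_by_region(
    footprints: Sequence[Footprint], region_map: RegionMap
) -> tuple[dict[str, int], int]:
    """Assign each P-site to exactly one region or to the excluded pool.

    A P-site on the canonical stop codon counts toward the CDS and one on
    the downstream stop toward the ISR, because those codons belong to the
    respective region intervals. Returns ``(counts, n_excluded)``.
    """
    counts = {name: 0 for name in REGION_NAMES}
    p = _p_sites(footprints)
    if p.size == 0:
        return counts, 0
    if p.min() < 0 or p.max() >= region_map.length:
        raise ValueError("P-site outside transcript bounds")
    excluded = np.zeros(p.shape, dtype=bool)
    for a, b in region_map.excluded:
        excluded |= (p >= a) & (p < b)
    boundaries = [region_map.regions[name][0] for name in REGION_NAMES]
    idx = np.searchsorted(boundaries, p[~excluded], side="right") - 1
    for i, name in enumerate(REGION_NAMES):
        counts[name] = int(np.sum(idx == i))
    return counts, int(np.sum(excluded))


def second_half_count(
    footprints: Sequence[Footprint], annotation: TranscriptAnnotation
) -> int:
    """P-sites in the second half of the ISR (exclusion zones NOT applied).

    The split point is ``cds_end + ceil(isr_length / 2)`` on the nominal ISR
    (downstream stop codon excluded from the length but included in the
    counted window, which ends at the stop2 3' boundary).
    """
    half_start = annotation.cds_end + math.ceil(annotation.isr_length / 2)
    end = annotation.stop2_start + 3
    p = _p_sites(footprints)
    if p.size == 0:
        return 0
    return int(np.sum((p >= half_start) & (p < end)))


def isr_coverage(
    footprints: Sequence[Footprint], annotation: TranscriptAnnotation
) -> float:
    """Fraction of the nominal ISR covered by the union of footprint spans.

    Full read spans are used (the criterion concerns coverage by footprints,
    not by P-sites). Raises :class:`ZeroLengthIsr` when the ISR has zero
    length (adjacent stop codons); callers treat that as an automatic
    failure of the coverage criterion.
    """
    a, b = annotation.isr
    if b - a == 0:
        raise ZeroLengthIsr(f"{annotation.transcript_id}: ISR has zero length")
    spans = _merge_intervals(
        (max(fp.start, a), min(fp.end, b))
        for fp in footprints
        if fp.end > a and fp.start < b
    )
    covered = sum(y - x for x, y in spans)
    return covered / (b - a)


def compute_region_stats(
    footprints: Sequence[Footprint],
    annotation: TranscriptAnnotation,
    region_map: RegionMap | None = None,
) -> RegionStats:
    """All per-region statistics needed by the caller, in one pass."""
    if region_map is None:
        region_map = partition_regions(annotation)
    counts, n_excluded = count_by_region(footprints, region_map)
    try:
        coverage = isr_coverage(footprints, annotation)
    except ZeroLengthIsr:
        coverage = 0.0  # zero-length ISR auto-fails the coverage criterion
    return RegionStats(
        transcript_id=annotation.transcript_id,
        counts=counts,
        n_excluded=n_excluded,
        n_isr_second_half=second_half_count(footprints, annotation),
        isr_coverage_fraction=coverage,
        effective_lengths={r: region_map.effective_length(r) for r in REGION_NAMES},
        nominal_lengths={r: region_map.nominal_length(r) for r in REGION_NAMES},
    )


def call_readthrough(
    stats: RegionStats,
    thresholds: ReadthroughThresholds = ReadthroughThresholds(),
    adjusted: bool = True,
) -> ReadthroughCall:
    """Apply the four readthrough criteria to precomputed region statistics."""
    ratio = stats.density_ratio(adjusted)
    return ReadthroughCall(
        transcript_id=stats.transcript_id,
        enough_cds_reads=stats.counts["cds"] >= thresholds.min_cds_reads,
        second_half_read=stats.n_isr_second_half >= thresholds.min_second_half_reads,
        enough_isr_coverage=stats.isr_coverage_fraction >= thresholds.min_isr_coverage,
        enough_density_ratio=ratio >= thresholds.min_density_ratio,
        density_ratio=ratio,
    )


def analyze_transcript(
    footprints: Sequence[Footprint],
    annotation: TranscriptAnnotation,
    exclusion_nt: int = 12,
    thresholds: ReadthroughThresholds = ReadthroughThresholds(),
    adjusted: bool = True,
) -> tuple[RegionStats, ReadthroughCall]:
    """Partition, count and call one transcript in a single step."""
    region_map = partition_regions(annotation, exclusion_nt)
    stats = compute_region_stats(footprints, annotation, region_map)
    return stats, call_readthrough(stats, thresholds, adjusted)
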