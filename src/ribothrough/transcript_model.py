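"""Transcript annotation for stop-codon readthrough analysis.

Translational readthrough produces a C-terminally extended protein when the
ribosome decodes the canonical stop codon as a sense codon and continues to
the next in-frame stop. The transcript segment between the two stops is the
inter-stop codon region (ISR). This module locates the downstream in-frame
stop, translates the ISR-encoded extension, and partitions the transcript
into the counting regions used for footprint-density analysis (5'UTR, CDS,
ISR, distal 3'UTR) with 12-nt exclusion zones downstream of the start codon
and of each stop codon, where initiation/termination peaks would otherwise
distort densities.

All coordinates are 0-based, half-open, on the transcript strand (5'->3').
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
#: Regions in 5'->3' order; they tile the transcript without overlap.
REGION_NAMES = ("utr5", "cds", "isr", "utr3_rest")

__all__ = [
    "STOP_CODONS",
    "REGION_NAMES",
    "BadCds",
    "NoDownstreamStop",
    "InvalidCodon",
    "TranscriptAnnotation",
    "RegionMap",
    "annotate_isr",
    "translate_extension",
    "partition_regions",
]


class BadCds(ValueError):
    """The declared CDS interval violates its preconditions."""


class NoDownstreamStop(ValueError):
    """No in-frame stop codon occurs between the canonical stop and the transcript end."""


class InvalidCodon(ValueError):
    """A codon contains characters outside A/C/G/T."""


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and non-overlapping."""
    ivs = sorted((a, b) for a, b in intervals if b > a)
    merged: list[tuple[int, int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _overlap_len(interval: tuple[int, int], others: Sequence[tuple[int, int]]) -> int:
    a, b = interval
    return sum(max(0, min(b, y) - max(a, x)) for x, y in others)


@dataclass(frozen=True)
class TranscriptAnnotation:
    """A transcript with its CDS, ISR and downstream in-frame stop codon.

    ``cds`` is ``[cds_start, cds_end)`` and *includes* the canonical stop
    codon as its last three nucleotides. ``isr`` is ``[cds_end, stop2_start)``
    and contains no in-frame stop; the downstream stop occupies
    ``[stop2_start, stop2_start + 3)``.
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int
    stop2_start: int

    def __post_init__(self) -> None:
        seq, cs, ce, s2 = self.sequence, self.cds_start, self.cds_end, self.stop2_start
        if not (0 <= cs < ce <= len(seq)):
            raise BadCds(f"CDS [{cs},{ce}) out of bounds for length {len(seq)}")
        if ce - cs < 6 or (ce - cs) % 3:
            raise BadCds(f"CDS length {ce - cs} must be >= 6 and a multiple of 3")
        if seq[ce - 3 : ce] not in STOP_CODONS:
            raise BadCds(f"CDS does not end in a stop codon: {seq[ce - 3:ce]!r}")
        if (s2 - ce) % 3 or s2 < ce or s2 + 3 > len(seq):
            raise BadCds(f"downstream stop at {s2} not in frame within bounds")
        if seq[s2 : s2 + 3] not in STOP_CODONS:
            raise BadCds(f"no stop codon at stop2 position {s2}")
        for i in range(ce, s2, 3):
            if seq[i : i + 3] in STOP_CODONS:
                raise BadCds(f"in-frame stop codon inside ISR at {i}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds(self) -> tuple[int, int]:
        return (self.cds_start, self.cds_end)

    @property
    def isr(self) -> tuple[int, int]:
        return (self.cds_end, self.stop2_start)

    @property
    def isr_length(self) -> int:
        return self.stop2_start - self.cds_end

    @property
    def stop2(self) -> tuple[int, int]:
        return (self.stop2_start, self.stop2_start + 3)

    @property
    def isr_codons(self) -> int:
        return self.isr_length // 3

    @property
    def isr_sequence(self) -> str:
        return self.sequence[self.cds_end : self.stop2_start]


@dataclass(frozen=True)
class RegionMap:
    """Tiling of a transcript into counting regions plus exclusion zones.

    ``regions`` maps each of :data:`REGION_NAMES` to its half-open interval;
    the CDS region includes the canonical stop codon and the ISR region
    includes the downstream stop codon (a P-site on either stop is counted
    with the region upstream of it). ``excluded`` holds the merged exclusion
    zones; ``effective_length`` of a region subtracts the excluded positions
    that fall inside it, so densities use count and length over the same
    position set.
    """

    transcript_id: str
    length: int
    regions: dict[str, tuple[int, int]]
    excluded: tuple[tuple[int, int], ...]

    def effective_length(self, region: str) -> int:
        a, b = self.regions[region]
        return (b - a) - _overlap_len((a, b), self.excluded)

    def nominal_length(self, region: str) -> int:
        a, b = self.regions[region]
        return b - a

    def is_excluded(self, pos: int) -> bool:
        return any(a <= pos < b for a, b in self.excluded)

    def region_of(self, pos: int, apply_exclusions: bool = True) -> str | None:
        """Region name for a P-site position, or None for excluded positions."""
        if apply_exclusions and self.is_excluded(pos):
            return None
        for name, (a, b) in self.regions.items():
            if a <= pos < b:
                return name
        raise ValueError(f"position {pos} outside transcript [0,{self.length})")


def annotate_isr(
    sequence: str,
    cds: tuple[int, int],
    transcript_id: str = "transcript",
    require_start: bool = True,
) -> TranscriptAnnotation:
    """Locate the first downstream in-frame stop codon and define the ISR.

    Parameters
    ----------
    sequence
        Transcript sequence (uppercase A/C/G/T).
    cds
        ``[cds_start, cds_end)``; the last three nucleotides must be the
        canonical stop codon.
    require_start
        If true, the CDS must begin with ATG.

    Returns
    -------
    TranscriptAnnotation
        With ``isr = [cds_end, stop2_start)`` where ``stop2_start`` is the
        first in-frame stop after the canonical one. Any deeper in-frame
        stops are ignored.

    Raises
    ------
    BadCds
        If the CDS interval violates its preconditions.
    NoDownstreamStop
        If no complete in-frame stop codon occurs before the transcript end.
    """
    cds_start, cds_end = cds
    if not (0 <= cds_start < cds_end <= len(sequence)):
        raise BadCds(f"CDS [{cds_start},{cds_end}) out of bounds")
    if cds_end - cds_start < 6 or (cds_end - cds_start) % 3:
        raise BadCds(f"CDS length {cds_end - cds_start} must be >= 6 and a multiple of 3")
    if require_start and sequence[cds_start : cds_start + 3] != START_CODON:
        raise BadCds(f"CDS does not start with ATG: {sequence[cds_start:cds_start + 3]!r}")
    if sequence[cds_end - 3 : cds_end] not in STOP_CODONS:
        raise BadCds(f"CDS does not end in a stop codon: {sequence[cds_end - 3:cds_end]!r}")

    for i in range(cds_end, len(sequence) - 2, 3):
        if sequence[i : i + 3] in STOP_CODONS:
            return TranscriptAnnotation(transcript_id, sequence, cds_start, cds_end, i)
    raise NoDownstreamStop(
        f"{transcript_id}: no in-frame stop codon downstream of position {cds_end}"
    )


def translate_extension(
    annotation: TranscriptAnnotation, readthrough_residue: str = "X"
) -> str:
    """Amino-acid sequence appended to the canonical protein upon readthrough.

    The extension is the residue inserted at the recoded stop codon
    (unknown a priori, placeholder ``'X'``) followed by the standard genetic
    code translation of the ISR codons; its length is ``isr_codons + 1``.
    """
    if len(readthrough_residue) != 1 or readthrough_residue not in "ACDEFGHIKLMNPQRSTVWYX":
        raise InvalidCodon(f"invalid readthrough residue {readthrough_residue!r}")
    isr_seq = annotation.isr_sequence
    if any(c not in "ACGT" for c in isr_seq):
        raise InvalidCodon(f"non-ACGT character in ISR of {annotation.transcript_id}")
    return readthrough_residue + str(Seq(isr_seq).translate())


def partition_regions(
    annotation: TranscriptAnnotation, exclusion_nt: int = 12
) -> RegionMap:
    """Partition a transcript into counting regions with exclusion zones.

    Regions: ``utr5=[0,cds_start)``, ``cds=[cds_start,cds_end)`` (canonical
    stop included), ``isr=[cds_end, stop2_start+3)`` (downstream stop
    included), ``utr3_rest=[stop2_start+3, L)``. Three exclusion zones of
    ``exclusion_nt`` nucleotides (clamped at the transcript end) start
    immediately after the start codon, the canonical stop and the downstream
    stop; they are subtracted from the effective lengths used as density
    denominators.
    """
    if exclusion_nt < 0:
        raise ValueError("exclusion_nt must be >= 0")
    L = annotation.length
    cs, ce, s2 = annotation.cds_start, annotation.cds_end, annotation.stop2_start
    regions = {
        "utr5": (0, cs),
        "cds": (cs, ce),
        "isr": (ce, s2 + 3),
        "utr3_rest": (s2 + 3, L),
    }
    zone_starts = (cs + 3, ce, s2 + 3)
    excluded = _merge_intervals(
        (start, min(start + exclusion_nt, L)) for start in zone_starts
    )
    return RegionMap(annotation.transcript_id, L, regions, tuple(excluded))
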