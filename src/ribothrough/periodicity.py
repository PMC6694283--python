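"""3-nucleotide periodicity diagnostics for ribosome profiling data.

Actively translated regions show a strong reading-frame bias: P-sites fall
preferentially in frame 0 of the coding frame grid. This module builds the
metagene profile of P-site counts around the start codon (offsets -24..62,
A of ATG at 0, stratified by fragment length), selects the fragment lengths
showing periodicity (defaults to 27-29 nt), and computes per-region frame
proportions and their coefficient of variation (CV). Frame-uniform regions
(RNA-seq-like, or untranslated) give CV near 0; strongly frame-biased
regions give large CV.

Frames are defined from the P-site relative to the start codon,
``(p_site - cds_start) mod 3``, so UTR positions inherit the CDS frame grid
and the ISR frame bias can be measured on the same scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Collection, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .footprint_mapper import Footprint
from .transcript_model import REGION_NAMES, RegionMap, TranscriptAnnotation

DEFAULT_PERIODIC_LENGTHS = frozenset({27, 28, 29})
METAGENE_WINDOW = (-24, 62)

__all__ = [
    "DEFAULT_PERIODIC_LENGTHS",
    "METAGENE_WINDOW",
    "EmptyRegion",
    "FrameProfile",
    "metagene_start_profile",
    "select_periodic_lengths",
    "frame_proportions",
    "coefficient_of_variation",
    "frame_table",
]


class EmptyRegion(ValueError):
    """No footprints fall in the requested region; proportions undefined."""


@dataclass(frozen=True)
class FrameProfile:
    """Frame-0/1/2 P-site proportions in one region and their CV."""

    region: str
    n: int
    proportions: tuple[float, float, float]
    cv: float

    @property
    def f0(self) -> float:
        return self.proportions[0]


def metagene_start_profile(
    footprints: Iterable[Footprint],
    cds_starts: Mapping[str, int],
    window: tuple[int, int] = METAGENE_WINDOW,
    lengths: Sequence[int] = tuple(range(24, 37)),
) -> pd.DataFrame:
    """Pooled log1p P-site counts around the start codon, by fragment length.

    Rows are fragment lengths, columns are offsets ``p_site - cds_start``
    within ``window`` (inclusive on both ends; the default spans 87 offsets),
    and cells hold ``log(count + 1)``. Footprints on transcripts absent from
    ``cds_starts`` are ignored.
    """
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    counts = np.zeros((len(lengths), offsets.size), dtype=np.int64)
    row = {length: i for i, length in enumerate(lengths)}
    for fp in footprints:
        if fp.transcript_id not in cds_starts or fp.length not in row:
            continue
        off = fp.p_site - cds_starts[fp.transcript_id]
        if lo <= off <= hi:
            counts[row[fp.length], off - lo] += 1
    return pd.DataFrame(np.log1p(counts), index=pd.Index(lengths, name="length"), columns=offsets)


def frame_proportions(
    footprints: Iterable[Footprint],
    region_map: RegionMap,
    region: str,
    cds_start: int,
    lengths: Collection[int] | None = None,
    cv_ddof: int = 1,
) -> FrameProfile:
    """Frame-0/1/2 proportions of P-sites in one region's counting positions.

    Only footprints whose P-site lies in the region outside the exclusion
    zones, and whose length passes the ``lengths`` filter (None = no filter),
    contribute. Raises :class:`EmptyRegion` when no footprint qualifies.
    """
    if region not in region_map.regions:
        raise KeyError(f"unknown region {region!r}")
    tally = np.zeros(3, dtype=np.int64)
    for fp in footprints:
        if lengths is not None and fp.length not in lengths:
            continue
        if region_map.region_of(fp.p_site) == region:
            tally[(fp.p_site - cds_start) % 3] += 1
    n = int(tally.sum())
    if n == 0:
        raise EmptyRegion(f"no qualifying footprints in region {region!r}")
    props = tuple(tally / n)
    return FrameProfile(region, n, props, coefficient_of_variation(props, ddof=cv_ddof))


def coefficient_of_variation(proportions: Sequence[float], ddof: int = 1) -> float:
    """CV of the three frame proportions: sd / mean.

    The sample standard deviation (``ddof=1``) is the default; since the
    proportions sum to 1 their mean is exactly 1/3, so the population
    convention (``ddof=0``) differs only by the constant factor sqrt(2/3).
    Equal proportions give 0; a single occupied frame gives sqrt(3) under
    the default convention.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size != 3:
        raise ValueError("expected exactly three frame proportions")
    return float(np.std(p, ddof=ddof) / np.mean(p))


def select_periodic_lengths(
    footprints: Iterable[Footprint] | None = None,
    annotations: Mapping[str, TranscriptAnnotation] | None = None,
    region_maps: Mapping[str, RegionMap] | None = None,
    default: Collection[int] = DEFAULT_PERIODIC_LENGTHS,
    auto: bool = False,
    min_frame0: float = 0.4,
) -> set[int]:
    """Fragment lengths to retain for frame analysis.

    By default returns the fixed periodic set (27-29 nt, the lengths with
    clear 3-nt periodicity in typical human Ribo-seq). In ``auto`` mode the
    in-CDS frame-0 share is computed per fragment length and lengths
    exceeding ``min_frame0`` (heuristic, default 0.4 vs the uniform 1/3) are
    kept; an empty result triggers a warning.
    """
    if not auto:
        return set(default)
    if footprints is None or annotations is None:
        raise ValueError("auto mode requires footprints and annotations")
    from .transcript_model import partition_regions

    if region_maps is None:
        region_maps = {tid: partition_regions(ann) for tid, ann in annotations.items()}
    by_length: dict[int, np.ndarray] = {}
    for fp in footprints:
        if fp.transcript_id not in annotations:
            continue
        rmap = region_maps[fp.transcript_id]
        if rmap.region_of(fp.p_site) != "cds":
            continue
        frame = (fp.p_site - annotations[fp.transcript_id].cds_start) % 3
        by_length.setdefault(fp.length, np.zeros(3, dtype=np.int64))[frame] += 1
    selected = {
        length for length, tally in by_length.items() if tally[0] / tally.sum() > min_frame0
    }
    if not selected:
        warnings.warn("no fragment length shows frame-0 bias above threshold", stacklevel=2)
    return selected


def frame_table(
    footprints: Sequence[Footprint],
    annotation: TranscriptAnnotation,
    region_map: RegionMap,
    lengths: Collection[int] | None = None,
    regions: Sequence[str] = ("cds", "isr", "utr3_rest"),
) -> pd.DataFrame:
    """Per-region frame proportions and CV as a tidy table.

    Regions without qualifying footprints get NaN proportions and CV.
    """
    rows = []
    for region in regions:
        if region not in REGION_NAMES:
            raise KeyError(f"unknown region {region!r}")
        try:
            prof = frame_proportions(footprints, region_map, region, annotation.cds_start, lengths)
            rows.append((region, prof.n, *prof.proportions, prof.cv))
        except EmptyRegion:
            rows.append((region, 0, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["region", "n", "f0", "f1", "f2", "cv"])
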