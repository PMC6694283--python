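"""Placement of ribosome footprints on transcripts and P-site assignment.

Footprints are mapped by exact (100%-identity, ungapped, forward-strand)
matching of the full read against the transcript set, mirroring a
stringent word-size-24 search: only reads of length >= 24 that occur
verbatim in a transcript are kept. Pre-aligned transcript-space SAM/BAM
records can be ingested instead, subject to the same filters.

The P-site is estimated as the central nucleotide of the footprint; for
even lengths the left-central position is used, so for a span ``[a, b)``
of length ``l`` the P-site is ``a + (l - 1) // 2`` in both parities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple

import pysam

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 24

__all__ = [
    "DEFAULT_MIN_LEN",
    "Footprint",
    "MappingStats",
    "UnknownReference",
    "assign_p_site",
    "exact_match_read",
    "map_reads",
    "ingest_alignments",
]


class UnknownReference(KeyError):
    """An alignment record names a transcript absent from the annotation set."""


class Footprint(NamedTuple):
    """One mapped footprint: half-open span on a transcript plus its P-site."""

    read_id: str
    transcript_id: str
    start: int
    end: int
    p_site: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MappingStats:
    """Bookkeeping for a mapping run (reads dropped and why)."""

    n_input: int = 0
    n_mapped: int = 0
    n_too_short: int = 0
    n_malformed: int = 0
    n_unmatched: int = 0
    n_multi_discarded: int = 0
    n_reverse: int = 0
    n_imperfect: int = 0
    n_unknown_reference: int = 0


def assign_p_site(span: tuple[int, int]) -> int:
    """Central-nucleotide P-site of a footprint span (left-central when even)."""
    a, b = span
    if b - a < 1:
        raise ValueError(f"empty span {span}")
    return a + (b - a - 1) // 2


def exact_match_read(
    read: str, transcript: str, min_len: int = DEFAULT_MIN_LEN
) -> list[tuple[int, int]]:
    """All forward-strand positions where ``read`` occurs verbatim.

    Returns an empty list for reads shorter than ``min_len``; occurrences may
    overlap. Mismatches, gaps and reverse-strand matches never count —
    identity must be 100% over the full read.
    """
    n = len(read)
    if n < min_len or n == 0:
        return []
    spans = []
    i = transcript.find(read)
    while i != -1:
        spans.append((i, i + n))
        i = transcript.find(read, i + 1)
    return spans


def map_reads(
    reads: Iterable[tuple[str, str]],
    transcripts: Mapping[str, str],
    min_len: int = DEFAULT_MIN_LEN,
    multi: str = "discard",
) -> tuple[list[Footprint], MappingStats]:
    """Map reads to a transcript set by exact matching.

    Parameters
    ----------
    reads
        Iterable of ``(read_id, sequence)``.
    transcripts
        Mapping ``transcript_id -> sequence``.
    multi
        Policy for reads matching more than one location across the
        transcript set: ``"discard"`` (default; ambiguous placements would
        double-count density) or ``"keep-all"``.
    """
    if multi not in ("discard", "keep-all"):
        raise ValueError(f"unknown multi policy {multi!r}")
    stats = MappingStats()
    footprints: list[Footprint] = []
    for read_id, seq in reads:
        stats.n_input += 1
        if any(c not in "ACGT" for c in seq):
            stats.n_malformed += 1  # e.g. N calls: cannot satisfy 100% identity
            continue
        if len(seq) < min_len:
            stats.n_too_short += 1
            continue
        hits = [
            (tid, span)
            for tid, tseq in transcripts.items()
            for span in exact_match_read(seq, tseq, min_len)
        ]
        if not hits:
            stats.n_unmatched += 1
        elif len(hits) > 1 and multi == "discard":
            stats.n_multi_discarded += 1
        else:
            for tid, (a, b) in hits:
                footprints.append(Footprint(read_id, tid, a, b, assign_p_site((a, b))))
            stats.n_mapped += 1
    if stats.n_malformed:
        logger.info("skipped %d reads with non-ACGT characters", stats.n_malformed)
    return footprints, stats


def _is_perfect(rec: pysam.AlignedSegment, reference: str | None) -> bool:
    """Ungapped, full-length, mismatch-free alignment."""
    cig = rec.cigartuples
    if cig is None or len(cig) != 1 or cig[0][0] != 0:  # single M op only
        return False
    if rec.has_tag("NM") and rec.get_tag("NM") != 0:
        return False
    if reference is not None:
        q = rec.query_sequence
        if q is None or reference[rec.reference_start : rec.reference_end] != q:
            return False
    return True


def ingest_alignments(
    path: str,
    transcripts: Mapping[str, str] | Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    require_perfect: bool = True,
) -> tuple[list[Footprint], MappingStats]:
    """Ingest transcript-space SAM/BAM alignments as footprints.

    Keeps mapped, forward-strand, ungapped records of length >= ``min_len``;
    with ``require_perfect`` (default) records must additionally be
    mismatch-free (NM tag, and sequence identity when transcript sequences
    are supplied rather than bare ids). Records naming unknown transcripts
    are logged and skipped.
    """
    if isinstance(transcripts, Mapping):
        known = transcripts
        seqs: Mapping[str, str] | None = transcripts
    else:
        known = {tid: "" for tid in transcripts}
        seqs = None
    stats = MappingStats()
    footprints: list[Footprint] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            stats.n_input += 1
            if rec.is_unmapped:
                stats.n_unmatched += 1
                continue
            if rec.reference_name not in known:
                stats.n_unknown_reference += 1
                logger.warning("unknown reference %r for read %r", rec.reference_name, rec.query_name)
                continue
            if rec.is_reverse:
                stats.n_reverse += 1
                continue
            if rec.query_length < min_len:
                stats.n_too_short += 1
                continue
            ref = seqs[rec.reference_name] if seqs is not None and seqs[rec.reference_name] else None
            if require_perfect and not _is_perfect(rec, ref):
                stats.n_imperfect += 1
                continue
            if not require_perfect and (
                rec.cigartuples is None or len(rec.cigartuples) != 1 or rec.cigartuples[0][0] != 0
            ):
                stats.n_imperfect += 1  # gapped records are never footprints
                continue
            a, b = rec.reference_start, rec.reference_end
            footprints.append(
                Footprint(rec.query_name, rec.reference_name, a, b, assign_p_site((a, b)))
            )
            stats.n_mapped += 1
    return footprints, stats
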