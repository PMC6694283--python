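"""Synthetic transcripts, ribosome footprints and reporter readouts.

The generator emulates the statistical structure a readthrough analysis
relies on, so every pipeline stage is testable without external data:

* a transcript with an ATG-initiated CDS ending in TGA, a stop-free ISR of
  chosen length closed by a TAA, and flanking UTRs; every 24-mer is unique
  so that exact matching is unambiguous;
* footprints of 24-36 nt allocated to regions in proportion to
  density x length, with P-site frame bias in the translated regions (CDS
  and ISR) and frame-uniform placement in the distal 3'UTR;
* paired FLuc/RLuc reporter readouts with multiplicative log-normal noise.

Defaults encode the conditions of a typical readthrough locus: region
densities cds:isr:utr3_rest = 50:5:1 (translation strong in the CDS, ~10%
of CDS level in the ISR, background beyond the second stop), a 99-nt ISR,
frame-0 probability 0.6 in translated regions, and fragment lengths
uniform on 27-29 nt. All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .footprint_mapper import Footprint, assign_p_site
from .transcript_model import STOP_CODONS, TranscriptAnnotation, annotate_isr

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

__all__ = [
    "SimSpec",
    "UnsatisfiableSpec",
    "make_transcript",
    "simulate_footprints",
    "true_footprints",
    "simulate_reporter",
    "write_fastq",
]


class UnsatisfiableSpec(RuntimeError):
    """No transcript satisfying the uniqueness constraints was found."""


@dataclass(frozen=True)
class SimSpec:
    """Design of one synthetic readthrough locus and its sequencing run."""

    utr5_len: int = 100
    cds_len: int = 600
    isr_len: int = 99
    utr3_rest_len: int = 400
    region_densities: Mapping[str, float] = field(
        default_factory=lambda: {"utr5": 0.2, "cds": 5.0, "isr": 0.5, "utr3_rest": 0.1}
    )
    frame_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)
    fragment_lengths: Mapping[int, float] = field(
        default_factory=lambda: {27: 1 / 3, 28: 1 / 3, 29: 1 / 3}
    )
    n_reads: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cds_len < 6 or self.cds_len % 3:
            raise ValueError("cds_len must be >= 6 and a multiple of 3")
        if self.isr_len < 0 or self.isr_len % 3:
            raise ValueError("isr_len must be >= 0 and a multiple of 3")
        if min(self.utr5_len, self.utr3_rest_len) < 0 or self.n_reads < 0:
            raise ValueError("lengths and n_reads must be >= 0")
        if any(d < 0 for d in self.region_densities.values()):
            raise ValueError("densities must be >= 0")
        if not math.isclose(sum(self.frame_probs), 1.0):
            raise ValueError("frame_probs must sum to 1")
        if any(not 24 <= length <= 36 for length in self.fragment_lengths):
            raise ValueError("fragment lengths must lie in 24-36")
        if not math.isclose(sum(self.fragment_lengths.values()), 1.0):
            raise ValueError("fragment_lengths probabilities must sum to 1")

    @property
    def transcript_length(self) -> int:
        return self.utr5_len + self.cds_len + self.isr_len + 3 + self.utr3_rest_len

    @property
    def cds(self) -> tuple[int, int]:
        return (self.utr5_len, self.utr5_len + self.cds_len)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _sense_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(_SENSE_CODONS)[rng.integers(0, len(_SENSE_CODONS), n)])


def _kmers_unique(seq: str, k: int = 24) -> bool:
    kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    return len(kmers) == len(seq) - k + 1


def make_transcript(
    spec: SimSpec,
    transcript_id: str = "sim_tx",
    rng: np.random.Generator | None = None,
    max_attempts: int = 50,
) -> TranscriptAnnotation:
    """Build a transcript realizing ``spec`` and annotate it.

    The CDS starts with ATG and ends with TGA (the leakiest stop codon, the
    one typically recoded), internal CDS and ISR codons are drawn from the
    61 sense codons so no unintended in-frame stop occurs, and the
    downstream stop is TAA. Sequences whose 24-mers are not all unique are
    rejected and resampled (up to ``max_attempts``) so the exact-matching
    mapper recovers every simulated read unambiguously.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    for _ in range(max_attempts):
        seq = (
            _random_nt(rng, spec.utr5_len)
            + "ATG"
            + _sense_codons(rng, spec.cds_len // 3 - 2)
            + "TGA"
            + _sense_codons(rng, spec.isr_len // 3)
            + "TAA"
            + _random_nt(rng, spec.utr3_rest_len)
        )
        if _kmers_unique(seq):
            return annotate_isr(seq, spec.cds, transcript_id)
    raise UnsatisfiableSpec(
        f"no sequence with unique 24-mers in {max_attempts} attempts "
        f"(transcript length {spec.transcript_length})"
    )


def _draw_p_sites(
    rng: np.random.Generator,
    n: int,
    interval: tuple[int, int],
    frame_probs: tuple[float, float, float] | None,
    cds_start: int,
) -> np.ndarray:
    """P-site positions uniform in ``interval``; frame-stratified if biased."""
    a, b = interval
    if frame_probs is None:
        return rng.integers(a, b, n)
    frames = rng.choice(3, size=n, p=frame_probs)
    out = np.empty(n, dtype=np.int64)
    for f in range(3):
        mask = frames == f
        # first position >= a congruent to cds_start + f (mod 3)
        first = a + (cds_start + f - a) % 3
        m = (b - first + 2) // 3  # count of in-frame positions in [a, b)
        if m <= 0:
            raise ValueError(f"no frame-{f} position in region [{a},{b})")
        out[mask] = first + 3 * rng.integers(0, m, int(mask.sum()))
    return out


def simulate_footprints(
    annotation: TranscriptAnnotation,
    spec: SimSpec,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate footprint reads from a transcript.

    ``spec.n_reads`` reads are allocated to regions multinomially with
    probability proportional to density x nominal region length (region
    intervals as in the analysis: CDS includes the canonical stop, ISR the
    downstream stop). Within the CDS and ISR the P-site frame is drawn from
    ``frame_probs``; elsewhere placement is uniform. Each read's fragment
    length is drawn independently and the read is laid out so its
    central-nucleotide P-site (left-central for even lengths) falls on the
    drawn position; placements that would run off the transcript are
    rejection-resampled within the region.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence)`` and ``truth`` is a DataFrame with the true span,
    P-site, region and frame per read.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    cs, ce, s2 = annotation.cds_start, annotation.cds_end, annotation.stop2_start
    L = annotation.length
    intervals = {
        "utr5": (0, cs),
        "cds": (cs, ce),
        "isr": (ce, s2 + 3),
        "utr3_rest": (s2 + 3, L),
    }
    weights = np.array(
        [spec.region_densities[r] * (iv[1] - iv[0]) for r, iv in intervals.items()],
        dtype=float,
    )
    if weights.sum() == 0:
        raise ValueError("all region weights are zero")
    n_per_region = rng.multinomial(spec.n_reads, weights / weights.sum())

    lengths_arr = np.array(list(spec.fragment_lengths), dtype=np.int64)
    length_p = np.array([spec.fragment_lengths[int(l)] for l in lengths_arr])

    rows = []
    reads: list[tuple[str, str]] = []
    read_no = 0
    for (region, interval), n in zip(intervals.items(), n_per_region):
        if n == 0:
            continue
        biased = spec.frame_probs if region in ("cds", "isr") else None
        p = _draw_p_sites(rng, int(n), interval, biased, cs)
        ell = lengths_arr[rng.choice(lengths_arr.size, size=int(n), p=length_p)]
        start = p - (ell - 1) // 2
        # resample placements whose read would overhang a transcript end
        for _ in range(100):
            bad = (start < 0) | (start + ell > L)
            if not bad.any():
                break
            nb = int(bad.sum())
            p[bad] = _draw_p_sites(rng, nb, interval, biased, cs)
            ell[bad] = lengths_arr[rng.choice(lengths_arr.size, size=nb, p=length_p)]
            start[bad] = p[bad] - (ell[bad] - 1) // 2
        else:
            raise UnsatisfiableSpec(f"cannot place reads inside region {region!r}")
        for pi, li, si in zip(p, ell, start):
            rid = f"read_{read_no:06d}"
            read_no += 1
            reads.append((rid, annotation.sequence[si : si + li]))
            rows.append((rid, int(si), int(si + li), int(pi), region, int((pi - cs) % 3)))
    truth = pd.DataFrame(
        rows, columns=["read_id", "start", "end", "p_site", "region", "frame"]
    )
    return reads, truth


def true_footprints(
    annotation: TranscriptAnnotation, truth: pd.DataFrame
) -> list[Footprint]:
    """Footprint records straight from a simulation truth table."""
    return [
        Footprint(r.read_id, annotation.transcript_id, r.start, r.end, r.p_site)
        for r in truth.itertuples()
    ]


def simulate_reporter(
    true_rt_fraction: float,
    noise_cv: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
    rluc_scale: float = 1e5,
):
    """Paired no-stop control and test reporter readouts.

    The control construct's FLuc/RLuc ratio has expectation 1 and the test
    construct's expectation ``true_rt_fraction``; both carry mean-one
    multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` (luminescence is positive and right-skewed). RLuc readouts
    share the same noise model around ``rluc_scale``.
    """
    from .assay_quant import ReporterSet

    if not 0 < true_rt_fraction <= 1:
        raise ValueError("true_rt_fraction must be in (0, 1]")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))

    def lognoise(n: int) -> np.ndarray:
        return np.exp(rng.normal(-sigma**2 / 2.0, sigma, n))

    def make(condition: str, ratio: float, control: bool) -> ReporterSet:
        rluc = rluc_scale * lognoise(n_replicates)
        fluc = ratio * rluc * lognoise(n_replicates)
        return ReporterSet(condition, tuple(fluc), tuple(rluc), is_no_stop_control=control)

    test = make("stop-ISR", true_rt_fraction, False)
    control = make("no-stop-ISR", 1.0, True)
    return test, control


def write_fastq(reads: Sequence[tuple[str, str]], path: str, seed: int | None = None) -> None:
    """Write simulated reads as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            header = f"@{rid}" + (f" seed={seed}" if seed is not None else "")
            fh.write(f"{header}\n{seq}\n+\n{'I' * len(seq)}\n")
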