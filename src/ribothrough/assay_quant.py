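"""Reporter-assay quantification of readthrough and set-overlap statistics.

In the dual-luciferase readthrough assay the test construct places firefly
luciferase (FLuc) downstream of, and in frame with, the gene's canonical
stop codon and ISR, so FLuc is produced only upon readthrough; a matched
no-stop construct (stop replaced by a sense codon such as GCA) measures
full expression. Readthrough efficiency is the FLuc/RLuc ratio of the test
construct relative to the no-stop control, as a percentage. RLuc is a
co-transfected normalizer.

In the tethering assay the regulated reporter is RLuc (recruited via
BoxB/N-peptide) and FLuc is the transfection control, so the normalized
quantity flips to RLuc/FLuc and effects are reported as percent change.

miRNA repertoire comparisons between protein isoforms reduce to exact set
overlaps of identifier lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection, Hashable

import numpy as np

__all__ = [
    "NonPositiveReadout",
    "ReporterSet",
    "ReadthroughEstimate",
    "OverlapResult",
    "percent_readthrough",
    "normalized_reporter_change",
    "set_overlap_stats",
]


class NonPositiveReadout(ValueError):
    """A luminescence readout is zero or negative."""


@dataclass(frozen=True)
class ReporterSet:
    """Replicate FLuc/RLuc readouts for one construct/condition."""

    condition: str
    fluc: tuple[float, ...]
    rluc: tuple[float, ...]
    is_no_stop_control: bool = False

    def __post_init__(self) -> None:
        if len(self.fluc) == 0 or len(self.fluc) != len(self.rluc):
            raise ValueError("need >= 1 replicate with paired FLuc/RLuc readouts")
        if min(self.fluc) <= 0 or min(self.rluc) <= 0:
            raise NonPositiveReadout(f"non-positive readout in {self.condition!r}")

    @property
    def n(self) -> int:
        return len(self.fluc)

    @property
    def ratios(self) -> np.ndarray:
        """Per-replicate FLuc/RLuc."""
        return np.asarray(self.fluc) / np.asarray(self.rluc)

    @property
    def inverse_ratios(self) -> np.ndarray:
        """Per-replicate RLuc/FLuc (tethering-assay orientation)."""
        return np.asarray(self.rluc) / np.asarray(self.fluc)


@dataclass(frozen=True)
class ReadthroughEstimate:
    percent: float
    se: float
    method: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.percent:.1f}% readthrough (SE {self.se:.2f}, {self.method})"


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else 0.0
    return m, se


def percent_readthrough(
    test: ReporterSet,
    control_no_stop: ReporterSet,
    method: str = "mean-ratios",
) -> ReadthroughEstimate:
    """Readthrough efficiency of ``test`` relative to the no-stop control.

    ``method="mean-ratios"`` (default) averages per-replicate FLuc/RLuc
    ratios within each condition and reports their quotient x 100;
    ``method="pooled-means"`` uses (mean FLuc / mean RLuc) per condition
    instead. The standard error is propagated from the replicate standard
    errors of the two means by the delta method:
    ``SE = pct * sqrt((SE_t/m_t)^2 + (SE_c/m_c)^2)``.

    The result is scale-invariant: rescaling all FLuc readouts (or all RLuc
    readouts) by a common factor leaves the percentage unchanged.
    """
    if method == "mean-ratios":
        m_t, se_t = _mean_se(test.ratios)
        m_c, se_c = _mean_se(control_no_stop.ratios)
    elif method == "pooled-means":
        # delta-method SE treating mean FLuc and mean RLuc as independent
        def pooled(rs: ReporterSet) -> tuple[float, float]:
            mf, sf = _mean_se(np.asarray(rs.fluc))
            mr, sr = _mean_se(np.asarray(rs.rluc))
            m = mf / mr
            return m, m * math.sqrt((sf / mf) ** 2 + (sr / mr) ** 2)

        m_t, se_t = pooled(test)
        m_c, se_c = pooled(control_no_stop)
    else:
        raise ValueError(f"unknown method {method!r}")
    pct = 100.0 * m_t / m_c
    se = pct * math.sqrt((se_t / m_t) ** 2 + (se_c / m_c) ** 2)
    return ReadthroughEstimate(pct, se, method)


def normalized_reporter_change(
    condition: ReporterSet, reference: ReporterSet
) -> float:
    """Percent change in relative (RLuc/FLuc) reporter activity vs reference.

    Returns ``100 * (mean(condition) / mean(reference) - 1)`` over the
    per-replicate RLuc/FLuc ratios — 0 for identical conditions, negative
    for repression of the tethered reporter.
    """
    m_c = float(np.mean(condition.inverse_ratios))
    m_r = float(np.mean(reference.inverse_ratios))
    return 100.0 * (m_c / m_r - 1.0)


@dataclass(frozen=True)
class OverlapResult:
    """Exact overlap between two identifier sets, as counts and percentages."""

    n_a: int
    n_b: int
    n_shared: int
    pct_of_a: float
    pct_of_b: float

    @property
    def pct_of_a_rounded(self) -> int:
        return round(self.pct_of_a)

    @property
    def pct_of_b_rounded(self) -> int:
        return round(self.pct_of_b)


def set_overlap_stats(
    set_a: Collection[Hashable], set_b: Collection[Hashable]
) -> OverlapResult:
    """Shared-identifier statistics between two sets (e.g. miRNA repertoires).

    Percentages are kept at full precision; nearest-integer values are
    available on the result for reporting. Empty sets yield 0%.
    """
    a, b = set(set_a), set(set_b)
    shared = len(a & b)
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_shared=shared,
        pct_of_a=100.0 * shared / len(a) if a else 0.0,
        pct_of_b=100.0 * shared / len(b) if b else 0.0,
    )
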