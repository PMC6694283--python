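"""Readthrough-variant protein databases and extension-specific peptides.

The residue inserted at a recoded stop codon is not known a priori, so the
search database carries 20 variants of the readthrough protein — the
canonical sequence, one of the 20 standard amino acids in place of the
stop, then the ISR-encoded extension. Mass-spectrometric evidence for
readthrough comes from tryptic peptides that overlap the readthrough
residue or the extension and occur nowhere else in the proteome.

This module builds the variant database, performs in-silico tryptic
digestion with missed cleavages (several K/R residues in a typical
extension make a generous missed-cleavage allowance necessary; default 5),
and flags extension-specific peptides by exact substring matching against a
reference proteome. Spectrum search and FDR control are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "AMINO_ACIDS",
    "InvalidResidue",
    "ReadthroughVariantDb",
    "PeptideMatch",
    "build_readthrough_db",
    "cleavage_sites",
    "tryptic_digest",
    "find_extension_specific_peptides",
    "unique_extension_peptides",
]


class InvalidResidue(ValueError):
    """A sequence contains a symbol outside the 20 standard amino acids."""


def _check_protein(seq: str, what: str, allow_empty: bool = False) -> None:
    if not seq and not allow_empty:
        raise InvalidResidue(f"{what} is empty")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise InvalidResidue(f"non-standard residue(s) {sorted(bad)} in {what}")


@dataclass(frozen=True)
class ReadthroughVariantDb:
    """The 20 candidate readthrough proteins for one transcript.

    Every variant is ``base_protein + X + extension`` with ``X`` ranging
    over the standard amino acids; variants therefore differ only at
    position ``len(base_protein)`` (the recoded stop).
    """

    base_protein: str
    extension: str
    variants: dict[str, str] = field(repr=False)

    @property
    def extension_start(self) -> int:
        """First variant position that evidences readthrough (the recoded stop)."""
        return len(self.base_protein)


@dataclass(frozen=True)
class PeptideMatch:
    """One digestion product located in its parent sequence."""

    peptide: str
    parent: str
    start: int
    missed_cleavages: int
    overlaps_extension: bool = False
    unique_to_extension: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.peptide)


def build_readthrough_db(
    base_protein: str, extension: str, id_prefix: str = "readthrough"
) -> ReadthroughVariantDb:
    """Enumerate the 20 stop-codon substitution variants.

    ``extension`` is the ISR-encoded amino-acid string and may be empty
    (adjacent stop codons); the readthrough residue itself is always added,
    so each variant is ``len(extension) + 1`` residues longer than the base.
    """
    _check_protein(base_protein, "base protein")
    _check_protein(extension, "extension", allow_empty=True)
    variants = {
        f"{id_prefix}_{aa}": base_protein + aa + extension for aa in AMINO_ACIDS
    }
    return ReadthroughVariantDb(base_protein, extension, variants)


def cleavage_sites(protein: str, proline_rule: bool = True) -> list[int]:
    """Positions after which trypsin cuts: after K or R, not before P by default."""
    return [
        i + 1
        for i, aa in enumerate(protein)
        if aa in "KR"
        and not (proline_rule and i + 1 < len(protein) and protein[i + 1] == "P")
    ]


def tryptic_digest(
    protein: str,
    max_missed: int = 5,
    proline_rule: bool = True,
    parent: str = "protein",
    min_len: int = 1,
    max_len: int | None = None,
) -> list[PeptideMatch]:
    """All tryptic peptides with up to ``max_missed`` internal missed cleavages.

    Peptides are every substring between two cleavage boundaries spanning at
    most ``max_missed`` internal cleavage sites, annotated with their start
    position and missed-cleavage count. ``min_len``/``max_len`` bound the
    reported peptide lengths (defaults report everything).
    """
    _check_protein(protein, "protein")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = [0, *cleavage_sites(protein, proline_rule), len(protein)]
    if bounds[-2] == len(protein):  # C-terminal K/R: terminal cut adds no boundary
        bounds.pop()
    peptides = []
    for j in range(len(bounds) - 1):
        for k in range(j + 1, min(j + 2 + max_missed, len(bounds))):
            a, b = bounds[j], bounds[k]
            if b - a < min_len or (max_len is not None and b - a > max_len):
                continue
            peptides.append(PeptideMatch(protein[a:b], parent, a, k - j - 1))
    return peptides


def _fold_il(seq: str) -> str:
    return seq.replace("I", "L")


def find_extension_specific_peptides(
    db: ReadthroughVariantDb,
    proteome: Mapping[str, str],
    max_missed: int = 5,
    proline_rule: bool = True,
    min_len: int = 7,
    max_len: int | None = 40,
    il_equivalent: bool = False,
) -> list[PeptideMatch]:
    """Digest all variants and flag peptides that uniquely evidence readthrough.

    A peptide ``overlaps_extension`` when it covers any position at or past
    the recoded stop (position ``len(base_protein)``). It is
    ``unique_to_extension`` when, additionally, it occurs as an exact
    substring of no proteome entry and of no canonical-only portion of the
    variants (i.e. not within the base protein). With ``il_equivalent``,
    isoleucine and leucine are treated as indistinguishable (as they are by
    mass) during the substring checks.

    Peptide length bounds default to the 7-40 residue range typical of
    search engines; pass ``min_len=1, max_len=None`` for an unbounded digest.
    """
    norm = _fold_il if il_equivalent else (lambda s: s)
    background = [norm(seq) for seq in proteome.values()]
    base = norm(db.base_protein)
    out = []
    for vid, vseq in db.variants.items():
        for pep in tryptic_digest(
            vseq, max_missed, proline_rule, parent=vid, min_len=min_len, max_len=max_len
        ):
            overlaps = pep.end > db.extension_start
            unique = (
                overlaps
                and norm(pep.peptide) not in base
                and not any(norm(pep.peptide) in entry for entry in background)
            )
            out.append(
                PeptideMatch(
                    pep.peptide, vid, pep.start, pep.missed_cleavages, overlaps, unique
                )
            )
    return out


def unique_extension_peptides(matches: Iterable[PeptideMatch]) -> set[str]:
    """Distinct peptide sequences that uniquely evidence readthrough."""
    return {m.peptide for m in matches if m.unique_to_extension}
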