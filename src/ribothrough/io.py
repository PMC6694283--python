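"""Readers and writers for the plain-text formats used across the pipeline.

FASTA/FASTQ go through Biopython; tables through pandas. Transcript CDS
coordinates are exchanged as a TSV with 0-based half-open columns
(``transcript_id``, ``cds_start``, ``cds_end``); regions and exclusion
zones export as BED (0-based half-open by construction).
"""

from __future__ import annotations

from typing import Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .assay_quant import ReporterSet
from .footprint_mapper import Footprint
from .proteogenomics import ReadthroughVariantDb
from .transcript_model import REGION_NAMES, RegionMap

FOOTPRINT_COLUMNS = ["read_id", "transcript_id", "start", "end", "p_site"]

__all__ = [
    "read_fasta",
    "read_fastq",
    "read_cds_table",
    "write_cds_table",
    "write_regions_bed",
    "write_footprints_tsv",
    "read_footprints_tsv",
    "write_variant_fasta",
    "write_extension_fasta",
    "read_reporter_tsv",
    "read_id_list",
]


def read_fasta(path: str) -> dict[str, str]:
    """FASTA as ``{record_id: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_fastq(path: str) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, uppercase sequence)`` from FASTQ."""
    for rec in SeqIO.parse(path, "fastq"):
        yield rec.id, str(rec.seq).upper()


def read_cds_table(path: str) -> dict[str, tuple[int, int]]:
    """CDS coordinate table (TSV; 0-based half-open) as ``{id: (start, end)}``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"transcript_id", "cds_start", "cds_end"}
    if not required.issubset(df.columns):
        raise ValueError(f"CDS table must have columns {sorted(required)}")
    return {
        str(r.transcript_id): (int(r.cds_start), int(r.cds_end))
        for r in df.itertuples()
    }


def write_cds_table(cds: Mapping[str, tuple[int, int]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based, half-open, transcript space\n")
        fh.write("transcript_id\tcds_start\tcds_end\n")
        for tid, (a, b) in cds.items():
            fh.write(f"{tid}\t{a}\t{b}\n")


def write_regions_bed(region_map: RegionMap, path: str) -> None:
    """Counting regions and exclusion zones as BED intervals."""
    with open(path, "w") as fh:
        for name in REGION_NAMES:
            a, b = region_map.regions[name]
            if b > a:
                fh.write(f"{region_map.transcript_id}\t{a}\t{b}\t{name}\n")
        for i, (a, b) in enumerate(region_map.excluded, 1):
            fh.write(f"{region_map.transcript_id}\t{a}\t{b}\texcluded_{i}\n")


def write_footprints_tsv(footprints: Sequence[Footprint], path: str) -> None:
    pd.DataFrame(footprints, columns=FOOTPRINT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_footprints_tsv(path: str) -> list[Footprint]:
    df = pd.read_csv(path, sep="\t")
    return [
        Footprint(str(r.read_id), str(r.transcript_id), int(r.start), int(r.end), int(r.p_site))
        for r in df.itertuples()
    ]


def write_variant_fasta(db: ReadthroughVariantDb, path: str) -> None:
    with open(path, "w") as fh:
        for vid, seq in db.variants.items():
            fh.write(f">{vid}\n{seq}\n")


def write_extension_fasta(extensions: Mapping[str, str], path: str) -> None:
    """C-terminal extension peptides, one record per transcript."""
    with open(path, "w") as fh:
        for tid, ext in extensions.items():
            fh.write(f">{tid}_extension\n{ext}\n")


def read_reporter_tsv(path: str) -> dict[str, ReporterSet]:
    """Reporter readouts (columns condition, replicate, fluc, rluc) by condition."""
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "fluc", "rluc"}
    if not required.issubset(df.columns):
        raise ValueError(f"reporter table must have columns {sorted(required)}")
    out = {}
    for condition, grp in df.groupby("condition", sort=False):
        out[str(condition)] = ReporterSet(
            str(condition), tuple(grp["fluc"]), tuple(grp["rluc"])
        )
    return out


def read_id_list(path: str) -> list[str]:
    """One identifier per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
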