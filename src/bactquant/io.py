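"""Readers and writers for the standard file formats the pipeline consumes.

FASTA goes through Biopython; tabular data through pandas.  Formats:

* aligned / unaligned FASTA (gap characters ``-`` and ``.``);
* taxonomy table TSV: ``seq_id  phylum  genus  species  ref_start  ref_end``;
* assay definition JSON: name plus one object per component
  (name, sequence, role, ref_start, ref_end);
* plate TSV: ``run_id  curve_id  well  known_copies  ct`` — a missing/blank
  ct is a non-detect and is dropped with a log entry.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import CoverageReport, TaxSeqRecord
from .design import AssayDefinition, Oligo
from .profile import AlignmentProfile, ConservedRegion
from .quant import DilutionPoint

logger = logging.getLogger(__name__)

TAXONOMY_COLUMNS = ["seq_id", "phylum", "genus", "species", "ref_start", "ref_end"]
PLATE_COLUMNS = ["run_id", "curve_id", "well", "known_copies", "ct"]


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records),
        str(path),
        "fasta",
    )


# -- taxonomy-annotated collections -----------------------------------------

def write_collection(
    records: Sequence[TaxSeqRecord],
    fasta_path: str | Path,
    taxonomy_path: str | Path,
) -> None:
    write_fasta([(r.seq_id, r.sequence) for r in records], fasta_path)
    pd.DataFrame(
        [
            {
                "seq_id": r.seq_id,
                "phylum": r.phylum,
                "genus": r.genus,
                "species": r.species,
                "ref_start": r.ref_start,
                "ref_end": r.ref_end,
            }
            for r in records
        ]
    ).to_csv(taxonomy_path, sep="\t", index=False)


def read_collection(
    fasta_path: str | Path, taxonomy_path: str | Path
) -> list[TaxSeqRecord]:
    seqs = dict(read_fasta(fasta_path))
    table = pd.read_csv(taxonomy_path, sep="\t", dtype={"seq_id": str})
    missing = [c for c in TAXONOMY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"taxonomy table lacks columns: {missing}")
    records = []
    for row in table.itertuples(index=False):
        if row.seq_id not in seqs:
            raise ValueError(f"taxonomy row {row.seq_id!r} has no FASTA sequence")
        records.append(
            TaxSeqRecord(
                seq_id=row.seq_id,
                phylum=str(row.phylum),
                genus=str(row.genus),
                species=str(row.species),
                sequence=seqs[row.seq_id],
                ref_start=None if pd.isna(row.ref_start) else int(row.ref_start),
                ref_end=None if pd.isna(row.ref_end) else int(row.ref_end),
            )
        )
    return records


# -- assay definitions -------------------------------------------------------

def assay_to_dict(assay: AssayDefinition) -> dict:
    return {
        "assay_name": assay.assay_name,
        "components": [
            {
                "name": o.name,
                "sequence": o.sequence,
                "role": o.role,
                "ref_start": o.ref_start,
                "ref_end": o.ref_end,
            }
            for o in (assay.forward, assay.reverse, assay.probe)
        ],
    }


def assay_from_dict(data: Mapping) -> AssayDefinition:
    oligos = {
        comp["role"]: Oligo(
            name=comp["name"],
            sequence=comp["sequence"],
            role=comp["role"],
            ref_start=int(comp["ref_start"]),
            ref_end=int(comp["ref_end"]),
        )
        for comp in data["components"]
    }
    for role in ("forward_primer", "reverse_primer", "probe"):
        if role not in oligos:
            raise ValueError(f"assay definition lacks a {role}")
    return AssayDefinition(
        assay_name=data["assay_name"],
        forward=oligos["forward_primer"],
        reverse=oligos["reverse_primer"],
        probe=oligos["probe"],
    )


def read_assay(path: str | Path) -> AssayDefinition:
    with open(path) as fh:
        return assay_from_dict(json.load(fh))


def write_assay(assay: AssayDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(assay_to_dict(assay), fh, indent=2)
        fh.write("\n")


# -- profile tables ----------------------------------------------------------

def profile_to_table(
    profile: AlignmentProfile, retained: set[int] | None = None
) -> pd.DataFrame:
    """Per-column base distribution table mirroring design-stage output."""
    rows = []
    for c in profile.columns:
        rows.append(
            {
                "column": c.column_index,
                "ref_position": profile.reference_map.get(c.column_index),
                "A": c.counts["A"],
                "C": c.counts["C"],
                "G": c.counts["G"],
                "T": c.counts["T"],
                "other": c.counts["other"],
                "gap": c.counts["gap"],
                "gap_fraction": c.gap_fraction,
                "diversity": c.diversity,
                "majority_base": c.majority_base,
                "retained": (
                    c.column_index in retained if retained is not None else True
                ),
            }
        )
    return pd.DataFrame(rows)


def regions_to_table(regions: Sequence[ConservedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_column": r.start_column,
                "end_column": r.end_column,
                "length_ungapped": r.length_ungapped,
                "max_diversity": r.max_diversity,
                "mean_gap_fraction": r.mean_gap_fraction,
            }
            for r in regions
        ]
    )


# -- coverage tables ---------------------------------------------------------

def coverage_to_table(reports: Mapping[str, CoverageReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "level": rep.level,
                "numerator": rep.numerator,
                "denominator": rep.denominator,
                "percent": rep.percent,
            }
            for rep in reports.values()
        ]
    )


def otu_lists_to_table(reports: Mapping[str, CoverageReport]) -> pd.DataFrame:
    rows = []
    for rep in reports.values():
        for otu in rep.covered:
            rows.append({"level": rep.level, "status": "covered", "otu": otu})
        for otu in rep.uncovered:
            rows.append({"level": rep.level, "status": "uncovered", "otu": otu})
    return pd.DataFrame(rows)


# -- plates ------------------------------------------------------------------

def write_plate(points: Sequence[DilutionPoint], path: str | Path) -> None:
    rows = []
    for p in points:
        for i, ct in enumerate(p.ct_values, start=1):
            rows.append(
                {
                    "run_id": p.run_id,
                    "curve_id": p.curve_id,
                    "well": f"{p.run_id}:{p.curve_id}:{p.known_copies:g}:{i}",
                    "known_copies": p.known_copies,
                    "ct": ct,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_plate(path: str | Path) -> list[DilutionPoint]:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in PLATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"plate table lacks columns: {missing}")
    n_nondetect = int(table["ct"].isna().sum())
    if n_nondetect:
        logger.warning("dropped %d non-detect well(s) (blank ct)", n_nondetect)
        table = table.dropna(subset=["ct"])
    points = []
    for (run_id, curve_id, copies), group in table.groupby(
        ["run_id", "curve_id", "known_copies"], sort=True
    ):
        points.append(
            DilutionPoint(
                known_copies=float(copies),
                ct_values=tuple(group["ct"].astype(float)),
                run_id=str(run_id),
                curve_id=str(curve_id),
            )
        )
    return points
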