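"""In silico assay coverage over a taxonomy-annotated 16S sequence collection.

Given unaligned 16S rRNA gene sequences with phylum/genus/species labels and
reference coordinate spans (as exported from curated databases such as RDP),
this module answers: what fraction of sequences and taxa does an assay
perfectly match?

Pipeline
--------
1. *Eligibility*: keep records whose reference span fully contains the assay
   amplicon, so every component has the data needed for match testing.
2. *Matching*: each component must match perfectly somewhere in the record
   (the whole record is scanned; coordinate metadata may be approximate).
   The forward primer and probe are matched as written, the reverse primer as
   its reverse complement — records are assumed in the standard 16S sense
   orientation, the only orientation in which one sequence can carry all
   three sites.  Two criteria: *stringent* uses full-length oligos; *relaxed*
   uses the 3'-terminal 8 nt of each primer plus the full-length probe.
   Degenerate letters on the assay side match their IUPAC class; ambiguity
   characters on the target side never match (conservative coverage).
3. *Assay match*: a record is covered when all three components hit.
4. *Dereplication*: coverage is reported stepwise for all eligible sequences
   and at species (Phylum|Genus|species), genus (Phylum|Genus) and phylum
   levels; an OTU is covered when at least one of its sequences is covered.
   Two ambiguous phyla ("Bacteria Insertia Sedis", "Unclassified Bacteria")
   are excluded from the phylum-level tally; names containing "unclassified"
   at lower levels are retained.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from . import iupac
from .design import AssayDefinition, Oligo, amplicon_span

logger = logging.getLogger(__name__)

Criterion = Literal["stringent", "relaxed"]
Level = Literal["all_sequences", "species", "genus", "phylum"]

LEVELS: tuple[Level, ...] = ("all_sequences", "species", "genus", "phylum")
RELAXED_PRIMER_LENGTH = 8
EXCLUDED_PHYLA = frozenset({"bacteria insertia sedis", "unclassified bacteria"})
DEFAULT_DELIMITER = "|"


@dataclass(frozen=True)
class TaxSeqRecord:
    """One target sequence with taxonomy labels and reference span."""

    seq_id: str
    phylum: str
    genus: str
    species: str
    sequence: str
    ref_start: int | None
    ref_end: int | None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.seq_id}: empty sequence")
        if (
            self.ref_start is not None
            and self.ref_end is not None
            and self.ref_start > self.ref_end
        ):
            raise ValueError(f"{self.seq_id}: ref_start beyond ref_end")

    def otu(self, level: Level, delimiter: str = DEFAULT_DELIMITER) -> str:
        if level == "all_sequences":
            return self.seq_id
        if level == "species":
            return delimiter.join((self.phylum, self.genus, self.species))
        if level == "genus":
            return delimiter.join((self.phylum, self.genus))
        return self.phylum


@dataclass(frozen=True)
class AssayMatch:
    seq_id: str
    forward_hit: bool
    reverse_hit: bool
    probe_hit: bool

    @property
    def assay_match(self) -> bool:
        return self.forward_hit and self.reverse_hit and self.probe_hit


@dataclass(frozen=True)
class CoverageReport:
    level: Level
    numerator: int
    denominator: int
    covered: tuple[str, ...]
    uncovered: tuple[str, ...]

    @property
    def percent(self) -> float:
        if self.denominator == 0:
            return 0.0
        return 100.0 * self.numerator / self.denominator


@dataclass(frozen=True)
class PhylumAnnotation:
    """Genus-level coverage within one phylum, with the comparison flags."""

    phylum: str
    phylum_covered: bool
    genera_covered: int
    genera_total: int
    not_covered: bool       # the phylum itself has no covered sequence
    poorly_covered: bool    # >50% of its genera are uncovered

    @property
    def genus_percent(self) -> float:
        if self.genera_total == 0:
            return 0.0
        return 100.0 * self.genera_covered / self.genera_total


@dataclass(frozen=True)
class AssayComparison:
    assay_a: str
    assay_b: str
    criterion: Criterion
    reports_a: Mapping[Level, CoverageReport]
    reports_b: Mapping[Level, CoverageReport]
    annotations_a: tuple[PhylumAnnotation, ...]
    annotations_b: tuple[PhylumAnnotation, ...]

    @property
    def improvement(self) -> dict[Level, float]:
        """percent(A) - percent(B) at each level."""
        return {
            lvl: self.reports_a[lvl].percent - self.reports_b[lvl].percent
            for lvl in LEVELS
        }


def filter_eligible(
    records: Iterable[TaxSeqRecord],
    assay: AssayDefinition,
    full_containment: bool = True,
    skipped: list[TaxSeqRecord] | None = None,
) -> list[TaxSeqRecord]:
    """Records whose reference span contains the assay amplicon.

    ``full_containment=False`` relaxes to any overlap with the amplicon.
    Records missing span metadata are excluded and counted via the module
    logger (and appended to *skipped* when given).
    """
    start, end, _ = amplicon_span(assay)
    eligible: list[TaxSeqRecord] = []
    n_missing = 0
    for rec in records:
        if rec.ref_start is None or rec.ref_end is None:
            n_missing += 1
            if skipped is not None:
                skipped.append(rec)
            continue
        if full_containment:
            ok = rec.ref_start <= start and rec.ref_end >= end
        else:
            ok = rec.ref_start <= end and rec.ref_end >= start
        if ok:
            eligible.append(rec)
    if n_missing:
        logger.warning(
            "%d record(s) lacked reference span metadata and were skipped",
            n_missing,
        )
    return eligible


def iupac_match(pattern: str, window: str) -> bool:
    """Equal-length perfect match: degenerate pattern vs plain-base window."""
    return iupac.matches(pattern, window)


def _search_pattern(oligo: Oligo, criterion: Criterion) -> str:
    """The strand-oriented pattern actually scanned against a record."""
    seq = oligo.sequence
    if criterion == "relaxed" and oligo.role != "probe":
        if len(seq) < RELAXED_PRIMER_LENGTH:
            raise ValueError(
                f"{oligo.name}: primer shorter than {RELAXED_PRIMER_LENGTH} nt "
                "cannot be matched under the relaxed criterion"
            )
        seq = seq[-RELAXED_PRIMER_LENGTH:]  # 3'-terminal 8-mer
    if oligo.role == "reverse_primer":
        seq = iupac.reverse_complement(seq)
    return seq


def component_hit(
    record: TaxSeqRecord, oligo: Oligo, criterion: Criterion = "stringent"
) -> bool:
    """True when the oligo perfectly matches some window of the record."""
    pattern = _search_pattern(oligo, criterion)
    return iupac.compile_pattern(pattern).search(record.sequence.upper()) is not None


def assay_match(
    record: TaxSeqRecord,
    assay: AssayDefinition,
    criterion: Criterion = "stringent",
) -> AssayMatch:
    """Per-component hits; the assay matches only when all three do."""
    return AssayMatch(
        seq_id=record.seq_id,
        forward_hit=component_hit(record, assay.forward, criterion),
        reverse_hit=component_hit(record, assay.reverse, criterion),
        probe_hit=component_hit(record, assay.probe, criterion),
    )


def _phylum_excluded(phylum: str) -> bool:
    return phylum.strip().lower() in EXCLUDED_PHYLA


def _level_report(
    records: Sequence[TaxSeqRecord],
    matched_ids: set[str],
    level: Level,
    delimiter: str,
) -> CoverageReport:
    if level == "phylum":
        records = [r for r in records if not _phylum_excluded(r.phylum)]
    all_otus = sorted({r.otu(level, delimiter) for r in records})
    covered = sorted(
        {r.otu(level, delimiter) for r in records if r.seq_id in matched_ids}
    )
    covered_set = set(covered)
    uncovered = [o for o in all_otus if o not in covered_set]
    return CoverageReport(
        level=level,
        numerator=len(covered),
        denominator=len(all_otus),
        covered=tuple(covered),
        uncovered=tuple(uncovered),
    )


def numerical_coverage(
    records: Sequence[TaxSeqRecord],
    assay: AssayDefinition,
    criterion: Criterion = "stringent",
    delimiter: str = DEFAULT_DELIMITER,
) -> dict[Level, CoverageReport]:
    """Stepwise coverage: all eligible sequences, then species, genus, phylum.

    *records* must already be eligibility-filtered.  At every taxonomic level
    an OTU counts as covered when at least one of its sequences is an assay
    perfect match under *criterion*.
    """
    if not records:
        raise ValueError("no eligible records: cannot compute coverage")
    matched_ids = {
        r.seq_id for r in records if assay_match(r, assay, criterion).assay_match
    }
    return {
        level: _level_report(records, matched_ids, level, delimiter)
        for level in LEVELS
    }


def taxonomic_coverage(
    records: Sequence[TaxSeqRecord],
    assay: AssayDefinition,
    criterion: Criterion = "stringent",
    delimiter: str = DEFAULT_DELIMITER,
) -> dict[Level, tuple[tuple[str, ...], tuple[str, ...]]]:
    """Per-level (covered, uncovered) OTU listings; a partition at each level."""
    reports = numerical_coverage(records, assay, criterion, delimiter)
    return {lvl: (rep.covered, rep.uncovered) for lvl, rep in reports.items()}


def _phylum_annotations(
    records: Sequence[TaxSeqRecord],
    reports: Mapping[Level, CoverageReport],
    delimiter: str,
) -> tuple[PhylumAnnotation, ...]:
    covered_phyla = set(reports["phylum"].covered)
    covered_genera = set(reports["genus"].covered)
    phyla = sorted(
        {r.phylum for r in records if not _phylum_excluded(r.phylum)}
    )
    annos = []
    for ph in phyla:
        genera = {
            r.otu("genus", delimiter) for r in records if r.phylum == ph
        }
        n_cov = len(genera & covered_genera)
        is_covered = ph in covered_phyla
        annos.append(
            PhylumAnnotation(
                phylum=ph,
                phylum_covered=is_covered,
                genera_covered=n_cov,
                genera_total=len(genera),
                not_covered=not is_covered,
                poorly_covered=(len(genera) - n_cov) > 0.5 * len(genera),
            )
        )
    return tuple(annos)


def compare_assays(
    records: Sequence[TaxSeqRecord],
    assay_a: AssayDefinition,
    assay_b: AssayDefinition,
    criterion: Criterion = "stringent",
    delimiter: str = DEFAULT_DELIMITER,
) -> AssayComparison:
    """Side-by-side coverage of two assays over one collection.

    Eligibility is computed independently per assay (the amplicons differ, so
    the denominators may differ).  Per-phylum annotations flag phyla that an
    assay leaves uncovered or covers poorly (>50% of genera uncovered).
    """
    eligible_a = filter_eligible(records, assay_a)
    eligible_b = filter_eligible(records, assay_b)
    reports_a = numerical_coverage(eligible_a, assay_a, criterion, delimiter)
    reports_b = numerical_coverage(eligible_b, assay_b, criterion, delimiter)
    return AssayComparison(
        assay_a=assay_a.assay_name,
        assay_b=assay_b.assay_name,
        criterion=criterion,
        reports_a=reports_a,
        reports_b=reports_b,
        annotations_a=_phylum_annotations(eligible_a, reports_a, delimiter),
        annotations_b=_phylum_annotations(eligible_b, reports_b, delimiter),
    )
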