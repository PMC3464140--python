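"""Synthetic inputs with exact planted ground truth for the whole pipeline.

Three generators, all deterministic under a seed:

* :func:`make_alignment` — a gapped multiple alignment built from column
  blocks (conserved, biallelic, random, gappy) with a per-column truth table
  of gap fraction and Simpson diversity.  Planted blocks use exact counts
  (``round(p*n)`` minor alleles, ``round(rate*n)`` gaps) rather than binomial
  draws so the truth is exact, not an expectation.
* :func:`make_collection` — a taxonomy-annotated 16S-like sequence collection
  in which every sequence carries exact expansions of an assay's three sites
  (reverse-primer site as its reverse complement), except where a planted
  miss substitutes a non-matching base at a chosen offset from the primer
  3' end (or within the probe).  Random background is scrubbed of chance
  matches to the assay's search patterns so the planted coverage truth —
  per level, under both stringent and relaxed criteria — is exact.
* :func:`make_plate` — a runs x in-run-curves x triplicates qPCR validation
  plate with Ct = intercept + slope*log10(copies) + N(0, sd), where
  slope = -1/log10(1 + efficiency); optional planted outlier wells.

These emulate the *shape* of real design/validation inputs (a pre-aligned
core set, a curated full-length 16S export, a 384-well validation series),
not their biology: there is no phylogenetic correlation structure, chimeras,
or sequencing error.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import iupac
from .coverage import RELAXED_PRIMER_LENGTH, CoverageReport, Level, TaxSeqRecord
from .design import AssayDefinition, Oligo, amplicon_span

BASES = "ACGT"

# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

BlockKind = Literal["conserved", "biallelic", "random", "gappy"]


@dataclass(frozen=True)
class Block:
    """A run of alignment columns sharing one generative recipe."""

    kind: BlockKind
    length: int
    p: float = 0.6       # major-allele fraction for biallelic columns
    rate: float = 0.25   # gap fraction for gappy columns

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("block length must be >= 1")
        if not (0.0 < self.p <= 1.0) or not (0.0 <= self.rate <= 1.0):
            raise ValueError("block probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class AlignmentSpec:
    n_sequences: int = 10
    blocks: tuple[Block, ...] = (Block("conserved", 100),)
    reference_id: str = "REF"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ValueError("need at least 2 sequences")


def make_alignment(
    spec: AlignmentSpec,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate (id, gapped sequence) rows plus a per-column truth table.

    Row 0 is the reference (never gapped, always carries the major allele) so
    reference coordinates are well defined.  Truth columns: ``column``,
    ``kind``, ``gap_fraction``, ``diversity``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sequences
    rows: list[list[str]] = [[] for _ in range(n)]
    truth_rows = []
    col = 0
    for block in spec.blocks:
        for _ in range(block.length):
            if block.kind == "conserved":
                base = rng.choice(list(BASES))
                chars = [base] * n
            elif block.kind == "biallelic":
                major, minor = rng.choice(list(BASES), size=2, replace=False)
                k_minor = n - round(block.p * n)
                if k_minor > n - 1:
                    raise ValueError("biallelic p too small: reference row must be major")
                chars = [major] * n
                for i in rng.choice(np.arange(1, n), size=k_minor, replace=False):
                    chars[i] = minor
            elif block.kind == "gappy":
                base = rng.choice(list(BASES))
                g = round(block.rate * n)
                if g > n - 1:
                    raise ValueError("gap rate too high: reference row stays ungapped")
                chars = [base] * n
                for i in rng.choice(np.arange(1, n), size=g, replace=False):
                    chars[i] = "-"
            else:  # random
                chars = list(rng.choice(list(BASES), size=n))
            counts = {b: chars.count(b) for b in BASES}
            n_plain = sum(counts.values())
            gap_fraction = chars.count("-") / n
            diversity = (
                1.0 - sum((c / n_plain) ** 2 for c in counts.values() if c)
                if n_plain
                else 0.0
            )
            truth_rows.append(
                {
                    "column": col,
                    "kind": block.kind,
                    "gap_fraction": gap_fraction,
                    "diversity": diversity,
                }
            )
            for i in range(n):
                rows[i].append(chars[i])
            col += 1

    ids = [spec.reference_id] + [f"SYN{i:04d}" for i in range(1, n)]
    records = [(sid, "".join(row)) for sid, row in zip(ids, rows)]
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# taxonomy-annotated collections
# ---------------------------------------------------------------------------

Component = Literal["forward", "reverse", "probe"]


@dataclass(frozen=True)
class PlantedMiss:
    """A substitution planted into one component's site for a chosen taxon.

    ``offset_3prime`` counts from the oligo's 3' end (0 = terminal base); for
    primers, offsets below 8 break both match criteria while larger offsets
    break only the stringent one.  ``genus``/``species`` of ``None`` widen the
    selection to the whole phylum / whole genus.
    """

    phylum: int
    component: Component
    offset_3prime: int = 0
    genus: int | None = None
    species: int | None = None

    def selects(self, p: int, g: int, s: int) -> bool:
        if self.phylum != p:
            return False
        if self.genus is not None and self.genus != g:
            return False
        if self.species is not None and self.species != s:
            return False
        return True


@dataclass(frozen=True)
class CollectionSpec:
    n_phyla: int = 34
    genera_per_phylum: int = 2
    species_per_genus: int = 2
    seqs_per_species: int = 2
    template_length: int = 1000
    span_coverage_fraction: float = 1.0
    planted_misses: tuple[PlantedMiss, ...] = ()
    seed: int = 0

    @property
    def n_records(self) -> int:
        return (
            self.n_phyla
            * self.genera_per_phylum
            * self.species_per_genus
            * self.seqs_per_species
        )


@dataclass(frozen=True)
class CollectionTruth:
    """Exact expected pipeline output for a generated collection."""

    eligible_ids: tuple[str, ...]
    matched_ids: dict[str, tuple[str, ...]]          # criterion -> seq ids
    reports: dict[str, dict[Level, CoverageReport]]  # criterion -> level -> report


def default_collection_spec(seed: int = 0) -> CollectionSpec:
    """The desk-scale fixture mirroring the shape of a database-wide analysis.

    34 phyla with three of them carrying probe-center misses (so the
    phylum-level report reads 31/34 = 91.2% under both criteria), one
    genus-level 5'-primer miss (uncovered only under the stringent
    criterion) and one species-level probe miss.
    """
    return CollectionSpec(
        n_phyla=34,
        genera_per_phylum=2,
        species_per_genus=2,
        seqs_per_species=2,
        planted_misses=(
            PlantedMiss(phylum=31, component="probe", offset_3prime=7),
            PlantedMiss(phylum=32, component="probe", offset_3prime=7),
            PlantedMiss(phylum=33, component="probe", offset_3prime=7),
            # stringent-only miss: outside the primer's 3' 8-mer
            PlantedMiss(phylum=0, genus=1, component="forward", offset_3prime=12),
            PlantedMiss(phylum=1, genus=0, species=1, component="probe",
                        offset_3prime=5),
        ),
        seed=seed,
    )


def _miss_breaks(miss: PlantedMiss, criterion: str) -> bool:
    """Does this planted miss break the assay match under the criterion?"""
    if criterion == "stringent" or miss.component == "probe":
        return True
    return miss.offset_3prime < RELAXED_PRIMER_LENGTH


def _mutate_oligo_expansion(
    expansion: str, oligo: Oligo, offset_3prime: int, rng: np.random.Generator
) -> str:
    if not 0 <= offset_3prime < len(oligo):
        raise ValueError(
            f"offset {offset_3prime} outside oligo {oligo.name} "
            f"(length {len(oligo)})"
        )
    pos = len(oligo) - 1 - offset_3prime
    allowed = iupac.IUPAC_CLASSES[oligo.sequence[pos]]
    candidates = [b for b in BASES if b not in allowed]
    if not candidates:
        raise ValueError(
            f"cannot plant a miss at {oligo.name} position {pos}: the IUPAC "
            "class covers every base"
        )
    sub = rng.choice(candidates)
    return expansion[:pos] + sub + expansion[pos + 1 :]


def _search_patterns(assay: AssayDefinition) -> dict[str, tuple[str, int]]:
    """pattern name -> (strand-oriented IUPAC pattern, intended 0-based start).

    These are exactly the patterns the coverage module scans with, under both
    criteria; intended starts are where a clean site matches them.
    """
    fw, rev, probe = assay.forward, assay.reverse, assay.probe
    k = RELAXED_PRIMER_LENGTH
    return {
        "forward_full": (fw.sequence, fw.ref_start - 1),
        "forward_3p8": (fw.sequence[-k:], fw.ref_start - 1 + len(fw) - k),
        "reverse_full": (iupac.reverse_complement(rev.sequence), rev.ref_start - 1),
        "reverse_3p8": (iupac.reverse_complement(rev.sequence[-k:]), rev.ref_start - 1),
        "probe_full": (probe.sequence, probe.ref_start - 1),
    }


def _scrub_chance_matches(
    seq: list[str],
    assay: AssayDefinition,
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> None:
    """Destroy matches of any search pattern outside its intended site.

    Short relaxed patterns (8-mers) hit kilobase-scale random background by
    chance often enough to corrupt planted truth; any such window gets one
    base flipped outside every protected site span until the sequence is
    clean.  Mutates *seq* in place.
    """
    patterns = _search_patterns(assay)
    for _ in range(max_rounds):
        dirty = False
        text = "".join(seq)
        for pat, intended in patterns.values():
            regex = iupac.compile_pattern(pat)
            start = 0
            while True:
                m = regex.search(text, start)
                if m is None:
                    break
                if m.start() != intended:
                    safe = [
                        i
                        for i in range(m.start(), m.end())
                        if not any(a <= i <= b for a, b in protected)
                    ]
                    if not safe:
                        raise RuntimeError(
                            "chance match fully inside a protected assay site"
                        )
                    i = int(rng.choice(safe))
                    allowed = iupac.IUPAC_CLASSES[pat[i - m.start()]]
                    seq[i] = rng.choice([b for b in BASES if b not in allowed])
                    text = "".join(seq)
                    dirty = True
                start = m.start() + 1
        if not dirty:
            return
    raise RuntimeError("could not scrub chance matches from background")


def make_collection(
    spec: CollectionSpec, assay: AssayDefinition
) -> tuple[list[TaxSeqRecord], CollectionTruth]:
    """Generate a collection plus its exact coverage truth under both criteria."""
    start, end, _ = amplicon_span(assay)
    if spec.template_length < assay.reverse.ref_end:
        raise ValueError(
            "template_length must reach past the reverse primer site"
        )
    rng = np.random.default_rng(spec.seed)
    n_records = spec.n_records
    n_eligible = round(spec.span_coverage_fraction * n_records)
    eligible_mask = np.zeros(n_records, dtype=bool)
    eligible_mask[
        rng.choice(n_records, size=n_eligible, replace=False)
    ] = True

    records: list[TaxSeqRecord] = []
    matched: dict[str, list[str]] = {"stringent": [], "relaxed": []}
    idx = 0
    for p in range(spec.n_phyla):
        for g in range(spec.genera_per_phylum):
            for s in range(spec.species_per_genus):
                misses = [
                    m for m in spec.planted_misses if m.selects(p, g, s)
                ]
                for _ in range(spec.seqs_per_species):
                    seq_id = f"SEQ{idx:05d}"
                    template = list(
                        rng.choice(list(BASES), size=spec.template_length)
                    )
                    # one exact expansion of each component per sequence
                    sites: dict[str, str] = {}
                    for comp, oligo in (
                        ("forward", assay.forward),
                        ("reverse", assay.reverse),
                        ("probe", assay.probe),
                    ):
                        choices = sorted(iupac.expand(oligo.sequence))
                        site = choices[rng.integers(len(choices))]
                        for miss in misses:
                            if miss.component == comp:
                                site = _mutate_oligo_expansion(
                                    site, oligo, miss.offset_3prime, rng
                                )
                        sites[comp] = site
                    protected = []
                    for comp, oligo in (
                        ("forward", assay.forward),
                        ("reverse", assay.reverse),
                        ("probe", assay.probe),
                    ):
                        site = sites[comp]
                        if comp == "reverse":
                            site = iupac.reverse_complement(site)
                        a, b = oligo.ref_start - 1, oligo.ref_end - 1
                        template[a : b + 1] = list(site)
                        protected.append((a, b))
                    _scrub_chance_matches(template, assay, protected, rng)

                    if eligible_mask[idx]:
                        ref_start, ref_end = 1, spec.template_length
                        sequence = "".join(template)
                        for criterion in ("stringent", "relaxed"):
                            if not any(
                                _miss_breaks(m, criterion) for m in misses
                            ):
                                matched[criterion].append(seq_id)
                    else:
                        # span starts inside the amplicon: forward site absent
                        ref_start = start + 100
                        ref_end = spec.template_length
                        sequence = "".join(template[ref_start - 1 :])
                    records.append(
                        TaxSeqRecord(
                            seq_id=seq_id,
                            phylum=f"Phylum{p:02d}",
                            genus=f"Genus{p:02d}.{g:02d}",
                            species=f"sp{p:02d}.{g:02d}.{s:02d}",
                            sequence=sequence,
                            ref_start=ref_start,
                            ref_end=ref_end,
                        )
                    )
                    idx += 1

    eligible_ids = tuple(
        r.seq_id for r, m in zip(records, eligible_mask) if m
    )
    truth_reports: dict[str, dict[Level, CoverageReport]] = {}
    by_id = {r.seq_id: r for r in records}
    for criterion in ("stringent", "relaxed"):
        matched_set = set(matched[criterion])
        eligible_records = [by_id[i] for i in eligible_ids]
        level_reports: dict[Level, CoverageReport] = {}
        for level in ("all_sequences", "species", "genus", "phylum"):
            all_otus = sorted({r.otu(level) for r in eligible_records})
            covered = sorted(
                {
                    r.otu(level)
                    for r in eligible_records
                    if r.seq_id in matched_set
                }
            )
            covered_set = set(covered)
            level_reports[level] = CoverageReport(
                level=level,
                numerator=len(covered),
                denominator=len(all_otus),
                covered=tuple(covered),
                uncovered=tuple(o for o in all_otus if o not in covered_set),
            )
        truth_reports[criterion] = level_reports

    truth = CollectionTruth(
        eligible_ids=eligible_ids,
        matched_ids={c: tuple(ids) for c, ids in matched.items()},
        reports=truth_reports,
    )
    return records, truth


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedOutlier:
    run: int
    curve: int
    concentration_index: int
    replicate: int
    delta_ct: float


@dataclass(frozen=True)
class PlateSpec:
    """A validation plate design: runs x in-run curves x triplicates.

    Defaults mirror the canonical MIQE-style validation layout: three runs,
    three standard curves per run, triplicate wells over a seven-decade
    dilution series (1e2..1e8 copies/reaction).
    """

    true_efficiency: float = 0.95
    intercept: float = 39.0
    decades: tuple[float, ...] = (1e2, 1e3, 1e4, 1e5, 1e6, 1e7, 1e8)
    n_runs: int = 3
    curves_per_run: int = 3
    replicates: int = 3
    ct_noise_sd: float = 0.15
    outliers: tuple[PlantedOutlier, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_efficiency <= 0:
            raise ValueError("efficiency must be positive")
        if any(d <= 0 for d in self.decades):
            raise ValueError("copy numbers must be positive")
        if self.ct_noise_sd < 0:
            raise ValueError("noise SD must be non-negative")

    @property
    def slope(self) -> float:
        return -1.0 / math.log10(1.0 + self.true_efficiency)


def make_plate(spec: PlateSpec):
    """Simulate the plate; returns (points, truth dict).

    Truth carries the generating ``slope``, ``intercept`` and ``efficiency``;
    at zero noise a standard-curve fit recovers them exactly.
    """
    from .quant import DilutionPoint  # local import avoids a cycle at import time

    rng = np.random.default_rng(spec.seed)
    points = []
    for run in range(spec.n_runs):
        for curve in range(spec.curves_per_run):
            for ci, copies in enumerate(spec.decades):
                cts = (
                    spec.intercept
                    + spec.slope * math.log10(copies)
                    + rng.normal(0.0, spec.ct_noise_sd, size=spec.replicates)
                )
                cts = list(cts)
                for o in spec.outliers:
                    if (o.run, o.curve, o.concentration_index) == (run, curve, ci):
                        cts[o.replicate] += o.delta_ct
                points.append(
                    DilutionPoint(
                        known_copies=copies,
                        ct_values=tuple(float(c) for c in cts),
                        run_id=f"run{run + 1}",
                        curve_id=f"curve{curve + 1}",
                    )
                )
    truth = {
        "slope": spec.slope,
        "intercept": spec.intercept,
        "efficiency": spec.true_efficiency,
    }
    return points, truth
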