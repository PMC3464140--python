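"""Per-column nucleotide distribution profiling of a 16S multiple alignment.

The design workflow for a broad-coverage qPCR assay starts from a large
pre-aligned 16S rRNA gene collection.  Each alignment column is summarised as
a nucleotide distribution (counts of A/C/G/T, ambiguity characters and gaps),
an allele-frequency vector, and a Simpson-based diversity score.  Columns with
too many gaps are masked from design consideration (the gap filter), and
maximal runs of low-diversity, low-gap columns of sufficient ungapped length
are reported as conserved regions suitable for primer/probe placement.

Conventions
-----------
* Gap characters are ``-`` and ``.``; parsing is case-insensitive.
* IUPAC ambiguity characters in alignment rows count as "other" and are
  excluded from allele frequencies: coverage matching treats target-side
  ambiguity as unmatchable, so design statistics must not credit them.
* Diversity is the Simpson complement 1 - sum(p_i^2) over non-gap A/C/G/T
  frequencies: 0 for a fully conserved column, approaching 0.75 for a uniform
  four-allele column.  The raw Simpson sum is available via ``complement=False``.
* Reference coordinates are 1-based positions in the named ungapped reference
  row (E. coli numbering in the canonical use).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from . import iupac

GAP_CHARS = frozenset("-.")
BASES = ("A", "C", "G", "T")

DEFAULT_GAP_THRESHOLD = 0.03
DEFAULT_CONSENSUS_INCLUSION = 0.05


@dataclass(frozen=True)
class ColumnProfile:
    """Nucleotide distribution of one alignment column."""

    column_index: int
    counts: Mapping[str, int]          # keys A,C,G,T,other,gap
    allele_freqs: Mapping[str, float]  # over A,C,G,T; empty if no plain base
    gap_fraction: float
    diversity: float
    majority_base: str


@dataclass(frozen=True)
class AlignmentProfile:
    """Column profiles plus the alignment-column -> reference-position map."""

    columns: tuple[ColumnProfile, ...]
    n_sequences: int
    reference_id: str
    reference_map: Mapping[int, int]   # 0-based column -> 1-based ref position

    @property
    def n_columns(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class ConservedRegion:
    """A maximal run of design-eligible columns."""

    start_column: int   # 0-based inclusive
    end_column: int     # 0-based inclusive
    length_ungapped: int
    max_diversity: float
    mean_gap_fraction: float


def simpson_diversity(
    allele_freqs: Mapping[str, float], complement: bool = True
) -> float:
    """Simpson's Diversity Index of an allele-frequency vector.

    Returns ``1 - sum(p_i^2)`` (default) or the raw ``sum(p_i^2)`` when
    ``complement=False``.  Frequencies must sum to 1 (tolerance 1e-9); an
    empty mapping (no scorable base) scores 0 diversity.
    """
    freqs = [f for f in allele_freqs.values() if f > 0]
    if not freqs:
        return 0.0 if complement else 1.0
    total = sum(freqs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies sum to {total!r}, not 1")
    s = sum(f * f for f in freqs)
    return 1.0 - s if complement else s


def _degenerate_consensus(
    allele_freqs: Mapping[str, float], inclusion_threshold: float
) -> str:
    alleles = frozenset(b for b in BASES if allele_freqs.get(b, 0.0) >= inclusion_threshold)
    if not alleles:
        # no plain base reaches the threshold (e.g. an all-gap column)
        return "N"
    return iupac.CODE_FOR_ALLELES[alleles]


def build_profile(
    alignment: Sequence[tuple[str, str]],
    reference_id: str,
    consensus_inclusion_threshold: float = DEFAULT_CONSENSUS_INCLUSION,
) -> AlignmentProfile:
    """Profile an aligned collection of (id, gapped-sequence) pairs.

    All sequences must share one length; *reference_id* names the row whose
    non-gap columns define the reference coordinate system.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 aligned sequences")
    ids = [sid for sid, _ in alignment]
    seqs = [s.upper() for _, s in alignment]
    length = len(seqs[0])
    for sid, s in zip(ids, seqs):
        if len(s) != length:
            raise ValueError(
                f"unequal alignment lengths: {sid!r} has {len(s)}, expected {length}"
            )
    try:
        ref_row = seqs[ids.index(reference_id)]
    except ValueError:
        raise KeyError(f"reference id {reference_id!r} not in alignment") from None

    n = len(seqs)
    columns: list[ColumnProfile] = []
    reference_map: dict[int, int] = {}
    ref_pos = 0
    for col in range(length):
        chars = [s[col] for s in seqs]
        counts = {b: 0 for b in BASES}
        counts["other"] = 0
        counts["gap"] = 0
        for c in chars:
            if c in GAP_CHARS:
                counts["gap"] += 1
            elif c in counts:
                counts[c] += 1
            else:
                counts["other"] += 1
        n_plain = sum(counts[b] for b in BASES)
        freqs = (
            {b: counts[b] / n_plain for b in BASES if counts[b]} if n_plain else {}
        )
        gap_fraction = counts["gap"] / n
        columns.append(
            ColumnProfile(
                column_index=col,
                counts=counts,
                allele_freqs=freqs,
                gap_fraction=gap_fraction,
                diversity=simpson_diversity(freqs),
                majority_base=_degenerate_consensus(
                    freqs, consensus_inclusion_threshold
                ),
            )
        )
        if ref_row[col] not in GAP_CHARS:
            ref_pos += 1
            reference_map[col] = ref_pos

    return AlignmentProfile(
        columns=tuple(columns),
        n_sequences=n,
        reference_id=reference_id,
        reference_map=reference_map,
    )


def gap_filter(
    profile: AlignmentProfile, threshold: float = DEFAULT_GAP_THRESHOLD
) -> set[int]:
    """Column indices whose gap fraction is at most *threshold*.

    Masked (high-gap) columns stay in the profile output; this only selects
    which columns design may consider.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("gap threshold must be within [0, 1]")
    return {
        c.column_index for c in profile.columns if c.gap_fraction <= threshold
    }


def find_conserved_regions(
    profile: AlignmentProfile,
    window_ungapped_length: int,
    diversity_ceiling: float,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
) -> list[ConservedRegion]:
    """Maximal runs of conserved columns long enough for assay placement.

    A column qualifies when it passes the gap filter and its diversity is at
    most *diversity_ceiling*.  A maximal run is reported when its ungapped
    length — the number of reference-mapped columns it spans — reaches
    *window_ungapped_length*.  Regions are disjoint and sorted by start.
    """
    if window_ungapped_length < 1:
        raise ValueError("window_ungapped_length must be >= 1")
    retained = gap_filter(profile, gap_threshold)
    regions: list[ConservedRegion] = []
    run: list[ColumnProfile] = []

    def flush() -> None:
        if not run:
            return
        ungapped = sum(
            1 for c in run if c.column_index in profile.reference_map
        )
        if ungapped >= window_ungapped_length:
            regions.append(
                ConservedRegion(
                    start_column=run[0].column_index,
                    end_column=run[-1].column_index,
                    length_ungapped=ungapped,
                    max_diversity=max(c.diversity for c in run),
                    mean_gap_fraction=(
                        sum(c.gap_fraction for c in run) / len(run)
                    ),
                )
            )
        run.clear()

    for col in profile.columns:
        if col.column_index in retained and col.diversity <= diversity_ceiling:
            run.append(col)
        else:
            flush()
    flush()
    return regions


def map_to_reference(
    profile: AlignmentProfile, start_col: int, end_col: int
) -> tuple[int, int]:
    """Reference positions (1-based inclusive) of an alignment-column span.

    When a boundary column is a reference gap, the nearest mapped column
    inside the span is used.  Raises ``ValueError`` when the span contains no
    reference-mapped column at all.
    """
    if start_col > end_col:
        raise ValueError(f"start_col {start_col} beyond end_col {end_col}")
    mapped = [
        c for c in range(start_col, end_col + 1) if c in profile.reference_map
    ]
    if not mapped:
        raise ValueError(
            f"columns {start_col}-{end_col} contain no reference position"
        )
    return profile.reference_map[mapped[0]], profile.reference_map[mapped[-1]]
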