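"""Assay representation, degeneracy rules, melting temperature, amplicon span.

A TaqMan-style broad-coverage assay is three oligonucleotides — forward
primer, reverse primer and hydrolysis probe — written 5'->3' in IUPAC codes
with 1-based inclusive coordinates on a reference 16S rRNA gene (E. coli
numbering).  Design rules for broad-coverage quantification: each primer may
carry at most three degenerate bases, the probe none (degeneracy in the probe
erodes quantitative signal).

Primer melting temperatures use the salt-adjusted formula of the common
online oligo calculator, reported as a min-max range over the full degenerate
expansion.  Probe Tm for MGB chemistry is a proprietary vendor model and is
deliberately not computed; store it as metadata if needed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal

from . import iupac

Role = Literal["forward_primer", "reverse_primer", "probe"]

MAX_PRIMER_DEGENERACIES = 3


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1") ** ndigits, ROUND_HALF_UP))


@dataclass(frozen=True)
class Oligo:
    """A primer or probe: IUPAC sequence plus 1-based inclusive reference span."""

    name: str
    sequence: str
    role: Role
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", iupac.validate_iupac(self.sequence))
        if not self.sequence:
            raise ValueError("empty oligo sequence")
        span = self.ref_end - self.ref_start + 1
        if span != len(self.sequence):
            raise ValueError(
                f"{self.name}: reference span {self.ref_start}-{self.ref_end} "
                f"({span} nt) does not match sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssayDefinition:
    """Forward primer + probe + reverse primer, ordered along the reference."""

    assay_name: str
    forward: Oligo
    reverse: Oligo
    probe: Oligo

    def __post_init__(self) -> None:
        if not (self.forward.ref_start < self.probe.ref_start < self.reverse.ref_end):
            raise ValueError(
                f"{self.assay_name}: components out of order on the reference "
                f"(forward {self.forward.ref_start}, probe {self.probe.ref_start}, "
                f"reverse end {self.reverse.ref_end})"
            )

    @property
    def oligos(self) -> tuple[Oligo, Oligo, Oligo]:
        return (self.forward, self.reverse, self.probe)


@dataclass(frozen=True)
class TmResult:
    """Min/max salt-adjusted Tm (°C, one decimal) over a degenerate expansion."""

    tm_min: float
    tm_max: float
    n_variants: int

    def __post_init__(self) -> None:
        if self.tm_min > self.tm_max:
            raise ValueError("tm_min exceeds tm_max")


@dataclass(frozen=True)
class RuleCheck:
    rule: str
    component: str
    passed: bool
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    assay_name: str
    checks: tuple[RuleCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def failures(self) -> tuple[RuleCheck, ...]:
        return tuple(c for c in self.checks if not c.passed)


def count_degeneracies(oligo: Oligo | str) -> int:
    """Number of degenerate positions (IUPAC class size > 1) in the oligo."""
    seq = oligo.sequence if isinstance(oligo, Oligo) else oligo
    return iupac.count_degenerate_positions(seq)


def validate_assay(assay: AssayDefinition) -> ValidationReport:
    """Check the degeneracy design rules.

    Rule 1: each primer carries at most three degenerate bases.
    Rule 2: the probe carries no degenerate base.
    """
    checks: list[RuleCheck] = []
    for oligo in (assay.forward, assay.reverse):
        n = count_degeneracies(oligo)
        checks.append(
            RuleCheck(
                rule="primer_max_degeneracies",
                component=oligo.role,
                passed=n <= MAX_PRIMER_DEGENERACIES,
                detail=f"{n} degenerate base(s), limit {MAX_PRIMER_DEGENERACIES}",
            )
        )
    n_probe = count_degeneracies(assay.probe)
    checks.append(
        RuleCheck(
            rule="probe_no_degeneracies",
            component="probe",
            passed=n_probe == 0,
            detail=f"{n_probe} degenerate base(s), limit 0",
        )
    )
    return ValidationReport(assay_name=assay.assay_name, checks=tuple(checks))


def expand_degenerate(sequence: str) -> set[str]:
    """All plain ACGT expansions of a degenerate IUPAC string."""
    return iupac.expand(sequence)


def salt_adjusted_tm(sequence: str, sodium_molar: float = 0.05) -> float:
    """Salt-adjusted melting temperature (°C) of a non-degenerate oligo.

    Two length regimes, matching the referenced online calculator:

    * N >= 14:  Tm = 100.5 + 41*(nG+nC)/N - 820/N + 16.6*log10([Na+])
    * N < 14:   Tm = 2*(nA+nT) + 4*(nG+nC) - 16.6*log10(0.050)
                     + 16.6*log10([Na+])   (Wallace rule, salt-corrected)

    Parameters
    ----------
    sequence : plain ACGT string, length >= 8.
    sodium_molar : monovalent cation concentration in mol/L (default 0.05).
    """
    seq = iupac.validate_iupac(sequence)
    if any(iupac.class_size(c) > 1 for c in seq):
        raise ValueError("degenerate sequence: use tm_range() instead")
    n = len(seq)
    if n < 8:
        raise ValueError(f"sequence too short for Tm calculation ({n} < 8 nt)")
    if sodium_molar <= 0:
        raise ValueError("sodium concentration must be positive")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if n >= 14:
        return 100.5 + 41.0 * gc / n - 820.0 / n + 16.6 * math.log10(sodium_molar)
    return (
        2.0 * at + 4.0 * gc
        - 16.6 * math.log10(0.050)
        + 16.6 * math.log10(sodium_molar)
    )


def tm_range(oligo: Oligo | str, sodium_molar: float = 0.05) -> TmResult:
    """Min-max salt-adjusted Tm over the full degenerate expansion, 1 decimal."""
    seq = oligo.sequence if isinstance(oligo, Oligo) else oligo
    tms = [salt_adjusted_tm(v, sodium_molar) for v in iupac.iter_expansions(seq)]
    return TmResult(
        tm_min=_round_half_up(min(tms)),
        tm_max=_round_half_up(max(tms)),
        n_variants=len(tms),
    )


def amplicon_span(assay: AssayDefinition) -> tuple[int, int, int]:
    """(start, end, length) of the amplicon, 1-based inclusive on the reference."""
    start = assay.forward.ref_start
    end = assay.reverse.ref_end
    if end <= start:
        raise ValueError(
            f"{assay.assay_name}: amplicon end {end} not beyond start {start}"
        )
    return start, end, end - start + 1
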