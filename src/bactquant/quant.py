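"""qPCR quantification arithmetic: standards, curves, CoV, bacteria:human ratios.

Covers the numerical side of MIQE-style validation of a broad-coverage 16S
qPCR assay:

* qPCR-based normalization of cloned plasmid standards via the dilution
  factor 2^(target Cp - measured Cp), exploiting per-cycle doubling;
* standard-curve regression of Ct on log10(copies), with reaction efficiency
  10^(-1/slope) - 1 and r^2;
* the triplicate outlier rule (exclude a clear outlier when the replicate SD
  exceeds 0.3 cycles);
* inter-run and intra-run coefficients of variation for Ct and for
  back-calculated copy number over a runs x in-run-curves x triplicates
  validation design;
* bacteria-to-human ribosomal gene copy and genome-equivalent ratios used to
  express the detection limit against a human gDNA background.

The limit of detection itself is never estimated from data (reagent
background DNA makes that unreliable); only the ratio arithmetic at
user-supplied dynamic-range bounds is provided.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TRIPLICATE_SD_TRIGGER = 0.3
TRIPLICATE_OUTLIER_DELTA = 0.3


def _round_half_up_int(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), ROUND_HALF_UP))


@dataclass(frozen=True)
class QuantConstants:
    """Copy-number and genome-size constants for ratio calculations.

    Defaults: 3.94 16S copies per average bacterial genome (rrnDB), 400 18S
    copies per human genome, and 5.887 pg per diploid human genome
    (5,758 Mb / 978 Mb/pg, as printed — the printed 3-decimal mass is used
    verbatim because downstream integer results depend on it).
    """

    bact_16s_copies_per_genome: float = 3.94
    human_18s_copies_per_genome: float = 400.0
    human_diploid_genome_pg: float = 5.887
    mb_per_pg: float = 978.0
    diploid_genome_mb: float = 5758.0


DEFAULT_CONSTANTS = QuantConstants()


@dataclass(frozen=True)
class DilutionPoint:
    """Replicate Ct values at one known concentration of one in-run curve."""

    known_copies: float
    ct_values: tuple[float, ...]
    run_id: str = "run1"
    curve_id: str = "curve1"

    def __post_init__(self) -> None:
        if self.known_copies <= 0:
            raise ValueError("known_copies must be positive")
        if not self.ct_values:
            raise ValueError("need at least one replicate Ct")
        object.__setattr__(self, "ct_values", tuple(float(c) for c in self.ct_values))


@dataclass(frozen=True)
class StandardCurveFit:
    """OLS fit of Ct on log10(copies) with derived reaction efficiency."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_points: int
    nonnegative_slope: bool = False

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency

    def copies_from_ct(self, ct: float) -> float:
        """Back-calculate template copies from a Ct via the fitted line."""
        return 10.0 ** ((ct - self.intercept) / self.slope)


@dataclass(frozen=True)
class OutlierResult:
    retained: tuple[float, ...]
    excluded: tuple[float, ...]
    flag: Literal["ok", "excluded", "dispersed"]


@dataclass(frozen=True)
class CoVReport:
    """Inter-run and intra-run CoV tables, percent, indexed by known copies.

    ``inter_run`` columns: ct_cov_pct, copies_cov_pct (sample SD over the
    per-curve means across all runs, divided by their mean).
    ``intra_run`` columns: ct_cov_mean_pct, ct_cov_sd_pct, copies_cov_mean_pct,
    copies_cov_sd_pct (each in-run curve yields one CoV over its replicates;
    mean and SD are taken over the curves).
    """

    inter_run: pd.DataFrame
    intra_run: pd.DataFrame
    n_runs: int
    n_curves: int
    n_excluded_wells: int


@dataclass(frozen=True)
class LodRatio:
    """Bacteria-to-human detection-limit ratios at given dynamic-range bounds."""

    bacterial_copies: float
    human_mass_ng: float
    human_ribosomal_copies: int
    bacterial_genomes: int
    human_genomes: int
    simplified: tuple[int, int]   # (1, human copies per bacterial copy)


def normalization_factor(cp: float, target_cp: float = 10.0) -> float:
    """Dilution factor 2^(target - measured Cp) for plasmid normalization.

    A stock measuring one cycle later than the target is at half the
    concentration, so the factor halves per +1 Cp.
    """
    if cp <= 0:
        raise ValueError("Cp must be positive")
    return 2.0 ** (target_cp - cp)


def efficiency_from_slope(slope: float) -> float:
    """Reaction efficiency 10^(-1/slope) - 1; slope -3.3219 gives 1.0 (100%)."""
    if slope == 0:
        raise ValueError("zero slope has no defined efficiency")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(
    points: Sequence[DilutionPoint], per_well: bool = False
) -> StandardCurveFit:
    """Least-squares standard curve over a dilution series.

    By default each concentration contributes its mean Ct; ``per_well=True``
    regresses every replicate well instead.  Requires at least three distinct
    concentrations spanning the dynamic range.
    """
    if len({p.known_copies for p in points}) < 3:
        raise ValueError("need >= 3 distinct concentrations for a standard curve")
    xs: list[float] = []
    ys: list[float] = []
    for p in points:
        lx = math.log10(p.known_copies)
        if per_well:
            xs.extend([lx] * len(p.ct_values))
            ys.extend(p.ct_values)
        else:
            xs.append(lx)
            ys.append(sum(p.ct_values) / len(p.ct_values))
    res = stats.linregress(xs, ys)
    slope = float(res.slope)
    nonneg = slope >= 0
    efficiency = math.nan if nonneg else efficiency_from_slope(slope)
    return StandardCurveFit(
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency=efficiency,
        n_points=len(xs),
        nonnegative_slope=nonneg,
    )


def exclude_outlier(ct_triplicate: Sequence[float]) -> OutlierResult:
    """Apply the triplicate outlier rule to three replicate Ct values.

    When the sample SD exceeds 0.3 cycles and exactly one value lies more
    than 0.3 cycles from *both* others while those two agree within 0.3, that
    well is excluded; otherwise all three are retained (flagged "dispersed"
    when the SD trigger fired but no clear outlier exists).
    """
    cts = tuple(float(c) for c in ct_triplicate)
    if len(cts) != 3:
        raise ValueError("outlier rule is defined for triplicates only")
    if float(np.std(cts, ddof=1)) <= TRIPLICATE_SD_TRIGGER:
        return OutlierResult(retained=cts, excluded=(), flag="ok")
    for i in range(3):
        others = [cts[j] for j in range(3) if j != i]
        if (
            abs(others[0] - others[1]) <= TRIPLICATE_OUTLIER_DELTA
            and all(abs(cts[i] - o) > TRIPLICATE_OUTLIER_DELTA for o in others)
        ):
            return OutlierResult(
                retained=tuple(others), excluded=(cts[i],), flag="excluded"
            )
    return OutlierResult(retained=cts, excluded=(), flag="dispersed")


def _apply_outlier_rule(points: Iterable[DilutionPoint]) -> tuple[list[DilutionPoint], int]:
    cleaned: list[DilutionPoint] = []
    n_excluded = 0
    for p in points:
        if len(p.ct_values) == 3:
            res = exclude_outlier(p.ct_values)
            n_excluded += len(res.excluded)
            cleaned.append(replace(p, ct_values=res.retained))
        else:
            cleaned.append(p)
    return cleaned, n_excluded


def _cov_pct(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return 0.0
    mean = arr.mean()
    if mean == 0:
        return 0.0
    return 100.0 * float(arr.std(ddof=1)) / float(mean)


def cov_report(
    points: Sequence[DilutionPoint],
    apply_outlier_rule: bool = True,
) -> CoVReport:
    """Inter- and intra-run CoV for Ct and copy number over a validation plate.

    *points* carry run and curve identifiers (e.g. 3 runs x 3 in-run curves x
    triplicates per concentration).  Copy numbers are back-calculated per well
    from each in-run curve's own fit — the only choice that yields nonzero
    copy-number CoV when every curve was loaded with the same nominal series.
    """
    points = list(points)
    runs = sorted({p.run_id for p in points})
    curve_keys = sorted({(p.run_id, p.curve_id) for p in points})
    if len(runs) < 2:
        raise ValueError("inter-run CoV needs >= 2 runs")
    if len(curve_keys) < 2:
        raise ValueError("intra-run CoV needs >= 2 in-run curves")
    if apply_outlier_rule:
        points, n_excluded = _apply_outlier_rule(points)
    else:
        n_excluded = 0

    curve_fits = {
        key: fit_standard_curve(
            [p for p in points if (p.run_id, p.curve_id) == key]
        )
        for key in curve_keys
    }

    concentrations = sorted({p.known_copies for p in points})
    inter_rows = []
    intra_rows = []
    for conc in concentrations:
        curve_ct_means: list[float] = []
        curve_copy_means: list[float] = []
        curve_ct_covs: list[float] = []
        curve_copy_covs: list[float] = []
        for key in curve_keys:
            cts = [
                ct
                for p in points
                if (p.run_id, p.curve_id) == key and p.known_copies == conc
                for ct in p.ct_values
            ]
            if not cts:
                continue
            copies = [curve_fits[key].copies_from_ct(ct) for ct in cts]
            curve_ct_means.append(float(np.mean(cts)))
            curve_copy_means.append(float(np.mean(copies)))
            curve_ct_covs.append(_cov_pct(cts))
            curve_copy_covs.append(_cov_pct(copies))
        inter_rows.append(
            {
                "known_copies": conc,
                "ct_cov_pct": _cov_pct(curve_ct_means),
                "copies_cov_pct": _cov_pct(curve_copy_means),
            }
        )
        intra_rows.append(
            {
                "known_copies": conc,
                "ct_cov_mean_pct": float(np.mean(curve_ct_covs)),
                "ct_cov_sd_pct": float(np.std(curve_ct_covs, ddof=1)),
                "copies_cov_mean_pct": float(np.mean(curve_copy_covs)),
                "copies_cov_sd_pct": float(np.std(curve_copy_covs, ddof=1)),
            }
        )
    return CoVReport(
        inter_run=pd.DataFrame(inter_rows).set_index("known_copies"),
        intra_run=pd.DataFrame(intra_rows).set_index("known_copies"),
        n_runs=len(runs),
        n_curves=len(curve_keys),
        n_excluded_wells=n_excluded,
    )


def human_ribosomal_copies(
    mass_ng: float, constants: QuantConstants = DEFAULT_CONSTANTS
) -> int:
    """18S rRNA gene copies in *mass_ng* of human genomic DNA (nearest integer).

    copies = mass[pg] / pg-per-diploid-genome * 18S-copies-per-genome; e.g.
    5 ng -> 339,732 copies with the default constants.
    """
    if mass_ng < 0:
        raise ValueError("mass must be non-negative")
    copies = (
        mass_ng * 1000.0 / constants.human_diploid_genome_pg
    ) * constants.human_18s_copies_per_genome
    return _round_half_up_int(copies)


def genome_equivalents(
    bacterial_copies: float,
    human_mass_ng: float,
    constants: QuantConstants = DEFAULT_CONSTANTS,
) -> tuple[int, int]:
    """(bacterial genomes, human genomes) for given 16S copies and human mass."""
    if bacterial_copies < 0 or human_mass_ng < 0:
        raise ValueError("inputs must be non-negative")
    bact = _round_half_up_int(bacterial_copies / constants.bact_16s_copies_per_genome)
    human = _round_half_up_int(
        human_mass_ng * 1000.0 / constants.human_diploid_genome_pg
    )
    return bact, human


def lod_ratio(
    bacterial_copies: float,
    human_mass_ng: float,
    constants: QuantConstants = DEFAULT_CONSTANTS,
) -> LodRatio:
    """Bacteria-to-human ratios at a dynamic-range bound.

    Returns the raw ribosomal copy pair, the genome-equivalent pair, and the
    per-bacterial-copy simplification (1 : human 18S copies per 16S copy);
    (1000 copies, 10 ng) simplifies to 1:679.
    """
    if bacterial_copies <= 0:
        raise ValueError("bacterial copies must be positive for a ratio")
    human_copies = human_ribosomal_copies(human_mass_ng, constants)
    bact_gen, human_gen = genome_equivalents(
        bacterial_copies, human_mass_ng, constants
    )
    return LodRatio(
        bacterial_copies=bacterial_copies,
        human_mass_ng=human_mass_ng,
        human_ribosomal_copies=human_copies,
        bacterial_genomes=bact_gen,
        human_genomes=human_gen,
        simplified=(1, _round_half_up_int(human_copies / bacterial_copies)),
    )
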