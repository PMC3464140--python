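# Methods

This note records the models, conventions and numerical choices behind
`bactquant`, in the order the pipeline uses them, together with what the
synthetic-data generators do and do not emulate.

## Conservation profiling

A multiple sequence alignment of 16S rRNA genes is reduced to one record per
column: counts of A/C/G/T, ambiguity characters ("other") and gaps; allele
frequencies over the plain bases only; the gap fraction; and a diversity
score.

**Diversity score.** We use the Simpson complement `D = 1 − Σᵢ pᵢ²` computed
over the non-gap A/C/G/T frequencies, so a fully conserved column scores 0
and a uniformly tetra-allelic one 0.75. The raw Simpson sum `Σ pᵢ²` is
available via `complement=False`. Gaps are excluded from the denominator:
the gap filter already handles indel-rich columns, and including gaps would
conflate indel polymorphism with substitution polymorphism. Ambiguity
characters are excluded from the frequencies because coverage matching
treats target-side ambiguity as unmatchable, so design statistics should
never credit an N to an allele.

**Gap filter.** Columns with gap fraction above the threshold (default 3%)
are masked from design consideration but remain in the distribution output
with a `retained` flag, since the masked columns are still informative when
reading the profile by eye. The filter is monotone in the threshold.

**Conserved regions.** A maximal run of columns that pass the gap filter
and have diversity at or below a ceiling is reported when its *ungapped*
length — the number of reference-mapped columns — reaches the requested
window (default 500, the scale of a usable assay design region). The
diversity ceiling default of 0.1 in the CLI tolerates rare variants at
otherwise conserved positions; a ceiling of 0 demands strict invariance.
The ceiling and window are free parameters because no single published
cutoff defines "conserved" for this purpose.

**Reference coordinates.** A named ungapped-reference row (E. coli
numbering in the canonical use) maps alignment columns to 1-based reference
positions; region boundaries falling on reference gaps snap inward to the
nearest mapped column.

**Degenerate consensus.** The per-column `majority_base` is the IUPAC code
covering every allele whose frequency reaches an inclusion threshold
(default 5%): degenerate bases are meant to capture common variants, not
singletons. Columns with no qualifying plain base report `N`.

## Assay representation and melting temperature

An assay is three oligos written 5′→3′ with 1-based inclusive reference
coordinates; the amplicon is `[forward start, reverse end]` and its length
`end − start + 1`. Design rules: at most three degenerate bases per primer,
none in the probe.

Primer Tm uses the common salt-adjusted formulas, in the two length regimes
of the usual online calculator:

- N ≥ 14 nt: `Tm = 100.5 + 41·(nG+nC)/N − 820/N + 16.6·log₁₀[Na⁺]`
- N < 14 nt: `Tm = 2·(nA+nT) + 4·(nG+nC) − 16.6·log₁₀(0.050) + 16.6·log₁₀[Na⁺]`

with `[Na⁺] = 0.05 M` by default (the calculator's default; exposed as a
flag). A degenerate oligo's Tm is reported as the min–max over its full
expansion, rounded half-up to one decimal, with no frequency weighting.
No nearest-neighbor thermodynamic model is attempted, and the probe Tm for
MGB chemistry is not computed at all — that model is proprietary to the
vendor software; store a measured or vendor-computed value as metadata if
needed.

## In silico coverage

**Eligibility.** A record is eligible for an assay when its reference span
fully contains the assay amplicon, so all three components have data to
match against. A partial-overlap mode exists behind a flag; full
containment is the default because a component without underlying data can
never match and would deflate coverage spuriously.

**Matching.** Components are matched by scanning the *whole* record rather
than a coordinate window (span metadata is often approximate). Records are
assumed in the standard 16S sense orientation, so the forward primer and
probe are matched as written and the reverse primer as its reverse
complement — the only orientation in which one strand carries all three
sites. A degenerate pattern position matches any base of its IUPAC class;
any non-A/C/G/T character in the target makes the position a mismatch,
which keeps the coverage estimate conservative. The stringent criterion
uses full-length oligos; the relaxed criterion replaces each primer by its
3′-terminal 8-mer (the polymerase-extension-critical end) and keeps the
full probe. A record is an assay match only when all three components hit
(conjunction — the assay is evaluated as a unit).

**Dereplication.** Coverage proceeds stepwise: all eligible sequences
(numerator = matched sequence IDs), then species, genus and phylum levels
with OTUs formed by concatenating Phylum|Genus|species labels (delimiter
configurable). An OTU is covered when at least one member sequence is an
assay match. At the phylum level the two ambiguous bins "Bacteria Insertia
Sedis" and "Unclassified Bacteria" are removed from both numerator and
denominator (matched case-insensitively, verbatim); names containing
"unclassified" at lower levels are retained because they are too abundant
to discard. Reports are sorted, so identical inputs yield byte-identical
outputs regardless of input order.

**Comparison.** Two assays are compared with independently computed
eligibility (their amplicons differ, so denominators may differ), per-level
percent improvements, and per-phylum genus-coverage annotations flagging a
phylum as *not covered* (no matching sequence) or *poorly covered* (more
than half of its genera uncovered).

## Quantification arithmetic

**Plasmid normalization.** A plasmid stock measured at crossing point `Cp`
is brought to the target scale (`Cp = 10`) by the dilution factor
`2^(10 − Cp)`, exploiting per-cycle doubling; the factor halves per +1 Cp.

**Standard curves.** Ordinary least squares of Ct on log₁₀(copies) — mean
Ct per concentration by default, per-well behind a flag — yields slope,
intercept and r²; reaction efficiency is `10^(−1/slope) − 1`, so perfect
doubling corresponds to slope −3.3219. Non-negative slopes are flagged
rather than silently converted. At least three distinct concentrations are
required.

**Outlier rule.** For a triplicate with sample SD above 0.3 cycles, a well
more than 0.3 cycles from *both* other wells — which themselves agree
within 0.3 — is excluded; a dispersed triplicate with no single clear
outlier is retained whole and flagged.

**CoV.** Per concentration, the inter-run CoV is the sample SD over the
per-curve mean values across all runs divided by their mean (×100); the
intra-run CoV is computed per in-run curve over its replicates and then
averaged (mean ± SD) across curves. Copy-number CoV uses copies
back-calculated per well from each in-run curve's own fit — the only
definition that yields a nonzero copy CoV when every curve is loaded with
the same nominal dilution series.

**Ratios.** With the default constants — 3.94 16S copies per average
bacterial genome, 400 18S copies per human genome, 5.887 pg per diploid
human genome (5,758 Mb at 978 Mb/pg) — a human gDNA mass converts to 18S
copies and genome equivalents; a detection bound of B bacterial copies
against M ng human DNA is reported as the raw copy pair, the
genome-equivalent pair, and the simplification 1 : (18S copies / B). All
integer outputs round half-up; the printed 3-decimal genome mass is used
verbatim because the published integer results depend on that precision,
and every constant is overridable. The detection limit itself is never
estimated from data — reagent-background bacterial DNA makes a plasmid-only
LOD unreliable — so only the ratio arithmetic is provided.

## Synthetic data

The generators produce inputs whose expected pipeline outputs are known by
construction, deterministically under a seed.

*Alignments* are built from column blocks: conserved, biallelic(p),
random, or gappy(rate). Planted blocks use exact counts — `round(p·n)`
major alleles, `round(rate·n)` gaps — rather than binomial draws, so the
per-column truth table (gap fraction, diversity) is exact rather than an
expectation; the reference row is never gapped and always carries the major
allele. Random blocks record their realized values.

*Collections* embed one exact expansion of each assay site at its
reference coordinates in every sequence (the reverse-primer site as its
reverse complement), inside an i.i.d. random background. Planted misses
substitute, for all sequences of a selected phylum/genus/species, a base
drawn from outside the pattern's IUPAC class at a chosen offset from the
oligo's 3′ end — so a primer miss at offset ≥ 8 breaks only the stringent
criterion while a probe miss breaks both. Because the relaxed 8-mer
patterns would hit a kilobase of random background by chance at a
non-negligible rate, every sequence is scrubbed: any match of any search
pattern outside its intended site is destroyed by a single base flip, which
makes the planted truth tables exact at every taxonomic level under both
criteria. A span-coverage fraction controls how many records contain the
full amplicon (ineligible records start inside it and are trimmed). The
default desk-scale fixture has 34 phyla of 2 genera × 2 species × 2
sequences with three phyla carrying probe misses — a phylum report of
31/34 (91.2%) — plus one stringent-only primer miss and one species-level
probe miss, mirroring the structure of a database-scale analysis at a size
that runs in milliseconds.

*Plates* simulate `Ct = intercept + slope·log₁₀(copies) + N(0, σ)` with
`slope = −1/log₁₀(1 + E)` over a default 3 runs × 3 in-run curves ×
triplicates × 7 decades (10²–10⁸ copies/reaction) design at intercept 39,
efficiency 95% and σ = 0.15 cycles — values typical of a well-optimized
TaqMan assay validation. Outlier wells can be planted with a chosen Ct
shift; shifts must exceed ≈0.52 cycles for a noiseless triplicate's sample
SD to cross the 0.3 trigger.

What passing tests on these inputs show — and what they do not: they verify
the pipeline's arithmetic, matching semantics, dereplication logic and
estimator behaviour exactly; they do not demonstrate coverage of real
bacterial diversity (no phylogenetic correlation, no indels at primer
sites, no chimeras or sequencing error) nor real-plate artifacts such as
pipetting trends or reagent contamination.

## Numerical conventions and degenerate inputs

- Rounding: Tm to one decimal, ratio outputs to integers, both half-up.
- Frequencies must sum to 1 within 1e-9 for a diversity score; an all-gap
  column scores diversity 0 and consensus `N`.
- Case-insensitive sequence parsing; both `-` and `.` are gaps.
- Curve fits refuse fewer than three distinct concentrations; CoV reports
  refuse fewer than two runs (inter) or two in-run curves (intra).
- Blank Ct entries in plate files are non-detects, dropped with a log entry.
- Ties in the outlier rule (e.g. two candidate outliers) retain all wells.

## Known limitations

- Tm ranges use uniform min–max over expansions; no per-variant abundance
  weighting and no nearest-neighbor model.
- Coverage matching is exact-match only; a single terminal mismatch that a
  polymerase might tolerate still counts as uncovered (by design —
  laboratory sensitivity generally exceeds these in silico predictions).
- Eligibility trusts the provided reference spans; sequences are not
  re-aligned to the reference.
- The comparison-assay fixture uses approximate reference coordinates.
- The per-sequence level of a collection uses sequence IDs as OTUs, so its
  "coverage" is a sequence fraction, not a taxon fraction.
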