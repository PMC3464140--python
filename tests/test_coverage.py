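"""IUPAC perfect-match testing, eligibility, dereplicated coverage reports."""
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bactquant import (
    BACTQUANT,
    PUBLISHED_COMPARISON,
    CollectionSpec,
    PlantedMiss,
    TaxSeqRecord,
    assay_match,
    compare_assays,
    component_hit,
    filter_eligible,
    iupac_match,
    make_collection,
    numerical_coverage,
    taxonomic_coverage,
)
from bactquant import iupac


def record(seq, seq_id="S1", phylum="P", genus="G", species="s", span=(1, None)):
    start, end = span
    return TaxSeqRecord(
        seq_id=seq_id,
        phylum=phylum,
        genus=genus,
        species=species,
        sequence=seq,
        ref_start=start,
        ref_end=end if end is not None else (start + len(seq) - 1),
    )


class TestIupacMatch:
    def test_identical_plain_sequences_match(self):
        assert iupac_match("CAGCAGCCGCGGTA", "CAGCAGCCGCGGTA")

    @pytest.mark.parametrize(
        "window_base,expected",
        [("A", True), ("G", True), ("T", True), ("C", False)],
    )
    def test_degenerate_d_excludes_only_c(self, window_base, expected):
        assert iupac_match("D", window_base) is expected

    def test_target_side_ambiguity_never_matches(self):
        # even N-vs-N: ambiguity in the target is unmatchable by convention
        assert not iupac_match("N", "N")
        assert not iupac_match("ACGT", "ACNT")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            iupac_match("ACGT", "ACG")

    @given(
        st.text(alphabet=sorted(iupac.IUPAC_CLASSES), min_size=1, max_size=6),
        st.text(alphabet="ACGTN", min_size=1, max_size=6),
    )
    def test_agrees_with_brute_force_expansion(self, pattern, window):
        if len(pattern) != len(window):
            window = (window * len(pattern))[: len(pattern)]
        expected = window in iupac.expand(pattern)
        assert iupac_match(pattern, window) is expected


class TestEligibility:
    def test_containment_rule(self, assay):
        full = record("A" * 1500, span=(1, 1500))
        partial = record("A" * 1001, seq_id="S2", span=(500, 1500))
        assert filter_eligible([full, partial], assay) == [full]

    def test_partial_overlap_mode(self, assay):
        partial = record("A" * 1001, span=(500, 1500))
        assert filter_eligible([partial], assay, full_containment=False) == [partial]

    def test_missing_span_skipped_and_logged(self, assay):
        no_span = TaxSeqRecord("S3", "P", "G", "s", "ACGT" * 300, None, None)
        skipped = []
        assert filter_eligible([no_span], assay, skipped=skipped) == []
        assert skipped == [no_span]

    def test_planted_eligibility_fraction(self, assay):
        spec = CollectionSpec(
            n_phyla=25,
            genera_per_phylum=1,
            species_per_genus=2,
            seqs_per_species=2,
            span_coverage_fraction=0.8,
            seed=11,
        )
        records, truth = make_collection(spec, assay)
        eligible = filter_eligible(records, assay)
        assert len(records) == 100 and len(eligible) == 80
        assert tuple(r.seq_id for r in eligible) == truth.eligible_ids


class TestComponentHit:
    def test_perfect_target_hits_all_components(self, assay, target_record):
        for criterion in ("stringent", "relaxed"):
            m = assay_match(target_record, assay, criterion)
            assert m.forward_hit and m.reverse_hit and m.probe_hit
            assert m.assay_match

    def test_five_prime_mismatch_distinguishes_criteria(self, assay, target_record):
        # break the forward site far from the 3' end (offset 12 of 16)
        pos = assay.forward.ref_start - 1 + 3
        seq = target_record.sequence
        broken = record(seq[:pos] + "G" + seq[pos + 1 :], span=(1, len(seq)))
        assert not component_hit(broken, assay.forward, "stringent")
        assert component_hit(broken, assay.forward, "relaxed")

    def test_three_prime_mismatch_breaks_both(self, assay, target_record):
        pos = assay.forward.ref_end - 1 - 2  # inside the 3' 8-mer
        seq = target_record.sequence
        base = "T" if seq[pos] != "T" else "A"
        broken = record(seq[:pos] + base + seq[pos + 1 :], span=(1, len(seq)))
        assert not component_hit(broken, assay.forward, "stringent")
        assert not component_hit(broken, assay.forward, "relaxed")

    def test_reverse_primer_matched_as_reverse_complement(self, assay):
        site = iupac.reverse_complement("GGACTACCAGGGTATCTAATC")
        rec = record("T" * 40 + site + "T" * 40)
        assert component_hit(rec, assay.reverse, "stringent")
        # the primer written 5'->3' is NOT present on this strand
        assert "GGACTACCAGGGTATCTAATC" not in rec.sequence

    def test_probe_hit_alone_is_not_an_assay_match(self, assay):
        rec = record("T" * 30 + "CAGCAGCCGCGGTA" + "T" * 30)
        m = assay_match(rec, assay)
        assert m.probe_hit and not m.forward_hit and not m.assay_match

    def test_short_primer_rejected_in_relaxed_mode(self, assay):
        from bactquant import Oligo

        stub = Oligo("f", "ACGTACG" + "T", "forward_primer", 1, 8)
        rec = record("ACGT" * 10)
        component_hit(rec, stub, "relaxed")  # exactly 8 nt is allowed
        with pytest.raises(ValueError, match="relaxed"):
            component_hit(
                rec, Oligo("f", "ACGTACG", "forward_primer", 1, 7), "relaxed"
            )

    def test_agrees_with_brute_force_substring_oracle(self, assay):
        rng = random.Random(42)
        oligo = assay.forward
        expansions = sorted(iupac.expand(oligo.sequence))
        for trial in range(200):
            seq = "".join(rng.choice("ACGT") for _ in range(60))
            if trial % 3 == 0:  # plant a real site sometimes
                site = rng.choice(expansions)
                i = rng.randrange(0, len(seq) - len(site))
                seq = seq[:i] + site + seq[i + len(site) :]
            rec = record(seq)
            expected = any(e in seq for e in expansions)
            assert component_hit(rec, oligo, "stringent") is expected


def toy_records(matched):
    """Three species in two genera of one phylum.

    *matched* maps (genus, species) to the set of within-species sequence
    indices that carry intact assay sites; everything else is unmatchable.
    """
    rows = []
    sid = 0
    for phylum, genus, species, n in [
        ("P1", "G1", "a", 2),
        ("P1", "G1", "b", 1),
        ("P1", "G2", "c", 5),
    ]:
        for k in range(n):
            seq = (
                make_matching_sequence()
                if k in matched.get((genus, species), set())
                else "T" * 900
            )
            rows.append(
                record(
                    seq,
                    seq_id=f"S{sid:03d}",
                    phylum=phylum,
                    genus=genus,
                    species=species,
                    span=(1, 900),
                )
            )
            sid += 1
    return rows


def make_matching_sequence():
    seq = ["T"] * 900
    seq[340:356] = "CCTACGGGAGGCAGCA"
    seq[518:532] = "CAGCAGCCGCGGTA"
    seq[785:806] = iupac.reverse_complement("GGACTACCAGGGTATCTAATC")
    return "".join(seq)


class TestCoverageReports:
    def test_species_level_two_of_three(self):
        records = toy_records({("G1", "a"): {0}, ("G2", "c"): {2}})
        reports = numerical_coverage(records, BACTQUANT, "stringent")
        species = reports["species"]
        assert (species.numerator, species.denominator) == (2, 3)
        assert species.percent == pytest.approx(66.7, abs=0.05)
        assert species.uncovered == ("P1|G1|b",)

    def test_at_least_one_sequence_covers_an_otu(self):
        # only 1 of the 5 G2/c sequences matches: the species is still covered
        records = toy_records({("G2", "c"): {3}})
        reports = numerical_coverage(records, BACTQUANT, "stringent")
        assert "P1|G2|c" in reports["species"].covered
        assert "P1|G2" in reports["genus"].covered
        assert reports["all_sequences"].numerator == 1

    def test_percent_and_partition(self):
        records = toy_records({("G1", "a"): {0}})
        reports = numerical_coverage(records, BACTQUANT, "stringent")
        for rep in reports.values():
            assert rep.numerator <= rep.denominator
            assert 0 <= rep.percent <= 100
            assert sorted(rep.covered + rep.uncovered) == sorted(
                set(rep.covered) | set(rep.uncovered)
            )
            assert len(rep.covered) + len(rep.uncovered) == rep.denominator

    def test_ambiguous_phyla_dropped_at_phylum_level_only(self, target_record):
        good = target_record
        odd1 = record(
            good.sequence, seq_id="X1", phylum="Bacteria Insertia Sedis",
            genus="g1", species="s1", span=(1, 900),
        )
        odd2 = record(
            "T" * 900, seq_id="X2", phylum="Unclassified Bacteria",
            genus="g2", species="s2", span=(1, 900),
        )
        reports = numerical_coverage([good, odd1, odd2], BACTQUANT)
        assert reports["phylum"].denominator == 1
        assert reports["phylum"].covered == ("Proteobacteria",)
        assert reports["genus"].denominator == 3  # retained below phylum level

    def test_unclassified_names_retained_at_lower_levels(self, target_record):
        unc = record(
            "T" * 900, seq_id="U1", phylum="P1",
            genus="unclassified_P1", species="unclassified", span=(1, 900),
        )
        reports = numerical_coverage([target_record, unc], BACTQUANT)
        assert "P1|unclassified_P1" in reports["genus"].uncovered

    def test_taxonomic_coverage_partitions_every_level(self, assay):
        spec = CollectionSpec(
            n_phyla=4, genera_per_phylum=2, species_per_genus=2,
            seqs_per_species=1,
            planted_misses=(PlantedMiss(phylum=2, component="probe"),),
            seed=5,
        )
        records, _ = make_collection(spec, assay)
        listings = taxonomic_coverage(records, assay, "stringent")
        assert "Phylum02" in listings["phylum"][1]
        reports = numerical_coverage(records, assay, "stringent")
        for level, (covered, uncovered) in listings.items():
            assert len(covered) + len(uncovered) == reports[level].denominator
            assert not set(covered) & set(uncovered)

    def test_hierarchy_consistency(self, assay):
        spec = CollectionSpec(
            n_phyla=6, genera_per_phylum=2, species_per_genus=2,
            seqs_per_species=1,
            planted_misses=(
                PlantedMiss(phylum=1, component="probe"),
                PlantedMiss(phylum=3, genus=0, component="reverse"),
            ),
            seed=6,
        )
        records, _ = make_collection(spec, assay)
        reports = numerical_coverage(records, assay, "stringent")
        for sp in reports["species"].covered:
            phylum, genus, _ = sp.split("|")
            assert f"{phylum}|{genus}" in reports["genus"].covered
            assert phylum in reports["phylum"].covered

    def test_reports_invariant_under_input_order(self, assay):
        spec = CollectionSpec(
            n_phyla=5, genera_per_phylum=2, species_per_genus=2,
            seqs_per_species=1,
            planted_misses=(PlantedMiss(phylum=0, component="forward"),),
            seed=7,
        )
        records, _ = make_collection(spec, assay)
        shuffled = list(records)
        random.Random(1).shuffle(shuffled)
        assert numerical_coverage(records, assay) == numerical_coverage(
            shuffled, assay
        )

    def test_empty_eligible_set_rejected(self, assay):
        with pytest.raises(ValueError, match="eligible"):
            numerical_coverage([], assay)


class TestCompareAssays:
    def test_identical_assays_have_zero_improvement(self, assay):
        spec = CollectionSpec(
            n_phyla=4, genera_per_phylum=2, species_per_genus=1,
            seqs_per_species=1, seed=8,
        )
        records, _ = make_collection(spec, assay)
        comp = compare_assays(records, assay, assay)
        assert all(v == 0.0 for v in comp.improvement.values())

    def test_planted_probe_miss_flags_phylum_for_one_assay_only(self, assay):
        # records carry clean BactQuant sites; assay B's probe cannot match
        from bactquant import AssayDefinition, Oligo

        assay_b = AssayDefinition(
            assay_name="B",
            forward=assay.forward,
            reverse=assay.reverse,
            probe=Oligo("pB", "CAGCAGCCGCGGAA", "probe", 519, 532),
        )
        spec = CollectionSpec(
            n_phyla=3, genera_per_phylum=2, species_per_genus=1,
            seqs_per_species=1, seed=9,
        )
        records, _ = make_collection(spec, assay)
        comp = compare_assays(records, assay, assay_b)
        assert all(a.phylum_covered for a in comp.annotations_a)
        assert all(b.not_covered for b in comp.annotations_b)
        assert comp.improvement["phylum"] == pytest.approx(100.0)

    def test_denominators_computed_per_assay(self, assay):
        # a narrower record covers the comparison amplicon but not BactQuant's
        span_b = (PUBLISHED_COMPARISON.forward.ref_start,
                  PUBLISHED_COMPARISON.reverse.ref_end)
        narrow = record(
            "T" * (span_b[1] - span_b[0] + 1), seq_id="N1", span=span_b
        )
        spec = CollectionSpec(
            n_phyla=2, genera_per_phylum=1, species_per_genus=1,
            seqs_per_species=1, seed=10,
        )
        records, _ = make_collection(spec, assay)
        comp = compare_assays(records + [narrow], assay, PUBLISHED_COMPARISON)
        assert comp.reports_a["all_sequences"].denominator == 2
        assert comp.reports_b["all_sequences"].denominator == 3
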