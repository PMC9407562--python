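"""Genotype calling: coverage gates, flags, drop-ins, rDoC, summaries.

The brute-force oracle re-states the locus rules independently with exact
rational arithmetic; the unit-level equivalence scan here covers small
totals, and the full enumeration up to 60 reads lives with the acceptance
checks.
"""

from fractions import Fraction
from itertools import product

import pytest
from hypothesis import given, settings, strategies as st

from mpspheno.calling import (
    HOM_SECOND_ALLELE_ALERT,
    LOW_COVERAGE,
    MAF_IMBALANCE,
    STRAND_FAIL,
    SampleLibrary,
    StrandBaseCounts,
    call_genotype,
    call_library,
    compute_rdoc,
    detect_drop_in,
    flag_summary,
    round_half_away,
)
from mpspheno.panel import Marker, Thresholds

from conftest import balanced_counts


def oracle_call(plus, minus, thr, var_allele, tokens=("A", "C", "G")):
    """Independent restatement of the locus rules with exact rationals.

    Returns (genotype alleles or None, flag set, drop-in list of
    (nucleotide, coverage, pct)).
    """
    total = sum(plus.values()) + sum(minus.values())
    if total < thr.min_total_cov:
        return None, {LOW_COVERAGE}, []
    if sum(plus.values()) <= thr.min_strand_cov or sum(minus.values()) <= thr.min_strand_cov:
        return None, {STRAND_FAIL}, []
    comb = {t: plus.get(t, 0) + minus.get(t, 0) for t in tokens}
    ranked = sorted(comb, key=lambda t: (-comb[t], t))
    top, second = ranked[0], ranked[1]
    flags = set()
    second_frac = Fraction(100 * comb[second], total)
    if second_frac > Fraction(str(thr.het_min_minor_pct)):
        alleles = tuple(sorted((top, second)))
        pair = comb[top] + comb[second]
        designated = var_allele if var_allele in alleles else second
        frac = Fraction(100 * comb[designated], pair)
        (l1, u1), (l2, u2) = [
            tuple(Fraction(str(b)) for b in rng) for rng in thr.imbalance_ranges
        ]
        if l1 <= frac <= u1 or l2 <= frac <= u2:
            flags.add(MAF_IMBALANCE)
    else:
        alleles = (top, top)
        lo, hi = (Fraction(str(b)) for b in thr.hom_alert_range)
        if comb[second] > 0 and lo <= second_frac <= hi:
            flags.add(HOM_SECOND_ALLELE_ALERT)
    dropins = []
    for t in tokens:
        if t in alleles or comb[t] == 0:
            continue
        frac = Fraction(100 * comb[t], total)
        if comb[t] >= thr.dropin_min_reads and frac >= Fraction(str(thr.dropin_min_pct)):
            # round half away from zero to one decimal, exactly
            tenths, rem = divmod(10 * frac, 1)
            pct = float((tenths + (1 if rem >= Fraction(1, 2) else 0)) / Fraction(10))
            dropins.append((t, comb[t], pct))
    dropins.sort(key=lambda d: (-d[1], d[0]))
    return alleles, flags, dropins


def assert_matches_oracle(plus, minus, thr, marker):
    counts = StrandBaseCounts(marker.rsid, plus, minus)
    call = call_genotype(counts, thr, marker)
    alleles, flags, dropins = oracle_call(plus, minus, thr, marker.var_allele)
    assert call.alleles == alleles, (plus, minus)
    assert set(call.flags) == flags, (plus, minus)
    assert [(d.nucleotide, d.coverage, d.pct) for d in call.dropins] == dropins, (
        plus,
        minus,
    )


class TestCoverageGates:
    def test_below_total_coverage_is_nn(self, thresholds, panel):
        counts = balanced_counts("rs683", {"A": 10, "C": 9})
        call = call_genotype(counts, thresholds, panel["rs683"])
        assert call.is_nn and call.flags == {LOW_COVERAGE}
        assert call.dropins == ()

    def test_twenty_reads_is_callable(self, thresholds, panel):
        counts = StrandBaseCounts("rs683", {"A": 11}, {"A": 11})
        call = call_genotype(counts, thresholds, panel["rs683"])
        assert call.genotype_str == "A/A"

    def test_strand_at_ten_fails(self, thresholds, panel):
        # "more than 10x" per strand is strict: 10 reads on a strand fail
        counts = StrandBaseCounts("rs683", {"A": 10}, {"A": 30})
        call = call_genotype(counts, thresholds, panel["rs683"])
        assert call.is_nn and call.flags == {STRAND_FAIL}
        counts = StrandBaseCounts("rs683", {"A": 11}, {"A": 30})
        assert not call_genotype(counts, thresholds, panel["rs683"]).is_nn

    def test_nn_iff_gate_flag(self, thresholds, panel):
        for combined in ({"A": 50}, {"A": 5}, {"A": 300, "C": 100}):
            call = call_genotype(
                balanced_counts("rs683", combined), thresholds, panel["rs683"]
            )
            assert call.is_nn == bool(call.flags & {LOW_COVERAGE, STRAND_FAIL})


class TestGenotypeRules:
    def test_reference_triallelic_het(self, thresholds, panel):
        counts = balanced_counts("rs1042602", {"A": 16538, "C": 23040, "T": 1079})
        call = call_genotype(counts, thresholds, panel["rs1042602"])
        assert call.genotype_str == "A/C"
        assert [(d.nucleotide, d.coverage, d.pct) for d in call.dropins] == [
            ("T", 1079, 2.7)
        ]

    def test_hom_second_allele_alert(self, thresholds, panel):
        counts = balanced_counts("rs12913832", {"A": 5000, "G": 200})
        call = call_genotype(counts, thresholds, panel["rs12913832"])
        assert call.genotype_str == "A/A"
        assert HOM_SECOND_ALLELE_ALERT in call.flags

    def test_het_with_imbalance_flag(self, thresholds, panel):
        # minor 620/5620 = 11.0% of total -> het; variant fraction 11.0 in [10.1, 35]
        counts = balanced_counts("rs12913832", {"A": 5000, "G": 620})
        call = call_genotype(counts, thresholds, panel["rs12913832"])
        assert call.genotype_str == "A/G"
        assert MAF_IMBALANCE in call.flags

    def test_balanced_het_unflagged(self, thresholds, panel):
        counts = balanced_counts("rs12913832", {"A": 5000, "G": 4500})
        call = call_genotype(counts, thresholds, panel["rs12913832"])
        assert call.genotype_str == "A/G"
        assert not call.flags

    def test_indel_marker_callable(self, thresholds, panel):
        counts = balanced_counts("rs796296176", {"INS": 900, "DEL": 1100})
        call = call_genotype(counts, thresholds, panel["rs796296176"])
        assert call.genotype_str == "DEL/INS"


class TestDropIn:
    def test_no_third_allele(self, thresholds):
        counts = balanced_counts("rs1", {"A": 1000, "G": 980})
        assert detect_drop_in(counts, ("A", "G"), thresholds) == ()

    def test_floor_on_reads_and_pct(self, thresholds):
        # 9 reads stays below the read floor even above 1% of coverage
        counts = balanced_counts("rs1", {"A": 500, "C": 300, "T": 9})
        assert detect_drop_in(counts, ("A", "C"), thresholds) == ()
        # 0.5% of coverage stays below the percent floor
        counts = balanced_counts("rs1", {"A": 2000, "C": 2000, "T": 20})
        assert detect_drop_in(counts, ("A", "C"), thresholds) == ()

    def test_pct_against_total_coverage(self, thresholds):
        counts = balanced_counts("rs1", {"A": 2576, "C": 3930, "T": 707})
        (rec,) = detect_drop_in(counts, ("A", "C"), thresholds)
        assert (rec.nucleotide, rec.coverage, rec.pct) == ("T", 707, 9.8)


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(3.2507, 3.3), (2.6539, 2.7), (6.25, 6.3), (6.3585, 6.4), (-6.25, -6.3), (0.05, 0.1)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x, 1) == expected


class TestRdoc:
    def test_uniform_library(self, panel):
        lib = SampleLibrary(
            "s1", "sk1", {m.rsid: balanced_counts(m.rsid, {"A": 100}) for m in panel}
        )
        rdoc = compute_rdoc(lib)
        assert all(abs(v - 1 / 24) < 1e-12 for v in rdoc.values())

    def test_share_and_normalisation(self):
        lib = SampleLibrary(
            "s1",
            "sk1",
            {
                "rs1": balanced_counts("rs1", {"A": 300}),
                "rs2": balanced_counts("rs2", {"C": 400}),
                "rs3": balanced_counts("rs3", {"G": 300}),
            },
        )
        rdoc = compute_rdoc(lib)
        assert rdoc["rs1"] == pytest.approx(0.30, abs=1e-12)
        assert abs(sum(rdoc.values()) - 1.0) < 1e-12

    def test_zero_library_is_an_error(self):
        lib = SampleLibrary("s1", "sk1", {"rs1": StrandBaseCounts("rs1", {}, {})})
        with pytest.raises(ValueError, match="rDoC"):
            compute_rdoc(lib)


class TestFlagSummary:
    def test_nn_percentage(self, thresholds, panel):
        marker = panel["rs683"]
        nn = call_genotype(balanced_counts("rs683", {"A": 5}), thresholds, marker)
        ok = call_genotype(balanced_counts("rs683", {"A": 600}), thresholds, marker)
        calls = [nn] * 51 + [ok] * 909
        summary = flag_summary(calls)
        assert summary["n_markers"] == 960
        assert summary["pct_nn"] == 5.3

    def test_clean_calls_have_zero_flag_rates(self, thresholds, panel):
        marker = panel["rs683"]
        ok = call_genotype(balanced_counts("rs683", {"A": 600}), thresholds, marker)
        summary = flag_summary([ok] * 10)
        assert summary["pct_nn"] == 0.0
        assert summary["pct_het_imbalanced"] == 0.0
        assert summary["pct_hom_alerted"] == 0.0
        assert summary["n_dropins"] == 0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            flag_summary([])


class TestNegativeControlContract:
    def test_all_zero_library_yields_all_nn(self, thresholds, panel):
        lib = SampleLibrary(
            "NTC", "NTC", {m.rsid: StrandBaseCounts(m.rsid, {}, {}) for m in panel},
            is_negative_control=True,
        )
        calls = call_library(lib, panel, thresholds)
        assert all(c.is_nn for c in calls.values())
        assert all(c.dropins == () for c in calls.values())


MARKER_AC = Marker("rsX", "A", "C", 100)


class TestOracleEquivalence:
    def test_exhaustive_small_totals(self, thresholds):
        # all vectors over 3 alleles with total <= 25, balanced strand split
        for a, c, g in product(range(26), repeat=3):
            if a + c + g > 25:
                continue
            comb = {"A": a, "C": c, "G": g}
            plus = {t: n // 2 for t, n in comb.items()}
            minus = {t: n - n // 2 for t, n in comb.items()}
            assert_matches_oracle(plus, minus, thresholds, MARKER_AC)

    @settings(max_examples=300, deadline=None)
    @given(
        st.tuples(*[st.integers(0, 40_000)] * 3),
        st.tuples(*[st.integers(0, 40_000)] * 3),
    )
    def test_random_large_vectors(self, plus_v, minus_v):
        thr = Thresholds()
        plus = dict(zip(("A", "C", "G"), plus_v))
        minus = dict(zip(("A", "C", "G"), minus_v))
        assert_matches_oracle(plus, minus, thr, MARKER_AC)


class TestProperties:
    @settings(max_examples=200, deadline=None)
    @given(
        st.tuples(*[st.integers(0, 2000)] * 3),
        st.integers(1, 5000),
    )
    def test_adding_called_allele_reads_never_makes_nn(self, comb_v, extra):
        thr = Thresholds()
        comb = dict(zip(("A", "C", "G"), comb_v))
        counts = balanced_counts("rsX", comb)
        call = call_genotype(counts, thr, MARKER_AC)
        if call.is_nn:
            return
        boosted = dict(comb)
        boosted[call.alleles[0]] += extra
        call2 = call_genotype(balanced_counts("rsX", boosted), thr, MARKER_AC)
        assert not call2.is_nn

    def test_determinism(self, thresholds):
        counts = balanced_counts("rsX", {"A": 123, "C": 456, "G": 78})
        c1 = call_genotype(counts, thresholds, MARKER_AC)
        c2 = call_genotype(counts, thresholds, MARKER_AC)
        assert (c1.alleles, c1.flags, c1.dropins) == (c2.alleles, c2.flags, c2.dropins)
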