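"""Grading, selection, the length correction and the abundance estimator.

The estimator is checked against an independent arbitrary-precision oracle
(fractions.Fraction evaluation of the three formulas).
"""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magprofile import (
    MagRecord,
    QualityGrade,
    abundance_table,
    count_filtered_reads,
    grade,
    select_mags,
    true_genome_length,
)
from magprofile.errors import (
    DegenerateInputError,
    ReconciliationError,
    ValidationError,
)
from magprofile.io_formats import CountRow, QualityRow, TaxonomyRow, parse_lineage
from magprofile.mag_model import aggregate_idxstats, build_mag_records


def oracle_percentages(mags):
    """Arbitrary-precision re-computation of the three estimator formulas."""
    true_lengths = [
        Fraction(m.size) * 100 / ((1 + Fraction(m.contamination) / 100) * Fraction(m.completeness))
        for m in mags
    ]
    normalized = [Fraction(m.mapped) / tl for m, tl in zip(mags, true_lengths)]
    total = sum(normalized)
    return [100 * n / total for n in normalized]


def make_mag(i, size, comp, cont, mapped):
    return MagRecord(f"M{i}", size, comp, cont, mapped=mapped)


mag_lists = st.lists(
    st.tuples(
        st.floats(1e5, 1e8),  # size
        st.floats(1.0, 100.0),  # completeness
        st.floats(0.0, 150.0),  # contamination
        st.integers(0, 10**9),  # mapped
    ),
    min_size=1,
    max_size=10,
).filter(lambda rows: any(r[3] > 0 for r in rows))


class TestGrade:
    @pytest.mark.parametrize(
        "comp, cont, expected",
        [
            (97.13, 0.62, QualityGrade.HIGH),
            (97.17, 7.9, QualityGrade.MEDIUM),
            (95.91, 7.9, QualityGrade.MEDIUM),
            (49.9, 1.0, QualityGrade.LOW),
            (90.0, 1.0, QualityGrade.MEDIUM),  # high needs strictly > 90
            (95.0, 5.0, QualityGrade.MEDIUM),  # high needs strictly < 5
            (50.0, 9.99, QualityGrade.MEDIUM),
            (95.0, 10.0, QualityGrade.LOW),  # medium needs strictly < 10
        ],
    )
    def test_mimag_boundaries(self, comp, cont, expected):
        assert grade(comp, cont) is expected


class TestSelection:
    def test_fixture_fully_retained(self, fixture_mags):
        assert len(select_mags(fixture_mags)) == 19

    def test_boundary_completeness_excluded(self):
        mags = [make_mag(1, 1e6, 89.99, 0.0, 10), make_mag(2, 1e6, 90.0, 0.0, 10)]
        assert [m.mag_id for m in select_mags(mags)] == ["M2"]

    def test_low_grade_excluded_despite_completeness(self):
        (kept,) = select_mags([make_mag(1, 1e6, 95.0, 12.0, 1), make_mag(2, 1e6, 95.0, 1.0, 1)])
        assert kept.mag_id == "M2"

    @given(mag_lists, st.floats(50, 95), st.floats(0, 45))
    def test_selection_monotone_in_threshold(self, rows, thresh, delta):
        mags = [make_mag(i, *r) for i, r in enumerate(rows)]
        stricter = {m.mag_id for m in select_mags(mags, thresh + delta)}
        looser = {m.mag_id for m in select_mags(mags, thresh)}
        assert stricter <= looser


class TestTrueLength:
    def test_fixture_mag1_value(self):
        # independent arbitrary-precision evaluation of the formula
        expected = Fraction(2_960_000) * 100 / ((1 + Fraction(62, 10_000)) * Fraction(9713, 100))
        assert true_genome_length(2_960_000, 97.13, 0.62) == pytest.approx(
            float(expected), rel=1e-12
        )

    def test_identity_when_perfect(self):
        assert true_genome_length(4.2e6, 100.0, 0.0) == pytest.approx(4.2e6)

    def test_half_complete_doubles(self):
        assert true_genome_length(4_000_000, 50.0, 0.0) == pytest.approx(8_000_000)

    def test_nonpositive_completeness_rejected(self):
        with pytest.raises(DegenerateInputError):
            true_genome_length(1e6, 0.0, 0.0)

    @given(st.floats(1e5, 1e8), st.floats(1, 100), st.floats(0, 150))
    def test_correction_direction(self, size, comp, cont):
        tl = true_genome_length(size, comp, cont)
        factor = (1 + cont / 100) * comp
        if factor < 100:
            assert tl > size
        elif factor > 100:
            assert tl < size

    def test_high_contamination_deflates(self):
        # a heavily contaminated near-complete bin: corrected length < size
        assert true_genome_length(7_850_000, 97.17, 7.9) < 7_850_000


class TestAbundanceTable:
    def test_equal_lengths_counts_dominate(self):
        mags = [make_mag(1, 1e6, 100, 0, 100), make_mag(2, 1e6, 100, 0, 300)]
        assert abundance_table(mags).percentages.tolist() == pytest.approx([25.0, 75.0])

    def test_single_mag_is_100(self):
        assert abundance_table([make_mag(1, 2e6, 95, 3, 7)]).percentages.tolist() == [100.0]

    def test_all_zero_counts_degenerate(self):
        with pytest.raises(DegenerateInputError):
            abundance_table([make_mag(1, 1e6, 95, 0, 0)])

    def test_zero_mapped_mag_retained_at_zero(self):
        table = abundance_table([make_mag(1, 1e6, 95, 0, 10), make_mag(2, 1e6, 95, 0, 0)])
        assert table.n == 2
        assert table.percentages["M2"] == 0.0

    def test_whole_metagenome_denominator_mode(self):
        mags = [make_mag(1, 1e6, 100, 0, 100), make_mag(2, 1e6, 100, 0, 300)]
        selected_total = abundance_table(mags).data["normalized"].sum()
        table = abundance_table(mags, total_normalized=2 * selected_total)
        assert table.percentages.sum() == pytest.approx(50.0)

    @settings(max_examples=200)
    @given(mag_lists)
    def test_matches_arbitrary_precision_oracle(self, rows):
        mags = [make_mag(i, *r) for i, r in enumerate(rows)]
        expected = [float(p) for p in oracle_percentages(mags)]
        got = abundance_table(mags).percentages.tolist()
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)
        assert sum(got) == pytest.approx(100.0, rel=1e-9)

    @given(mag_lists, st.integers(2, 1000))
    def test_scale_invariance(self, rows, factor):
        mags = [make_mag(i, *r) for i, r in enumerate(rows)]
        scaled = [
            MagRecord(m.mag_id, m.size, m.completeness, m.contamination, mapped=m.mapped * factor)
            for m in mags
        ]
        assert abundance_table(scaled).percentages.tolist() == pytest.approx(
            abundance_table(mags).percentages.tolist(), rel=1e-12
        )

    @given(mag_lists, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, rows, rnd):
        mags = [make_mag(i, *r) for i, r in enumerate(rows)]
        shuffled = list(mags)
        rnd.shuffle(shuffled)
        a = abundance_table(mags).percentages
        b = abundance_table(shuffled).percentages
        assert dict(b) == pytest.approx(dict(a), rel=1e-12)


class TestReadFilter:
    def test_threshold_inclusive(self):
        records = [("r1", "A", 60), ("r2", "A", 30), ("r3", "B", 60)]
        assert dict(count_filtered_reads(records, 60)) == {"A": 1, "B": 1}

    def test_empty_stream(self):
        assert dict(count_filtered_reads([], 60)) == {}

    def test_zero_threshold_counts_everything(self):
        records = [("r1", "A", 0), ("r2", "A", 59), ("r3", "B", 60)]
        assert dict(count_filtered_reads(records, 0)) == {"A": 2, "B": 1}

    def test_negative_mapq_rejected(self):
        with pytest.raises(ValidationError):
            count_filtered_reads([("r1", "A", -1)], 60)
        with pytest.raises(ValidationError):
            count_filtered_reads([], -1)


class TestJoins:
    LIN = "d__Bacteria;p__X;c__;o__;f__;g__;s__"

    def test_idxstats_aggregation_ignores_unbinned(self):
        rows = [CountRow("c1", 100, 5), CountRow("c2", 100, 7), CountRow("c3", 100, 99)]
        totals = aggregate_idxstats(rows, {"c1": "m1", "c2": "m1"})
        assert totals == {"m1": 12}

    def test_build_records_joins_tables(self):
        mags = build_mag_records(
            [QualityRow("m1", 95.0, 1.0)],
            [TaxonomyRow("m1", parse_lineage(self.LIN))],
            {"m1": 42},
            {"m1": 3e6},
        )
        assert mags[0].mapped == 42 and mags[0].lineage.phylum == "X"

    def test_orphan_ids_reported(self):
        with pytest.raises(ReconciliationError, match="m1"):
            build_mag_records([QualityRow("m1", 95.0, 1.0)], [], {}, {"m1": 3e6})
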