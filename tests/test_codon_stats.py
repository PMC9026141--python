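import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonusage.codon_stats import (
    CLASS_NO_BIAS,
    CLASS_ORDER,
    CLASS_PREFERRED,
    CLASS_SIG_PREFERRED,
    CLASS_SIG_UNPREFERRED,
    CLASS_UNPREFERRED,
    CodonCountTable,
    classify,
    classify_value,
    count_codons,
    mean_rscu,
    rscu,
    rscu_from_values,
    rscu_range,
)
from codonusage.data import CPMMV_RSCU
from codonusage.errors import (
    CdsValidationError,
    InsufficientGroupsError,
    UndefinedStatisticError,
)
from codonusage.genetic_code import standard_code
from codonusage.sequence_io import SequenceRecord


class TestCountCodons:
    def test_small_cds_counts_and_total(self):
        table = count_codons([SequenceRecord(id="x", seq="AUGAAAUAA")])
        assert table.counts["AUG"] == 1
        assert table.counts["AAA"] == 1
        assert table.counts["UAA"] == 1
        assert table.n_codons == 2  # stop excluded

    def test_additivity_under_duplication(self):
        rec = SequenceRecord(id="x", seq="AUGAAACCCUAA")
        single = count_codons([rec])
        double = count_codons([rec, rec])
        assert all(double.counts[c] == 2 * single.counts[c] for c in single.counts)

    def test_invalid_record_raises_without_force(self):
        bad = SequenceRecord(id="bad", seq="AUGAAAA")
        with pytest.raises(CdsValidationError, match="bad"):
            count_codons([bad])
        table = count_codons([bad], force=True)
        assert table.counts["AUG"] == 1

    def test_ambiguous_codons_skipped_and_tallied(self):
        rec = SequenceRecord(id="x", seq="AUGANAUAA")
        table = count_codons([rec], force=True)
        assert table.ambiguous_skipped == 1
        assert table.n_codons == 1


class TestRscu:
    def test_two_fold_family_formula(self):
        table = CodonCountTable(counts={"AAA": 3, "AAG": 1})
        t = rscu(table)
        assert t.values["AAA"] == pytest.approx(1.5)
        assert t.values["AAG"] == pytest.approx(0.5)

    def test_equal_usage_is_unbiased(self):
        code = standard_code()
        counts = {c: 7 for c in code.sense_codons}
        t = rscu(CodonCountTable(counts=counts))
        assert all(v == pytest.approx(1.0) for v in t.values.values())

    def test_engineered_arginine_family(self):
        counts = {"AGA": 36, "AGG": 38, "CGU": 9, "CGC": 5, "CGA": 11, "CGG": 3}
        t = rscu(CodonCountTable(counts=counts))
        assert t.values["AGG"] == pytest.approx(6 * 38 / 102)
        assert t.classes["AGG"] == CLASS_SIG_PREFERRED

    def test_missing_family_is_missing_not_zero(self):
        t = rscu(CodonCountTable(counts={"AAA": 2, "AAG": 2}))
        assert "GGG" in t.missing
        assert "GGG" not in t.values
        assert t.classes["GGG"] == "missing"

    def test_empty_table_raises(self):
        with pytest.raises(UndefinedStatisticError):
            rscu(CodonCountTable(counts={}))

    @settings(max_examples=50, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(standard_code().sense_codons),
            st.integers(min_value=0, max_value=50),
            min_size=3,
        ),
        st.integers(min_value=1, max_value=9),
    )
    def test_normalization_and_scaling_invariance(self, counts, factor):
        code = standard_code()
        if all(v == 0 for v in counts.values()):
            counts[code.sense_codons[0]] = 1
        t = rscu(CodonCountTable(counts=counts))
        # family sums equal family size; family means equal 1
        for aa, family in code.families.items():
            vals = [t.values[c] for c in family if c in t.values]
            if vals:
                assert math.isclose(sum(vals), len(family), abs_tol=1e-9)
                assert math.isclose(
                    sum(vals) / len(family), 1.0, abs_tol=1e-9
                )
        scaled = rscu(
            CodonCountTable(counts={c: v * factor for c, v in counts.items()})
        )
        assert scaled.values.keys() == t.values.keys()
        for c in t.values:
            assert math.isclose(scaled.values[c], t.values[c], abs_tol=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (2.0, CLASS_SIG_PREFERRED),
            (1.5 + 1e-9, CLASS_SIG_PREFERRED),
            (1.5, CLASS_PREFERRED),  # boundary is exclusive
            (1.2, CLASS_PREFERRED),
            (1.0, CLASS_NO_BIAS),
            (0.8, CLASS_UNPREFERRED),
            (0.6, CLASS_UNPREFERRED),  # boundary is exclusive
            (0.6 - 1e-9, CLASS_SIG_UNPREFERRED),
            (0.1, CLASS_SIG_UNPREFERRED),
        ],
    )
    def test_boundaries(self, value, expected):
        assert classify_value(value) == expected

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=10.0))
    def test_classes_are_exhaustive_and_exclusive(self, value):
        assert classify_value(value) in CLASS_ORDER

    def test_all_equal_usage_classifies_as_no_bias(self):
        code = standard_code()
        t = rscu(CodonCountTable(counts={c: 5 for c in code.sense_codons}))
        cls = classify(t)
        assert len(cls[CLASS_NO_BIAS]) == 59

    def test_published_table_counts(self):
        cls = classify(rscu_from_values(CPMMV_RSCU))
        assert len(cls[CLASS_SIG_PREFERRED]) == 9
        assert len(cls[CLASS_SIG_UNPREFERRED]) == 12


class TestRscuRange:
    def _table(self, overrides):
        values = dict(CPMMV_RSCU)
        values.update(overrides)
        # keep family sums valid by scaling the Pro family explicitly
        return rscu_from_values(values)

    def test_identical_groups_have_zero_range(self):
        t = rscu_from_values(CPMMV_RSCU)
        ranges = rscu_range({"a": t, "b": t})
        assert all(r.range == 0 for r in ranges)

    def test_two_group_range_and_argminmax(self):
        hi = rscu_from_values(
            {**CPMMV_RSCU, "CCA": 1.8, "CCU": 1.68, "CCC": 0.4, "CCG": 0.12}
        )
        lo = rscu_from_values(
            {**CPMMV_RSCU, "CCA": 1.0, "CCU": 1.68, "CCC": 1.2, "CCG": 0.12}
        )
        ranges = {r.codon: r for r in rscu_range({"hi": hi, "lo": lo})}
        assert ranges["CCA"].range == pytest.approx(0.8)
        assert ranges["CCA"].argmax == "hi"
        assert ranges["CCA"].argmin == "lo"
        # output sorted by descending range
        out = rscu_range({"hi": hi, "lo": lo})
        assert out[0].range == max(r.range for r in out)

    def test_single_group_raises(self):
        with pytest.raises(InsufficientGroupsError):
            rscu_range({"only": rscu_from_values(CPMMV_RSCU)})


class TestMeanRscu:
    def test_mean_of_two_tables(self):
        a = rscu(CodonCountTable(counts={"AAA": 3, "AAG": 1}))
        b = rscu(CodonCountTable(counts={"AAA": 1, "AAG": 3}))
        m = mean_rscu([a, b])
        assert m.values["AAA"] == pytest.approx(1.0)

    def test_family_missing_everywhere_stays_missing(self):
        a = rscu(CodonCountTable(counts={"AAA": 2, "AAG": 2}))
        m = mean_rscu([a, a])
        assert "GGG" in m.missing
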