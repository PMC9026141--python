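import math

import numpy as np
import pytest

from codonusage.codon_stats import CodonCountTable, count_codons
from codonusage.composition import positional_gc
from codonusage.enc import (
    ENC_MAX,
    ENC_MIN,
    enc_expected,
    enc_plot_points,
    enc_value,
    family_homozygosity,
)
from codonusage.errors import UndefinedStatisticError
from codonusage.genetic_code import standard_code
from codonusage.sequence_io import extract_orfs
from codonusage.synthetic import GeneratorSpec, generate_cds


def wright_enc_oracle(counts: dict[str, int]) -> float:
    """From-scratch ENC: per-family homozygosity, class means, combine.

    Deliberately written as plain loops over the family structure, with
    the same conventions (skip n<2 and F=0 families, impute the
    three-fold class from the two- and four-fold means, clamp).
    """
    code = standard_code()
    class_fs = {2: [], 3: [], 4: [], 6: []}
    for aa, family in code.families.items():
        if len(family) == 1:
            continue
        xs = [counts.get(c, 0) for c in family]
        n = sum(xs)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in xs) - 1) / (n - 1)
        if f > 0:
            class_fs[len(family)].append(f)
    fbar = {k: sum(v) / len(v) for k, v in class_fs.items() if v}
    if len(fbar) < 2:
        raise ValueError("undefined")
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    mean_avail = sum(fbar.values()) / len(fbar)
    for k in (2, 3, 4, 6):
        fbar.setdefault(k, mean_avail)
    enc = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(max(enc, 20.0), 61.0)


class TestFamilyHomozygosity:
    def test_single_codon_used(self):
        assert family_homozygosity({"AAA": 10, "AAG": 0}) == pytest.approx(1.0)

    def test_even_two_codon_split(self):
        assert family_homozygosity({"AAA": 5, "AAG": 5}) == pytest.approx(4 / 9)

    def test_minimal_even_split_is_zero(self):
        assert family_homozygosity({"AAA": 1, "AAG": 1}) == pytest.approx(0.0)

    def test_family_below_two_is_skipped(self):
        assert family_homozygosity({"AAA": 1, "AAG": 0}) is None

    def test_f_decreases_towards_even_usage(self):
        # two-codon family, n fixed: F is minimal at the even split
        n = 10
        fs = [family_homozygosity([k, n - k]) for k in range(n + 1)]
        assert fs[5] == min(fs)
        assert fs[0] == fs[n] == 1.0


class TestEncValue:
    def test_one_codon_per_family_gives_20(self):
        code = standard_code()
        counts = {family[0]: 50 for family in code.families.values()}
        assert enc_value(CodonCountTable(counts=counts)).enc == pytest.approx(20.0)

    def test_uniform_59_codon_usage_approaches_61(self):
        code = standard_code()
        counts = {c: 10_000 for c in code.sense_codons}
        assert enc_value(CodonCountTable(counts=counts)).enc == pytest.approx(
            61.0, abs=1e-6
        )

    def test_enc_asymptotically_invariant_to_count_scaling(self):
        # F carries a finite-sample correction, so exact invariance
        # holds only in the large-count limit
        counts = {"AAA": 6000, "AAG": 2000, "GGU": 3000, "GGC": 1000,
                  "AUU": 4000, "AUA": 1000}
        e1 = enc_value(CodonCountTable(counts=counts)).enc
        e2 = enc_value(
            CodonCountTable(counts={c: 10 * v for c, v in counts.items()})
        ).enc
        assert e1 == pytest.approx(e2, abs=0.01)

    def test_missing_isoleucine_class_is_imputed(self):
        counts = {"AAA": 6, "AAG": 2, "GGU": 3, "GGC": 1}
        res = enc_value(CodonCountTable(counts=counts))
        assert 3 in res.imputed_classes
        assert res.f_bar[3] == pytest.approx((res.f_bar[2] + res.f_bar[4]) / 2)

    def test_fewer_than_two_classes_raises(self):
        with pytest.raises(UndefinedStatisticError):
            enc_value(CodonCountTable(counts={"AAA": 5, "AAG": 3}))

    def test_matches_oracle_on_random_tables(self, rng):
        code = standard_code()
        for _ in range(100):
            k = rng.integers(5, 30)
            codons = rng.choice(code.sense_codons, size=k, replace=False)
            counts = {c: int(rng.integers(1, 40)) for c in codons}
            try:
                expected = wright_enc_oracle(counts)
            except ValueError:
                continue
            got = enc_value(CodonCountTable(counts=counts)).enc
            assert got == pytest.approx(expected, abs=1e-9)


class TestExpectedCurve:
    def test_closed_form_at_half(self):
        assert enc_expected(0.5) == pytest.approx(60.5)

    def test_maximum_is_at_half(self):
        grid = np.linspace(0.01, 0.99, 197)
        values = [enc_expected(s) for s in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(0.5, abs=0.01)

    def test_low_gc_limit(self):
        # 29/(s^2+(1-s)^2) -> 29(1+2s), so the curve approaches 31 + 59s
        s = 1e-6
        assert enc_expected(s) == pytest.approx(31 + s, abs=1e-4)

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.2, 1.5])
    def test_domain_error(self, s):
        with pytest.raises(ValueError):
            enc_expected(s)


class TestEncPlot:
    def test_flag_is_strict_inequality(self):
        s = 0.4
        on_curve = enc_expected(s)
        pts = enc_plot_points(
            [("on", s, on_curve), ("below", s, on_curve - 0.1)]
        )
        assert [p.below_curve for p in pts] == [False, True]

    def test_maximally_biased_isolates_fall_below(self):
        code = standard_code()
        counts = {family[0]: 100 for family in code.families.values()}
        table = CodonCountTable(counts=counts)
        enc = enc_value(table).enc
        gc3 = positional_gc(table).gc3
        (pt,) = enc_plot_points([("x", gc3, enc)])
        assert pt.below_curve

    def test_null_model_sequences_land_on_curve(self):
        # within-family codon choice driven purely by third-position
        # base composition: ENC must match the expected curve closely
        code = standard_code()
        base_p = {"A": 0.30, "U": 0.30, "C": 0.20, "G": 0.20}
        codon_probs = {}
        for aa, family in code.families.items():
            w = {c: base_p[c[2]] for c in family}
            z = sum(w.values())
            codon_probs[aa] = {c: v / z for c, v in w.items()}
        spec = GeneratorSpec(codon_probs=codon_probs, seed=21)
        cds = generate_cds(spec, n_codons=200_000)
        table = count_codons(extract_orfs(cds, min_length=1))
        gc3s = positional_gc(table, synonymous_only_gc3=True).gc3
        enc = enc_value(table).enc
        assert enc == pytest.approx(enc_expected(gc3s), abs=1.0)
        assert ENC_MIN <= enc <= ENC_MAX
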