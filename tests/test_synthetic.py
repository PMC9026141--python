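import math

import numpy as np
import pytest

from codonusage.codon_stats import count_codons, rscu
from codonusage.composition import positional_gc
from codonusage.enc import enc_value
from codonusage.errors import FeasibilityError, GeneratorSpecError
from codonusage.genetic_code import standard_code, translate
from codonusage.neutrality import neutrality_regression
from codonusage.sequence_io import extract_orfs, validate_cds
from codonusage.synthetic import (
    GeneratorSpec,
    cpmmv_like_spec,
    generate_cds,
    generate_isolate_set,
    suppress_dinucleotides,
)


def one_codon_per_family_probs():
    code = standard_code()
    return {
        aa: {c: (1.0 if i == 0 else 0.0) for i, c in enumerate(family)}
        for aa, family in code.families.items()
    }


class TestSpecValidation:
    def test_bad_aa_profile_rejected(self):
        profile = dict.fromkeys("ACDEFGHIKLMNPQRSTVWY", 0.05)
        profile["A"] = 0.5
        with pytest.raises(GeneratorSpecError):
            GeneratorSpec(aa_profile=profile)

    def test_bad_suppression_factor_rejected(self):
        with pytest.raises(GeneratorSpecError):
            GeneratorSpec(cpg_suppression=0.0)
        with pytest.raises(GeneratorSpecError):
            GeneratorSpec(upa_suppression=1.5)


class TestGenerateCds:
    def test_structure_start_body_stop(self):
        cds = generate_cds(GeneratorSpec(seed=1), n_codons=50)
        assert cds.seq.startswith("AUG")
        assert cds.seq[-3:] in ("UAA", "UAG", "UGA")
        assert len(cds.seq) == 3 * 52
        assert validate_cds(cds, min_length=1).passed

    def test_determinism_under_fixed_seed(self):
        a = generate_cds(GeneratorSpec(seed=99), n_codons=300)
        b = generate_cds(GeneratorSpec(seed=99), n_codons=300)
        assert a.seq == b.seq

    def test_one_codon_per_family_forces_enc_20(self):
        spec = GeneratorSpec(codon_probs=one_codon_per_family_probs(), seed=2)
        cds = generate_cds(spec, n_codons=3000)
        table = count_codons(extract_orfs(cds, min_length=1))
        assert enc_value(table).enc == pytest.approx(20.0, abs=1e-9)

    def test_uniform_codon_probs_give_unbiased_rscu(self):
        code = standard_code()
        uniform = {
            aa: {c: 1 / len(family) for c in family}
            for aa, family in code.families.items()
        }
        spec = GeneratorSpec(codon_probs=uniform, seed=3)
        cds = generate_cds(spec, n_codons=100_000)
        table = count_codons(extract_orfs(cds, min_length=1))
        t = rscu(table)
        for codon in code.classifiable_codons:
            fam = code.family_of(codon)
            k = len(fam)
            n_fam = sum(table.counts[c] for c in fam)
            se = k * math.sqrt((1 / k) * (1 - 1 / k) / n_fam)
            assert abs(t.values[codon] - 1.0) < 3 * se


class TestIsolateSet:
    def test_determinism_identical_records(self):
        spec_kwargs = dict(n_isolates=4, n_codons=300, n_orfs=2, utr_length=40)
        a = generate_isolate_set(cpmmv_like_spec(seed=5, **spec_kwargs))
        b = generate_isolate_set(cpmmv_like_spec(seed=5, **spec_kwargs))
        assert [(r.id, r.seq, r.regions) for r in a] == [
            (r.id, r.seq, r.regions) for r in b
        ]

    def test_orfs_annotated_and_valid(self, small_isolate_set):
        for rec in small_isolate_set:
            orfs = extract_orfs(rec, strategy="annotated-spans")
            assert len(orfs) == 3
            assert all(validate_cds(o, min_length=1).passed for o in orfs)
            assert rec.meta["host"] in ("soybean", "cowpea", "papaya")

    def test_zero_noise_recovers_slope_to_grid_precision(self):
        spec = GeneratorSpec(
            seed=17, slope=0.4, intercept=0.25, noise_sd=0.0,
            n_isolates=15, n_codons=20_000, n_orfs=1, utr_length=0,
        )
        recs = generate_isolate_set(spec)
        pts = []
        for rec in recs:
            table = count_codons(extract_orfs(rec, min_length=1))
            pos = positional_gc(table)
            pts.append((pos.gc3, pos.gc12))
        res = neutrality_regression(pts)
        assert abs(res.slope - 0.4) < 0.02

    def test_zero_slope_recovered(self):
        spec = GeneratorSpec(
            seed=23, slope=0.0, intercept=0.41, noise_sd=0.005,
            n_isolates=20, n_codons=5000, n_orfs=1, utr_length=0,
        )
        recs = generate_isolate_set(spec)
        pts = []
        for rec in recs:
            pos = positional_gc(count_codons(extract_orfs(rec, min_length=1)))
            pts.append((pos.gc3, pos.gc12))
        res = neutrality_regression(pts)
        assert abs(res.slope) < 3 * res.stderr

    def test_infeasible_gc12_target_raises(self):
        spec = GeneratorSpec(seed=1, intercept=1.5, n_isolates=3, n_codons=100)
        with pytest.raises(FeasibilityError):
            generate_isolate_set(spec)


class TestSuppression:
    def test_translation_is_invariant(self):
        spec = GeneratorSpec(seed=31, cpg_suppression=0.4, upa_suppression=0.5)
        cds = generate_cds(GeneratorSpec(seed=31), n_codons=2000)
        out = suppress_dinucleotides(cds, spec)
        assert translate(out.seq) == translate(cds.seq)
        assert out.seq != cds.seq  # suppression really resampled codons

    def test_factor_one_is_exact_identity(self):
        spec = GeneratorSpec(seed=31)
        cds = generate_cds(spec, n_codons=500)
        out = suppress_dinucleotides(cds, spec)
        assert out.seq == cds.seq

    def test_suppression_reduces_cpg(self):
        from codonusage.dinucleotide import dinucleotide_odds

        base_spec = GeneratorSpec(seed=41)
        cds = generate_cds(base_spec, n_codons=20_000)
        spec = GeneratorSpec(seed=41, cpg_suppression=0.5)
        out = suppress_dinucleotides(cds, spec)
        before = dinucleotide_odds([cds.seq]).rho["CG"]
        after = dinucleotide_odds([out.seq]).rho["CG"]
        assert after < before
        assert after <= 0.78
        # UpA unaffected beyond sampling error
        ua_before = dinucleotide_odds([cds.seq]).rho["UA"]
        ua_after = dinucleotide_odds([out.seq]).rho["UA"]
        assert abs(ua_after - ua_before) < 0.1
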