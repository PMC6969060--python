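"""Count-correction rules, purity scaling, and per-sample composition."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonetrace.io_formats import (
    CnaSegment,
    CnaState,
    LesionType,
    SampleMeta,
    Sex,
    VariantCall,
)
from clonetrace.vaf_correction import (
    FLAG_AMBIGUOUS,
    FLAG_CAPPED,
    adjust_counts,
    correct_sample,
    purity_correct,
)


def _meta(tumor_content=1.0, sex=Sex.FEMALE):
    return SampleMeta(
        "S1", "P1", LesionType.PRIMARY, "rectum", 1, False, tumor_content, sex
    )


class TestAdjustCounts:
    @pytest.mark.parametrize(
        "ref,alt,state,expected",
        [
            (50, 50, CnaState.AMP, (Fraction(50), Fraction(25))),
            (30, 70, CnaState.DEL, (Fraction(100), Fraction(70))),
            (40, 60, CnaState.CN_LOH, (Fraction(70), Fraction(30))),
            (60, 40, CnaState.NEUTRAL, (Fraction(60), Fraction(40))),
        ],
    )
    def test_autosomal_rules(self, ref, alt, state, expected):
        assert adjust_counts(ref, alt, state) == expected

    def test_male_x_rule(self):
        assert adjust_counts(10, 80, CnaState.NEUTRAL, chrom="chrX", sex=Sex.MALE) == (
            Fraction(100),
            Fraction(80),
        )

    def test_male_x_rule_overrides_segment_state(self):
        # the hemizygous rule replaces, never composes with, the CNA rule
        assert adjust_counts(10, 80, CnaState.AMP, chrom="chrX", sex=Sex.MALE) == (
            Fraction(100),
            Fraction(80),
        )

    def test_female_x_behaves_like_autosome(self):
        assert adjust_counts(50, 50, CnaState.AMP, chrom="chrX", sex=Sex.FEMALE) == (
            Fraction(50),
            Fraction(25),
        )

    def test_x_with_unknown_sex_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            adjust_counts(10, 10, CnaState.NEUTRAL, chrom="chrX", sex=Sex.UNKNOWN)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            adjust_counts(0, 0, CnaState.NEUTRAL)

    def test_odd_alt_keeps_exact_halves(self):
        ref_adj, alt_adj = adjust_counts(10, 7, CnaState.AMP)
        assert alt_adj == Fraction(7, 2)

    @given(
        ref=st.integers(min_value=0, max_value=500),
        alt=st.integers(min_value=0, max_value=500),
        scale=st.integers(min_value=1, max_value=20),
        state=st.sampled_from(list(CnaState)),
    )
    def test_corrected_vaf_scale_invariant(self, ref, alt, scale, state):
        if ref + alt == 0:
            return
        a = purity_correct(*adjust_counts(ref, alt, state), Fraction(1))
        b = purity_correct(*adjust_counts(ref * scale, alt * scale, state), Fraction(1))
        assert a == b


class TestPurityCorrect:
    def test_forced_division(self):
        vaf, capped = purity_correct(80, 20, Fraction(1, 2))
        assert vaf == Fraction(2, 5) and not capped

    def test_full_purity_is_identity(self):
        vaf, _ = purity_correct(60, 40, Fraction(1))
        assert vaf == Fraction(2, 5)

    def test_cap_and_flag(self):
        vaf, capped = purity_correct(20, 80, Fraction(1, 2))
        assert vaf == 1 and capped

    def test_invalid_tumor_content(self):
        with pytest.raises(ValueError):
            purity_correct(50, 50, 0)


class TestCorrectSample:
    def _variant(self, chrom="chr1", pos=100, ref=60, alt=40):
        return VariantCall(chrom, pos, "A", "T", ref, alt)

    def test_variant_in_amp_segment_uses_amp_rule(self):
        segs = [CnaSegment("chr1", 0, 1000, CnaState.AMP)]
        (c,), _ = correct_sample([self._variant(ref=50, alt=50)], segs, _meta())
        assert c.cna_state is CnaState.AMP
        assert c.corrected_vaf == pytest.approx(1 / 3)

    def test_uncovered_variant_is_neutral(self):
        segs = [CnaSegment("chr2", 0, 1000, CnaState.DEL)]
        (c,), _ = correct_sample([self._variant()], segs, _meta())
        assert c.cna_state is CnaState.NEUTRAL
        assert c.corrected_vaf == pytest.approx(0.4)

    def test_neutral_full_purity_is_identity_on_raw_vaf(self):
        (c,), _ = correct_sample([self._variant()], [], _meta(1.0))
        assert c.corrected_vaf == c.raw_vaf

    def test_exclusions_reported(self):
        variants = [
            self._variant(),
            VariantCall("chrY", 5, "A", "T", 10, 10),
            VariantCall("chrX", 5, "A", "T", 10, 10),
        ]
        corrected, excluded = correct_sample(variants, [], _meta(sex=Sex.UNKNOWN))
        assert len(corrected) == 1
        reasons = {e.variant_id: e.reason for e in excluded}
        assert "chrY:5:A>T" in reasons and "sex unknown" in reasons["chrX:5:A>T"]

    def test_capped_flagged(self):
        (c,), _ = correct_sample(
            [self._variant(ref=10, alt=90)], [], _meta(tumor_content=0.5)
        )
        assert c.corrected_vaf == 1.0 and FLAG_CAPPED in c.flags

    def test_male_x_in_aberrant_segment_flagged_ambiguous(self):
        segs = [CnaSegment("chrX", 0, 1000, CnaState.AMP)]
        (c,), _ = correct_sample(
            [self._variant(chrom="chrX")], segs, _meta(sex=Sex.MALE)
        )
        assert FLAG_AMBIGUOUS in c.flags

    def test_simulated_sample_corrects_to_truth_proportion(self):
        """At 1000x the corrected VAF tracks proportion/2 to within 0.03."""
        from clonetrace.io_formats import Sex as _Sex
        from clonetrace.synthetic_data import (
            CloneSpec,
            LesionSpec,
            SimConfig,
            simulate_patient,
        )

        purity = 0.6
        # a nested lineage: each subclone is a subset of its parent
        proportions = [1.0, 0.8, 0.5, 0.25]
        clones = tuple(
            CloneSpec(f"c{i}", 50, {"T": p}, parent_id=f"c{i-1}" if i else None)
            for i, p in enumerate(proportions)
        )
        config = SimConfig(
            patient_id="SIM-D",
            lesions=(LesionSpec("T", LesionType.PRIMARY, "colon", purity, 1000.0),),
            clones=clones,
            seed=31,
            sex=_Sex.FEMALE,
        )
        patient = simulate_patient(config)
        corrected, _ = correct_sample(
            patient.variants["T"], patient.segments["T"], patient.sample_sheet[0]
        )
        truth = patient.truth["variants"]
        errors = [
            abs(c.corrected_vaf - truth[c.variant_id]["lesions"]["T"]["proportion"] / 2)
            for c in corrected
        ]
        assert np.mean(errors) < 0.03


def _closed_form(ref, alt, state):
    """Independent statement of the printed rules (oracle)."""
    ref, alt = Fraction(ref), Fraction(alt)
    return {
        CnaState.AMP: (ref, alt / 2),
        CnaState.DEL: (ref + alt, alt),
        CnaState.CN_LOH: (ref + alt / 2, alt / 2),
        CnaState.NEUTRAL: (ref, alt),
    }[state]


def test_rules_match_closed_form_on_small_grid():
    """Exhaustive rational oracle on depths up to 60 (full 200 in acceptance)."""
    for total in range(1, 61):
        for alt in range(0, total + 1):
            ref = total - alt
            for state in CnaState:
                assert adjust_counts(ref, alt, state) == _closed_form(ref, alt, state)
            assert adjust_counts(ref, alt, CnaState.NEUTRAL, "chrX", Sex.MALE) == (
                ref * 2 + alt,
                Fraction(alt),
            )
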