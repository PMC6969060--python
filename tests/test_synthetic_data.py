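"""Forward-model correctness: closed forms, determinism, truth consistency."""

from fractions import Fraction

import numpy as np
import pytest

from clonetrace.io_formats import CnaState, LesionType, Sex
from clonetrace.synthetic_data import (
    CloneSpec,
    CnaSpec,
    ConfigError,
    LesionSpec,
    SimConfig,
    expected_vaf,
    simulate_patient,
    simulate_signature_mutations,
    synthetic_signature_matrix,
    three_clone_two_lesion_config,
)


class TestExpectedVaf:
    def test_clonal_neutral_full_purity_is_half(self):
        assert expected_vaf(1.0, 1.0, CnaState.NEUTRAL) == 0.5

    def test_half_purity_clonal_neutral(self):
        assert expected_vaf(0.5, 1.0, CnaState.NEUTRAL) == 0.25

    def test_state_copy_conventions(self):
        pi, p = Fraction(1), Fraction(1)
        assert expected_vaf(pi, p, CnaState.AMP) == Fraction(2, 3)
        assert expected_vaf(pi, p, CnaState.DEL) == Fraction(1)
        assert expected_vaf(pi, p, CnaState.CN_LOH) == Fraction(1)

    def test_alternative_amp_convention(self):
        assert expected_vaf(1.0, 1.0, CnaState.AMP, amp_on_mutated_allele=False) == pytest.approx(1 / 3)


class TestConfigValidation:
    def _lesion(self, **kw):
        kw.setdefault("sample_id", "T")
        return LesionSpec(**kw)

    def test_purity_bounds(self):
        with pytest.raises(ConfigError):
            LesionSpec(sample_id="T", purity=0.0)

    def test_child_exceeding_parent_rejected(self):
        config = SimConfig(
            patient_id="P",
            lesions=(self._lesion(),),
            clones=(
                CloneSpec("root", 5, {"T": 0.5}),
                CloneSpec("kid", 5, {"T": 0.8}, parent_id="root"),
            ),
        )
        with pytest.raises(ConfigError, match="children"):
            simulate_patient(config)

    def test_sibling_sum_exceeding_one_rejected(self):
        config = SimConfig(
            patient_id="P",
            lesions=(self._lesion(),),
            clones=(
                CloneSpec("a", 5, {"T": 0.7}),
                CloneSpec("b", 5, {"T": 0.6}),
            ),
        )
        with pytest.raises(ConfigError):
            simulate_patient(config)

    def test_unknown_arm_rejected(self):
        config = SimConfig(
            patient_id="P",
            lesions=(self._lesion(),),
            clones=(CloneSpec("a", 5, {"T": 0.5}),),
            cnas=(CnaSpec(arm="99z", state=CnaState.AMP),),
        )
        with pytest.raises(ConfigError, match="99z"):
            simulate_patient(config)


class TestSimulatePatient:
    def test_ultra_deep_clonal_mean_vaf_near_half(self):
        config = SimConfig(
            patient_id="P",
            lesions=(LesionSpec("T", LesionType.PRIMARY, "colon", 1.0, 25000.0),),
            clones=(CloneSpec("clonal", 100, {"T": 1.0}),),
            seed=19,
        )
        patient = simulate_patient(config)
        vafs = [v.vaf for v in patient.variants["T"]]
        assert abs(np.mean(vafs) - 0.5) < 0.01

    def test_byte_identical_under_same_seed(self, tmp_path):
        for d in ("a", "b"):
            simulate_patient(three_clone_two_lesion_config(seed=3)).write(tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        a = simulate_patient(three_clone_two_lesion_config(seed=3))
        b = simulate_patient(three_clone_two_lesion_config(seed=4))
        assert a.variants["P"] != b.variants["P"]

    def test_truth_expected_vafs_recompute_exactly(self, simulated_pair):
        config = simulated_pair.config
        purity = {l.sample_id: l.purity for l in config.lesions}
        for vid, entry in simulated_pair.truth["variants"].items():
            for sample_id, rec in entry["lesions"].items():
                recomputed = (
                    float(
                        expected_vaf(
                            purity[sample_id],
                            rec["proportion"],
                            CnaState(rec["state"]),
                            config.amp_on_mutated_allele,
                        )
                    )
                    if rec["proportion"] > 0
                    else 0.0
                )
                assert recomputed == rec["expected_vaf"]

    def test_emitted_formats_read_back(self, simulated_pair, tmp_path):
        from clonetrace.io_formats import (
            read_het_snps,
            read_sample_sheet,
            read_segments,
            read_variants,
        )

        simulated_pair.write(tmp_path)
        metas = read_sample_sheet(tmp_path / "sample_sheet.tsv")
        assert [m.sample_id for m in metas] == ["P", "M"]
        variants = read_variants(tmp_path / "P.variants.tsv")
        assert variants == simulated_pair.variants["P"]
        assert read_het_snps(tmp_path / "P.het_snps.tsv") == simulated_pair.het_snps["P"]
        assert read_segments(tmp_path / "P.segments.tsv") == simulated_pair.segments["P"]

    def test_private_clone_absent_from_other_lesion(self, simulated_pair):
        truth = simulated_pair.truth["variants"]
        met_ids = {v.variant_id for v in simulated_pair.variants["M"]}
        primary_private = [
            vid for vid, e in truth.items() if e["clone_id"] == "primary_private"
        ]
        assert primary_private and not met_ids.intersection(primary_private)


class TestSimulateSignatureMutations:
    def test_single_column_support(self, reference_signatures):
        subs, truth = simulate_signature_mutations(
            200, [1.0, 0.0], reference_signatures, seed=2
        )
        assert truth == {"SYN1": 1.0, "SYN2": 0.0}
        from clonetrace.signatures import context_label

        support = {
            c
            for c, w in zip(
                reference_signatures.contexts, reference_signatures.column("SYN1")
            )
            if w > 0
        }
        assert {context_label(*s) for s in subs} <= support

    def test_empty_draw(self, reference_signatures):
        subs, _ = simulate_signature_mutations(0, [0.5, 0.5], reference_signatures, seed=1)
        assert subs == []

    def test_invalid_mixture_rejected(self, reference_signatures):
        with pytest.raises(ConfigError):
            simulate_signature_mutations(10, [], reference_signatures, seed=1)
        with pytest.raises(ConfigError):
            simulate_signature_mutations(10, [0.7, 0.7], reference_signatures, seed=1)


def test_synthetic_matrix_is_valid_and_disjoint():
    m = synthetic_signature_matrix(4, seed=3, disjoint=True)
    np.testing.assert_allclose(m.weights.sum(axis=0), 1.0, atol=1e-9)
    support = (m.weights > 0).astype(int)
    assert np.all(support.sum(axis=1) <= 1)
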