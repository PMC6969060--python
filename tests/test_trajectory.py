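"""Clone-fate classification, driver persistence, and report assembly."""

import itertools

import pytest

from clonetrace.clustering import CloneCluster
from clonetrace.io_formats import Annotation, LesionType, SampleMeta, Sex, VariantCall
from clonetrace.trajectory import (
    Fate,
    PairResult,
    assemble_report,
    classify_fates,
    driver_persistence,
    flag_hypermutation,
)


def _cluster(cid, center, members=()):
    return CloneCluster(
        cluster_id=cid,
        center=center,
        member_variant_ids=tuple(members),
        weight=0.3,
        presence=tuple(c >= 0.05 for c in center),
    )


class TestClassifyFates:
    @pytest.mark.parametrize(
        "center,fate",
        [
            ((0.40, 0.41), Fate.MAINTAINED),
            ((0.22, 0.01), Fate.LOST),
            ((0.02, 0.18), Fate.EMERGENT),
        ],
    )
    def test_fate_from_presence(self, center, fate):
        (call,) = classify_fates([_cluster(0, center)])
        assert call.fate is fate

    def test_maintained_delta_on_proportion_scale(self):
        (call,) = classify_fates([_cluster(0, (0.40, 0.41))])
        assert call.proportion_a == pytest.approx(0.80)
        assert call.delta == pytest.approx(0.02)

    def test_permutation_invariance_and_conservation(self):
        clusters = [
            _cluster(0, (0.4, 0.4)),
            _cluster(1, (0.25, 0.0)),
            _cluster(2, (0.0, 0.2)),
        ]
        baseline = {c.cluster_id: f.fate for c, f in zip(clusters, classify_fates(clusters))}
        for perm in itertools.permutations(clusters):
            calls = classify_fates(list(perm))
            assert len(calls) == len(clusters)
            for cluster, call in zip(perm, calls):
                assert call.fate is baseline[cluster.cluster_id]

    def test_driver_annotation_attached(self):
        driver_ids = {"v1": ("KRAS",), "v2": ("APC",)}
        (call,) = classify_fates(
            [_cluster(0, (0.4, 0.4), members=("v1", "v2", "v3"))], driver_ids
        )
        assert call.driver_mutations == ("APC", "KRAS")


def _driver_variant(gene, vaf=0.3, depth=100, annotation=Annotation.NONSILENT, pos=100):
    alt = max(int(round(vaf * depth)), 0)
    return VariantCall("chr12", pos, "G", "T", depth - alt, alt, gene=gene, annotation=annotation)


class TestDriverPersistence:
    def test_kras_present_in_both_lesions(self):
        matrix = driver_persistence(
            {
                "P": [_driver_variant("KRAS", 0.3)],
                "M": [_driver_variant("KRAS", 0.28)],
            }
        )
        assert matrix.loc["KRAS", "P"] and matrix.loc["KRAS", "M"]

    def test_absent_gene_all_false(self):
        matrix = driver_persistence({"P": [], "M": []})
        assert not matrix.loc["BRAF"].any()

    def test_alt_count_floor(self):
        low = VariantCall("chr12", 100, "G", "T", 98, 2, gene="KRAS",
                          annotation=Annotation.NONSILENT)
        matrix = driver_persistence({"P": [low]})
        assert not matrix.loc["KRAS", "P"]

    def test_silent_variants_ignored(self):
        matrix = driver_persistence(
            {"P": [_driver_variant("TP53", annotation=Annotation.SILENT)]}
        )
        assert not matrix.loc["TP53", "P"]

    def test_liver_pair_shares_drivers_lung_pair_does_not(self):
        """Multi-metastasis fixture: matched liver lesions carry identical
        driver sets (Jaccard 1) while each lung lesion has an exclusive one."""
        shared = [_driver_variant("APC", pos=100), _driver_variant("TP53", pos=200)]
        lung1 = shared + [_driver_variant("KRAS", pos=300)]
        lung2 = shared + [_driver_variant("PIK3CA", pos=400)]
        matrix = driver_persistence(
            {"liver1": shared, "liver2": shared, "lung1": lung1, "lung2": lung2}
        )

        def jaccard(a, b):
            sa = set(matrix.index[matrix[a]])
            sb = set(matrix.index[matrix[b]])
            return len(sa & sb) / len(sa | sb)

        assert jaccard("liver1", "liver2") == 1.0
        assert jaccard("lung1", "lung2") < 1.0
        assert jaccard("liver1", "lung1") < 1.0


class TestHypermutation:
    def _variants(self, n):
        return [
            VariantCall("chr1", i + 1, "C", "T", 50, 10) for i in range(n)
        ]

    def test_hypermutated_burden(self):
        assert flag_hypermutation(self._variants(1285))

    def test_typical_burden(self):
        assert not flag_hypermutation(self._variants(116))

    def test_threshold_inclusive(self):
        assert flag_hypermutation(self._variants(1000))


class TestAssembleReport:
    def _metas(self, n=2):
        types = [LesionType.PRIMARY] + [LesionType.METASTASIS] * (n - 1)
        return [
            SampleMeta(f"S{i+1}", "P1", types[i], "liver", i + 1, i == 1, 0.6, Sex.FEMALE)
            for i in range(n)
        ]

    def _pair(self):
        clusters = (_cluster(0, (0.4, 0.41)),)
        return PairResult("S1", "S2", True, clusters, tuple(classify_fates(clusters)))

    def test_two_lesion_report(self):
        report = assemble_report(self._metas(), [self._pair()])
        d = report.to_dict()
        assert d["pairs"][0]["fate_counts"]["MAINTAINED"] == 1
        assert d["lesions"][0]["sample_id"] == "S1"
        assert "1 maintained" in report.narrative()

    def test_single_sample_report_has_no_pairs(self):
        report = assemble_report(self._metas(1), [])
        assert report.to_dict()["pairs"] == []

    def test_missing_pair_noted_as_gap(self):
        report = assemble_report(
            self._metas(), [], expected_pairs=[("S1", "S2")]
        )
        assert any("S1 vs S2" in g for g in report.gaps)

    def test_mixed_patients_rejected(self):
        metas = self._metas()
        other = SampleMeta("Z1", "P2", LesionType.PRIMARY, "colon", 1, False, 0.5)
        with pytest.raises(ValueError, match="patients"):
            assemble_report(metas + [other], [])
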