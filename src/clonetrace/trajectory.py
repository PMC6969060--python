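"""Clone-fate tracking between lesions and per-patient reporting.

Each mixture cluster from a lesion pair is classified by its presence
flags: MAINTAINED when present in both lesions, LOST when present only in
the earlier lesion, EMERGENT when present only in the later one.
Proportion changes are reported on the cellular-proportion scale
(2 x corrected-VAF center, capped at 1).  Interpretation of fates in
terms of dormancy or therapy-driven elimination is deliberately left to
the analyst: the report carries the therapy annotations alongside the
quantitative fates, never an automatic causal inference.

Driver persistence is tabulated over a configurable gene list (default:
the six clinically-relevant colorectal-cancer genes APC, TP53, KRAS,
NRAS, PIK3CA, BRAF) with a sensitivity floor matched to ultra-deep
targeted sequencing (alt reads >= 3 and VAF >= 2%).  Samples with at
least 1000 exonic somatic mutations are flagged hypermutated.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .clustering import CloneCluster
from .io_formats import Annotation, SampleMeta, VariantCall
from .signatures import SignatureExposure

__all__ = [
    "Fate",
    "TrajectoryCall",
    "PairResult",
    "PatientReport",
    "DEFAULT_DRIVER_GENES",
    "classify_fates",
    "driver_persistence",
    "flag_hypermutation",
    "assemble_report",
    "plot_cluster_dynamics",
]

DEFAULT_DRIVER_GENES = ("APC", "TP53", "KRAS", "NRAS", "PIK3CA", "BRAF")

HYPERMUTATION_THRESHOLD = 1000


class Fate(enum.Enum):
    MAINTAINED = "MAINTAINED"
    LOST = "LOST"
    EMERGENT = "EMERGENT"


@dataclass(frozen=True)
class TrajectoryCall:
    """The fate of one clone cluster between two lesions."""

    cluster_id: int
    fate: Fate
    proportion_a: float
    proportion_b: float
    delta: float
    driver_mutations: tuple[str, ...] = ()


@dataclass(frozen=True)
class PairResult:
    """All per-pair outputs for one (lesion A, lesion B) comparison."""

    sample_a: str
    sample_b: str
    interval_therapy: bool
    clusters: tuple[CloneCluster, ...]
    calls: tuple[TrajectoryCall, ...]

    def fate_counts(self) -> dict[str, int]:
        counts = {f.value: 0 for f in Fate}
        for call in self.calls:
            counts[call.fate.value] += 1
        return counts


def _proportion(center_coord: float) -> float:
    return min(2.0 * center_coord, 1.0)


def classify_fates(
    clusters: Sequence[CloneCluster],
    driver_ids: Mapping[str, Sequence[str]] | None = None,
) -> list[TrajectoryCall]:
    """Derive each cluster's fate from its per-lesion presence flags.

    Pure function of the presence flags — permuting cluster order never
    changes any fate.  A noise cluster absent from both lesions (possible
    on the edge of the presence floor) is mapped to LOST or EMERGENT by
    whichever lesion has the larger center, keeping the conservation
    property |MAINTAINED| + |LOST| + |EMERGENT| = k.

    ``driver_ids`` optionally maps variant_id -> gene symbols to annotate
    driver-bearing clusters.
    """
    calls = []
    for c in clusters:
        if len(c.presence) != 2:
            raise ValueError("fate classification requires a lesion pair")
        in_a, in_b = c.presence
        if in_a and in_b:
            fate = Fate.MAINTAINED
        elif in_a:
            fate = Fate.LOST
        elif in_b:
            fate = Fate.EMERGENT
        else:
            fate = Fate.LOST if c.center[0] >= c.center[1] else Fate.EMERGENT
        drivers: tuple[str, ...] = ()
        if driver_ids:
            drivers = tuple(
                sorted(
                    {
                        gene
                        for vid in c.member_variant_ids
                        for gene in driver_ids.get(vid, ())
                    }
                )
            )
        pa, pb = _proportion(c.center[0]), _proportion(c.center[1])
        calls.append(
            TrajectoryCall(
                cluster_id=c.cluster_id,
                fate=fate,
                proportion_a=pa,
                proportion_b=pb,
                delta=pb - pa,
                driver_mutations=drivers,
            )
        )
    return calls


def driver_persistence(
    variants_per_lesion: Mapping[str, Sequence[VariantCall]],
    driver_genes: Sequence[str] = DEFAULT_DRIVER_GENES,
    alt_min: int = 3,
    vaf_min: float = 0.02,
) -> pd.DataFrame:
    """Gene x lesion presence matrix for driver genes.

    A gene is present in a lesion when any non-silent variant of that gene
    has ``alt_count >= alt_min`` and ``VAF >= vaf_min`` there.
    """
    lesions = list(variants_per_lesion)
    data = {}
    for lesion in lesions:
        present = set()
        for v in variants_per_lesion[lesion]:
            if (
                v.gene in driver_genes
                and v.annotation is Annotation.NONSILENT
                and v.alt_count >= alt_min
                and v.vaf >= vaf_min
            ):
                present.add(v.gene)
        data[lesion] = [g in present for g in driver_genes]
    return pd.DataFrame(data, index=list(driver_genes))


def flag_hypermutation(
    variants: Sequence[VariantCall], threshold: int = HYPERMUTATION_THRESHOLD
) -> bool:
    """True when the sample's exonic somatic burden reaches the threshold."""
    return len(variants) >= threshold


@dataclass
class PatientReport:
    """Machine-readable per-patient evolution report."""

    patient_id: str
    lesions: list[SampleMeta]
    pairs: list[PairResult]
    driver_matrix: pd.DataFrame | None = None
    hypermutated: dict[str, bool] = field(default_factory=dict)
    exposures: dict[str, SignatureExposure] = field(default_factory=dict)
    gaps: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d: dict = {
            "patient_id": self.patient_id,
            "lesions": [
                {
                    "sample_id": m.sample_id,
                    "lesion_type": m.lesion_type.value,
                    "site": m.site,
                    "resection_index": m.resection_index,
                    "interval_therapy": m.interval_therapy,
                    "tumor_content": m.tumor_content,
                    "hypermutated": self.hypermutated.get(m.sample_id, False),
                }
                for m in self.lesions
            ],
            "pairs": [
                {
                    "sample_a": p.sample_a,
                    "sample_b": p.sample_b,
                    "interval_therapy": p.interval_therapy,
                    "fate_counts": p.fate_counts(),
                    "clusters": [
                        {
                            "cluster_id": call.cluster_id,
                            "fate": call.fate.value,
                            "proportion_a": call.proportion_a,
                            "proportion_b": call.proportion_b,
                            "delta": call.delta,
                            "drivers": list(call.driver_mutations),
                        }
                        for call in p.calls
                    ],
                }
                for p in self.pairs
            ],
            "gaps": list(self.gaps),
        }
        if self.driver_matrix is not None:
            d["driver_persistence"] = {
                gene: {
                    lesion: bool(self.driver_matrix.loc[gene, lesion])
                    for lesion in self.driver_matrix.columns
                }
                for gene in self.driver_matrix.index
            }
        if self.exposures:
            d["signature_exposures"] = {
                sample: {
                    "exposures": exp.exposures,
                    "residual": exp.residual,
                    "reconstruction_cosine": exp.reconstruction_cosine,
                    "flags": list(exp.flags),
                }
                for sample, exp in self.exposures.items()
            }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def narrative(self) -> str:
        """Plain-text block: per interval, therapy flag and fate counts."""
        lines = [f"patient {self.patient_id}"]
        for p in self.pairs:
            counts = p.fate_counts()
            lines.append(
                f"  {p.sample_a} -> {p.sample_b} "
                f"(interval therapy: {'yes' if p.interval_therapy else 'no'}): "
                f"{counts['MAINTAINED']} maintained, {counts['LOST']} lost, "
                f"{counts['EMERGENT']} emergent"
            )
        for sample, flag in sorted(self.hypermutated.items()):
            if flag:
                lines.append(f"  {sample}: hypermutated")
        return "\n".join(lines)


def assemble_report(
    metas: Sequence[SampleMeta],
    pair_results: Sequence[PairResult],
    exposures: Mapping[str, SignatureExposure] | None = None,
    driver_matrix: pd.DataFrame | None = None,
    hypermutated: Mapping[str, bool] | None = None,
    expected_pairs: Sequence[tuple[str, str]] | None = None,
) -> PatientReport:
    """Assemble all per-patient evidence into one report.

    Lesions are ordered by resection index; expected pairs without a
    result are noted as gaps rather than failing.
    """
    if not metas:
        raise ValueError("no samples for report")
    patients = {m.patient_id for m in metas}
    if len(patients) != 1:
        raise ValueError(f"samples span multiple patients: {sorted(patients)}")
    lesions = sorted(metas, key=lambda m: m.resection_index)
    have = {(p.sample_a, p.sample_b) for p in pair_results}
    gaps = []
    if expected_pairs:
        for pair in expected_pairs:
            if tuple(pair) not in have:
                gaps.append(f"missing pair result: {pair[0]} vs {pair[1]}")
    return PatientReport(
        patient_id=lesions[0].patient_id,
        lesions=lesions,
        pairs=list(pair_results),
        driver_matrix=driver_matrix,
        hypermutated=dict(hypermutated or {}),
        exposures=dict(exposures or {}),
        gaps=gaps,
    )


def plot_cluster_dynamics(pair: PairResult, path: str | Path) -> None:
    """Line plot of cluster proportions from lesion A to lesion B."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    colors = {"MAINTAINED": "#d4a017", "LOST": "#c0392b", "EMERGENT": "#2e6da4"}
    for call in pair.calls:
        ax.plot(
            [0, 1],
            [call.proportion_a, call.proportion_b],
            marker="o",
            label=f"cluster {call.cluster_id} ({call.fate.value.lower()})",
            color=colors[call.fate.value],
        )
    ax.set_xticks([0, 1])
    ax.set_xticklabels([pair.sample_a, pair.sample_b])
    ax.set_ylabel("cell population proportion")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
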