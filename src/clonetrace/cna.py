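"""Arm-level copy-number aberration calling from BAF deviation and coverage.

A segment (or whole chromosome arm) is classified from two observed-scale
statistics:

* ``baf_dev`` — the mean folded deviation of het-SNP B-allele frequencies
  from 0.5, ``mean(|alt/(ref+alt) - 0.5|)``, in [0, 0.5];
* ``cov_ratio`` — mean normalized read depth over the segment divided by a
  genome-wide baseline.

The decision rules: a BAF deviation with increased coverage is an
amplification (AMP); with decreased coverage a deletion (DEL); with flat
coverage a copy-neutral loss of heterozygosity (CN_LOH); no BAF deviation
is NEUTRAL.  "Increased"/"decreased" are operationalized as fixed,
config-exposed ratio thresholds (gain >= 1.15, loss <= 0.85) with a
minimum-SNP gate, rather than an unspecified statistical test.  Tumor
purity attenuates both statistics; classification operates on observed
values without purity back-correction.

Segmentation (breakpoint discovery) is not performed: segments are taken
from input or from fixed arm boundaries (a GRCh37 arm table ships with the
package).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import CnaSegment, CnaState, FormatError, HetSnp

__all__ = [
    "CnaThresholds",
    "Arm",
    "ArmCall",
    "UNCALLABLE",
    "load_arm_table",
    "normalize_coverage",
    "segment_baf_dev",
    "classify_segment",
    "arm_calls",
    "call_arms_from_snps",
]

#: Sentinel state for arms/segments without enough evidence to call.
UNCALLABLE = "UNCALLABLE"


@dataclass(frozen=True)
class CnaThresholds:
    """Decision thresholds for copy-state classification.

    baf_dev_min: minimum mean folded BAF deviation to call any aberration.
    cov_gain_min: coverage ratio at or above which a deviated segment is AMP.
    cov_loss_max: coverage ratio at or below which a deviated segment is DEL.
    min_snps: minimum het SNPs for a segment to be callable.
    """

    baf_dev_min: float = 0.10
    cov_gain_min: float = 1.15
    cov_loss_max: float = 0.85
    min_snps: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.cov_loss_max < self.cov_gain_min):
            raise ValueError("require 0 < cov_loss_max < cov_gain_min")
        if not (0 < self.baf_dev_min <= 0.5):
            raise ValueError("baf_dev_min must be in (0, 0.5]")


@dataclass(frozen=True)
class Arm:
    """A chromosome arm interval (0-based half-open)."""

    chrom: str
    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ArmCall:
    arm: str
    state: CnaState | str  # CnaState or UNCALLABLE
    baf_dev: float | None = None
    cov_ratio: float | None = None
    n_snps: int = 0


def load_arm_table(path: str | Path | None = None) -> list[Arm]:
    """Load chromosome-arm boundaries (default: packaged GRCh37 table)."""
    if path is None:
        source = resources.files("clonetrace.data").joinpath("grch37_arms.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    arms = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, name, start, end = line.split("\t")
        arms.append(Arm(chrom, name, int(start), int(end)))
    if not arms:
        raise FormatError("arm table is empty")
    return arms


def normalize_coverage(
    depths_per_bin: Sequence[tuple[object, float]], baseline: float | None = None
) -> list[tuple[object, float]]:
    """Divide per-bin mean depths by a baseline depth.

    ``baseline`` defaults to the genome-wide mean of the per-bin depths, in
    which case the mean of the returned ratios is 1 by construction.
    """
    if not depths_per_bin:
        raise ValueError("empty bin list")
    depths = np.array([d for _, d in depths_per_bin], dtype=float)
    if baseline is None:
        baseline = float(depths.mean())
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return [
        (interval, float(d) / baseline) for (interval, _), d in zip(depths_per_bin, depths)
    ]


def segment_baf_dev(snps: Sequence[HetSnp]) -> tuple[float, int]:
    """Mean folded BAF deviation |alt/(ref+alt) - 0.5| over a segment.

    Returns ``(baf_dev, n_snps)``; SNPs with zero depth are ignored.
    Callability (``n_snps >= min_snps``) is the caller's decision so that
    thin segments are marked UNCALLABLE rather than raising.
    """
    devs = [abs(s.baf - 0.5) for s in snps if s.depth > 0]
    if not devs:
        return 0.0, 0
    return float(np.mean(devs)), len(devs)


def classify_segment(
    baf_dev: float,
    cov_ratio: float,
    n_snps: int | None = None,
    thresholds: CnaThresholds = CnaThresholds(),
) -> CnaState | str:
    """Classify one segment; total and deterministic over valid inputs.

    The four outcomes partition the (baf_dev, cov_ratio) plane.  With
    ``n_snps`` given and below the gate, returns UNCALLABLE.
    """
    if n_snps is not None and n_snps < thresholds.min_snps:
        return UNCALLABLE
    if baf_dev < thresholds.baf_dev_min:
        return CnaState.NEUTRAL
    if cov_ratio >= thresholds.cov_gain_min:
        return CnaState.AMP
    if cov_ratio <= thresholds.cov_loss_max:
        return CnaState.DEL
    return CnaState.CN_LOH


def arm_calls(
    segments: Iterable[CnaSegment],
    arm_table: Sequence[Arm] | None = None,
    majority: float = 0.80,
) -> list[ArmCall]:
    """Aggregate segment calls to whole-arm calls.

    An arm receives a non-NEUTRAL state when at least ``majority`` (default
    80%) of its callable length (total length of overlapping segments)
    shares that state; otherwise NEUTRAL.  Arms with no callable segments
    are UNCALLABLE.
    """
    arms = arm_table if arm_table is not None else load_arm_table()
    out = []
    segments = list(segments)
    for arm in arms:
        by_state: dict[CnaState, int] = {}
        callable_len = 0
        for seg in segments:
            if seg.chrom != arm.chrom:
                continue
            overlap = min(seg.end, arm.end) - max(seg.start, arm.start)
            if overlap <= 0:
                continue
            callable_len += overlap
            by_state[seg.state] = by_state.get(seg.state, 0) + overlap
        if callable_len == 0:
            out.append(ArmCall(arm.name, UNCALLABLE))
            continue
        state = CnaState.NEUTRAL
        for s, length in by_state.items():
            if s is not CnaState.NEUTRAL and length >= majority * callable_len:
                state = s
        out.append(ArmCall(arm.name, state))
    return out


def call_arms_from_snps(
    snps: Sequence[HetSnp],
    arm_table: Sequence[Arm] | None = None,
    thresholds: CnaThresholds = CnaThresholds(),
    baseline: float | None = None,
) -> list[ArmCall]:
    """Call copy states per arm directly from het-SNP counts.

    The SNP depths double as the coverage signal: each arm's ``cov_ratio``
    is its mean SNP depth over the genome-wide mean SNP depth (or an
    explicit ``baseline``).  Suitable when no external segmentation is
    available, matching arm-scale analyses.
    """
    arms = arm_table if arm_table is not None else load_arm_table()
    usable = [s for s in snps if s.depth > 0]
    if not usable:
        raise ValueError("no het SNPs with nonzero depth")
    if baseline is None:
        baseline = float(np.mean([s.depth for s in usable]))
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    out = []
    for arm in arms:
        arm_snps = [
            s
            for s in usable
            if s.chrom == arm.chrom and arm.start <= s.pos - 1 < arm.end
        ]
        if len(arm_snps) < thresholds.min_snps:
            out.append(ArmCall(arm.name, UNCALLABLE, n_snps=len(arm_snps)))
            continue
        baf_dev, n_snps = segment_baf_dev(arm_snps)
        cov_ratio = float(np.mean([s.depth for s in arm_snps])) / baseline
        state = classify_segment(baf_dev, cov_ratio, n_snps, thresholds)
        out.append(ArmCall(arm.name, state, baf_dev, cov_ratio, n_snps))
    return out


def segments_from_arm_calls(
    calls: Sequence[ArmCall], arm_table: Sequence[Arm] | None = None
) -> list[CnaSegment]:
    """Materialize non-neutral arm calls as segments (for VAF correction)."""
    arms = {a.name: a for a in (arm_table if arm_table is not None else load_arm_table())}
    segs = []
    for call in calls:
        if not isinstance(call.state, CnaState) or call.state is CnaState.NEUTRAL:
            continue
        arm = arms[call.arm]
        segs.append(
            CnaSegment(
                chrom=arm.chrom,
                start=arm.start,
                end=arm.end,
                state=call.state,
                arm=arm.name,
                baf_dev=call.baf_dev,
                cov_ratio=call.cov_ratio,
                n_snps=call.n_snps,
            )
        )
    return segs
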