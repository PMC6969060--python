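"""Copy-number- and purity-aware correction of somatic allele frequencies.

Read counts are first adjusted for the copy state of the surrounding
segment under the deliberately naive assumption that the aberration always
affects the mutated allele to the largest extent (a duplication duplicates
the mutated copy; a deletion removes the reference copy):

* duplication (AMP):        Ref' = Ref,            Alt' = Alt/2
* deletion (DEL):           Ref' = Ref + Alt,      Alt' = Alt
* copy-neutral LOH:         Ref' = Ref + Alt/2,    Alt' = Alt/2
* gene on X, male patient:  Ref' = Ref*2 + Alt,    Alt' = Alt   (hemizygous,
  treated as an LOH case; applies on X regardless of the segment state)
* neutral:                  identity

Adjusted counts are kept as exact rationals (``fractions.Fraction``) so
Alt/2 on odd counts loses nothing.  The adjusted frequency is then divided
by the histology-estimated tumor content and capped at 1 (flag ``CAPPED``):

    corrected_vaf = min( (Alt'/(Ref'+Alt')) / tumor_content, 1 )

``cellular_proportion = min(2 * corrected_vaf, 1)`` converts to the
fraction of tumor cells carrying the mutation under a heterozygous
single-copy model; clustering operates on ``corrected_vaf``, reporting on
``cellular_proportion``.

X variants in patients of unknown sex, and variants on Y/MT, are excluded
(flag ``EXCLUDED``) rather than guessed at.  X variants inside a
non-neutral segment keep the X rule but are flagged ``AMBIGUOUS`` since no
composition of the two rules is defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .io_formats import (
    CnaSegment,
    CnaState,
    SampleMeta,
    Sex,
    VariantCall,
    is_autosome,
    is_x,
)

__all__ = [
    "CorrectedVariant",
    "ExclusionRecord",
    "adjust_counts",
    "purity_correct",
    "correct_sample",
    "FLAG_CAPPED",
    "FLAG_AMBIGUOUS",
    "FLAG_EXCLUDED",
]

FLAG_CAPPED = "CAPPED"
FLAG_AMBIGUOUS = "AMBIGUOUS"
FLAG_EXCLUDED = "EXCLUDED"

Number = int | float | Fraction


@dataclass(frozen=True)
class CorrectedVariant:
    """A variant with CNA- and purity-corrected allele frequency."""

    variant_id: str
    raw_vaf: float
    cna_state: CnaState
    ref_adj: Fraction
    alt_adj: Fraction
    corrected_vaf: float
    cellular_proportion: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ExclusionRecord:
    variant_id: str
    reason: str


def adjust_counts(
    ref: Number,
    alt: Number,
    cna_state: CnaState,
    chrom: str = "1",
    sex: Sex = Sex.UNKNOWN,
) -> tuple[Fraction, Fraction]:
    """Apply the copy-state read-count correction rule.

    Exact rational arithmetic; accepts integers or Fractions.  On the X
    chromosome of a male patient the hemizygous rule replaces (never
    composes with) the segment rule.  Raises for X with unknown sex — the
    caller is expected to exclude such variants instead.
    """
    ref = Fraction(ref)
    alt = Fraction(alt)
    if ref < 0 or alt < 0 or ref + alt == 0:
        raise ValueError("require ref >= 0, alt >= 0, ref + alt > 0")
    if is_x(chrom):
        if sex is Sex.UNKNOWN:
            raise ValueError(
                f"variant on X with unknown patient sex cannot be corrected"
            )
        if sex is Sex.MALE:
            return ref * 2 + alt, alt
        # female X behaves like an autosome
    if cna_state is CnaState.AMP:
        return ref, alt / 2
    if cna_state is CnaState.DEL:
        return ref + alt, alt
    if cna_state is CnaState.CN_LOH:
        return ref + alt / 2, alt / 2
    return ref, alt


def purity_correct(
    ref_adj: Number, alt_adj: Number, tumor_content: Number
) -> tuple[Fraction, bool]:
    """Scale the adjusted VAF by 1/tumor_content, capping at 1.

    Returns ``(corrected_vaf, capped)``; exact when inputs are rational.
    """
    tc = Fraction(tumor_content)
    if tc <= 0 or tc > 1:
        raise ValueError(f"tumor_content must be in (0, 1], got {tumor_content}")
    ref_adj = Fraction(ref_adj)
    alt_adj = Fraction(alt_adj)
    scaled = (alt_adj / (ref_adj + alt_adj)) / tc
    if scaled > 1:
        return Fraction(1), True
    return scaled, False


def _find_segment(
    variant: VariantCall, segments: Sequence[CnaSegment]
) -> CnaSegment | None:
    for seg in segments:
        if seg.contains(variant.chrom, variant.pos):
            return seg
    return None


def correct_sample(
    variants: Sequence[VariantCall],
    segments: Sequence[CnaSegment],
    meta: SampleMeta,
) -> tuple[list[CorrectedVariant], list[ExclusionRecord]]:
    """Correct every variant of one sample; returns (corrected, exclusions).

    A variant takes the state of its containing segment (segments must be
    non-overlapping), NEUTRAL when uncovered.  Excluded: zero-depth
    variants, X with unknown sex, and non-autosome non-X chromosomes
    (Y, MT), each with a reason in the exclusion report.
    """
    corrected: list[CorrectedVariant] = []
    excluded: list[ExclusionRecord] = []
    for v in variants:
        if v.depth == 0:
            excluded.append(ExclusionRecord(v.variant_id, "zero depth"))
            continue
        if not is_autosome(v.chrom) and not is_x(v.chrom):
            excluded.append(
                ExclusionRecord(v.variant_id, f"non-autosome chromosome {v.chrom}")
            )
            continue
        if is_x(v.chrom) and meta.sex is Sex.UNKNOWN:
            excluded.append(ExclusionRecord(v.variant_id, "X variant, sex unknown"))
            continue
        seg = _find_segment(v, segments)
        state = seg.state if seg is not None else CnaState.NEUTRAL
        flags: list[str] = []
        if is_x(v.chrom) and meta.sex is Sex.MALE and state is not CnaState.NEUTRAL:
            flags.append(FLAG_AMBIGUOUS)
        ref_adj, alt_adj = adjust_counts(
            v.ref_count, v.alt_count, state, chrom=v.chrom, sex=meta.sex
        )
        vaf, capped = purity_correct(ref_adj, alt_adj, Fraction(meta.tumor_content))
        if capped:
            flags.append(FLAG_CAPPED)
        corrected_vaf = float(vaf)
        corrected.append(
            CorrectedVariant(
                variant_id=v.variant_id,
                raw_vaf=v.vaf,
                cna_state=state,
                ref_adj=ref_adj,
                alt_adj=alt_adj,
                corrected_vaf=corrected_vaf,
                cellular_proportion=min(2.0 * corrected_vaf, 1.0),
                flags=tuple(flags),
            )
        )
    return corrected, excluded


def write_corrected(path, corrected: Sequence[CorrectedVariant]) -> None:
    """Write the corrected-variant table (canonical TSV dialect)."""
    lines = [
        "#variant_id\traw_vaf\tcna_state\tcorrected_vaf\tcellular_proportion\tflags"
    ]
    for c in corrected:
        lines.append(
            "\t".join(
                [
                    c.variant_id,
                    repr(float(c.raw_vaf)),
                    c.cna_state.value,
                    repr(float(c.corrected_vaf)),
                    repr(float(c.cellular_proportion)),
                    ",".join(c.flags) if c.flags else ".",
                ]
            )
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
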