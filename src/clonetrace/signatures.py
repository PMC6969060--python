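"""96-context substitution profiles and reference-signature refitting.

Single-base substitutions are tallied into the 96 canonical bins: the six
pyrimidine-frame substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 16 combinations of 5' and 3' flanking bases.
Purine-reference substitutions are reverse-complemented into the
pyrimidine frame before binning, so e.g. a G>A at CGT counts as C>T at
ACG ("A[C>T]G").

Exposures are estimated by refitting: the normalized profile is projected
onto the reference signature columns by nonnegative least squares, then
signatures with fitted weight below ``min_weight`` (default 6%) are
iteratively discarded and the fit repeated on the survivors until stable.
Exposures are renormalized to sum at most 1; the remainder is reported as
``residual`` together with the cosine similarity between the
reconstructed and observed profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import nnls

from .io_formats import SignatureMatrix, ValidationError

__all__ = [
    "CONTEXT_LABELS_96",
    "ContextProfile",
    "SignatureExposure",
    "count_contexts",
    "refit_exposures",
    "context_label",
    "parse_context_label",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")


def _build_labels() -> tuple[str, ...]:
    labels = []
    for sub in _SUBSTITUTIONS:
        ref = sub[0]
        for five in _BASES:
            for three in _BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


#: Canonical ordering of the 96 context bins (COSMIC convention:
#: substitution class, then 5' base, then 3' base).
CONTEXT_LABELS_96: tuple[str, ...] = _build_labels()
_LABEL_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS_96)}


def context_label(ref: str, alt: str, context: str) -> str:
    """Fold a substitution into its canonical pyrimidine-frame bin label.

    ``context`` is the 3-mer reference context; its middle base must equal
    ``ref``.  Raises :class:`ValidationError` for malformed records.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or len(ref) != 1 or len(alt) != 1:
        raise ValidationError(f"malformed substitution {ref}>{alt} at {context}")
    if any(b not in _COMPLEMENT for b in context) or alt not in _COMPLEMENT:
        raise ValidationError(f"non-ACGT base in {ref}>{alt} at {context}")
    if context[1] != ref:
        raise ValidationError(
            f"context middle base {context[1]!r} does not match ref {ref!r}"
        )
    if alt == ref:
        raise ValidationError(f"alt equals ref in {ref}>{alt}")
    if ref in ("A", "G"):  # purine frame: reverse complement
        context = "".join(_COMPLEMENT[b] for b in reversed(context))
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def parse_context_label(label: str) -> tuple[str, str, str]:
    """Inverse of :func:`context_label`: returns (ref, alt, 3-mer context)."""
    if label not in _LABEL_INDEX:
        raise ValidationError(f"unknown context label {label!r}")
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    return ref, alt, f"{five}{ref}{three}"


@dataclass(frozen=True)
class ContextProfile:
    """Counts of a sample's substitutions over the 96 context bins."""

    counts: np.ndarray  # (96,) nonnegative ints
    n_invalid: int = 0
    sample_id: str | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        object.__setattr__(self, "counts", c)
        if c.shape != (96,):
            raise ValidationError(f"profile must have 96 bins, got {c.shape}")
        if np.any(c < 0):
            raise ValidationError("negative context counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalize an empty profile")
        return self.counts / self.total


@dataclass(frozen=True)
class SignatureExposure:
    """Nonnegative signature weights reconstructing one sample's profile."""

    exposures: dict[str, float]  # signature name -> weight (only survivors)
    residual: float
    reconstruction_cosine: float
    flags: tuple[str, ...] = ()
    sample_id: str | None = None

    def weight(self, name: str) -> float:
        return self.exposures.get(name, 0.0)


FLAG_LOW_COUNT = "LOW_COUNT"


def count_contexts(
    substitutions: Iterable[tuple[str, str, str]], sample_id: str | None = None
) -> ContextProfile:
    """Tally (ref, alt, 3-mer context) substitutions into a 96-bin profile.

    Invalid records (middle base mismatch, non-SNV, non-ACGT) are counted
    in ``n_invalid`` and reported, never silently dropped.
    """
    counts = np.zeros(96, dtype=int)
    n_invalid = 0
    for ref, alt, context in substitutions:
        try:
            label = context_label(ref, alt, context)
        except ValidationError:
            n_invalid += 1
            continue
        counts[_LABEL_INDEX[label]] += 1
    return ContextProfile(counts=counts, n_invalid=n_invalid, sample_id=sample_id)


def refit_exposures(
    profile: ContextProfile,
    reference: SignatureMatrix,
    min_weight: float = 0.06,
    min_mutations: int = 20,
) -> SignatureExposure:
    """Refit a profile against reference signatures by iterative NNLS.

    Signatures whose fitted weight falls below ``min_weight`` are removed
    and the fit repeated on the surviving set until stable.  Profiles with
    fewer than ``min_mutations`` substitutions are fitted but flagged
    ``LOW_COUNT``.  Invariant to profile scaling.
    """
    if profile.total == 0:
        raise ValueError("cannot refit an empty profile")
    if len(reference.names) < 1:
        raise ValueError("reference matrix has no signature columns")
    ref = reference.reordered(CONTEXT_LABELS_96)
    target = profile.normalized()
    active = list(range(len(ref.names)))
    weights = np.zeros(len(ref.names))
    while True:
        w_active, _ = nnls(ref.weights[:, active], target)
        weights = np.zeros(len(ref.names))
        weights[active] = w_active
        drop = [j for j, w in zip(active, w_active) if w < min_weight]
        survivors = [j for j in active if j not in drop]
        if not survivors:
            # keep the single best signature rather than returning nothing
            best = active[int(np.argmax(w_active))]
            w_best, _ = nnls(ref.weights[:, [best]], target)
            weights = np.zeros(len(ref.names))
            weights[best] = w_best[0]
            active = [best]
            break
        if survivors == active:
            break
        active = survivors
    total = weights.sum()
    if total > 1.0:
        weights = weights / total
    reconstruction = ref.weights @ weights
    denom = np.linalg.norm(reconstruction) * np.linalg.norm(target)
    cosine = float(reconstruction @ target / denom) if denom > 0 else 0.0
    flags = (FLAG_LOW_COUNT,) if profile.total < min_mutations else ()
    exposures = {
        ref.names[j]: float(weights[j]) for j in range(len(ref.names)) if weights[j] > 0
    }
    return SignatureExposure(
        exposures=exposures,
        residual=float(max(0.0, 1.0 - weights.sum())),
        reconstruction_cosine=cosine,
        flags=flags,
        sample_id=profile.sample_id,
    )


def write_profile(path, profile: ContextProfile) -> None:
    lines = ["#context\tcount"]
    for label, count in zip(CONTEXT_LABELS_96, profile.counts):
        lines.append(f"{label}\t{int(count)}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_exposures(path, exposure: SignatureExposure) -> None:
    lines = ["#signature\tweight"]
    for name in sorted(exposure.exposures):
        lines.append(f"{name}\t{exposure.exposures[name]!r}")
    lines.append(f"__residual__\t{exposure.residual!r}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
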