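"""Typed records and readers/writers for the pipeline's external file formats.

Everything downstream of this module consumes typed records
(:class:`VariantCall`, :class:`CnaSegment`, :class:`SampleMeta`,
:class:`SignatureMatrix`) rather than raw files.

The canonical on-disk dialect is tab-separated UTF-8 with a single
``#``-prefixed header line and ``.`` for missing values.  Files written by
this module round-trip byte-identically (floats are serialized with their
shortest exact ``repr``).  Genomic intervals are 0-based half-open
internally; VCF positions are converted from/to 1-based at the boundary.

Variants on non-autosomes other than X (Y, MT) are accepted by the readers
but are excluded from clustering downstream: the read-count correction
rules cover autosomes and the male X only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "ValidationError",
    "Annotation",
    "CnaState",
    "LesionType",
    "Sex",
    "VariantCall",
    "CnaSegment",
    "HetSnp",
    "SampleMeta",
    "SignatureMatrix",
    "read_variants",
    "write_variants",
    "read_segments",
    "write_segments",
    "read_het_snps",
    "write_het_snps",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_signature_matrix",
    "write_signature_matrix",
    "normalize_chrom",
    "is_autosome",
    "is_x",
]

MISSING = "."


class FormatError(ValueError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(ValueError):
    """A record violates an invariant (reported with its line number)."""


class Annotation(enum.Enum):
    SILENT = "SILENT"
    NONSILENT = "NONSILENT"
    UNKNOWN = "UNKNOWN"


class CnaState(enum.Enum):
    """Copy-state of a genomic segment.

    AMP: one homolog gained (BAF deviates, coverage up).
    DEL: one homolog lost (BAF deviates, coverage down).
    CN_LOH: copy-neutral loss of heterozygosity (BAF deviates, coverage flat).
    NEUTRAL: diploid heterozygous.
    """

    AMP = "AMP"
    DEL = "DEL"
    CN_LOH = "CN_LOH"
    NEUTRAL = "NEUTRAL"


class LesionType(enum.Enum):
    PRIMARY = "PRIMARY"
    METASTASIS = "METASTASIS"
    RECURRENCE = "RECURRENCE"


class Sex(enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix and uppercase X/Y/MT for comparisons."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return c.upper() if c.lower() in ("x", "y", "mt", "m") else c


def is_autosome(chrom: str) -> bool:
    c = normalize_chrom(chrom)
    return c.isdigit() and 1 <= int(c) <= 22


def is_x(chrom: str) -> bool:
    return normalize_chrom(chrom) == "X"


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant observed in one sample.

    ``pos`` is 1-based (as in VCF).  ``context`` is the 3-mer reference
    context centred on the variant, or ``None`` when unknown.  ``gene`` is
    an optional symbol used for driver-persistence reporting.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_count: int
    alt_count: int
    context: str | None = None
    annotation: Annotation = Annotation.UNKNOWN
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(
                f"negative read count for {self.chrom}:{self.pos}"
            )
        if self.alt_allele == self.ref_allele:
            raise ValidationError(
                f"alt allele equals ref allele at {self.chrom}:{self.pos}"
            )

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            return 0.0
        return self.alt_count / self.depth


@dataclass(frozen=True)
class CnaSegment:
    """A genomic interval with a copy-state call (0-based half-open)."""

    chrom: str
    start: int
    end: int
    state: CnaState
    arm: str | None = None
    baf_dev: float | None = None
    cov_ratio: float | None = None
    n_snps: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"segment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.baf_dev is not None and not (0.0 <= self.baf_dev <= 0.5):
            raise ValidationError(f"baf_dev outside [0, 0.5]: {self.baf_dev}")
        if self.cov_ratio is not None and self.cov_ratio <= 0:
            raise ValidationError(f"cov_ratio must be positive: {self.cov_ratio}")

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether the 1-based position falls inside this segment."""
        return self.chrom == chrom and self.start <= pos - 1 < self.end


@dataclass(frozen=True)
class HetSnp:
    """A heterozygous germline SNP carrying B-allele-frequency evidence."""

    chrom: str
    pos: int
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(f"negative read count at {self.chrom}:{self.pos}")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def baf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.5


@dataclass(frozen=True)
class SampleMeta:
    """Clinical annotations for one sequenced lesion.

    ``tumor_content`` is the histology-estimated fraction of tumor cells
    (purity), in (0, 1].  ``interval_therapy`` flags systemic therapy given
    since the previous resection of the same patient.  ``assay``
    distinguishes whole-exome from ultra-deep targeted samples; the two are
    kept as separate samples, never merged.
    """

    sample_id: str
    patient_id: str
    lesion_type: LesionType
    site: str
    resection_index: int
    interval_therapy: bool
    tumor_content: float
    sex: Sex = Sex.UNKNOWN
    assay: str = "WES"

    def __post_init__(self) -> None:
        if not (0.0 < self.tumor_content <= 1.0):
            raise ValidationError(
                f"tumor_content must be in (0, 1], got {self.tumor_content} "
                f"for sample {self.sample_id}"
            )
        if self.resection_index < 1:
            raise ValidationError(
                f"resection_index must be >= 1 for sample {self.sample_id}"
            )


@dataclass(frozen=True)
class SignatureMatrix:
    """Reference mutational signatures over the 96 trinucleotide contexts.

    ``weights`` is a 96 x S column-stochastic matrix: column *j* is the
    probability distribution of signature ``names[j]`` over ``contexts``.
    """

    contexts: tuple[str, ...]
    names: tuple[str, ...]
    weights: np.ndarray  # shape (96, S)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if len(self.contexts) != 96 or w.shape != (96, len(self.names)):
            raise ValidationError(
                f"signature matrix must be 96 x S, got {w.shape} with "
                f"{len(self.contexts)} context labels"
            )
        if np.any(w < 0):
            raise ValidationError("signature weights must be nonnegative")
        sums = w.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = [self.names[j] for j in np.where(np.abs(sums - 1.0) > 1e-6)[0]]
            raise ValidationError(f"signature columns must sum to 1: {bad}")

    def column(self, name: str) -> np.ndarray:
        return self.weights[:, self.names.index(name)]

    def reordered(self, contexts: Sequence[str]) -> "SignatureMatrix":
        """Return a copy with rows permuted into the given context order."""
        index = {c: i for i, c in enumerate(self.contexts)}
        try:
            rows = [index[c] for c in contexts]
        except KeyError as exc:
            raise ValidationError(f"context label missing from matrix: {exc}")
        return SignatureMatrix(
            tuple(contexts), self.names, self.weights[rows, :]
        )


# ---------------------------------------------------------------------------
# Low-level TSV helpers
# ---------------------------------------------------------------------------


def _fmt_float(x: float | None) -> str:
    if x is None:
        return MISSING
    return repr(float(x))


def _read_table(path: str | Path, required: Sequence[str]):
    """Parse a canonical TSV into (header, rows-with-line-numbers).

    Raises :class:`FormatError` naming the first missing required column.
    Never silently drops a data line.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file, expected a '#'-prefixed header")
    header_line = lines[0]
    if not header_line.startswith("#"):
        raise FormatError(f"{path}: first line must be a '#'-prefixed header")
    header = header_line.lstrip("#").rstrip("\n").split("\t")
    for col in required:
        if col not in header:
            raise FormatError(f"{path}: missing required column '{col}'")
    idx = {c: i for i, c in enumerate(header)}
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}, line {lineno}: expected {len(header)} fields, "
                f"got {len(fields)}"
            )
        rows.append((lineno, {c: fields[i] for c, i in idx.items()}))
    return header, rows


def _opt(value: str | None) -> str | None:
    return None if value is None or value == MISSING else value


def _parse_int(value: str, what: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValidationError(f"line {lineno}: {what} is not an integer: {value!r}")


def _parse_float(value: str, what: str, lineno: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValidationError(f"line {lineno}: {what} is not a number: {value!r}")


def _parse_bool(value: str, what: str, lineno: int) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise ValidationError(f"line {lineno}: {what} is not a boolean: {value!r}")


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_count",
    "alt_count",
    "context",
    "annotation",
    "gene",
)


def read_variants(
    path: str | Path, format: str = "tsv", sample: str | None = None
) -> list[VariantCall]:
    """Read somatic variants from a canonical TSV or a VCF.

    For VCF input, per-sample ref/alt depths are taken from the AD format
    field; ``sample`` selects the column (defaults to the only sample).
    Input order is preserved; ``variant_id`` must be unique per file.
    """
    if format.lower() == "vcf":
        records = _read_variants_vcf(path, sample)
    elif format.lower() == "tsv":
        records = _read_variants_tsv(path)
    else:
        raise ValueError(f"unknown variant format: {format!r}")
    seen: set[str] = set()
    for rec in records:
        if rec.variant_id in seen:
            raise ValidationError(f"duplicate variant_id: {rec.variant_id}")
        seen.add(rec.variant_id)
    return records


def _read_variants_tsv(path: str | Path) -> list[VariantCall]:
    _, rows = _read_table(
        path, required=("chrom", "pos", "ref", "alt", "ref_count", "alt_count")
    )
    out = []
    for lineno, row in rows:
        ref_count = _parse_int(row["ref_count"], "ref_count", lineno)
        alt_count = _parse_int(row["alt_count"], "alt_count", lineno)
        if ref_count < 0 or alt_count < 0:
            raise ValidationError(f"line {lineno}: negative read count")
        ann = _opt(row.get("annotation"))
        try:
            out.append(
                VariantCall(
                    chrom=row["chrom"],
                    pos=_parse_int(row["pos"], "pos", lineno),
                    ref_allele=row["ref"],
                    alt_allele=row["alt"],
                    ref_count=ref_count,
                    alt_count=alt_count,
                    context=_opt(row.get("context")),
                    annotation=Annotation(ann) if ann else Annotation.UNKNOWN,
                    gene=_opt(row.get("gene")),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}")
    return out


def _read_variants_vcf(path: str | Path, sample: str | None) -> list[VariantCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample is None:
        if len(samples) != 1:
            raise FormatError(
                f"{path}: multi-sample VCF, specify sample= (have {samples})"
            )
        sidx = 0
    else:
        if sample not in samples:
            raise FormatError(f"{path}: sample {sample!r} not in VCF ({samples})")
        sidx = samples.index(sample)
    out = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise FormatError(f"{path}: VCF record at {rec.CHROM}:{rec.POS} lacks AD")
        ref_count = int(ad[sidx][0])
        alt_count = int(ad[sidx][1])
        context = rec.INFO.get("CONTEXT")
        out.append(
            VariantCall(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                ref_count=max(ref_count, 0),
                alt_count=max(alt_count, 0),
                context=context,
            )
        )
    return out


def write_variants(path: str | Path, records: Iterable[VariantCall]) -> None:
    lines = ["#" + "\t".join(_VARIANT_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    str(r.pos),
                    r.ref_allele,
                    r.alt_allele,
                    str(r.ref_count),
                    str(r.alt_count),
                    r.context if r.context is not None else MISSING,
                    r.annotation.value,
                    r.gene if r.gene is not None else MISSING,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------

_SEGMENT_COLUMNS = ("chrom", "start", "end", "state", "arm", "baf_dev", "cov_ratio", "n_snps")


def read_segments(path: str | Path) -> list[CnaSegment]:
    """Read a BED-like copy-state segment table (0-based half-open).

    Overlapping segments on the same chromosome are rejected.
    """
    _, rows = _read_table(path, required=("chrom", "start", "end", "state"))
    out = []
    for lineno, row in rows:
        state_label = row["state"]
        try:
            state = CnaState(state_label)
        except ValueError:
            allowed = ", ".join(s.value for s in CnaState)
            raise ValidationError(
                f"line {lineno}: unknown state {state_label!r}; allowed: {allowed}"
            )
        start = _parse_int(row["start"], "start", lineno)
        end = _parse_int(row["end"], "end", lineno)
        if end <= start:
            raise ValidationError(f"line {lineno}: end ({end}) <= start ({start})")
        baf_dev = _opt(row.get("baf_dev"))
        cov_ratio = _opt(row.get("cov_ratio"))
        n_snps = _opt(row.get("n_snps"))
        out.append(
            CnaSegment(
                chrom=row["chrom"],
                start=start,
                end=end,
                state=state,
                arm=_opt(row.get("arm")),
                baf_dev=_parse_float(baf_dev, "baf_dev", lineno) if baf_dev else None,
                cov_ratio=_parse_float(cov_ratio, "cov_ratio", lineno)
                if cov_ratio
                else None,
                n_snps=_parse_int(n_snps, "n_snps", lineno) if n_snps else None,
            )
        )
    _check_no_overlap(out)
    return out


def _check_no_overlap(segments: Sequence[CnaSegment]) -> None:
    by_chrom: dict[str, list[CnaSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def write_segments(path: str | Path, segments: Iterable[CnaSegment]) -> None:
    lines = ["#" + "\t".join(_SEGMENT_COLUMNS)]
    for s in segments:
        lines.append(
            "\t".join(
                [
                    s.chrom,
                    str(s.start),
                    str(s.end),
                    s.state.value,
                    s.arm if s.arm is not None else MISSING,
                    _fmt_float(s.baf_dev),
                    _fmt_float(s.cov_ratio),
                    str(s.n_snps) if s.n_snps is not None else MISSING,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Het SNPs
# ---------------------------------------------------------------------------


def read_het_snps(path: str | Path) -> list[HetSnp]:
    _, rows = _read_table(path, required=("chrom", "pos", "ref_count", "alt_count"))
    out = []
    for lineno, row in rows:
        ref_count = _parse_int(row["ref_count"], "ref_count", lineno)
        alt_count = _parse_int(row["alt_count"], "alt_count", lineno)
        if ref_count < 0 or alt_count < 0:
            raise ValidationError(f"line {lineno}: negative read count")
        out.append(
            HetSnp(
                chrom=row["chrom"],
                pos=_parse_int(row["pos"], "pos", lineno),
                ref_count=ref_count,
                alt_count=alt_count,
            )
        )
    return out


def write_het_snps(path: str | Path, snps: Iterable[HetSnp]) -> None:
    lines = ["#chrom\tpos\tref_count\talt_count"]
    for s in snps:
        lines.append(f"{s.chrom}\t{s.pos}\t{s.ref_count}\t{s.alt_count}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = (
    "sample_id",
    "patient_id",
    "lesion_type",
    "site",
    "resection_index",
    "interval_therapy",
    "tumor_content",
    "sex",
    "assay",
)


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the per-lesion sample sheet.

    Enforces unique sample ids and, per patient, unique resection indices
    contiguous from 1.
    """
    _, rows = _read_table(
        path,
        required=(
            "sample_id",
            "patient_id",
            "lesion_type",
            "site",
            "resection_index",
            "interval_therapy",
            "tumor_content",
        ),
    )
    out = []
    seen_ids: set[str] = set()
    for lineno, row in rows:
        sample_id = row["sample_id"]
        if sample_id in seen_ids:
            raise ValidationError(f"line {lineno}: duplicate sample_id {sample_id!r}")
        seen_ids.add(sample_id)
        try:
            lesion_type = LesionType(row["lesion_type"])
        except ValueError:
            raise ValidationError(
                f"line {lineno}: unknown lesion_type {row['lesion_type']!r}"
            )
        sex_label = _opt(row.get("sex"))
        try:
            meta = SampleMeta(
                sample_id=sample_id,
                patient_id=row["patient_id"],
                lesion_type=lesion_type,
                site=row["site"],
                resection_index=_parse_int(
                    row["resection_index"], "resection_index", lineno
                ),
                interval_therapy=_parse_bool(
                    row["interval_therapy"], "interval_therapy", lineno
                ),
                tumor_content=_parse_float(
                    row["tumor_content"], "tumor_content", lineno
                ),
                sex=Sex(sex_label) if sex_label else Sex.UNKNOWN,
                assay=_opt(row.get("assay")) or "WES",
            )
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}")
        out.append(meta)
    by_patient: dict[str, list[int]] = {}
    for m in out:
        by_patient.setdefault(m.patient_id, []).append(m.resection_index)
    for patient, indices in by_patient.items():
        if sorted(indices) != list(range(1, len(indices) + 1)):
            raise ValidationError(
                f"patient {patient}: resection_index values must be unique "
                f"and contiguous from 1, got {sorted(indices)}"
            )
    return out


def write_sample_sheet(path: str | Path, metas: Iterable[SampleMeta]) -> None:
    lines = ["#" + "\t".join(_SHEET_COLUMNS)]
    for m in metas:
        lines.append(
            "\t".join(
                [
                    m.sample_id,
                    m.patient_id,
                    m.lesion_type.value,
                    m.site,
                    str(m.resection_index),
                    "true" if m.interval_therapy else "false",
                    repr(float(m.tumor_content)),
                    m.sex.value,
                    m.assay,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Signature matrix
# ---------------------------------------------------------------------------


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read a 96-row reference signature matrix (rows labelled 'A[C>A]A')."""
    header, rows = _read_table(path, required=("context",))
    names = tuple(c for c in header if c != "context")
    if not names:
        raise FormatError(f"{path}: signature matrix has no signature columns")
    contexts = []
    weights = []
    for lineno, row in rows:
        contexts.append(row["context"])
        weights.append(
            [_parse_float(row[n], f"weight[{n}]", lineno) for n in names]
        )
    return SignatureMatrix(tuple(contexts), names, np.array(weights, dtype=float))


def write_signature_matrix(path: str | Path, matrix: SignatureMatrix) -> None:
    lines = ["#context\t" + "\t".join(matrix.names)]
    for i, ctx in enumerate(matrix.contexts):
        lines.append(
            ctx + "\t" + "\t".join(repr(float(w)) for w in matrix.weights[i])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
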