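"""Forward simulation of multi-lesion patients with known ground truth.

The generator emulates the study design every downstream stage expects:
patient-matched lesions sharing a clone tree, lesion-private subclones,
arm-level copy-number aberrations, histology-scale purities (30-80%), and
binomial read sampling at whole-exome (~95x) or ultra-deep targeted
(~25000x) depth.

For a mutation carried by clone *c* (cellular proportion *p* in lesion
*l*), in a lesion of purity *pi*, at a locus whose copy state implies
total tumor copy number *C* and mutation multiplicity *m*:

    expected VAF = pi * p * m / (pi * C + 2 * (1 - pi))

with (C, m) = NEUTRAL (2, 1); AMP (3, 2) — the gain duplicates the
mutated allele, matching the correction module's "largest extent"
assumption (an ``amp_on_mutated_allele=False`` flag gives (3, 1) to test
robustness to the alternative); DEL (1, 1) — the reference copy is lost;
CN_LOH (2, 2).  Site depth is Poisson(assay mean), alt reads are
Binomial(depth, expected VAF); there is no sequencing-error model beyond
the binomial sampling.  Het SNPs for the CNA caller are emitted per arm
with B-allele fractions implied by the same copy states and purity.

Identical config + seed produces byte-identical output files, and the
closed-form expected VAF for every emitted variant is serialized in the
truth record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cna import Arm, load_arm_table
from .io_formats import (
    Annotation,
    CnaSegment,
    CnaState,
    HetSnp,
    LesionType,
    SampleMeta,
    Sex,
    SignatureMatrix,
    VariantCall,
    write_het_snps,
    write_sample_sheet,
    write_segments,
    write_variants,
)
from .signatures import CONTEXT_LABELS_96, parse_context_label

__all__ = [
    "LesionSpec",
    "CloneSpec",
    "CnaSpec",
    "SimConfig",
    "SimulatedPatient",
    "expected_vaf",
    "simulate_patient",
    "simulate_signature_mutations",
    "synthetic_signature_matrix",
    "three_clone_two_lesion_config",
    "arm_recovery_config",
]

#: (total tumor copy number C, mutation multiplicity m) per copy state,
#: under the mutated-allele-gain convention.
_STATE_CN = {
    CnaState.NEUTRAL: (2, 1),
    CnaState.AMP: (3, 2),
    CnaState.DEL: (1, 1),
    CnaState.CN_LOH: (2, 2),
}

#: Homolog copy numbers (affected homolog, other homolog) per state, for
#: het-SNP B-allele fractions.
_STATE_HOMOLOGS = {
    CnaState.NEUTRAL: (1, 1),
    CnaState.AMP: (2, 1),
    CnaState.DEL: (1, 0),
    CnaState.CN_LOH: (2, 0),
}


class ConfigError(ValueError):
    """An inconsistent simulation configuration."""


@dataclass(frozen=True)
class LesionSpec:
    """One simulated lesion: site, purity and sequencing depth."""

    sample_id: str
    lesion_type: LesionType = LesionType.METASTASIS
    site: str = "liver"
    purity: float = 0.6
    depth_mean: float = 95.0  # whole-exome scale; targeted assays use ~25000
    het_depth_mean: float | None = None  # defaults to depth_mean
    therapy_before: bool = False
    assay: str = "WES"

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ConfigError(f"purity must be in (0, 1], got {self.purity}")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")


@dataclass(frozen=True)
class CloneSpec:
    """A truth clone: its mutations and per-lesion cellular proportions."""

    clone_id: str
    n_mutations: int
    proportions: Mapping[str, float]  # sample_id -> proportion in [0, 1]
    parent_id: str | None = None
    drivers: tuple[str, ...] = ()  # gene symbols, one mutation each
    signature_mixture: Mapping[str, float] | None = None  # signature name -> weight


@dataclass(frozen=True)
class CnaSpec:
    """An arm-level aberration, optionally restricted to some lesions."""

    arm: str
    state: CnaState
    samples: tuple[str, ...] = ()  # empty tuple = all lesions


@dataclass(frozen=True)
class SimConfig:
    patient_id: str
    lesions: tuple[LesionSpec, ...]
    clones: tuple[CloneSpec, ...]
    cnas: tuple[CnaSpec, ...] = ()
    n_het_snps_per_arm: int = 200
    sex: Sex = Sex.FEMALE
    seed: int = 0
    amp_on_mutated_allele: bool = True
    reference_signatures: SignatureMatrix | None = None


@dataclass
class SimulatedPatient:
    """Everything one simulation emits, plus the serializable truth."""

    config: SimConfig
    sample_sheet: list[SampleMeta]
    variants: dict[str, list[VariantCall]]  # sample_id -> calls
    het_snps: dict[str, list[HetSnp]]
    segments: dict[str, list[CnaSegment]]  # truth aberrant segments per lesion
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Emit the exact file formats the readers consume, plus truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sample_sheet(outdir / "sample_sheet.tsv", self.sample_sheet)
        for sample_id in sorted(self.variants):
            write_variants(outdir / f"{sample_id}.variants.tsv", self.variants[sample_id])
            write_het_snps(outdir / f"{sample_id}.het_snps.tsv", self.het_snps[sample_id])
            write_segments(outdir / f"{sample_id}.segments.tsv", self.segments[sample_id])
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True), encoding="utf-8"
        )


def expected_vaf(purity, proportion, state: CnaState, amp_on_mutated_allele: bool = True):
    """Closed-form expected VAF; exact when given Fractions.

    ``pi * p * m / (pi * C + 2 * (1 - pi))`` with (C, m) from the copy
    state; the copy-number aberration is carried by all tumor cells.
    """
    C, m = _STATE_CN[state]
    if state is CnaState.AMP and not amp_on_mutated_allele:
        m = 1
    ev = purity * proportion * m / (purity * C + 2 * (1 - purity))
    if ev > 1:
        raise ConfigError(
            f"config implies expected VAF {ev} > 1 for state {state.value}"
        )
    return ev


def _coverage_ratio(purity: float, state: CnaState) -> float:
    """Locus coverage relative to diploid: (pi*C + 2(1-pi)) / 2."""
    C, _ = _STATE_CN[state]
    return (purity * C + 2 * (1 - purity)) / 2.0


def _validate_clone_tree(config: SimConfig) -> None:
    ids = [c.clone_id for c in config.clones]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate clone_id")
    by_id = {c.clone_id: c for c in config.clones}
    samples = [l.sample_id for l in config.lesions]
    if len(set(samples)) != len(samples):
        raise ConfigError("duplicate sample_id among lesions")
    children: dict[str | None, list[CloneSpec]] = {}
    for c in config.clones:
        if c.parent_id is not None and c.parent_id not in by_id:
            raise ConfigError(f"clone {c.clone_id}: unknown parent {c.parent_id}")
        children.setdefault(c.parent_id, []).append(c)
        for sample_id, p in c.proportions.items():
            if sample_id not in samples:
                raise ConfigError(
                    f"clone {c.clone_id}: proportion for unknown lesion {sample_id}"
                )
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"clone {c.clone_id}: proportion {p} outside [0, 1]")
    eps = 1e-9
    for sample_id in samples:
        for parent_id, kids in children.items():
            total = sum(k.proportions.get(sample_id, 0.0) for k in kids)
            limit = (
                1.0
                if parent_id is None
                else by_id[parent_id].proportions.get(sample_id, 0.0)
            )
            if total > limit + eps:
                raise ConfigError(
                    f"lesion {sample_id}: children of {parent_id or 'root'} sum to "
                    f"{total} > {limit}"
                )


def _arm_states(config: SimConfig, sample_id: str, arms: Sequence[Arm]) -> dict[str, CnaState]:
    known = {a.name for a in arms}
    states: dict[str, CnaState] = {}
    for spec in config.cnas:
        if spec.arm not in known:
            raise ConfigError(f"unknown arm in CNA spec: {spec.arm}")
        if spec.samples and sample_id not in spec.samples:
            continue
        if spec.arm in states:
            raise ConfigError(f"conflicting CNA specs for arm {spec.arm}")
        states[spec.arm] = spec.state
    return states


def _draw_context(rng: np.random.Generator, mixture, reference) -> str:
    if mixture is None or reference is None:
        return CONTEXT_LABELS_96[rng.integers(96)]
    names = sorted(mixture)
    probs = np.array([mixture[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    name = names[rng.choice(len(names), p=probs)]
    col = reference.column(name)
    return reference.contexts[rng.choice(96, p=col / col.sum())]


def simulate_patient(config: SimConfig) -> SimulatedPatient:
    """Run the forward model; deterministic given config.seed."""
    _validate_clone_tree(config)
    arms = load_arm_table()
    autosomal_arms = [a for a in arms if a.chrom != "chrX"]
    lengths = np.array([a.length for a in autosomal_arms], dtype=float)
    arm_probs = lengths / lengths.sum()
    rng = np.random.default_rng(config.seed)

    # --- assign loci, contexts and genes to every truth mutation ---------
    mutations = []  # (mutation_id, clone, arm, pos, ref, alt, context, gene, annotation)
    used_positions: set[tuple[str, int]] = set()
    for clone in config.clones:
        for i in range(clone.n_mutations):
            while True:
                arm = autosomal_arms[rng.choice(len(autosomal_arms), p=arm_probs)]
                pos = int(rng.integers(arm.start + 1, arm.end + 1))  # 1-based
                if (arm.chrom, pos) not in used_positions:
                    used_positions.add((arm.chrom, pos))
                    break
            label = _draw_context(
                rng, clone.signature_mixture, config.reference_signatures
            )
            ref, alt, context = parse_context_label(label)
            gene = clone.drivers[i] if i < len(clone.drivers) else None
            annotation = (
                Annotation.NONSILENT
                if gene is not None or rng.random() < 0.7
                else Annotation.SILENT
            )
            mutations.append(
                {
                    "clone": clone,
                    "arm": arm,
                    "chrom": arm.chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "context": context,
                    "gene": gene,
                    "annotation": annotation,
                }
            )

    # --- het SNP loci, shared across lesions -----------------------------
    snp_loci = []  # (arm, pos, b_on_affected_homolog)
    for arm in arms:
        if arm.chrom == "chrX" and config.sex is Sex.MALE:
            continue  # male X carries no het SNPs
        n_snps = min(config.n_het_snps_per_arm, arm.length)
        chosen: set[int] = set()
        while len(chosen) < n_snps:  # collisions are vanishingly rare
            chosen.add(int(rng.integers(arm.start + 1, arm.end + 1)))
        positions = sorted(chosen)
        b_sides = rng.random(len(positions)) < 0.5
        for pos, b_side in zip(positions, b_sides):
            snp_loci.append((arm, int(pos), bool(b_side)))

    # --- per-lesion sampling ---------------------------------------------
    sample_sheet = []
    variants: dict[str, list[VariantCall]] = {}
    het_snps: dict[str, list[HetSnp]] = {}
    segments: dict[str, list[CnaSegment]] = {}
    truth_variants: dict[str, dict] = {}
    arm_by_name = {a.name: a for a in arms}

    for index, lesion in enumerate(config.lesions, start=1):
        states = _arm_states(config, lesion.sample_id, arms)
        pi = lesion.purity
        segs = []
        for arm_name in sorted(states):
            a = arm_by_name[arm_name]
            segs.append(
                CnaSegment(
                    chrom=a.chrom, start=a.start, end=a.end,
                    state=states[arm_name], arm=arm_name,
                )
            )
        segments[lesion.sample_id] = segs
        sample_sheet.append(
            SampleMeta(
                sample_id=lesion.sample_id,
                patient_id=config.patient_id,
                lesion_type=lesion.lesion_type,
                site=lesion.site,
                resection_index=index,
                interval_therapy=lesion.therapy_before,
                tumor_content=pi,
                sex=config.sex,
                assay=lesion.assay,
            )
        )

        lesion_variants = []
        for mut in mutations:
            p = mut["clone"].proportions.get(lesion.sample_id, 0.0)
            state = states.get(mut["arm"].name, CnaState.NEUTRAL)
            ev = (
                float(expected_vaf(pi, p, state, config.amp_on_mutated_allele))
                if p > 0
                else 0.0
            )
            cov_ratio = _coverage_ratio(pi, state)
            vid = f"{mut['chrom']}:{mut['pos']}:{mut['ref']}>{mut['alt']}"
            entry = truth_variants.setdefault(
                vid,
                {
                    "clone_id": mut["clone"].clone_id,
                    "gene": mut["gene"],
                    "context": mut["context"],
                    "lesions": {},
                },
            )
            depth = int(rng.poisson(lesion.depth_mean * cov_ratio))
            alt_count = int(rng.binomial(depth, ev)) if depth > 0 and ev > 0 else 0
            entry["lesions"][lesion.sample_id] = {
                "proportion": p,
                "state": state.value,
                "expected_vaf": ev,
            }
            if alt_count == 0:
                continue  # not observed in this lesion
            lesion_variants.append(
                VariantCall(
                    chrom=mut["chrom"],
                    pos=mut["pos"],
                    ref_allele=mut["ref"],
                    alt_allele=mut["alt"],
                    ref_count=depth - alt_count,
                    alt_count=alt_count,
                    context=mut["context"],
                    annotation=mut["annotation"],
                    gene=mut["gene"],
                )
            )
        variants[lesion.sample_id] = lesion_variants

        het_depth = lesion.het_depth_mean or lesion.depth_mean
        lesion_snps = []
        for arm, pos, b_on_affected in snp_loci:
            state = states.get(arm.name, CnaState.NEUTRAL)
            affected, other = _STATE_HOMOLOGS[state]
            c_b = affected if b_on_affected else other
            c_total = affected + other
            b_frac = (pi * c_b + (1 - pi)) / (pi * c_total + 2 * (1 - pi))
            depth = int(rng.poisson(het_depth * _coverage_ratio(pi, state)))
            if depth == 0:
                continue
            alt_count = int(rng.binomial(depth, b_frac))
            lesion_snps.append(
                HetSnp(chrom=arm.chrom, pos=pos, ref_count=depth - alt_count, alt_count=alt_count)
            )
        het_snps[lesion.sample_id] = lesion_snps

    truth = {
        "patient_id": config.patient_id,
        "seed": config.seed,
        "amp_on_mutated_allele": config.amp_on_mutated_allele,
        "clones": [
            {
                "clone_id": c.clone_id,
                "parent_id": c.parent_id,
                "n_mutations": c.n_mutations,
                "proportions": dict(c.proportions),
                "drivers": list(c.drivers),
            }
            for c in config.clones
        ],
        "cnas": [
            {"arm": s.arm, "state": s.state.value, "samples": list(s.samples)}
            for s in config.cnas
        ],
        "lesions": [
            {"sample_id": l.sample_id, "purity": l.purity, "depth_mean": l.depth_mean}
            for l in config.lesions
        ],
        "variants": truth_variants,
    }
    return SimulatedPatient(
        config=config,
        sample_sheet=sample_sheet,
        variants=variants,
        het_snps=het_snps,
        segments=segments,
        truth=truth,
    )


def simulate_signature_mutations(
    n: int,
    mixture: Sequence[float],
    reference: SignatureMatrix,
    seed: int,
) -> tuple[list[tuple[str, str, str]], dict[str, float]]:
    """Draw substitutions from a mixture of reference signature columns.

    Returns ``(substitutions, truth_mixture)`` where each substitution is
    a (ref, alt, 3-mer context) triple in the pyrimidine frame.
    """
    mixture = np.asarray(mixture, dtype=float)
    if mixture.size == 0:
        raise ConfigError("empty signature mixture")
    if mixture.size != len(reference.names):
        raise ConfigError("mixture length does not match reference columns")
    if np.any(mixture < 0) or not np.isclose(mixture.sum(), 1.0):
        raise ConfigError("mixture weights must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    ref96 = reference.reordered(CONTEXT_LABELS_96)
    subs = []
    for _ in range(n):
        j = int(rng.choice(len(mixture), p=mixture))
        col = ref96.weights[:, j]
        label = CONTEXT_LABELS_96[int(rng.choice(96, p=col / col.sum()))]
        subs.append(parse_context_label(label))
    truth = {name: float(w) for name, w in zip(reference.names, mixture)}
    return subs, truth


def synthetic_signature_matrix(
    n_signatures: int = 2, seed: int = 0, disjoint: bool = True
) -> SignatureMatrix:
    """Generate synthetic reference signatures for tests and simulations.

    These are random sparse distributions over the 96 bins, not COSMIC
    signatures; real reference matrices are user-supplied input.  With
    ``disjoint=True`` each signature is supported on its own block of
    bins, making exposures identifiable by construction.
    """
    if n_signatures < 1:
        raise ConfigError("need at least one signature")
    rng = np.random.default_rng(seed)
    weights = np.zeros((96, n_signatures))
    if disjoint:
        blocks = np.array_split(np.arange(96), n_signatures)
        for j, block in enumerate(blocks):
            w = rng.dirichlet(np.full(len(block), 0.5))
            weights[block, j] = w
    else:
        for j in range(n_signatures):
            weights[:, j] = rng.dirichlet(np.full(96, 0.3))
    names = tuple(f"SYN{j + 1}" for j in range(n_signatures))
    return SignatureMatrix(CONTEXT_LABELS_96, names, weights)


# ---------------------------------------------------------------------------
# Canonical study-condition scenarios
# ---------------------------------------------------------------------------


def three_clone_two_lesion_config(
    seed: int,
    n_mutations: int = 100,
    depth_mean: float = 100.0,
    purities: tuple[float, float] = (0.6, 0.55),
) -> SimConfig:
    """Primary/metastasis pair with one shared and two private clones.

    The canonical three-fate scenario: a shared clone at cellular
    proportion 0.8 in both lesions (corrected-VAF center ~0.4/0.4), a
    primary-private clone at 0.5 (center ~0.25/0) and a
    metastasis-private clone at 0.4 (center ~0/0.2), 100 mutations per
    clone, diploid genome.  The shared clone carries the persistent
    drivers.
    """
    primary = LesionSpec(
        sample_id="P", lesion_type=LesionType.PRIMARY, site="rectum",
        purity=purities[0], depth_mean=depth_mean,
    )
    met = LesionSpec(
        sample_id="M", lesion_type=LesionType.METASTASIS, site="liver",
        purity=purities[1], depth_mean=depth_mean,
    )
    clones = (
        CloneSpec(
            clone_id="shared", n_mutations=n_mutations,
            proportions={"P": 0.8, "M": 0.8},
            drivers=("APC", "TP53", "KRAS"),
        ),
        CloneSpec(
            clone_id="primary_private", n_mutations=n_mutations,
            proportions={"P": 0.5, "M": 0.0}, parent_id="shared",
        ),
        CloneSpec(
            clone_id="met_private", n_mutations=n_mutations,
            proportions={"P": 0.0, "M": 0.4}, parent_id="shared",
        ),
    )
    return SimConfig(
        patient_id="SIM-001", lesions=(primary, met), clones=clones, seed=seed
    )


def arm_recovery_config(
    seed: int,
    purity: float = 0.7,
    n_het_snps_per_arm: int = 200,
    depth_mean: float = 60.0,
) -> SimConfig:
    """Single lesion with truth {13q AMP, 18q DEL, 17p CN_LOH}, rest neutral."""
    lesion = LesionSpec(
        sample_id="T", lesion_type=LesionType.PRIMARY, site="colon",
        purity=purity, depth_mean=depth_mean,
    )
    clone = CloneSpec(clone_id="clonal", n_mutations=50, proportions={"T": 1.0})
    cnas = (
        CnaSpec(arm="13q", state=CnaState.AMP),
        CnaSpec(arm="18q", state=CnaState.DEL),
        CnaSpec(arm="17p", state=CnaState.CN_LOH),
    )
    return SimConfig(
        patient_id="SIM-CNA",
        lesions=(lesion,),
        clones=(clone,),
        cnas=cnas,
        n_het_snps_per_arm=n_het_snps_per_arm,
        seed=seed,
    )
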