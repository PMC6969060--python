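"""End-to-end per-patient orchestration.

Stages run in a fixed order: read inputs -> CNA arm calling (when raw
het-SNP inputs are given and no segment table is) -> VAF correction ->
per-pair EM clustering -> clone-fate classification -> signature
refitting -> report assembly.  Every run directory has a fixed layout::

    outdir/
      tables/       corrected variants, clusters, trajectories, drivers,
                    exposures (canonical TSV)
      figures/      optional cluster-dynamics plots
      report.json   the PatientReport
      manifest.json seed, thresholds, inputs, stage records
      log.txt

All thresholds live in one :class:`PipelineThresholds` namespace so every
manifest records the complete decision surface of a run.  Given identical
inputs, config and seed, ``report.json`` and everything under ``tables/``
are byte-identical across reruns (timestamps appear only in ``log.txt``).

Lesion pairs follow the study design: every later lesion is compared
against the first (the primary when one exists), plus consecutive
metastasis pairs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .cna import (
    CnaThresholds,
    call_arms_from_snps,
    segments_from_arm_calls,
)
from .clustering import (
    DEFAULT_SEED,
    build_vaf_matrix,
    extract_clusters,
    select_k,
    write_clusters,
    write_scatter,
)
from .io_formats import (
    SampleMeta,
    read_het_snps,
    read_sample_sheet,
    read_segments,
    read_signature_matrix,
    read_variants,
)
from .signatures import count_contexts, refit_exposures, write_exposures
from .trajectory import (
    DEFAULT_DRIVER_GENES,
    HYPERMUTATION_THRESHOLD,
    PairResult,
    PatientReport,
    assemble_report,
    classify_fates,
    driver_persistence,
    flag_hypermutation,
    plot_cluster_dynamics,
)
from .vaf_correction import correct_sample, write_corrected

__all__ = [
    "PipelineThresholds",
    "SampleInputs",
    "RunConfig",
    "PipelineError",
    "run_patient",
    "simulate_and_run",
    "lesion_pairs",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineThresholds:
    """Every tunable decision in one auditable namespace."""

    presence_min: float = 0.05
    min_depth: int = 10
    baf_dev_min: float = 0.10
    cov_gain_min: float = 1.15
    cov_loss_max: float = 0.85
    min_snps: int = 10
    driver_alt_min: int = 3
    driver_vaf_min: float = 0.02
    hypermutation_threshold: int = HYPERMUTATION_THRESHOLD
    signature_min_weight: float = 0.06
    signature_min_mutations: int = 20
    k_min: int = 1
    k_max: int = 6
    n_restarts: int = 5
    em_tol: float = 1e-8
    em_max_iter: int = 500

    def cna(self) -> CnaThresholds:
        return CnaThresholds(
            baf_dev_min=self.baf_dev_min,
            cov_gain_min=self.cov_gain_min,
            cov_loss_max=self.cov_loss_max,
            min_snps=self.min_snps,
        )


@dataclass(frozen=True)
class SampleInputs:
    variants: str
    segments: str | None = None
    het_snps: str | None = None
    variant_format: str = "tsv"


@dataclass(frozen=True)
class RunConfig:
    sample_sheet: str
    samples: Mapping[str, SampleInputs]
    outdir: str
    signature_matrix: str | None = None
    seed: int = DEFAULT_SEED
    thresholds: PipelineThresholds = PipelineThresholds()
    make_plots: bool = False
    require_segments: bool = False

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        samples = {
            sid: SampleInputs(**entry) for sid, entry in raw.pop("samples").items()
        }
        thresholds = PipelineThresholds(**raw.pop("thresholds", {}))
        return RunConfig(samples=samples, thresholds=thresholds, **raw)

    def validate(self) -> None:
        missing = []
        for p in [self.sample_sheet, self.signature_matrix]:
            if p and not Path(p).exists():
                missing.append(p)
        for sid, inp in self.samples.items():
            for p in [inp.variants, inp.segments, inp.het_snps]:
                if p and not Path(p).exists():
                    missing.append(p)
        if missing:
            raise PipelineError(f"config references missing paths: {missing}")


def lesion_pairs(metas: Sequence[SampleMeta]) -> list[tuple[str, str]]:
    """All later lesions against the first, plus consecutive pairs."""
    ordered = [m.sample_id for m in sorted(metas, key=lambda m: m.resection_index)]
    pairs: list[tuple[str, str]] = []
    for later in ordered[1:]:
        pairs.append((ordered[0], later))
    for a, b in zip(ordered[1:], ordered[2:]):
        if (a, b) not in pairs:
            pairs.append((a, b))
    return pairs


def _setup_logging(outdir: Path) -> logging.Logger:
    logger = logging.getLogger(f"clonetrace.{outdir.name}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fh = logging.FileHandler(outdir / "log.txt", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    sh = logging.StreamHandler()
    sh.setLevel(logging.WARNING)
    logger.addHandler(sh)
    return logger


def run_patient(config: RunConfig) -> PatientReport:
    """Run all stages for one patient; artifacts land under config.outdir.

    A stage failure raises :class:`PipelineError` naming the stage, after
    writing the outputs of every completed stage and a structured error
    record in the manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    (outdir / "figures").mkdir(exist_ok=True)
    logger = _setup_logging(outdir)
    th = config.thresholds
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(th),
        "inputs": {
            "sample_sheet": str(config.sample_sheet),
            "signature_matrix": str(config.signature_matrix)
            if config.signature_matrix
            else None,
            "samples": {
                sid: dataclasses.asdict(inp) for sid, inp in config.samples.items()
            },
        },
        "stages": [],
        "stage_errors": [],
    }

    def _fail(stage: str, message: str):
        manifest["stage_errors"].append({"stage": stage, "error": message})
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        logger.error("stage %s failed: %s", stage, message)
        raise PipelineError(f"stage {stage} failed: {message}")

    # --- stage: io --------------------------------------------------------
    stage = "io"
    try:
        metas = [
            m
            for m in read_sample_sheet(config.sample_sheet)
            if m.sample_id in config.samples
        ]
        if not metas:
            raise ValueError("no configured samples found in sample sheet")
        meta_by_id = {m.sample_id: m for m in metas}
        variants = {
            sid: read_variants(inp.variants, format=inp.variant_format)
            for sid, inp in config.samples.items()
        }
        reference = (
            read_signature_matrix(config.signature_matrix)
            if config.signature_matrix
            else None
        )
        manifest["stages"].append(stage)
        logger.info("io: %d samples", len(metas))
    except Exception as exc:  # noqa: BLE001 - converted to stage error
        _fail(stage, str(exc))

    # --- stage: cna -------------------------------------------------------
    stage = "cna"
    segments = {}
    try:
        for sid, inp in config.samples.items():
            if inp.segments:
                segments[sid] = read_segments(inp.segments)
            elif inp.het_snps:
                snps = read_het_snps(inp.het_snps)
                calls = call_arms_from_snps(snps, thresholds=th.cna())
                segments[sid] = segments_from_arm_calls(calls)
            elif config.require_segments:
                raise ValueError(f"cna inputs missing for sample {sid}")
            else:
                segments[sid] = []
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        _fail(stage, str(exc))

    # --- stage: correction ------------------------------------------------
    stage = "correction"
    corrected = {}
    exclusions = {}
    try:
        for sid in sorted(config.samples):
            corr, excl = correct_sample(variants[sid], segments[sid], meta_by_id[sid])
            corrected[sid] = corr
            exclusions[sid] = excl
            write_corrected(outdir / "tables" / f"{sid}.corrected.tsv", corr)
            logger.info(
                "correction: %s %d corrected, %d excluded", sid, len(corr), len(excl)
            )
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        _fail(stage, str(exc))

    # --- stages: clustering + trajectory per pair -------------------------
    stage = "clustering"
    pair_results = []
    try:
        pairs = lesion_pairs(metas)
        pair_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(config.seed).spawn(max(len(pairs), 1))
        ]
        driver_ids = {
            v.variant_id: (v.gene,)
            for sid in config.samples
            for v in variants[sid]
            if v.gene
        }
        for (sid_a, sid_b), pair_seed in zip(pairs, pair_seeds):
            if not corrected[sid_a] and not corrected[sid_b]:
                logger.info("clustering: %s vs %s skipped (no variants)", sid_a, sid_b)
                continue
            ids, matrix, dropped = build_vaf_matrix(
                corrected[sid_a], corrected[sid_b], min_depth=th.min_depth
            )
            model = select_k(
                matrix,
                seed=pair_seed,
                k_range=range(th.k_min, th.k_max + 1),
                n_restarts=th.n_restarts,
                max_iter=th.em_max_iter,
                tol=th.em_tol,
            )
            clusters = extract_clusters(model, matrix, ids, presence_min=th.presence_min)
            calls = classify_fates(clusters, driver_ids=driver_ids)
            pair_results.append(
                PairResult(
                    sample_a=sid_a,
                    sample_b=sid_b,
                    interval_therapy=meta_by_id[sid_b].interval_therapy,
                    clusters=tuple(clusters),
                    calls=tuple(calls),
                )
            )
            tag = f"{sid_a}_vs_{sid_b}"
            write_clusters(outdir / "tables" / f"{tag}.clusters.tsv", clusters)
            write_scatter(outdir / "tables" / f"{tag}.scatter.tsv", ids, matrix, clusters)
            _write_trajectory(outdir / "tables" / f"{tag}.trajectory.tsv", calls)
            if config.make_plots:
                plot_cluster_dynamics(
                    pair_results[-1], outdir / "figures" / f"{tag}.png"
                )
            logger.info(
                "clustering: %s k=%d (%d variants, %d dropped)",
                tag,
                model.k,
                len(ids),
                len(dropped),
            )
        manifest["stages"].extend(["clustering", "trajectory"])
    except Exception as exc:  # noqa: BLE001
        _fail(stage, str(exc))

    # --- stage: signatures ------------------------------------------------
    stage = "signatures"
    exposures = {}
    try:
        if reference is not None:
            for sid in sorted(config.samples):
                subs = [
                    (v.ref_allele, v.alt_allele, v.context)
                    for v in variants[sid]
                    if v.context
                ]
                if not subs:
                    continue
                profile = count_contexts(subs, sample_id=sid)
                if profile.total == 0:
                    continue
                exposure = refit_exposures(
                    profile,
                    reference,
                    min_weight=th.signature_min_weight,
                    min_mutations=th.signature_min_mutations,
                )
                exposures[sid] = exposure
                write_exposures(outdir / "tables" / f"{sid}.exposures.tsv", exposure)
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        _fail(stage, str(exc))

    # --- stage: report ----------------------------------------------------
    stage = "report"
    try:
        driver_matrix = driver_persistence(
            {sid: variants[sid] for sid in sorted(config.samples)},
            driver_genes=DEFAULT_DRIVER_GENES,
            alt_min=th.driver_alt_min,
            vaf_min=th.driver_vaf_min,
        )
        driver_matrix.to_csv(outdir / "tables" / "driver_matrix.tsv", sep="\t")
        hyper = {
            sid: flag_hypermutation(variants[sid], th.hypermutation_threshold)
            for sid in config.samples
        }
        report = assemble_report(
            metas,
            pair_results,
            exposures=exposures,
            driver_matrix=driver_matrix,
            hypermutated=hyper,
            expected_pairs=lesion_pairs(metas),
        )
        (outdir / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")
        manifest["stages"].append(stage)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        logger.info("report written")
    except Exception as exc:  # noqa: BLE001
        _fail(stage, str(exc))
    return report


def _write_trajectory(path: Path, calls) -> None:
    lines = ["#cluster_id\tfate\tproportion_a\tproportion_b\tdelta\tdrivers"]
    for c in calls:
        lines.append(
            "\t".join(
                [
                    str(c.cluster_id),
                    c.fate.value,
                    repr(float(c.proportion_a)),
                    repr(float(c.proportion_b)),
                    repr(float(c.delta)),
                    ",".join(c.driver_mutations) if c.driver_mutations else ".",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Truth-vs-inferred harness
# ---------------------------------------------------------------------------


def simulate_and_run(
    sim_config,
    outdir: str | Path,
    thresholds: PipelineThresholds = PipelineThresholds(),
    run_seed: int | None = None,
) -> dict:
    """Simulate a patient, run the pipeline on its files, score vs truth.

    Returns (and writes as ``metrics.json``) truth-vs-inferred tables:
    per-pair matched cluster-center error and fate confusion matrix,
    arm-level CNA confusion counts, and signature-exposure errors when a
    reference matrix is configured.
    """
    from scipy.optimize import linear_sum_assignment

    from .synthetic_data import simulate_patient

    outdir = Path(outdir)
    datadir = outdir / "data"
    patient = simulate_patient(sim_config)
    patient.write(datadir)
    samples = {
        l.sample_id: SampleInputs(
            variants=str(datadir / f"{l.sample_id}.variants.tsv"),
            segments=str(datadir / f"{l.sample_id}.segments.tsv"),
            het_snps=str(datadir / f"{l.sample_id}.het_snps.tsv"),
        )
        for l in sim_config.lesions
    }
    run_config = RunConfig(
        sample_sheet=str(datadir / "sample_sheet.tsv"),
        samples=samples,
        outdir=str(outdir / "run"),
        seed=run_seed if run_seed is not None else sim_config.seed,
        thresholds=thresholds,
    )
    report = run_patient(run_config)

    metrics: dict = {"pairs": [], "cna": None, "n_variants": {
        sid: len(v) for sid, v in patient.variants.items()
    }}

    # --- cluster recovery per pair ---------------------------------------
    presence = thresholds.presence_min
    for pair in report.pairs:
        truth_centers = []
        truth_fates = []
        for clone in sim_config.clones:
            pa = clone.proportions.get(pair.sample_a, 0.0) / 2.0
            pb = clone.proportions.get(pair.sample_b, 0.0) / 2.0
            if pa < presence and pb < presence:
                continue
            truth_centers.append((pa, pb))
            if pa >= presence and pb >= presence:
                truth_fates.append("MAINTAINED")
            elif pa >= presence:
                truth_fates.append("LOST")
            else:
                truth_fates.append("EMERGENT")
        inferred = [(c.center[0], c.center[1]) for c in pair.clusters]
        call_by_cluster = {c.cluster_id: c for c in pair.calls}
        cost = np.array(
            [
                [np.hypot(tc[0] - ic[0], tc[1] - ic[1]) for ic in inferred]
                for tc in truth_centers
            ]
        )
        rows, cols = linear_sum_assignment(cost)
        matched = []
        confusion: dict[str, dict[str, int]] = {
            t: {"MAINTAINED": 0, "LOST": 0, "EMERGENT": 0}
            for t in ("MAINTAINED", "LOST", "EMERGENT")
        }
        for r, c in zip(rows, cols):
            cluster = pair.clusters[c]
            inferred_fate = call_by_cluster[cluster.cluster_id].fate.value
            confusion[truth_fates[r]][inferred_fate] += 1
            matched.append(
                {
                    "truth_center": list(truth_centers[r]),
                    "inferred_center": list(inferred[c]),
                    "center_error": float(cost[r, c]),
                    "coord_error": float(
                        max(
                            abs(truth_centers[r][0] - inferred[c][0]),
                            abs(truth_centers[r][1] - inferred[c][1]),
                        )
                    ),
                    "truth_fate": truth_fates[r],
                    "inferred_fate": inferred_fate,
                }
            )
        metrics["pairs"].append(
            {
                "sample_a": pair.sample_a,
                "sample_b": pair.sample_b,
                "k_truth": len(truth_centers),
                "k_inferred": len(pair.clusters),
                "max_center_error": max((m["center_error"] for m in matched), default=None),
                "max_coord_error": max((m["coord_error"] for m in matched), default=None),
                "fate_confusion": confusion,
                "matches": matched,
            }
        )

    # --- CNA arm recovery -------------------------------------------------
    cna_rows = []
    for lesion in sim_config.lesions:
        truth_states = {}
        for spec in sim_config.cnas:
            if not spec.samples or lesion.sample_id in spec.samples:
                truth_states[spec.arm] = spec.state.value
        calls = call_arms_from_snps(
            patient.het_snps[lesion.sample_id], thresholds=thresholds.cna()
        )
        for call in calls:
            truth = truth_states.get(call.arm, "NEUTRAL")
            inferred = call.state.value if hasattr(call.state, "value") else call.state
            cna_rows.append(
                {
                    "sample": lesion.sample_id,
                    "arm": call.arm,
                    "truth": truth,
                    "inferred": inferred,
                    "correct": truth == inferred,
                }
            )
    if cna_rows:
        metrics["cna"] = {
            "accuracy": float(np.mean([r["correct"] for r in cna_rows])),
            "n_arms": len(cna_rows),
            "errors": [r for r in cna_rows if not r["correct"]],
        }

    (outdir / "metrics.json").write_text(
        json.dumps(metrics, indent=2, sort_keys=True), encoding="utf-8"
    )
    return metrics
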