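"""End-to-end recalibration pipeline.

Stages: simulate a reference (optionally with diverged repeats and
implanted SNPs) -> simulate truth-annotated reads -> align with the
built-in brute-force aligner (or ingest a user SAM) -> extract features
-> label against the truth -> cross-validate -> fit the final logistic
model -> rewrite MAPQ in the evaluation SAM -> emit precision/recall,
calibration and (when SNPs are implanted) SNP-calling reports.

Every stochastic stage draws its seed deterministically from the single
master seed via a stage-name-keyed substream, so a run is reproducible
bit for bit from (config, seed).
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .evaluate import (
    CalibrationBin,
    ContingencyResult,
    FoldResult,
    PRPoint,
    calibration_curve,
    cross_validate,
    precision_recall_sweep,
    snp_eval,
)
from .features import features_for_records, features_to_frame
from .model import (
    LabeledExample,
    LogisticModel,
    fit_logistic,
    predict_probabilities,
    recalibrate_sam,
)
from .pileup import pileup_snp_call
from .samio import parse_sam, write_sam
from .simulate import (
    QualityModel,
    ReferenceSequence,
    SimulatedRead,
    SnpSpec,
    generate_reference,
    generate_repetitive_reference,
    implant_snps,
    simulate_reads,
    write_fasta,
    write_fastq,
    write_truth_table,
)
from .toyalign import toy_align


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] >> 1)  # < 2**31


@dataclass
class PipelineConfig:
    """Parameters of a full simulate-train-recalibrate-evaluate run."""

    outdir: str = "mapqcal_run"
    seed: int = 7
    # reference
    ref_length: int = 10_000
    repetitive: bool = True
    n_repeat_families: int = 2  # ~30% repeat content on the 10 kb demo; scale with ref_length
    repeat_length: int = 500
    copies_per_family: int = 3
    repeat_divergence: float = 0.01
    n_snps: int = 0
    # reads
    n_train_reads: int = 5_000
    n_eval_reads: int = 2_000
    read_len: int = 50
    quality_model: QualityModel = field(default_factory=QualityModel)
    # aligner
    max_mismatches: int = 5
    max_hits: int = 10
    # model
    l2: float = 1e-6
    cap: float = 60.0
    label_tolerance: int = 0
    cv_folds: int = 5
    # SNP demo filters (same depth/fraction on both arms)
    raw_snp_min_mapq: float = 20.0
    recal_snp_min_mapq: float = 3.0
    snp_min_depth: int = 3
    snp_min_alt_frac: float = 0.5


@dataclass
class PipelineResult:
    config: PipelineConfig
    reference: ReferenceSequence
    snps: list[SnpSpec]
    model: LogisticModel
    cv_results: list[FoldResult]
    eval_probs: np.ndarray
    eval_labels: np.ndarray
    pr_recal: list[PRPoint]
    pr_raw: list[PRPoint]
    calibration: list[CalibrationBin]
    snp_raw: ContingencyResult | None
    snp_recal: ContingencyResult | None
    paths: dict[str, Path]


def _label_records(records, truth_by_id, tolerance: int) -> np.ndarray:
    from .model import label_mapping

    labels = np.empty(len(records), dtype=bool)
    for i, record in enumerate(records):
        labels[i] = label_mapping(record, truth_by_id[record.read_id], tolerance)
    return labels


def _simulate_and_align(
    genome: ReferenceSequence,
    align_to: ReferenceSequence,
    n_reads: int,
    config: PipelineConfig,
    seed: int,
    prefix: str,
    outdir: Path,
) -> tuple[list[SimulatedRead], list, Path]:
    reads = simulate_reads(
        genome,
        n_reads,
        read_len=config.read_len,
        qmodel=config.quality_model,
        seed=seed,
        id_prefix=prefix,
    )
    write_fastq(reads, outdir / f"{prefix}.fastq")
    write_truth_table(reads, outdir / f"{prefix}_truth.tsv")
    records = toy_align(
        reads, align_to, max_mismatches=config.max_mismatches, max_hits=config.max_hits
    )
    sam_path = outdir / f"{prefix}.sam"
    write_sam(records, sam_path, references=[(align_to.name, align_to.length)])
    return reads, records, sam_path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; artifacts land in ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    log_lines = [f"mapqcal {__version__}", f"master seed {config.seed}"]
    for key, value in dataclasses.asdict(config).items():
        log_lines.append(f"config {key} = {value}")

    # --- reference and donor -------------------------------------------------
    if config.repetitive:
        ref = generate_repetitive_reference(
            config.ref_length,
            stage_seed(config.seed, "reference"),
            n_families=config.n_repeat_families,
            repeat_length=config.repeat_length,
            copies_per_family=config.copies_per_family,
            divergence=config.repeat_divergence,
        )
    else:
        ref = generate_reference(config.ref_length, stage_seed(config.seed, "reference"))
    write_fasta(ref, outdir / "reference.fasta")
    paths["reference"] = outdir / "reference.fasta"

    snps: list[SnpSpec] = []
    donor = ref
    if config.n_snps:
        donor, snps = implant_snps(ref, config.n_snps, stage_seed(config.seed, "snps"))
        write_fasta(donor, outdir / "donor.fasta")
        with open(outdir / "snp_truth.tsv", "w") as handle:
            handle.write("position\tref_allele\talt_allele\n")
            for snp in snps:
                handle.write(f"{snp.position}\t{snp.ref_allele}\t{snp.alt_allele}\n")
        paths["snp_truth"] = outdir / "snp_truth.tsv"

    # --- training: reads from the plain reference, aligned back to it --------
    train_reads, train_records, train_sam = _simulate_and_align(
        ref, ref, config.n_train_reads, config, stage_seed(config.seed, "train-reads"),
        "train", outdir,
    )
    paths["train_sam"] = train_sam
    truth_train = {read.read_id: read for read in train_reads}
    scored_train, vectors_train = features_for_records(train_records)
    labels_train = _label_records(scored_train, truth_train, config.label_tolerance)
    examples = [
        LabeledExample(features=vector, label=bool(label))
        for vector, label in zip(vectors_train, labels_train)
    ]
    frame = features_to_frame(scored_train, vectors_train)
    frame["label"] = labels_train.astype(int)
    frame.to_csv(outdir / "train_features.tsv", sep="\t", index=False)
    paths["train_features"] = outdir / "train_features.tsv"

    # --- cross-validation and final fit --------------------------------------
    cv_results = cross_validate(
        examples, k=config.cv_folds, seed=stage_seed(config.seed, "cv"), l2=config.l2
    )
    cv_rows = [
        {
            "fold": result.fold,
            "n_test": len(result.test_indices),
            "tp": result.contingency.tp,
            "fp": result.contingency.fp,
            "fn": result.contingency.fn,
            "precision": result.contingency.precision,
            "recall": result.contingency.recall,
            "f_paper": result.contingency.f_paper,
            "accuracy": result.accuracy,
        }
        for result in cv_results
    ]
    pd.DataFrame(cv_rows).to_csv(outdir / "cv_report.tsv", sep="\t", index=False)
    paths["cv_report"] = outdir / "cv_report.tsv"

    model = fit_logistic(examples, l2=config.l2, cap=config.cap)
    model.to_json(outdir / "model.json")
    paths["model"] = outdir / "model.json"

    # --- evaluation: reads from the donor (with any SNPs), aligned to ref ----
    eval_reads, eval_records, eval_sam = _simulate_and_align(
        donor, ref, config.n_eval_reads, config, stage_seed(config.seed, "eval-reads"),
        "eval", outdir,
    )
    paths["eval_sam"] = eval_sam
    recal_sam = outdir / "eval_recal.sam"
    recalibrate_sam(eval_sam, model, recal_sam, scores_out=outdir / "eval_scores.tsv")
    paths["eval_recal_sam"] = recal_sam
    paths["eval_scores"] = outdir / "eval_scores.tsv"

    truth_eval = {read.read_id: read for read in eval_reads}
    scored_eval, vectors_eval = features_for_records(eval_records)
    labels_eval = _label_records(scored_eval, truth_eval, config.label_tolerance)
    X_eval = np.array([vector.to_array() for vector in vectors_eval])
    probs_eval = predict_probabilities(model, X_eval) if len(scored_eval) else np.empty(0)

    pr_recal = precision_recall_sweep(
        probs_eval, labels_eval, thresholds=np.round(np.arange(0.0, 1.0001, 0.05), 4)
    )
    raw_scores = np.array(
        [0.0 if record.mapq is None else float(record.mapq) for record in scored_eval]
    )
    pr_raw = precision_recall_sweep(
        raw_scores, labels_eval, thresholds=np.arange(0.0, 31.0, 1.0)
    )
    calibration = calibration_curve(probs_eval, labels_eval, n_bins=10, cap=config.cap)

    def _pr_frame(points):
        return pd.DataFrame(
            [
                {
                    "threshold": point.threshold,
                    "tp": point.tp,
                    "fp": point.fp,
                    "fn": point.fn,
                    "precision": point.precision,
                    "recall": point.recall,
                }
                for point in points
            ]
        )

    _pr_frame(pr_recal).to_csv(outdir / "pr_recalibrated.tsv", sep="\t", index=False)
    _pr_frame(pr_raw).to_csv(outdir / "pr_raw.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "bin": b.bin_index,
                "n": b.n,
                "mean_p": b.mean_p,
                "mean_predicted_q": b.mean_predicted_q,
                "theoretical_accuracy": b.theoretical_accuracy,
                "empirical_accuracy": b.empirical_accuracy,
            }
            for b in calibration
        ]
    ).to_csv(outdir / "calibration.tsv", sep="\t", index=False)
    paths["pr_recalibrated"] = outdir / "pr_recalibrated.tsv"
    paths["pr_raw"] = outdir / "pr_raw.tsv"
    paths["calibration"] = outdir / "calibration.tsv"

    # --- SNP-calling comparison ----------------------------------------------
    snp_raw = snp_recal = None
    if config.n_snps:
        raw_calls = pileup_snp_call(
            list(parse_sam(eval_sam)),
            ref,
            min_mapq=config.raw_snp_min_mapq,
            min_depth=config.snp_min_depth,
            min_alt_frac=config.snp_min_alt_frac,
        )
        recal_calls = pileup_snp_call(
            list(parse_sam(recal_sam)),
            ref,
            min_mapq=config.recal_snp_min_mapq,
            min_depth=config.snp_min_depth,
            min_alt_frac=config.snp_min_alt_frac,
        )
        snp_raw = snp_eval(raw_calls, snps)
        snp_recal = snp_eval(recal_calls, snps)
        pd.DataFrame(
            [
                {"arm": "raw_mapq", **dataclasses.asdict(snp_raw)},
                {"arm": "recalibrated", **dataclasses.asdict(snp_recal)},
            ]
        ).to_csv(outdir / "snp_comparison.tsv", sep="\t", index=False)
        paths["snp_comparison"] = outdir / "snp_comparison.tsv"

    for name in ("reference", "train-reads", "eval-reads", "snps", "cv"):
        log_lines.append(f"stage seed {name} = {stage_seed(config.seed, name)}")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    paths["log"] = outdir / "run.log"

    return PipelineResult(
        config=config,
        reference=ref,
        snps=snps,
        model=model,
        cv_results=cv_results,
        eval_probs=probs_eval,
        eval_labels=labels_eval,
        pr_recal=pr_recal,
        pr_raw=pr_raw,
        calibration=calibration,
        snp_raw=snp_raw,
        snp_recal=snp_recal,
        paths=paths,
    )
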