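"""End-to-end orchestration of the five pipeline stages.

simulate → select channel → denoise → featurize → split/train/predict
→ evaluate.  Each stage is importable on its own; this module wires
them together, tracks per-stage record counts and rejection reasons,
and writes the interchange files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pulsebp.config import PipelineConfig, stage_seed
from pulsebp.emd import UnusableChannelError, denoise, select_best_channel
from pulsebp.evaluate import (
    AgreementReport,
    build_report,
    dataset_summary,
    plot_bland_altman,
    plot_correlation,
    render_tables,
)
from pulsebp.features import (
    FEATURE_NAMES,
    RecordRejectedError,
    featurize_recording,
)
from pulsebp.io import (
    write_feature_csv,
    write_ground_truth,
    write_references_csv,
)
from pulsebp.models import (
    ModelSpec,
    predict,
    split_dataset,
    train_model,
)
from pulsebp.records import WaveformRecording
from pulsebp.simulate import GroundTruth, generate_dataset

logger = logging.getLogger("pulsebp")

__all__ = ["PipelineResult", "extract_features", "fit_and_evaluate",
           "run_pipeline"]

_SEED_BY_ALG = {"RFR": "rfr", "GBR": "gbr", "ABR": "abr"}


@dataclass
class PipelineResult:
    """Everything a run produces, plus bookkeeping for diagnostics."""

    features: pd.DataFrame
    report: AgreementReport
    tables: dict[str, pd.DataFrame]
    summary: dict
    n_generated: int
    n_accepted: int
    rejections: dict[str, str]       # record_id -> reason
    predictions: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]


def extract_features(
    recordings: list[WaveformRecording],
    references: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Stages 2–3 for a corpus: channel selection, denoising, features.

    Returns the labelled feature table (one row per accepted record)
    and a map of rejected record ids to reason codes.
    """
    ref_by_id = references.set_index("record_id")
    rows = []
    rejections: dict[str, str] = {}
    for rec in recordings:
        try:
            quality = select_best_channel(rec)
            cleaned = denoise(
                rec.channels[quality.selected_channel],
                rec.sampling_rate_hz,
                beat_band_hz=config.emd.beat_band_hz,
                sd_threshold=config.emd.sd_threshold,
                max_imfs=config.emd.max_imfs,
            )
            fv, n_beats = featurize_recording(
                cleaned, rec.sampling_rate_hz,
                hr_bounds_bpm=config.features.hr_bounds_bpm,
                ai_convention=config.features.ai_convention,
                min_beats=config.features.min_beats,
            )
        except (UnusableChannelError, RecordRejectedError) as err:
            rejections[rec.record_id] = str(err)
            logger.debug("rejected %s: %s", rec.record_id, err)
            continue
        row = {"record_id": rec.record_id, "subject_id": rec.subject_id}
        row.update(dict(zip(FEATURE_NAMES, fv.as_array())))
        row["n_beats"] = n_beats
        row["sbp_mmHg"] = float(ref_by_id.loc[rec.record_id, "sbp_mmHg"])
        row["dbp_mmHg"] = float(ref_by_id.loc[rec.record_id, "dbp_mmHg"])
        rows.append(row)
    features = pd.DataFrame(rows)
    logger.info("featurized %d/%d records (%d rejected)",
                len(rows), len(recordings), len(rejections))
    return features, rejections


def fit_and_evaluate(
    features: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[AgreementReport, dict, pd.DataFrame]:
    """Stages 4–5: split, train each (algorithm, target), evaluate.

    Returns the agreement report, the raw (reference, estimate) pairs
    per cell, and the feature table with its split labels attached.
    """
    labelled = split_dataset(
        features,
        ratio=config.model.split_ratio,
        seed=stage_seed(config.seed, "split"),
        mode=config.model.split_mode,
    )
    train_df = labelled[labelled["split"] == "train"]
    test_df = labelled[labelled["split"] == "test"]
    logger.info("split (%s mode): %d train / %d test",
                config.model.split_mode, len(train_df), len(test_df))

    predictions: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for alg in config.model.algorithms:
        for target, column in (("SBP", "sbp_mmHg"), ("DBP", "dbp_mmHg")):
            spec = ModelSpec(
                algorithm=alg, target=target,
                n_estimators=config.model.n_estimators,
                max_depth=config.model.rfr_max_depth,
                base_depth=config.model.base_depth,
                learning_rate=config.model.learning_rate,
                seed=stage_seed(config.seed, _SEED_BY_ALG[alg]),
            )
            model = train_model(spec, train_df)
            estimate = predict(model, test_df)
            reference = test_df[column].to_numpy(dtype=float)
            predictions[(alg, target)] = (reference, estimate)
    report = build_report(predictions, config.evaluation.thresholds_mmHg)
    return report, predictions, labelled


def run_pipeline(config: PipelineConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full pipeline and write its artifacts under ``outdir``.

    Writes: references CSV, ground-truth ledger, feature CSV (with
    split labels), rendered agreement tables, and (optionally)
    correlation / Bland–Altman plots per algorithm and target.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("simulating corpus: %d subjects x %d records",
                config.simulation.n_subjects,
                config.simulation.records_per_subject)
    recordings, references, truths = generate_dataset(config.simulation)
    write_references_csv(references, out / "references.csv")
    write_ground_truth(truths, out / "ground_truth.json")

    features, rejections = extract_features(recordings, references, config)
    if len(features) == 0:
        raise RuntimeError("feature extraction rejected every record")

    report, predictions, labelled = fit_and_evaluate(features, config)
    write_feature_csv(labelled, out / "features.csv")
    labelled.to_csv(out / "features_with_split.csv", index=False)

    tables = render_tables(report)
    with open(out / "agreement_report.txt", "w") as fh:
        fh.write(f"split mode: {config.model.split_mode}, "
                 f"ratio {config.model.split_ratio}, "
                 f"seed {config.seed}\n")
        fh.write(f"records: {len(labelled)} accepted, "
                 f"{len(rejections)} rejected\n\n")
        for target, table in tables.items():
            fh.write(f"== {target} ==\n{table.to_string()}\n\n")
    for target, table in tables.items():
        table.to_csv(out / f"agreement_{target.lower()}.csv")

    if config.evaluation.make_plots:
        for (alg, target), (ref, est) in predictions.items():
            stem = f"{alg.lower()}_{target.lower()}"
            plot_correlation(ref, est, out / f"correlation_{stem}.png",
                             label=f"{alg} {target}")
            plot_bland_altman(ref, est, out / f"bland_altman_{stem}.png",
                              label=f"{alg} {target}")

    summary = dataset_summary(references)
    n_gen = len(recordings)
    result = PipelineResult(
        features=labelled, report=report, tables=tables, summary=summary,
        n_generated=n_gen, n_accepted=len(features),
        rejections=rejections, predictions=predictions,
    )
    assert result.n_accepted + len(rejections) == n_gen
    return result
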