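#!/usr/bin/env python
"""Fit the three ensemble regressors and evaluate BP agreement.

Reads results/features.csv (run 04_extract_features.py first, or this
driver regenerates it), splits 80/20 at record level, trains RFR, GBR
and ABR separately for SBP and DBP, and reports R², Bland–Altman bias
with limits of agreement, and the <5/<10/<15 mmHg error-band table.
Also fits the subject-level split for comparison — with ~49 records
per subject a record-level split shares every subject between train
and test, so the subject split is the harder, leakage-free protocol.
Writes the agreement tables and correlation/Bland–Altman figures.
"""

import dataclasses
from pathlib import Path

from pulsebp.config import PipelineConfig
from pulsebp.evaluate import plot_bland_altman, plot_correlation, \
    render_tables
from pulsebp.io import read_feature_csv
from pulsebp.pipeline import extract_features, fit_and_evaluate
from pulsebp.simulate import generate_dataset

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def _features(config):
    path = OUT / "features.csv"
    if path.exists():
        return read_feature_csv(path)
    recordings, references, _ = generate_dataset(config.simulation)
    features, _ = extract_features(recordings, references, config)
    return features


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = PipelineConfig(seed=SEED).with_seed(SEED)
    features = _features(config)

    for mode in ("record", "subject"):
        cfg = dataclasses.replace(config)
        cfg.model = dataclasses.replace(config.model, split_mode=mode)
        report, predictions, labelled = fit_and_evaluate(features, cfg)
        n_tr = (labelled["split"] == "train").sum()
        n_te = (labelled["split"] == "test").sum()
        print(f"\n=== {mode}-level split: {n_tr} train / {n_te} test ===")
        for target, table in render_tables(report).items():
            print(f"-- {target} --")
            print(table.to_string())
            table.to_csv(OUT / f"agreement_{target.lower()}_{mode}.csv")
        if mode == "record":
            for (alg, tgt), (ref, est) in predictions.items():
                stem = f"{alg.lower()}_{tgt.lower()}"
                plot_correlation(ref, est, OUT / f"correlation_{stem}.png",
                                 label=f"{alg} {tgt}")
                plot_bland_altman(ref, est,
                                  OUT / f"bland_altman_{stem}.png",
                                  label=f"{alg} {tgt}")


if __name__ == "__main__":
    main()
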