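#!/usr/bin/env python
"""How reliably does the quality score find the aligned array element?

In the measurement scenario only one of the three sensing elements sits
well over the radial artery; its neighbours see an attenuated copy of
the pulse under the same noise.  The quality score (mean beat-template
correlation x beat amplitude) should recover that channel.  This
driver measures the selection accuracy over 100 fresh recordings at
the default noise conditions and writes the per-recording scores.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pulsebp.emd import select_best_channel
from pulsebp.simulate import SimulationConfig, generate_recording

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1
N = 100


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimulationConfig()
    rng = np.random.default_rng(SEED)
    rows = []
    for k in range(N):
        bp = (rng.uniform(99, 137), rng.uniform(59, 80))
        rec, truth = generate_recording(cfg, bp, seed=SEED * 1000 + k)
        quality = select_best_channel(rec)
        rows.append({
            "recording": k,
            "selected": quality.selected_channel,
            "aligned": truth.aligned_channel,
            "correct": quality.selected_channel == truth.aligned_channel,
            **{f"score_ch{i + 1}": s
               for i, s in enumerate(quality.scores)},
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "channel_selection.csv", index=False)
    acc = df["correct"].mean()
    print(f"selected the aligned channel on {df['correct'].sum()}/{N} "
          f"recordings ({100 * acc:.1f}%)")
    print("mean quality scores:",
          df[[c for c in df.columns if c.startswith('score')]]
          .mean().round(3).to_dict())


if __name__ == "__main__":
    main()
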