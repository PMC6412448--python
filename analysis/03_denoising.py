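#!/usr/bin/env python
"""Does EMD-based denoising actually clean the pulse signal?

Adds white noise at 10 dB SNR and 0.1 Hz baseline wander to noise-free
recordings, denoises by partial IMF reconstruction, and measures (a)
RMSE to the clean reference before vs after, (b) suppression of
sub-0.3 Hz wander power, (c) EMD reconstruction completeness.  Also
saves a before/after figure for one example record.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from pulsebp.emd import denoise, emd_decompose
from pulsebp.simulate import SimulationConfig, generate_recording

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1
N = 20


def main() -> None:
    OUT.mkdir(exist_ok=True)
    clean_cfg = SimulationConfig(noise_sd=0.0, baseline_amp=0.0,
                                 artifact_prob=0.0)
    fs = clean_cfg.sampling_rate_hz
    rows = []
    example = None
    for k in range(N):
        rec, truth = generate_recording(clean_cfg, (118, 70),
                                        seed=SEED * 2000 + k)
        clean = rec.channels[1]
        rng = np.random.default_rng(SEED * 3000 + k)
        noise = rng.normal(0, np.sqrt(np.var(clean) / 10), len(clean))
        t = np.arange(len(clean)) / fs
        wander = (0.2 * truth.params.systolic_amp
                  * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi)))
        noisy = clean + noise + wander
        den = denoise(noisy, fs)
        ref = clean - clean.mean()
        rmse_before = float(np.sqrt(np.mean(
            (noisy - noisy.mean() - ref) ** 2)))
        rmse_after = float(np.sqrt(np.mean(
            (den - den.mean() - ref) ** 2)))
        f, p0 = periodogram(noisy - noisy.mean(), fs, window="hann")
        _, p1 = periodogram(den - den.mean(), fs, window="hann")
        low = (f > 0) & (f < 0.3)
        imfset = emd_decompose(noisy, fs)
        rows.append({
            "record": k,
            "rmse_before": rmse_before,
            "rmse_after": rmse_after,
            "wander_reduction": 1 - p1[low].sum() / p0[low].sum(),
            "n_imfs": imfset.n_imfs,
            "recon_rel_err": float(np.max(np.abs(
                imfset.reconstruct() - noisy)) / np.ptp(noisy)),
        })
        if example is None:
            example = (t, noisy, den, clean)
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "denoising_metrics.csv", index=False)
    print(f"RMSE improved on {(df.rmse_after < df.rmse_before).sum()}/{N} "
          f"records (median {df.rmse_before.median():.3f} -> "
          f"{df.rmse_after.median():.3f})")
    print(f"sub-0.3 Hz wander power reduced by "
          f"{100 * df.wander_reduction.min():.1f}% (worst) / "
          f"{100 * df.wander_reduction.mean():.1f}% (mean)")
    print(f"max EMD reconstruction error "
          f"{df.recon_rel_err.max():.2e} (relative)")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    t, noisy, den, clean = example
    fig, axes = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
    axes[0].plot(t, noisy, lw=0.6)
    axes[0].set_title("raw channel (10 dB SNR + 0.1 Hz wander)")
    axes[1].plot(t, den, lw=0.6)
    axes[1].plot(t, clean - clean.mean(), lw=0.6, alpha=0.6)
    axes[1].set_title("after EMD denoising (clean reference overlaid)")
    axes[1].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(OUT / "denoising_example.png", dpi=110)
    print(f"example figure -> {OUT / 'denoising_example.png'}")


if __name__ == "__main__":
    main()
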