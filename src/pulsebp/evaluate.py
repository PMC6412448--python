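"""Agreement statistics between estimated and reference blood pressure.

Three complementary views, matching standard practice for validating a
cuffless monitor against a cuff reference:

* the coefficient of determination R² of estimates against references;
* Bland–Altman analysis: bias (mean of estimate − reference) and the
  95% limits of agreement bias ± 1.96·SD of the differences;
* error-band accuracy: the fraction of estimates whose absolute error
  is strictly below 5, 10 and 15 mmHg.

Sign convention throughout: difference = estimate − reference.
Band membership is strict (|d| < threshold); a difference exactly at a
threshold falls outside the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CellStats",
    "AgreementReport",
    "r_squared",
    "bland_altman",
    "band_accuracy",
    "build_report",
    "render_tables",
    "dataset_summary",
    "plot_correlation",
    "plot_bland_altman",
]

DEFAULT_THRESHOLDS_MMHG = (5.0, 10.0, 15.0)


def _validate_pair(reference, estimate) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape or ref.ndim != 1:
        raise ValueError("reference and estimate must be equal-length 1-D")
    if len(ref) < 2:
        raise ValueError("need at least two paired observations")
    return ref, est


def r_squared(reference, estimate) -> float:
    """1 − SS_res/SS_tot with SS_tot about the reference mean.

    Returns NaN (undefined) when the reference has zero variance.
    """
    ref, est = _validate_pair(reference, estimate)
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((ref - est) ** 2))
    return 1.0 - ss_res / ss_tot


def bland_altman(reference, estimate) -> tuple[float, float, float, np.ndarray]:
    """Bias and 95% limits of agreement of estimate − reference.

    Returns ``(bias, loa_low, loa_high, differences)`` with limits
    ``bias ± 1.96 × sample SD`` (n−1 denominator).
    """
    ref, est = _validate_pair(reference, estimate)
    diff = est - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, diff


def band_accuracy(differences,
                  thresholds=DEFAULT_THRESHOLDS_MMHG) -> np.ndarray:
    """Fraction of |difference| strictly below each threshold."""
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("empty differences")
    thr = np.asarray(thresholds, dtype=float)
    if np.any(thr <= 0) or np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be positive and increasing")
    return np.array([float(np.mean(np.abs(d) < t)) for t in thr])


@dataclass
class CellStats:
    """Agreement statistics for one (algorithm, target) cell."""

    r2: float
    bias: float
    loa_low: float
    loa_high: float
    band_fractions: dict[float, float]
    n_test: int

    def __post_init__(self) -> None:
        fr = list(self.band_fractions.values())
        if any(not 0 <= v <= 1 for v in fr):
            raise ValueError("band fractions must lie in [0, 1]")
        if np.any(np.diff(fr) < 0):
            raise ValueError("band fractions must be non-decreasing")
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValueError("limits of agreement must bracket the bias")


@dataclass
class AgreementReport:
    """Per-(target, algorithm) agreement cells; missing cells are None."""

    cells: dict[tuple[str, str], CellStats | None]
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS_MMHG

    def get(self, algorithm: str, target: str) -> CellStats | None:
        return self.cells.get((algorithm, target))


def build_report(
    predictions: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]],
    thresholds=DEFAULT_THRESHOLDS_MMHG,
) -> AgreementReport:
    """Aggregate (reference, estimate) pairs into one report.

    ``predictions`` maps (algorithm, target) to a (reference, estimate)
    pair on the test fold.  Missing combinations yield explicit ``None``
    cells rather than an error, so a partial run still reports.
    """
    if not predictions:
        raise ValueError("no predictions supplied")
    algorithms = sorted({k[0] for k in predictions})
    targets = sorted({k[1] for k in predictions})
    cells: dict[tuple[str, str], CellStats | None] = {}
    for alg in algorithms:
        for tgt in targets:
            pair = predictions.get((alg, tgt))
            if pair is None:
                cells[(alg, tgt)] = None
                continue
            ref, est = pair
            bias, lo, hi, diff = bland_altman(ref, est)
            fractions = band_accuracy(diff, thresholds)
            cells[(alg, tgt)] = CellStats(
                r2=r_squared(ref, est),
                bias=bias, loa_low=lo, loa_high=hi,
                band_fractions=dict(zip(map(float, thresholds), fractions)),
                n_test=len(ref),
            )
    return AgreementReport(cells=cells, thresholds=tuple(thresholds))


def render_tables(report: AgreementReport) -> dict[str, pd.DataFrame]:
    """One table per target: algorithms × error bands, cells in % (1 dp),
    plus R², bias and limits-of-agreement columns."""
    tables = {}
    targets = sorted({t for (_, t) in report.cells})
    algorithms = sorted({a for (a, _) in report.cells})
    for tgt in targets:
        rows = []
        for alg in algorithms:
            cell = report.get(alg, tgt)
            if cell is None:
                rows.append({"algorithm": alg})
                continue
            row = {"algorithm": alg, "R2": round(cell.r2, 3),
                   "bias_mmHg": round(cell.bias, 2),
                   "loa_low_mmHg": round(cell.loa_low, 2),
                   "loa_high_mmHg": round(cell.loa_high, 2),
                   "n_test": cell.n_test}
            for thr, frac in cell.band_fractions.items():
                row[f"<{thr:g} mmHg"] = round(100.0 * frac, 1)
            rows.append(row)
        tables[tgt] = pd.DataFrame(rows).set_index("algorithm")
    return tables


def dataset_summary(references: pd.DataFrame) -> dict:
    """Histogram (1 mmHg bins) and min/max of the reference SBP and DBP."""
    if len(references) == 0:
        raise ValueError("empty reference table")
    out = {}
    for name, col in (("sbp", "sbp_mmHg"), ("dbp", "dbp_mmHg")):
        vals = references[col].to_numpy(dtype=float)
        edges = np.arange(np.floor(vals.min()), np.ceil(vals.max()) + 1.0)
        if len(edges) < 2:
            edges = np.array([np.floor(vals.min()), np.floor(vals.min()) + 1])
        counts, edges = np.histogram(vals, bins=edges)
        out[name] = {
            "counts": counts, "bin_edges": edges,
            "min": float(vals.min()), "max": float(vals.max()),
            "n": int(len(vals)),
        }
    return out


def plot_correlation(reference, estimate, path: str | Path,
                     label: str = "") -> None:
    """Scatter of estimate vs reference with the identity line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(reference, float)
    est = np.asarray(estimate, float)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(ref, est, s=10, alpha=0.6)
    lims = [min(ref.min(), est.min()) - 2, max(ref.max(), est.max()) + 2]
    ax.plot(lims, lims, "k--", lw=1)
    r2 = r_squared(ref, est)
    ax.set_xlabel("reference BP (mmHg)")
    ax.set_ylabel("estimated BP (mmHg)")
    ax.set_title(f"{label} R$^2$ = {r2:.3f}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_bland_altman(reference, estimate, path: str | Path,
                      label: str = "") -> None:
    """Bland–Altman plot: differences vs pair means with bias/LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(reference, float)
    est = np.asarray(estimate, float)
    bias, lo, hi, diff = bland_altman(ref, est)
    mean = 0.5 * (ref + est)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(mean, diff, s=10, alpha=0.6)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel("mean of reference and estimate (mmHg)")
    ax.set_ylabel("estimate − reference (mmHg)")
    ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
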