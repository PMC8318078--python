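"""Odor-response quantification from calcium-imaging traces.

For each cell-odor pair, fluorescence is normalized to dF/F against a
pre-odor baseline, trials of the same odor are averaged, and the response is
the Z score of the mean dF/F in the 1 s window from inhalation onset,
relative to the mean and SD of the baseline frames of the averaged trace.
A pair is responsive when Z > 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats


def dff(trace, baseline: slice | np.ndarray) -> np.ndarray:
    """(F - F0) / F0 with F0 the mean over the baseline window.

    Works on a single trace or any array whose last axis is frames.
    Raises when any baseline mean is non-positive (the trace is invalid).
    """
    trace = np.asarray(trace, dtype=float)
    f0 = trace[..., baseline].mean(axis=-1, keepdims=True)
    if np.any(f0 <= 0):
        raise ValueError("non-positive baseline fluorescence")
    return (trace - f0) / f0


def response_zscore(
    dff_trials: np.ndarray,
    onset_frame: int,
    frame_rate: float,
    window_s: float = 1.0,
    baseline_s: float = 2.0,
    per_trial: bool = False,
):
    """Odor-window Z score from per-trial dF/F traces.

    ``dff_trials`` has frames on the last axis and trials on the second-to-
    last.  Trials are averaged first (default), then
    Z = (mean dF/F in the window - baseline mean) / baseline SD, with the
    baseline the ``baseline_s`` seconds ending at inhalation onset.
    ``per_trial=True`` instead computes Z per trial and averages the Zs.
    Returns NaN where the baseline SD is zero (undefined).
    """
    dff_trials = np.asarray(dff_trials, dtype=float)
    win = int(round(window_s * frame_rate))
    n_base = int(round(baseline_s * frame_rate))
    if onset_frame + win > dff_trials.shape[-1]:
        raise ValueError("odor window extends past the trace")
    b0 = max(onset_frame - n_base, 0)
    if onset_frame - b0 < 10:
        raise ValueError("need at least 10 baseline frames")

    def _z(tr):
        base = tr[..., b0:onset_frame]
        sd = base.std(axis=-1, ddof=1)
        num = tr[..., onset_frame : onset_frame + win].mean(axis=-1) - base.mean(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sd > 0, num / sd, np.nan)

    if per_trial:
        return _z(dff_trials).mean(axis=-1)
    return _z(dff_trials.mean(axis=-2))


def traceset_zscores(traces, window_s: float = 1.0, baseline_s: float = 2.0) -> np.ndarray:
    """Z per cell-odor pair for a simulated/loaded TraceSet."""
    d = dff(traces.f, slice(max(traces.onset_frame - int(round(baseline_s * traces.frame_rate)), 0),
                            traces.onset_frame))
    return response_zscore(d, traces.onset_frame, traces.frame_rate, window_s, baseline_s)


def responsiveness_summary(z: np.ndarray, threshold: float = 2.0) -> dict:
    """Fraction of responsive cell-odor pairs and per-cell responsive counts.

    ``z`` is cells x odors.  Returns the fraction of pairs with Z above
    threshold, the per-cell count of responsive odors, and its histogram.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    resp = z > threshold
    counts = resp.sum(axis=1)
    n_pairs = z.size
    hist = np.bincount(counts, minlength=z.shape[1] + 1)
    return {
        "fraction_responsive": float(resp.sum() / n_pairs) if n_pairs else 0.0,
        "n_pairs": int(n_pairs),
        "n_responsive": int(resp.sum()),
        "counts_per_cell": counts,
        "count_histogram": hist,
    }


def amplitude_comparison(amplitudes_a, amplitudes_b) -> dict:
    """Two-sample KS comparison of response-amplitude distributions."""
    res = sstats.ks_2samp(np.asarray(amplitudes_a), np.asarray(amplitudes_b))
    return {"ks_statistic": float(res.statistic), "pvalue": float(res.pvalue)}


def zscore_table(z: np.ndarray) -> pd.DataFrame:
    """Long-format Z table (cell, odor, z) for CSV export."""
    z = np.atleast_2d(z)
    cells, odors = np.indices(z.shape)
    return pd.DataFrame({"cell": cells.ravel(), "odor": odors.ravel(), "z": z.ravel()})
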