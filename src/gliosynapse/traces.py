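"""Fluorescence time-series quantification and band densitometry.

ΔF/F for calcium (GCaMP6s) transients, transient duration as the contiguous
supra-zero epoch containing the peak, the SEP/PSD95-RFP ratio used for
surface-receptor live imaging, and percent-of-control normalization of
surface-protein band densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluorTrace",
    "TransientResult",
    "delta_f_over_f",
    "transient_duration",
    "sep_psd95_ratio",
    "surface_band_percent",
]


@dataclass
class FluorTrace:
    """A single-ROI fluorescence time series.

    Parameters
    ----------
    samples
        Mean ROI intensity per frame.
    fs
        Sampling rate in Hz.
    baseline_window
        Half-open index range ``(start, stop)`` of pre-stimulus samples whose
        mean defines the basal fluorescence F.  The stimulus is taken to occur
        at ``stop``.
    background
        Scalar background intensity subtracted before ΔF/F (0 if the trace is
        already background-corrected).
    """

    samples: np.ndarray
    fs: float
    baseline_window: tuple = None
    background: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size < 2:
            raise ValueError("trace must contain at least two samples")
        if self.baseline_window is None:
            # default: first half of the trace is pre-stimulus
            self.baseline_window = (0, self.samples.size // 2)
        b0, b1 = self.baseline_window
        if not (0 <= b0 < b1 <= self.samples.size):
            raise ValueError("baseline window must be a non-empty valid index range")

    @property
    def stimulus_index(self) -> int:
        return self.baseline_window[1]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class TransientResult:
    """ΔF/F quantification of one trace."""

    f0: float
    peak_dff: float
    peak_index: int
    dff: np.ndarray
    duration_s: float | None = None


def delta_f_over_f(trace: FluorTrace) -> TransientResult:
    """Compute ΔF/F with F the background-corrected mean of the baseline window.

    ``f0 = mean(samples[baseline]) - background``; ``dff(t) =
    (samples(t) - background - f0) / f0``.  The peak is the maximal ΔF/F over
    the post-stimulus samples.  Raises if ``f0 <= 0``.
    """
    b0, b1 = trace.baseline_window
    f0 = float(trace.samples[b0:b1].mean() - trace.background)
    if f0 <= 0:
        raise ValueError(f"basal fluorescence must be positive (got {f0:g})")
    dff = (trace.samples - trace.background - f0) / f0
    post = dff[trace.stimulus_index :]
    if post.size == 0:
        raise ValueError("no post-stimulus samples")
    peak_index = trace.stimulus_index + int(np.argmax(post))
    return TransientResult(
        f0=f0, peak_dff=float(dff[peak_index]), peak_index=peak_index, dff=dff
    )


def transient_duration(
    dff: np.ndarray,
    fs: float,
    peak_index: int | None = None,
    threshold: float = 0.0,
    mode: str = "contiguous",
) -> float:
    """Seconds for which ΔF/F stays above ``threshold``.

    ``mode="contiguous"`` (default) measures the maximal contiguous run of
    supra-threshold samples containing the peak — the length of one transient.
    ``mode="total"`` sums every supra-threshold sample instead.  A peak at or
    below the threshold yields 0.
    """
    dff = np.asarray(dff, dtype=float).ravel()
    if fs <= 0:
        raise ValueError("fs must be positive")
    if mode not in ("contiguous", "total"):
        raise ValueError("mode must be 'contiguous' or 'total'")
    if peak_index is None:
        peak_index = int(np.argmax(dff))
    if dff[peak_index] <= threshold:
        return 0.0
    above = dff > threshold
    if mode == "total":
        return float(above.sum() / fs)
    lo = peak_index
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_index
    while hi < dff.size - 1 and above[hi + 1]:
        hi += 1
    return float((hi - lo + 1) / fs)


def sep_psd95_ratio(
    sep: np.ndarray,
    rfp: np.ndarray,
    fs: float,
    baseline_window: tuple | None = None,
):
    """SEP-GluA2 / PSD95-RFP ratio series and its ΔF/F.

    Dividing the pH-sensitive SEP signal by the co-localized PSD95-RFP signal
    cancels intensity drift (photobleaching, z-drift).  Returns
    ``(ratio, result)`` where ``result`` is the :class:`TransientResult` of
    ΔF/F applied to the ratio trace (basal ratio from the baseline window).
    Raises if any RFP sample is <= 0.
    """
    sep = np.asarray(sep, dtype=float).ravel()
    rfp = np.asarray(rfp, dtype=float).ravel()
    if sep.shape != rfp.shape:
        raise ValueError("sep and rfp traces must be aligned (equal length)")
    if np.any(rfp <= 0):
        raise ValueError("all PSD95-RFP samples must be positive")
    ratio = sep / rfp
    trace = FluorTrace(samples=ratio, fs=fs, baseline_window=baseline_window)
    return ratio, delta_f_over_f(trace)


def surface_band_percent(
    bands: pd.DataFrame,
    control_group: str,
    band_col: str = "band",
    loading_col: str = "loading",
    group_col: str = "group",
) -> pd.DataFrame:
    """Percent-of-control surface-protein levels from band densitometry.

    Each lane's band density is normalized to its loading (total-protein)
    density; each normalized value is then expressed as a percentage of the
    mean normalized value over the control lanes, so controls average 100%
    by construction.

    Parameters
    ----------
    bands
        One row per lane with band density, loading density and group label.
    control_group
        Value of ``group_col`` identifying the control lanes.

    Returns a copy of ``bands`` with ``normalized`` and ``percent_of_control``
    columns.
    """
    for col in (band_col, loading_col, group_col):
        if col not in bands.columns:
            raise ValueError(f"missing column {col!r}")
    band = bands[band_col].to_numpy(float)
    loading = bands[loading_col].to_numpy(float)
    if np.any(loading <= 0):
        raise ValueError("loading densities must be positive")
    if np.any(band <= 0):
        raise ValueError("band densities must be positive")
    control = bands[group_col] == control_group
    if not control.any():
        raise ValueError(f"no lanes in control group {control_group!r}")
    out = bands.copy()
    out["normalized"] = band / loading
    control_mean = out.loc[control, "normalized"].mean()
    out["percent_of_control"] = 100.0 * out["normalized"] / control_mean
    return out
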