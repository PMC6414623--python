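"""Pulsatile intensity tracking in OCT tomograms and SLO videos.

During venous collapse the lumen turns hyperreflective (attributed to
orientation changes of red blood cells rather than absorption), so the
mean backscattered intensity in a fixed region of interest oscillates
synchronously with the cardiac cycle.  This module extracts that
normalized ROI intensity trace from an OCT intensity tomogram sequence and
from an en-face SLO-like video, and correlates the two modalities.

Averaging is done in linear intensity: dB tomograms are converted with
10^(dB/10) before the ROI mean is taken (mean reflectivity is the physical
quantity; SLO videos are linear already).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate
from scipy.stats import pearsonr

from .vessel_quant import normalize_series

__all__ = ["RoiIntensitySeries", "roi_mean_intensity", "compare_modalities"]


@dataclass
class RoiIntensitySeries:
    """Mean-intensity time series of one ROI (half-open pixel bounds)."""

    t_s: np.ndarray
    mean_intensity: np.ndarray     # linear units
    norm_intensity: np.ndarray     # normalized to maximum
    roi: tuple[int, int, int, int]
    modality: str                  # "OCT" | "SLO"


def roi_mean_intensity(frames, timestamps_s, roi, modality: str = "OCT",
                       frames_in_db: bool | None = None) -> RoiIntensitySeries:
    """Per-frame arithmetic mean of linear intensity over an ROI.

    Parameters
    ----------
    frames : ndarray (n_frames, depth/height, width)
        Intensity stack.  Interpreted as dB (and converted to linear) when
        ``frames_in_db`` is True; by default OCT sequences are assumed dB
        and SLO sequences linear.
    roi : (z0, z1, x0, x1)
        Half-open pixel bounds; must be nonempty and within the frame.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a 3-D stack")
    z0, z1, x0, x1 = roi
    h, w = frames.shape[1:]
    if not (0 <= z0 < z1 <= h and 0 <= x0 < x1 <= w):
        raise ValueError(f"roi {roi} out of bounds for frames of shape {(h, w)}")
    if frames_in_db is None:
        frames_in_db = modality.upper() == "OCT"
    sub = frames[:, z0:z1, x0:x1]
    if frames_in_db:
        sub = 10.0 ** (sub / 10.0)
    mean = sub.mean(axis=(1, 2))
    return RoiIntensitySeries(
        t_s=np.asarray(timestamps_s, dtype=float),
        mean_intensity=mean,
        norm_intensity=normalize_series(mean),
        roi=tuple(roi),
        modality=modality,
    )


def resample_to(series: RoiIntensitySeries, t_target: np.ndarray) -> np.ndarray:
    """Linear resampling of the normalized trace onto target timestamps."""
    return np.interp(t_target, series.t_s, series.norm_intensity)


def compare_modalities(oct_series: RoiIntensitySeries,
                       slo_series: RoiIntensitySeries):
    """Correlate the OCT and SLO pulsatile intensity traces.

    The faster-sampled trace is linearly resampled onto the slower trace's
    timestamps (no information is invented at the lower rate).  Returns the
    Pearson correlation and the best cross-correlation lag in seconds
    (positive: the second trace lags the first).
    """
    overlap = (min(oct_series.t_s[-1], slo_series.t_s[-1])
               - max(oct_series.t_s[0], slo_series.t_s[0]))
    if overlap <= 0:
        raise ValueError("traces do not overlap in time")

    rate_oct = 1.0 / np.mean(np.diff(oct_series.t_s))
    rate_slo = 1.0 / np.mean(np.diff(slo_series.t_s))
    if rate_oct >= rate_slo:
        slow, fast = slo_series, oct_series
    else:
        slow, fast = oct_series, slo_series
    t = slow.t_s
    keep = (t >= fast.t_s[0]) & (t <= fast.t_s[-1])
    t = t[keep]
    if len(t) < 3:
        raise ValueError("insufficient overlap between traces")
    x = slow.norm_intensity[keep]
    y = resample_to(fast, t)

    r = float(pearsonr(x, y)[0])
    dt = float(np.mean(np.diff(t)))
    x0 = (x - x.mean())
    y0 = (y - y.mean())
    cc = correlate(y0, x0, mode="full")
    lags = np.arange(-(len(x0) - 1), len(x0))
    lag_s = float(lags[int(np.argmax(cc))] * dt)
    return r, lag_s
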