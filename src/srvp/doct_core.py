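"""Phase-resolved (Doppler) OCT core processing.

Converts complex-valued B-scan sequences into co-registered intensity and
phase-difference (Doppler) tomograms.  The Doppler contrast is formed between
*laterally adjacent A-scans within a frame*: for an A-scan period tau the
per-pixel phase difference

    dphi(z, j) = arg( C(z, j+1) * conj(C(z, j)) )   in [-pi, pi)

maps to axial velocity via

    v_axial = lambda0 * dphi / (4 * pi * n * tau)

with n the tissue refractive index.  Dual-channel acquisitions that
inter-A-scan switch between two retinal locations are de-interleaved here,
which doubles the effective per-channel A-scan period (50 kHz per channel at
a 100 kHz sweep rate) and therefore doubles the phase per unit velocity.

All phase aggregation uses circular statistics since the phase difference is
a wrapped variable on the half-open interval [-pi, pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ComplexTomogramSequence",
    "DopplerFrame",
    "wrap_phase",
    "circular_mean",
    "circular_std",
    "circular_median",
    "intensity_tomogram",
    "phase_difference_tomogram",
    "demux_channels",
    "bulk_motion_correct",
    "phase_to_velocity",
    "process_sequence",
    "interleave_channels",
]

#: dB floor applied to log-magnitude tomograms.
INTENSITY_FLOOR_DB = -60.0

#: |cos(theta)| below which the absolute velocity is declared undetermined
#: (Doppler angle within ~2.9 degrees of 90).
COS_THETA_MIN = 0.05


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ComplexTomogramSequence:
    """Time-ordered complex B-scan frames plus acquisition metadata.

    Attributes
    ----------
    frames : ndarray, complex, shape (n_frames, depth, n_ascans)
        Complex tomogram stack; rows are depth (increasing downward),
        columns are lateral A-scan position (0-based).
    timestamps_s : ndarray, shape (n_frames,)
        Frame acquisition times; strictly increasing, uniform within 1%.
    tau_s : float
        Per-channel inter-A-scan period in seconds.
    lambda0_nm : float
        Centre wavelength of the source.
    axial_px_um, lateral_px_um : float
        Pixel pitches.
    channel_id : int
        Which acquisition channel this sequence came from.
    location_offset_mm : float
        Lateral displacement of this channel's B-scan from channel 0.
    """

    frames: np.ndarray
    timestamps_s: np.ndarray
    tau_s: float
    lambda0_nm: float
    axial_px_um: float
    lateral_px_um: float
    channel_id: int = 0
    location_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, depth, lateral) stack")
        if len(self.timestamps_s) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if len(self.timestamps_s) > 1:
            dt = np.diff(self.timestamps_s)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.ptp(dt) > 0.01 * dt.mean():
                raise ValueError("timestamps must be uniform within 1%")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_rate_fps(self) -> float:
        if len(self.timestamps_s) < 2:
            return float("nan")
        return 1.0 / float(np.mean(np.diff(self.timestamps_s)))


@dataclass
class DopplerFrame:
    """Wrapped per-pixel phase differences co-registered to intensity.

    ``dphi`` is one column narrower than the source frame (no wrap-around
    A-scan pair is formed); the intensity frame is cropped to match.
    """

    dphi: np.ndarray                 # radians in [-pi, pi)
    intensity_db: np.ndarray         # log-magnitude, floored
    mask_valid: np.ndarray           # intensity above noise floor + 3 dB
    tau_s: float
    axial_px_um: float
    lateral_px_um: float
    timestamp_s: float = 0.0
    bulk_corrected: bool = False
    quality_flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# circular / phase primitives
# ---------------------------------------------------------------------------

def wrap_phase(x):
    """Wrap angles to the half-open interval [-pi, pi).

    Idempotent; +pi maps to -pi so every angle has one representation.
    """
    x = np.asarray(x, dtype=float)
    out = np.mod(x + np.pi, 2.0 * np.pi) - np.pi
    return out if out.ndim else float(out)


def circular_mean(phi, axis=None):
    """Sign-preserving circular mean, arg of the mean resultant vector."""
    phi = np.asarray(phi, dtype=float)
    z = np.exp(1j * phi).mean(axis=axis)
    return np.angle(z)


def circular_std(phi, axis=None):
    """Circular standard deviation sqrt(-2 ln R) of the resultant length R.

    For tightly clustered angles this converges to the linear std; for a
    uniform distribution it diverges (clipped at 2*pi here).
    """
    phi = np.asarray(phi, dtype=float)
    r = np.abs(np.exp(1j * phi).mean(axis=axis))
    r = np.clip(r, np.exp(-2.0 * np.pi ** 2), 1.0)
    return np.sqrt(-2.0 * np.log(r))


def circular_median(phi):
    """Approximate circular median for clustered angle samples.

    The samples are centred on their circular mean, the ordinary median of
    the wrapped residuals is taken and shifted back.  Exact for data within
    a half-circle of the mean, which is the regime of tissue bulk phase.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        return 0.0
    c = circular_mean(phi)
    return wrap_phase(c + np.median(wrap_phase(phi - c)))


# ---------------------------------------------------------------------------
# tomogram formation
# ---------------------------------------------------------------------------

def intensity_tomogram(frame: np.ndarray, ref: float | None = None) -> np.ndarray:
    """Log-magnitude tomogram 20*log10(|C|/ref), floored at -60 dB.

    Parameters
    ----------
    frame : complex ndarray
    ref : float, optional
        Reference magnitude.  When omitted, the median magnitude of the
        frame itself (median tissue magnitude) is used; for sequences, pass
        the reference derived from the first frame so all frames share one
        scale.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    mag = np.abs(frame)
    if not np.any(mag > 0):
        raise ValueError("empty frame")
    if ref is None:
        ref = float(np.median(mag))
    if ref <= 0:
        raise ValueError("non-positive intensity reference")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(mag / ref)
    return np.maximum(db, INTENSITY_FLOOR_DB)


def _noise_floor_db(intensity_db: np.ndarray) -> float:
    """Noise floor estimate: median of the dimmest 5% of pixels."""
    flat = np.sort(intensity_db.ravel())
    n = max(1, int(0.05 * flat.size))
    return float(np.median(flat[:n]))


def phase_difference_tomogram(
    frame: np.ndarray,
    tau_s: float,
    ref: float | None = None,
    noise_floor_db: float | None = None,
    **meta,
) -> DopplerFrame:
    """Form the Doppler tomogram of one complex frame.

    dphi(z, j) = arg(C(z, j+1) * conj(C(z, j))) wrapped to [-pi, pi); the
    paired intensity frame is cropped by the last column so the two images
    stay co-registered.  ``mask_valid`` marks pixels whose intensity exceeds
    the noise floor by 3 dB.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.shape[1] < 2:
        raise ValueError("frame must have at least 2 A-scans")
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    prod = frame[:, 1:] * np.conj(frame[:, :-1])
    dphi = wrap_phase(np.angle(prod))
    inten = intensity_tomogram(frame, ref=ref)[:, :-1]
    if noise_floor_db is None:
        noise_floor_db = _noise_floor_db(inten)
    mask = inten > noise_floor_db + 3.0
    return DopplerFrame(
        dphi=dphi,
        intensity_db=inten,
        mask_valid=mask,
        tau_s=tau_s,
        axial_px_um=meta.get("axial_px_um", 1.0),
        lateral_px_um=meta.get("lateral_px_um", 1.0),
        timestamp_s=meta.get("timestamp_s", 0.0),
    )


def demux_channels(
    seq: ComplexTomogramSequence, n_channels: int
) -> list[ComplexTomogramSequence]:
    """Split an inter-A-scan-switched sequence into per-channel sequences.

    A-scans j, j+n, j+2n, ... belong to channel j.  Each output sequence has
    its inter-A-scan period and lateral pitch scaled by ``n_channels``.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if n_channels == 1:
        return [seq]
    if seq.frames.shape[2] % n_channels:
        raise ValueError(
            f"A-scan count {seq.frames.shape[2]} not divisible by {n_channels}"
        )
    out = []
    for k in range(n_channels):
        out.append(
            ComplexTomogramSequence(
                frames=seq.frames[:, :, k::n_channels],
                timestamps_s=seq.timestamps_s.copy(),
                tau_s=seq.tau_s * n_channels,
                lambda0_nm=seq.lambda0_nm,
                axial_px_um=seq.axial_px_um,
                lateral_px_um=seq.lateral_px_um * n_channels,
                channel_id=k,
                location_offset_mm=seq.location_offset_mm,
            )
        )
    return out


def interleave_channels(seqs: Sequence[ComplexTomogramSequence]) -> ComplexTomogramSequence:
    """Inverse of :func:`demux_channels`: merge per-channel sequences into
    one inter-A-scan-switched raw sequence (column j of channel k becomes
    raw column j*n + k)."""
    n = len(seqs)
    if n == 1:
        return seqs[0]
    shape = seqs[0].frames.shape
    raw = np.empty((shape[0], shape[1], shape[2] * n), dtype=seqs[0].frames.dtype)
    for k, s in enumerate(seqs):
        if s.frames.shape != shape:
            raise ValueError("channel sequences must share one shape")
        raw[:, :, k::n] = s.frames
    return ComplexTomogramSequence(
        frames=raw,
        timestamps_s=seqs[0].timestamps_s.copy(),
        tau_s=seqs[0].tau_s / n,
        lambda0_nm=seqs[0].lambda0_nm,
        axial_px_um=seqs[0].axial_px_um,
        lateral_px_um=seqs[0].lateral_px_um / n,
        channel_id=-1,
        location_offset_mm=seqs[0].location_offset_mm,
    )


# ---------------------------------------------------------------------------
# bulk motion correction
# ---------------------------------------------------------------------------

MIN_TISSUE_PIXELS = 100


def bulk_motion_correct(
    d: DopplerFrame, exclude_mask: np.ndarray | None = None
) -> DopplerFrame:
    """Remove per-A-scan bulk phase using the circular median of tissue.

    Axial eye motion adds a common phase offset per A-scan.  For every
    column the circular median of the phase difference over *tissue* pixels
    (valid pixels outside ``exclude_mask``, e.g. outside the lumen ROI or
    the current flow mask) is subtracted and the result re-wrapped, so the
    static-tissue circular median is ~0 afterwards.

    If fewer than ``MIN_TISSUE_PIXELS`` tissue pixels exist the frame is
    passed through unchanged with a quality flag.
    """
    tissue = d.mask_valid.copy()
    if exclude_mask is not None:
        tissue &= ~np.asarray(exclude_mask, dtype=bool)
    if tissue.sum() < MIN_TISSUE_PIXELS:
        warnings.warn("too few tissue pixels for bulk motion correction")
        out = replace(d)
        out.quality_flags = d.quality_flags + ["bulk_correction_skipped"]
        return out

    ncols = d.dphi.shape[1]
    offsets = np.zeros(ncols)
    for j in range(ncols):
        col_tissue = d.dphi[tissue[:, j], j]
        if col_tissue.size:
            offsets[j] = circular_median(col_tissue)
    corrected = wrap_phase(d.dphi - offsets[None, :])
    out = replace(d, dphi=corrected, bulk_corrected=True)
    out.quality_flags = list(d.quality_flags)
    return out


# ---------------------------------------------------------------------------
# velocity conversion
# ---------------------------------------------------------------------------

def phase_to_velocity(
    dphi_rad,
    lambda0_nm: float,
    tau_s: float,
    n_index: float = 1.38,
    theta_deg: float | None = None,
):
    """Convert phase differences to axial (and optionally absolute) velocity.

    v_axial = lambda0 * dphi / (4 pi n tau); the absolute velocity
    v_axial / cos(theta) is only returned when |cos(theta)| > 0.05 — close
    to a 90-degree Doppler angle the geometry cannot determine it.

    Returns
    -------
    (v_axial_mm_s, v_abs_mm_s, determined)
        ``v_abs_mm_s`` is NaN and ``determined`` False when the Doppler
        angle is unsuitable or not given.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    dphi = np.asarray(dphi_rad, dtype=float)
    if not np.all(np.isfinite(dphi)):
        raise ValueError("dphi must be finite")
    lam_m = lambda0_nm * 1e-9
    v_axial = lam_m * dphi / (4.0 * np.pi * n_index * tau_s) * 1e3  # mm/s
    if theta_deg is None:
        return v_axial, np.full_like(v_axial, np.nan), False
    cos_t = np.cos(np.deg2rad(theta_deg))
    if abs(cos_t) <= COS_THETA_MIN:
        return v_axial, np.full_like(v_axial, np.nan), False
    return v_axial, v_axial / cos_t, True


# ---------------------------------------------------------------------------
# sequence-level driver
# ---------------------------------------------------------------------------

def process_sequence(
    seq: ComplexTomogramSequence,
    bulk_correction: bool = True,
    lumen_roi: tuple[int, int, int, int] | None = None,
) -> list[DopplerFrame]:
    """Run intensity + Doppler formation (and bulk correction) per frame.

    The intensity reference (median magnitude) and noise floor are derived
    from the first frame and reused so the dB scale is common to the whole
    sequence.  ``lumen_roi`` = (z0, z1, x0, x1) half-open bounds excluded
    from the tissue used for bulk correction.
    """
    ref = float(np.median(np.abs(seq.frames[0])))
    exclude = None
    first = None
    out: list[DopplerFrame] = []
    for i, frame in enumerate(seq.frames):
        d = phase_difference_tomogram(
            frame,
            seq.tau_s,
            ref=ref,
            noise_floor_db=None if first is None else first,
            axial_px_um=seq.axial_px_um,
            lateral_px_um=seq.lateral_px_um,
            timestamp_s=float(seq.timestamps_s[i]),
        )
        if first is None:
            first = _noise_floor_db(d.intensity_db)
            d.mask_valid = d.intensity_db > first + 3.0
            if lumen_roi is not None:
                z0, z1, x0, x1 = lumen_roi
                exclude = np.zeros_like(d.mask_valid)
                exclude[z0:z1, x0:x1] = True
        if bulk_correction:
            d = bulk_motion_correct(d, exclude_mask=exclude)
        out.append(d)
    return out
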