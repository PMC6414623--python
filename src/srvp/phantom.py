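"""Synthetic Doppler-OCT phantom of a partially collapsing retinal vein.

The generator emulates repeated linear B-scans at a fixed retinal location
with a swept-source system (centre wavelength 1045 nm, 100 kHz A-scan rate,
optionally inter-A-scan switched over two channels at 50 kHz each whose
B-scans are 0.9 mm apart), plus an en-face SLO-like intensity video at
10 fps.  It produces complex tomogram sequences together with a full
ground-truth record so that downstream segmentation and pulsatility
quantification can be tested as a parameter-recovery problem.

Forward model in brief
----------------------
* Static tissue below a vitreous gap is fully developed speckle: per-pixel
  Rayleigh magnitude on a depth-decaying mean-power profile.  The signal
  phase along the lateral direction is the *cumulative deterministic
  Doppler increment* on top of a random per-row origin, so adjacent-A-scan
  phase differences are exactly the modelled Doppler phase; lateral speckle
  decorrelation noise is deliberately not modelled (phase noise is purely
  SNR-driven additive complex Gaussian noise, the sigma ~ SNR^-1/2 regime).
* The vein lumen is an ellipse with independently modulated semi-axes
  a(t) = a0 (1 - m_lat c(t)), b(t) = b0 (1 - m_ax c(t)) driven by a cardiac
  collapse waveform c(t) in [0, 1] — the minimal shape consistent with the
  axial-dominant caliber change of venous collapse.
* Flow is parabolic on the elliptical lumen with a conserved volumetric
  flow Q(t) = Q0 (1 + flow_mod s(t)) (s: standardized venous waveform), so
  the centre-line velocity scales with A0 / A(t): a collapsing lumen speeds
  up, producing the phase/area anti-correlation seen in a real collapse.
  Phase per pixel: dphi = 4 pi n v_z tau / lambda0 with v_z = v cos(theta).
* Collapse-synchronous hyperreflectivity multiplies the lumen mean power
  by (1 + intensity_mod c(t)).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import h5py
import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter1d

from .doct_core import ComplexTomogramSequence

__all__ = [
    "CardiacModel",
    "VesselModel",
    "PhantomConfig",
    "GroundTruth",
    "CardiacWaveforms",
    "SLOSequence",
    "make_cardiac_waveforms",
    "vessel_geometry_at",
    "simulate_complex_sequence",
    "simulate_slo_sequence",
    "doppler_phase_per_mm_s",
    "get_preset",
    "PRESETS",
    "default_search_roi",
    "default_intensity_roi",
    "write_phantom_h5",
    "read_phantom_h5",
    "write_slo_tiff",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 1045


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class CardiacModel:
    """Cardiac driving waveforms.

    The arterial pulse is a systolic Gaussian peak (position and width as
    fractions of the cycle) with a small dicrotic-notch bump.  The venous
    waveform is the arterial one smoothed with a symmetric Gaussian kernel
    of width ``venous_smoothing_s`` (the "washed-out" profile); the collapse
    waveform is the venous one delayed by ``collapse_phase_offset_s``
    (default 0: collapse peaks coincide with arterial peaks).
    """

    heart_rate_bpm: float = 60.0
    hrv_frac: float = 0.05           # per-cycle period jitter fraction
    arterial_peak_frac: float = 0.10  # systolic peak time as cycle fraction
    arterial_width_frac: float = 0.10
    dicrotic_notch_amp: float = 0.15
    venous_smoothing_s: float = 0.12
    collapse_phase_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")
        if not 0 <= self.hrv_frac < 0.3:
            raise ValueError("hrv_frac must be in [0, 0.3)")


@dataclass
class VesselModel:
    """Elliptical vessel lumen with independently modulated axes.

    ``geometry='cross'`` is the usual transverse cut (elliptical lumen);
    ``geometry='along'`` models a scan *along* the vessel: a depth band
    spanning all A-scans with a parabolic profile in depth only, and an
    optionally varying Doppler angle across the scan
    (``doppler_angle_deg`` at the left edge to ``doppler_angle_end_deg`` at
    the right), which reproduces the sign flip where the angle crosses 90.
    """

    center_z_px: int = 80
    center_x_px: Optional[int] = None   # None -> frame centre
    a0_um: float = 60.0                 # resting lateral semi-axis
    b0_um: float = 60.0                 # resting axial semi-axis
    m_lat: float = 0.0                  # fractional lateral collapse
    m_ax: float = 0.0                   # fractional axial collapse
    v_peak_mm_s: float = 15.0           # resting centre-line velocity
    doppler_angle_deg: float = 60.0
    doppler_angle_end_deg: Optional[float] = None
    flow_mod: float = 0.0               # fractional flow-waveform amplitude
    intensity_mod: float = 0.0          # collapse-coupled hyperreflectivity
    reflectivity: float = 1.0           # lumen/tissue mean-power ratio
    kind: str = "vein"                  # "vein" | "artery"
    geometry: str = "cross"             # "cross" | "along"

    def __post_init__(self) -> None:
        if not (0 <= self.m_lat < 1 and 0 <= self.m_ax < 1):
            raise ValueError("collapse fractions must be in [0, 1)")
        if self.a0_um <= 0 or self.b0_um <= 0:
            raise ValueError("semi-axes must be positive")
        for th in (self.doppler_angle_deg, self.doppler_angle_end_deg):
            if th is not None and not 0.0 < th < 180.0:
                raise ValueError("doppler angle must be in (0, 180) degrees")
        if self.kind not in ("vein", "artery"):
            raise ValueError("kind must be 'vein' or 'artery'")
        if self.geometry not in ("cross", "along"):
            raise ValueError("geometry must be 'cross' or 'along'")


@dataclass
class PhantomConfig:
    """Full generative parameterization of one acquisition."""

    lambda0_nm: float = 1045.0
    bandwidth_nm: float = 100.0          # metadata only (no axial PSF model)
    ascan_rate_hz: float = 100_000.0
    n_channels: int = 1
    channel_separation_mm: float = 0.9
    bscan_length_mm: float = 0.8
    n_ascans: int = 1024                 # total (interleaved) A-scans
    frame_rate_fps: float = 24.0
    slo_frame_rate_fps: float = 10.0
    duration_s: float = 3.2
    depth_px: int = 160
    axial_px_um: float = 4.0
    lateral_px_um: Optional[float] = None  # derived from length/density
    tissue_refractive_index: float = 1.38
    tissue_surface_px: int = 20
    tissue_decay_um: float = 400.0
    vessel: VesselModel = field(default_factory=VesselModel)
    artery: Optional[VesselModel] = None
    cardiac: CardiacModel = field(default_factory=CardiacModel)
    snr_db: Optional[float] = 25.0       # None -> noise-free
    pwv_mm_s: float = float("inf")       # pulse wave velocity between sites
    drift_um_per_s: float = 0.0          # optional linear eye-motion drift
    slo_size_px: int = 256
    slo_noise_frac: float = 0.02
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_channels not in (1, 2):
            raise ValueError("n_channels must be 1 or 2")
        for name in ("ascan_rate_hz", "frame_rate_fps", "slo_frame_rate_fps",
                     "duration_s", "axial_px_um", "bscan_length_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_ascans % self.n_channels:
            raise ValueError("n_ascans must be divisible by n_channels")
        if self.lateral_px_um is None:
            self.lateral_px_um = (
                self.bscan_length_mm * 1000.0 / self.ascans_per_channel
            )
        n_cycles = self.duration_s * self.cardiac.heart_rate_bpm / 60.0
        if n_cycles < 1.0:
            raise ValueError("insufficient duration: less than one cardiac cycle")

    @property
    def ascans_per_channel(self) -> int:
        return self.n_ascans // self.n_channels

    @property
    def tau_s(self) -> float:
        """Per-channel inter-A-scan period (doubles in dual-channel mode)."""
        return self.n_channels / self.ascan_rate_hz

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_fps))

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if isinstance(d.get("vessel"), dict):
            d["vessel"] = VesselModel(**d["vessel"])
        if isinstance(d.get("artery"), dict):
            d["artery"] = VesselModel(**d["artery"])
        if isinstance(d.get("cardiac"), dict):
            d["cardiac"] = CardiacModel(**d["cardiac"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True per-frame time courses of one channel (the recovery oracle)."""

    t_s: np.ndarray
    true_lat_diameter_um: np.ndarray
    true_ax_diameter_um: np.ndarray
    true_area_um2: np.ndarray
    true_mean_vz_mm_s: np.ndarray
    true_flow_au: np.ndarray
    collapse_series: np.ndarray
    arterial_series: np.ndarray
    cycle_starts_s: np.ndarray
    pwv_mm_s: float = float("inf")


@dataclass
class CardiacWaveforms:
    t_s: np.ndarray
    arterial: np.ndarray
    venous: np.ndarray
    collapse: np.ndarray
    cycle_starts_s: np.ndarray


@dataclass
class SLOSequence:
    """En-face SLO-like intensity video (linear units)."""

    frames: np.ndarray          # (n_frames, height, width) float
    timestamps_s: np.ndarray
    px_um: float
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cardiac waveforms
# ---------------------------------------------------------------------------

_FINE_DT = 1e-3  # internal evaluation grid for smoothing, seconds


def _draw_cycle_periods(cardiac: CardiacModel, t_end: float, rng) -> np.ndarray:
    """Cycle periods with per-cycle uniform jitter, covering [0, t_end]."""
    t0 = 60.0 / cardiac.heart_rate_bpm
    periods = []
    total = 0.0
    while total < t_end + t0:
        jit = rng.uniform(-cardiac.hrv_frac, cardiac.hrv_frac)
        p = t0 * (1.0 + jit)
        periods.append(p)
        total += p
    return np.asarray(periods)


def _arterial_pulse_shape(phase: np.ndarray, cardiac: CardiacModel) -> np.ndarray:
    """Arterial pulse as a function of cycle phase in [0, 1)."""
    p = np.exp(-0.5 * ((phase - cardiac.arterial_peak_frac)
                       / cardiac.arterial_width_frac) ** 2)
    p = p + cardiac.dicrotic_notch_amp * np.exp(
        -0.5 * ((phase - 0.35) / 0.08) ** 2
    )
    return p / p.max() if p.size else p


def make_cardiac_waveforms(
    cardiac: CardiacModel, t_s: np.ndarray, seed: int = DEFAULT_SEED
) -> CardiacWaveforms:
    """Arterial, venous and collapse series on the given uniform time grid.

    All three series are normalized to [0, 1].  The series are evaluated on
    an internal 1 ms grid (so the same seed yields consistent waveforms for
    OCT and SLO frame grids) and sampled at ``t_s`` by linear interpolation.
    Cycle starts are the drawn cycle boundaries within the grid span.
    """
    t_s = np.asarray(t_s, dtype=float)
    if t_s.ndim != 1 or len(t_s) < 2:
        raise ValueError("time grid must be 1-D with at least 2 samples")
    dt = np.diff(t_s)
    if np.ptp(dt) > 1e-9 + 1e-6 * dt.mean():
        raise ValueError("time grid must be uniform")
    span = float(t_s[-1] - t_s[0])
    period0 = 60.0 / cardiac.heart_rate_bpm
    if span < period0:
        raise ValueError("insufficient duration: grid shorter than one cardiac period")

    rng = np.random.default_rng(seed)
    pad = 4.0 * cardiac.venous_smoothing_s + abs(cardiac.collapse_phase_offset_s) + period0
    t_end = float(t_s[-1]) + pad
    periods = _draw_cycle_periods(cardiac, t_end, rng)
    starts = np.concatenate([[0.0], np.cumsum(periods)])

    fine = np.arange(-pad, t_end + _FINE_DT, _FINE_DT)
    # cycle phase at each fine sample; negative times use the first cycle
    # extended periodically backward
    idx = np.clip(np.searchsorted(starts, fine, side="right") - 1, 0, len(periods) - 1)
    phase = (fine - starts[idx]) / periods[idx]
    phase = np.mod(phase, 1.0)
    arterial_fine = _arterial_pulse_shape(phase, cardiac)

    if cardiac.venous_smoothing_s > 0:
        venous_fine = gaussian_filter1d(
            arterial_fine, cardiac.venous_smoothing_s / _FINE_DT, mode="nearest"
        )
        vmin, vmax = venous_fine.min(), venous_fine.max()
        venous_fine = (venous_fine - vmin) / (vmax - vmin)
    else:
        venous_fine = arterial_fine.copy()

    arterial = np.interp(t_s, fine, arterial_fine)
    venous = np.interp(t_s, fine, venous_fine)
    collapse = np.interp(t_s - cardiac.collapse_phase_offset_s, fine, venous_fine)
    c0, c1 = collapse.min(), collapse.max()
    if c1 > c0:
        collapse = (collapse - c0) / (c1 - c0)

    in_span = starts[(starts >= t_s[0]) & (starts <= t_s[-1])]
    return CardiacWaveforms(
        t_s=t_s, arterial=arterial, venous=venous, collapse=collapse,
        cycle_starts_s=in_span,
    )


# ---------------------------------------------------------------------------
# geometry and Doppler scale
# ---------------------------------------------------------------------------

def vessel_geometry_at(v: VesselModel, collapse_value: float):
    """Instantaneous semi-axes and area of the elliptical lumen.

    a = a0 (1 - m_lat c), b = b0 (1 - m_ax c), area = pi a b; the relative
    area loss at full collapse is 1 - (1 - m_lat)(1 - m_ax).
    """
    if not 0.0 <= collapse_value <= 1.0:
        raise ValueError("collapse_value must be in [0, 1]")
    a = v.a0_um * (1.0 - v.m_lat * collapse_value)
    b = v.b0_um * (1.0 - v.m_ax * collapse_value)
    return a, b, np.pi * a * b


def doppler_phase_per_mm_s(lambda0_nm: float, tau_s: float, n_index: float) -> float:
    """Phase difference (rad) per mm/s of axial velocity: 4 pi n tau / lambda0."""
    return 4.0 * np.pi * n_index * tau_s / (lambda0_nm * 1e-9) * 1e-3


# ---------------------------------------------------------------------------
# complex sequence synthesis
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    """Zero-mean series scaled so max |x| = 1 (flow modulation driver)."""
    x = x - x.mean()
    m = np.max(np.abs(x))
    return x / m if m > 0 else x


def _vessel_phase_and_power(
    vessel: VesselModel,
    cfg: PhantomConfig,
    flow_factor: float,
    collapse_value: float,
    zz: np.ndarray,
    xx: np.ndarray,
):
    """Per-pixel Doppler phase increment and power factor of one vessel.

    ``flow_factor`` multiplies the resting volumetric flow; the centre-line
    velocity additionally scales with A0/A(t) (flow conservation through
    the collapse).
    """
    k_phase = doppler_phase_per_mm_s(
        cfg.lambda0_nm, cfg.tau_s, cfg.tissue_refractive_index
    )
    a_um, b_um, area = vessel_geometry_at(vessel, collapse_value)
    a0, b0, area0 = vessel_geometry_at(vessel, 0.0)
    cx = vessel.center_x_px
    if cx is None:
        cx = cfg.ascans_per_channel // 2
    a_px = a_um / cfg.lateral_px_um
    b_px = b_um / cfg.axial_px_um

    if vessel.geometry == "along":
        rho2 = ((zz - vessel.center_z_px) / b_px) ** 2
    else:
        rho2 = (((xx - cx) / a_px) ** 2
                + ((zz - vessel.center_z_px) / b_px) ** 2)
    inside = rho2 < 1.0

    v_center = vessel.v_peak_mm_s * flow_factor * (area0 / area)
    if vessel.doppler_angle_end_deg is not None:
        ncols = xx.shape[1]
        theta = np.deg2rad(
            vessel.doppler_angle_deg
            + (vessel.doppler_angle_end_deg - vessel.doppler_angle_deg)
            * xx / max(ncols - 1, 1)
        )
        cos_t = np.cos(theta)
    else:
        cos_t = np.cos(np.deg2rad(vessel.doppler_angle_deg))

    dphi = np.where(inside, k_phase * v_center * (1.0 - rho2) * cos_t, 0.0)
    power = np.where(
        inside,
        vessel.reflectivity * (1.0 + vessel.intensity_mod * collapse_value),
        1.0,
    )
    return dphi, power, inside


def _synthesize_channel(
    cfg: PhantomConfig,
    vessels: list[VesselModel],
    flow_series: dict[str, np.ndarray],
    collapse: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Complex frame stack for one channel (vectorized per frame)."""
    depth, cols = cfg.depth_px, cfg.ascans_per_channel
    n_frames = cfg.n_frames
    zz, xx = np.meshgrid(np.arange(depth), np.arange(cols), indexing="ij")

    # depth-decaying tissue power profile above a vitreous (noise-only) gap
    z_rel = (zz - cfg.tissue_surface_px) * cfg.axial_px_um
    tissue_power = np.where(
        zz >= cfg.tissue_surface_px, np.exp(-z_rel / cfg.tissue_decay_um), 0.0
    )

    # noise power pinned to the lumen SNR at the vein's depth
    vein = vessels[0]
    p_lumen = float(
        np.exp(-(vein.center_z_px - cfg.tissue_surface_px)
               * cfg.axial_px_um / cfg.tissue_decay_um) * vein.reflectivity
    )
    if cfg.snr_db is None:
        p_noise = 0.0
    else:
        p_noise = p_lumen / 10.0 ** (cfg.snr_db / 10.0)

    # warn once if the resting centre-line phase would wrap
    k_phase = doppler_phase_per_mm_s(
        cfg.lambda0_nm, cfg.tau_s, cfg.tissue_refractive_index
    )
    for v in vessels:
        cos_ref = np.cos(np.deg2rad(v.doppler_angle_deg))
        if abs(k_phase * v.v_peak_mm_s * cos_ref) > np.pi:
            warnings.warn("phase wrapping in phantom")

    # static scatterers: one frozen Rayleigh speckle magnitude field per
    # channel (re-imaging the same location reproduces the same speckle);
    # additive detection noise is redrawn every frame
    speckle = np.hypot(rng.standard_normal((depth, cols)),
                       rng.standard_normal((depth, cols)))

    frames = np.empty((n_frames, depth, cols), dtype=np.complex64)
    for i in range(n_frames):
        dphi_map = np.zeros((depth, cols))
        power = tissue_power.copy()
        for v in vessels:
            c_val = float(collapse[i]) if v.kind == "vein" else 0.0
            ff = float(flow_series[v.kind][i])
            dphi_v, pow_v, inside = _vessel_phase_and_power(
                v, cfg, ff, c_val, zz, xx
            )
            dphi_map = np.where(inside, dphi_v, dphi_map)
            power = np.where(inside, power * pow_v, power)
        # cumulative deterministic phase along the lateral direction
        phi = np.concatenate(
            [np.zeros((depth, 1)), np.cumsum(dphi_map[:, :-1], axis=1)], axis=1
        )
        phi += rng.uniform(0.0, 2.0 * np.pi, size=(depth, 1))
        mag = np.sqrt(power / 2.0) * speckle
        c = mag * np.exp(1j * phi)
        if p_noise > 0:
            c = c + np.sqrt(p_noise / 2.0) * (
                rng.standard_normal((depth, cols))
                + 1j * rng.standard_normal((depth, cols))
            )
        frames[i] = c.astype(np.complex64)
    return frames


def simulate_complex_sequence(cfg: PhantomConfig):
    """Generate per-channel complex B-scan sequences plus ground truth.

    Returns
    -------
    (sequences, truths)
        Lists of :class:`ComplexTomogramSequence` and :class:`GroundTruth`,
        one entry per channel.  Channel 1 (if present) images a
        non-collapsing section of the same vein ``channel_separation_mm``
        away, with the flow waveform delayed by separation / PWV.

    Deterministic for a given config (seeded RNG per channel).
    """
    t = np.arange(cfg.n_frames) / cfg.frame_rate_fps
    ss = np.random.SeedSequence(cfg.seed)
    wave_seed, *chan_seeds = [int(s.generate_state(1)[0] % 2**31)
                              for s in ss.spawn(1 + cfg.n_channels)]
    waves = make_cardiac_waveforms(cfg.cardiac, t, seed=wave_seed)

    # fine-grid venous waveform for delayed (site-B) sampling
    fine_t = np.arange(0.0, cfg.duration_s + 1.0, _FINE_DT)
    fine_waves = make_cardiac_waveforms(cfg.cardiac, fine_t, seed=wave_seed)
    s_fine = _standardize(fine_waves.venous)
    s_art_fine = _standardize(fine_waves.arterial)

    if np.isfinite(cfg.pwv_mm_s) and cfg.pwv_mm_s > 0:
        delay_s = cfg.channel_separation_mm / cfg.pwv_mm_s
    else:
        delay_s = 0.0

    sequences, truths = [], []
    for ch in range(cfg.n_channels):
        ch_delay = ch * delay_s
        t_eff = np.clip(t - ch_delay, 0.0, fine_t[-1])
        s_ven = np.interp(t_eff, fine_t, s_fine)
        s_art = np.interp(t_eff, fine_t, s_art_fine)
        collapse = waves.collapse if ch == 0 else np.interp(
            t_eff, fine_t, _renorm01(fine_waves.collapse)
        )

        vein = cfg.vessel if ch == 0 else replace(cfg.vessel, m_lat=0.0, m_ax=0.0)
        vessels = [vein] + ([cfg.artery] if cfg.artery is not None else [])
        flow_series = {
            "vein": 1.0 + vein.flow_mod * s_ven,
            "artery": (1.0 + cfg.artery.flow_mod * s_art)
            if cfg.artery is not None else np.ones_like(t),
        }
        arterial = np.interp(t_eff, fine_t, _renorm01(fine_waves.arterial))
        rng = np.random.default_rng(chan_seeds[ch])
        frames = _synthesize_channel(cfg, vessels, flow_series, collapse, rng)
        sequences.append(
            ComplexTomogramSequence(
                frames=frames,
                timestamps_s=t,
                tau_s=cfg.tau_s,
                lambda0_nm=cfg.lambda0_nm,
                axial_px_um=cfg.axial_px_um,
                lateral_px_um=cfg.lateral_px_um,
                channel_id=ch,
                location_offset_mm=ch * cfg.channel_separation_mm,
            )
        )
        truths.append(_ground_truth(cfg, vein, t, collapse, arterial,
                                    flow_series["vein"], waves.cycle_starts_s))
    return sequences, truths


def _renorm01(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)


def _ground_truth(cfg, vessel, t, collapse, arterial, vein_flow, cycle_starts):
    a = vessel.a0_um * (1.0 - vessel.m_lat * collapse)
    b = vessel.b0_um * (1.0 - vessel.m_ax * collapse)
    area = np.pi * a * b
    area0 = np.pi * vessel.a0_um * vessel.b0_um
    v_center = vessel.v_peak_mm_s * vein_flow * (area0 / area)
    mean_v = 0.5 * v_center                   # parabolic profile: mean = centre/2
    cos_t = np.cos(np.deg2rad(vessel.doppler_angle_deg))
    return GroundTruth(
        t_s=t,
        true_lat_diameter_um=2.0 * a,
        true_ax_diameter_um=2.0 * b,
        true_area_um2=area,
        true_mean_vz_mm_s=mean_v * cos_t,
        true_flow_au=mean_v * area,
        collapse_series=collapse,
        arterial_series=arterial,
        cycle_starts_s=cycle_starts,
        pwv_mm_s=cfg.pwv_mm_s,
    )


# ---------------------------------------------------------------------------
# SLO-like en-face video
# ---------------------------------------------------------------------------

def simulate_slo_sequence(cfg: PhantomConfig) -> SLOSequence:
    """En-face SLO-like intensity video of the same vessel and cardiac cycle.

    Depth-integrated reflectivity: the vessel appears as a dark vertical
    band of width 2 a(t) whose in-band brightness follows the
    collapse-coupled hyperreflectivity (1 + intensity_mod c(t)).  Frames at
    ``slo_frame_rate_fps`` with seeded multiplicative noise.
    """
    n_frames = int(round(cfg.duration_s * cfg.slo_frame_rate_fps))
    t = np.arange(n_frames) / cfg.slo_frame_rate_fps
    ss = np.random.SeedSequence(cfg.seed)
    wave_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
    waves = make_cardiac_waveforms(cfg.cardiac, t, seed=wave_seed)

    size = cfg.slo_size_px
    px_um = cfg.bscan_length_mm * 1000.0 / size
    x_um = (np.arange(size) + 0.5) * px_um
    cx_px = cfg.vessel.center_x_px
    if cx_px is None:
        cx_px = cfg.ascans_per_channel // 2
    cx_um = cx_px * cfg.lateral_px_um

    rng = np.random.default_rng(int(ss.spawn(2)[1].generate_state(1)[0] % 2**31))
    frames = np.empty((n_frames, size, size), dtype=float)
    band_attenuation = 0.5
    for i in range(n_frames):
        a_um, _, _ = vessel_geometry_at(cfg.vessel, float(waves.collapse[i]))
        profile = np.ones(size)
        in_band = np.abs(x_um - cx_um) < a_um
        profile[in_band] = band_attenuation * (
            1.0 + cfg.vessel.intensity_mod * waves.collapse[i]
        )
        img = np.tile(profile, (size, 1))
        img *= 1.0 + cfg.slo_noise_frac * rng.standard_normal((size, size))
        frames[i] = np.clip(img, 0.0, None)
    return SLOSequence(
        frames=frames,
        timestamps_s=t,
        px_um=px_um,
        metadata={
            "slo_frame_rate_fps": cfg.slo_frame_rate_fps,
            "vessel_center_x_um": cx_um,
            "band_attenuation": band_attenuation,
            "seed": cfg.seed,
        },
    )


# ---------------------------------------------------------------------------
# calibrated presets
# ---------------------------------------------------------------------------

def _preset_s1() -> PhantomConfig:
    """Subject-1-like single-channel phantom: 50% area collapse
    (m_lat = 0.20, m_ax = 0.375 -> 1 - 0.8 * 0.625 = 0.50)."""
    return PhantomConfig(
        vessel=VesselModel(
            m_lat=0.20, m_ax=0.375, doppler_angle_deg=60.0,
            intensity_mod=0.30, flow_mod=0.0,
        ),
    )


def _preset_s2() -> PhantomConfig:
    """Subject-2-like phantom: 60% area collapse (m_lat = 0.20, m_ax = 0.50)."""
    return PhantomConfig(
        vessel=VesselModel(
            m_lat=0.20, m_ax=0.50, doppler_angle_deg=70.0,
            intensity_mod=0.30, flow_mod=0.0,
        ),
    )


def _preset_flow() -> PhantomConfig:
    """Dual-channel flow phantom: mildly collapsing vein at site A, the
    same (non-collapsing) vein 0.9 mm away at site B, flow oscillation
    +-20%, plus a nearby artery; PWV 200 mm/s (sub-frame delay at 24 fps)."""
    return PhantomConfig(
        n_channels=2,
        n_ascans=2048,
        vessel=VesselModel(
            center_x_px=384, m_lat=0.10, m_ax=0.20,
            doppler_angle_deg=80.0, flow_mod=0.20, intensity_mod=0.20,
        ),
        artery=VesselModel(
            center_x_px=768, a0_um=35.0, b0_um=35.0, v_peak_mm_s=10.0,
            doppler_angle_deg=110.0, flow_mod=0.50, kind="artery",
        ),
        pwv_mm_s=200.0,
    )


def _preset_along() -> PhantomConfig:
    """Scan along the vessel with the Doppler angle sweeping 80 -> 100
    degrees across the B-scan (sign flip at the 90-degree crossing)."""
    return PhantomConfig(
        vessel=VesselModel(
            geometry="along", b0_um=50.0,
            doppler_angle_deg=80.0, doppler_angle_end_deg=100.0,
        ),
    )


PRESETS = {
    "phantom_S1": _preset_s1,
    "phantom_S2": _preset_s2,
    "phantom_flow": _preset_flow,
    "phantom_along": _preset_along,
}


def get_preset(name: str, seed: int | None = None, **overrides) -> PhantomConfig:
    """Named calibrated phantom config, optionally re-seeded/overridden."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def default_search_roi(cfg: PhantomConfig, vessel: VesselModel | None = None,
                       pad: float = 1.6):
    """Search ROI (z0, z1, x0, x1) around the resting vessel, padded."""
    v = vessel or cfg.vessel
    cx = v.center_x_px if v.center_x_px is not None else cfg.ascans_per_channel // 2
    az = pad * v.b0_um / cfg.axial_px_um
    ax = pad * v.a0_um / cfg.lateral_px_um
    z0 = max(0, int(v.center_z_px - az))
    z1 = min(cfg.depth_px, int(v.center_z_px + az) + 1)
    x0 = max(0, int(cx - ax))
    x1 = min(cfg.ascans_per_channel, int(cx + ax) + 1)
    return (z0, z1, x0, x1)


def default_intensity_roi(cfg: PhantomConfig):
    """Canonical intensity ROI: central half of the resting lumen."""
    v = cfg.vessel
    cx = v.center_x_px if v.center_x_px is not None else cfg.ascans_per_channel // 2
    az = 0.5 * v.b0_um / cfg.axial_px_um
    ax = 0.5 * v.a0_um / cfg.lateral_px_um
    return (int(v.center_z_px - az), int(v.center_z_px + az) + 1,
            int(cx - ax), int(cx + ax) + 1)


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def write_phantom_h5(path, sequences, truths, cfg: PhantomConfig) -> None:
    """HDF5 layout: /chan{k}/real, /chan{k}/imag (frames, depth, ascans),
    /truth/chan{k}/* arrays, config fields as root attributes (nested
    models as JSON strings)."""
    with h5py.File(path, "w") as f:
        for attr, value in asdict(cfg).items():
            if isinstance(value, dict) or value is None:
                f.attrs[attr] = json.dumps(value)
            else:
                f.attrs[attr] = value
        for seq, gt in zip(sequences, truths):
            g = f.create_group(f"chan{seq.channel_id}")
            g.create_dataset("real", data=seq.frames.real, dtype="f4")
            g.create_dataset("imag", data=seq.frames.imag, dtype="f4")
            g.attrs["tau_s"] = seq.tau_s
            g.attrs["location_offset_mm"] = seq.location_offset_mm
            tg = f.create_group(f"truth/chan{seq.channel_id}")
            for name, arr in asdict(gt).items():
                if name == "pwv_mm_s":
                    tg.attrs[name] = arr
                else:
                    tg.create_dataset(name, data=np.asarray(arr))


def read_phantom_h5(path):
    """Read the phantom container back into sequences, truths and config."""
    with h5py.File(path, "r") as f:
        cfg_dict = {}
        for key, value in f.attrs.items():
            if isinstance(value, (bytes, str)):
                cfg_dict[key] = json.loads(value)
            elif isinstance(value, np.generic):
                cfg_dict[key] = value.item()
            else:
                cfg_dict[key] = value
        cfg = PhantomConfig.from_dict(cfg_dict)
        sequences, truths = [], []
        t = np.arange(cfg.n_frames) / cfg.frame_rate_fps
        for ch in range(cfg.n_channels):
            g = f[f"chan{ch}"]
            frames = g["real"][()] + 1j * g["imag"][()]
            sequences.append(
                ComplexTomogramSequence(
                    frames=frames.astype(np.complex64),
                    timestamps_s=t,
                    tau_s=float(g.attrs["tau_s"]),
                    lambda0_nm=cfg.lambda0_nm,
                    axial_px_um=cfg.axial_px_um,
                    lateral_px_um=cfg.lateral_px_um,
                    channel_id=ch,
                    location_offset_mm=float(g.attrs["location_offset_mm"]),
                )
            )
            tg = f[f"truth/chan{ch}"]
            truths.append(
                GroundTruth(
                    **{name: tg[name][()] for name in tg},
                    pwv_mm_s=float(tg.attrs["pwv_mm_s"]),
                )
            )
    return sequences, truths, cfg


def write_slo_tiff(path, slo: SLOSequence) -> None:
    """Multi-page 16-bit grayscale TIFF plus a JSON metadata sidecar."""
    peak = slo.frames.max()
    scaled = (slo.frames / peak * 65535.0).astype(np.uint16) if peak > 0 else (
        np.zeros_like(slo.frames, dtype=np.uint16)
    )
    tifffile.imwrite(str(path), scaled)
    meta = dict(slo.metadata)
    meta.update({
        "px_um": slo.px_um,
        "timestamps_s": [float(x) for x in slo.timestamps_s],
        "intensity_scale": float(peak) / 65535.0 if peak > 0 else 1.0,
    })
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_slo_tiff(path) -> SLOSequence:
    data = tifffile.imread(str(path)).astype(float)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    scale = meta.pop("intensity_scale", 1.0)
    t = np.asarray(meta.pop("timestamps_s"))
    px_um = meta.pop("px_um")
    return SLOSequence(frames=data * scale, timestamps_s=t, px_um=px_um,
                       metadata=meta)
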