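"""Phantom generator: cardiac waveforms, geometry, forward model, SLO."""

import numpy as np
import pytest

from srvp import phantom
from srvp.phantom import (
    CardiacModel,
    PhantomConfig,
    VesselModel,
    doppler_phase_per_mm_s,
    make_cardiac_waveforms,
    simulate_complex_sequence,
    simulate_slo_sequence,
    vessel_geometry_at,
)

from conftest import small_config


# ---------------------------------------------------------------------------
# cardiac waveforms
# ---------------------------------------------------------------------------

class TestCardiacWaveforms:
    def test_no_jitter_periodicity(self, uniform_time_grid):
        """Zero HRV at 60 bpm over 3.2 s gives cycle starts at whole seconds."""
        w = make_cardiac_waveforms(CardiacModel(hrv_frac=0.0), uniform_time_grid)
        assert np.allclose(w.cycle_starts_s, [0.0, 1.0, 2.0, 3.0])
        # consecutive cycles are identical
        fps = 24
        c0, c1 = w.arterial[:fps], w.arterial[fps:2 * fps]
        assert np.allclose(c0, c1, atol=1e-6)

    def test_series_bounded(self, uniform_time_grid):
        w = make_cardiac_waveforms(CardiacModel(hrv_frac=0.1), uniform_time_grid,
                                   seed=7)
        for s in (w.arterial, w.venous, w.collapse):
            assert s.min() >= 0.0 and s.max() <= 1.0 + 1e-12

    def test_collapse_peaks_coincide_with_arterial(self, uniform_time_grid):
        """With zero phase offset the collapse maximum of each cycle falls on
        the arterial systolic peak (within one frame)."""
        w = make_cardiac_waveforms(CardiacModel(hrv_frac=0.0), uniform_time_grid)
        fps = 24
        for k in range(3):
            cyc = slice(k * fps, (k + 1) * fps)
            assert abs(int(np.argmax(w.collapse[cyc]))
                       - int(np.argmax(w.arterial[cyc]))) <= 1

    def test_zero_smoothing_limit_identity(self, uniform_time_grid):
        w = make_cardiac_waveforms(
            CardiacModel(hrv_frac=0.0, venous_smoothing_s=0.0), uniform_time_grid
        )
        assert np.allclose(w.venous, w.arterial)

    def test_venous_is_smoother_than_arterial(self, uniform_time_grid):
        """The washed-out venous profile has smaller frame-to-frame jumps."""
        w = make_cardiac_waveforms(CardiacModel(hrv_frac=0.0), uniform_time_grid)
        assert np.abs(np.diff(w.venous)).max() < np.abs(np.diff(w.arterial)).max()

    def test_jitter_varies_cycle_periods(self):
        t = np.arange(0.0, 8.0, 1.0 / 24.0)
        w = make_cardiac_waveforms(CardiacModel(hrv_frac=0.2), t, seed=11)
        periods = np.diff(w.cycle_starts_s)
        assert np.ptp(periods) > 0.05

    def test_insufficient_duration_raises(self):
        with pytest.raises(ValueError, match="insufficient duration"):
            make_cardiac_waveforms(CardiacModel(), np.arange(0.0, 0.5, 0.01))


# ---------------------------------------------------------------------------
# lumen geometry
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "m_lat,m_ax,c,expected_area_loss",
    [
        (0.2, 0.5, 1.0, 0.60),     # 1 - 0.8*0.5
        (0.2, 0.375, 1.0, 0.50),   # 1 - 0.8*0.625
        (0.3, 0.3, 0.0, 0.0),      # rest state
    ],
)
def test_vessel_geometry_area_loss(m_lat, m_ax, c, expected_area_loss):
    v = VesselModel(a0_um=60, b0_um=60, m_lat=m_lat, m_ax=m_ax)
    a, b, area = vessel_geometry_at(v, c)
    area0 = np.pi * 60 * 60
    assert a == pytest.approx(60 * (1 - m_lat * c))
    assert b == pytest.approx(60 * (1 - m_ax * c))
    assert 1 - area / area0 == pytest.approx(expected_area_loss)


def test_ground_truth_ellipse_identity(s1_small):
    """GroundTruth area equals pi * a(t) * b(t) at every frame."""
    _cfg, _seq, gt = s1_small
    a = gt.true_lat_diameter_um / 2.0
    b = gt.true_ax_diameter_um / 2.0
    assert np.allclose(gt.true_area_um2, np.pi * a * b, rtol=1e-12)


# ---------------------------------------------------------------------------
# complex-sequence forward model
# ---------------------------------------------------------------------------

class TestComplexSequence:
    def test_reproducibility_bit_identical(self):
        cfg = small_config(duration_s=1.2)
        s1, _ = simulate_complex_sequence(cfg)
        s2, _ = simulate_complex_sequence(cfg)
        assert np.array_equal(s1[0].frames, s2[0].frames)

    def test_seed_changes_realization(self):
        a, _ = simulate_complex_sequence(small_config(duration_s=1.2, seed=1))
        b, _ = simulate_complex_sequence(small_config(duration_s=1.2, seed=2))
        assert not np.array_equal(a[0].frames, b[0].frames)

    def test_static_phantom_zero_phase(self):
        """v_peak = 0: adjacent-A-scan phase differences vanish in the lumen."""
        cfg = small_config(
            duration_s=1.2, snr_db=None,
            vessel=VesselModel(center_z_px=48, v_peak_mm_s=0.0),
        )
        seqs, _ = simulate_complex_sequence(cfg)
        f = seqs[0].frames[0]
        dphi = np.angle(f[:, 1:] * np.conj(f[:, :-1]))
        assert np.abs(dphi).max() < 1e-5

    def test_doppler_angle_90_zero_phase(self):
        cfg = small_config(
            duration_s=1.2, snr_db=None,
            vessel=VesselModel(center_z_px=48, doppler_angle_deg=90.0),
        )
        seqs, _ = simulate_complex_sequence(cfg)
        f = seqs[0].frames[0]
        dphi = np.angle(f[:, 1:] * np.conj(f[:, :-1]))
        assert np.abs(dphi).max() < 1e-4

    def test_sign_symmetry_of_doppler_angle(self):
        """Angles theta and 180 - theta give phase of equal magnitude and
        opposite sign in the lumen."""
        means = []
        for theta in (60.0, 120.0):
            cfg = small_config(
                duration_s=1.2, snr_db=None,
                vessel=VesselModel(center_z_px=48, doppler_angle_deg=theta),
            )
            seqs, _ = simulate_complex_sequence(cfg)
            f = seqs[0].frames[0]
            dphi = np.angle(f[:, 1:] * np.conj(f[:, :-1]))
            lum = np.abs(dphi) > 1e-6
            means.append(dphi[lum].mean())
        assert means[0] > 0 > means[1]
        assert means[0] == pytest.approx(-means[1], rel=1e-3)

    def test_lumen_phase_matches_forward_model(self):
        """Mean lumen phase equals half the centre-line phase (parabolic
        profile) predicted from the Doppler relation."""
        cfg = small_config(duration_s=1.2, snr_db=None,
                           vessel=VesselModel(center_z_px=48,
                                              doppler_angle_deg=60.0))
        seqs, _ = simulate_complex_sequence(cfg)
        f = seqs[0].frames[0]
        dphi = np.angle(f[:, 1:] * np.conj(f[:, :-1]))
        lum = np.abs(dphi) > 1e-6
        k = doppler_phase_per_mm_s(cfg.lambda0_nm, cfg.tau_s,
                                   cfg.tissue_refractive_index)
        phi_center = k * 15.0 * np.cos(np.deg2rad(60.0))
        # area-mean of phi_c * (1 - rho^2) over the ellipse is phi_c / 2
        assert dphi[lum].mean() == pytest.approx(phi_center / 2.0, rel=0.05)

    def test_lumen_snr_calibration(self):
        """Measured lumen SNR (lumen signal power over vitreous noise power)
        is within 1 dB of the configured value."""
        cfg = small_config(
            duration_s=1.2, snr_db=20.0,
            tissue_decay_um=1e9,   # flat depth profile isolates the ratio
            vessel=VesselModel(center_z_px=48, intensity_mod=0.0),
        )
        seqs, _ = simulate_complex_sequence(cfg)
        f = np.asarray(seqs[0].frames)
        noise_power = np.mean(np.abs(f[:, :8, :]) ** 2)   # vitreous rows
        zz, xx = np.meshgrid(np.arange(cfg.depth_px),
                             np.arange(cfg.ascans_per_channel), indexing="ij")
        v = cfg.vessel
        rho2 = (((xx - cfg.ascans_per_channel // 2)
                 / (v.a0_um / cfg.lateral_px_um)) ** 2
                + ((zz - v.center_z_px) / (v.b0_um / cfg.axial_px_um)) ** 2)
        lumen = rho2 < 0.5
        assert lumen.sum() * len(f) > 1000
        lumen_power = np.mean(np.abs(f[0][lumen]) ** 2) - noise_power
        snr_db = 10 * np.log10(lumen_power / noise_power)
        assert abs(snr_db - 20.0) < 1.0

    def test_dual_channel_tau_and_offset(self):
        cfg = small_config(duration_s=1.2, n_channels=2, n_ascans=512,
                           pwv_mm_s=200.0)
        seqs, truths = simulate_complex_sequence(cfg)
        assert len(seqs) == 2
        assert seqs[0].tau_s == pytest.approx(2.0 / cfg.ascan_rate_hz)
        assert seqs[1].location_offset_mm == pytest.approx(0.9)
        # channel 2 images a non-collapsing section
        assert np.ptp(truths[1].true_area_um2) < 1e-9
        assert np.ptp(truths[0].true_area_um2) > 0

    def test_phase_wrapping_warning(self):
        cfg = small_config(
            duration_s=1.2, snr_db=None,
            vessel=VesselModel(center_z_px=48, v_peak_mm_s=200.0,
                               doppler_angle_deg=20.0),
        )
        with pytest.warns(UserWarning, match="phase wrapping"):
            simulate_complex_sequence(cfg)


# ---------------------------------------------------------------------------
# SLO sequence
# ---------------------------------------------------------------------------

class TestSLO:
    def test_frame_count_at_10_fps(self):
        cfg = small_config()
        slo = simulate_slo_sequence(cfg)
        assert len(slo.frames) == round(cfg.duration_s * 10)

    def test_static_vessel_constant_band(self):
        cfg = small_config(
            duration_s=1.6, slo_noise_frac=0.0,
            vessel=VesselModel(center_z_px=48, m_lat=0.0, m_ax=0.0,
                               intensity_mod=0.0),
        )
        slo = simulate_slo_sequence(cfg)
        assert np.ptp(slo.frames, axis=0).max() < 1e-12

    def test_band_width_modulates_with_m_lat(self):
        """Apparent dark-band width tracks the true lateral diameter."""
        cfg = small_config(slo_noise_frac=0.0)
        slo = simulate_slo_sequence(cfg)

        def width(frame):
            profile = frame.mean(axis=0)
            thr = 0.5 * (profile.max() + profile.min())
            return (profile < thr).sum() * slo.px_um

        widths = np.array([width(f) for f in slo.frames])
        t = np.arange(len(widths)) / cfg.slo_frame_rate_fps
        waves = make_cardiac_waveforms(
            cfg.cardiac, t,
            seed=int(np.random.SeedSequence(cfg.seed).spawn(1)[0]
                     .generate_state(1)[0] % 2**31),
        )
        true_width = 2 * cfg.vessel.a0_um * (1 - cfg.vessel.m_lat * waves.collapse)
        assert np.all(np.abs(widths - true_width) <= 2 * slo.px_um)
        rel = 1 - widths.min() / widths.max()
        assert rel == pytest.approx(cfg.vessel.m_lat, abs=0.04)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def test_h5_roundtrip(tmp_path, s1_small):
    cfg, seq, gt = s1_small
    path = tmp_path / "phantom.h5"
    phantom.write_phantom_h5(path, [seq], [gt], cfg)
    seqs2, truths2, cfg2 = phantom.read_phantom_h5(path)
    assert np.allclose(seqs2[0].frames, seq.frames)
    assert np.allclose(truths2[0].true_area_um2, gt.true_area_um2)
    assert cfg2.vessel.m_ax == cfg.vessel.m_ax
    assert cfg2.tau_s == cfg.tau_s


def test_slo_tiff_roundtrip(tmp_path):
    cfg = small_config(duration_s=1.6)
    slo = simulate_slo_sequence(cfg)
    path = tmp_path / "slo.tif"
    phantom.write_slo_tiff(path, slo)
    back = phantom.read_slo_tiff(path)
    assert back.frames.shape == slo.frames.shape
    assert np.allclose(back.frames, slo.frames, atol=slo.frames.max() / 1000)
    assert np.allclose(back.timestamps_s, slo.timestamps_s)


def test_config_validation():
    with pytest.raises(ValueError):
        PhantomConfig(n_channels=3)
    with pytest.raises(ValueError):
        PhantomConfig(n_channels=2, n_ascans=1023)
    with pytest.raises(ValueError):
        VesselModel(m_lat=1.2)
    with pytest.raises(ValueError):
        VesselModel(doppler_angle_deg=0.0)
    with pytest.raises(ValueError):
        CardiacModel(hrv_frac=0.5)
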