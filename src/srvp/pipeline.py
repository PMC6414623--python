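"""End-to-end pipeline: simulate -> process -> quantify -> pulse wave ->
intensity pulsatility, driven by a single run configuration.

One seed governs every stochastic stage (sub-seeds are derived
deterministically from it), so re-running an identical config reproduces
all numeric outputs bit-identically.  Stage outputs: the phantom HDF5
container and SLO TIFF, per-channel per-frame measurement CSVs, and a
summary JSON validated against the schema shipped with the package.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import doct_core, intensity_puls, phantom, pulse_wave, vessel_quant

__all__ = ["RunConfig", "run_pipeline", "validate_summary", "load_run_config"]

log = logging.getLogger("srvp")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``phantom_config``/``preset`` or ``input_path`` must be
    set: either a phantom is generated or an existing container is read.
    """

    output_dir: str = "srvp_out"
    phantom_config: Optional[phantom.PhantomConfig] = None
    preset: Optional[str] = None
    input_path: Optional[str] = None
    seed: Optional[int] = None
    bulk_correction: bool = True
    threshold_k: float = 3.0
    quantify_roi: Optional[tuple[int, int, int, int]] = None
    heart_rate_band: tuple[float, float] = (40.0, 120.0)
    separation_mm: Optional[float] = None
    intensity_roi: Optional[tuple[int, int, int, int]] = None
    write_phantom: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sources = sum(x is not None
                      for x in (self.phantom_config, self.preset, self.input_path))
        if sources != 1:
            raise ValueError(
                "exactly one of phantom_config, preset or input_path required"
            )


def load_run_config(path) -> RunConfig:
    """Load a YAML run config (keys mirror :class:`RunConfig` fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "phantom" in raw:
        ph = raw.pop("phantom")
        if isinstance(ph, str):
            raw["input_path"] = ph
        else:
            raw["phantom_config"] = phantom.PhantomConfig.from_dict(ph)
    for key in ("quantify_roi", "intensity_roi", "heart_rate_band"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _config_hash(cfg: phantom.PhantomConfig) -> str:
    return hashlib.sha256(cfg.to_json().encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all applicable stages and write CSVs plus a summary JSON.

    Returns the summary dict.  A stage failure aborts the run; partial
    outputs are kept and a FAILED marker file names the failing stage.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        summary = _run_stages(cfg, out)
    except Exception as exc:
        stage = getattr(exc, "_srvp_stage", stage)
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise
    return summary


def _stage(name):
    """Tag exceptions with the stage they occurred in."""
    class _Ctx:
        def __enter__(self):
            log.info("stage %s", name)
            return self

        def __exit__(self, etype, evalue, tb):
            if evalue is not None:
                evalue._srvp_stage = name
            return False
    return _Ctx()


def _run_stages(cfg: RunConfig, out: Path) -> dict:
    # --- simulate / load -------------------------------------------------
    with _stage("simulate"):
        if cfg.input_path is not None:
            seqs, truths, pcfg = phantom.read_phantom_h5(cfg.input_path)
            slo = None
        else:
            pcfg = (phantom.get_preset(cfg.preset) if cfg.preset
                    else cfg.phantom_config)
            if cfg.seed is not None:
                from dataclasses import replace
                pcfg = replace(pcfg, seed=int(cfg.seed))
            seqs, truths = phantom.simulate_complex_sequence(pcfg)
            slo = phantom.simulate_slo_sequence(pcfg)
            if cfg.write_phantom:
                phantom.write_phantom_h5(out / "phantom.h5", seqs, truths, pcfg)
                phantom.write_slo_tiff(out / "slo.tif", slo)

    # --- process ----------------------------------------------------------
    with _stage("process"):
        roi = cfg.quantify_roi or phantom.default_search_roi(pcfg)
        doppler = [
            doct_core.process_sequence(
                seq, bulk_correction=cfg.bulk_correction, lumen_roi=roi
            )
            for seq in seqs
        ]

    # --- quantify ---------------------------------------------------------
    with _stage("quantify"):
        params = vessel_quant.SegmentationParams(k=cfg.threshold_k, roi=roi)
        per_channel = []
        for ch, frames in enumerate(doppler):
            table, series, summ = vessel_quant.quantify_sequence(
                frames, params, bpm_band=cfg.heart_rate_band
            )
            table.to_csv(out / f"measurements_chan{ch}.csv", index=False,
                         float_format="%.9g")
            summ["channel"] = ch
            per_channel.append({"summary": summ, "series": series})

    # --- pulse wave (dual channel only) ------------------------------------
    with _stage("pulsewave"):
        pw = None
        if len(per_channel) == 2:
            sep = cfg.separation_mm or pcfg.channel_separation_mm
            fps = pcfg.frame_rate_fps
            fa = per_channel[0]["series"].norm_flow
            fb = per_channel[1]["series"].norm_flow
            rec = pulse_wave.analyze_dual_site(fa, fb, fps, sep)
            rmsd, r = pulse_wave.check_flow_conservation(
                fa, fb, rec.delay_s if rec.detectable else 0.0, fps
            )
            pw = {
                "delay_s": rec.delay_s,
                "delay_frames": rec.delay_frames,
                "detectable": bool(rec.detectable),
                "pwv_mm_s": rec.pwv_mm_s,
                "max_resolvable_pwv_mm_s": rec.max_resolvable_pwv_mm_s,
                "conservation_rmsd": rmsd,
                "conservation_r": r,
            }

    # --- intensity pulsatility ---------------------------------------------
    with _stage("intensity"):
        intensity = None
        if slo is not None:
            iroi = cfg.intensity_roi or phantom.default_intensity_roi(pcfg)
            inten_stack = np.stack([d.intensity_db for d in doppler[0]])
            oct_series = intensity_puls.roi_mean_intensity(
                inten_stack, seqs[0].timestamps_s, iroi, modality="OCT"
            )
            # SLO ROI: the central band of the vessel, full height
            cx = int(slo.metadata["vessel_center_x_um"] / slo.px_um)
            half = max(2, int(0.5 * pcfg.vessel.a0_um / slo.px_um))
            size = slo.frames.shape[1]
            sroi = (0, size, max(0, cx - half), min(size, cx + half))
            slo_series = intensity_puls.roi_mean_intensity(
                slo.frames, slo.timestamps_s, sroi, modality="SLO"
            )
            r, lag_s = intensity_puls.compare_modalities(oct_series, slo_series)
            intensity = {"oct_slo_r": r, "lag_s": lag_s,
                         "oct_roi": list(iroi), "slo_roi": list(sroi)}

    # --- summary ------------------------------------------------------------
    with _stage("summary"):
        ch0 = per_channel[0]["summary"]
        summary = {
            "config_hash": _config_hash(pcfg),
            "seed": int(pcfg.seed),
            "n_channels": len(per_channel),
            "diameter_amplitude_pct": ch0["diameter_amplitude_pct"],
            "area_amplitude_pct": ch0["area_amplitude_pct"],
            "sensitivity_ratio": ch0["sensitivity_ratio"],
            "flow_oscillation_pct": ch0["flow_oscillation_pct"],
            "per_channel": [c["summary"] for c in per_channel],
            "pulse_wave": pw,
            "intensity": intensity,
        }
        validate_summary(summary)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# summary schema
# ---------------------------------------------------------------------------

_TYPE_MAP = {
    "number": (int, float),
    "integer": int,
    "string": str,
    "boolean": bool,
    "array": list,
    "object": dict,
}


def _schema() -> dict:
    with resources.files("srvp").joinpath("data/summary_schema.json").open() as fh:
        return json.load(fh)


def validate_summary(summary: dict) -> None:
    """Check the summary dict against the shipped JSON schema.

    Minimal structural validation: required keys present and value types
    matching (null allowed where the schema says nullable).
    """
    schema = _schema()
    for key in schema["required"]:
        if key not in summary:
            raise ValueError(f"summary missing required key {key!r}")
    for key, spec in schema["properties"].items():
        if key not in summary:
            continue
        value = summary[key]
        if value is None:
            if spec.get("nullable", False):
                continue
            raise ValueError(f"summary key {key!r} may not be null")
        expected = _TYPE_MAP[spec["type"]]
        if spec["type"] == "number" and isinstance(value, bool):
            raise ValueError(f"summary key {key!r} has wrong type")
        if not isinstance(value, expected):
            raise ValueError(
                f"summary key {key!r}: expected {spec['type']}, "
                f"got {type(value).__name__}"
            )
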