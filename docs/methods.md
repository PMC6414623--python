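# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `srvp`. Everything stated here is computed by the package's
tests or scripts; nothing is quoted from external measurements.

## Doppler tomogram formation

Phase differences are taken between *laterally adjacent A-scans within a
frame*, matching a high-A-scan-rate prototype whose Doppler contrast comes
from the ~10 µs inter-A-scan interval (frame-to-frame Doppler is out of
scope). The Doppler frame is one column narrower than the source frame (no
wrap-around pair is formed) and the intensity frame is cropped to match.
Phase lives on the half-open interval [−π, π) — a single representation of
±π — and all aggregation uses circular statistics (mean = argument of the
resultant vector, std = √(−2 ln R̄), median = ordinary median of residuals
around the circular mean, exact for data within a half circle).

Dual-channel acquisitions inter-A-scan switch between two retinal
locations: A-scans j, j+2, … belong to one channel, so de-interleaving
doubles the per-channel A-scan period τ (50 kHz per channel at a 100 kHz
sweep) and with it the phase per unit velocity. The velocity conversion is
v_axial = λ₀·Δφ/(4π·n·τ); the absolute velocity v_axial/cos θ is refused
(flagged undetermined) for |cos θ| ≤ 0.05, i.e. a Doppler angle within
about 2.9° of 90°, where the geometry carries no magnitude information.

Bulk axial eye motion adds a per-A-scan common phase. The correction
subtracts the per-column circular median over *tissue* pixels (valid
pixels outside the configured lumen ROI, or outside the current flow
mask) and re-wraps. The underlying acquisitions here contain no bulk
motion, so the correction is near-neutral on phantoms; it is retained as a
documented, toggleable stage because real recordings need it. Frames with
fewer than 100 tissue pixels pass through unchanged with a quality flag.

The intensity reference (0 dB) is the median magnitude of the first frame;
a −60 dB floor keeps zero-magnitude pixels finite. The noise floor is
estimated as the median of the dimmest 5% of pixels of the first frame
(the phantom's vitreous gap guarantees a pure-noise population there), and
validity requires 3 dB above it.

## Phantom forward model

The phantom emulates repeated linear B-scans of a partially collapsing
retinal vein near the optic nerve head, plus an en-face SLO-like video.

**Speckle and noise.** Static tissue below a vitreous gap is fully
developed speckle: per-pixel Rayleigh magnitude on a depth-decaying mean
power profile (decay constant 400 µm). The speckle magnitude field is
*frozen* over time per channel — re-imaging the same location reproduces
the same scatterer configuration — while complex additive detection noise
is redrawn every frame. The signal phase along the lateral direction is
the cumulative modelled Doppler increment on top of a random per-row
origin, so the adjacent-A-scan phase difference equals the model exactly
and the measured phase noise is purely SNR-driven (σ_Δφ ≈ √2·SNR^−1/2),
the standard shot-noise-limited regime. Lateral speckle decorrelation
noise and the axial point-spread function are deliberately not modelled
(the source bandwidth is carried as metadata only): they are not needed to
exercise segmentation and quantification, and their absence is a stated
limit on what passing tests show about real data. `snr_db` (default 25)
pins the ratio of mean lumen signal power at the vessel depth to noise
power.

**Lumen geometry.** The cross-section is an ellipse with independently
modulated semi-axes, a(t) = a₀(1 − m_lat·c(t)), b(t) = b₀(1 − m_ax·c(t)),
driven by a collapse waveform c(t) ∈ [0, 1]. Real collapses are irregular;
the ellipse is the minimal parametric shape that expresses an
axial-dominant caliber change (m_ax > m_lat). The relative area loss at
full collapse is 1 − (1 − m_lat)(1 − m_ax).

**Flow.** Flow is parabolic on the elliptical lumen, zero at the wall.
One rule generates all velocity behaviour: the volumetric flow is
Q(t) = Q₀(1 + flow_mod·s(t)) with s the standardized venous waveform, and
the centre-line velocity is derived as v_c(t) = v_peak·(Q(t)/Q₀)·(A₀/A(t)).
Collapse at conserved flow (flow_mod = 0) therefore accelerates the blood,
producing the phase–area anti-correlation characteristic of a partial
collapse. The per-pixel phase is Δφ = (4π n τ/λ₀)·v·cos θ. A useful
analytic identity: for the parabolic profile the *circular* mean phase
over the lumen is exactly half the centre phase and linear in velocity, so
the flow proxy (mean phase × area) tracks Q(t) faithfully.

**Cardiac driver.** The arterial pulse is a systolic Gaussian peak (at
10% of the cycle, width 10%) with a small dicrotic notch (amplitude 0.15);
cycle periods jitter uniformly by ±hrv_frac (default 5%). The venous
waveform is the arterial one smoothed with a *symmetric* Gaussian kernel
(σ = 0.12 s), giving the washed-out venous profile while keeping each
cycle's maximum aligned with the arterial peak; the collapse waveform is
the venous one, optionally delayed (default 0: collapse peaks coincide
with arterial peaks). Waveforms are evaluated on an internal 1 ms grid and
interpolated, so OCT (24 fps) and SLO (10 fps) grids sample one consistent
realization per seed. Heart rate defaults to 60 bpm, so the default 3.2 s
recording holds three complete cycles.

**Hyperreflectivity and SLO.** Collapse-synchronous hyperreflectivity
multiplies the lumen power by (1 + intensity_mod·c(t)) — a phenomenological
stand-in for flow-dependent red-blood-cell orientation scattering; no
mechanistic RBC model is attempted. The SLO video is a depth-integrated
view: a dark band of width 2a(t) and in-band brightness following the same
hyperreflectivity factor, with multiplicative noise, at 10 fps.

**Dual-channel mode.** Channel 1 images a non-collapsing section of the
same vein at 0.9 mm offset; its flow waveform is delayed by
separation/PWV. The phantom's PWV (default ∞; 200 mm/s in the flow
preset) sets a sub-frame true delay at 24 fps, reproducing the
non-detectability regime. An optional artery (its own waveform, opposite
Doppler sign) can share the frame.

**Presets.** Calibrated configurations are fixed a priori from the forward
model so that resting and peak centre-line phases stay below π (no
wrapping): `phantom_S1` (m_lat 0.20, m_ax 0.375 → 50% area collapse,
Doppler angle 60°), `phantom_S2` (m_lat 0.20, m_ax 0.50 → 60%, 70°),
`phantom_flow` (dual channel, mild collapse, flow_mod 0.20, 80°, artery at
110°, PWV 200 mm/s), `phantom_along` (scan along the vessel, angle
sweeping 80°→100° across the B-scan). Absolute vessel size and speed
(a₀ = b₀ = 60 µm, v_peak = 15 mm/s) are plausible retinal-vein defaults,
not measured values. Default seed 1045; identical config + seed yields
bit-identical sequences. Optional linear eye-motion drift exists and is
off by default.

## Lumen segmentation and quantification

Segmentation operationalizes the expert-reader rule "mark the borderline
between static and dynamic tissue": median filter (3×3) the Doppler frame,
estimate the tissue phase-noise circular std σ̂, threshold |Δφ| > kσ̂
(k = 3), close with a 1 px disk, fill holes, keep the largest connected
component inside the search ROI. σ̂ is estimated in two passes: dynamic
pixels found with the first-pass threshold are dilated and excluded before
re-estimation, so a second vessel in the frame cannot inflate the tissue
estimate. An absolute threshold floor of 1e−6 rad prevents a numerically
noise-free frame from segmenting rounding error. An empty mask (total
collapse, or no flow) is a valid, flagged result.

Diameters come from mask extents (transversal at the row band of widest
lateral extent, matching a measurement at the site of highest collapse
amplitude), area from pixel count × pixel pitches, mean phase from the
sign-preserving circular mean over the mask. Cardiac cycles are detected
as successive maxima of a reference trace (the inverted area trace by
default, so collapse minima become peaks; a lightly smoothed copy is used
for peak finding only) with minimum separation 60/bpm_max (band default
40–120 bpm). Relative amplitudes (max − min)/max are reported per cycle
(median summarized) and once over the whole analyzed span; the
per-sequence value is the headline "maximum relative change".
Normalization of traces is to the maximum (|max| for signed phase/flow).

**Known bias.** Thresholding a parabolic profile at kσ̂ finds the region
where |Δφ| exceeds the threshold, an ellipse shrunk by the factor
(1 − kσ̂/φ_c); since the centre phase φ_c rises during collapse (conserved
flow), the shrinkage is larger at rest than at collapse and the recovered
area amplitude underestimates truth by ~3–5 percentage points at 25 dB
SNR (e.g. ~47% recovered for a generated 50%). This is inherent to the
borderline rule, vanishes as noise → 0 (the noise-free recovery test is
exact to pixel discretization), and is left uncorrected because the area
is defined as the pixel count of the mask — a model-based correction would
presume the very profile shape being measured.

## Pulse delay and conservation

The two-site delay is the maximum of the normalized cross-correlation of
the flow traces, computed with a fixed central template of trace A slid
across trace B so every lag is scored on an identical-length window
(boundary effects would otherwise skew the peak), refined by a parabolic
fit through the peak and its neighbours. The lag search is bounded by ±
one cardiac period (estimated from trace A's own peak spacing) and
near-maximal ties — which occur for near-periodic traces at ± one period —
resolve to the smallest |lag|. A delay counts as detectable only when its
magnitude reaches one frame interval; otherwise the PWV is reported
undetermined together with the resolvability bound separation × frame
rate (21.6 mm/s at 0.9 mm and 24 fps). Sub-frame refinement is kept even
for undetectable delays so the 0.99/1.01-frame boundary behaves exactly.
Flow conservation is the RMS difference and Pearson correlation of the
delay-aligned normalized traces. Travel-direction determination and
HRV-compensated multi-beat PWV averaging are out of scope.

## Intensity pulsatility

ROI means are taken in linear intensity (dB converted via 10^(dB/10));
mean reflectivity is the physical quantity and SLO data are linear
already. For the OCT-vs-SLO comparison the faster trace is linearly
resampled onto the slower grid (no information invented at 10 fps);
Pearson r and the best cross-correlation lag are reported. The canonical
phantom ROI is the central half of the resting lumen; on real data the
ROI is a required user input.

## Problem sizes and determinism

Default phantom frames are 160 × 1024 px (0.8 mm B-scan, 0.78 µm lateral
and 4 µm axial pitch) over 77 frames; the test suite uses reduced frames
(96 × 256 and smaller) that preserve pitches and physics while keeping a
full simulate–process–quantify pass under a second. Property tests that
average over seeds use 20 replicates. All randomness flows from one seed
per config through `numpy` SeedSequence spawning; hypothesis-based
property tests run derandomized. The pipeline writes no timestamps into
numeric outputs, so identical runs are byte-identical.

## Limitations

Beyond the modelling limits above: no raw spectral processing
(k-linearization, dispersion), no galvo/scan geometry, no multi-vessel
tracking or artery/vein classification, no absolute volumetric flow in
physical units (the proxy is proportional only), and the phantom's
speckle, noise and waveform models are idealized — passing recovery tests
demonstrates correctness of the analysis chain under those idealizations,
not performance on clinical recordings.
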