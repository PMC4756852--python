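# Methods

## Dosimetry model

The chain from an instrument power setting to physical dose is:

1. **Focal spot.** The beam is treated as filling the objective aperture
   and focusing to a diffraction-limited spot of Airy diameter
   d = 1.22 λ / NA, modeled spatially as a uniform disc. For the two
   bundled platforms this gives 697 nm (800 nm / 1.4 NA) and 732 nm
   (780 nm / 1.3 NA).
2. **In-situ pulse energy.** The measured calibration maps the power
   setting to the energy per pulse at the focal spot, already folding in
   the side-port→back-aperture optics and the objective transmission
   (≈47% for both platforms; that constant is carried as metadata, not
   re-derived). Two calibration modes exist:
   - *linear throughput* (Mira-900-style, setting in mW): the measured
     rows are consistent with strict linearity, so a single coefficient
     (2.665×10⁻³ nJ/mW, fitted from the 20 mW row) is used;
   - *lookup* (Meta-style, setting in percent): the software
     transmission parameter is visibly non-linear in delivered energy,
     so the measured rows are kept verbatim, with linear interpolation
     in energy between rows and a hard refusal to extrapolate.
3. **Peak irradiance.** I = (E / t_p) / (π (d/2)²), i.e. a top-hat pulse
   over the pulse width and a uniform disc over the Airy diameter. All
   arithmetic is done in SI; nJ, fs, nm, mW and W/cm² exist only at the
   interface.

Printed calibration values are rounded to 3 significant figures, so every
comparison against them in the test suite uses a 1% relative tolerance
(0.5% for the confinement quantities, which are printed with more slack).

## Biophysics calculus

Three closed forms, applied verbatim rather than replaced with more
elaborate physics:

- **Thermal diffusion time** T_d = 0.124 λ² / (k NA²), with k the thermal
  diffusivity of water (1.4×10⁻⁷ m²/s). T_d ≫ t_p for both platforms
  (≈289 ns and ≈319 ns versus 200 fs and 140 fs), so photothermal
  confinement holds during each micropulse.
- **Inter-macropulse cooling.** The chromatin target is idealized as a
  uniformly heated 1 μm slab; the retained fraction of the temperature
  rise after a delay t is 1 − exp(−d²/(4kt)). For the gated delivery mode
  (10 ms exposures separated by 100 ms gaps) this gives ≈1.78×10⁻⁵ —
  essentially complete cooling between macropulses. The formula is
  implemented exactly as stated even though it is an unconventional form
  for slab cooling; no "corrected" physics is substituted, because the
  package's job is to reproduce this calculus, not to improve it.
  Continuous raster-scanned delivery has no inter-macropulse gap, so the
  report leaves the field empty rather than inventing a delay.
- **Stress relaxation factor** τ_m = t_p·c_s/d with c_s = 2600 m/s. With
  a 1 μm slab the two platforms give 5.2×10⁻⁴ (200 fs) and 3.64×10⁻⁴
  (140 fs); both ≪ 1, so thermoelastic stress is confined. (Some
  published renditions of these two numbers swap the platforms; the
  implementation follows the formula, which unambiguously assigns the
  larger factor to the longer pulse.)

**Threshold classification** compares a peak irradiance against fixed
literature thresholds — photochemical damage 0.26×10¹² W/cm²,
thermoelastic-stress damage 5×10¹², plasma formation 6×10¹² — plus a
low-density-plasma flag at 5% of the plasma threshold. Comparisons are
inclusive (≥): the boundary convention is a package decision, since the
source material only ever describes strictly-above/strictly-below cases.
Thresholds are compared, never derived; there is no plasma-dynamics or
shockwave simulation.

## DDR regime model

Dose bands are defined operationally in instrument settings per system
(Mira-900: sub-threshold < 25 mW ≤ low < 85 mW ≤ high; Meta: 15% low,
25% high), because that is how detection thresholds are measured; the
dosimetry module is available to express any band edge in W/cm², and the
bands are deliberately *system-relative* — the "high" irradiance of a
scanning system can be numerically below the "high" of a point-and-shoot
system.

Each band has a fixed baseline marker table; treatments modify it through
predicate rules evaluated on the whole condition set in one pass, making
the predictor a pure function (and modifier order-independence a
structural property rather than a tested coincidence). Recruitment-type
markers use a 4-point ordinal scale `none < weak < robust < enhanced`;
"upgrade/downgrade one level" is defined on that scale. Pattern markers
(γH2AX, MDC1, pChk1/2) are categorical.

Key rules: PARP inhibition (or PARP1 knockdown) abolishes PAR-dependent
TRF2 recruitment; PARP inhibition additionally upgrades early 53BP1
(partial restore at high dose, enhancement at low dose); ATM+DNA-PK
inhibition re-localizes γH2AX and MDC1, suppresses pChk2, and partially
restores 53BP1 at high dose; all three inhibitors together restore 53BP1
fully in both bands; PARG inhibition stabilizes PAR and suppresses 53BP1
at low dose; Hoechst photosensitization upgrades γH2AX and is required to
visualize endogenous TRF2; TRF2 knockdown changes nothing the model
tracks. A high-band site suppresses early 53BP1 at co-irradiated low-band
sites in the same nucleus unless PARP or ATM+DNA-PK signaling is
inhibited.

Two declared extrapolations: (1) ATM or DNA-PK inhibition *alone* was
only characterized as "the combination"; a singleton is modeled as a
partial 53BP1 restore at high dose with no pattern changes. (2) The band
model treats everything at or above the high edge uniformly, although
intermediate settings (95–125 mW) are only partially characterized.

## Quantification

- **Normalization**: mean intensity over the damage ROI divided by the
  mean over a user-supplied nucleoplasmic background ROI, minus one. The
  *mean* (not median) is used. No background subtraction precedes the
  ratio. The trace is exactly invariant under global multiplicative
  rescaling, which is also why uniform photobleaching cancels.
- **Recruitment call**: "detectable" is operationalized as normalized
  contrast > 0.1 sustained for ≥2 consecutive frames within the
  monitoring window (15 min for 53BP1-type, 6 min for TRF2-type); both
  knobs are configurable. On well-separated synthetic data the resulting
  threshold power is insensitive to the exact level (the presets cross
  0.1 with steep margins).
- **Threshold power**: lowest tabulated power with recruited fraction
  strictly > 0.5 (strict majority; exactly half does not qualify).
- **Kinetic fits**: `scipy.optimize.curve_fit` on two fixed model
  classes, A(1−e^(−t/τ_on))+b and A(e^(−t/τ_off)−e^(−t/τ_on))+b with
  τ_off > τ_on enforced by parametrizing τ_off = τ_on + Δτ, Δτ > 0.
  Initialization is deterministic (amplitude from the data range, τ from
  time-to-half-max, baseline from the first frame); no random restarts.
  A known accrual delay is handled by fitting frames at t ≥ t₀ with time
  re-zeroed, rather than adding a delay parameter to the model. The
  transient pulse peaks at t* = τ_on τ_off ln(τ_off/τ_on)/(τ_off−τ_on),
  used as a closed-form cross-check on fits.
- **Group comparison**: two-sided permutation test on the difference of
  means (the specific test behind published "P < 0.05" asterisks is
  typically unstated, so a distribution-free default is the honest
  choice), 10⁴ permutations by default, add-one p-value estimator,
  seeded generator for reproducibility.

## Synthetic data generator

The generator emulates single-nucleus stripe-irradiation movies: an
elliptical nucleus (baseline 1000 counts) on a dark background
(100 counts) with a rectangular stripe whose contrast follows a
ground-truth kinetic profile; scaled Poisson noise
(variance = poisson_scale × mean) then additive Gaussian noise
(default σ = 5 counts), both drawn from one seeded generator in that
fixed order, so identical parameters and seed give bit-identical stacks.
Stacks are float64 in memory (so noiseless round-trips are exact to
≤10⁻⁹); TIFF output is quantized to 16-bit.

The kinetic functional forms are the package's choice — observed
time courses were published as curves, not equations. Presets encode the
published timing, not amplitudes (no absolute intensity scale exists for
normalized curves, so preset amplitudes are chosen for testability):

- `53BP1@60mW`: saturating rise, delay 5 min, τ_on 5 min, amplitude 0.8;
  crosses contrast 0.1 at ≈5.7 min, inside the observed 5–7 min
  detectability window, and stays up through 15 min.
- `TRF2@100mW`: transient pulse, delay 0.5 min, τ_on 0.15 min,
  τ_off 1.5 min, amplitude 0.9; peaks at ≈0.88 min (within the first
  minute) and is below detection again by ≈4 min, matching the
  "mostly limited to the first five minutes" behavior.
- `none`: amplitude 0 (non-responder cells).

Cohorts use `SeedSequence.spawn`, so each cell is an independent,
reproducible stream. The end-to-end run derives cohort composition from
the regime model with deterministic responder counts: fraction 1.0 for a
robustly responding power, 0.75 at the exact threshold power (a strict
majority, but not unanimity — the defining behavior of a threshold
power), 0.25 for "weak", 0 for "none". Default cohorts are 8 cells per
power, matching the per-power cell counts typical of these experiments.
Default geometry is a 48×64 px frame with a 6-row stripe; frame intervals
are 1 min (15 min window) and 0.25 min (6 min window), and the parameter
recovery study uses 50 cells of 61 frames each — sizes chosen so the
whole simulation battery runs at desk scale while leaving dozens of
pixels per ROI and clear separation between noise (trace-level SNR ≥ 5)
and signal.

What the generator does **not** emulate: optics (no PSF, the stripe has
hard edges), cell motion and nuclear deformation, 3D sectioning,
multi-channel imaging, spatial heterogeneity of chromatin, and
non-uniform bleaching. Passing tests therefore demonstrate that the
quantification pipeline is correct *given* ratio-normalizable,
motion-free data; they do not validate robustness to segmentation or
registration errors, which are declared out of scope (ROIs are
user-supplied).

## Degenerate inputs and numerical conventions

- Settings outside a calibration's measured domain raise an
  out-of-range error; there is no extrapolation path.
- A zero cooling delay returns the limit value 1 with a warning record
  (via an optional caller-supplied list, keeping the function pure).
- A non-positive background ROI mean is a degenerate-input error, not a
  NaN propagation.
- Pixel conventions: 0-based, row-major, half-open rectangles; masks
  take precedence over rectangles when both are given; damage and
  background ROIs must be disjoint and non-empty.
- CSV output uses 6 significant digits and locale-independent decimal
  points; every artifact directory carries a `run.json` with the
  resolved config hash and seed.

## Known limitations

- The regime model is qualitative by design: it reproduces rule-level
  outcomes (which markers, which direction, which band), not cell-to-cell
  variability or signal magnitudes; variability lives in the synthetic
  cohort layer.
- The linear-throughput assumption for mW-calibrated systems rests on the
  internal consistency of the measured rows, not on an optical model of
  the polarizer chain.
- Literature damage thresholds are point estimates for idealized media;
  classification near a threshold should be read with the underlying
  measurement uncertainty in mind.
- The permutation test assumes exchangeability under the null; paired or
  hierarchical designs (multiple sites per cell) need a different test.
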