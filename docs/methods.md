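# Methods

## Signal model

The simulator evolves longitudinal magnetization of up to three pools —
δ-[1-¹³C]gluconolactone (`dGL`), γ-[1-¹³C]gluconolactone (`gGL`) and
[1-¹³C]6-phosphogluconate (`6PG`) — under first-order kinetics:

    dM/dt = K·M − M/T1 + u(t)·b

where `K` contains the δ↔γ anomer exchange (`k_dg`, `k_gd`) and the
δ → 6PG conversion (`k_pgls`, the PGLS flux surrogate; the γ anomer is
rendered but never converted, since only the δ route is phosphorylated and
hydrolyzed), `T1` is metabolite-specific, and `u(t)·b` is the injection
input split δ:γ by the initial anomer partition. Each excitation is an
idealized instantaneous pulse: pool *p* emits `M_p·sin θ_p` and retains
`M_p·cos θ_p`. Relaxation during the readout window is neglected (TR of 3 s
is much longer than the acquisition window) and there is no chemical-shift
evolution during pulses, B0/B1 inhomogeneity, slice profile or k-space
encoding — voxel spectra are synthesized directly.

Propagation is exact, not stepped: on bolus-free intervals the state is
advanced with the matrix exponential of `K − diag(1/T1)`; during the bolus
the input (a constant plus a decaying exponential, see below) is folded into
an augmented state matrix and exponentiated as well. The closed-form pulsed
decay `M0 sin θ cosⁱθ e^(−i·TR/T1)` is therefore reproduced to machine
precision; the test suite pins this at rel. 1e−6.

### Bolus input

In vivo mode injects the dose over `bolus_duration_s` = 15 s. A hard boxcar
is unphysical at the leading edge, so the input rate is
`u(t) ∝ 1 − exp(−(t − t_start)/τ)` with rise time `τ` = 2 s, supported only
on `[t_start, t_start + duration]` and normalized so exactly `M0` is
delivered. Keeping the support finite (rather than smoothing both edges
with an exponential tail) preserves the invariant that no magnetization
enters the system after the injection ends. Cell/solution mode
(`bolus_duration_s = 0`) pre-loads `M0` at t = 0, split δ:γ.

### Default parameters

| parameter | default | why |
|---|---|---|
| shifts (δ, γ, 6PG) | 173.8, 177.0, 178.6 ppm | published line positions |
| flip angles, in vivo | 3.4°, 12°, 15.3° | the spectral-spatial EPSI scheme: minimal depletion on the substrate, aggressive sampling of the product |
| flip angle, 11.7 T dynamics | 13° (all lines) | solution/cell acquisition |
| TR | 3 s | temporal resolution of the dynamic acquisitions |
| substrate T1 | 31.7 s (3 T), 15.7 s (11.7 T) | measured field-dependent values |
| γ T1 | = δ T1 | same molecule; unmeasured separately |
| 6PG T1 | 25 s (3 T), 12 s (11.7 T) | plausible shorter values for the phosphorylated product; unreported |
| δ:γ partition | 0.6 : 0.4, exchange 0.005 s⁻¹ each way | the anomers equilibrate slowly in aqueous solution; the ratio is unreported, so a mild δ excess is assumed. Ratio metrics to *total* gluconolactone are insensitive to this choice |
| linewidths | 4 Hz (solution/cell), 8 Hz (in vivo) | typical shimmed vs in vivo widths |
| spectral axis | 128 pts / 20 ppm (in vivo EPSI), finer for solution work | acquisition spec; axis stored descending (downfield left), centred at 176.25 ppm so all three lines sit on-axis |
| phantom | 8×8 grid, 4.375×4.375×8 mm³ voxels; border ring signal-free; 2×2 tumor k = 0.02 s⁻¹ vs brain 0.005 s⁻¹; uniform delivery | native EPSI matrix and geometry; the two-rate layout produces the tumor/contralateral contrast the in vivo analysis expects |

## Processing

**Apodization.** 5 Hz exponential line broadening, implemented as inverse
FFT → symmetric exponential weighting → forward FFT. The symmetric (two-sided)
weighting is exactly a convolution with a unit-area Lorentzian of FWHM
`lb_hz`, independent of the frequency-ordering convention of the stored
spectrum: Lorentzian widths add by `lb_hz` and total integrals are
preserved (pinned at rel. 1e−3 for peak areas, exact at lb = 0).

**Quantification.** All quantification uses the real (absorption) part.
Peak areas are trapezoidal integrals over closed ppm windows defaulting to
centre ± 0.5 ppm — non-overlapping for the 1.6 ppm γ/6PG separation — since
no window widths are published. Noise is the sample SD of the real part in a
signal-free region (an outside-the-brain voxel for EPSI, or a ppm range ≥ 5
ppm from any declared line); SNR is peak height over that σ. Peak detection
refines local maxima with three-point parabolic interpolation (pinned at
±0.02 ppm on a 2048-point axis). Phasing is not needed for synthetic
absorption-mode data and no baseline correction is applied (baselines are
flat by construction).

**T1 fitting.** Areas are corrected by `sin θ · cosⁱθ` and fitted with a
mono-exponential: the closed-form log-linear least squares when all
corrected values are positive, otherwise bounded nonlinear least squares —
deterministic in both branches. Metabolism is not modelled in the substrate
fit (solution QC data contain no enzyme). At 90° no longitudinal
magnetization survives the first pulse, so fits are refused there.

**Polarization.** Thermal polarization is
`P_th = tanh(ħγB₀ / 2k_BT)` (γ = 6.72828×10⁷ rad s⁻¹ T⁻¹); the thermal
reference temperature defaults to 298 K (unreported). The enhancement is the
flip-angle-corrected hyperpolarized/thermal area ratio — thermal spectra use
the *summed*-averages convention (amplitude ∝ NA), mirrored exactly by the
thermal renderer — decay-corrected over the dissolution delay, and
`P₀ = enhancement × P_th`. The round trip is exact for any consistent
(delay, T1) pair and invariant to the absolute signal scale. Because the
per-experiment delay (18–25 s) and thermal temperature are unreported, the
absolute enhancement is meaningful only to order of magnitude; at 14.7%
polarization and 298 K it comes out ≈ 14.6×10³.

**Maps.** EPSI spectra are summed over time before height measurement (the
alternative, peak-timepoint heights, is not what a time-integrated flux map
wants; the summed-spectrum σ is the per-timepoint σ scaled by √n). SNR
grids are upsampled 8×8 → 256×256 with a separable Lanczos-2 kernel
(`L(x) = sinc(x)·sinc(x/2)`, |x| < 2) using imresize conventions:
half-pixel coordinate mapping, replicated edges, weights normalized to sum
to one (constant maps are exactly preserved; the 2-D response equals the
tensor product of 1-D responses, test-pinned against a direct per-pixel
oracle). Ratio maps divide the *interpolated* product map by the
interpolated substrate map — interpolate-then-divide, recorded in map
metadata — masking pixels whose substrate SNR falls below a floor
(default 5; no published floor exists, but a ratio against noise-level
substrate is meaningless). ROI statistics accept any voxel or pixel set and
record the realized volume, so a 28.13 mm³ region is expressible as a
sub-voxel pixel box on the interpolated map. Tumor volume is the sum of
per-slice contoured areas × slice thickness.

**Statistics.** Group differences use the unpaired two-tailed Welch t-test
computed from the defining formulas with the Student-t CDF as the only
numerical primitive (cross-checked against an independent implementation in
the tests); no multiple-testing correction, matching the per-endpoint
α = 0.05 design; day-to-day comparisons are unpaired. Significance tiers
\*/\*\*/\*\*\* at 0.05/0.01/0.001.

## Study workflows and noise conditions

The cell study anchors its noise on the **product** peak: σ is set so the
noiseless 6PG line reaches SNR 50 at its temporal maximum. The substrate is
orders of magnitude stronger, so anchoring on it would make the product —
the metabolically informative signal — essentially undetectable inside the
wide default integration windows; anchoring on the weakest line of interest
is how an experimenter would state the sensitivity of such a study. The in
vivo study adds a per-animal lognormal scale on delivered magnetization
(CV 0.18, taken from the measured 14.7 ± 2.6% preparation-to-preparation
polarization spread). This cancels exactly in ratio maps but spreads
absolute SNR values across animals, as in real cohorts.

Problem sizes used by the default workflows: 100 timepoints × 1024 spectral
points for 300 s cell acquisitions; 40 timepoints × 8×8 × 128 points in
vivo; n = 3/arm (cells) and n = 6 animals, matching the study designs.

## What the generator does and does not emulate

It emulates the statistical structure the analysis relies on: three
Lorentzian lines at the published shifts, T1- and RF-governed signal decay,
metabolite-specific flip angles, bolus delivery, spatially varying
conversion with a signal-free border for noise estimation, i.i.d. complex
Gaussian noise, and injection-to-injection scale variability. It does not
emulate B0 drift or shim gradients (no frequency error between voxels),
baseline distortions, partial-volume mixing at region borders, perfusion
heterogeneity or substrate replenishment after the bolus, or physiological
motion. Passing tests therefore demonstrate the correctness and statistical
calibration of the *analysis* under its stated assumptions — not robustness
to every artifact of real scanner data.

One consequence worth stating: with the phantom's conversion rates
(0.02 vs 0.005 s⁻¹), conversion measurably depletes the tumor's substrate
pool (~20–25% over a 2 min acquisition), so the substrate-SNR comparison
between tumor and contralateral brain — reported alongside the ratios — is
not reliably non-significant in this simulator even though real cohorts,
with their larger physiological variability, typically show no difference.
The ratio comparisons are unaffected.

## Numerical choices and degenerate inputs

Matrix exponentials are cached per interval length; trajectories are exact
to solver-free machine precision. Seeded `numpy` Generators make every
dataset bit-reproducible; workflow replicate *i* uses seed list[*i*],
derived from one base seed via `SeedSequence` when not given explicitly.
Degenerate inputs fail loudly: zero substrate AUC (undefined ratio),
all-zero decay series, zero-variance SNR denominators, empty ROIs and
contour sets, mask/shape mismatches, windows or resonances outside the
spectral axis (named in the error), noise regions overlapping declared
lines. Two constant equal groups give p = 1 by convention.

## Known limitations

- Rate constants are not estimated (the analysis quantifies AUC ratios, by
  design); no multi-exponential T1.
- Zero-order phasing only; no lineshape fitting or frequency-drift
  correction.
- The δ:γ partition and exchange rate, 6PG T1 values, thermal reference
  temperature and integration window widths are declared defaults, not
  measured quantities; all are configurable.
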