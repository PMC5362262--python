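# Methods

This note documents the models, estimators, parameter defaults and design
choices behind `flagstorm`, and what the synthetic tests do and do not
demonstrate about real data.

## Synthetic flagellum model

The principal piece of the sperm flagellum is modelled as a straight (or,
optionally, gently arced) cylinder. Membrane protein nanodomains are four
longitudinal stripes at the quadrant diagonals (45°, 135°, 225°, 315°),
each with a uniform angular spread of ±15°. Emitters are a Poisson point
process along each stripe; they lie *exactly* on the cylinder surface,
which gives the geometric stages an exact oracle.

Fragmentation is a square-wave mask on the longitudinal coordinate s:
within each period P, the interval [kP, kP + duty·P) is emitter-free, with
each boundary optionally jittered by independent Gaussian offsets. The mask
is shared across the four stripes (circumferential fibrous-sheath ribs
would gate all quadrants together); per-stripe masks are not modelled.

Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| length | 10 µm | typical analyzed span of a principal piece |
| radius | 300 nm | flagellar scale at the proximal principal piece |
| stripe half-width | 15° | stripes resolved but not point-like |
| gap period / duty | 800 nm / 0.5 | fibrous-sheath rib spacing; half-on/half-off fragmentation |
| emitter density | 0.05 /nm/stripe | dense SMLM labeling (~500 emitters/stripe/10 µm) |
| localizations per emitter | Poisson(3) | repeated blinks of one fluorophore |
| σ_xy, σ_z | 10 nm, 25 nm | typical STORM localization precision |
| background | 5 /µm³ | sparse nonspecific localizations |
| photons | Gamma(2, mean 5000) | bright-dye photon budget |

The localization-noise model displaces each blink by N(0, σ_xy²) in the two
lateral axes and N(0, σ_z²) axially — the optical axis is the laboratory z,
independent of the flagellum's orientation. Random streams are split by
purpose (emitters, gap phases, blinks, noise, background, photons, shot
noise), so toggling the background never perturbs the emitter draws.

Not emulated: blinking kinetics and duty cycles, drift, multi-emitter
overlap, sCMOS noise maps, axial-dependence of labeling efficiency. Tests
passing on this generator therefore demonstrate correctness of the
*analysis*, not robustness to every artifact of real STORM data.

## Astigmatic 3D localization

The calibration is analytic: wₓ(z) = w₀√(1+((z−c)/d)²) and the mirrored
w_y, with w₀ = 150 nm, c = 150 nm, d = 400 nm, valid over ±400 nm (the
width ratio is strictly monotonic for \|z\| < √(c²+d²) ≈ 427 nm). A
bead-stack-derived calibration is out of scope.

Detection runs on a Gaussian-smoothed frame (σ = 1 px). The noise scale is
the larger of the analytic shot-noise SD of the smoothed field,
√(background · Σw²) with w the discrete smoothing kernel, and the robust
MAD SD; the default threshold is background + 5σ. A border margin is
excluded — reflected-boundary smoothing inflates edge variance, and edge
spots cannot be fit with a full ROI anyway. With these choices a flat
Poisson frame stays empty in ≳99% of realizations, as a Gaussian tail
bound predicts; raw-pixel thresholding does not achieve this because the
discrete Poisson tail is heavier at any practical background level.

Fitting is least-squares on a pixel-integrated elliptical Gaussian (erf
differences), 11×11 px ROI at 100 nm/px. Degenerate patches return a
non-converged flag rather than raising. z is the argmin over the valid
range of the distance in √width space (the established astigmatism
convention; plain widths are an option), resolved on a 2 nm grid and
refined by bounded scalar minimization. Minima on the range boundary, or
ambiguous double minima (possible outside the monotonic range, resolved
toward smaller \|z\|), are flagged out-of-range and dropped by the stack
localizer. At 5000 photons this yields ~13 nm axial MAE over ±300 nm and
lateral errors at ~1.1× the photon limit √((w² + a²/12)/N).

## Cylindrical projection

The axis is the first principal direction of the centered cloud (SVD); a
cloud with first-to-second singular-value ratio < 2 is rejected as
isotropic. The annulus — the longitudinal origin — must be supplied by the
caller (an explicit point or a "min-s"/"max-s" end flag): on real data it
is identified morphologically, which localizations alone cannot automate.

The θ = 0 reference defaults to the second principal direction, but for a
four-fold symmetric cloud the cross-sectional covariance is nearly
isotropic and that direction is arbitrary; `AxisModel` therefore accepts an
explicit reference direction, and only relative angles are meaningful when
none is given. The synthetic tests pass the generator's known frame so
absolute peak angles can be checked.

Curved flagella: an opt-in refinement replaces the straight axis by a
polyline of 1 µm windowed centroids (end segments extrapolated to cover the
whole span), with the cross-sectional frame parallel-transported along
segments. This recovers arc length on gently arced synthetic flagella to a
few percent; strongly curled cells are out of scope.

Surface selection keeps radii within ±3σ_r of the modal radius (10 nm-bin
histogram mode; σ_r is the MAD spread of radii within 100 nm of the mode).
An explicit band overrides the automatic rule. Selection always partitions
the input: selected + rejected = total.

## Angular profiling

Angular histograms use 10° bins (bin widths are snapped to the nearest
divisor of 2π); profile maps use 50 nm × 10° bins. Peaks are circular local
maxima with prominence ≥ 0.3× the maximum bin, found on a tripled copy of
the histogram so wraparound is exact, then refined to the count-weighted
circular mean of the contiguous bins above half the peak height — this
gives sub-bin (≲2°) accuracy at the default noise. Stripe assignment is
nearest-peak in circular distance, ties toward the lower peak index.

## Periodicity

Longitudinal densities use 20 nm bins from s = 0, giving ≥ 10 bins per
cycle at the shortest period of interest. The ACF uses the constant-
denominator (biased) estimator, so ρ(0) = 1 and values are comparable
across lags; the per-lag (unbiased) denominator is an option. Note that for
a pure square wave the biased estimator's value at one-bin lag slightly
exceeds its value at the true period (the numerator loses terms with lag);
the period is still the largest local maximum away from the origin, which
is what first-peak detection uses. Per-domain ACFs are averaged pointwise
(truncated to the shortest); the first peak is the smallest lag > 200 nm
that is a local maximum with prominence ≥ 0.2, refined by 3-point parabolic
interpolation. The prominence default separates the ~0.7 modulation of
duty-0.5 fragmentation from the ≤ 0.1 estimator noise of unmodulated
domains at the default study conditions.

Modulation depth is the first-peak value minus the preceding trough value;
when no peak qualifies, the maximum beyond the minimum lag stands in, so
unmodulated data report a small (possibly negative) depth rather than
nothing.

The Fourier route operates on the pooled all-stripe 1D projection:
mean-detrended, unwindowed, zero-padded 4× (frequency resolution ~16 nm at
an 800 nm period over 10 µm), DC excluded. The fundamental is the in-band
(default 300–3000 nm) power maximum, parabolic-refined, accepted only if it
passes two gates: (i) power ≥ mean + 3 SD of the out-of-band power, and
(ii) power above the 99th percentile of a seeded block-permutation null
(199 shuffles of 10-bin blocks). Blocks rather than single bins are
shuffled because repeated blinks of one emitter correlate neighboring
bins; a bin-level permutation null misattributes that broadband clustering
excess to periodicity. The residual false-positive rate of the FFT gate on
continuous-stripe data is ~5–10% per dataset; the ACF route is the more
specific detector, and the two are reported side by side with a
concordance flag (agreement within one bin) rather than reconciled.

Between the two estimates, finite length, duty cycle and estimator bias
can produce discrepancies of a few tens of nm on identical data; the
package reports both without preferring either.

## Pipeline and reproducibility

`run_pipeline` simulates `n_cells` flagella with seeds derived from the
config seed, projects each in its own frame, pools stripes across cells as
separate domains for ACF averaging (the default demos use 2 cells × 4
stripes = 8 domains), and pools all localizations for the Fourier route.
Identical config + seed reproduces the report bit-for-bit on numeric
fields. Reports validate against `report_schema.json`, generated from the
pydantic report model and shipped with the package.

Problem sizes in the test suite and acceptance script (10 µm flagella,
~2,900 localizations per fragmented cell, 15-run recovery sweeps, 200
emitters in the rendering round trip) were chosen so the statistical
properties under test are well-resolved while the whole suite runs in a
few seconds.

## Known limitations

- The surface-selection band and the annulus convention are explicit
  stand-ins for steps that are morphological or unspecified in practice.
- No cross-cell registration of stripe phases; peak angles are only
  comparable across cells when a common reference direction is supplied.
- The permutation significance gate assumes the colored-noise correlation
  length is below the block size (200 nm); pathological clustering at
  longer scales would require larger blocks.
- No model-based (mixture) angular fitting; heavily overlapping stripes
  (half-width ≳ 40°) will merge peaks.
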