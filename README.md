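# flagstorm

Quantification of flagellar membrane nanodomain organization from 3D-STORM
single-molecule localization data.

## The problem

The CatSper Ca²⁺ channel complex of the sperm flagellum is organized into
four linear membrane nanodomains ("racing stripes") running down the
quadrants of the principal piece. Loss of the CatSperζ subunit fragments
each stripe into periodically spaced segments at roughly the fibrous-sheath
rib spacing (~0.8 µm), while the overall four-fold arrangement persists.
Detecting and quantifying this reorganization from stochastic optical
reconstruction microscopy (STORM) data requires a chain of steps that this
package implements as a tested, reusable pipeline:

1. **Astigmatic 3D localization** (`flagstorm.loc3d`) — spot detection and
   elliptical-Gaussian fitting of raw camera frames; the axial position is
   decoded from the PSF ellipticity through the defocus calibration
   wₓ(z) = w₀√(1 + ((z−c)/d)²), w_y(z) = w₀√(1 + ((z+c)/d)²).
2. **Cylindrical projection** (`flagstorm.geometry`) — the flagellar axis is
   the dominant principal direction of the localization cloud; every
   molecule is mapped to (s, r, θ) with s = 0 at the annulus, and membrane
   ("surface") molecules are selected by a radial band around the modal
   radius.
3. **Angular profiling** (`flagstorm.profiles`) — circular histograms and
   2D (s, θ) maps resolve the four stripes; peaks are circular local maxima
   reported as count-weighted circular means; each localization is assigned
   to its nearest stripe.
4. **Periodicity analysis** (`flagstorm.periodicity`) — per-stripe 1D
   densities d(s) feed the normalized autocorrelation
   ρ(k) = Σᵢ(dᵢ−d̄)(dᵢ₊ₖ−d̄) / Σᵢ(dᵢ−d̄)², averaged over domains; the lag of
   the first off-origin peak estimates the fragmentation period. In
   parallel, the Fourier power spectrum of the pooled 1D projection yields
   the fundamental spatial frequency, gated by an analytic and a
   block-permutation significance test.
5. **Synthetic ground truth** (`flagstorm.synthgen`) — a parametric striped
   cylinder (radius 300 nm, four stripes at the quadrant diagonals,
   optional jittered square-wave gaps) with Gaussian localization error,
   repeated blinks, uniform background, and an astigmatic frame renderer,
   so every stage is testable without any experimental download.

## Worked example

```python
from flagstorm.pipeline import null_model_config, run_pipeline

report = run_pipeline(null_model_config(seed=0))   # two fragmented flagella
p = report.periodicity
print(report.angular_peaks.n_peaks)        # 4
print(round(p.acf_first_peak_nm, 1))       # 796.6
print(round(p.fft_fundamental_period_nm, 1))  # 802.5
print(p.concordant, p.n_domains_averaged)  # True 8
```

The demo simulates two CatSperζ-null-like flagella (gap period 800 nm,
duty 0.5), projects the ~5,800 localizations to cylindrical coordinates,
finds the four stripe peaks, and recovers the fragmentation period from
both estimators: the averaged autocorrelation of the 8 stripe domains
peaks at 796.6 nm and the Fourier fundamental of the pooled longitudinal
density is 802.5 nm — both within one 20 nm bin of the generator's truth,
and concordant with each other. The same pipeline on the continuous-stripe
configuration (`wt_model_config`) still reports 4 angular peaks but flags
"no periodicity": neither estimator finds a significant period.

The same run is available from the shell:

```
flagstorm run --demo null --seed 0 --out report.json
flagstorm simulate --gap-period-nm 800 --seed 1 --out locs.csv
flagstorm analyze --input-csv locs.csv --out report.json
```

## Scope

The package analyzes localization tables (CSV: `frame,x_nm,y_nm,z_nm,
photons[,sigma_x_nm,sigma_y_nm]`) or renders/fits its own synthetic frame
stacks (TIFF). It does not do drift correction, multi-emitter fitting,
image rendering for display, cross-genotype statistics, or segmentation of
multi-cell scenes. See `docs/methods.md` for the model, parameter defaults
and their rationale, and known limitations.
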