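# Methods

## Model

MINSTED localizes a single active fluorophore with the intensity minimum of
a STED doughnut as a movable reference coordinate. The fluorescence ability
surviving depletion is modelled as a Gaussian effective point-spread
function (E-PSF) centred on the doughnut minimum, with FWHM

    d(I) = λ / (2 NA √(1 + I/I_s)),

λ the STED wavelength (default 775 nm), NA the numerical aperture (default
1.4), I the doughnut peak intensity and I_s the saturation intensity. All
intensities are dimensionless multiples of I_s (I_s ≡ 1); conversion to
physical MW cm⁻² is out of scope. The zero-intensity width d₀ = λ/(2 NA)
uses the STED wavelength; `EPSFModel(d0_override=...)` substitutes any
other diffraction limit.

The localizer circles the beam at radius `R_i = ratio_Rd · d_i` around the
centre estimate `C_i`. On each photon detection at scan phase φ the centre
shifts by `alpha · R_i` toward the doughnut position `S_i = C_i + R_i
(cos φ, sin φ)`, then `d` and `R` shrink by `gamma` until the floors
`d_min` / `R_min` are reached; afterwards only the centre moves. The final
estimate averages `C_i` from the floor-reaching detection `N_c` to `N`.
The update order (shift first, then shrink) is a deliberate choice — the
two operations commute only approximately — and is locked by a golden-trace
test that asserts bit-for-bit equality against frozen values.

## Photon statistics

Conditioned on a detection, the scan phase follows
`p(φ) ∝ epsf(d, |S(φ) − r_FL|) + 1/SBR`, the Gaussian emission probability
at the doughnut position plus a uniform background whose weight is the
inverse peak signal-to-background ratio. Expanding the squared distance
shows the signal component is exactly von Mises with concentration
`κ = 8 ln2 · R·ρ₀ / d²` toward the emitter (ρ₀ the centre-to-emitter
distance), with mixture weight `exp(−4ln2(R²+ρ₀²)/d²)·I₀(κ)` against
`1/SBR`. Sampling is therefore exact (Bernoulli mixture of a von Mises and
a uniform draw), with no grid, CDF-inversion or rejection error; tests
cross-check it against quadrature of the raw density.

Assumptions, and what the generator does not emulate:

- Phases are i.i.d. from the instantaneous stationary density (the beam
  circles many times between detections); no explicit time axis, so
  revolution-rate effects and detector dead time are absent.
- Background photons are indistinguishable from signal and drive the same
  update — this is precisely how low SBR degrades convergence.
- SBR is held constant as `d` shrinks (a real STED doughnut also suppresses
  background; an experiment near that regime behaves between our finite-SBR
  and SBR=∞ predictions).
- The photon budget before bleaching is geometric with mean 1000
  detections; blinking, triplet states, drift and activation scheduling are
  not modelled. Passing tests therefore validate the estimator and its
  scaling laws, not robustness to drift or photophysics.
- Pre-identification of an emitter is modelled as a Gaussian starting
  offset of the scan centre (σ₀ = 60 nm per axis by default) rather than by
  simulating the overview scan.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| alpha | 0.15 | centre step, fraction of R per detection |
| gamma | 0.97 | shrink factor of d and R per detection |
| ratio_Rd | 0.5 | scan radius over FWHM |
| d0 | 276.8 nm | starting FWHM (775 nm / 2·1.4) |
| d_min | 40 nm | FWHM floor (N_c = 64 detections from d0) |
| R_min | ratio_Rd·d_min | radius floor |
| I_max | ∞ | intensity cap; a finite cap raises the width floor to d(I_max) |
| SBR | 20 | peak signal-to-background ratio |
| σ₀ | 60 nm | starting-offset std per axis |
| budget_mean | 1000 | mean photon budget |

With these defaults the simulated pooled precision of the final estimates
over 500 replicates is ≈3.4 nm at N=100 total detections and ≈1.1 nm at
N=500 (≈0.76 nm at N=1000), scaling as `d_min/√(N−N_c+1)` with a log–log
slope of −0.47 over floor-phase counts 25–1000.

## Precision estimate

The per-localization precision estimate is
`sigma_hat = κ · d_min / √(N − N_c + 1)` with κ = 0.58, calibrated once
against this package's own ensemble simulator at SBR = 20, d_min = 40 nm
(seed 1, long traces; κ plateaus at 0.575–0.58 for floor-phase counts
≥ 500 and is slightly smaller, ≈0.52, at very short tails). κ is exposed in
the `localizer:` config block. A small-noise analysis of the floor-phase
walk reproduces the calibration: the centre follows an
Ornstein–Uhlenbeck-like chain with per-step noise `(αR)²/2` per axis and
relaxation rate `λ = α·4ln2·s·R²/d²` (s the signal fraction), giving
`Var(C̄) ≈ d⁴ / (2 R² s² (4ln2)² n)` per axis — independent of α, the
usual averaged-stochastic-approximation efficiency.

## Estimators and numerical choices

- Ensemble precision σ is the pooled per-axis standard deviation of the
  final estimates around their *ensemble mean*; the bias relative to the
  true position is reported separately. Replicates whose final centre is
  further than the current FWHM from the emitter are classified lost,
  excluded from σ and reported as a fraction.
- σ_C of a single localization pools x and y as √((var_x+var_y)/2) with
  sample variances (n−1 denominator).
- Segment precision σ_M uses consecutive non-overlapping floor-phase
  segments of M detections (trailing partial segment discarded);
  overlapping windows would correlate the segment means. Traces shorter
  than max(2M, min_tail) are rejected with the shortfall named.
- The convergence count of the fixed-width study is the first detection at
  which the ensemble-mean distance to the emitter enters a ±5% band around
  its tail mean (mean over the last 20% of detections).
- Clustering of repeated localizations is single linkage (transitive
  chaining) cut at 25 nm; sets of at least 6 localizations are retained.
  Complete linkage is available. Quality filtering drops dim rows
  (N − N_c below threshold, default 250) before the excessive-sigma rule
  (default cutoff 3× the table median of sigma_hat), and a row failing
  both is attributed to dimness.
- Rendering integrates each localization's Gaussian, std
  `max(sigma_hat, 3 nm)`, exactly over pixels via the error function, so
  the image sums to the rendered count up to boundary truncation (logged).
  Float32 TIFF is the lossless output; the optional PNG preview is min-max
  scaled.
- Sweeps derive per-grid-point RNG streams from one `SeedSequence`, making
  every study bit-for-bit reproducible from (spec, seed); σ values carry
  bootstrap standard errors (200 resamples).

## Problem sizes

Monte-Carlo tests and the headline precision computations use 500
replicates (300–400 for the ordering and scaling checks), N up to ~1100
detections per localization, 10⁵ draws for the sampling-law
(Kolmogorov–Smirnov) check and 2×10⁴ draws for histogram-based checks;
single-trace segment-precision checks use 8–12k floor-phase detections.
These sizes put Monte-Carlo standard errors well inside the asserted
tolerances while the whole suite runs in well under a minute.

## Known limitations

- The diffusive centre walk at small step sizes means the maximal excursion
  of a converged scan scales as √α, not α; arbitrarily small steps make the
  walk slow, not arbitrarily tight.
- At the default schedule the simulated precision at N=500, SBR=20 is
  ≈1.1 nm; 1 nm is reached near N≈650 (and N≈500 only marginally misses it
  even with no background). See the precision table above.
- Sequentially activated emitters are simulated independently; interference
  between emitters closer than the minimum separation
  `d_i + (1+2α)R_i` is warned about but not physically modelled.
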