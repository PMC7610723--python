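# minsted

Photon-by-photon simulation and analysis of **MINSTED** single-fluorophore
localization — the super-resolution scheme in which the intensity minimum of
a STED doughnut serves as a steerable reference coordinate that homes in on
one active fluorophore at a time.

The package is for microscopists and methods developers who want to study
the localizer's behaviour quantitatively: how precision scales with photon
count, background and beam parameters, and how the downstream filtering,
clustering and rendering pipeline turns localization tables into images.

## Model in brief

The fluorescence ability under STED is a Gaussian effective PSF of FWHM

    d(I) = λ / (2 NA √(1 + I/I_s)),      σ_E ≈ 0.42 d,

centred on the doughnut minimum. The localizer circles the beam at radius
`R_i = d_i/2` around the centre estimate `C_i`; each photon detection at
scan phase φ pulls the centre by `α·R_i` toward the doughnut position and
shrinks `d` and `R` by `γ` until a floor `d_min` is reached (after
`N_c` detections), from where only the centre moves. The estimate is
`C̄_N = ⟨C_i⟩, N_c ≤ i ≤ N`, with precision scaling as
`d_min/√(N − N_c + 1)`. Detection phases are drawn from the exact law
`p(φ) ∝ epsf(d, |S(φ) − r_FL|) + 1/SBR` — a von Mises signal component
pointing at the emitter mixed with a uniform background set by the peak
signal-to-background ratio.

Modules: `psf` (optics model), `localizer` (update rule and records),
`simulate` (photon source, scenes, ensembles), `experiments` (precision /
convergence sweeps), `analysis` (segment precision, clustering, filters,
rendering), plus CSV/TIFF I/O, YAML config and a `minsted` CLI.

## Worked example

Localization precision of the standard schedule (α=0.15, γ=0.97, R/d=0.5,
d_min=40 nm, SBR=20, 60 nm starting offset), 500 replicates at N=100
detections:

```python
import numpy as np
from minsted import LocalizerParams, PhotonScene, run_ensemble, ensemble_sigma

run = run_ensemble(PhotonScene(sbr=20.0, sigma0=60.0), LocalizerParams(),
                   100, 500, rng=np.random.default_rng(1))
sigma, bias, lost, _ = ensemble_sigma(run)
print(f"N=100: sigma = {sigma:.2f} nm  (bias {bias:.2f} nm, "
      f"lost {lost:.1%}, N_c = {run.N_c})")
```

prints

```
N=100: sigma = 3.47 nm  (bias 0.28 nm, lost 0.0%, N_c = 64)
```

i.e. the FWHM floor is reached after 64 detections and the pooled per-axis
standard deviation of the 500 final estimates is ≈3.5 nm, with negligible
bias and no lost runs. Raising N to 500/1000 detections brings σ to
≈1.1/0.76 nm.

The same pipeline from the shell, for a ring of 8 emitters (50 nm radius,
the geometry of small ring-like protein assemblies at mitochondrial crista
junctions):

```
$ minsted simulate --config cfg.yaml --seed 1 --out sim_out
wrote 8 localizations to sim_out/localizations.csv
$ minsted analyze --table sim_out/localizations.csv --min-tail 250 \
      --min-cluster-size 1 --out ana_out
kept 8/8 localizations (100.0%)
$ minsted render --table ana_out/filtered.csv --pixel-size 2 \
      --sigma-floor 3 --out ring.tif
rendered 8 localizations to ring.tif (75x76 px, sum=8.00)
```

where `cfg.yaml` holds the `optics:`, `localizer:` and `scene:` blocks (see
`minsted.config`). The localization table carries
`id,Cx,Cy,N,Nc,sigma_C,sigma_hat,converged`; the rendered TIFF sums to the
number of rendered localizations because each one is splatted as a
unit-integral Gaussian of std `max(sigma_hat, 3 nm)`.

See `docs/methods.md` for the model assumptions, estimator definitions and
default-parameter rationale.

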