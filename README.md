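# nanotrack

Single-particle analysis of plasma-membrane nanodomain dynamics.

Proteins such as flotillins and hypersensitive-induced-reaction proteins
organize into sub-micron membrane nanodomains whose lateral mobility,
surface density and residence time change under biotic and abiotic
stress.  Quantifying that behaviour from TIRF-style movies requires a
chain of estimators — spot detection, trajectory linking, mean-square-
displacement analysis, dwell-time fitting, two-channel colocalization,
FRAP recovery kinetics and FCS particle counting — each of which is easy
to get subtly wrong.  `nanotrack` implements the full chain as a tested
library with a ground-truthed synthetic-movie generator, so every
estimator can be validated by parameter recovery instead of trust.

It is intended for microscopists and image analysts working with sparse
single-particle membrane data, and for anyone who needs a reference
implementation of these estimators with explicit conventions.

## The quantities it computes

* **Per-track diffusion coefficient** `D = slope/4` from a linear fit of
  the time-averaged MSD over the first 4 lags,
  `MSD(nΔt) = ⟨|r(t+nΔt) − r(t)|²⟩`, intercept free.
* **Characteristic coefficients Ĝ**: per-track `D` (or speed) values are
  log10-transformed, fitted with 1- and 2-component Gaussian mixtures, the
  model chosen by BIC; each `Ĝ = 10^μ` is the peak of the log-binned
  distribution — the signature used to separate slow and fast membrane
  subpopulations.
* **Dwell time τ** from an exponential fit `A·exp(−t/τ)` to the
  dwell-time histogram (censored tracks excluded).
* **Object colocalization** `100·n_matched/n_A` by one-to-one center
  matching (optimal assignment) within a 2-px radius, with the
  closed-form chance level `100(1 − exp(−ρ_B π r²))`.
* **FRAP mobile fraction** `100(P − F0)/(1 − F0)` from
  `F(t) = F0 + (P − F0)(1 − e^{−kt})` on double-normalized recovery
  curves, plus sub-ROI (edge vs. middle strip) kinetics.
* **FCS particle number and density** from `G(τ) = G0/(1 + τ/τ_D)`,
  `N = 1/G0`, `density = N/(π w₀²)`.
* **Condition comparisons** via Student's t-test with `*`, `**`, `***`
  codes.

Conventions, defaults and numerical choices are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a movie of a two-population membrane protein and run the full
pipeline:

```python
import numpy as np
from nanotrack import (PopulationSpec, ImagingSpec, RunConfig,
                       simulate_movie)
from nanotrack.pipeline import run_pipeline
from nanotrack.dynamics import log_binned_peaks

pops = [
    PopulationSpec(diffusion_coefficient=1.8e-3, fraction=0.5,
                   mean_dwell=3.0, mean_intensity=1200.0),
    PopulationSpec(diffusion_coefficient=3.5e-2, fraction=0.5,
                   mean_dwell=3.0, mean_intensity=1200.0),
]
imaging = ImagingSpec(n_frames=120, shape=(128, 128))   # 0.1 µm px, 0.1 s
movie, truth = simulate_movie(pops, imaging, density=0.10, seed=7)

result = run_pipeline(RunConfig(), movie, outdir="scratch/demo")
print(result.summary)
print(result.peaks)
```

Output:

```
{'n_spots': 2466, 'n_tracks': 90, 'n_dwells': 58, 'mean_dwell_s': 2.1068965517241383}
  quantity  component     G_hat   weight  standard_error  n_components
0        D          0  0.002126  0.40003        0.000328             2
1        D          1  0.034123  0.59997        0.002797             2
```

The movie contained two equal subpopulations generated at
D = 1.8 × 10⁻³ and 3.5 × 10⁻² µm²/s.  The pipeline detects ~20 spots per
frame, links them into 90 trajectories, and the log-binned peak
decomposition selects two components with characteristic coefficients
Ĝ ≈ 2.1 × 10⁻³ and 3.4 × 10⁻² µm²/s — the generating mixture, recovered
from rendered images alone.  (The weights tilt toward the fast component
because slow tracks are likelier to be censored; `mean_dwell_s` is the raw
mean of the 58 uncensored dwells, which is why dwell statistics use the
exponential fit rather than raw means.)

A command-line surface wraps the same stages:

```sh
nanotrack simulate --out scratch/demo.tif --frames 100 --density 0.1 --seed 1
nanotrack detect scratch/demo.tif --out scratch/spots.csv
nanotrack track scratch/spots.csv --out scratch/tracks.csv
nanotrack dynamics scratch/demo.tif --out scratch/run
```

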