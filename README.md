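# xdiscreen

Similarity-score screening of phase-retrieved electron density maps in
X-ray diffraction imaging (XDI).

## The problem

In XDI a non-crystalline particle (e.g. a cluster of colloidal gold
spheres) is illuminated with coherent X-rays and its oversampled
Fraunhofer diffraction pattern is recorded. Only intensities are
measured, so the projected electron density ρ(x, y) must be recovered by
iterative phase retrieval (HIO / shrink-wrap / ER). With a beamstop
hiding the smallest scattering angles and Poisson noise in the counts,
many of the independently started retrievals converge to non-realistic
maps. Practitioners therefore run hundreds to thousands of retrievals
and need an automatic way to pick out the consistent, realistic ones.

`xdiscreen` implements that screening workflow around the **similarity
score** between two retrieved maps,

    score(i, j) = sqrt( Σ (ρ_i − ρ_j)² / Σ (ρ_i + ρ_j)² ),

which by Parseval's theorem has the reciprocal-space form

    sqrt( Σ |F_i − F_j|² / Σ |F_i + F_j|² )
      = sqrt( Σ |F_obs|² sin²(Δα/2) / Σ |F_obs|² cos²(Δα/2) ),

where Δα(S) = α_i(S) − α_j(S) is the phase difference between the two
maps' structure factors, which share the observed amplitudes |F_obs(S)|.
Since low-resolution amplitudes dominate the weights, a small score
means the maps agree at low resolution — pairs of successful
reconstructions score below ≈ 0.2 while failed ones scatter above it.

The package provides, end to end on synthetic data:

- **Simulation** — disk-cluster and urchin phantoms, Poisson photon
  statistics, square beamstop shadow, detector-gap stripes,
  centro-symmetric (Friedel) averaging, and the analytic Airy
  (`2J₁(x)/x`) amplitude of a uniform disk.
- **Phase retrieval** — HIO with periodic shrink-wrap support updates
  and an ER finish, the 4%-of-autocorrelation initial support, and the
  Fourier-error diagnostic.
- **Alignment** — center-of-gravity and phase-only-correlation
  registration with π-rotation correction, plus the two-pass reference
  selection (the globally best-scoring pair defines the reference).
- **Scoring** — similarity score in both spaces, lack of identity,
  per-shell averaged |cos(Δα/2)| / |sin(Δα/2)| terms, the random phase
  limit 2/π ≈ 0.64, figure of merit (FoM), PRTF, half-bit threshold
  curve, and effective-resolution estimation.
- **Classification** — K-means on the aligned maps, PCA projection,
  class representatives, and score/PC funnel-landscape coordinates.

## Worked example

```python
from xdiscreen import (PhantomSpec, NoiseAndMaskSpec, PRConfig,
                       PipelineConfig, run_screening_pipeline)

cfg = PipelineConfig(
    grid_n=128,
    phantom=PhantomSpec(kind="disk_cluster", n_particles=10,
                        particle_radius_px=5.0, seed=1),
    noise=NoiseAndMaskSpec(total_photons=1e8, beamstop_halfwidth_px=2, seed=1),
    pr=PRConfig(n_hio=2000, sw_every=100, n_er=200, n_repeats=20, seed=0),
    n_shells=25, k=5, kmeans_seed=0,
)
report = run_screening_pipeline(cfg, outdir="demo")
```

prints (seeds fixed, so exactly reproducible):

```
maps retrieved:          20
reference map index:     3
best pair:               (3, 15) (score 0.0017)
maps scoring < 0.2:      100%
classes passing screen:  [0, 1, 2, 3, 4]
best class-average corr with ground truth: 1.000
effective resolution (cosine term vs 0.64): 19.6 um^-1 (51.0 nm), crossed=False
```

Read: all 20 retrievals of this high-signal pattern converged to the
same solution (best-pair score 0.0017 ≪ 0.2); every class average
matches the ground-truth phantom; and the shell-averaged cosine term
never falls to the random phase limit 0.64, so the maps remain
consistent out to the highest recorded resolution (19.6 µm⁻¹, i.e. the
51 nm Fourier period). Lowering `total_photons` and widening the
beamstop produces the opposite regime: scattered scores, few or no
classes passing the 0.2 screen.

The same stages are available as a CLI for shell use:

```
xdi-screen simulate --n 10 --photons 1e8 --beamstop 2 --seed 1 -o pattern.h5
xdi-screen retrieve pattern.h5 --repeats 50 -o maps.h5
xdi-screen align maps.h5 -o aligned.h5
xdi-screen classify aligned.h5 --k 10 -o classes.csv
xdi-screen score aligned.h5 --shells 25 -o report/
xdi-screen run -o out/          # the whole pipeline in one command
```

## Documentation

See `docs/methods.md` for the model conventions, parameter defaults and
their rationale, what the synthetic data do and do not emulate, and
known limitations.
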