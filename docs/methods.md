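# Methods

## Conventions

Real-space maps are `N×N` (N even) arrays of projected electron density
with a pixel size in nanometres. The structure factor is the *centered*
unnormalised DFT of the density (zero frequency at index `(N/2, N/2)`,
scattering vector of pixel `(u, v)` equal to `((u−N/2), (v−N/2))·q_step`
with `q_step = 1/(N·pixel_size)` in µm⁻¹); the inverse transform carries
the `1/N²` factor, so Parseval's identity reads `Σ|ρ|² = Σ|F|²/N²`.
This bookkeeping is what makes the real- and reciprocal-space forms of
the similarity score equal to one another on full grids, a property the
test suite checks to 1e−10.

All translations are integer and circular (toroidal). That is exact for
the DFT and harmless physically because the oversampling condition keeps
the object inside the central half-box. A point reflection about the
center pixel maps index `i` to `(−i) mod N`; for a real density the
structure factor then satisfies Friedel symmetry `F(−S) = conj(F(S))`,
which is also why every diffraction pattern determines its map only up
to a π rotation.

Resolution shells are equal-width |S| annuli from 0 to the inscribed
maximum `(N/2)·q_step`; corner pixels outside that circle are excluded.
Shell widths are nowhere critical — defaults are 25 shells at 128² and
50 at 256², giving several hundred to several thousand pixels per shell
so that shell means of trigonometric quantities are stable.

## Similarity score

The score between aligned maps is
`sqrt(Σ(ρ_i−ρ_j)² / Σ(ρ_i+ρ_j)²)`. The square-root L2 ratio is the form
consistent with the per-shell constant-phase limit: restricted to a
shell where the phase difference Δα is constant (the exact situation for
uniform-disk objects, whose Airy-form structure factor has phase 0 or π
between consecutive Bessel zeros), the score collapses to `|tan(Δα/2)|` —
0 at Δα = 0, 1 at π/2, divergent at π. An L1 variant is available
(`norm="l1"`) for comparison but is not used anywhere.

Masked (beamstop/gap) pixels are excluded from every reciprocal-space
sum and from shell statistics; the real-space score uses all pixels.

Shell-averaged `|cos(Δα/2)|` and `|sin(Δα/2)|` are **frequency**
averages — amplitude weighting enters only the score itself. Their
limit under uniformly random phase differences is `2/π ≈ 0.6366`
(quoted as 0.64), the *random phase limit*: shells whose cosine term has
fallen to this value carry no mutual phase information between maps.

The figure of merit at a pixel is the magnitude of the
probability-weighted mean phasor of the phase values across an ensemble
(36 bins of 10° by default; `n_bins=None` gives the exact unbinned
resultant). FoM = 0.5 corresponds to phases spread ±60° about their
mean, the conventional interpretability threshold. The PRTF is the
shell average of `|(1/M)Σ exp(iα_m)|`; for M = 2 it equals the shell
cosine term identically. Effective resolution is reported as the first
shell-center q where a curve falls to its criterion — 0.64 for the
cosine term, a fixed 0.5 or 1/e for the PRTF, or the shell-size-aware
half-bit curve `T(n) = (0.2071 + 1.9102/√n)/(1.2071 + 0.9102/√n)` with n
the shell pixel count halved for Friedel symmetry. A curve that never
crosses is reported at the highest recorded q with `crossed=False`.

## Phase retrieval

One repeat = `n_hio` HIO iterations with a shrink-wrap support update
every `sw_every`, then `n_er` ER iterations; the final map is masked by
the final support. The magnitude projection replaces amplitudes with
`sqrt(counts)` on valid pixels and leaves invalid (beamstop/gap) pixels
unconstrained. HIO feedback uses β = 0.9; density is kept non-negative
inside the support (the unknown is a projected electron density). The
initial support thresholds the pattern's autocorrelation at 4% of its
maximum. The per-map diagnostic is the Fourier error
`sqrt(Σ_valid(|F_obs|−|F_cal|)²/Σ_valid|F_obs|²)` with `F_cal` from the
support-masked map.

Shrink-wrap blurs |ρ| with a σ = 3 px Gaussian (toroidal wrap, matching
the shift conventions) and keeps pixels above `sw_threshold_frac` of the
blurred maximum. The default threshold is **0.20**: at looser values
(0.10) the support balloons until the iterate has enough freedom to fit
the Poisson-noisy amplitudes *below* the noise floor while bearing no
resemblance to the object — exactly the failure mode the screening score
is designed to catch, but not one the generator should manufacture by
default. With 0.20 the retrieval succeeds essentially always on
high-signal, small-beamstop patterns and degrades gracefully as photons
are removed and the beamstop widened.

Default desk-scale schedule: 2000 HIO / SW every 100 / 200 ER / 50
repeats (about 1.5 s per repeat at 128²). The full-scale protocol
(10000 HIO, 1000 ER, 1000 repeats) is a config choice away and changes
nothing structurally.

## Alignment and reference selection

Maps are registered by integer circular shifts only: density centroid
matching first, then phase-only correlation (POC — argmax of the inverse
transform of the unit-normalised cross-power spectrum). The π-rotation
ambiguity is resolved by comparing the POC peak of a map against that of
its point reflection (exact ties → not rotated). Reference selection is
two-pass: centroid-align everything to an arbitrary member and score all
M(M−1)/2 pairs; the lowest-scoring pair is the most probable pair and
its lower-index member becomes the reference; then POC-align every map
(with π-rotation correction) to the reference and re-score against it.
Either member of the best pair gives nearly the same scores, and the
tests assert the median relative change is below 5%.

## Classification

K-means (k = 10 by default, k-means++ seeding, 10 restarts, best inertia
kept) runs on the flattened aligned maps — deliberately without any
score feature, so the grouping and the score are independent pieces of
evidence. PCA coordinates are for display and landscape construction
only; because clustering precedes the dimensionality reduction, classes
separated along PC3+ can overlap in the PC1–PC2 plane. Maps are not
intensity-normalised before clustering (retrieved maps share |F_obs|, so
their overall scale is already common); a caller can normalise upstream
if desired.

## What the simulator does and does not emulate

Emulated: oversampled Fraunhofer intensities `∝ |F|²`, expected total
photon count as the single SNR knob, Poisson statistics, a square
beamstop shadow spanning a chosen number of pixels, panel-gap stripes,
Friedel-pair averaging (which provably halves the variance on
doubly-valid pairs and restores gap-masked pixels from their mates).

Not emulated: background scattering from membranes (assumed subtracted
upstream), detector physics (gain maps, charge sharing), partial
coherence, and per-pulse fluence fluctuations. Passing tests therefore
demonstrate the *screening logic* — that consistent retrievals score low
and inconsistent ones high, with the expected resolution-resolved phase
behaviour — on clean, well-calibrated patterns; they do not certify
performance against uncorrected experimental backgrounds.

Phantom defaults (10 disks of radius 5 px, density 1, support fraction
0.4 on a 128² grid) are chosen so that a non-overlapping cluster
actually packs into the support box while keeping the oversampling
condition. Urchin phantoms add 12 tapering radial spikes of length
0.5·r to each disk, purely to give fine structure that splits classes.

## Study conditions used by the end-to-end tests

The screening property is exercised at desk scale on 128² grids with 50
retrieval repeats: a high-SNR condition (10⁸ photons, beamstop
half-width 2 px, partially covering the ~3 px central speckle) and a
degraded condition (10⁶ photons, half-width 9 px ≈ 3 speckles). The
first yields a class of sub-0.2 scores whose average reproduces the
phantom; the second yields strictly fewer sub-0.2 maps — the qualitative
success-rate ordering of easy versus hard experimental patterns. The
constructed effective-resolution check uses 512² grids with 16 shells so
that outer shells hold ~10⁴ samples and the shell mean of |cos(Δα/2)|
estimates its limit to ~0.003.

## Numerical notes

- Degenerate inputs are rejected with messages naming the offence
  (non-square grid, non-finite pixel, zero total density, empty support,
  zero score denominator); an empty shrink-wrap support retains the
  previous support instead of aborting the run.
- Zero-amplitude pixels in the magnitude projection are assigned phase 0.
- Empty shells are reported as NaN ("absent"), never as 0.
- Per-repeat retrieval failures (NaN in an update) are recorded and
  skipped, not fatal to the ensemble.
- All stochastic stages (phantom placement, Poisson draws, retrieval
  starts, K-means) take explicit seeds; repeat r of a retrieval campaign
  uses `seed + r`, making ensembles bitwise reproducible.

## Known limitations

- Integer-pixel registration only; at sub-pixel misalignments the score
  acquires a small positive floor (irrelevant at the resolutions the
  score is used for, but visible on noiseless duplicates).
- The screening assumption — that realistic maps recur and resemble each
  other — can break when failed retrievals happen to agree; the score is
  a necessary, not sufficient, condition and class averages should still
  be inspected.
- 2D projections only; no 3D reconstruction, no ptychographic complex
  transmission functions, no alternative projection algorithms (RAAR,
  difference map), no GPU path.
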