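# Methods

## Problem setting

In roots expressing a lacO array at one locus with LacI-EGFP, each
interphase nucleus shows two sub-resolution fluorescent dots, one per
homologous chromosome. The quantities of interest are the 3D physical
distance between the dots (the inter-allelic distance), the fraction of
nuclei in which the dots overlap into one signal (paired loci), the
nuclear volume, and — after γ-irradiation — the dose- and time-dependence
of these quantities together with comet-assay DSB levels. The package
implements the measurement pipeline for these quantities and a synthetic
image generator that emulates their statistical structure, so every
estimator is validated against known ground truth.

## Synthetic nucleus model

A nucleus is an ellipsoid with semi-axes (z, y, x) in μm and a concentric
spherical nucleolus; the two loci are placed uniformly at random in the
nucleoplasm (inside the ellipsoid, outside the nucleolus) subject to a
prescribed separation. Placement is rejection sampling: the first point
uniform in the nucleoplasm, the second at the requested distance in a
uniform random direction, accepted when it also lands in the nucleoplasm.
If a requested separation cannot be placed (it may exceed the largest
nucleoplasm chord), a fresh size jitter is drawn a bounded number of times
before a `SeparationInfeasibleError` is raised.

Defaults, chosen to represent the two root zones:

| parameter | meristematic | elongation | note |
|---|---|---|---|
| semi-axes (μm) | 2.3, 2.3, 2.3 | 2.9, 3.7, 4.6 | elongation ≈ 4× volume (endoreplication) |
| nucleolus radius (μm) | 1.17 | 1.8 | matches the shell-null geometry |
| separation mean ± SD (μm) | 3.5 ± 1.0 | 4.5 ± 1.2 | truncated normal, lower bound 0 |
| focus amplitude (photons) | 2000 | 2000 | integrated per focus |
| background (photons/voxel) | 10 | 10 | |
| PSF σ lateral / axial (μm) | 0.125 / 0.3 | same | typical high-NA confocal at EGFP wavelengths |
| voxel (z, y, x) (μm) | 0.5, 0.1, 0.1 | same | 0.5-μm z-steps; lateral chosen as typical spinning-disk sampling |

The nucleus radius of 2.3 μm and nucleolus radius of 1.17 μm are the
shell-null radii (below); the meristematic separation of 3.5 μm is the
reported scale of the measurement this pipeline replaces. Lateral pixel
size, PSF and signal levels are conventional choices (none are published
for the original acquisition); defaults give a focus peak SNR of roughly
10 under Poisson shot noise plus Gaussian read noise (σ = 2).

A per-nucleus lognormal size jitter (σ = 0.12) rescales all nuclear
lengths and scales the separation mean with nuclear size. This one knob
produces the positive distance–volume relationship observed across growing
nuclei; within the default meristematic population it yields a Pearson r
of roughly 0.4–0.7 depending on sample, bracketing the reported value.

Two truncations act on the separation law. The normal is truncated at
zero, and geometry truncates it above: no separation can exceed the
nucleoplasm chord (4.6 μm in the default meristematic sphere). The
requested mean/SD are therefore the *pre-truncation* parameters; they are
recovered empirically only for geometries that do not clip the law, which
is how the distribution test is set up.

Foci are rendered as separable anisotropic Gaussians sampled at voxel
centres and scaled by the voxel volume, so the voxel sum of one focus
equals its integrated amplitude to better than 1% (midpoint-rule error at
σ_z/Δz = 0.6 is ~10⁻³). Physical positions are voxel-centre coordinates,
`position = index × voxel_size`. The rendered stack is reproducible
bit-for-bit from its seed; panels derive per-nucleus substreams from a
single `SeedSequence`, so element i of a panel is independent of the other
elements' settings — in particular the volume draw at index i is identical
across dose groups, which encodes exactly the "irradiation does not change
nuclear volume" assumption.

### Dose response

The mean separation under dose D (Gy) at time t (h) after irradiation is

    mean(D, t) = baseline − amplitude · (1 − exp(−D/D₅₀)) · exp(−t/τ)

with defaults baseline 3.5 μm, amplitude 1.2 μm, D₅₀ = 50 Gy, τ = 5 h.
The observations being emulated are monotone shortening with dose and
recovery to baseline by 24 h; the saturating-exponential form itself is a
modelling choice (the residual shortening at 24 h is ~0.01 μm, well inside
any measurement noise). A dose-dependent fraction of nuclei undergoes full
pairing (one merged dot), rising from a 2% baseline by up to 20 percentage
points on the same saturation curve. "Repair-deficient" genotypes are pure
generator switches — shortening amplitude and pairing boost set to zero —
and carry no molecular claim.

### Comet images

A comet is a hard-edged head disc (centrally peaked profile) plus a tail
strip along +x between the head edge and the tail endpoint, with an
exponential axial decay and Gaussian lateral profile. The requested tail
fraction of the total signal is placed in the tail *exactly* before noise,
so pixel sums against the truth masks are an exact oracle. Tail length is
defined from the head centre. In study panels, per-comet tail fractions
are Beta-distributed around the group mean (concentration 4), reflecting
the large cell-to-cell dispersion of real comet assays; without this
dispersion a 3-point difference in group means would be declared
significant at n = 20, which no real comet experiment would support.

## Focus detection and distance measurement

Candidates come from a negative Laplacian-of-Gaussian filter whose
per-axis sigma is the expected physical spot size divided by the voxel
size — equivalent to filtering the physically rescaled volume without
interpolation. The detection threshold is `min_snr` (default 5) robust
standard deviations (1.4826·MAD) above the median LoG response; for
noise-free images, where the MAD vanishes on the flat background, the
threshold falls back to 10% of the response range, so a constant image
still yields nothing. Local maxima are de-duplicated with an anisotropic
minimum separation of 2σ per axis and refined by least-squares fitting of
an isotropic-in-voxel-units Gaussian with free amplitude, background and
position (sigmas fixed at the expected spot size); if the fit fails or
leaves the window, an intensity-weighted centroid over a 5-voxel window is
used instead. Localization errors on noiseless defaults are ~2 nm lateral;
with default noise the measured distance over 100 nuclei at a true 3.5-μm
separation recovers the truth within 0.01 μm (SD ~0.1 μm per nucleus).

The top two candidates by score define the locus pair. One detection is
interpreted as a fully merged pair (distance 0, paired); more than two
candidates are flagged via `n_candidates` but only the top two are used,
since the tagged line carries one insertion per homolog and extra dots
indicate noise or replicated sisters. The pairing threshold of 0.4 μm is
roughly the separation below which two EGFP dots merge visually
(~2–3 lateral PSF sigmas); it is configurable and recorded in every
output. Distance summaries exclude paired nuclei (they enter the pairing
frequency instead), so every measurable nucleus contributes to exactly one
statistic. Time series are measured frame-independently: the distance is
symmetric in the two foci and invariant to nuclear translation, so no
registration or identity tracking is needed; frames with no measurable
pair are reported missing, never interpolated.

## Nucleus segmentation and volumetry

The chromatin channel is Gaussian-smoothed (0.2 μm), thresholded by Otsu's
method, hole-filled, and reduced to its largest connected component;
volume is voxel count × voxel volume. Degenerate inputs (constant images,
pure noise with no separable foreground) raise a segmentation error; the
foreground must clear the background by 3 background SDs. Masks leaning on
the stack border (more than 2% of mask voxels) are flagged clipped and
excluded from volume statistics. Voxel counting carries a
resolution-dependent bias: ~3% at 1.0 × 0.4 × 0.4 μm voxels, ~0.8% at the
default 0.5 × 0.1 × 0.1 μm, converging as the voxel shrinks (no
marching-cubes correction is applied). Distance–volume association uses
Pearson correlation; group comparisons use Welch's t-test by default with
Mann–Whitney behind a flag. Two identical constant groups are reported
with p = 1 by convention.

## The nucleoplasm-shell null

The null model draws point pairs independently and uniformly from the
shell r′ < r_x ≤ r (nucleus radius r, nucleolus radius r′). Radii use the
inverse CDF of the volume-uniform law, `r_x = (r′³ + u(r³ − r′³))^(1/3)`,
directions are normalised Gaussian triplets; the sampler is exact and
branch-free, and a cube-rejection sampler serves as an independent oracle
in the tests. Note the geometric constraint itself forces the nucleolus to
be the smaller radius; the constructor rejects r′ ≥ r with a message to
that effect, guarding against sources that print the two radii swapped.
Defaults: r = 2.3 μm, r′ = 1.17 μm, 10⁶ pairs. Closed-form anchors: mean
pairwise distance 36r/35 in the full ball (r′ = 0) and 4r/3 in the
surface limit (r′ → r); the default shell gives a mean of ≈ 2.50 μm,
below the measured 3.5-μm scale.

`compare_to_null` tests whether measured distances exceed the null by
resampling: draw |measured| distances from the simulated null, record how
often the resampled mean is at least the observed mean, and report
`(1 + hits)/(n_resamples + 1)`. This matches the model-vs-data design
without distributional assumptions; a one-sided Welch t-test against the
null sample is available by flag. Both sample sizes (measured nuclei,
simulated pairs) are reported explicitly since they play different roles.

## Grouped statistics and the study runner

`grouped_distance_test` compares each group against a designated control
(Welch or Mann–Whitney, two-sided), applies Holm correction across the
comparisons (raw p-values are also reported), and assigns significance
stars at 0.05/0.01 on the corrected values. `run_study` executes the whole
design from one seed: zone comparison (30 nuclei/zone), distance–volume
correlation on the pooled zones, measured-vs-null, a 4-dose panel
(25 nuclei/dose) with volume invariance, 24-h recovery (25 nuclei), a
genotype × irradiation panel (5 roots × 30 nuclei per cell, the root as
replication unit), and a 3-group comet time course (20 comets/group) —
about 800 rendered nuclei, ≈45 s on one CPU. These sizes mirror the
reported group sizes of the original design at desk scale. The report is a
plain JSON-serialisable dict embedding the resolved configuration and
seed; identical configuration gives byte-identical reports.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the analysis assumes:
two PSF-blurred dots with Poisson/read noise, nucleoplasm geometry,
size-linked separations, dose-dependent shortening with recovery,
dose-invariant volumes, and comet tails with controlled DNA fractions.
Passing tests therefore demonstrate estimator correctness and calibration
(unbiased distance recovery, volume accuracy, null-model exactness,
type-I error control), not biological validity on real data. Not emulated:
optical aberrations and depth-dependent PSF changes, photobleaching,
autofluorescent background structure, chromocenters or any intranuclear
texture, multiple nuclei per field, mitotic figures, off-centre or
non-spherical nucleoli, and comet overlap or atypical morphologies. Real
stacks in the supported layout can be fed to the same measurement CLI, but
thresholds (detection SNR, pairing distance, comet background window)
should be re-examined on real noise before trusting absolute numbers.

## Numerical and design notes

- All physical quantities are μm; arrays are (channel, z, y, x); voxel
  indices are 0-based and positions are voxel centres.
- Sample SD (ddof = 1) throughout; SD of a single value is reported as 0.
- Welch rather than Student throughout: group variances are not assumed
  equal, and the original analyses name no test.
- The comet migration axis is +x by convention; real images must be
  rotated accordingly before measurement.
- Comet tail length is measured along the migration axis; with noisy
  images the above-threshold extent underestimates the true tail end where
  the exponential tail sinks below the detection threshold.
- The resampling p-value lower bound is 1/(n_resamples + 1); defaults use
  9999 resamples.
- Known limitations: single nucleus per stack; spherical nucleolus
  concentric with the nucleus; no ellipsoidal shell null (the spherical
  geometry is an explicit extension point); volume by voxel counting
  without surface correction; pairing threshold is optical, not molecular.
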