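# locipair

Quantitative analysis of the 3D distance between homologous tagged loci
("inter-allelic distance") in plant root nuclei, built around live-cell
imaging with the lacO/LacI-EGFP system. Each interphase nucleus shows two
diffraction-limited EGFP dots, one per homolog; the package detects and
localizes them with subvoxel precision, measures their physical separation,
classifies overlapping ("paired") loci, segments nuclei for volumetry,
compares observed distances with a Monte Carlo random-placement null, and
quantifies DNA double-strand-break (DSB) load from neutral comet-assay
images. A synthetic-data module generates image stacks with known ground
truth for every analysis, so the whole pipeline is testable without
microscope data.

It is intended for plant cell biologists and image analysts studying
chromatin arrangement and the DSB response (γ-irradiation or radiomimetic
treatment) in *Arabidopsis thaliana* roots, and for anyone needing a
transparent, scriptable replacement for closed ImageJ plugins in this kind
of two-dot distance assay.

## The core quantities

**Inter-allelic distance.** Foci are detected by a scale-matched
Laplacian-of-Gaussian filter with per-axis sigmas in voxel units (so
anisotropic sampling, e.g. 0.1 × 0.1 × 0.5 μm voxels, needs no resampling)
and refined by least-squares Gaussian fitting. For the top two foci at
positions **x**₁, **x**₂ (μm), the distance is d = ‖**x**₁ − **x**₂‖.
Pairs with d below a threshold (default 0.4 μm) are scored as *paired*
(overlapping) loci; a nucleus showing a single merged dot is scored paired
with d = 0. Paired nuclei are excluded from distance statistics and
counted separately as a pairing frequency, with the root as the
replication unit.

**Random-placement null.** Under the null hypothesis that the two loci sit
at independent uniform positions in the nucleoplasm — a spherical shell
between the nucleolus (radius r′) and the nuclear envelope (radius r),
i.e. r′ < r_x ≤ r — the distance distribution is sampled by Monte Carlo:
directions uniform on the sphere, radii from the inverse CDF of the
volume-uniform (r³) law restricted to (r′³, r³]. Closed forms anchor the
sampler: the full-ball mean pairwise distance is 36r/35 and the thin-shell
limit is 4r/3. Measured distances are tested against the null by
resampling the null at the measured sample size. Defaults r = 2.3 μm,
r′ = 1.17 μm (the nucleolus must be the smaller sphere for the shell
constraint to be satisfiable).

**Comet metrics.** For a neutral comet image with the tail along +x:
tail DNA % = 100 · I_tail / (I_head + I_tail); tail length = distance from
the head centre to the farthest above-threshold tail column; Olive tail
moment = tail DNA % × head-to-tail centroid separation.

## Worked example

```python
import numpy as np
from locipair import (
    meristematic_model, generate_nucleus_stack, detect_foci, measure_pair,
    segment_nucleus, ShellGeometry, simulate_null, compare_to_null,
)

# one synthetic meristematic-zone nucleus, two tagged loci
model = meristematic_model()
stack, truth = generate_nucleus_stack(model, seed=42)
pair = measure_pair(detect_foci(stack))
print(f"truth separation: {truth.separation_um:.3f} um")
print(f"measured distance: {pair.distance_um:.3f} um (paired: {pair.paired})")

mask, meas = segment_nucleus(stack)
print(f"nucleus volume: {meas.volume_um3:.1f} um^3 (truth {truth.volume_um3:.1f})")

# random-placement null in the nucleoplasm shell
null = simulate_null(ShellGeometry(r=2.3, r_prime=1.17), 1_000_000, seed=1)
print(f"null mean: {null.mean:.3f} um (sd {null.sd:.3f})")

report = compare_to_null(np.random.default_rng(0).normal(3.5, 0.9, 105),
                         ShellGeometry(2.3, 1.17), seed=1)
print(f"measured mean {report['measured_mean_um']:.3f} vs "
      f"null {report['null_mean_um']:.3f}, p = {report['p_value']:.4g}")
```

Output:

```
truth separation: 2.590 um
measured distance: 2.586 um (paired: False)
nucleus volume: 57.2 um^3 (truth 56.9)
null mean: 2.502 um (sd 0.896)
measured mean 3.579 vs null 2.502, p = 0.0001
```

The measured distance tracks the generator's truth to a few nanometres;
the segmented volume is within ~1% of the analytic ellipsoid volume; and a
sample of distances around 3.5 μm is significantly longer than the
random-placement null mean of ~2.5 μm — random positioning in the
nucleoplasm cannot explain separations of that size.

## Command line

```bash
locipair simulate nuclei --n 20 --out sim/ --seed 1
locipair measure --manifest sim/manifest.csv --threshold-um 0.4 --out measured.csv
locipair morphometry --manifest sim/manifest.csv --out volumes.csv
locipair null --r-um 2.3 --rprime-um 1.17 --n 1000000 --seed 1 --out null.csv
locipair compare --measured measured.csv --seed 1 --out comparison.json
locipair simulate comets --n 10 --tail-fraction 0.4 --out comets/ --seed 1
locipair comet --manifest comets/manifest.csv --out comet_metrics.csv
locipair run --out report/ --seed 1        # the full seeded study
```

`locipair run` executes every stage on generated data and writes a report
with the study-level comparisons: elongation-zone vs meristematic-zone
distances, the distance–volume correlation, measured vs null, the γ-ray
dose response with volume invariance and 24-h recovery, the genotype
comparison (repair-proficient vs repair-deficient generator settings) with
pairing frequencies, and the comet time course.

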