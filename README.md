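# tomolink

Quantitative analysis of short pleomorphic linkers — **tethers** (vesicle to
plasma membrane), **connectors** (vesicle to vesicle) and **protrusions**
(membrane-attached, one contact) — in cryo-electron tomograms of neuronal
boutons, together with the vesicle and membrane morphometrics and the count
statistics that accompany such studies.

It is written for structural cell biologists who have a reconstructed,
denoised tomogram (MRC) plus manually segmented *boundaries* (vesicles, plasma
membrane, microtubules, SER) and want reproducible, scriptable measurements:
per-vesicle linker counts and lengths, vesicle occupancy as a function of
distance to the plasma membrane, radial density traces with dense-core /
halo / light lumen classification, distances to microtubules, microtubule
curvature, and the associated hypothesis tests. Because real tomograms are
rarely shareable, the package ships a phantom generator that produces
density/label volumes with exact ground truth, so every stage is testable
end to end.

## The methods at the core

**Hierarchical connectivity segmentation.** Density is signed so that *lower
values are denser*. Given a set of thresholds t_1 < t_2 < … < t_n (by default
25 levels spanning [mu_cyto − 3 sigma_cyto, mu_cyto] of the cytoplasmic
density), the detector forms 6-connected components of sub-threshold,
unlabeled voxels at each level, starting from the densest. A component is
accepted as a linker at the *densest* level at which it touches exactly two
distinct boundaries (6-neighborhood contact); laxer-level supersets of an
accepted segment are skipped, so each linker is reported once, in its
strongest-density form. Two vesicle contacts make a connector; exactly one
plasma-membrane contact makes a tether; three or more contacts at every level
make a "multi" segment. Protrusions are segmented at a single threshold (the
mean density of the vesicle membranes) so their counts are comparable across
vesicles. Segments smaller than 3 voxels or larger than 320 nm³ are
reclassified as rejected (never silently dropped).

**Length modes.** B2C (membrane edge to edge: minimum distance between the
two contact regions, measured between voxel faces) and C2C (contact-centroid
to contact-centroid) for 2-bound segments; B-max (largest distance from a
segment voxel to its contact region) for protrusions.

**Zero-truncated Poisson (ZTP) null for per-bouton counts.** For counts
k ≥ 1,

    P(k) = λ^k / ((e^λ − 1) k!),   with mean  m = λ / (1 − e^{−λ}),

λ recovered from the observed mean by Brent root finding. Observed counts are
pooled into bins {1}…{5}, {6–8}, {>8} and compared with the binned ZTP mass by
the G-test, G = 2 Σ f_i ln(f_i / f̂_i), against χ² with (bins − 1) degrees of
freedom.

**Summary-statistic tests.** Pooled two-sample t-test directly from
(mean, sd, n) pairs (Welch behind a flag), the uncorrected 2×2 chi-square
χ² = N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)), and Pearson correlation.

**Curvature.** Microtubule polylines are resampled to equal spacing d
(default 0.5 µm); curvature is the inverse circumradius κ = 1/R of each
consecutive point triple, reported as the per-polyline maximum, with the
chord-angle conversion 2 arcsin(κd/2)/d to compare against studies that
report turning angle per unit length.

## Worked example

Generate a noisy phantom bouton, detect its linkers, and measure them:

```python
import tomolink as tl
from tomolink.pipeline import compare_to_truth

spec = tl.PhantomSpec(
    volume_shape=(96, 96, 96), voxel_size_nm=3.2, rng_seed=1,
    vesicles=[tl.VesicleSpec(kind="sv", diameter_nm=40, count=12)],
    plasma_membrane=tl.MembraneSpec(),
    connectors=tl.LinkerSpec(fraction_of_vesicles_connected=0.5),
    tethers=tl.LinkerSpec(fraction_of_vesicles_connected=0.25,
                          length_mean_nm=19.8, length_sd_nm=11.7),
    noise_sd=1.0,
)
density, labels, truth = tl.generate_phantom(spec)

smoothed = tl.smooth_stand_in(density, 1.6)          # light low-pass
schedule = tl.make_schedule(smoothed, labels, n_levels=25)
segments = tl.hierarchical_segment(smoothed, labels, schedule)
segments = tl.filter_segments(segments, density.voxel_size_nm)
segments = tl.measure_segments(segments, labels, density.voxel_size_nm)

match = compare_to_truth(segments, truth)
print(f"recall {match['recall']:.2f}, "
      f"mean |B2C - true gap| {match['mean_abs_length_error_nm']:.1f} nm")

r = tl.t_test_from_summary(23.0, 8.5, 15, 15.0, 9.0, 207)
print(f"connector-length t-test: t = {r.t:.2f}, df = {r.df:.0f}, p = {r.p_value:.4f}")
```

This prints:

```
recall 0.83, mean |B2C - true gap| 0.9 nm
connector-length t-test: t = 3.34, df = 220, p = 0.0010
```

Five of the six planted linkers are recovered from the noisy volume
(signal-to-noise 2:1 on the membranes) and their membrane edge-to-edge
lengths are within a fraction of a voxel of the planted gaps. The t-test
compares two linker-length populations given only their printed summaries —
here it shows that 23.0 ± 8.5 nm (n = 15) is significantly longer than
15.0 ± 9.0 nm (n = 207).

A command-line interface mirrors the library (`tomolink phantom`, `detect`,
`morpho`, `stats`, `run`, `compare`); `tomolink run --config run.yaml` executes
the whole pipeline from a YAML config and writes a versioned JSON report plus
CSV tables.

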