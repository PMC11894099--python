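# nucleodyn

Quantification of nuclear plasticity of migrating immune cells in
time-lapse fluorescence microscopy.

Leukocytes navigating living tissue squeeze through spaces narrower than
their own nucleus — most dramatically inside vessel-like channels and
during transmigration across vessel walls. `nucleodyn` implements the full
measurement chain needed to quantify this behaviour from 4D (t, z, y, x)
movies of fluorescently labelled nuclei:

1. **Segmentation** — a trainable filter-bank pixel classifier produces a
   per-voxel nuclear probability map; thresholding and 26-connected
   component labelling yield 3D nuclei per frame.
2. **Tracking** — greedy nearest-neighbour linking with gap closing;
   tracks with fewer than 4 timepoints, or mostly outside the vessel
   region, are excluded.
3. **Shape** — from each nucleus's 2D maximum projection, the central
   second moments give the equivalent-ellipse semi-axes *a* ≥ *b* and the
   **Shape Factor**

   SF = (a − b) / (a + b),

   0 for a round nucleus and → 1 for an elongated one; plus area,
   Crofton circularity and rotating-calipers min/max Feret diameters.
4. **Dynamics** — a nucleus is "squeezing" in any frame with SF ≥ 0.4;
   maximal runs of squeezing frames are events with count and duration;
   per-track summaries include mean/max SF, squeezing proportion, speed,
   and 15-min standardised path length, Euclidean distance and
   persistence; Spearman/Pearson correlation matrices and 17 px (≈ 5 μm)
   spatial mean-SF heatmaps.
5. **Intensity** — nuclear-lamina rim intensities from line profiles with
   same-z background subtraction, normalization to the epithelial average
   of the same age group, relative A-type/B-type Lamin stoichiometry from
   age-normalised medians, 3D nuclear means with negative-control
   correction, phagosome counts and nuclear-instability rates.
6. **Vessel** — wall-to-wall diameter from paired intensity peaks with
   subpixel refinement, measured before/during/after nuclear transit;
   relative dilation `D_during / D_pre` and residual space
   `D_during − D_nucleus`.

Because no primary imaging data accompany the study this pipeline
re-implements, the package ships a first-class synthetic generator
(`nucleodyn.synth`) producing seeded movies and fixtures with exact ground
truth: nuclei as uniform ellipsoids whose elongation follows a two-state
Markov chain (stationary squeezing occupancy `p_enter/(p_enter+p_exit)`,
mean event length `1/p_exit` frames), lamina-rim fixtures with a known
hemocyte:epithelial intensity ratio, and two-channel vessel-transit movies
with a known dilation factor.

## Worked example

```python
from nucleodyn.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, regime="vessel", n_nuclei=3, n_frames=40)
res = run_pipeline(cfg, "out")
summ = res["summaries"]
print(summ[["track_id", "mean_sf", "squeeze_proportion",
            "n_events", "mean_event_duration_min"]].round(3))
```

prints (seed 1):

```
   track_id  mean_sf  squeeze_proportion  n_events  mean_event_duration_min
0         0    0.361               0.600         7                    1.714
1         1    0.322               0.475         8                    1.188
2         2    0.327               0.500         5                    2.000
```

Three nuclei were simulated in a 6 μm vessel channel, segmented, tracked
over 40 frames (30 s interval), and summarised: each spent roughly half
its track squeezing (SF ≥ 0.4) in 5–8 events of 1–2 min — consistent with
the generating Markov regime (stationary occupancy 0.5, mean event
100 s).  The output directory holds `tracks.csv` (the per-frame table),
`summaries.csv`, heatmap TIFFs, labels, the run log and a `config.yaml`
snapshot that reproduces the run byte-for-byte.

The same stages are available from the shell:

```sh
nucleodyn simulate --regime vessel --n-nuclei 3 --seed 1 --out movie.tif
nucleodyn run --seed 1 --regime vessel --out out/
nucleodyn summarize --tracks out/tracks.csv --threshold 0.4 --out summ.csv
```

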