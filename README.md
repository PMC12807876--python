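# nemquant

Quantitative image analysis of inner-nuclear-membrane (INM) tension
sensing from confocal fluorescence microscopy.

When a cell nucleus swells — osmotic shock, colloid dilution, or the
prelytic phase of ferroptosis — tension in the inner nuclear membrane
rises and creates lipid-packing defects. Amphipathic sensors
(cPLA₂-C2-type domains, ARFGAP1-ALPS "ALPIN" biosensors) adsorb to these
defects, so the ratio of sensor fluorescence on the nuclear rim to the
nucleoplasm is a live proxy for INM tension. The ER buffers that tension
by feeding membrane into the nuclear envelope; Ca²⁺-driven ER
vesiculation severs the connection. `nemquant` implements the full
measurement stack around this biology:

- **Nuclei** (`nemquant.nuclei`): 3-D masked-object thresholding +
  marker-controlled watershed segmentation of the nuclear envelope,
  greedy mutual-nearest-neighbour tracking, nuclear volume *V*, and the
  ratiometric adsorption signal
  *S* = median(sensor on a 3-px membrane contour at the mid-slice) /
  median(sensor on a 3-px nucleoplasmic background ring), plus the
  Lmnb1-normalized alternative and the published QC exclusions
  (mid-slice area < 8,000 px², border contact, > 130 px frame jumps,
  broken tracks).
- **Envelope folds** (`nemquant.folds`): shrivelling quantified as the
  number of condensed branch points on a skeletonized ridge-filtered
  (thickness 1.6 ≈ 3–4 px) outline of the mid-slice envelope.
- **ER morphology** (`nemquant.er`): luminal (watershed) or membrane
  (filament-filter) segmentation; per-object area and circularity
  Cir = 4π·A/P² on the representative mid-section with the Crofton
  perimeter estimator; per-FOV summaries (largest object area, mean
  circularity) and baseline/control normalization.
- **GUV binding** (`nemquant.guv`): rim-median protein binding on giant
  unilamellar vesicle midplanes and bounded nonlinear least-squares fits
  of the Hill-expanded Langmuir isotherm
  *B*(c) = *B*<sub>max</sub>·c<sup>H</sup>/(c<sup>H</sup> + K′<sub>d</sub><sup>H</sup>).
- **FLIP** (`nemquant.flip`): fluorescence-loss-in-photobleaching ROI
  traces (bleach site, median axis, opposite site, nuclear mask,
  neighbouring-cell control) scoring ER–NE diffusional connectivity.
- **Statistics** (`nemquant.stats`): the gated decision tree
  (Shapiro–Wilk → Levene → Student/Welch/Mann–Whitney;
  Welch-ANOVA + Games–Howell / Kruskal–Wallis + Dunn), pooled OLS
  adsorption rates over the linear t = 4–5 min window with
  Breusch–Pagan/Shapiro–Wilk diagnostics and HC3 fallback, Pearson fits,
  and the named normalization schemes.
- **Synthetic scenes** (`nemquant.synth`): generators with exact ground
  truth for every assay — ellipsoidal nuclei with adjustable rim
  enrichment, fold spurs, motion/volume/lysis schedules; ER tube
  networks that vesiculate; GUV titrations; two-pool FLIP dynamics —
  so each stage has a recovery oracle.

## Worked example

Measure sensor adsorption on a swelling synthetic nucleus whose true rim
enrichment is ρ = 2:

```python
from nemquant.synth import NucleusSpec, SynthScene, NoiseSpec, synth_nucleus_timelapse
from nemquant.nuclei import preprocess, segment_nuclei, track_nuclei, measure_nucleus

scene = SynthScene(
    fov_shape=(24, 96, 96), n_frames=3, seed=0,
    nuclei=[NucleusSpec(centre=(12, 48, 48), semi_axes=(9, 22, 22),
                        rim_enrichment=2.0, volume_scale=[1.0, 1.15, 1.3])],
    noise=NoiseSpec())
stack, truth = synth_nucleus_timelapse(scene)

labels = segment_nuclei(preprocess(stack, "ne_marker"))
track = track_nuclei(labels)[0]
measure_nucleus(stack, labels, track)
for frame, v, s in zip(track.frames, track.volume_um3, track.s_ratio):
    print(f"frame {frame}: V = {v:7.0f} um^3   S = {s:.2f}")
```

```
frame 0: V =   18764 um^3   S = 1.91
frame 1: V =   21740 um^3   S = 1.88
frame 2: V =   24583 um^3   S = 1.85
```

The nucleus swells by the prescribed 15% per frame and the measured
rim-to-centre ratio *S* tracks the true enrichment of 2 to within a few
percent; in a real hypo-osmotic time lapse a rising *S* reports sensor
adsorption to the stretched INM.

The same stages are exposed as a CLI
(`nemquant synth|nuclei|folds|er|guv|flip|stats`), e.g.

```bash
nemquant guv --preset c2-ca20 --seed 3 --out fit.json
# -> K_d' = 21.6 nM (converged=True)
```

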