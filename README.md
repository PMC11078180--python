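# mobflim

Label-free metabolic profiling of single living cells from phasor FLIM.

Fluorescence-lifetime imaging (FLIM) of the autofluorescent coenzymes
NAD(P)H and FAD reports on cellular metabolism without any staining: the
lifetime of NAD(P)H differs between its free and enzyme-bound states, and
the FAD/NAD(P)H intensity ratio (optical redox ratio, ORR) tracks
oxidative metabolism. `mobflim` implements a full pipeline that turns
such acquisitions into per-cell **metabolic optical biomarkers (MOBs)**
and a scalar **MOB score** of metabolic stemness, aimed at stem-cell
biologists tracking differentiation and division patterns (e.g. in
hematopoietic stem cells) in live-cell, low-photon-budget imaging.

## What it computes

1. **Phasor decomposition** (`mobflim.phasor`). Per-pixel decays are
   Fourier-transformed to phasor coordinates

   `g = Σ I(t)cos(ωt) / Σ I(t)`, `s = Σ I(t)sin(ωt) / Σ I(t)`,

   median-filtered (3×3), and decomposed geometrically on the universal
   semicircle `(g−½)² + s² = ¼`: fixing the free-NAD(P)H anchor at
   τ_free = 0.45 ns, the line from the anchor through a pixel re-intersects
   the semicircle at the pure bound species, giving the bound lifetime
   τ_bound = s/(ωg) and the bound fraction α_bound as the distance ratio
   along the chord. This is fit-free and works at the ~20–30
   photons/pixel of gentle live-cell imaging. ORR is computed in the
   mitochondrial region and corrected by subtracting the
   cytoplasmic/nuclear ratio, which cancels constant NAD(P)H spectral
   bleed-through into the FAD channel.
2. **Segmentation** (`mobflim.segmentation`). Photon-count thresholding
   of NAD(P)H intensity, watershed splitting on the distance transform,
   size exclusion, and a per-cell Otsu split of FAD intensity into
   mitochondrial vs cytoplasmic/nuclear subregions.
3. **Feature library** (`mobflim.features`). A declarative registry of
   210 per-cell features: signal strength, distribution, and GLCM/GLRLM
   spatial texture of each MOB channel per subregion, mito↔cyto
   compartmentalization `(m−c)/(m+c)`, and morphology.
4. **Feature selection** (`mobflim.selection`). Per-feature logistic F1
   gate (> 0.6) and trending index
   `TI = Σ Δmean / Σ |Δmean|` (|TI| > 0.5) across differentiation
   stages, required jointly in two independent datasets, then reduced to
   representatives via a knowledge graph of feature subcategories; SVM
   ROC benchmarks any subset.
5. **MOB score** (`mobflim.scoring`). Robust scaling (training median →
   0, quartiles → ±1), density-based outlier removal, equal-n trimming,
   and a 3-dimensional maximum-likelihood factor model whose first
   latent variable is the MOB score; feature weights are the
   correlations between LV1 and each scaled feature. A two-component
   Gaussian mixture over scores yields a stem/differentiated threshold.
6. **Division analysis** (`mobflim.division`). Micropattern-based
   parent/daughter pairing, the sibling score gap ΔMOB, a double-Gaussian
   mixture threshold separating metabolically symmetric from asymmetric
   divisions, parent–daughter inheritance correlations, post-division
   score dynamics, and treatment screens.
7. **Synthetic ground truth** (`mobflim.synthetic`). Poisson photon
   physics over two-exponential decays, disk cells with punctate
   mitochondria, monotone population trends, and division tables with
   controlled inheritance — so every stage is testable without external
   data.

## Worked example

```python
import numpy as np
from mobflim import synthetic as syn, pipeline as pl

spec = syn.SceneSpec(
    image_size=(128, 128),
    cells=[
        syn.CellSpec(center=(40, 40), radius_px=13, true_alpha_bound=0.7,
                     true_tau_bound=3.6, nadph_rate=28, fad_rate=12),
        syn.CellSpec(center=(88, 88), radius_px=13, true_alpha_bound=0.35,
                     true_tau_bound=2.8, nadph_rate=22, fad_rate=14),
    ],
    seed=7)
nadph, fad, truth = syn.simulate_decay_image(spec)
res = pl.process_scene(nadph, fad)
print(res.features[["cell_id", "alpha_bound_mito_average",
                    "tau_bound_mito_average", "orr_corrected",
                    "morph_size"]].round(3).to_string(index=False))
```

prints

```
 cell_id  alpha_bound_mito_average  tau_bound_mito_average  orr_corrected  morph_size
       1                     0.723                   3.618          1.696       17.14
       2                     0.363                   2.699          2.597       17.14
```

Cell 1 was generated with a bound fraction of 0.7 and a bound lifetime of
3.6 ns, cell 2 with 0.35 and 2.8 ns; at ~25 photons/pixel the pipeline
recovers both to a few percent. `orr_corrected` is the
baseline-corrected mitochondrial FAD/NAD(P)H ratio (the 5× mitochondrial
FAD contrast of the generator, minus the cytoplasmic baseline), and
`morph_size` is the cell area in µm² at 0.18 µm pixels.

A command-line interface mirrors the stages:

```
mobflim simulate --seed 7 --out-dir scene/
mobflim run-all --scene-dir scene/ --out-dir out/      # phasor → segment → features
mobflim score --model model.json --features out/features.csv --out scored.csv
mobflim divisions --pairs pairs.csv --out report.json
```

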