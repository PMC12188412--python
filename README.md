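# scembi — single-cell elemental bioimaging

`scembi` quantifies the distribution of a metal drug (platinum, e.g. from
oxaliplatin) in multiplexed LA-ICP-TOFMS tissue images at absolute,
single-cell resolution.  It is written for analytical chemists and imaging
mass cytometry groups who have per-pixel, per-mass-channel count maps of
FFPE tissue plus microdroplet calibration standards, and who want: molar
concentration maps, per-cell drug content in femtograms, a statistically
defined per-cell detection limit, regional concentration strata, and drug
uptake per cellular phenotype.

## The analysis chain

1. **Calibration.** Microdroplet standards of known element mass
   (volume-normalized: m·V_meas/V_nom) are regressed against integrated
   counts by OLS, giving a sensitivity *S* in counts/fg:
   `counts = S·m + b`.
2. **Concentration mapping.** With pixel size *p* (µm) and section
   thickness *t* (µm, default 5), each pixel is a tissue voxel of
   `p²·t·10⁻¹⁵` L and `c [µM] = m_fg / (M·p²·t) · 10⁶` (M = 195.084 g/mol
   for Pt).
3. **Segmentation.** Watershed on the Ir nucleus channel, expanded over the
   CD44 + E-cadherin membrane composite into cell bodies.
4. **Per-cell quantification.** Summed pixel mass, concentration and
   per-channel means per label.
5. **Detection limit.** Control-tissue cells are fit with a compound
   Poisson–gamma background (method of moments on mean, variance and zero
   fraction); `L_D` is the (1−α) Monte-Carlo quantile (α = 0.001 default).
   Cells are drug-positive only when `m > L_D`.
6. **Regional strata.** Exact 1-D k-means (dynamic programming — provably
   optimal WCSS, deterministic) on masked pixel concentrations; cluster
   means in ascending order.  Also used to compare consecutive sections.
7. **Phenotyping.** PhenoGraph-style clustering (kNN + Jaccard weights +
   Leiden) of arcsinh/z-scored marker means, marker-rule naming (CAF,
   proliferating, mitotic, apoptotic/necrotic, epithelial, ...), and
   per-phenotype Pt statistics with `L_D` overlays, plus pixel- and
   cell-level Pearson colocalization.

A first-class synthetic-data module generates tumor images ("parental",
"resistant"), control tissue, an organ preset and droplet arrays with
complete ground truth for every stage; see `docs/methods.md` for the model
and its limits.

## Worked example

Quantify a simulated resistant-layout tumor end to end:

```python
import numpy as np
from scembi import (GeneratorConfig, generate_droplet_array, generate_tumor_image,
                    fit_calibration, counts_to_mass, pixel_concentration, tissue_mask,
                    cell_quantify, fit_background, compute_ld, flag_cells,
                    transform_features, cluster_phenotypes, name_phenotypes,
                    phenotype_pt_stats, segment_cells)
from scembi.quantification import kmeans_region_means

cfg = GeneratorConfig(seed=1, image_size=(800, 800))
model = fit_calibration(generate_droplet_array(cfg), "Pt", force_zero_intercept=True)
print(f"sensitivity: {model.sensitivity:.1f} counts/fg (R^2 = {model.r_squared:.4f})")

image, truth = generate_tumor_image(cfg)
mask = segment_cells(image)
mass, _ = counts_to_mass(image.get("Pt"), model)
cells = cell_quantify(mass, mask, image)

ctrl, _ = generate_tumor_image(GeneratorConfig(seed=2, region_layout="control",
                                               image_size=(800, 800)))
ctrl_cells = cell_quantify(counts_to_mass(ctrl.get("Pt"), model)[0],
                           segment_cells(ctrl), ctrl)
ld = compute_ld(fit_background(ctrl_cells), alpha=0.001, seed=1)
print(f"detection limit: {ld.ld_fg:.3f} fg/cell")
cells = flag_cells(cells, ld)

features, markers = transform_features(cells)
result = name_phenotypes(cluster_phenotypes(features, seed=1, marker_names=markers))
cells["phenotype"] = result.cell_phenotypes()
print(phenotype_pt_stats(cells)[["phenotype", "n", "mean_fg", "frac_above_ld"]]
      .round(3).to_string(index=False))
```

prints

```
sensitivity: 199.9 counts/fg (R^2 = 0.9997)
detection limit: 0.204 fg/cell
             phenotype   n  mean_fg  frac_above_ld
                   CAF 377    0.951          0.979
    apoptotic/necrotic 357    2.687          0.980
            epithelial 261    0.509          0.847
epithelial/mesenchymal 133    0.931          0.925
               mitotic  49    0.408          0.714
         proliferating 272    0.509          0.871
```

The sensitivity recovers the generator's true 200 counts/fg; the detection
limit (~0.2 fg/cell, a far-tail quantile of a background averaging only
0.02 fg/cell) separates real uptake from noise; and the phenotype table
shows the resistant-tumor pattern — stromal fibroblasts (CAF) and
apoptotic/necrotic cells accumulate severalfold more Pt than viable
epithelial and proliferating cells.  (Means from predicted masks include
some peri-cellular matrix signal; quantifying on ground-truth masks
recovers the configured 0.23/0.58/0.82 fg per cell.)

Regional stratification of a pixel-based overview acquisition (2.5 µm):

```python
overview, _ = generate_tumor_image(GeneratorConfig.pixel_based(seed=1))
mass, _ = counts_to_mass(overview.get("Pt"), model)
conc = pixel_concentration(mass, overview.pixel_size, overview.thickness)
regions = kmeans_region_means(conc, tissue_mask(overview), k=3)
for name, mean, n in zip(("parenchyma", "stroma", "necrosis"),
                         regions.means_uM, regions.pixel_counts):
    print(f"{name:11s} {mean:6.1f} uM  ({n} px)")
```

```
parenchyma    13.4 uM  (54469 px)
stroma        33.5 uM  (33363 px)
necrosis      88.2 uM  (28638 px)
```

— the three strata recover the preset's regional means, with the necrotic
core of the resistant layout holding the bulk of the drug.

## Command line

Every stage is a subcommand of `scembi` (see `--help`): `simulate`,
`calibrate`, `segment`, `quantify`, `detection-limit`, `cluster-regions`,
`phenotype`, and `run` (full pipeline from a YAML config, writing per-stage
artifacts and a deterministic `summary.json`).

```sh
scembi simulate --preset resistant --seed 1 --out sim/
scembi calibrate --droplets sim/droplets.csv --zero-intercept --out cal.json
scembi segment --image sim/image.tif --out mask.tif
scembi quantify --image sim/image.tif --cal cal.json --mask mask.tif \
    --out cells.csv --conc conc.tif
```

## Layout

```
src/scembi/
  synthetic.py       # generator: tumor/control/organ images, droplet arrays
  io.py              # TIFF + JSON-sidecar images, masks, CSV cell tables
  calibration.py     # droplet standards -> counts/fg sensitivity
  quantification.py  # concentration maps, per-cell totals, exact 1-D k-means
  segmentation.py    # watershed nuclei + membrane expansion, IoU metrics
  detection.py       # compound Poisson-gamma background, L_D, flagging
  phenotyping.py     # transforms, SNN-Leiden clustering, naming, stats
  pipeline.py, cli.py
```
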