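# Methods

`scembi` implements the quantitative analysis chain for single-cell elemental
bioimaging of a metal drug (platinum, e.g. from oxaliplatin) in multiplexed
LA-ICP-TOFMS tissue maps, together with a synthetic-data generator that
provides study-condition inputs with complete ground truth.  This note
documents the models, the parameters that matter, the numerical choices, and
what the synthetic data does and does not establish about real acquisitions.

## Calibration

Microdroplet standards (nominally 400 ± 10 pL of gelatin-bound multielement
standard) of known element mass are ablated whole; their integrated counts
are regressed on the volume-normalized mass

    m_norm = m_nominal * V_measured / V_nominal,

by ordinary least squares, giving the sensitivity S in counts/fg.  The
regression is unweighted and transparent; inverse-variance weighting is not
applied.  A free intercept is available and absorbs residual background in
the droplet integration, but the pipeline default forces the intercept to
zero for pixel-level conversion: a noisy counts-scale intercept, subtracted
per pixel with clipping at zero, introduces a systematic positive bias of
order `intercept / S` per pixel, which is material for sub-fg per-cell
totals summed over ~100 pixels.  Fits with fewer than three distinct mass
levels or with a non-positive slope are rejected.  Conversion back to mass
is `m = max(0, counts - intercept) / S`, with the number of zero-clipped
pixels reported.

## Concentration mapping

A pixel of edge `p` µm in a section of thickness `t` µm (default 5 µm)
defines a tissue voxel of `p²·t` µm³ = `p²·t·1e-15` L.  Mass per pixel
converts to a molar tissue concentration

    c [µM] = m_fg / (M · p² · t) · 1e6,

with M = 195.084 g/mol for Pt.  The voxel volume is purely geometric; no
tissue-density correction is applied.  Worked example: 0.975 fg distributed
over a 100 µm² footprint at 5 µm thickness (500 µm³ = 5·10⁻¹³ L) gives
10.0 µM.

## Segmentation

Classical watershed, fully deterministic: Gaussian-smooth the Ir
(DNA-intercalator) channel (σ = 1.5 px), Otsu threshold, distance-transform
maxima (minimum separation 5 px) as seeds, watershed on the inverted
distance for nuclei.  Cell bodies are grown from the nuclei by a second
watershed over the membrane composite — the pixel-wise maximum of the
membrane channels (CD44 and E-cadherin), each normalized to its 99.5th
percentile.  Expansion is doubly constrained: at most `expand_px` (default
3 px) beyond any nucleus pixel, and only into membrane-positive area (Otsu
threshold of the smoothed, arcsinh-compressed composite).  The membrane gate
prevents bleeding into unlabeled extracellular space; the 3 px cap reflects
that detected nuclear blobs (~3.5 px radius at 1 µm pixels) plus 3 px match
a ~6 µm cell radius.  Labels outside the area bounds (20–2000 px) are
dropped and the rest relabeled sequentially.  External masks (e.g. from a
learned segmenter) can be substituted anywhere a mask is accepted.

Object-level quality is scored by greedy one-to-one IoU matching
(threshold 0.5) against ground truth, reporting precision, recall, F1 and
mean matched IoU.

## Per-cell quantification

Per label: summed pixel mass (fg), concentration from the cell's own voxel
volume (area · thickness), and mean counts of every channel.  Sums are
exact (integer-weighted bincount); a random-mask fixture is tested against
an explicit per-pixel loop.  Mass is conserved: cell totals never exceed
the grid total, with equality when the mask covers all non-zero pixels.

## Regional stratification — exact 1-D k-means

Pixel concentrations under the tissue mask are partitioned by k-means.
Because the data are one-dimensional, the globally optimal partition is
computed exactly by dynamic programming over sorted unique values with
multiplicity weights (optimal 1-D clusters are contiguous in sorted order).
This replaces restarted Lloyd iterations: the result provably attains the
minimum within-cluster sum of squares, is deterministic, and needs no seed
(the `seed` argument is accepted for interface stability and ignored).
Above 8192 unique values the input is quantile-binned first; counts-derived
concentration grids are far below that in practice.  Clusters are reported
in ascending mean order with pixel counts and a label map.

The tissue mask is Otsu's threshold on the arcsinh of the smoothed
(σ = 2 px) sum of nucleus, membrane and marker channels.  Smoothing plus
arcsinh compression make the threshold separate tissue from glass rather
than bright cells from everything else.

Consecutive-section comparison clusters each map independently, pairs
clusters by rank, and reports |Δmean|/mean_ref per rank (reference: first
section) with a configurable consistency tolerance (default 20 %).

## Detection limit

Control-tissue cells carry a sparse Pt background modeled as a compound
Poisson–gamma law: N ~ Poisson(λ) events per cell, each of
gamma(shape, scale) mass.  The fit is by the method of moments on
(mean, variance, zero fraction):

    λ = −ln P(m = 0),   shape·scale = mean/λ,
    scale = var/(λ·shape·scale) − shape·scale.

If the moments are inconsistent with the model (no zeros, all zeros, or a
non-positive solved scale) the fit falls back to the empirical quantile of
the control sample and records that it did.  The detection limit L_D is the
(1 − α) quantile of the fitted law, evaluated by seeded Monte Carlo
(default 10⁶ draws; a cell with N events needs one gamma(N·shape, scale)
draw).  α defaults to 0.001 and is a first-class knob — the appropriate
false-positive rate is a study decision, and published per-cell thresholds
correspond to far-tail quantiles whose exact rule is rarely stated.  Cells
are flagged Pt-positive by strict inequality `m > L_D`.

## Phenotyping

Per-cell marker means (all channels except the nucleus stain and the drug)
are arcsinh-transformed (cofactor 5, the cytometry convention) and
z-scored.  A kNN graph (k = 15, Euclidean) is reweighted by shared-neighbor
Jaccard overlap and partitioned by Leiden modularity optimization with a
fixed seed; singleton communities merge into the nearest cluster by
centroid distance, and clusters are relabeled by decreasing size.  The
resolution default is 0.3: at resolution 1.0 the kNN-Jaccard graph of a
few hundred cells over-splits even perfectly separated Gaussian blobs
(9 communities where 3 exist), while 0.3 recovers exactly one community
per blob; the parameter stays exposed.  Note that kNN graphs of *any*
continuous point cloud carry strong spatial community structure, so
absolute modularity is not a useful "no structure" diagnostic; cluster
separation (silhouette) is used instead.

Clusters are named by an ordered rule table on the cluster-mean z-profile:
first rule whose required-high markers all exceed +0.5 z and required-low
markers fall below 0 z wins.  Defaults: CAF (vimentin, α-SMA, collagen,
Fe), mitotic (pHH3), proliferating (Ki-67, pS6), apoptotic/necrotic (CD44,
pan-keratin high; vimentin, Ki-67, E-cadherin low), epithelial (E-cadherin,
pan-keratin); unmatched clusters with signal become
"epithelial/mesenchymal", flat profiles "unassigned".  The ±0.5/0
thresholds are repository conventions for what is, in practice, a
qualitative heatmap judgement.

Per-phenotype reports give n, mean/SD/max Pt mass, the fraction above L_D,
and a fixed-bin histogram (0.1 fg bins, 0–10 fg).  Colocalization is
Pearson correlation at both levels — pixel (drug concentration vs channel
counts over the tissue mask) and cell (drug mass vs mean channel counts) —
with constant channels reported as null.

## Synthetic data

The generator emulates xenograft tumor sections as imaged by multiplexed
LA-ICP-TOFMS, with every downstream estimand available as ground truth.

**Geometry.** An elliptical tissue blob with a wavy boundary on silent
glass.  Regions are carved by quantile thresholds on smooth Gaussian random
fields (plus a radial term), which makes the configured region fractions
exact by construction: the resistant layout has a compact central necrotic
core and a collagen-dense outer stroma; the parental layout has dispersed
necrotic patches and Fe-rich microvessel filaments; the control layout has
parenchyma and stroma only; the spleen layout has red pulp, white pulp and
capsule.  Defaults: 1000×1000 px at 1 µm (the field-of-view scale is a
free choice), 5 µm thickness.

**Cells.** A jittered hexagonal lattice at ~3000 cells/mm² (a typical
segmentation density for packed tumor tissue), restricted to eroded tissue;
cell bodies are disks (radius 6 µm) resolved by nearest-center competition,
nuclei are Gaussian intensity bumps on the Ir channel.  Phenotypes are
drawn per region (parenchyma: epithelial/proliferating/mitotic mixes;
stroma: CAFs; necrosis: apoptotic-necrotic).  Marker levels are lognormal
per (cell, phenotype) with a printed default profile table implementing the
qualitative marker logic; tissue additionally carries a diffuse 0.5
counts/px nonspecific background on every channel, which is what
tissue-vs-glass masking keys on.

**Drug signal.**  Two microstructure modes reflect the two acquisition
styles:

* `cell_partitioned` (default; single-cell imaging at 1 µm): each cell
  draws its Pt content from a phenotype-level lognormal (resistant preset
  means 0.23 / 0.58 / 0.82 fg per cell for proliferating / CAF /
  apoptotic-necrotic, heavier tail for necrotic cells reaching ~10 fg); the
  extracellular level per region is then solved so the total region pixel
  mean equals the configured region concentration (13.4 / 32.6 / 87.8 µM in
  the resistant preset).  Both cellular and regional truths hold in one
  image, consistent with a drug largely excluded from viable cells.
* `uniform_region` (pixel-based overviews at 2.5 µm,
  `GeneratorConfig.pixel_based()`): every tissue pixel rides its region
  level, and per-cell content follows from the pixel field.  In this mode
  intensity-based k-means strata correspond to regions.  One configuration
  cannot make both the sub-fg cell contents and region-mean-recovering
  strata true simultaneously: with the drug mostly extracellular, the
  within-region pixel distribution is bimodal (cell pixels at a few µM vs
  matrix), which displaces intensity-cluster means from region means.

Within-region heterogeneity is gamma-distributed with CV 10 %, keeping
Poisson counting noise the dominant pixel-level variance at 2.5 µm while
leaving regional strata resolvable.  Counts on every channel are Poisson
around the expected intensity; the Pt channel is Poisson(S_true · m_px +
background), with S_true = 200 counts/fg by default and zero instrument
background.  A separate `noise_seed` redraws only the counting noise, so
consecutive-section pairs share identical ground truth.

**Control background.** Per-cell content is compound Poisson–gamma with
event rate λ = 0.5 and gamma moments solved from the target mean 0.02 fg
and SD 0.03 fg per cell, the distributional family the detection-limit
stage assumes.

**Droplets.** One record per mass level × replicate (default 8 levels
0.25–32 fg × 10 replicates), volumes Normal(400, 10) pL truncated positive,
counts Poisson around sensitivity × volume-adjusted mass; a noiseless mode
gives exact linearity for oracle tests.

**What the generator does not emulate.** Laser aerosol transport, spot
overlap/dosage deconvolution, TOF spectral interference, isotope channels,
autofluorescence-like channel crosstalk, irregular cell shapes, tissue
folds and section artifacts.  Passing recovery tests on this generator
therefore establishes the correctness of the analysis chain under its
stated statistical assumptions — not the fitness of any particular real
acquisition, which adds the above effects.

## Determinism and numerics

All randomness flows through seeded `numpy` generators; the DP k-means and
watershed are deterministic; Leiden uses a fixed seed; JSON writers sort
keys and CSV writers fix column order and float formatting, so a pipeline
rerun with an identical config is byte-identical.  Degenerate inputs have
defined behavior: empty masks yield empty tables, an all-zero control
sample yields L_D = 0 via the empirical fallback, constant channels yield
null correlations, flat images yield an empty mask with a warning, and a
label count above 65535 is an error rather than a 16-bit wrap.

## Problem sizes in tests

The shipped tests run the chain at moderate field sizes (400–1200 px
images, 10–20 seeds per property, 10⁵–10⁶ Monte Carlo draws), chosen as
the smallest sizes at which the tested statistical properties are stable;
all tolerances are stated in the tests themselves.
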