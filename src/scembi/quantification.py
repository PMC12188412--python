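"""Mass-to-concentration conversion, per-cell aggregation and region clustering.

A pixel of a calibrated elemental map holds an absolute mass (fg).  With the
pixel area and the section thickness (default 5 um) defining a tissue voxel,
that mass becomes a molar tissue concentration:

    c [uM] = (m_fg * 1e-15 g / M g/mol) / (pixel_size^2 * thickness * 1e-15 L) * 1e6

Per-cell quantities are obtained by summing pixel masses under a segmentation
label; regional concentration strata are obtained by k-means on the masked
pixel concentrations.  The 1-D k-means here is solved exactly by dynamic
programming over sorted unique values, so the reported partition attains the
global minimum within-cluster sum of squares and is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import MultiplexImage, SegmentationMask, validate_cell_table

__all__ = [
    "PT_MOLAR_MASS",
    "ConcentrationMap",
    "RegionClusterResult",
    "SectionComparison",
    "pixel_concentration",
    "cell_quantify",
    "tissue_mask",
    "kmeans_1d",
    "kmeans_region_means",
    "compare_consecutive_sections",
]

#: Standard atomic weight of platinum, g/mol.
PT_MOLAR_MASS = 195.084


@dataclass
class ConcentrationMap:
    """2-D molar tissue concentration grid (uM) with voxel geometry."""

    values: np.ndarray  # uM
    element: str
    pixel_size: float  # um
    thickness: float  # um
    molar_mass: float = PT_MOLAR_MASS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.pixel_size <= 0 or self.thickness <= 0:
            raise ValueError("pixel_size and thickness must be > 0")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be > 0")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def voxel_volume_L(self) -> float:
        """Volume of one tissue voxel in litres (1 um^3 == 1e-15 L)."""
        return self.pixel_size**2 * self.thickness * 1e-15


def pixel_concentration(
    mass_grid: np.ndarray,
    pixel_size: float,
    thickness: float,
    molar_mass: float = PT_MOLAR_MASS,
    element: str = "Pt",
) -> ConcentrationMap:
    """Convert a per-pixel mass grid (fg) into molar concentrations (uM)."""
    if pixel_size <= 0 or thickness <= 0:
        raise ValueError("pixel_size and thickness must be > 0")
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    mass_grid = np.asarray(mass_grid, dtype=float)
    voxel_um3 = pixel_size**2 * thickness
    values = mass_grid / (molar_mass * voxel_um3) * 1e6
    return ConcentrationMap(
        values=values,
        element=element,
        pixel_size=pixel_size,
        thickness=thickness,
        molar_mass=molar_mass,
    )


def cell_quantify(
    mass_grid: np.ndarray,
    mask: SegmentationMask,
    image: MultiplexImage,
    molar_mass: float = PT_MOLAR_MASS,
) -> pd.DataFrame:
    """Aggregate per-pixel masses and channel counts into a cell table.

    Per cell: ``pt_mass_fg`` is the sum of pixel masses under the label;
    ``pt_conc_uM`` divides that mass by the cell's voxel volume
    (area_um2 * thickness); ``mean_<channel>`` is the mean count of every
    channel over the label.  An empty mask yields an empty table.
    """
    mass_grid = np.asarray(mass_grid, dtype=float)
    if mask.labels.shape != mass_grid.shape:
        raise ValueError("mask shape does not match mass grid shape")
    if image.shape != mass_grid.shape:
        raise ValueError("image shape does not match mass grid shape")

    ids = mask.cell_ids()
    columns = (
        ["cell_id", "centroid_row", "centroid_col", "area_px", "area_um2"]
        + [f"mean_{name}" for name in image.channel_names]
        + ["pt_mass_fg", "pt_conc_uM"]
    )
    if ids.size == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in columns})

    labels = mask.labels
    flat = labels.ravel()
    nbins = int(ids.max()) + 1
    area_px = np.bincount(flat, minlength=nbins)[ids]
    rows, cols = np.indices(labels.shape)
    centroid_row = np.bincount(flat, weights=rows.ravel(), minlength=nbins)[ids] / area_px
    centroid_col = np.bincount(flat, weights=cols.ravel(), minlength=nbins)[ids] / area_px
    pt_mass = np.bincount(flat, weights=mass_grid.ravel(), minlength=nbins)[ids]

    area_um2 = area_px * image.pixel_size**2
    voxel_um3 = area_um2 * image.thickness
    pt_conc = pt_mass / (molar_mass * voxel_um3) * 1e6

    table = pd.DataFrame(
        {
            "cell_id": ids.astype(int),
            "centroid_row": centroid_row,
            "centroid_col": centroid_col,
            "area_px": area_px.astype(int),
            "area_um2": area_um2,
        }
    )
    for ci, name in enumerate(image.channel_names):
        sums = np.bincount(flat, weights=image.data[ci].ravel().astype(float), minlength=nbins)[ids]
        table[f"mean_{name}"] = sums / area_px
    table["pt_mass_fg"] = pt_mass
    table["pt_conc_uM"] = pt_conc
    return validate_cell_table(table)


def tissue_mask(image: MultiplexImage) -> np.ndarray:
    """Boolean tissue-vs-glass mask from nucleus plus marker/membrane signal.

    The summed nucleus/membrane/marker composite is Gaussian-smoothed,
    arcsinh-compressed and thresholded by Otsu's method; tissue is where the
    composite exceeds the threshold.
    """
    names = (
        image.channels_with_role("nucleus")
        + image.channels_with_role("membrane")
        + image.channels_with_role("marker")
    )
    if not names:
        raise ValueError("no nucleus/membrane/marker channels for tissue masking")
    composite = np.sum([image.get(n).astype(float) for n in names], axis=0)
    # smooth over a few pixels and compress with arcsinh so the threshold
    # separates tissue from glass rather than bright cells from everything
    composite = np.arcsinh(ndimage.gaussian_filter(composite, sigma=2.0))
    if composite.max() == composite.min():
        return np.zeros(image.shape, dtype=bool)
    thr = threshold_otsu(composite)
    return composite > thr


# ---------------------------------------------------------------------------
# exact 1-D k-means (weighted dynamic programming over sorted unique values)
# ---------------------------------------------------------------------------


def _compress(values: np.ndarray, max_unique: int = 8192):
    """Sorted unique values with multiplicities; quantile-binned if too many."""
    x, w = np.unique(values, return_counts=True)
    if x.size > max_unique:
        edges = np.quantile(values, np.linspace(0, 1, max_unique + 1))
        edges = np.unique(edges)
        idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, edges.size - 2)
        sums = np.bincount(idx, weights=values, minlength=edges.size - 1)
        cnts = np.bincount(idx, minlength=edges.size - 1)
        keep = cnts > 0
        x = sums[keep] / cnts[keep]
        w = cnts[keep]
    return x.astype(float), w.astype(float)


def kmeans_1d(values: np.ndarray, k: int):
    """Globally optimal 1-D k-means.

    Returns ``(labels, centers, wcss)`` where clusters are indexed in
    ascending order of their centers and ``wcss`` is the attained global
    minimum within-cluster sum of squares.  Solved by dynamic programming
    over sorted unique values with multiplicity weights (contiguity of
    optimal 1-D clusters makes the DP exact).
    """
    values = np.asarray(values, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    x, w = _compress(values)
    u = x.size
    if u < k:
        raise ValueError(f"k={k} exceeds the {u} distinct values")

    # prefix sums for O(1) segment SSE: cost(i..j) = Q - S^2 / W
    W = np.concatenate([[0.0], np.cumsum(w)])
    S = np.concatenate([[0.0], np.cumsum(w * x)])
    Q = np.concatenate([[0.0], np.cumsum(w * x * x)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        ww = W[j + 1] - W[i]
        ss = S[j + 1] - S[i]
        qq = Q[j + 1] - Q[i]
        return qq - ss * ss / ww

    D = np.empty((k, u))
    B = np.zeros((k, u), dtype=int)
    D[0] = Q[1:] - S[1:] ** 2 / W[1:]  # cost of the single segment 0..j
    for m in range(1, k):
        D[m, :m] = np.inf
        for j in range(m, u):
            i = np.arange(m, j + 1)  # start of the last cluster
            cand = D[m - 1, i - 1] + seg_cost(i, j)
            best = int(np.argmin(cand))
            D[m, j] = cand[best]
            B[m, j] = m + best

    # backtrack cluster boundaries
    bounds = np.empty(k + 1, dtype=int)
    bounds[k] = u
    j = u - 1
    for m in range(k - 1, 0, -1):
        i = B[m, j]
        bounds[m] = i
        j = i - 1
    bounds[0] = 0

    centers = np.empty(k)
    for m in range(k):
        lo, hi = bounds[m], bounds[m + 1]
        centers[m] = (S[hi] - S[lo]) / (W[hi] - W[lo])
    wcss = float(D[k - 1, u - 1])

    # map original values to clusters via the boundary values
    cut_values = x[bounds[1:k]] if k > 1 else np.empty(0)
    labels = np.searchsorted(cut_values, values, side="right") if k > 1 else np.zeros(
        values.size, dtype=int
    )
    return labels.astype(int), centers, wcss


@dataclass
class RegionClusterResult:
    """k-means partition of masked pixel concentrations.

    Clusters are reported in ascending order of mean concentration;
    ``label_map`` holds 0 for unmasked pixels and 1..k for clusters.
    """

    k: int
    means_uM: np.ndarray  # ascending
    pixel_counts: np.ndarray
    label_map: np.ndarray
    wcss: float


def kmeans_region_means(
    conc: ConcentrationMap,
    mask: np.ndarray,
    k: int,
    seed: int | None = None,
) -> RegionClusterResult:
    """Partition masked pixel concentrations into k strata by exact 1-D k-means.

    ``seed`` is accepted for interface stability but unused: the exact DP
    solver is deterministic.  Raises if ``k`` exceeds the number of distinct
    masked values.
    """
    del seed
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != conc.values.shape:
        raise ValueError("mask shape does not match concentration map")
    vals = conc.values[mask]
    if vals.size == 0:
        raise ValueError("empty tissue mask")
    labels, centers, wcss = kmeans_1d(vals, k)
    counts = np.bincount(labels, minlength=k)
    label_map = np.zeros(conc.values.shape, dtype=np.int32)
    label_map[mask] = labels + 1
    return RegionClusterResult(
        k=k,
        means_uM=centers,
        pixel_counts=counts,
        label_map=label_map,
        wcss=wcss,
    )


@dataclass
class SectionComparison:
    """Rank-paired cluster-mean comparison of two consecutive sections."""

    k: int
    means_a_uM: np.ndarray
    means_b_uM: np.ndarray
    relative_difference: np.ndarray  # |a - b| / a per rank
    tolerance: float
    consistent: bool

    @property
    def verdict(self) -> str:
        return "consistent" if self.consistent else "inconsistent"


def compare_consecutive_sections(
    conc_a: ConcentrationMap,
    conc_b: ConcentrationMap,
    k: int = 3,
    tolerance: float = 0.20,
    mask_a: np.ndarray | None = None,
    mask_b: np.ndarray | None = None,
    seed: int | None = None,
) -> SectionComparison:
    """Compare Pt strata of two consecutive sections (e.g. labeled/unlabeled).

    Each map is clustered independently; clusters are paired by rank and the
    relative mean difference per rank (section a as reference) is compared to
    the tolerance (default 20 %).
    """
    if mask_a is None:
        mask_a = np.ones(conc_a.values.shape, dtype=bool)
    if mask_b is None:
        mask_b = np.ones(conc_b.values.shape, dtype=bool)
    ra = kmeans_region_means(conc_a, mask_a, k, seed=seed)
    rb = kmeans_region_means(conc_b, mask_b, k, seed=seed)
    ref = np.where(ra.means_uM > 0, ra.means_uM, np.inf)
    rel = np.abs(ra.means_uM - rb.means_uM) / ref
    rel = np.where(
        (ra.means_uM == 0) & (rb.means_uM == 0), 0.0, rel
    )
    return SectionComparison(
        k=k,
        means_a_uM=ra.means_uM,
        means_b_uM=rb.means_uM,
        relative_difference=rel,
        tolerance=tolerance,
        consistent=bool(np.all(rel <= tolerance)),
    )
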