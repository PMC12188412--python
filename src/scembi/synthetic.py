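"""Synthetic LA-ICP-TOFMS tumor images with known ground truth.

The generator emulates the statistical structure of multiplexed elemental
maps of xenograft tumor sections: a tissue blob on glass, partitioned into
viable parenchyma, stroma (fibroblast-rich) and a necrotic compartment, each
with its own mean Pt tissue concentration; cells on a jittered lattice with
region-dependent phenotypes, lognormal marker expression and phenotype-level
Pt content; Poisson counting noise on every channel; and microdroplet
calibration arrays (nominally 400 +/- 10 pL) with known element mass.

Layouts
-------
``resistant``
    Pt-rich central necrotic core, dense collagen-rich outer stroma;
    region Pt means default to 13.4 / 32.6 / 87.8 uM and phenotype Pt
    content to 0.23 fg/cell (proliferating), 0.58 (CAF), 0.82
    (apoptotic/necrotic).
``parental``
    Dispersed small necrotic patches and Fe-rich microvessels; lower,
    stroma-dominated Pt levels (7.1 / 17.6 / 37.8 uM).
``control``
    No drug: per-cell Pt follows a compound Poisson-gamma background
    (default mean 0.02 fg, SD 0.03 fg per cell).
``organ_spleen``
    Red pulp / white pulp / capsule with a tissue-mean Pt of 88.2 uM and an
    Fe channel proportional to Pt (strong Fe-Pt correlation).

Every quantity the downstream stages estimate is returned as ground truth,
so recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .calibration import DropletStandard
from .io import Channel, MultiplexImage, SegmentationMask, write_mask
from .quantification import PT_MOLAR_MASS

__all__ = ["GeneratorConfig", "GroundTruth", "generate_tumor_image", "generate_droplet_array"]

LAYOUTS = ("parental", "resistant", "control", "organ_spleen")

#: Channel panel: nucleus stain, two membrane markers, six state markers,
#: endogenous Fe and the drug channel.
CHANNEL_PANEL = [
    Channel("Ir", element="Ir", role="nucleus"),
    Channel("CD44", element="Nd146", role="membrane"),
    Channel("Ecad", element="Er167", role="membrane"),
    Channel("panCK", element="Pr141", role="marker"),
    Channel("vimentin", element="Sm154", role="marker"),
    Channel("aSMA", element="Gd160", role="marker"),
    Channel("collagen", element="Tm169", role="marker"),
    Channel("Ki67", element="Er168", role="marker"),
    Channel("pS6", element="Yb175", role="marker"),
    Channel("pHH3", element="Eu153", role="marker"),
    Channel("Fe", element="Fe", role="element"),
    Channel("Pt", element="Pt", role="drug"),
]

MARKERS = ["CD44", "Ecad", "panCK", "vimentin", "aSMA", "collagen", "Ki67", "pS6", "pHH3", "Fe"]

_REGION_NAMES = {
    "parental": {1: "parenchyma", 2: "stroma", 3: "necrosis"},
    "resistant": {1: "parenchyma", 2: "stroma", 3: "necrosis"},
    "control": {1: "parenchyma", 2: "stroma"},
    "organ_spleen": {1: "white_pulp", 2: "red_pulp", 3: "capsule"},
}

_REGION_PT_MEANS = {
    "resistant": {"parenchyma": 13.4, "stroma": 32.6, "necrosis": 87.8},
    "parental": {"parenchyma": 7.1, "stroma": 17.6, "necrosis": 37.8},
    "control": {"parenchyma": 0.0, "stroma": 0.0},
    # fractions 0.25/0.65/0.10 below give a tissue mean of 88.2 uM
    "organ_spleen": {"white_pulp": 30.0, "red_pulp": 108.0, "capsule": 105.0},
}

_REGION_FRACTIONS = {
    "resistant": {"parenchyma": 0.45, "stroma": 0.30, "necrosis": 0.25},
    "parental": {"parenchyma": 0.55, "stroma": 0.35, "necrosis": 0.10},
    "control": {"parenchyma": 0.70, "stroma": 0.30},
    "organ_spleen": {"white_pulp": 0.25, "red_pulp": 0.65, "capsule": 0.10},
}

_PHENOTYPE_FRACTIONS = {
    "parenchyma": {
        "epithelial": 0.45,
        "proliferating": 0.40,
        "mitotic": 0.08,
        "epithelial/mesenchymal": 0.07,
    },
    "stroma": {"CAF": 0.88, "epithelial/mesenchymal": 0.12},
    "necrosis": {"apoptotic/necrotic": 1.0},
    "white_pulp": {"splenocyte": 1.0},
    "red_pulp": {"splenocyte": 1.0},
    "capsule": {"splenocyte": 1.0},
}

_PHENOTYPE_PT_MEANS = {
    "resistant": {
        "epithelial": 0.20,
        "proliferating": 0.23,
        "mitotic": 0.23,
        "epithelial/mesenchymal": 0.30,
        "CAF": 0.58,
        "apoptotic/necrotic": 0.82,
    },
    "parental": {
        "epithelial": 0.22,
        "proliferating": 0.25,
        "mitotic": 0.25,
        "epithelial/mesenchymal": 0.25,
        "CAF": 0.29,
        "apoptotic/necrotic": 0.30,
    },
    "organ_spleen": {"splenocyte": 0.30},
    "control": {},
}

_PT_SIGMA_DEFAULT = 0.6
_PT_SIGMA = {"apoptotic/necrotic": 0.8}  # heavy tail: occasional cells near 10 fg

#: Lognormal (median counts, sigma) marker profiles per phenotype; markers
#: not listed default to (1.5, 0.4).  The marker logic follows the field's
#: qualitative rules: CAFs vimentin/aSMA/collagen/Fe-high, proliferating
#: cells Ki-67/pS6-high, mitotic cells pHH3-high, apoptotic/necrotic cells
#: CD44/pan-keratin-high, epithelial cells E-cadherin/pan-keratin-high.
_MARKER_PROFILES = {
    "epithelial": {"Ecad": 28, "panCK": 26, "CD44": 3},
    "proliferating": {"Ecad": 16, "panCK": 16, "Ki67": 28, "pS6": 24},
    "mitotic": {"Ecad": 14, "panCK": 14, "Ki67": 10, "pS6": 8, "pHH3": 32},
    "epithelial/mesenchymal": {"Ecad": 12, "vimentin": 14, "CD44": 12, "panCK": 8},
    "CAF": {"vimentin": 30, "aSMA": 26, "collagen": 26, "Fe": 16, "CD44": 14},
    "apoptotic/necrotic": {"CD44": 30, "panCK": 22},
    "splenocyte": {"CD44": 6, "vimentin": 6},
}
_MARKER_LOW = (1.5, 0.4)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-image generator.

    Defaults are the study conditions: 1000x1000 px field at 1 um pixels,
    5 um section thickness, ~3000 cells/mm^2, sensitivity 200 counts/fg and
    the layout presets documented in the module docstring.  Identical config
    plus seed yields bit-identical output.
    """

    seed: int = 0
    image_size: tuple[int, int] = (1000, 1000)
    pixel_size: float = 1.0  # um
    thickness: float = 5.0  # um
    region_layout: str = "resistant"
    region_pt_means: Mapping[str, float] | None = None  # uM
    region_fractions: Mapping[str, float] | None = None
    cell_density: float = 3000.0  # cells per mm^2
    phenotype_fractions: Mapping[str, Mapping[str, float]] | None = None
    phenotype_pt_means_fg: Mapping[str, float] | None = None
    marker_profiles: Mapping[str, Mapping[str, tuple[float, float]]] | None = None
    sensitivity_true: float = 200.0  # counts per fg
    background_rate: float = 0.0  # instrument counts per pixel on the drug channel
    droplet_masses: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    droplet_replicates: int = 10
    droplet_volume_nominal: float = 400.0  # pL
    droplet_volume_sd: float = 10.0  # pL
    # control-tissue per-cell background: compound Poisson(lam) of gamma events,
    # gamma moments solved from the target mean/SD
    background_cell_event_rate: float = 0.5
    background_cell_mean_fg: float = 0.02
    background_cell_sd_fg: float = 0.03
    extracellular_gamma_shape: float = 100.0  # pixel-level heterogeneity (CV 10 %)
    nucleus_radius_um: float = 3.2
    cell_radius_um: float = 6.0
    ir_amplitude: float = 60.0
    #: How drug mass is laid out within a region.  ``cell_partitioned`` gives
    #: cells their phenotype-level content and solves the extracellular level
    #: so the region pixel mean still matches region_pt_means (single-cell
    #: emulation, 1 um pixels).  ``uniform_region`` draws every tissue pixel
    #: around its region mean (pixel-based overview emulation, 2.5 um pixels)
    #: and derives per-cell content from the pixel field.
    pt_microstructure: str = "cell_partitioned"
    #: Separate seed for the Poisson counting-noise stage; with a fixed
    #: ``seed`` and varying ``noise_seed``, images share identical ground
    #: truth and differ only in counting noise (consecutive-section pairs).
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.region_layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.region_layout!r}; expected {LAYOUTS}")
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image size must be positive")
        if self.pixel_size <= 0 or self.thickness <= 0:
            raise ValueError("pixel_size and thickness must be > 0")
        if self.cell_density < 0 or self.sensitivity_true < 0 or self.background_rate < 0:
            raise ValueError("densities, sensitivities and rates must be >= 0")
        if any(m < 0 for m in self.droplet_masses):
            raise ValueError("droplet masses must be >= 0")
        if self.pt_microstructure not in ("cell_partitioned", "uniform_region"):
            raise ValueError(f"unknown pt_microstructure {self.pt_microstructure!r}")
        for v in self.region_means().values():
            if v < 0:
                raise ValueError("region Pt means must be >= 0")
        frac = self.fractions()
        if abs(sum(frac.values()) - 1.0) > 1e-9:
            raise ValueError("region fractions must sum to 1 over tissue")

    # -- resolved (preset-aware) accessors ------------------------------------

    def region_means(self) -> dict[str, float]:
        if self.region_pt_means is not None:
            return dict(self.region_pt_means)
        return dict(_REGION_PT_MEANS[self.region_layout])

    def fractions(self) -> dict[str, float]:
        if self.region_fractions is not None:
            return dict(self.region_fractions)
        return dict(_REGION_FRACTIONS[self.region_layout])

    def phenotype_mix(self) -> dict[str, dict[str, float]]:
        if self.phenotype_fractions is not None:
            return {k: dict(v) for k, v in self.phenotype_fractions.items()}
        return {k: dict(v) for k, v in _PHENOTYPE_FRACTIONS.items()}

    def phenotype_pt(self) -> dict[str, float]:
        if self.phenotype_pt_means_fg is not None:
            return dict(self.phenotype_pt_means_fg)
        return dict(_PHENOTYPE_PT_MEANS[self.region_layout])

    def profiles(self) -> dict[str, dict[str, tuple[float, float]]]:
        if self.marker_profiles is not None:
            return {k: dict(v) for k, v in self.marker_profiles.items()}
        return {k: {m: (v, 0.4) for m, v in prof.items()} for k, prof in _MARKER_PROFILES.items()}

    @classmethod
    def pixel_based(cls, region_layout: str = "resistant", seed: int = 0, **overrides):
        """Preset for pixel-based overview acquisitions: 2.5 um pixels over a
        1 mm field with region-homogeneous drug distribution."""
        params = dict(
            seed=seed,
            region_layout=region_layout,
            pixel_size=2.5,
            image_size=(400, 400),
            pt_microstructure="uniform_region",
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class GroundTruth:
    """Everything downstream stages are supposed to recover."""

    region_map: np.ndarray  # 0 = glass, codes per region_names
    region_names: dict[int, str]
    cell_mask_true: SegmentationMask
    cell_phenotype_true: np.ndarray  # phenotype name per cell, index = label - 1
    cell_pt_true: np.ndarray  # fg per cell, index = label - 1
    pixel_concentration_true: np.ndarray  # uM

    def region_pixels(self, name: str) -> np.ndarray:
        code = {v: k for k, v in self.region_names.items()}[name]
        return self.region_map == code

    def cell_table(self) -> pd.DataFrame:
        ids = np.arange(1, self.cell_pt_true.size + 1)
        return pd.DataFrame(
            {
                "cell_id": ids,
                "phenotype_true": self.cell_phenotype_true,
                "pt_true_fg": self.cell_pt_true,
            }
        )

    def save(self, directory: str | Path, prefix: str = "truth") -> None:
        directory = Path(directory)
        write_mask(self.cell_mask_true, directory / f"{prefix}_cell_mask.tif")
        import tifffile

        tifffile.imwrite(
            directory / f"{prefix}_region_map.tif", self.region_map.astype(np.uint16)
        )
        self.cell_table().to_csv(
            directory / f"{prefix}_cells.csv", index=False, float_format="%.10g"
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean unit-SD Gaussian random field."""
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _tissue_blob(rng: np.random.Generator, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical tissue section with a wavy boundary; returns (mask, radial).

    ``radial`` is the normalized elliptical radius (0 center, 1 at the
    nominal boundary), used to place cores and capsules.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    radial = np.sqrt(((rr - h / 2) / (0.47 * h)) ** 2 + ((cc - w / 2) / (0.47 * w)) ** 2)
    wobble = 0.06 * _smooth_field(rng, shape, sigma=max(min(h, w) / 8, 2))
    mask = radial + wobble <= 1.0
    return mask, radial


def _split_by_quantile(score: np.ndarray, select: np.ndarray, fraction: float) -> np.ndarray:
    """Top-``fraction`` of ``select`` pixels by score (exact pixel count)."""
    n = int(round(fraction * select.sum()))
    out = np.zeros_like(select)
    if n <= 0:
        return out
    flat_sel = np.flatnonzero(select.ravel())
    top = np.argsort(-score.ravel()[flat_sel], kind="stable")[:n]
    out.ravel()[flat_sel[top]] = True
    return out


def _region_map(cfg: GeneratorConfig, rng: np.random.Generator):
    """Region label image (0 glass) honoring region fractions exactly."""
    shape = cfg.image_size
    tissue, radial = _tissue_blob(rng, shape)
    frac = cfg.fractions()
    names = _REGION_NAMES[cfg.region_layout]
    code_of = {v: k for k, v in names.items()}
    region = np.zeros(shape, dtype=np.int16)
    sigma = max(min(shape) / 16, 2)
    f1 = _smooth_field(rng, shape, sigma)
    f2 = _smooth_field(rng, shape, sigma / 2)

    layout = cfg.region_layout
    if layout in ("parental", "resistant"):
        if layout == "resistant":
            # compact Pt-rich core: strongly center-weighted
            core_score = -1.2 * radial + 0.6 * f1
        else:
            # dispersed necrotic patches
            core_score = f1
        nec = _split_by_quantile(core_score, tissue, frac.get("necrosis", 0.0))
        remaining = tissue & ~nec
        rem_frac = frac["stroma"] / max(frac["stroma"] + frac["parenchyma"], 1e-12)
        if layout == "resistant":
            # dense stromal/collagen layer toward the outer regions
            stroma_score = 0.8 * radial + 0.6 * f2
        else:
            stroma_score = f2
        stroma = _split_by_quantile(stroma_score, remaining, rem_frac)
        region[nec] = code_of["necrosis"]
        region[stroma] = code_of["stroma"]
        region[remaining & ~stroma] = code_of["parenchyma"]
    elif layout == "control":
        rem_frac = frac["stroma"]
        stroma = _split_by_quantile(f2, tissue, rem_frac)
        region[stroma] = code_of["stroma"]
        region[tissue & ~stroma] = code_of["parenchyma"]
    else:  # organ_spleen
        capsule = _split_by_quantile(radial + 0.2 * f2, tissue, frac["capsule"])
        remaining = tissue & ~capsule
        rem_frac = frac["white_pulp"] / max(frac["white_pulp"] + frac["red_pulp"], 1e-12)
        white = _split_by_quantile(f1, remaining, rem_frac)
        region[capsule] = code_of["capsule"]
        region[white] = code_of["white_pulp"]
        region[remaining & ~white] = code_of["red_pulp"]
    return region, names, tissue, radial


def _place_cells(cfg: GeneratorConfig, rng: np.random.Generator, tissue: np.ndarray):
    """Jittered hexagonal lattice of cell centers inside (eroded) tissue."""
    if cfg.cell_density <= 0:
        return np.empty((0, 2))
    h, w = cfg.image_size
    spacing_px = np.sqrt(1e6 / cfg.cell_density) / cfg.pixel_size
    cell_r_px = cfg.cell_radius_um / cfg.pixel_size
    interior = ndimage.binary_erosion(
        tissue, iterations=max(int(np.ceil(cell_r_px)), 1)
    )
    rows = np.arange(spacing_px / 2, h, spacing_px * np.sqrt(3) / 2)
    centers = []
    for i, r in enumerate(rows):
        offset = (spacing_px / 2) if i % 2 else 0.0
        cols = np.arange(spacing_px / 2 + offset, w, spacing_px)
        for c in cols:
            centers.append((r, c))
    centers = np.array(centers)
    if centers.size == 0:
        return np.empty((0, 2))
    jitter = rng.uniform(-0.35 * spacing_px, 0.35 * spacing_px, size=centers.shape)
    centers = centers + jitter
    centers[:, 0] = np.clip(centers[:, 0], 0, h - 1)
    centers[:, 1] = np.clip(centers[:, 1], 0, w - 1)
    keep = interior[centers[:, 0].astype(int), centers[:, 1].astype(int)]
    return centers[keep]


def _cell_mask(cfg: GeneratorConfig, centers: np.ndarray, tissue: np.ndarray):
    """Label image of cell disks (nearest-center competition) + center distance."""
    h, w = cfg.image_size
    labels = np.zeros((h, w), dtype=np.int32)
    dist_to_center = np.full((h, w), np.inf)
    if centers.shape[0] == 0:
        return labels, dist_to_center, centers
    cell_r_px = cfg.cell_radius_um / cfg.pixel_size
    tree = cKDTree(centers)
    rr, cc = np.mgrid[0:h, 0:w]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, nearest = tree.query(pts, k=1, workers=1)
    dist = dist.reshape(h, w)
    nearest = nearest.reshape(h, w)
    inside = (dist <= cell_r_px) & tissue
    labels[inside] = nearest[inside] + 1
    dist_to_center = dist

    # drop empty labels, relabel contiguously, keep center bookkeeping aligned
    present = np.unique(labels[labels > 0])
    remap = np.zeros(centers.shape[0] + 1, dtype=np.int32)
    remap[present] = np.arange(1, present.size + 1)
    labels = remap[labels]
    centers = centers[present - 1]
    return labels, dist_to_center, centers


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean."""
    if mean <= 0:
        return np.zeros(size)
    mu = np.log(mean) - sigma**2 / 2
    return rng.lognormal(mu, sigma, size=size)


def _compound_poisson_gamma(
    rng: np.random.Generator, lam: float, mean: float, sd: float, size: int
) -> np.ndarray:
    """Per-cell background masses: Poisson(lam) events of gamma mass.

    Gamma shape/scale are solved from the target mean and SD; requires
    lam > mean^2 / sd^2 for a consistent solution.
    """
    if mean <= 0:
        return np.zeros(size)
    a = mean / lam
    theta = sd**2 / (lam * a) - a
    if theta <= 0:
        raise ValueError(
            "inconsistent background moments: need event_rate > (mean/sd)^2"
        )
    shape = a / theta
    n = rng.poisson(lam, size=size)
    out = np.zeros(size)
    occ = n > 0
    out[occ] = rng.gamma(n[occ] * shape, theta)
    return out


def _uM_to_fg_per_px(c_uM: float, cfg: GeneratorConfig) -> float:
    """Invert the concentration formula: mean fg per pixel at a given uM."""
    voxel_um3 = cfg.pixel_size**2 * cfg.thickness
    return c_uM * PT_MOLAR_MASS * voxel_um3 * 1e-6


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------


def generate_tumor_image(cfg: GeneratorConfig) -> tuple[MultiplexImage, GroundTruth]:
    """Generate one multichannel image plus complete ground truth.

    The Pt channel is Poisson around ``sensitivity_true`` times the per-pixel
    true mass (plus the instrument background rate); with zero sensitivity
    and zero background the Pt channel is identically zero.  Control layouts
    draw per-cell Pt from the compound Poisson-gamma background only.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    region, region_names, tissue, radial = _region_map(cfg, rng)
    code_of = {v: k for k, v in region_names.items()}

    centers = _place_cells(cfg, rng, tissue)
    labels, dist_to_center, centers = _cell_mask(cfg, centers, tissue)
    n_cells = int(labels.max())
    cell_px = np.bincount(labels.ravel(), minlength=n_cells + 1)[1:]

    # phenotype per cell from the region of its center
    mix = cfg.phenotype_mix()
    phenotypes = np.empty(n_cells, dtype=object)
    if n_cells:
        center_region = region[centers[:, 0].astype(int), centers[:, 1].astype(int)]
        for code, rname in region_names.items():
            sel = np.flatnonzero(center_region == code)
            if sel.size == 0:
                continue
            rmix = mix.get(rname)
            if not rmix:
                raise ValueError(f"no phenotype mix for region {rname!r}")
            names = sorted(rmix)
            p = np.array([rmix[nm] for nm in names], dtype=float)
            phenotypes[sel] = rng.choice(names, size=sel.size, p=p / p.sum())
        # cells whose center landed on glass border artifacts: nearest region
        orphan = np.flatnonzero(center_region == 0)
        for i in orphan:
            phenotypes[i] = "epithelial/mesenchymal" if cfg.region_layout != "organ_spleen" else "splenocyte"

    # per-pixel true mass and per-cell Pt content (fg)
    mass_true = np.zeros((h, w))
    cell_pt = np.zeros(n_cells)
    g = cfg.extracellular_gamma_shape
    if cfg.region_layout == "control":
        # background only: sparse compound Poisson-gamma per-cell content
        if n_cells:
            cell_pt = _compound_poisson_gamma(
                rng,
                cfg.background_cell_event_rate,
                cfg.background_cell_mean_fg,
                cfg.background_cell_sd_fg,
                n_cells,
            )
            per_px = np.concatenate([[0.0], cell_pt / np.maximum(cell_px, 1)])
            mass_true = per_px[labels]
    elif cfg.pt_microstructure == "uniform_region":
        # every tissue pixel rides its region level; cell content follows
        for code, rname in region_names.items():
            target = cfg.region_means().get(rname, 0.0)
            if target <= 0:
                continue
            in_region = region == code
            level = _uM_to_fg_per_px(target, cfg)
            mass_true[in_region] = rng.gamma(g, level / g, size=int(in_region.sum()))
        if n_cells:
            cell_pt = np.bincount(
                labels.ravel(), weights=mass_true.ravel(), minlength=n_cells + 1
            )[1:]
    else:
        # cells carry phenotype-level content; the extracellular level is
        # solved so the region pixel mean still hits region_pt_means
        if n_cells:
            pt_means = cfg.phenotype_pt()
            for ph in np.unique(phenotypes.astype(str)):
                sel = np.flatnonzero(phenotypes == ph)
                mean = pt_means.get(ph, 0.25)
                sigma = _PT_SIGMA.get(ph, _PT_SIGMA_DEFAULT)
                cell_pt[sel] = _lognormal_mean(rng, mean, sigma, sel.size)
            per_px = np.concatenate([[0.0], cell_pt / np.maximum(cell_px, 1)])
            mass_true = per_px[labels]
        ext = (labels == 0) & tissue
        for code, rname in region_names.items():
            target = cfg.region_means().get(rname, 0.0)
            if target <= 0:
                continue
            in_region = region == code
            n_px = int(in_region.sum())
            if n_px == 0:
                continue
            cell_mass_in_region = float(mass_true[in_region].sum())
            ext_px = ext & in_region
            n_ext = int(ext_px.sum())
            if n_ext == 0:
                continue
            target_mass = _uM_to_fg_per_px(target, cfg) * n_px
            level = max(target_mass - cell_mass_in_region, 0.0) / n_ext
            if level > 0:
                mass_true[ext_px] = rng.gamma(g, level / g, size=n_ext)

    voxel_um3 = cfg.pixel_size**2 * cfg.thickness
    conc_true = mass_true / (PT_MOLAR_MASS * voxel_um3) * 1e6

    # ---- expected channel intensities, then Poisson counts ----
    profiles = cfg.profiles()
    # glass is nearly silent; tissue carries a diffuse nonspecific background
    # on every channel (matrix binding), which is what tissue-vs-glass
    # masking keys on in real acquisitions
    expected = {name: np.full((h, w), 0.02) for name in MARKERS}
    for name in MARKERS:
        expected[name][tissue] += 0.5
    # nucleus: Gaussian bump per cell around its center
    nuc_sigma = max(0.6 * cfg.nucleus_radius_um / cfg.pixel_size, 0.5)
    ir = np.full((h, w), 0.02)
    ir[tissue] += 0.3
    if n_cells:
        amp = _lognormal_mean(rng, cfg.ir_amplitude, 0.25, n_cells)
        in_cell = labels > 0
        ir_cell = amp[labels[in_cell] - 1] * np.exp(
            -(dist_to_center[in_cell] ** 2) / (2 * nuc_sigma**2)
        )
        ir[in_cell] += ir_cell
        # cellular marker expression: one lognormal level per (cell, marker)
        for m in MARKERS:
            levels = np.zeros(n_cells)
            for ph in np.unique(phenotypes.astype(str)):
                sel = np.flatnonzero(phenotypes == ph)
                median, sigma = profiles.get(ph, {}).get(m, _MARKER_LOW)
                levels[sel] = rng.lognormal(np.log(median), sigma, size=sel.size)
            expected[m][in_cell] += levels[labels[in_cell] - 1]

    # diffuse structural signal
    if cfg.region_layout in ("parental", "resistant"):
        stroma_px = region == code_of.get("stroma", -1)
        nec_px = region == code_of.get("necrosis", -1)
        expected["collagen"][stroma_px] += 8.0
        expected["vimentin"][stroma_px] += 3.0
        # necrotic debris retains keratin; CD44 stays cellular so the membrane
        # composite remains cell-specific
        expected["panCK"][nec_px] += 3.0
        # Fe-rich microvessels: thin high-quantile filaments of a smooth field
        vessel_frac = 0.06 if cfg.region_layout == "parental" else 0.03
        f = _smooth_field(rng, (h, w), max(min(h, w) / 60, 1.5))
        vessels = _split_by_quantile(f, tissue, vessel_frac)
        expected["Fe"][vessels] += 20.0
        expected["Fe"][stroma_px] += 2.0
    elif cfg.region_layout == "control":
        stroma_px = region == code_of.get("stroma", -1)
        expected["collagen"][stroma_px] += 8.0
        expected["vimentin"][stroma_px] += 3.0
    else:  # organ_spleen: Fe tracks the Pt concentration (plus red-pulp base)
        expected["Fe"][tissue] += 2.0 + 0.8 * conc_true[tissue]

    noise_rng = rng if cfg.noise_seed is None else np.random.default_rng(cfg.noise_seed)
    data = np.zeros((len(CHANNEL_PANEL), h, w), dtype=np.uint32)
    for ci, ch in enumerate(CHANNEL_PANEL):
        if ch.name == "Ir":
            lam = ir
        elif ch.name == "Pt":
            lam = cfg.sensitivity_true * mass_true + cfg.background_rate
        else:
            lam = expected[ch.name]
        data[ci] = noise_rng.poisson(lam).astype(np.uint32)

    image = MultiplexImage(
        channels=list(CHANNEL_PANEL),
        data=data,
        pixel_size=cfg.pixel_size,
        thickness=cfg.thickness,
    )
    truth = GroundTruth(
        region_map=region,
        region_names=dict(region_names),
        cell_mask_true=SegmentationMask(labels=labels, provenance="synthetic ground truth"),
        cell_phenotype_true=phenotypes.astype(str) if n_cells else np.empty(0, dtype=str),
        cell_pt_true=cell_pt,
        pixel_concentration_true=conc_true,
    )
    return image, truth


def generate_droplet_array(
    cfg: GeneratorConfig, element: str = "Pt", noiseless: bool = False
) -> list[DropletStandard]:
    """Microdroplet standards: one record per (mass level x replicate).

    Measured volumes are Normal(nominal, sd) truncated positive; integrated
    counts are Poisson around sensitivity x volume-adjusted mass plus the
    background rate.  In ``noiseless`` mode volumes equal the nominal volume
    and counts equal sensitivity x mass exactly.
    """
    if not cfg.droplet_masses:
        raise ValueError("droplet_masses must be non-empty")
    if any(m < 0 for m in cfg.droplet_masses):
        raise ValueError("droplet masses must be >= 0")
    rng = np.random.default_rng(cfg.seed + 1)
    out: list[DropletStandard] = []
    for mass in cfg.droplet_masses:
        for rep in range(cfg.droplet_replicates):
            if noiseless or cfg.droplet_volume_sd == 0:
                vol = cfg.droplet_volume_nominal
            else:
                vol = 0.0
                while vol <= 0:
                    vol = rng.normal(cfg.droplet_volume_nominal, cfg.droplet_volume_sd)
            actual_mass = mass * vol / cfg.droplet_volume_nominal
            lam = cfg.sensitivity_true * actual_mass + cfg.background_rate
            counts = lam if noiseless else float(rng.poisson(lam))
            out.append(
                DropletStandard(
                    droplet_id=f"{element}-{mass:g}-{rep}",
                    element=element,
                    mass_fg=mass,
                    volume_nominal_pL=cfg.droplet_volume_nominal,
                    volume_measured_pL=vol,
                    counts=counts,
                )
            )
    return out
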