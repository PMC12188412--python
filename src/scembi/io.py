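"""Readers and writers for the pipeline's on-disk artifacts.

Every image carries explicit physical geometry (pixel size and section
thickness in micrometres) in a JSON sidecar so that downstream unit
conversions never rely on silent defaults.  Conventions:

* pixel coordinates are 0-based ``(row, col)`` with the origin top-left;
* areas are reported both in px^2 and um^2;
* multichannel count images are stored as multi-page TIFF (one page per
  channel) next to ``<stem>.json`` holding channel metadata and geometry;
* label masks are 16-bit TIFF — more than 65535 cells is an explicit error;
* tables are RFC 4180 CSV, UTF-8, ``.`` decimal, stable column order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "Channel",
    "MultiplexImage",
    "SegmentationMask",
    "IOValidationError",
    "CELL_TABLE_BASE_COLUMNS",
    "read_multiplex",
    "write_multiplex",
    "read_mask",
    "write_mask",
    "read_cell_table",
    "write_cell_table",
    "read_json",
    "write_json",
]

CHANNEL_ROLES = ("nucleus", "membrane", "marker", "element", "drug")

#: Fixed leading columns of a cell table; per-channel means follow as
#: ``mean_<channel>`` and the trailing columns are ``pt_mass_fg``,
#: ``pt_conc_uM``, ``phenotype`` (nullable) and ``above_ld`` (nullable).
CELL_TABLE_BASE_COLUMNS = [
    "cell_id",
    "centroid_row",
    "centroid_col",
    "area_px",
    "area_um2",
]


class IOValidationError(ValueError):
    """An on-disk artifact violated a structural or unit contract."""


@dataclass(frozen=True)
class Channel:
    """Descriptor of one acquisition channel (mass channel or marker)."""

    name: str
    element: str | None = None
    role: str = "marker"

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise IOValidationError(
                f"unknown channel role {self.role!r}; expected one of {CHANNEL_ROLES}"
            )


@dataclass
class MultiplexImage:
    """A stack of per-channel 2-D count grids with physical geometry.

    Parameters
    ----------
    channels
        Ordered channel descriptors, one per page of ``data``.
    data
        Array of shape ``(n_channels, H, W)`` of non-negative finite counts.
    pixel_size
        Lateral pixel edge length in micrometres.
    thickness
        Section thickness in micrometres (ablated depth per pixel).
    """

    channels: list[Channel]
    data: np.ndarray
    pixel_size: float
    thickness: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise IOValidationError("image data must be (n_channels, H, W)")
        if len(self.channels) != self.data.shape[0]:
            raise IOValidationError(
                "channel count mismatch: "
                f"{len(self.channels)} descriptors vs {self.data.shape[0]} planes"
            )
        if len({c.name for c in self.channels}) != len(self.channels):
            raise IOValidationError("duplicate channel names")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise IOValidationError("pixel_size must be > 0")
        if not (np.isfinite(self.thickness) and self.thickness > 0):
            raise IOValidationError("thickness must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise IOValidationError("counts must be finite")
        if np.any(self.data < 0):
            raise IOValidationError("counts must be non-negative")

    # -- convenience accessors -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def index(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if c.name == name:
                return i
        raise KeyError(f"no channel named {name!r}")

    def get(self, name: str) -> np.ndarray:
        """Return the 2-D count grid of the named channel."""
        return self.data[self.index(name)]

    def channels_with_role(self, role: str) -> list[str]:
        return [c.name for c in self.channels if c.role == role]


@dataclass
class SegmentationMask:
    """Cell label image: 0 is background, k > 0 is cell k."""

    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise IOValidationError("label mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise IOValidationError("label mask must be integer-typed")
        if self.labels.min(initial=0) < 0:
            raise IOValidationError("label mask must be non-negative")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max(initial=0))

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def validate_connectivity(self) -> None:
        """Check every positive label forms one connected component (8-conn)."""
        structure = np.ones((3, 3), bool)
        for lab in self.cell_ids():
            _, n = ndimage.label(self.labels == lab, structure=structure)
            if n != 1:
                raise IOValidationError(
                    f"label {lab} splits into {n} connected components"
                )


# ---------------------------------------------------------------------------
# multichannel image TIFF + sidecar
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_multiplex(image: MultiplexImage, path: str | Path) -> None:
    """Write a multi-page TIFF plus a JSON sidecar with channels and geometry."""
    path = Path(path)
    data = image.data
    if np.issubdtype(data.dtype, np.floating):
        if not np.allclose(data, np.round(data)):
            raise IOValidationError("count grids must hold integer counts")
        data = np.round(data).astype(np.uint32)
    tifffile.imwrite(path, np.asarray(data, dtype=np.uint32))
    meta = {
        "pixel_size_um": image.pixel_size,
        "thickness_um": image.thickness,
        "channels": [
            {"name": c.name, "element": c.element, "role": c.role}
            for c in image.channels
        ],
    }
    write_json(meta, _sidecar_path(path))


def read_multiplex(path: str | Path) -> MultiplexImage:
    """Read a multi-page TIFF written by :func:`write_multiplex`.

    The sidecar must be present, list one channel per TIFF page and state
    both pixel size and thickness; geometry is never defaulted.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if not sidecar.exists():
        raise IOValidationError(f"missing sidecar metadata: {sidecar}")
    meta = read_json(sidecar)
    if "channels" not in meta or not meta["channels"]:
        raise IOValidationError("sidecar lists no channels")
    if "pixel_size_um" not in meta or meta["pixel_size_um"] is None:
        raise IOValidationError("pixel size missing from sidecar")
    if "thickness_um" not in meta or meta["thickness_um"] is None:
        raise IOValidationError("thickness missing from sidecar")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(meta["channels"]):
        raise IOValidationError(
            "channel count mismatch: sidecar lists "
            f"{len(meta['channels'])} channels but file has {data.shape[0]} pages"
        )
    channels = [
        Channel(name=c["name"], element=c.get("element"), role=c.get("role", "marker"))
        for c in meta["channels"]
    ]
    return MultiplexImage(
        channels=channels,
        data=data,
        pixel_size=float(meta["pixel_size_um"]),
        thickness=float(meta["thickness_um"]),
    )


# ---------------------------------------------------------------------------
# label masks
# ---------------------------------------------------------------------------


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    if mask.n_cells > 65535:
        raise IOValidationError(
            f"{mask.n_cells} labels exceed the 16-bit mask limit of 65535"
        )
    tifffile.imwrite(Path(path), mask.labels.astype(np.uint16))
    if mask.provenance:
        write_json({"provenance": mask.provenance}, _sidecar_path(Path(path)))


def read_mask(path: str | Path) -> SegmentationMask:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    provenance = ""
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        provenance = read_json(sidecar).get("provenance", "")
    return SegmentationMask(labels=labels, provenance=provenance)


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------


def validate_cell_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the cell-table schema; returns the table unchanged."""
    for col in CELL_TABLE_BASE_COLUMNS:
        if col not in table.columns:
            raise IOValidationError(f"cell table missing column {col!r}")
    if len(table) == 0:
        return table
    if table["cell_id"].duplicated().any():
        dup = table.loc[table["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise IOValidationError(f"duplicate cell_id {dup}")
    if (table["area_px"] <= 0).any() or (table["area_um2"] <= 0).any():
        raise IOValidationError("cell areas must be positive")
    if "pt_mass_fg" in table.columns and (table["pt_mass_fg"] < 0).any():
        raise IOValidationError("pt_mass_fg must be non-negative")
    return table


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_cell_table(table)
    cols = [c for c in CELL_TABLE_BASE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c.startswith("mean_")]
    cols += [
        c
        for c in ("pt_mass_fg", "pt_conc_uM", "phenotype", "above_ld")
        if c in table.columns
    ]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(Path(path), index=False, float_format="%.10g", lineterminator="\n")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cell table not found: {path}")
    table = pd.read_csv(path)
    if "above_ld" in table.columns:
        table["above_ld"] = table["above_ld"].astype("boolean")
    return validate_cell_table(table)


# ---------------------------------------------------------------------------
# JSON (deterministic)
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer: sorted keys, fixed separators, newline EOF."""
    text = json.dumps(obj, indent=2, sort_keys=True, default=_jsonable)
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
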