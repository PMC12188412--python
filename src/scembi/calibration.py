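"""Microdroplet calibration: from droplet standards to counts-per-fg sensitivity.

Gelatin microdroplets of known element content (nominally 400 pL) are ablated
whole; the integrated counts over each droplet footprint, regressed against
the volume-normalized element mass, give the instrument sensitivity in counts
per femtogram.  That single slope converts every pixel of an elemental map
into absolute mass.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import IOValidationError, write_json, read_json

__all__ = [
    "DropletStandard",
    "CalibrationModel",
    "CalibrationError",
    "normalize_droplet_mass",
    "fit_calibration",
    "counts_to_mass",
    "read_droplets",
    "write_droplets",
]


class CalibrationError(ValueError):
    """Raised when droplet data cannot support a valid calibration."""


@dataclass(frozen=True)
class DropletStandard:
    """One ablated microdroplet standard.

    ``mass_fg`` is the element mass dispensed at the nominal volume; the
    measured volume is used to normalize it to the actually dispensed mass.
    ``counts`` are integrated, background-corrected counts over the droplet
    footprint.
    """

    droplet_id: str
    element: str
    mass_fg: float
    volume_nominal_pL: float
    volume_measured_pL: float
    counts: float

    def __post_init__(self) -> None:
        if self.mass_fg < 0:
            raise CalibrationError("droplet mass must be >= 0")
        if self.volume_nominal_pL <= 0 or self.volume_measured_pL <= 0:
            raise CalibrationError("droplet volumes must be > 0")
        if self.counts < 0:
            raise CalibrationError("droplet counts must be >= 0")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear counts = sensitivity * mass_fg + intercept model for one element."""

    element: str
    sensitivity: float  # counts per fg
    intercept: float  # counts
    r_squared: float
    n_droplets: int
    mass_range_fg: tuple[float, float]

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["mass_range_fg"] = list(self.mass_range_fg)
        write_json(d, path)

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = read_json(path)
        d["mass_range_fg"] = tuple(d["mass_range_fg"])
        return cls(**d)


def normalize_droplet_mass(droplet: DropletStandard) -> float:
    """Element mass actually dispensed, scaled by measured/nominal volume."""
    if droplet.volume_measured_pL <= 0 or droplet.volume_nominal_pL <= 0:
        raise CalibrationError("droplet volumes must be > 0")
    return droplet.mass_fg * droplet.volume_measured_pL / droplet.volume_nominal_pL


def fit_calibration(
    droplets: Sequence[DropletStandard],
    element: str,
    force_zero_intercept: bool = False,
) -> CalibrationModel:
    """Ordinary least squares of integrated counts on normalized droplet mass.

    Requires at least three distinct normalized mass levels.  A fit with a
    non-positive slope is rejected as an invalid calibration.  R^2 is the
    ordinary coefficient of determination about the mean; for an exact line
    it is 1 by construction.
    """
    sel = [d for d in droplets if d.element == element]
    if not sel:
        raise CalibrationError(f"no droplets for element {element!r}")
    mass = np.array([normalize_droplet_mass(d) for d in sel], dtype=float)
    counts = np.array([d.counts for d in sel], dtype=float)

    # distinct mass levels, tolerant of float jitter from volume normalization
    levels = np.unique(np.round(mass, 9))
    if levels.size < 3:
        raise CalibrationError(
            f"need >= 3 distinct mass levels, got {levels.size}"
        )

    if force_zero_intercept:
        denom = float(np.dot(mass, mass))
        slope = float(np.dot(mass, counts)) / denom
        intercept = 0.0
    else:
        slope, intercept = np.polyfit(mass, counts, 1)
        slope, intercept = float(slope), float(intercept)
    if slope <= 0:
        raise CalibrationError("invalid calibration: non-positive slope")

    resid = counts - (slope * mass + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))

    return CalibrationModel(
        element=element,
        sensitivity=slope,
        intercept=intercept,
        r_squared=r2,
        n_droplets=len(sel),
        mass_range_fg=(float(mass.min()), float(mass.max())),
    )


def counts_to_mass(
    counts_grid: np.ndarray, model: CalibrationModel
) -> tuple[np.ndarray, int]:
    """Convert a counts grid to fg per pixel via the calibration model.

    mass = max(0, counts - intercept) / sensitivity, element-wise.  Returns
    the mass grid and the number of pixels clipped at zero (pixels whose
    counts fell below the intercept).
    """
    if model.sensitivity <= 0:
        raise CalibrationError("invalid calibration: non-positive sensitivity")
    counts_grid = np.asarray(counts_grid, dtype=float)
    shifted = counts_grid - model.intercept
    n_clipped = int(np.sum(shifted < 0))
    mass = np.maximum(shifted, 0.0) / model.sensitivity
    return mass, n_clipped


# ---------------------------------------------------------------------------
# droplet table CSV
# ---------------------------------------------------------------------------

_DROPLET_COLUMNS = [
    "droplet_id",
    "element",
    "mass_fg",
    "volume_nominal_pL",
    "volume_measured_pL",
    "counts",
]


def write_droplets(droplets: Iterable[DropletStandard], path: str | Path) -> None:
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DROPLET_COLUMNS)
        for d in droplets:
            writer.writerow(
                [
                    d.droplet_id,
                    d.element,
                    repr(float(d.mass_fg)),
                    repr(float(d.volume_nominal_pL)),
                    repr(float(d.volume_measured_pL)),
                    repr(float(d.counts)),
                ]
            )


def read_droplets(path: str | Path) -> list[DropletStandard]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"droplet table not found: {path}")
    out: list[DropletStandard] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_DROPLET_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise IOValidationError(f"droplet table missing columns {sorted(missing)}")
        for row in reader:
            out.append(
                DropletStandard(
                    droplet_id=row["droplet_id"],
                    element=row["element"],
                    mass_fg=float(row["mass_fg"]),
                    volume_nominal_pL=float(row["volume_nominal_pL"]),
                    volume_measured_pL=float(row["volume_measured_pL"]),
                    counts=float(row["counts"]),
                )
            )
    return out
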