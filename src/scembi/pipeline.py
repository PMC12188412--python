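"""End-to-end run: calibrate -> segment -> quantify -> L_D -> regions -> phenotypes.

A run is described by a YAML config (paths plus per-stage parameters, every
random stage with an explicit seed).  All stage artifacts are written to the
output directory together with one machine-readable ``summary.json`` that
embeds the config verbatim; reruns with an identical config are byte-
identical.  Any stage failure aborts the run with the stage name prefixed to
the cause.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import calibration as cal
from . import detection as det
from . import phenotyping as phe
from . import quantification as quant
from . import segmentation as seg
from .io import (
    read_cell_table,
    read_mask,
    read_multiplex,
    write_cell_table,
    write_json,
    write_mask,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("scembi")


class PipelineError(RuntimeError):
    """A stage failed; the message is '<stage>: <cause>'."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"{stage}: {cause}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except FileNotFoundError as exc:
        raise PipelineError(name, f"file not found ({exc})") from exc
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    log.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)


@dataclass
class RunConfig:
    """Paths and stage parameters of one pipeline run.

    ``control_cells`` may point at an existing control cell table (CSV); when
    instead ``control_image`` is given, the control image is segmented and
    quantified with the same parameters first.
    """

    image: str
    droplets: str
    output_dir: str
    control_cells: str | None = None
    control_image: str | None = None
    mask: str | None = None  # optional externally provided mask
    element: str = "Pt"
    force_zero_intercept: bool = True
    segmentation: dict = field(default_factory=dict)
    region_k: int = 4
    ld_alpha: float = 0.001
    ld_mc_draws: int = 1_000_000
    ld_seed: int = 1
    phenotype_k_neighbors: int = 15
    phenotype_resolution: float = 0.3
    phenotype_seed: int = 1
    phenotype_cofactor: float = 5.0
    rules: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in self.__dict__.items()
        }


def _quantify_image(image_path: str, mask_path: str | None, model, seg_params, out_dir, tag):
    """Shared segment+quantify chain for the treated and control images."""
    image = read_multiplex(image_path)
    if mask_path:
        mask = read_mask(mask_path)
    else:
        mask = seg.segment_cells(image, seg_params)
        write_mask(mask, out_dir / f"{tag}_mask.tif")
    pt_counts = image.get("Pt")
    mass, n_clipped = cal.counts_to_mass(pt_counts, model)
    conc = quant.pixel_concentration(mass, image.pixel_size, image.thickness)
    cells = quant.cell_quantify(mass, mask, image)
    return image, mask, mass, conc, cells, n_clipped


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the summary report."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict()}

    with _stage("calibration"):
        droplets = cal.read_droplets(config.droplets)
        model = cal.fit_calibration(
            droplets, config.element, force_zero_intercept=config.force_zero_intercept
        )
        model.to_json(out_dir / "calibration.json")
        summary["calibration"] = {
            "sensitivity_counts_per_fg": model.sensitivity,
            "intercept_counts": model.intercept,
            "r_squared": model.r_squared,
            "n_droplets": model.n_droplets,
        }

    seg_params = seg.SegmentationParams(**config.segmentation)

    with _stage("quantify"):
        image, mask, mass, conc, cells, n_clipped = _quantify_image(
            config.image, config.mask, model, seg_params, out_dir, "image"
        )
        tissue = quant.tissue_mask(image)
        tifffile.imwrite(out_dir / "concentration_uM.tif", conc.values.astype(np.float32))
        summary["quantify"] = {
            "n_cells": int(len(cells)),
            "n_pixels_clipped": int(n_clipped),
            "mean_tissue_conc_uM": float(conc.values[tissue].mean()) if tissue.any() else 0.0,
        }

    with _stage("detection-limit"):
        if config.control_cells:
            control_cells = read_cell_table(config.control_cells)
        elif config.control_image:
            *_, control_cells, _ = _quantify_image(
                config.control_image, None, model, seg_params, out_dir, "control"
            )
            write_cell_table(control_cells, out_dir / "control_cells.csv")
        else:
            raise PipelineError(
                "detection-limit", "neither control_cells nor control_image configured"
            )
        fit = det.fit_background(control_cells)
        ld = det.compute_ld(
            fit, alpha=config.ld_alpha, mc_draws=config.ld_mc_draws, seed=config.ld_seed
        )
        ld.to_json(out_dir / "detection_limit.json")
        cells = det.flag_cells(cells, ld)
        summary["detection_limit"] = {
            "ld_fg": ld.ld_fg,
            "alpha": ld.alpha,
            "method": ld.method,
            "background_mean_fg": fit.mean_fg,
            "background_sd_fg": fit.sd_fg,
            "n_control_cells": fit.n_cells,
        }

    with _stage("cluster-regions"):
        regions = quant.kmeans_region_means(conc, tissue, config.region_k)
        summary["regions"] = {
            "k": regions.k,
            "means_uM": [float(x) for x in regions.means_uM],
            "pixel_counts": [int(x) for x in regions.pixel_counts],
        }

    with _stage("phenotype"):
        rules = (
            phe.PhenotypeRuleTable.from_yaml(config.rules)
            if config.rules
            else phe.DEFAULT_RULES
        )
        features, markers = phe.transform_features(
            cells, cofactor=config.phenotype_cofactor
        )
        result = phe.cluster_phenotypes(
            features,
            k_neighbors=config.phenotype_k_neighbors,
            resolution=config.phenotype_resolution,
            seed=config.phenotype_seed,
            marker_names=markers,
        )
        result = phe.name_phenotypes(result, rules)
        cells = cells.copy()
        cells["phenotype"] = result.cell_phenotypes()
        write_cell_table(cells, out_dir / "cells.csv")
        stats = phe.phenotype_pt_stats(cells)
        stats.to_csv(out_dir / "phenotype_stats.csv", index=False, float_format="%.10g")
        summary["phenotypes"] = {
            "n_clusters": result.n_clusters,
            "modularity": result.modularity,
            "stats": {
                row["phenotype"]: {
                    "n": int(row["n"]),
                    "mean_fg": None if np.isnan(row["mean_fg"]) else float(row["mean_fg"]),
                    "frac_above_ld": (
                        None if np.isnan(row["frac_above_ld"]) else float(row["frac_above_ld"])
                    ),
                }
                for _, row in stats.iterrows()
            },
        }

    with _stage("correlate"):
        report = phe.correlation_report(conc, image, tissue, cells)
        report.to_csv(out_dir / "correlations.csv", index=False, float_format="%.10g")
        summary["correlations"] = {
            row["channel"]: {
                "pixel_r": None if row["pixel_r"] is None else float(row["pixel_r"]),
                "cell_r": None if row["cell_r"] is None else float(row["cell_r"]),
            }
            for _, row in report.iterrows()
        }

    write_json(summary, out_dir / "summary.json")
    return summary
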