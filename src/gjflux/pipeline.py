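"""End-to-end per-field 2D quantification wiring.

Chains illumination correction, nuclei/cell segmentation, optional
transfection partitioning, puncta detection on the Cx43 and marker channels,
surface-object identification, and compartment assignment into a single
per-field record suitable for the aggregation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import image2d
from .image2d import CompartmentFractions, GainField, ImageSet, PunctaSet


@dataclass
class FieldConfig:
    """Tunable knobs of the per-field pipeline (paper defaults)."""

    nucleus_min_diameter_px: float = 20.0
    nucleus_max_diameter_px: float = 60.0
    nucleus_solidity_min: float = 0.8
    puncta_d_min_px: float = 8.0
    puncta_d_max_px: float = 20.0
    nuclei_threshold: str | float = "otsu"
    # confluent monolayers have almost no background, so the cell-channel
    # threshold must sit below the dim cell-body signal; a low quantile does
    # that robustly where Otsu would latch onto the bright boundary rim
    cell_threshold: str | float = "quantile:0.01"
    puncta_threshold: str | float = "otsu"
    surface_threshold: str | float = "otsu"
    gfp_threshold: str | float = "otsu"
    colocalization_mode: str = "pixel"
    partition_transfected: bool = False


@dataclass
class FieldResult:
    """Everything measured on one field of view."""

    imageset: ImageSet
    nuclei_mask: object
    cell_mask: object
    cx43: PunctaSet
    marker_punctae: dict[str, PunctaSet]
    surface_mask: object
    surface_stats: dict
    fractions: CompartmentFractions
    puncta_table: pd.DataFrame
    transfected: dict[int, bool] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(self.cell_mask.max())

    def site_record(self) -> dict:
        """Flat per-site record for aggregation."""
        table = self.cx43.table
        return {
            "well_id": self.imageset.well_id,
            "site_id": self.imageset.site_id,
            "n_cells": self.n_cells,
            "n_punctae": len(table),
            "punctae_per_cell": len(table) / self.n_cells
            if self.n_cells
            else float("nan"),
            "mean_puncta_intensity": float(table["integrated_intensity"].mean())
            if len(table)
            else float("nan"),
            "pct_surface": self.fractions.pct_surface,
            "pct_early_endosome": self.fractions.pct_early_endosome,
            "pct_lysosome": self.fractions.pct_lysosome,
            "surface_area_um2": self.surface_stats["area_um2"],
        }


def quantify_field(
    imageset: ImageSet,
    gains: dict[str, GainField] | None = None,
    cfg: FieldConfig | None = None,
) -> FieldResult:
    """Run the full 2D pipeline on one multi-channel field."""
    cfg = cfg or FieldConfig()
    if gains:
        imageset = image2d.correct_imageset(imageset, gains)

    nuclei = image2d.segment_nuclei(
        imageset["DNA"],
        min_diameter_px=cfg.nucleus_min_diameter_px,
        max_diameter_px=cfg.nucleus_max_diameter_px,
        solidity_min=cfg.nucleus_solidity_min,
        threshold=cfg.nuclei_threshold,
    )
    cells = image2d.segment_cells(nuclei, imageset["ITGA3"], threshold=cfg.cell_threshold)

    transfected: dict[int, bool] = {}
    if cfg.partition_transfected:
        transfected = image2d.partition_transfected(
            cells, imageset.channels.get("GFP"), threshold=cfg.gfp_threshold
        )

    cx43 = image2d.detect_punctae(
        imageset["CX43"],
        cells,
        d_min=cfg.puncta_d_min_px,
        d_max=cfg.puncta_d_max_px,
        threshold=cfg.puncta_threshold,
        transfected=transfected or None,
    )
    marker_punctae = {}
    for kind in ("EEA1", "LAMP1"):
        if kind in imageset.channels:
            marker_punctae[kind] = image2d.detect_punctae(
                imageset[kind],
                cells,
                d_min=cfg.puncta_d_min_px,
                d_max=cfg.puncta_d_max_px,
                threshold=cfg.puncta_threshold,
            )
    surface_mask, surface_stats = image2d.surface_objects(
        imageset["ITGA3"],
        threshold=cfg.surface_threshold,
        pixel_size_um=imageset.pixel_size_um,
    )
    fractions, puncta_table = image2d.assign_compartments(
        cx43,
        surface_mask,
        marker_punctae,
        n_cells=int(cells.max()),
        mode=cfg.colocalization_mode,
    )
    return FieldResult(
        imageset=imageset,
        nuclei_mask=nuclei,
        cell_mask=cells,
        cx43=cx43,
        marker_punctae=marker_punctae,
        surface_mask=surface_mask,
        surface_stats=surface_stats,
        fractions=fractions,
        puncta_table=puncta_table,
        transfected=transfected,
    )
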