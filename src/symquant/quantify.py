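"""Per-cell protein-quantity statistic V over segmented regions.

V for a cell is the plain sum of projection intensities over the cell's
labeled region, V = Σ_{(x,y) ∈ cell} I(x,y), in raw acquisition units. The
sum is taken with ``math.fsum`` (exactly rounded), so it is independent of
pixel traversal order and, for integer-valued images, exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import CellLabelMap, CellRecord, ImageStack
from .segmentation import Projection, project_stack

__all__ = ["QuantTable", "total_intensity", "quantify_scene"]


@dataclass
class QuantTable:
    """Cell records of one or more scenes, one per nonzero label."""

    records: list[CellRecord] = field(default_factory=list)
    source: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [r.cell_id for r in self.records],
                "class_label": [r.class_label for r in self.records],
                "experiment_id": [r.experiment_id for r in self.records],
                "V": [r.V for r in self.records],
                "area": [r.area for r in self.records],
                "centroid_row": [r.centroid[0] for r in self.records],
                "centroid_col": [r.centroid[1] for r in self.records],
            }
        )

    def extend(self, other: "QuantTable") -> None:
        self.records.extend(other.records)

    def __len__(self) -> int:
        return len(self.records)


def total_intensity(projection: Projection, labels: CellLabelMap,
                    cell_id: int) -> float:
    """Exactly rounded sum of projection pixels where ``labels == cell_id``."""
    if cell_id < 1 or cell_id > labels.n_cells:
        raise KeyError(f"cell_id {cell_id} not present in label map")
    if labels.labels.shape != projection.image.shape:
        raise ValueError("label map shape does not match projection")
    return math.fsum(projection.image[labels.labels == cell_id].tolist())


def quantify_scene(stack: ImageStack, labels: CellLabelMap,
                   projection_method: str = "sum",
                   subtract_background: bool = False) -> QuantTable:
    """One :class:`~symquant.io.CellRecord` per cell of the scene.

    V is computed over the same projection the segmentation used (sum by
    default), so with uniform layer handling V is the stack-total intensity
    of the cell's region. By default no background is subtracted (V is the
    raw regional sum); with ``subtract_background`` the median of the
    unlabeled (background) pixels times the cell area is removed from each
    V, clamped at 0 — use this when an additive offset would bias ratios.
    """
    if labels.labels.shape != stack.shape:
        raise ValueError(
            f"label map shape {labels.labels.shape} does not match "
            f"stack layers {stack.shape}"
        )
    proj = project_stack(stack, projection_method)
    bg_median = 0.0
    if subtract_background:
        bg_pixels = proj.image[labels.labels == 0]
        if bg_pixels.size:
            bg_median = float(np.median(bg_pixels))
    records: list[CellRecord] = []
    if labels.n_cells:
        centroids = ndimage.center_of_mass(
            np.ones_like(labels.labels), labels.labels, labels.cell_ids()
        )
        areas = labels.areas()
        for k in labels.cell_ids():
            v = total_intensity(proj, labels, k)
            if subtract_background:
                v = max(v - bg_median * int(areas[k - 1]), 0.0)
            records.append(
                CellRecord(
                    cell_id=k,
                    class_label=stack.class_label,
                    experiment_id=stack.experiment_id,
                    V=v,
                    area=int(areas[k - 1]),
                    centroid=(float(centroids[k - 1][0]),
                              float(centroids[k - 1][1])),
                )
            )
    return QuantTable(records=records, source=stack.source_path)
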