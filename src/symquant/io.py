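"""Core data types and file I/O for the quantification pipeline.

The pipeline's unit of input is a single-channel confocal field of view
stored as a single- or multi-page TIFF (one page per optical section).
Intensities are promoted to float64 *without rescaling*: the per-cell
statistic V is a sum of raw acquisition units and must stay comparable
across fields imaged with identical settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "ImageStack",
    "CellLabelMap",
    "CellRecord",
    "read_stack",
    "write_stack",
    "read_label_map",
    "write_label_map",
    "write_cell_table",
    "read_cell_table",
    "relabel_contiguous",
]


@dataclass
class ImageStack:
    """A z-stack of one field of view: ``pixels[layer, row, col]`` ≥ 0.

    ``class_label`` tags the biological class of every cell in the field
    (e.g. ``CD34+``, ``KG1_C``); ``experiment_id`` tags the biological
    replicate the field belongs to.
    """

    pixels: np.ndarray
    class_label: str
    experiment_id: str
    pixel_size: float = 1.0
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[np.newaxis, ...]
        if self.pixels.ndim != 3:
            raise ValueError(
                f"pixels must be (layer, row, col); got ndim={self.pixels.ndim}"
            )
        if self.pixels.size == 0:
            raise ValueError("zero-size image stack")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("stack contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValueError("stack contains negative intensities")

    @property
    def n_layers(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of each layer."""
        return self.pixels.shape[1:]


@dataclass
class CellLabelMap:
    """Integer segmentation labels: 0 = background, k ≥ 1 = cell k.

    Labels are kept contiguous ({0..K}); ``provenance`` records whether the
    map was computed by the pipeline or supplied by the user.
    """

    labels: np.ndarray
    provenance: str = "computed"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"label map must be integer-valued, got {labels.dtype}")
        if labels.ndim != 2:
            raise ValueError("label map must be 2-D (rows, cols)")
        if labels.size and labels.min() < 0:
            raise ValueError("label map contains negative labels")
        if self.provenance not in ("computed", "provided"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        self.labels = labels.astype(np.int32, copy=False)
        present = np.unique(self.labels)
        expected = np.arange(int(present.max()) + 1 if present.size else 1)
        if not np.array_equal(np.union1d(present, [0]), expected):
            raise ValueError(
                "labels must form a contiguous set {0..K}; use relabel_contiguous"
            )

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    def cell_ids(self) -> list[int]:
        return list(range(1, self.n_cells + 1))

    def areas(self) -> np.ndarray:
        """Pixel count per cell, index 0 = cell 1."""
        return np.bincount(self.labels.ravel(), minlength=self.n_cells + 1)[1:]

    def check_connectivity(self) -> None:
        """Raise if any nonzero label is not a single 4-connected region."""
        struct = ndimage.generate_binary_structure(2, 1)
        for k in self.cell_ids():
            _, n = ndimage.label(self.labels == k, structure=struct)
            if n != 1:
                raise ValueError(f"label {k} consists of {n} 4-connected components")


@dataclass
class CellRecord:
    """One segmented cell: its class, replicate and total intensity V."""

    cell_id: int
    class_label: str
    experiment_id: str
    V: float
    area: int
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        if self.V < 0:
            raise ValueError("V must be non-negative")
        if self.area < 1:
            raise ValueError("area must be positive")


def relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Map label values onto {0..K}, preserving ascending value order.

    Region geometry is untouched: every pixel keeps its region, only the
    integer id changes.
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size and labels.max() > 0 else 1,
                   dtype=np.int32)
    for new, old in enumerate(present, start=1):
        lut[old] = new
    return lut[labels]


def read_stack(path: str | Path, class_label: str, experiment_id: str) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Multi-channel (RGB or multi-sample) TIFFs are rejected: the quantified
    signal is a single fluorophore and silently collapsing channels would
    corrupt V.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image stack: no such file {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            for page in tif.pages:
                if page.samplesperpixel > 1:
                    raise ValueError(
                        f"{path}: multi-channel TIFF "
                        f"({page.samplesperpixel} samples/pixel) is not supported"
                    )
            arr = tif.asarray()
    except ValueError:
        raise
    except Exception as exc:  # noqa: BLE001 - reraise with the offending path
        raise IOError(f"cannot read image stack {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"{path}: zero-size image")
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path}: expected 2-D pages, got array of ndim {arr.ndim}")
    return ImageStack(
        pixels=arr,
        class_label=class_label,
        experiment_id=experiment_id,
        source_path=str(path),
    )


def write_stack(stack: ImageStack, path: str | Path,
                dtype: np.dtype | str | None = None) -> Path:
    """Write a stack as a multi-page TIFF (float64 unless ``dtype`` given)."""
    path = Path(path)
    data = stack.pixels if dtype is None else stack.pixels.astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def read_label_map(path: str | Path) -> CellLabelMap:
    """Read a label image (TIFF or PNG) and relabel to contiguous {0..K}."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read label map: no such file {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(arr == np.round(arr)):
            raise ValueError(f"{path}: label map has non-integer values")
        arr = arr.astype(np.int64)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: label map has non-integer dtype {arr.dtype}")
    if arr.ndim != 2:
        raise ValueError(f"{path}: label map must be single-channel 2-D")
    if arr.size and arr.min() < 0:
        raise ValueError(f"{path}: label map contains negative values")
    return CellLabelMap(labels=relabel_contiguous(arr), provenance="provided")


def write_label_map(label_map: CellLabelMap, path: str | Path) -> Path:
    """Write labels as 16-bit (or 32-bit if needed) single-page image."""
    path = Path(path)
    labels = label_map.labels
    dtype = np.uint16 if labels.max() < 2 ** 16 else np.uint32
    out = labels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out, photometric="minisblack")
    else:
        iio.imwrite(path, out)
    return path


_TABLE_COLUMNS = [
    "cell_id", "class_label", "experiment_id", "V", "area",
    "centroid_row", "centroid_col",
]


def write_cell_table(records: Sequence[CellRecord], path: str | Path) -> Path:
    """Write cell records as CSV; reals at full round-trip precision."""
    path = Path(path)
    rows = [
        {
            "cell_id": r.cell_id,
            "class_label": r.class_label,
            "experiment_id": r.experiment_id,
            "V": r.V,
            "area": r.area,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    try:
        frame.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise IOError(f"cannot write cell table to {path}: {exc}") from exc
    return path


def read_cell_table(path: str | Path) -> list[CellRecord]:
    frame = pd.read_csv(
        path, dtype={"class_label": str, "experiment_id": str}
    )
    missing = set(_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: cell table missing columns {sorted(missing)}")
    return [
        CellRecord(
            cell_id=int(row.cell_id),
            class_label=str(row.class_label),
            experiment_id=str(row.experiment_id),
            V=float(row.V),
            area=int(row.area),
            centroid=(float(row.centroid_row), float(row.centroid_col)),
        )
        for row in frame.itertuples()
    ]
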