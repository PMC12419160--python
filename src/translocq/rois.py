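"""Reading and writing ROI sets.

Two dialects:

* **Label image** (``.tif``): a single integer image where 1 = cell,
  2 = cytosol (implies cell), 3 = background, 4 = nucleus (implies cell).
  Overlap of the nested regions is encoded by the implication rules.
* **Polygon JSON** (``.json``): ``{"image_shape": [Y, X], "cell": [[y, x],
  ...], ...}`` with one closed polygon per region, rasterized on 0-based
  pixel centers (boundary pixels included).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from skimage.draw import polygon as _draw_polygon

from .quantify import RoiSet

__all__ = ["read_rois", "write_rois", "rasterize_polygon"]

_LABELS = {"cell": 1, "cytosol": 2, "background": 3, "nucleus": 4}


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of a closed polygon given as (y, x) vertices."""
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 3:
        raise ValueError("polygon needs >= 3 (y, x) vertices")
    rr, cc = _draw_polygon(vertices[:, 0], vertices[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def write_rois(rois: RoiSet, path: str | Path) -> Path:
    """Write a RoiSet as a label-image TIFF."""
    path = Path(path)
    labels = np.zeros(rois.cell.shape, dtype=np.uint8)
    labels[rois.cell] = _LABELS["cell"]
    labels[rois.cytosol] = _LABELS["cytosol"]
    if rois.nucleus is not None:
        labels[rois.nucleus] = _LABELS["nucleus"]
    labels[rois.background] = _LABELS["background"]
    tifffile.imwrite(path, labels)
    return path


def _from_labels(labels: np.ndarray) -> RoiSet:
    cell = np.isin(labels, [_LABELS["cell"], _LABELS["cytosol"], _LABELS["nucleus"]])
    nucleus = labels == _LABELS["nucleus"]
    return RoiSet(
        cell=cell,
        cytosol=labels == _LABELS["cytosol"],
        background=labels == _LABELS["background"],
        nucleus=nucleus if nucleus.any() else None,
    )


def read_rois(path: str | Path) -> RoiSet:
    """Read a RoiSet from either dialect, chosen by file extension."""
    path = Path(path)
    if path.suffix == ".json":
        spec = json.loads(path.read_text())
        if "image_shape" not in spec:
            raise ValueError(f"{path}: polygon ROI file needs 'image_shape'")
        shape = tuple(spec["image_shape"])
        regions = {}
        for name in ("cell", "cytosol", "background", "nucleus"):
            if name in spec:
                regions[name] = rasterize_polygon(np.asarray(spec[name]), shape)
        for required in ("cell", "cytosol", "background"):
            if required not in regions:
                raise ValueError(f"{path}: missing region {required!r}")
        return RoiSet(
            cell=regions["cell"],
            cytosol=regions["cytosol"] & regions["cell"],
            background=regions["background"],
            nucleus=regions.get("nucleus"),
        )
    labels = tifffile.imread(path)
    if labels.size == 0:
        raise ValueError(f"{path}: empty label image")
    return _from_labels(np.asarray(labels))
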