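"""Plant morphometrics from binary silhouette masks.

Each camera view (side or top) yields a binary occupancy mask per plant
instance. From the side view we measure silhouette area, height, width and
centroid; from the top view, area, centroid and depth. All quantities are
converted to physical units through the camera's cm-per-pixel scale.

Coordinate convention: masks are row-major with the origin at the top-left
pixel and 0-based indices. Centroids are reported as (x, y) = (column, row)
in cm. Extents are bounding-box spans of the foreground (a single pixel has
extent 1 px); the depth axis of the top view defaults to image rows, i.e. the
axis perpendicular to the side camera's width axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage import measure

View = Literal["side", "top"]


class EmptyMaskError(ValueError):
    """Raised when a mask that should contain a plant has no foreground."""


@dataclass(frozen=True)
class ViewMask:
    """A single-plant binary mask from one camera view.

    pixels: 2-D boolean array, True = plant.
    view: "side" or "top".
    scale: physical length per pixel (cm/pixel), > 0.
    instance_id: 1-based plant index.
    """

    pixels: np.ndarray
    view: View
    scale: float
    instance_id: int = 1
    timestamp: Optional[datetime] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a non-empty 2-D grid")
        if px.dtype != bool:
            uniq = np.unique(px)
            if not np.isin(uniq, (0, 1, 255)).all():
                raise ValueError("mask must be binary (0/1 or 0/255)")
            px = px > 0
        object.__setattr__(self, "pixels", px)
        if self.view not in ("side", "top"):
            raise ValueError(f"view must be 'side' or 'top', got {self.view!r}")
        if not self.scale > 0:
            raise ValueError("scale must be > 0")


@dataclass
class PlantFeatureRecord:
    """Morphometric feature set for one plant instance at one timestamp.

    Side-derived fields (area_side, height, width, centroid_side) and
    top-derived fields (area_top, centroid_top, depth) may each be None when
    only one view is available. Areas are cm^2, extents cm.
    """

    instance_id: int
    timestamp: Optional[datetime] = None
    area_side: Optional[float] = None
    height: Optional[float] = None
    width: Optional[float] = None
    centroid_side: Optional[tuple[float, float]] = None
    area_top: Optional[float] = None
    centroid_top: Optional[tuple[float, float]] = None
    depth: Optional[float] = None

    def merged_with(self, other: "PlantFeatureRecord") -> "PlantFeatureRecord":
        """Combine side- and top-derived partial records for one instance."""
        if other.instance_id != self.instance_id:
            raise ValueError("cannot merge records of different instances")
        out = PlantFeatureRecord(self.instance_id, self.timestamp or other.timestamp)
        for name in ("area_side", "height", "width", "centroid_side",
                     "area_top", "centroid_top", "depth"):
            setattr(out, name, getattr(self, name) if getattr(self, name) is not None
                    else getattr(other, name))
        return out


def _foreground_stats(mask: ViewMask):
    rows, cols = np.nonzero(mask.pixels)
    if rows.size == 0:
        raise EmptyMaskError(
            f"no plant detected in {mask.view} mask (instance {mask.instance_id})")
    s = mask.scale
    area = rows.size * s * s
    row_extent = (rows.max() - rows.min() + 1) * s
    col_extent = (cols.max() - cols.min() + 1) * s
    centroid = (cols.mean() * s, rows.mean() * s)  # (x, y)
    return area, row_extent, col_extent, centroid


def extract_side_features(mask: ViewMask) -> PlantFeatureRecord:
    """Measure side-view area, height, width and centroid.

    Area is the foreground pixel count times scale^2 (interior holes are not
    filled). Height and width are the vertical and horizontal bounding-box
    extents of the foreground.
    """
    if mask.view != "side":
        raise ValueError("extract_side_features requires a side-view mask")
    area, height, width, centroid = _foreground_stats(mask)
    return PlantFeatureRecord(mask.instance_id, mask.timestamp,
                              area_side=area, height=height, width=width,
                              centroid_side=centroid)


def extract_top_features(mask: ViewMask, depth_axis: str = "rows") -> PlantFeatureRecord:
    """Measure top-view area, centroid and depth.

    ``depth_axis`` selects which image axis of the top view corresponds to
    depth (distance from the side camera): "rows" (default) or "cols".
    """
    if mask.view != "top":
        raise ValueError("extract_top_features requires a top-view mask")
    if depth_axis not in ("rows", "cols"):
        raise ValueError("depth_axis must be 'rows' or 'cols'")
    area, row_extent, col_extent, centroid = _foreground_stats(mask)
    depth = row_extent if depth_axis == "rows" else col_extent
    return PlantFeatureRecord(mask.instance_id, mask.timestamp,
                              area_top=area, centroid_top=centroid, depth=depth)


def segment_synthetic(image: np.ndarray, view: View, scale: float,
                      threshold: float = 0.5, min_pixels: int = 8,
                      timestamp: Optional[datetime] = None) -> list[ViewMask]:
    """Threshold-and-label segmentation for synthetic grow-bed images.

    A stand-in for the learned instance segmenter used on real photographs:
    the image is thresholded, connected foreground components below
    ``min_pixels`` are discarded, and surviving components become one
    ViewMask each, numbered 1..n left-to-right by leftmost column.

    Accepts grayscale images scaled either [0, 1] or [0, 255]; ``threshold``
    is on the [0, 1] scale. Returns an empty list when nothing is detected.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.max() > 1.0:
        img = img / 255.0
    labels = measure.label(img > threshold, connectivity=2)
    comps = []
    for region in measure.regionprops(labels):
        if region.area < min_pixels:
            continue
        comps.append((region.bbox[1], region.label))  # leftmost column
    comps.sort()
    masks = []
    for new_id, (_, lab) in enumerate(comps, start=1):
        masks.append(ViewMask(labels == lab, view=view, scale=scale,
                              instance_id=new_id, timestamp=timestamp))
    return masks


def read_mask_png(path, view: View, scale: float, instance_id: int = 1,
                  timestamp: Optional[datetime] = None) -> ViewMask:
    """Read a single-channel PNG mask (0 = background, nonzero = plant)."""
    arr = np.asarray(Image.open(path).convert("L"))
    return ViewMask(arr > 0, view=view, scale=scale,
                    instance_id=instance_id, timestamp=timestamp)


def write_mask_png(mask: ViewMask, path) -> None:
    """Write a mask as an 8-bit PNG (foreground 255)."""
    Image.fromarray(np.where(mask.pixels, 255, 0).astype(np.uint8)).save(path)


def records_to_frame(records: Sequence[PlantFeatureRecord]) -> pd.DataFrame:
    """Tabulate feature records, one row per (instance, timestamp)."""
    rows = []
    for r in records:
        row = {"instance_id": r.instance_id, "timestamp": r.timestamp,
               "area_side": r.area_side, "height": r.height, "width": r.width,
               "area_top": r.area_top, "depth": r.depth}
        if r.centroid_side is not None:
            row["centroid_side_x"], row["centroid_side_y"] = r.centroid_side
        if r.centroid_top is not None:
            row["centroid_top_x"], row["centroid_top_y"] = r.centroid_top
        rows.append(row)
    base_cols = ["instance_id", "timestamp", "area_side", "height", "width",
                 "area_top", "depth"]
    if not rows:
        return pd.DataFrame(columns=base_cols)
    return pd.DataFrame(rows)
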