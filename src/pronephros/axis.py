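"""Duct-axis geometry: polyline rasterization, circular ROI masks,
cumulative distances.

The user traces the duct from the glomerular end to the excretory pore as a
polyline over the GFP maximum-intensity projection.  Each straight segment is
rasterized with Bresenham's algorithm; consecutive pixels are therefore
8-connected, so physical step lengths are ``pixel_size`` or
``sqrt(2)*pixel_size``.  Cumulative distance is the 2D arc length of that
pixel chain (z drift of the duct is not added).
"""

from __future__ import annotations

import csv
import struct
import zipfile
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import line as _bresenham_line

from .errors import FormatError, GeometryError

__all__ = [
    "PolylineAxis",
    "AxisPixels",
    "rasterize_polyline",
    "circular_mask",
    "read_polyline_csv",
    "read_imagej_roi",
]


def _round_half_up(values) -> np.ndarray:
    return np.floor(np.asarray(values, dtype=float) + 0.5).astype(int)


@dataclass(frozen=True)
class PolylineAxis:
    """Ordered (x, y) vertices tracing the duct, glomerular end first."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("vertices must be an (n>=2, 2) array of (x, y)")
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        object.__setattr__(self, "vertices", v)

    def reversed(self) -> "PolylineAxis":
        return PolylineAxis(self.vertices[::-1].copy())


@dataclass
class AxisPixels:
    """Rasterized axis: ordered integer pixels with physical step lengths.

    ``step_lengths[0] == 0``; for i >= 1 each step is ``pixel_size`` or
    ``sqrt(2)*pixel_size``.  ``cumulative_distance`` is the running sum.
    """

    pixels: np.ndarray  # (n, 2) int, columns (x, y)
    step_lengths: np.ndarray  # um
    cumulative_distance: np.ndarray  # um
    pixel_size_xy: float

    @property
    def total_length(self) -> float:
        return float(self.cumulative_distance[-1])

    def __len__(self) -> int:
        return len(self.pixels)


def _segment_pixels(p0: tuple, p1: tuple) -> np.ndarray:
    """Bresenham pixels from p0 to p1 inclusive, symmetric under endpoint
    swap (the lexicographically smaller endpoint is always rasterized first,
    then the order is flipped to follow the requested direction)."""
    flip = (p1[0], p1[1]) < (p0[0], p0[1])
    a, b = (p1, p0) if flip else (p0, p1)
    rr, cc = _bresenham_line(a[1], a[0], b[1], b[0])  # skimage takes (row, col)
    pix = np.column_stack([cc, rr])
    return pix[::-1] if flip else pix


def rasterize_polyline(
    axis: PolylineAxis,
    pixel_size_xy: float = 1.0,
    image_shape: tuple | None = None,
) -> AxisPixels:
    """Rasterize the polyline segment by segment into an ordered pixel chain.

    Non-integer vertices are rounded half-up to the pixel grid first.  The
    shared vertex of adjacent segments is kept once (first occurrence);
    revisited pixels elsewhere along the path are retained.

    Raises ``GeometryError`` if ``image_shape`` (height, width) is given and
    any vertex falls outside it.
    """
    verts = _round_half_up(axis.vertices)
    if image_shape is not None:
        h, w = image_shape
        bad = (
            (verts[:, 0] < 0)
            | (verts[:, 0] >= w)
            | (verts[:, 1] < 0)
            | (verts[:, 1] >= h)
        )
        if np.any(bad):
            raise GeometryError(
                f"polyline vertices outside image {image_shape}: "
                f"{verts[bad].tolist()}"
            )
    chunks = []
    for k in range(len(verts) - 1):
        seg = _segment_pixels(tuple(verts[k]), tuple(verts[k + 1]))
        if chunks and len(seg) and np.array_equal(seg[0], chunks[-1][-1]):
            seg = seg[1:]  # drop duplicated shared vertex, keep first
        if len(seg):
            chunks.append(seg)
    pixels = np.concatenate(chunks, axis=0)
    diffs = np.diff(pixels, axis=0)
    steps = np.hypot(diffs[:, 0], diffs[:, 1]) * pixel_size_xy
    step_lengths = np.concatenate([[0.0], steps])
    return AxisPixels(
        pixels=pixels,
        step_lengths=step_lengths,
        cumulative_distance=np.cumsum(step_lengths),
        pixel_size_xy=pixel_size_xy,
    )


def circular_mask(
    center: tuple, diameter: float, image_shape: tuple
) -> tuple[np.ndarray, np.ndarray]:
    """Pixels whose centers lie within ``diameter/2`` of ``center``
    (boundary inclusive), clipped to the image.

    Parameters
    ----------
    center : (x, y) integer pixel coordinates.
    diameter : ROI diameter in pixels (> 0).
    image_shape : (height, width).

    Returns
    -------
    (xs, ys) : integer index arrays (possibly empty), row-major order.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    cx, cy = int(center[0]), int(center[1])
    h, w = image_shape
    r = diameter / 2.0
    ri = int(np.floor(r))
    y0, y1 = max(0, cy - ri), min(h - 1, cy + ri)
    x0, x1 = max(0, cx - ri), min(w - 1, cx + ri)
    if y0 > y1 or x0 > x1:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r
    return xs[inside].ravel(), ys[inside].ravel()


def read_polyline_csv(path) -> PolylineAxis:
    """Read a polyline from a CSV with ``x`` and ``y`` columns."""
    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise FormatError(f"{path}: expected 'x' and 'y' columns, got {list(df.columns)}")
    return PolylineAxis(np.column_stack([df[cols["x"]], df[cols["y"]]]))


def write_polyline_csv(axis: PolylineAxis, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        writer.writerows(axis.vertices.tolist())


# ImageJ .roi binary layout (header fields used here):
#   0-3   magic "Iout"
#   6     roi type (0 polygon, 4 freeline, 5 polyline, 7 freehand, 8 traced)
#   8,10  top, left (int16)
#   16    n_coordinates (int16)
#   64..  n int16 x offsets from left, then n int16 y offsets from top
_POLY_TYPES = {0, 4, 5, 7, 8}


def _parse_roi_bytes(buf: bytes, name: str) -> PolylineAxis:
    if len(buf) < 64 or buf[:4] != b"Iout":
        raise FormatError(f"{name}: not an ImageJ ROI file")
    roi_type = buf[6]
    if roi_type not in _POLY_TYPES:
        raise FormatError(f"{name}: ROI type {roi_type} is not a polyline/polygon")
    top, left = struct.unpack(">hh", buf[8:12])
    (n,) = struct.unpack(">h", buf[16:18])
    if n < 2:
        raise FormatError(f"{name}: ROI has {n} points, need >= 2")
    need = 64 + 4 * n
    if len(buf) < need:
        raise FormatError(f"{name}: truncated ROI (need {need} bytes)")
    xs = np.frombuffer(buf, dtype=">i2", count=n, offset=64).astype(int) + left
    ys = np.frombuffer(buf, dtype=">i2", count=n, offset=64 + 2 * n).astype(int) + top
    return PolylineAxis(np.column_stack([xs, ys]))


def read_imagej_roi(path) -> PolylineAxis:
    """Read a polyline-like ROI from an ImageJ ``.roi`` file, or the first
    such ROI from an ImageJ ``.zip`` export."""
    path = str(path)
    if path.lower().endswith(".zip"):
        with zipfile.ZipFile(path) as zf:
            for entry in zf.namelist():
                if entry.lower().endswith(".roi"):
                    return _parse_roi_bytes(zf.read(entry), entry)
        raise FormatError(f"{path}: zip contains no .roi entries")
    with open(path, "rb") as fh:
        return _parse_roi_bytes(fh.read(), path)
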