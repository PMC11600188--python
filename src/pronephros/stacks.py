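"""Calibrated two-channel confocal z-stacks: container, TIFF I/O, MIP.

Intensities are held as nonnegative floats regardless of the on-disk integer
depth so that downstream ROI statistics are uniform.  Coordinate convention:
0-based indices, ``(x, y)`` means ``(col, row)``, pixel centers at integer
coordinates.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import CalibrationError, FormatError, MissingChannelError

__all__ = ["ZStack", "read_zstack", "write_zstack", "max_intensity_projection"]

GFP = "GFP"
DYE = "dye"


@dataclass
class ZStack:
    """A two-channel 3D intensity grid with physical calibration.

    Attributes
    ----------
    voxels : ndarray, shape (n_channels, n_slices, height, width)
        Nonnegative intensities, float.
    channel_labels : tuple of str
        Must contain "GFP" (duct wall label) and "dye" (tracer) exactly once.
    pixel_size_xy : float
        Lateral pixel size in um/px.
    z_interval : float
        Axial slice spacing in um.
    """

    voxels: np.ndarray
    channel_labels: tuple = (GFP, DYE)
    pixel_size_xy: float = 1.0
    z_interval: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be (channel, slice, row, col)")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.voxels.shape[0]:
            raise ValueError("one label per channel required")
        for required in (GFP, DYE):
            if self.channel_labels.count(required) != 1:
                raise MissingChannelError(
                    f"channel {required!r} must appear exactly once, "
                    f"got labels {self.channel_labels}"
                )
        if min(self.voxels.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValueError("intensities must be finite and nonnegative")
        if not (self.pixel_size_xy > 0 and self.z_interval > 0):
            raise CalibrationError("pixel_size_xy and z_interval must be > 0")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[1]

    @property
    def image_shape(self) -> tuple:
        """(height, width) of each slice."""
        return self.voxels.shape[2:]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise MissingChannelError(
                f"no channel {label!r}; have {self.channel_labels}"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        """The (slice, row, col) grid of one channel."""
        return self.voxels[self.channel_index(label)]


def write_zstack(stack: ZStack, path) -> None:
    """Write as OME-TIFF (axes CZYX) with physical calibration and channel
    names embedded, voxels as float32."""
    tifffile.imwrite(
        str(path),
        stack.voxels.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.pixel_size_xy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_xy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_interval,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_labels)},
        },
    )


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_ome(xml_text: str) -> dict:
    """Extract PhysicalSizeX/Z and channel names from OME-XML, namespace
    agnostically."""
    out: dict = {}
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return out
    names = []
    for el in root.iter():
        tag = _strip_ns(el.tag)
        if tag == "Pixels":
            for key in ("PhysicalSizeX", "PhysicalSizeZ"):
                if key in el.attrib:
                    out[key] = float(el.attrib[key])
        elif tag == "Channel":
            names.append(el.attrib.get("Name"))
    if names and all(n is not None for n in names):
        out["channel_names"] = names
    return out


def read_zstack(
    path,
    channel_map: dict | None = None,
    pixel_size_xy: float | None = None,
    z_interval: float | None = None,
) -> ZStack:
    """Read a multi-page TIFF / OME-TIFF into a ZStack.

    Parameters
    ----------
    channel_map : dict, optional
        Maps the labels "GFP" and "dye" to channel indices along the channel
        axis.  Required for files without embedded channel names; overrides
        embedded names when given.
    pixel_size_xy, z_interval : float, optional
        Explicit calibration in um; overrides embedded OME metadata.  An
        error is raised if neither source provides a value.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            ome = _parse_ome(tif.ome_metadata) if tif.ome_metadata else {}
    except (tifffile.TiffFileError, OSError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc

    # Normalise to (C, Z, Y, X): samples count as channels; anonymous page
    # axes are assigned from the right as slices, then channels; any axis
    # absent from the file is added with length 1.
    axes = list(axes.replace("S", "C"))
    for i in reversed(range(len(axes))):
        if axes[i] in "IQ":
            if "Z" not in axes:
                axes[i] = "Z"
            elif "C" not in axes:
                axes[i] = "C"
    axes = "".join(axes)
    for letter in "CZYX":
        if letter not in axes:
            data = np.expand_dims(data, 0)
            axes = letter + axes
    if data.ndim != 4 or sorted(axes) != ["C", "X", "Y", "Z"]:
        raise FormatError(
            f"unsupported TIFF layout (axes {series.axes!r}, shape {data.shape})"
        )
    order = [axes.index(a) for a in "CZYX"]
    data = np.transpose(data, order)

    embedded_names = ome.get("channel_names")
    n_channels = data.shape[0]
    if channel_map is not None:
        for required in (GFP, DYE):
            if required not in channel_map:
                raise MissingChannelError(
                    f"channel_map has no entry for {required!r}"
                )
        labels = [None] * n_channels
        for label, idx in channel_map.items():
            if not 0 <= idx < n_channels:
                raise MissingChannelError(
                    f"channel_map points {label!r} at index {idx}, "
                    f"but file has {n_channels} channel(s)"
                )
            labels[idx] = label
        labels = [l if l is not None else f"ch{i}" for i, l in enumerate(labels)]
    elif embedded_names and len(embedded_names) == n_channels:
        labels = embedded_names
    else:
        raise MissingChannelError(
            "no channel_map given and the file embeds no channel names"
        )

    px = pixel_size_xy if pixel_size_xy is not None else ome.get("PhysicalSizeX")
    dz = z_interval if z_interval is not None else ome.get("PhysicalSizeZ")
    if px is None or dz is None:
        raise CalibrationError(
            "pixel_size_xy / z_interval neither supplied nor embedded in the file"
        )
    return ZStack(
        voxels=np.asarray(data, dtype=float),
        channel_labels=tuple(labels),
        pixel_size_xy=float(px),
        z_interval=float(dz),
    )


def max_intensity_projection(stack: ZStack, channel: str) -> np.ndarray:
    """Pixelwise maximum over slices for one channel; shape (row, col)."""
    return stack.channel(channel).max(axis=0)


def write_projection(image: np.ndarray, path) -> None:
    """Export a 2D projection as 16-bit TIFF (values clipped/rounded)."""
    img = np.clip(np.rint(image), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), img)
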