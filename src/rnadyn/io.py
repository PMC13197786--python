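"""Calibrated image containers and file I/O.

An :class:`ImageStack` is a non-negative (T, Z, Y, X) array plus the
physical calibration needed downstream: pixel size (um/px), z step (um)
and frame interval (s).  Stacks round-trip through OME-TIFF with the
calibration stored in the OME pixel metadata.  Cell regions of interest
are pairs of disjoint nucleus/cytoplasm label masks.

Coordinate convention: 0-based pixel indices, pixel centers at integer
coordinates, origin at the top-left; physical position in micrometres is
``index * pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "CellROI",
    "FormatError",
    "read_stack",
    "write_stack",
    "load_rois",
    "read_table",
    "write_table",
]


class FormatError(ValueError):
    """Raised when a file cannot be interpreted as expected."""


@dataclass
class ImageStack:
    """Calibrated multi-dimensional pixel data ordered (T, Z, Y, X)."""

    pixels: np.ndarray
    pixel_size_um: float
    z_step_um: float = 0.0
    frame_interval_s: float = 1.0
    channel_label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim > 4:
            raise FormatError(f"at most 4 axes (T,Z,Y,X) supported, got {px.ndim}")
        while px.ndim < 4:  # promote (Y,X) -> (1,1,Y,X), (Z/T,Y,X) -> (1,.,Y,X)
            px = px[np.newaxis]
        if px.size == 0:
            raise FormatError("empty pixel array")
        if np.any(px < 0):
            raise FormatError("pixel intensities must be non-negative")
        self.pixels = px
        if not self.pixel_size_um > 0:
            raise FormatError("pixel_size_um must be > 0")
        if self.n_slices > 1 and not self.z_step_um > 0:
            raise FormatError("z_step_um must be > 0 for a multi-slice stack")
        if self.z_step_um < 0:
            raise FormatError("z_step_um must be >= 0")
        if self.n_frames > 1 and not self.frame_interval_s > 0:
            raise FormatError("frame_interval_s must be > 0 for a movie")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def frame(self, t: int, z: int = 0) -> np.ndarray:
        """Single (Y, X) plane."""
        return self.pixels[t, z]


@dataclass
class CellROI:
    """Disjoint nucleus and cytoplasm masks for one cell."""

    cell_id: int
    nucleus_mask: np.ndarray
    cytoplasm_mask: np.ndarray

    def __post_init__(self) -> None:
        nuc = np.asarray(self.nucleus_mask, dtype=bool)
        cyt = np.asarray(self.cytoplasm_mask, dtype=bool)
        if nuc.shape != cyt.shape:
            raise FormatError("nucleus and cytoplasm masks must share a shape")
        if np.any(nuc & cyt):
            raise FormatError(
                f"cell {self.cell_id}: nucleus and cytoplasm masks overlap"
            )
        self.nucleus_mask = nuc
        self.cytoplasm_mask = cyt


_AX_ORDER = "TZYX"


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an OME-TIFF with calibration in the pixel metadata."""
    meta = {
        "axes": _AX_ORDER,
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
    }
    if stack.z_step_um > 0:
        meta["PhysicalSizeZ"] = stack.z_step_um
        meta["PhysicalSizeZUnit"] = "µm"
    meta["TimeIncrement"] = stack.frame_interval_s
    meta["TimeIncrementUnit"] = "s"
    tifffile.imwrite(str(path), stack.pixels, ome=True, metadata=meta)


def _axes_to_tzyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand an arbitrary tifffile axes string to (T,Z,Y,X)."""
    axes = axes.upper()
    if "Y" not in axes or "X" not in axes:
        raise FormatError(f"cannot interpret axes {axes!r}: missing Y/X")
    # squeeze singleton axes we do not model (e.g. C, S) — refuse non-singleton
    keep = []
    for i, ax in enumerate(axes):
        if ax in _AX_ORDER:
            keep.append((ax, i))
        elif data.shape[i] != 1:
            raise FormatError(f"unsupported non-singleton axis {ax!r} in {axes!r}")
    data = data.transpose([i for _, i in keep]).reshape(
        [data.shape[i] for _, i in keep]
    )
    present = [ax for ax, _ in keep]
    order = np.argsort([_AX_ORDER.index(ax) for ax in present])
    data = data.transpose(order)
    for pos, ax in enumerate(_AX_ORDER):
        if ax not in present:
            data = np.expand_dims(data, pos)
    return data


def read_stack(
    path: str | Path,
    *,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    frame_interval_s: float | None = None,
    channel_label: str = "",
) -> ImageStack:
    """Read a TIFF/OME-TIFF, normalising axes to (T, Z, Y, X).

    Calibration is taken from OME metadata where present; keyword
    overrides win.  A stack with no pixel size in its metadata and no
    override raises :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        ome = tf.ome_metadata
    pixels = _axes_to_tzyx(np.asarray(data), axes)

    meta_px = meta_z = meta_dt = None
    if ome:
        d = tifffile.xml2dict(ome)
        try:
            pix = d["OME"]["Image"]
            if isinstance(pix, list):
                pix = pix[0]
            pix = pix["Pixels"]
            meta_px = pix.get("PhysicalSizeX")
            meta_z = pix.get("PhysicalSizeZ")
            meta_dt = pix.get("TimeIncrement")
        except (KeyError, TypeError):
            pass

    px = pixel_size_um if pixel_size_um is not None else meta_px
    if px is None:
        raise FormatError(
            f"{path}: no pixel size in metadata and no pixel_size_um override"
        )
    zs = z_step_um if z_step_um is not None else meta_z
    if zs is None:
        zs = 0.0
    dt = frame_interval_s if frame_interval_s is not None else meta_dt
    if dt is None:
        dt = 1.0
    return ImageStack(
        pixels=pixels,
        pixel_size_um=float(px),
        z_step_um=float(zs),
        frame_interval_s=float(dt),
        channel_label=channel_label,
    )


def load_rois(path: str | Path, *, cytoplasm_offset: int = 1000) -> list[CellROI]:
    """Load cell ROIs from a label image.

    Two layouts are accepted:

    * a single 2D label plane, where nucleus of cell ``k`` is labelled
      ``k`` and its cytoplasm ``k + cytoplasm_offset``;
    * a 2-plane image, plane 0 holding nucleus labels and plane 1
      cytoplasm labels, both labelled ``k`` for cell ``k``.

    Overlapping nucleus/cytoplasm pixels for a cell raise
    :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI label file not found: {path}")
    labels = np.asarray(iio.imread(str(path)))
    labels = np.squeeze(labels)
    if labels.ndim == 2:
        nuc_plane = np.where(labels < cytoplasm_offset, labels, 0)
        cyt_plane = np.where(labels >= cytoplasm_offset, labels - cytoplasm_offset, 0)
    elif labels.ndim == 3 and labels.shape[0] == 2:
        nuc_plane, cyt_plane = labels[0], labels[1]
    else:
        raise FormatError(
            f"{path}: expected a 2D label plane or a 2-plane label image, "
            f"got shape {labels.shape}"
        )
    cell_ids = sorted(set(np.unique(nuc_plane)) | set(np.unique(cyt_plane)) - {0})
    cell_ids = [int(c) for c in cell_ids if c != 0]
    return [
        CellROI(
            cell_id=cid,
            nucleus_mask=nuc_plane == cid,
            cytoplasm_mask=cyt_plane == cid,
        )
        for cid in cell_ids
    ]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV with a header row, UTF-8, '.' decimal."""
    pd.DataFrame(df).to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path)
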