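"""Image and ROI input/output, coordinate conventions, and configuration.

Conventions used throughout the package
---------------------------------------
* Voxel arrays are ordered ``(channel, z, y, x)`` with 0-based indices.
* Polygon vertices are ``(x, y)`` pairs in pixel coordinates; a pixel
  center sits at integer coordinates.
* Polygons are closed and boundary-inclusive: a point lying exactly on a
  polygon edge counts as inside (``shapely`` ``covers`` semantics).
* z ranges are half-open ``[z0, z1)``, consistent with array slicing.
"""

from __future__ import annotations

import json
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import shapely
import tifffile
import yaml
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

#: default channel order for simulated embryos
DEFAULT_CHANNELS = ("smFISH", "junction-GFP", "AJM-1", "DAPI")

#: polygon roles understood by the pipeline
ROI_ROLES = (
    "total",
    "interior",
    "nuclear",
    "apical",
    "profile_band_apicobasal",
    "profile_band_apical",
)


class FormatError(ValueError):
    """Raised when a file cannot be read as the expected format."""


class RoiValidationError(ValueError):
    """Raised when an ROI set violates its geometric invariants."""


# ---------------------------------------------------------------------------
# ImageStack
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """A multi-channel 3D fluorescence stack.

    Parameters
    ----------
    voxels
        Array of shape ``(n_channels, n_z, n_y, n_x)``, non-negative.
    voxel_size
        Physical voxel size ``(z, y, x)`` in micrometres.
    channel_names
        One label per channel.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be 4D (channel, z, y, x); got shape {self.voxels.shape}"
            )
        if min(self.voxels.shape) < 1:
            raise ValueError(f"all dimensions must be positive: {self.voxels.shape}")
        if not self.channel_names:
            self.channel_names = tuple(
                f"channel_{i}" for i in range(self.voxels.shape[0])
            )
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )
        self.channel_names = tuple(self.channel_names)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_z(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.voxels.shape[2], self.voxels.shape[3]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"unknown channel {channel!r}; have {self.channel_names}"
                ) from None
        return int(channel)

    def channel(self, channel: int | str) -> np.ndarray:
        """Return the ``(z, y, x)`` sub-array of one channel."""
        return self.voxels[self.channel_index(channel)]


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as OME-TIFF, recording voxel size and channel names."""
    vz, vy, vx = stack.voxel_size
    tifffile.imwrite(
        str(path),
        stack.voxels,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": vx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": vy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": vz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
        ome=True,
    )


def _parse_ome_metadata(xml_text: str):
    """Extract (voxel_size, channel_names, declared_size) from OME-XML."""
    voxel_size = None
    channel_names: list[str] = []
    declared_size = None
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return None, [], None
    for elem in root.iter():
        tag = elem.tag.rsplit("}", 1)[-1]
        if tag == "Pixels":
            vx = float(elem.get("PhysicalSizeX", 1.0))
            vy = float(elem.get("PhysicalSizeY", 1.0))
            vz = float(elem.get("PhysicalSizeZ", 1.0))
            voxel_size = (vz, vy, vx)
            try:
                declared_size = int(
                    np.prod([int(elem.get(f"Size{a}", 1))
                             for a in ("T", "C", "Z", "Y", "X")])
                )
            except (TypeError, ValueError):
                declared_size = None
        elif tag == "Channel":
            name = elem.get("Name")
            if name is not None:
                channel_names.append(name)
    return voxel_size, channel_names, declared_size


def read_stack(path) -> ImageStack:
    """Read a TIFF/OME-TIFF file as an :class:`ImageStack`.

    Plain 2D TIFFs are promoted to shape ``(1, 1, y, x)``; 3D arrays
    without axis metadata are taken as ``(z, y, x)`` single-channel.
    Missing voxel-size metadata falls back to 1.0 µm with a warning.
    """
    # tifffile reports structural damage (broken IFD chains, bad tag
    # offsets) through its logger and then returns a partial read; the
    # error contract here is to fail loudly instead
    tiff_errors: list[str] = []

    class _Capture(logging.Handler):
        def emit(self, record: logging.LogRecord) -> None:
            if record.levelno >= logging.ERROR:
                tiff_errors.append(record.getMessage())

    capture = _Capture()
    tifffile_logger = logging.getLogger("tifffile")
    tifffile_logger.addHandler(capture)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            arr = series.asarray()
            axes = series.axes
            ome_xml = tf.ome_metadata
    except Exception as exc:  # tifffile raises a mix of OSError/ValueError
        raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc
    finally:
        tifffile_logger.removeHandler(capture)
    if tiff_errors:
        raise FormatError(
            f"{path}: file is truncated or corrupt: {tiff_errors[0]}"
        )

    voxel_size = None
    channel_names: list[str] = []
    if ome_xml:
        voxel_size, channel_names, declared_size = _parse_ome_metadata(ome_xml)
        if declared_size is not None and declared_size != arr.size:
            raise FormatError(
                f"{path}: file is truncated or corrupt — OME metadata "
                f"declares {declared_size} voxels but {arr.size} were read"
            )

    # Normalise axis order to CZYX, adding missing axes of length 1.
    axes = axes.replace("S", "C")  # treat samples as channels
    if arr.ndim == 2:
        arr = arr[None, None]
    elif set(axes) >= {"C", "Z", "Y", "X"} and arr.ndim == 4:
        order = [axes.index(a) for a in "CZYX"]
        arr = np.transpose(arr, order)
    elif arr.ndim == 3:
        if "C" in axes and "Z" not in axes:
            arr = arr[:, None]
        else:
            arr = arr[None]
    elif arr.ndim != 4:
        raise FormatError(f"unsupported TIFF dimensionality: shape {arr.shape}")

    if arr.shape[0] < 1:
        raise FormatError(f"{path}: no channels present")
    if voxel_size is None:
        logger.warning("%s: no voxel-size metadata; assuming 1.0 µm per axis", path)
        voxel_size = (1.0, 1.0, 1.0)
    if len(channel_names) != arr.shape[0]:
        channel_names = [f"channel_{i}" for i in range(arr.shape[0])]
    return ImageStack(arr, voxel_size=voxel_size, channel_names=tuple(channel_names))


def max_project(stack: ImageStack, channel: int | str, z_range=None) -> np.ndarray:
    """Maximum-intensity projection of one channel over ``[z0, z1)``.

    ``z_range=None`` projects over the full depth.
    """
    vol = stack.channel(channel)
    if z_range is None:
        z0, z1 = 0, vol.shape[0]
    else:
        z0, z1 = int(z_range[0]), int(z_range[1])
    if not (0 <= z0 < z1 <= vol.shape[0]):
        raise ValueError(
            f"empty or out-of-bounds z_range [{z0}, {z1}) for depth {vol.shape[0]}"
        )
    return vol[z0:z1].max(axis=0)


# ---------------------------------------------------------------------------
# RoiSet
# ---------------------------------------------------------------------------


@dataclass
class CellRois:
    """Named polygon outlines for one cell.

    ``polygons`` maps a role (see :data:`ROI_ROLES`) to a shapely polygon.
    ``metadata`` records free-form provenance such as which fluorescence
    channel guided each outline.
    """

    cell_id: str
    polygons: dict[str, Polygon]
    embryo_id: str = ""
    condition: str = ""
    stage: str = ""
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, role: str) -> Polygon:
        return self.polygons[role]

    def get(self, role: str):
        return self.polygons.get(role)


@dataclass
class RoiSet:
    """A collection of per-cell outlines, validated on construction."""

    cells: list[CellRois] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def __iter__(self):
        return iter(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, cell_id: str) -> CellRois:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)

    def validate(self) -> None:
        seen: set[str] = set()
        for cell in self.cells:
            cid = cell.cell_id
            if cid in seen:
                raise RoiValidationError(f"duplicate cell_id {cid!r}")
            seen.add(cid)
            for role, poly in cell.polygons.items():
                if not isinstance(poly, Polygon) or poly.is_empty:
                    raise RoiValidationError(f"cell {cid!r}: {role} is not a polygon")
                if not (poly.is_valid and poly.is_simple):
                    raise RoiValidationError(
                        f"cell {cid!r}: {role} polygon is self-intersecting"
                    )
            total = cell.get("total")
            interior = cell.get("interior")
            nuclear = cell.get("nuclear")
            if total is not None and interior is not None:
                if not total.covers(interior):
                    raise RoiValidationError(
                        f"cell {cid!r}: interior outline not contained in total"
                    )
            if interior is not None and nuclear is not None:
                if not interior.covers(nuclear):
                    raise RoiValidationError(
                        f"cell {cid!r}: nuclear outline not contained in interior"
                    )


def _poly_to_coords(poly: Polygon) -> list[list[float]]:
    return [[float(x), float(y)] for x, y in list(poly.exterior.coords)[:-1]]


def write_rois(rois: RoiSet, path) -> None:
    """Write an ROI set to the package's JSON schema."""
    payload = {
        "schema": "seamfish-rois-v1",
        "cells": [
            {
                "cell_id": c.cell_id,
                "embryo_id": c.embryo_id,
                "condition": c.condition,
                "stage": c.stage,
                "metadata": c.metadata,
                "polygons": {r: _poly_to_coords(p) for r, p in c.polygons.items()},
            }
            for c in rois.cells
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_rois(path) -> RoiSet:
    """Read an ROI JSON file; an empty file yields an empty RoiSet."""
    with open(path) as fh:
        text = fh.read().strip()
    if not text:
        return RoiSet([])
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    cells = []
    for rec in payload.get("cells", []):
        polys = {
            role: Polygon([(float(x), float(y)) for x, y in coords])
            for role, coords in rec.get("polygons", {}).items()
        }
        cells.append(
            CellRois(
                cell_id=str(rec["cell_id"]),
                polygons=polys,
                embryo_id=str(rec.get("embryo_id", "")),
                condition=str(rec.get("condition", "")),
                stage=str(rec.get("stage", "")),
                metadata=rec.get("metadata", {}),
            )
        )
    return RoiSet(cells)


# ---------------------------------------------------------------------------
# Point-in-polygon helpers (boundary-inclusive)
# ---------------------------------------------------------------------------


def points_covered(poly: Polygon, xy: np.ndarray) -> np.ndarray:
    """Boolean mask of points ``(n, 2)`` as (x, y) covered by ``poly``.

    Boundary-inclusive: points exactly on an edge count as inside.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    pts = shapely.points(xy[:, 0], xy[:, 1])
    return shapely.covers(poly, pts)


def polygon_mask(poly: Polygon, shape_yx: tuple[int, int]) -> np.ndarray:
    """Rasterise a polygon over pixel centers to a boolean (y, x) mask."""
    ny, nx = shape_yx
    minx, miny, maxx, maxy = poly.bounds
    x0 = max(0, int(np.floor(minx)))
    x1 = min(nx - 1, int(np.ceil(maxx)))
    y0 = max(0, int(np.floor(miny)))
    y1 = min(ny - 1, int(np.ceil(maxy)))
    mask = np.zeros((ny, nx), dtype=bool)
    if x1 < x0 or y1 < y0:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = points_covered(poly, np.column_stack([xs.ravel(), ys.ravel()]))
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside.reshape(ys.shape)
    return mask


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "detection": {
        "log_sigma": 1.0,
        "threshold": None,  # None -> robust auto threshold (k_mad * MAD)
        "k_mad": 5.0,
        "min_separation": 3.0,
        "fit_window_factor": 4.0,
        "mode": "projection",  # or "3d"
    },
    "calibration": {"n_spots": 5, "metric": "amplitude", "scope": "image"},
    "quantify": {"interior_offset_px": 2.0, "fraction_mode": "standard",
                 "weighting": "units"},
    "profile": {"min_prominence_frac": 0.2, "min_separation_px": 3.0,
                "dna_threshold": None},
    "stats": {"whiskers": "tukey", "tails": 2},
    "seed": 0,
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Load a YAML/JSON config file merged over :data:`DEFAULT_CONFIG`."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return _deep_update(DEFAULT_CONFIG, user)


def warn_and_log(message: str) -> None:
    logger.warning(message)
    warnings.warn(message, stacklevel=3)
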