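"""End-to-end orchestration: stack → spots → units → compartment counts.

Thin glue over the module-level operations, shared by the CLI and the
test/acceptance harnesses.  Calibration scope defaults to per-image
(all cells of one embryo share a unit).
"""

from __future__ import annotations

import numpy as np

from .compartments import CompartmentCounts, assign_spots, counts_table, \
    offset_polygon_inward
from .io import ImageStack, RoiSet, max_project
from .spots import DetectionParams, SpotSet, UnitCalibration, calibrate_unit, \
    count_mrna, detect_spots


def ensure_interior_outlines(rois: RoiSet, offset_px: float) -> RoiSet:
    """Fill missing interior outlines by insetting each total outline.

    Cells that already carry an interior polygon are left untouched.
    """
    for cell in rois:
        if cell.get("interior") is None:
            cell.polygons["interior"] = offset_polygon_inward(
                cell["total"], offset_px
            )
    rois.validate()
    return rois


def detect_and_count(
    stack: ImageStack,
    channel="smFISH",
    det_params: DetectionParams | None = None,
    z_range=None,
    n_calibration_spots: int = 5,
    metric: str = "amplitude",
) -> tuple[SpotSet, UnitCalibration]:
    """Detect spots on the smFISH channel and convert them to mRNA units.

    Detection runs on the maximum-intensity projection over ``z_range``
    (full depth by default) unless ``det_params.mode == "3d"``.
    """
    if det_params is None:
        det_params = DetectionParams()
    if det_params.mode == "3d":
        image = stack.channel(channel)
    else:
        image = max_project(stack, channel, z_range)
    spots = detect_spots(image, det_params)
    cal = calibrate_unit(spots, n_spots=n_calibration_spots)
    spots = count_mrna(spots, cal, metric=metric)
    return spots, cal


def quantify_embryo(
    stack: ImageStack,
    rois: RoiSet,
    det_params: DetectionParams | None = None,
    interior_offset_px: float = 2.0,
    fraction_mode: str = "standard",
    weighting: str = "units",
    z_range=None,
    metric: str = "amplitude",
):
    """Full per-embryo quantification.

    Returns ``(table, counts, spots, calibration, unassigned_units)``
    where ``table`` is the long-format per-cell fraction table.
    """
    rois = ensure_interior_outlines(rois, interior_offset_px)
    spots, cal = detect_and_count(
        stack, det_params=det_params, z_range=z_range, metric=metric
    )
    counts, unassigned = assign_spots(spots, rois, weighting=weighting)
    table = counts_table(counts, mode=fraction_mode)
    return table, counts, spots, cal, unassigned


def conservation_ok(counts: list[CompartmentCounts]) -> bool:
    """Exact conservation check: membrane + interior = total and
    nuclear ≤ interior ≤ total for every cell."""
    return all(
        c.membrane + c.interior == c.total
        and 0 <= c.nuclear <= c.interior <= c.total
        for c in counts
    )
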