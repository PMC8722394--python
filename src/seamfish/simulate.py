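"""Synthetic seam-cell embryos with known spot ground truth.

The simulator emulates the imaging substrate of seam-cell smFISH
experiments at the bean/comma stage: a lateral row of polygonal
epithelial cells whose borders carry an apical-junction belt
(DLG-1::GFP and AJM-1 channels), a central nucleus (DAPI channel), and
diffraction-limited smFISH spots (mRNA channel) whose compartment
(membrane band / interior cytoplasm / nucleus) and per-spot mRNA
multiplicity are drawn from controlled distributions.  Spots are
rendered as 3D Gaussians at ``multiplicity x unit_amplitude`` peak
height over a constant background, with Poisson shot noise and additive
Gaussian read noise.

Every scene is fully determined by its :class:`SceneParams` (including
the seed), and every spot's true position, compartment and multiplicity
is recorded, so downstream detection, counting and localization stages
can be tested by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
import shapely
from shapely.geometry import Point, Polygon, box

from .io import DEFAULT_CHANNELS, CellRois, ImageStack, RoiSet, polygon_mask


class GeometryError(ValueError):
    """Scene geometry that cannot be constructed (e.g. nucleus too large)."""


@dataclass
class SceneParams:
    """Parameters of one simulated embryo.

    Geometric sizes are in pixels; intensities are on an arbitrary
    photon-like scale shared by ``unit_amplitude``, ``background_level``
    and the noise model.
    """

    n_cells: int = 5
    cell_width_px: int = 40
    cell_height_px: int = 60
    membrane_band_px: float = 2.0
    junction_belt_px: float = 2.0
    nucleus_radius_px: float = 8.0
    apical_band_px: float = 4.0
    n_spots_per_cell: int = 30
    membrane_fraction: float = 0.6
    nuclear_fraction: float = 0.1
    multiplicity_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.8, 2: 0.15, 4: 0.05}
    )
    unit_amplitude: float = 1000.0
    psf_sigma_px: tuple[float, float] = (2.0, 1.3)  # (axial z, lateral y/x)
    background_level: float = 20.0
    gaussian_noise_sd: float = 2.0
    poisson_noise: bool = True
    junction_amplitude: float = 300.0
    dapi_amplitude: float = 200.0
    n_z: int = 14
    margin_px: int = 10
    cell_gap_px: float = 1.0
    min_spot_separation_px: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("cell_width_px", "cell_height_px", "nucleus_radius_px",
                     "membrane_band_px", "junction_belt_px", "apical_band_px",
                     "n_z", "margin_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_spots_per_cell < 0:
            raise ValueError("n_spots_per_cell must be >= 0")
        if not 0.0 <= self.membrane_fraction <= 1.0:
            raise ValueError("membrane_fraction must be in [0, 1]")
        if not 0.0 <= self.nuclear_fraction <= 1.0:
            raise ValueError("nuclear_fraction must be in [0, 1]")
        if self.membrane_fraction + self.nuclear_fraction > 1.0 + 1e-12:
            raise ValueError("membrane_fraction + nuclear_fraction must be <= 1")
        probs = np.array(list(self.multiplicity_dist.values()), dtype=float)
        mults = list(self.multiplicity_dist.keys())
        if any((not float(m).is_integer()) or m < 1 for m in mults):
            raise ValueError("multiplicities must be positive integers")
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("multiplicity_dist must be a probability distribution")

    # -- derived geometry -------------------------------------------------

    @property
    def sigma_z(self) -> float:
        return float(self.psf_sigma_px[0])

    @property
    def sigma_xy(self) -> float:
        return float(self.psf_sigma_px[1])

    @property
    def image_shape(self) -> tuple[int, int, int]:
        """(n_z, n_y, n_x) of the rendered stack."""
        ny = self.cell_height_px + 2 * self.margin_px
        nx = int(
            np.ceil(
                self.n_cells * self.cell_width_px
                + (self.n_cells - 1) * self.cell_gap_px
                + 2 * self.margin_px
            )
        )
        return self.n_z, ny, nx

    def cell_bounds(self, i: int) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of cell ``i``'s border rectangle."""
        x0 = self.margin_px + i * (self.cell_width_px + self.cell_gap_px)
        return (
            x0,
            float(self.margin_px),
            x0 + self.cell_width_px,
            float(self.margin_px + self.cell_height_px),
        )

    def junction_x_positions(self) -> np.ndarray:
        """Ground-truth x coordinates of the rendered junction lines.

        ``n_cells`` cells in a row carry ``n_cells + 1`` junctions: the two
        outer borders plus one shared junction between each adjacent pair.
        Positions are the centerlines of the rendered belts: outer belts
        lie wholly inside the cell border (half a belt width in), and the
        two abutting belts of an interior junction blur into one peak
        centered on the gap.
        """
        half_belt = self.junction_belt_px / 2.0
        pos = [self.cell_bounds(0)[0] + half_belt]
        for i in range(self.n_cells - 1):
            pos.append(self.cell_bounds(i)[2] + self.cell_gap_px / 2.0)
        pos.append(self.cell_bounds(self.n_cells - 1)[2] - half_belt)
        return np.asarray(pos)


@dataclass
class SpotTruth:
    cell_id: str
    z: float
    y: float
    x: float
    compartment: str  # membrane | cytoplasm | nucleus
    multiplicity: int


@dataclass
class GroundTruth:
    """Per-spot labels and scene provenance for parameter-recovery tests."""

    spots: list[SpotTruth]
    junctions_x: np.ndarray
    seed: int
    params: SceneParams

    def positions(self) -> np.ndarray:
        """(n, 3) array of true (z, y, x) positions."""
        return np.array([[s.z, s.y, s.x] for s in self.spots]).reshape(-1, 3)

    def cell_unit_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.spots:
            out[s.cell_id] = out.get(s.cell_id, 0) + s.multiplicity
        return out

    def true_fractions(self) -> dict[str, dict[str, float]]:
        """Per-cell unit-weighted compartment fractions.

        membrane fraction = sum of multiplicities of membrane spots over
        the sum over all the cell's spots.
        """
        acc: dict[str, dict[str, float]] = {}
        for s in self.spots:
            d = acc.setdefault(
                s.cell_id, {"membrane": 0, "cytoplasm": 0, "nucleus": 0}
            )
            d[s.compartment] += s.multiplicity
        out = {}
        for cid, d in acc.items():
            total = d["membrane"] + d["cytoplasm"] + d["nucleus"]
            out[cid] = {
                "total_units": total,
                "membrane_fraction": d["membrane"] / total if total else np.nan,
                "nuclear_fraction": d["nucleus"] / total if total else np.nan,
            }
        return out


def classify_point(x: float, y: float, cell: CellRois) -> str | None:
    """Compartment label of a point against one cell's outlines.

    Containment chain semantics: nucleus before cytoplasm before
    membrane; ``None`` if outside the total outline.  Boundary-inclusive.
    """
    pt = Point(x, y)
    if not cell["total"].covers(pt):
        return None
    if "nuclear" in cell.polygons and cell["nuclear"].covers(pt):
        return "nucleus"
    if cell["interior"].covers(pt):
        return "cytoplasm"
    return "membrane"


def _cell_polygons(params: SceneParams, i: int) -> dict[str, Polygon]:
    x0, y0, x1, y1 = params.cell_bounds(i)
    w, h = x1 - x0, y1 - y0
    b = params.membrane_band_px
    if 2 * b >= min(w, h):
        raise GeometryError(
            f"cell_{i}: membrane band {b} px too wide for cell {w}x{h} px"
        )
    total = box(x0, y0, x1, y1)
    interior = box(x0 + b, y0 + b, x1 - b, y1 - b)
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    r = params.nucleus_radius_px
    if r + b >= min(w, h) / 2.0 - 1.0:
        raise GeometryError(
            f"cell_{i}: nucleus radius {r} px does not fit in cell {w}x{h} px"
        )
    nuclear = Point(cx, cy).buffer(r, quad_segs=16)
    apical = box(x0, y0, x1, y0 + params.apical_band_px)
    return {"total": total, "interior": interior, "nuclear": nuclear,
            "apical": apical}


def _profile_bands(params: SceneParams) -> dict[str, Polygon]:
    _, ny, nx = params.image_shape
    x_left = params.cell_bounds(0)[0] - 5.0
    x_right = params.cell_bounds(params.n_cells - 1)[2] + 5.0
    cy = params.margin_px + params.cell_height_px / 2.0
    half = 4.0
    apicobasal = box(x_left, cy - half, x_right, cy + half)
    y0 = float(params.margin_px)
    apical = box(x_left, y0, x_right, y0 + params.apical_band_px)
    return {"profile_band_apicobasal": apicobasal, "profile_band_apical": apical}


def _sample_in_region(rng, region_test, bounds, min_sep, placed, max_tries):
    """Rejection-sample one point: inside the region (vectorised batch
    test) and at least ``min_sep`` from every previously placed spot."""
    x0, y0, x1, y1 = bounds
    batch = 128
    arr = np.asarray(placed) if placed else None
    for _ in range(0, max_tries, batch):
        xs = rng.uniform(x0, x1, batch)
        ys = rng.uniform(y0, y1, batch)
        for i in np.nonzero(region_test(xs, ys))[0]:
            if min_sep > 0 and arr is not None:
                d2 = (arr[:, 0] - xs[i]) ** 2 + (arr[:, 1] - ys[i]) ** 2
                if (d2 < min_sep**2).any():
                    continue
            return float(xs[i]), float(ys[i])
    raise GeometryError(
        "could not place a spot satisfying the minimum separation; "
        "scene too dense for min_spot_separation_px"
    )


def generate_scene(
    params: SceneParams,
    embryo_id: str = "embryo_0",
    condition: str = "",
    stage: str = "bean",
) -> tuple[RoiSet, GroundTruth]:
    """Draw the scene geometry and the ground-truth spot set.

    Deterministic given ``params`` (including ``params.seed``).  Spots are
    kept at least 3 PSF sigma away from the lateral image border (cells
    are inset by ``margin_px``) and are separated pairwise by at least
    ``min_spot_separation_px`` so that rendered spots remain resolvable.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(0,)))
    bands = _profile_bands(params)
    mults = np.array(sorted(params.multiplicity_dist), dtype=int)
    probs = np.array([params.multiplicity_dist[int(m)] for m in mults])

    nz = params.n_z
    z_lo, z_hi = 3 * params.sigma_z, (nz - 1) - 3 * params.sigma_z
    if z_hi < z_lo:
        raise GeometryError("n_z too small for 3 sigma_z axial clearance")

    cells: list[CellRois] = []
    spots: list[SpotTruth] = []
    # separation is enforced scene-wide: spots of adjacent cells sit just
    # across the junction gap and would otherwise be unresolvable
    placed: list[tuple[float, float]] = []
    for i in range(params.n_cells):
        cid = f"cell_{i}"
        polys = _cell_polygons(params, i)
        polys.update(bands)
        cell = CellRois(
            cell_id=cid, polygons=polys, embryo_id=embryo_id,
            condition=condition, stage=stage,
            metadata={"outline_channel": "junction-GFP"},
        )
        cells.append(cell)

        total, interior, nuclear = polys["total"], polys["interior"], polys["nuclear"]

        def _covers(poly):
            return lambda xs, ys: shapely.covers(poly, shapely.points(xs, ys))

        in_total, in_interior, in_nuclear = map(_covers, (total, interior, nuclear))
        tests = {
            "membrane": lambda xs, ys: in_total(xs, ys) & ~in_interior(xs, ys),
            "nucleus": in_nuclear,
            "cytoplasm": lambda xs, ys: in_interior(xs, ys) & ~in_nuclear(xs, ys),
        }
        p_m, p_n = params.membrane_fraction, params.nuclear_fraction
        # sequential placement can jam locally in the narrow membrane
        # band; on failure the whole cell is re-placed from scratch
        for attempt in range(20):
            cell_spots: list[SpotTruth] = []
            cell_placed: list[tuple[float, float]] = []
            try:
                for _ in range(params.n_spots_per_cell):
                    u = rng.uniform()
                    target = "membrane" if u < p_m else (
                        "nucleus" if u < p_m + p_n else "cytoplasm"
                    )
                    x, y = _sample_in_region(
                        rng, tests[target], total.bounds,
                        params.min_spot_separation_px, placed + cell_placed,
                        max_tries=20000,
                    )
                    cell_placed.append((x, y))
                    label = classify_point(x, y, cell)
                    assert label == target  # sampling and classification agree
                    z = rng.uniform(z_lo, z_hi)
                    m = int(mults[rng.choice(len(mults), p=probs)])
                    cell_spots.append(SpotTruth(cid, z, y, x, label, m))
            except GeometryError:
                continue
            break
        else:
            raise GeometryError(
                f"{cid}: could not place {params.n_spots_per_cell} spots at "
                f"min separation {params.min_spot_separation_px} px; "
                "scene too dense"
            )
        placed.extend(cell_placed)
        spots.extend(cell_spots)

    truth = GroundTruth(
        spots=spots,
        junctions_x=params.junction_x_positions(),
        seed=params.seed,
        params=params,
    )
    return RoiSet(cells), truth


def _add_gaussian_3d(vol, z, y, x, amp, sz, sxy) -> None:
    nz, ny, nx = vol.shape
    rz, rxy = int(np.ceil(4 * sz)), int(np.ceil(4 * sxy))
    z0, z1 = max(0, int(z) - rz), min(nz, int(z) + rz + 1)
    y0, y1 = max(0, int(y) - rxy), min(ny, int(y) + rxy + 1)
    x0, x1 = max(0, int(x) - rxy), min(nx, int(x) + rxy + 1)
    gz = np.exp(-((np.arange(z0, z1) - z) ** 2) / (2 * sz**2))
    gy = np.exp(-((np.arange(y0, y1) - y) ** 2) / (2 * sxy**2))
    gx = np.exp(-((np.arange(x0, x1) - x) ** 2) / (2 * sxy**2))
    vol[z0:z1, y0:y1, x0:x1] += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def render_stack(rois: RoiSet, truth: GroundTruth, params: SceneParams) -> ImageStack:
    """Render the 4-channel stack for a generated scene.

    Channel order: 0 = smFISH mRNA, 1 = junction marker (DLG-1::GFP),
    2 = AJM-1 immunostain, 3 = DAPI.  Each smFISH spot is a 3D Gaussian
    of peak amplitude ``multiplicity x unit_amplitude``; the junction
    channels carry a belt of width ``junction_belt_px`` along each cell
    border; DAPI fills the nuclear discs.  Noise (Poisson on the signal,
    then additive Gaussian) is applied last, from its own seeded stream,
    so the noise-free image of a scene never depends on the noise flags.
    """
    params.validate()
    nz, ny, nx = params.image_shape
    if min(nz, ny, nx) <= 0:
        raise ValueError(f"non-positive image dimensions {(nz, ny, nx)}")
    vol = np.full((4, nz, ny, nx), float(params.background_level))

    for s in truth.spots:
        _add_gaussian_3d(
            vol[0], s.z, s.y, s.x,
            s.multiplicity * params.unit_amplitude,
            params.sigma_z, params.sigma_xy,
        )

    junction2d = np.zeros((ny, nx))
    dapi2d = np.zeros((ny, nx))
    for cell in rois:
        total = cell["total"]
        belt_inner = total.buffer(-params.junction_belt_px, join_style="mitre")
        band = polygon_mask(total, (ny, nx)) & ~polygon_mask(belt_inner, (ny, nx))
        junction2d[band] = params.junction_amplitude
        dapi2d[polygon_mask(cell["nuclear"], (ny, nx))] = params.dapi_amplitude
    junction2d = gaussian_filter(junction2d, params.sigma_xy)
    dapi2d = gaussian_filter(dapi2d, params.sigma_xy)
    vol[1] += junction2d[None]
    vol[2] += junction2d[None]
    vol[3] += dapi2d[None]

    if params.poisson_noise or params.gaussian_noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(params.seed, spawn_key=(1,))
        )
        if params.poisson_noise:
            vol = rng.poisson(vol).astype(float)
        if params.gaussian_noise_sd > 0:
            vol += rng.normal(0.0, params.gaussian_noise_sd, size=vol.shape)
        np.clip(vol, 0.0, None, out=vol)

    return ImageStack(vol, voxel_size=(0.3, 0.1, 0.1), channel_names=DEFAULT_CHANNELS)


def simulate_embryo(params: SceneParams, **scene_kwargs):
    """Generate and render one embryo: returns (stack, rois, truth)."""
    rois, truth = generate_scene(params, **scene_kwargs)
    stack = render_stack(rois, truth, params)
    return stack, rois, truth


def sample_cell_fractions(
    n_cells: int,
    n_spots: int,
    membrane_fraction: float,
    nuclear_fraction: float = 0.1,
    multiplicity_dist: dict[int, float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-cell unit-weighted membrane fractions from the scene's
    statistical model, without geometry or rendering.

    This is the fast path for power / type-I simulations: each cell draws
    ``n_spots`` compartments i.i.d. and a multiplicity per spot, exactly
    as :func:`generate_scene` does, and returns membrane units over total
    units per cell.
    """
    if rng is None:
        rng = np.random.default_rng()
    if multiplicity_dist is None:
        multiplicity_dist = {1: 0.8, 2: 0.15, 4: 0.05}
    mults = np.array(sorted(multiplicity_dist), dtype=float)
    probs = np.array([multiplicity_dist[int(m)] for m in mults])
    out = np.empty(n_cells)
    for c in range(n_cells):
        u = rng.uniform(size=n_spots)
        membrane = u < membrane_fraction
        m = mults[rng.choice(len(mults), size=n_spots, p=probs)]
        out[c] = m[membrane].sum() / m.sum()
    return out


# ---------------------------------------------------------------------------
# Ground-truth JSON round trip
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "seed": truth.seed,
        "junctions_x": [float(v) for v in truth.junctions_x],
        "params": {
            **asdict(truth.params),
            "multiplicity_dist": {
                str(k): v for k, v in truth.params.multiplicity_dist.items()
            },
            "psf_sigma_px": list(truth.params.psf_sigma_px),
        },
        "spots": [asdict(s) for s in truth.spots],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    p = payload["params"]
    p["multiplicity_dist"] = {int(k): v for k, v in p["multiplicity_dist"].items()}
    p["psf_sigma_px"] = tuple(p["psf_sigma_px"])
    params = SceneParams(**p)
    spots = [SpotTruth(**s) for s in payload["spots"]]
    return GroundTruth(
        spots=spots,
        junctions_x=np.asarray(payload["junctions_x"], dtype=float),
        seed=int(payload["seed"]),
        params=params,
    )
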