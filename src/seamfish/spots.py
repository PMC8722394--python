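"""smFISH spot detection, Gaussian amplitude fitting, and intensity-unit
mRNA counting.

The counting model follows the intensity-unit approach: after spots are
detected and their peak amplitudes fitted, the "unit" — the intensity of
a single mRNA — is calibrated as the mean amplitude of the five dimmest
retained spots, and every spot's amplitude is divided by that unit to
estimate how many mRNAs the dot contains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_laplace
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised when the single-mRNA unit cannot be calibrated."""


@dataclass
class DetectionParams:
    """Tunables for LoG detection and Gaussian refinement.

    ``threshold`` is an absolute cutoff on the scale-normalised LoG
    response; ``None`` selects a robust automatic threshold of
    ``k_mad`` times the MAD-estimated noise sd of the response.
    ``min_separation`` is the Euclidean merge radius on refined
    positions (the brighter spot of a closer pair is kept).
    """

    log_sigma: float = 1.0
    threshold: float | None = None
    k_mad: float = 5.0
    min_separation: float = 3.0
    fit_window_factor: float = 4.0
    sigma_bounds: tuple[float, float] = (0.4, 4.0)
    mode: str = "projection"  # how 3D inputs are handled: projection | 3d


@dataclass
class Spot:
    y: float
    x: float
    z: float | None = None
    amplitude: float = np.nan  # fitted peak height above background
    background: float = np.nan
    sigma: float = np.nan
    quality: float = np.nan  # RMS fit residual / amplitude
    units: int | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def ok_for_calibration(self) -> bool:
        return not self.flags and np.isfinite(self.amplitude) and self.amplitude > 0

    @property
    def integrated_intensity(self) -> float:
        """Volume under the fitted 2D Gaussian, above background."""
        return float(2.0 * np.pi * self.sigma**2 * self.amplitude)


@dataclass
class SpotSet:
    spots: list[Spot] = field(default_factory=list)

    def __iter__(self):
        return iter(self.spots)

    def __len__(self) -> int:
        return len(self.spots)

    def __getitem__(self, i):
        return self.spots[i]

    @property
    def retained(self) -> list[Spot]:
        return [s for s in self.spots if s.ok_for_calibration]

    def positions(self) -> np.ndarray:
        """(n, 2) array of (y, x) refined positions."""
        return np.array([[s.y, s.x] for s in self.spots]).reshape(-1, 2)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "y": [s.y for s in self.spots],
                "x": [s.x for s in self.spots],
                "z": [s.z if s.z is not None else np.nan for s in self.spots],
                "amplitude": [s.amplitude for s in self.spots],
                "background": [s.background for s in self.spots],
                "sigma": [s.sigma for s in self.spots],
                "quality": [s.quality for s in self.spots],
                "units": [s.units if s.units is not None else np.nan
                          for s in self.spots],
                "flags": [",".join(sorted(s.flags)) for s in self.spots],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpotSet":
        spots = []
        for rec in df.itertuples(index=False):
            spots.append(
                Spot(
                    y=float(rec.y), x=float(rec.x),
                    z=None if np.isnan(rec.z) else float(rec.z),
                    amplitude=float(rec.amplitude),
                    background=float(rec.background),
                    sigma=float(rec.sigma), quality=float(rec.quality),
                    units=None if np.isnan(rec.units) else int(rec.units),
                    flags=set(rec.flags.split(",")) if rec.flags else set(),
                )
            )
        return cls(spots)


@dataclass
class UnitCalibration:
    """The single-mRNA intensity unit.

    ``unit_amplitude`` is the mean fitted amplitude of the ``n_spots_used``
    dimmest retained spots; ``unit_integrated`` is the matching mean of
    their integrated intensities, for the integrated-intensity counting
    mode.
    """

    unit_amplitude: float
    unit_integrated: float
    n_spots_used: int = 5
    source: str = ""

    def __post_init__(self) -> None:
        if not self.unit_amplitude > 0:
            raise CalibrationError("unit_amplitude must be positive")


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def _gauss2d(coords, amp, y0, x0, sigma, offset):
    y, x = coords
    return (
        amp * np.exp(-(((y - y0) ** 2 + (x - x0) ** 2) / (2.0 * sigma**2))) + offset
    ).ravel()


def fit_amplitude(image: np.ndarray, y: int | float, x: int | float,
                  params: DetectionParams,
                  exclude_centers: np.ndarray | None = None) -> Spot:
    """Least-squares 2D Gaussian fit in a window around a candidate.

    The window half-size is ``fit_window_factor x log_sigma`` (default
    4 sigma).  When other candidate centers are supplied
    (``exclude_centers``, shape (k, 2) as (y, x)), window pixels closer
    to another candidate than to this one are excluded from the fit, so
    neighbouring spots inside the window cannot capture it.  A window
    clipped by the image edge flags the spot ``edge`` and excludes it
    from calibration; a non-convergent fit flags it ``fit_failed``.
    """
    ny, nx = image.shape
    r = int(np.ceil(params.fit_window_factor * params.log_sigma))
    yi, xi = int(round(y)), int(round(x))
    spot = Spot(y=float(y), x=float(x))
    if yi - r < 0 or xi - r < 0 or yi + r >= ny or xi + r >= nx:
        spot.flags.add("edge")
        return spot
    win = image[yi - r : yi + r + 1, xi - r : xi + r + 1].astype(float)
    yy, xx = np.mgrid[yi - r : yi + r + 1, xi - r : xi + r + 1]
    keep = np.ones(win.shape, dtype=bool)
    if exclude_centers is not None and len(exclude_centers):
        own = (yy - yi) ** 2 + (xx - xi) ** 2
        for cy, cx in exclude_centers:
            if (cy, cx) == (yi, xi):
                continue
            if abs(cy - yi) <= 2 * r and abs(cx - xi) <= 2 * r:
                keep &= own <= (yy - cy) ** 2 + (xx - cx) ** 2
    ys, xs, vals = yy[keep], xx[keep], win[keep]
    lo = float(vals.min())
    p0 = [max(float(vals.max()) - lo, 1e-6), float(yi), float(xi),
          params.log_sigma, lo]
    smin, smax = params.sigma_bounds
    # the center may move only ~1 px from its candidate maximum
    dr = 1.5
    bounds = (
        [0.0, yi - dr, xi - dr, smin, -np.inf],
        [np.inf, yi + dr, xi + dr, smax, np.inf],
    )
    try:
        popt, _ = curve_fit(
            _gauss2d, (ys, xs), vals.ravel(), p0=p0, bounds=bounds, maxfev=2000
        )
    except (RuntimeError, ValueError):
        logger.info("non-convergent Gaussian fit at (%.1f, %.1f); spot dropped", y, x)
        spot.flags.add("fit_failed")
        return spot
    amp, y0, x0, sigma, offset = popt
    resid = vals.ravel() - _gauss2d((ys, xs), *popt)
    spot.y, spot.x = float(y0), float(x0)
    spot.amplitude = float(amp)
    spot.background = float(offset)
    spot.sigma = float(sigma)
    spot.quality = float(np.sqrt(np.mean(resid**2)) / max(amp, 1e-12))
    return spot


def _merge_close(spots: list[Spot], min_sep: float) -> list[Spot]:
    """Greedy brightest-first merge: drop any spot within ``min_sep`` of a
    brighter kept spot."""
    order = sorted(spots, key=lambda s: -(s.amplitude if np.isfinite(s.amplitude)
                                          else -np.inf))
    kept: list[Spot] = []
    for s in order:
        if any((s.y - k.y) ** 2 + (s.x - k.x) ** 2 < min_sep**2 for k in kept):
            continue
        kept.append(s)
    return sorted(kept, key=lambda s: (s.y, s.x))


def detect_spots(image: np.ndarray, params: DetectionParams | None = None) -> SpotSet:
    """Detect diffraction-limited spots in a 2D image or 3D volume.

    Candidates are local maxima of the scale-normalised negated
    Laplacian-of-Gaussian response above ``threshold``; each candidate is
    refined to subpixel position by a local Gaussian fit, then spots
    closer than ``min_separation`` are merged keeping the brighter.
    Deterministic.

    For 3D input the default ``mode="projection"`` detects on the
    maximum-intensity projection and assigns z by the brightest slice at
    the spot position; ``mode="3d"`` runs detection per the full volume.
    """
    if params is None:
        params = DetectionParams()
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")

    if image.ndim == 3:
        if params.mode == "3d":
            return _detect_spots_3d(image, params)
        proj = image.max(axis=0)
        spots = detect_spots(proj, params)
        for s in spots:
            yi = int(np.clip(round(s.y), 0, image.shape[1] - 1))
            xi = int(np.clip(round(s.x), 0, image.shape[2] - 1))
            s.z = float(np.argmax(image[:, yi, xi]))
        return spots
    if image.ndim != 2:
        raise ValueError(f"expected 2D or 3D image, got shape {image.shape}")

    if np.ptp(image) == 0:
        warnings.warn("zero-variance image: no spots detected", stacklevel=2)
        return SpotSet([])

    response = -gaussian_laplace(image, params.log_sigma) * params.log_sigma**2
    thr = params.threshold
    if thr is None:
        # robust noise estimate; the floor (0.1% of the peak response)
        # guards noiseless images whose MAD is numerical ripple
        mad = np.median(np.abs(response - np.median(response)))
        thr = max(params.k_mad * 1.4826 * mad, 1e-3 * response.max())
    coords = peak_local_max(
        response, min_distance=1, threshold_abs=thr, exclude_border=False
    )
    fitted = []
    for yi, xi in coords:
        s = fit_amplitude(image, yi, xi, params, exclude_centers=coords)
        if "fit_failed" in s.flags:
            continue
        if "edge" in s.flags:
            # keep position and LoG response as a crude amplitude proxy,
            # flagged out of calibration
            s.amplitude = float(response[yi, xi])
            fitted.append(s)
            continue
        if s.amplitude <= 0:
            continue
        fitted.append(s)
    return SpotSet(_merge_close(fitted, params.min_separation))


def _detect_spots_3d(volume: np.ndarray, params: DetectionParams) -> SpotSet:
    """Full-3D detection: 3D LoG maxima, refined laterally on the local
    best slice with axial center-of-mass refinement."""
    sz = max(params.log_sigma / 2.0, 0.5)
    response = (
        -gaussian_laplace(volume, (sz, params.log_sigma, params.log_sigma))
        * params.log_sigma**2
    )
    thr = params.threshold
    if thr is None:
        mad = np.median(np.abs(response - np.median(response)))
        thr = max(params.k_mad * 1.4826 * mad, 1e-3 * response.max())
    coords = peak_local_max(
        response, min_distance=1, threshold_abs=thr, exclude_border=False
    )
    fitted = []
    nz = volume.shape[0]
    for zi, yi, xi in coords:
        s = fit_amplitude(volume[zi], yi, xi, params)
        if "fit_failed" in s.flags or ("edge" not in s.flags and s.amplitude <= 0):
            continue
        z0, z1 = max(0, zi - 2), min(nz, zi + 3)
        prof = volume[z0:z1, yi, xi] - volume[z0:z1, yi, xi].min()
        s.z = float((np.arange(z0, z1) * prof).sum() / prof.sum()) if prof.sum() else float(zi)
        fitted.append(s)
    return SpotSet(_merge_close(fitted, params.min_separation))


# ---------------------------------------------------------------------------
# Unit calibration and counting
# ---------------------------------------------------------------------------


def calibrate_unit(
    spots: SpotSet, n_spots: int = 5, allow_fewer: bool = False, source: str = ""
) -> UnitCalibration:
    """Calibrate the single-mRNA unit from the dimmest retained spots.

    The unit is the arithmetic mean of the ``n_spots`` lowest fitted
    amplitudes ("lightest" dots read as dimmest, i.e. single mRNAs).
    """
    retained = sorted(spots.retained, key=lambda s: s.amplitude)
    if len(retained) < n_spots:
        if not allow_fewer or not retained:
            raise CalibrationError(
                f"need >= {n_spots} retained spots to calibrate, have {len(retained)}"
            )
        logger.warning(
            "calibrating from %d spots instead of %d (allow_fewer)",
            len(retained), n_spots,
        )
        n_spots = len(retained)
    dimmest = retained[:n_spots]
    return UnitCalibration(
        unit_amplitude=float(np.mean([s.amplitude for s in dimmest])),
        unit_integrated=float(np.mean([s.integrated_intensity for s in dimmest])),
        n_spots_used=n_spots,
        source=source,
    )


def count_mrna(
    spots: SpotSet, cal: UnitCalibration, metric: str = "amplitude"
) -> SpotSet:
    """Fill ``units`` on each retained spot by dividing its intensity by
    the calibrated unit.

    Rounding is half-up to the nearest integer with a floor of one: a
    detected, retained dot represents at least one mRNA.  ``metric`` may
    be ``"amplitude"`` (fitted peak height, default) or ``"integrated"``
    (volume under the fitted Gaussian).
    """
    if metric == "amplitude":
        unit = cal.unit_amplitude
        value = lambda s: s.amplitude  # noqa: E731
    elif metric == "integrated":
        unit = cal.unit_integrated
        value = lambda s: s.integrated_intensity  # noqa: E731
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if not unit > 0:
        raise CalibrationError("non-positive unit intensity")
    out = []
    for s in spots:
        units = None
        if np.isfinite(s.amplitude) and s.amplitude > 0:
            units = max(1, int(np.floor(value(s) / unit + 0.5)))
        out.append(replace(s, flags=set(s.flags), units=units))
    return SpotSet(out)
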