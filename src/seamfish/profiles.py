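"""Apicobasal/apical intensity profiles, nuclear-signal eviction, and
junction localization from AJM-1 intensity peaks.

A profile is taken over a rectangular-ish band polygon: for each 1 px
bin along the band's axis, each channel's mean intensity over the band
pixels falling in that bin.  Nuclear bins (DNA channel above threshold)
are *evicted* from the mRNA channel — marked missing, never zeroed — so
transcription-site signal cannot masquerade as localized mRNA and peak
finding cannot hallucinate edges at span boundaries.  Junctions (CeAJ)
are the prominent peaks of the AJM-1 trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .io import ImageStack, polygon_mask


@dataclass
class PeakParams:
    """Peak-calling tunables: prominence relative to the trace maximum,
    and minimum peak separation in bins."""

    min_prominence_frac: float = 0.2
    min_separation_px: float = 3.0


@dataclass
class ProfileTrace:
    """Per-channel intensity samples along a band axis.

    ``positions`` are bin centers in pixel coordinates along the axis;
    ``channels`` maps channel name to a same-length intensity array
    (NaN marks evicted/empty bins); ``nuclear_spans`` are closed bin
    intervals ``(start_position, end_position)`` flagged as nuclear.
    """

    positions: np.ndarray
    channels: dict[str, np.ndarray]
    axis: str = "x"
    nuclear_spans: list[tuple[float, float]] = field(default_factory=list)
    junction_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.positions)
        for name, arr in self.channels.items():
            if len(arr) != n:
                raise ValueError(f"channel {name!r} length {len(arr)} != {n}")

    def copy(self) -> "ProfileTrace":
        return replace(
            self,
            positions=self.positions.copy(),
            channels={k: v.copy() for k, v in self.channels.items()},
            nuclear_spans=list(self.nuclear_spans),
            junction_positions=None if self.junction_positions is None
            else self.junction_positions.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"position": self.positions})
        for name, arr in self.channels.items():
            df[name] = arr
        in_span = np.zeros(len(self.positions), dtype=bool)
        for lo, hi in self.nuclear_spans:
            in_span |= (self.positions >= lo) & (self.positions <= hi)
        df["nuclear_span"] = in_span
        return df


def extract_band_profile(
    image: np.ndarray | ImageStack,
    band_polygon,
    axis: str = "x",
    channel_names=None,
    z_range=None,
) -> ProfileTrace:
    """Mean per-channel intensity per 1 px axial bin across a band.

    ``image`` is a ``(channels, y, x)`` array or an :class:`ImageStack`
    (maximum-projected over ``z_range`` per channel).  Bins of the
    band's bounding range that contain no band pixels are NaN.
    """
    if isinstance(image, ImageStack):
        from .io import max_project

        arr = np.stack(
            [max_project(image, c, z_range) for c in range(image.n_channels)]
        )
        if channel_names is None:
            channel_names = image.channel_names
    else:
        arr = np.asarray(image, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
    if channel_names is None:
        channel_names = [f"channel_{i}" for i in range(arr.shape[0])]
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")

    mask = polygon_mask(band_polygon, arr.shape[1:])
    if not mask.any():
        raise ValueError("band polygon covers no pixels of the image")
    ys, xs = np.nonzero(mask)
    along = xs if axis == "x" else ys
    lo, hi = int(along.min()), int(along.max())
    if lo == hi:
        raise ValueError("zero-width band along the requested axis")
    positions = np.arange(lo, hi + 1, dtype=float)
    channels = {}
    for ci, name in enumerate(channel_names):
        vals = arr[ci][ys, xs]
        sums = np.bincount(along - lo, weights=vals, minlength=len(positions))
        npix = np.bincount(along - lo, minlength=len(positions))
        with np.errstate(invalid="ignore"):
            channels[name] = np.where(npix > 0, sums / np.maximum(npix, 1), np.nan)
    return ProfileTrace(positions=positions, channels=channels, axis=axis)


def evict_nuclear_signal(
    trace: ProfileTrace,
    dna_threshold: float | None = None,
    dna_channel: str = "DAPI",
    mrna_channel: str = "smFISH",
    dilate_bins: int = 1,
) -> ProfileTrace:
    """Mask the mRNA channel wherever the DNA channel exceeds threshold.

    ``dna_threshold=None`` uses Otsu's threshold on the DNA trace.
    Thresholded spans are dilated by ``dilate_bins`` (default one bin,
    about one PSF sigma) so that eviction stays conservative: PSF
    blurring softens the nuclear boundary and the un-dilated crossing
    sits slightly inside the true nucleus.  Evicted bins become NaN in
    the mRNA channel only; the DNA trace is untouched, which makes the
    operation idempotent.
    """
    if dna_channel not in trace.channels:
        raise KeyError(f"trace has no {dna_channel!r} channel")
    dna = trace.channels[dna_channel]
    if dna_threshold is None:
        finite = dna[np.isfinite(dna)]
        if finite.size == 0 or np.ptp(finite) == 0:
            return trace.copy()
        dna_threshold = float(threshold_otsu(finite))
    if dna_threshold <= 0:
        raise ValueError("dna_threshold must be positive")

    out = trace.copy()
    above = np.isfinite(dna) & (dna > dna_threshold)
    if dilate_bins > 0 and above.any():
        above = binary_dilation(above, iterations=int(dilate_bins))
    out.channels[mrna_channel] = np.where(above, np.nan, out.channels[mrna_channel])
    spans: list[tuple[float, float]] = []
    i = 0
    pos = trace.positions
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            spans.append((float(pos[i]), float(pos[j])))
            i = j + 1
        else:
            i += 1
    out.nuclear_spans = spans
    return out


def normalize_per_trace(trace: ProfileTrace) -> ProfileTrace:
    """Min-max scale each channel to [0, 1] over the whole trace.

    The raw-intensity trace is the primary output; this per-trace
    variant eases overlaying channels of very different brightness.
    NaN (evicted/empty) bins stay NaN; a constant channel maps to 0.
    """
    out = trace.copy()
    for name, arr in out.channels.items():
        finite = arr[np.isfinite(arr)]
        if finite.size == 0:
            continue
        lo, hi = finite.min(), finite.max()
        out.channels[name] = (arr - lo) / (hi - lo) if hi > lo else arr - lo
    return out


def _refine_parabolic(y: np.ndarray, i: int) -> float:
    """Subpixel peak offset from a 3-point parabola through ``i``."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0 or not np.isfinite(denom):
        return 0.0
    return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))


def _find_channel_peaks(values: np.ndarray, positions: np.ndarray,
                        params: PeakParams) -> np.ndarray:
    """Prominence/separation-filtered local maxima of one channel, NaN-
    tolerant (NaN bins cannot be peaks), subpixel-refined, boundary
    maxima included."""
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size == 0 or np.ptp(finite) == 0:
        warnings.warn("flat or empty trace: no peaks", stacklevel=3)
        return np.array([])
    vmin, vmax = finite.min(), finite.max()
    filled = np.where(np.isfinite(v), v, vmin)
    # pad with the minimum so maxima at the trace ends are still peaks
    padded = np.concatenate([[vmin], filled, [vmin]])
    prominence = params.min_prominence_frac * (vmax - vmin)
    idx, _ = find_peaks(
        padded,
        prominence=max(prominence, np.finfo(float).eps),
        distance=max(1, int(round(params.min_separation_px))),
    )
    idx = idx - 1
    idx = idx[(idx >= 0) & (idx < len(v))]
    step = positions[1] - positions[0] if len(positions) > 1 else 1.0
    return np.array(
        [positions[i] + _refine_parabolic(filled, i) * step for i in idx]
    )


def locate_junctions(
    trace: ProfileTrace,
    peak_params: PeakParams | None = None,
    channel: str = "AJM-1",
) -> np.ndarray:
    """CeAJ positions: prominent peaks of the AJM-1 intensity trace.

    Prominence is relative to the trace's dynamic range, so junction
    calls are invariant under uniform intensity scaling.  A flat trace
    yields an empty list with a warning.  The called positions are also
    stored on the trace (``junction_positions``).
    """
    if peak_params is None:
        peak_params = PeakParams()
    if channel not in trace.channels:
        raise KeyError(f"trace has no {channel!r} channel")
    pos = _find_channel_peaks(trace.channels[channel], trace.positions, peak_params)
    trace.junction_positions = pos
    return pos


def peak_overlap_summary(
    trace: ProfileTrace,
    tol_px: float,
    peak_params: PeakParams | None = None,
    mrna_channel: str = "smFISH",
    protein_channel: str = "junction-GFP",
) -> dict:
    """Fraction of mRNA (and protein) peaks within ``tol_px`` of a called
    junction.

    Requires junctions to have been called on the trace.  A channel with
    no peaks reports ``None`` for its fraction.
    """
    if trace.junction_positions is None:
        raise ValueError("call locate_junctions before peak_overlap_summary")
    if peak_params is None:
        peak_params = PeakParams()
    junctions = np.asarray(trace.junction_positions, dtype=float)

    def frac_near(channel: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            peaks = _find_channel_peaks(
                trace.channels[channel], trace.positions, peak_params
            )
        if peaks.size == 0:
            return None, 0
        if junctions.size == 0:
            return 0.0, int(peaks.size)
        dmin = np.abs(peaks[:, None] - junctions[None, :]).min(axis=1)
        return float((dmin <= tol_px).mean()), int(peaks.size)

    mrna_frac, n_mrna = frac_near(mrna_channel)
    prot_frac, n_prot = frac_near(protein_channel)
    return {
        "mrna_peak_overlap": mrna_frac,
        "n_mrna_peaks": n_mrna,
        "protein_peak_overlap": prot_frac,
        "n_protein_peaks": n_prot,
        "n_junctions": int(junctions.size),
        "tol_px": float(tol_px),
    }
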