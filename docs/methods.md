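# Methods

This note documents the models, conventions, parameter choices and
known limitations of the `seamfish` pipeline and its synthetic-embryo
simulator.

## Coordinate and geometry conventions

Voxel arrays are `(channel, z, y, x)`, 0-based; z ranges are half-open
`[z0, z1)` to match array slicing. Polygon vertices are `(x, y)` pixel
coordinates, pixel centers at integers. Point-in-polygon tests are
boundary-inclusive everywhere (shapely `covers`): a spot sitting exactly
on a drawn outline counts as inside it. The interior offset uses a
mitred negative buffer, so a rectangle inset by *d* is exactly the
rectangle shrunk by *d* on each side; an offset at or beyond the
inradius is a hard error rather than a silently empty polygon.

ROIs are stored in a transparent JSON schema (`seamfish-rois-v1`): per
cell, a role→vertex-list map plus embryo/condition/stage labels and
free-form metadata (e.g. which channel guided an outline). Containment
invariants (interior ⊂ total, nuclear ⊂ interior, polygons simple) are
enforced at load time. Images are OME-TIFF with channel names and voxel
size recorded; structurally damaged files fail loudly instead of
returning partial data.

## The synthetic embryo

The simulator emulates the measurement substrate of bean/comma-stage
seam-cell smFISH imaging: a lateral row of rectangular cells (1 px gap
between neighbours, standing in for the shared junction), each with

* a membrane band of configurable width inside the border — the
  operational "membrane" compartment (default 2 px; the class is
  defined by proximity to the lateral membrane, not by a biophysical
  boundary);
* a junction belt along the border rendered into both junction-marker
  channels (DLG-1::GFP and AJM-1);
* a centred nuclear disc (DAPI channel);
* smFISH spots rendered as 3D Gaussians of peak amplitude
  multiplicity × `unit_amplitude` over a constant background.

Spot compartments are drawn i.i.d. (membrane / nucleus / remainder
cytoplasm) with configurable probabilities, and per-spot multiplicity
from a discrete distribution, default P(1)=0.8, P(2)=0.15, P(4)=0.05 —
enough singletons that the dimmest-five unit calibration is well posed.
Noise is Poisson on the signal plus additive Gaussian read noise
(sd 2), applied last and clipped at zero.

Default photometry: background 20, single-mRNA peak amplitude 1000
(peak SNR ≈ 30, appropriate for bright probe sets), lateral PSF sigma
1.3 px, axial sigma 2.0 px at a 0.3 µm z-step (axial FWHM ≈ 1.4 µm,
typical confocal axial resolution). With quantification on maximum
projections, a narrow axial PSF would make the projected peak depend
strongly on the spot's subpixel z position; the realistic axial width
keeps that projection loss below ~2%.

Spots keep a minimum pairwise separation (default 5 px, scene-wide, so
spots of adjacent cells just across the junction gap are included) and
stay 3σ clear of image borders and stack ends. The separation reflects
what single-spot counting can resolve at this PSF; real tissues contain
genuinely overlapping dots, which this generator deliberately does not
model (the unit-division step, not detection, is the method's answer
to those). Placement is rejection sampling with whole-cell restarts if
the narrow membrane band jams locally.

Determinism: one `SeedSequence` per scene with two child streams —
geometry/spot placement and rendering noise — so re-rendering the same
scene with noise on or off never changes spot positions. Identical
`SceneParams` give bit-identical scenes, ground truth and stacks.

Ground-truth labels are re-derived from the placed position against the
cell's polygons with the same boundary-inclusive predicate used by
compartment assignment, so simulator and pipeline share one geometry by
construction.

## Spot detection and fitting

Candidates are local maxima of the scale-normalised negated LoG
response. The filter sigma (default 1.0 px) is chosen slightly below
the PSF sigma: the response width is √(σ_psf² + σ_log²), and a matched
filter would merge spot pairs below ~3.7 px, whereas the narrower
filter resolves pairs down to ~3 px at these SNRs. The detection
threshold defaults to 5× the MAD-estimated noise sd of the response,
with a floor of 0.1% of the peak response to guard noiseless images;
an absolute threshold can be configured instead.

Each candidate is refined by least-squares 2D Gaussian fit in a window
of half-size 4σ. Window pixels closer to another candidate than to this
one are excluded from the fit (a Voronoi mask), and the fitted center is
bounded to ±1.5 px of its candidate maximum — without these, a
neighbouring spot inside the window captures the fit and two resolved
spots collapse onto their midpoint. Edge-clipped windows flag the spot
and exclude it from calibration; non-convergent fits drop the spot with
a log entry. Refined spots closer than the minimum separation (default
3 px) are merged keeping the brighter.

Detection runs on maximum-intensity projections by default (the
top-view seam-cell workflow); a full-3D mode (3D LoG, axial
center-of-mass refinement) is available behind a flag.

## Unit calibration and counting

"Lightest" is read as dimmest: the unit is the arithmetic mean of the
five lowest fitted amplitudes among retained spots, per image (all
cells of an embryo share a unit; per-cell scope is configurable). Units
per dot are amplitude/unit rounded half-up with a floor of one — a
detected, retained dot is at least one mRNA. An integrated-intensity
mode (Gaussian volume instead of peak height) is provided but
non-default.

The dimmest-five estimator is intentionally order-statistic biased low
(by roughly two fit-noise standard deviations); at the default SNR this
keeps the calibrated unit within ~10% of truth, and the bias largely
cancels in the unit division since all dots share it.

## Compartment assignment

Counts are unit-weighted sums over boundary-inclusive point-in-polygon
membership per cell (a raw dot-count mode exists for sensitivity
analysis). Membrane is always `total − interior`, never measured;
nuclear spots propagate down the containment chain (nuclear ⊆ interior
⊆ total), which makes the conservation identity exact by construction.
A spot covered by two cells' total outlines is a hard error (outlines
must not overlap); spots outside every cell accumulate in an
"unassigned" bucket. The interior-offset distance is a config parameter
(default 2 px, matching the simulator's membrane band; no drawn-offset
distance is canonical). Fraction modes: `standard` (membrane/total,
default), `txn_corrected` (membrane/(total−nuclear), for strong
transcription-site signal; it overestimates localization and must be
selected explicitly), `apical` (apical/total).

## Profiles, eviction, junctions

A band profile is the per-1 px-bin mean of each channel over the band's
pixels. Nuclear eviction thresholds the DNA trace (Otsu by default),
dilates the thresholded spans by one bin to compensate the PSF's
softening of the nuclear boundary (the un-dilated crossing sits
slightly inside the true nucleus), and sets the mRNA channel to NaN
there — missing, not zero, so downstream peak finding cannot
hallucinate edges at span boundaries. The DNA trace itself is never
modified, which makes eviction idempotent.

Junctions are peaks of the AJM-1 trace with prominence ≥ 20% of the
trace's dynamic range and minimum separation 3 px (both configurable;
relative prominence makes calls invariant under uniform intensity
scaling). Trace-end maxima are eligible (the trace is padded with its
minimum), and positions are refined by 3-point parabolic interpolation.
Peak-overlap summaries report the fraction of mRNA (and protein) peaks
within a tolerance of a called junction, with `None` when a channel has
no peaks.

## Statistics

Welch's unequal-variance t-test is the default comparison — the
original analyses specify only "t-test" computed in R, whose default is
Welch — with the statistic and Welch–Satterthwaite df computed in
closed form and one-tailed p in the caller-specified direction. Both
groups constant and equal gives t=0, p=1 by convention. Quartiles use
linear interpolation; whiskers default to Tukey 1.5×IQR (the ggplot2
default behind the original plots) with a min/max option. Stars:
p<0.05 \*, p<0.01 \*\*, p<0.001 \*\*\*, strict inequalities. The unit
of analysis is the cell; embryo-level aggregation is available but not
default. No multiple-testing correction is applied.

## Validation studies and problem sizes

The canonical studies in `seamfish.experiments` (run by the test suite
and `scripts/acceptance.py`):

* **Spot recovery** — three default embryos (15 cells, ~450 spots):
  matching within 1 px, recall/precision, calibration and count errors.
* **Fraction recovery** — conditions with true membrane fractions
  0.25/0.60/0.80; 25 cells per condition as 5 embryos × 5 cells with
  200 spots per cell. These scenes use large cells (160×200 px), an
  8 px membrane band with the matching interior offset, and 4 px
  minimum spot spacing: 160 membrane spots must remain individually
  resolvable along the cell perimeter, which fixes the band capacity.
  Recovered condition means are judged against the central 95% interval
  of a *single cell's* true fraction (Monte-Carlo over the generator's
  own compartment/multiplicity model) and must order strictly.
* **Profile study** — three 3-cell scenes (60×80 px cells, 12 px
  nuclei): junction-call error vs the rendered belt centerlines, and
  eviction coverage of the true nuclear projections.
* **Power study** — 200 replicates of 25-cell conditions drawn from the
  generator's statistical model without rendering (the geometric and
  statistical samplers agree by construction; a test asserts it):
  one-tailed power at p<0.001 for 75% vs 30% localization, and
  null-vs-null type-I rate at α=0.05.

## What passing these tests does and does not show

The simulator reproduces the *geometry and bookkeeping* of the analysis
— compartment definitions, unit arithmetic, profile conventions — under
a simplified optical model (Gaussian PSF, Poisson+Gaussian noise, flat
background, rectangular cells, no aberrations, bleaching, curvature,
deconvolution artifacts, or genuinely overlapping dots). Recovery on
these scenes validates the implementation, not the biology: it shows
the pipeline measures what it claims to measure when its assumptions
hold, and says nothing about probe efficiency, segmentation quality or
outline-drawing variability in real micrographs. Published values from
real embryos depend on those real images and are not reproduced here.

## Known limitations

* Detection assumes isolated diffraction-limited dots; dense clusters
  beyond the unit-division model (e.g. transcription-site decomposition)
  are out of scope.
* The ROI schema is bespoke JSON; ImageJ `.roi` import is not provided.
* Automated outline extraction from the junction channel is a
  convenience in the simulator, not a segmentation method.
* Profile intensities are reported raw; per-trace normalization is
  available, per-cell normalization is not attempted since the original
  convention is not recoverable.
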