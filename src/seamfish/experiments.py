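"""Canonical simulation studies used to validate the pipeline.

Each experiment builds its scenes from :class:`~seamfish.simulate.SceneParams`,
runs the full pipeline on the rendered images, and returns recovery
metrics against the generator's ground truth.  The configurations are
the package's study conditions (documented in the methods note):

* ``spot_recovery`` — default sparse bean-stage scenes: detection
  recall/precision, subpixel position error, unit-calibration and
  per-cell count recovery.
* ``fraction_recovery`` — three conditions with true membrane fractions
  0.25 / 0.60 / 0.80, 25 cells each (5 embryos x 5 cells, 200 spots per
  cell in large seam cells), mirroring a construct-series comparison of
  strongly, moderately and weakly localized mRNAs.
* ``profile_study`` — 3-cell scenes for junction calling and nuclear
  eviction.
* ``power_study`` — statistical power and type-I error of the per-cell
  Welch test design (n = 25 cells per condition).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .evaluate import match_spots, per_cell_unit_errors
from .pipeline import quantify_embryo
from .profiles import evict_nuclear_signal, extract_band_profile, locate_junctions
from .simulate import SceneParams, sample_cell_fractions, simulate_embryo
from .stats import t_test

#: large-cell, high-expression scene for localization-fraction recovery:
#: 200 spots per cell need a wide membrane band and large perimeter to
#: stay individually resolvable (minimum spot spacing 4 px)
DENSE_SCENE = dict(
    n_cells=5,
    cell_width_px=160,
    cell_height_px=200,
    membrane_band_px=8.0,
    nucleus_radius_px=25.0,
    n_spots_per_cell=200,
    nuclear_fraction=0.1,
    min_spot_separation_px=4.0,
)

#: 3-cell scene for intensity-profile analyses (three contiguous cells)
PROFILE_SCENE = dict(
    n_cells=3,
    cell_width_px=60,
    cell_height_px=80,
    nucleus_radius_px=12.0,
    n_spots_per_cell=40,
    membrane_fraction=0.7,
)


def _seed_stream(seed: int):
    """Child seeds (< 2**31) derived from one master seed."""
    rng = np.random.default_rng(seed)
    while True:
        yield int(rng.integers(0, 2**31 - 1))


def spot_recovery(seed: int = 0, n_embryos: int = 3) -> dict:
    """Detection, calibration and counting recovery on default scenes."""
    seeds = _seed_stream(seed)
    recalls, precisions, errors, unit_errs, count_errs = [], [], [], [], []
    for _ in range(n_embryos):
        params = SceneParams(seed=next(seeds))
        stack, rois, truth = simulate_embryo(params)
        table, counts, spots, cal, _ = quantify_embryo(
            stack, rois, interior_offset_px=params.membrane_band_px
        )
        m = match_spots(spots, truth, tol_px=1.0)
        recalls.append(m.recall)
        precisions.append(m.precision)
        errors.extend(m.position_errors)
        unit_errs.append(
            abs(cal.unit_amplitude - params.unit_amplitude) / params.unit_amplitude
        )
        count_errs.extend(
            per_cell_unit_errors({c.cell_id: c.total for c in counts}, truth)
        )
    errors = np.asarray(errors)
    return {
        "recall": float(np.mean(recalls)),
        "precision": float(np.mean(precisions)),
        "position_rmse_px": float(np.sqrt(np.mean(errors**2))),
        "position_max_px": float(errors.max()),
        "unit_calibration_rel_error": float(np.mean(unit_errs)),
        "count_median_rel_error": float(np.median(count_errs)),
        "n_cells": n_embryos * 5,
    }


def fraction_recovery(
    seed: int = 0,
    true_fractions=(0.25, 0.60, 0.80),
    n_embryos: int = 5,
) -> pd.DataFrame:
    """Per-cell estimated vs true membrane fractions for several
    conditions.

    Returns a long table with one row per cell: condition label, true
    per-cell fraction (multiplicity-weighted ground truth) and the
    pipeline's estimate, both as percentages.
    """
    seeds = _seed_stream(seed)
    rows = []
    for p_true in true_fractions:
        label = f"p{int(round(100 * p_true)):02d}"
        for e in range(n_embryos):
            params = SceneParams(
                seed=next(seeds), membrane_fraction=p_true, **DENSE_SCENE
            )
            stack, rois, truth = simulate_embryo(
                params, embryo_id=f"{label}_embryo_{e}", condition=label
            )
            table, counts, spots, cal, _ = quantify_embryo(
                stack, rois, interior_offset_px=params.membrane_band_px
            )
            tf = truth.true_fractions()
            for _, rec in table.iterrows():
                rows.append(
                    {
                        "condition": label,
                        "true_fraction": p_true,
                        "embryo_id": rec["embryo_id"],
                        "cell_id": rec["cell_id"],
                        "stage": rec["stage"],
                        "mode": rec["mode"],
                        "cell_true_percent": 100.0
                        * tf[rec["cell_id"]]["membrane_fraction"],
                        "fraction_percent": rec["fraction_percent"],
                    }
                )
    return pd.DataFrame(rows)


def profile_study(seed: int = 0, n_scenes: int = 3) -> dict:
    """Junction-call accuracy and nuclear-eviction coverage."""
    seeds = _seed_stream(seed)
    junction_errors, coverages = [], []
    for _ in range(n_scenes):
        params = SceneParams(seed=next(seeds), **PROFILE_SCENE)
        stack, rois, truth = simulate_embryo(params)
        trace = extract_band_profile(
            stack, rois.cells[0]["profile_band_apicobasal"]
        )
        trace = evict_nuclear_signal(trace)
        called = locate_junctions(trace)
        true_j = truth.junctions_x
        if len(called) != len(true_j):
            junction_errors.append(np.inf)
        else:
            junction_errors.extend(np.abs(np.sort(called) - np.sort(true_j)))
        pos = trace.positions
        covered = np.zeros(len(pos), dtype=bool)
        for lo, hi in trace.nuclear_spans:
            covered |= (pos >= lo) & (pos <= hi)
        true_nuclear = np.zeros(len(pos), dtype=bool)
        for cell in rois:
            b = cell["nuclear"].bounds
            true_nuclear |= (pos >= b[0]) & (pos <= b[2])
        coverages.append(float(covered[true_nuclear].mean()))
    return {
        "junction_max_error_px": float(np.max(junction_errors)),
        "nuclear_eviction_coverage": float(np.mean(coverages)),
        "n_scenes": n_scenes,
    }


def power_study(
    seed: int = 0,
    n_replicates: int = 200,
    n_cells: int = 25,
    n_spots: int = 200,
    p_localized: float = 0.75,
    p_unlocalized: float = 0.30,
    alpha_power: float = 0.001,
    alpha_type1: float = 0.05,
) -> dict:
    """Power and type-I error of the one-tailed per-cell Welch design.

    Power: fraction of replicates where localized (p=0.75) vs
    unlocalized (p=0.30) at 25 cells per group gives one-tailed
    p < 0.001.  Type-I: fraction of null-vs-null replicates (both groups
    at the same fraction) with p < 0.05.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        a = sample_cell_fractions(n_cells, n_spots, p_localized, rng=rng)
        b = sample_cell_fractions(n_cells, n_spots, p_unlocalized, rng=rng)
        _, _, p = t_test(100 * a, 100 * b, tails=1, direction="greater")
        hits += p < alpha_power
    false_pos = 0
    for _ in range(n_replicates):
        a = sample_cell_fractions(n_cells, n_spots, 0.5, rng=rng)
        b = sample_cell_fractions(n_cells, n_spots, 0.5, rng=rng)
        _, _, p = t_test(100 * a, 100 * b, tails=2)
        false_pos += p < alpha_type1
    return {
        "power": hits / n_replicates,
        "type_i_rate": false_pos / n_replicates,
        "n_replicates": n_replicates,
    }


def fraction_sampling_interval(
    p_true: float, n_spots: int, params: SceneParams | None = None,
    n_draws: int = 4000, seed: int = 12345,
) -> tuple[float, float]:
    """Central 95% interval of a single cell's true membrane fraction.

    Monte-Carlo over the generator's own statistical model
    (compartment draws + multiplicity weighting), used to judge whether
    recovered condition means sit within one cell's sampling spread.
    """
    rng = np.random.default_rng(seed)
    draws = sample_cell_fractions(n_draws, n_spots, p_true, rng=rng)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return float(lo), float(hi)
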