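"""Parameter-recovery metrics against simulator ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import GroundTruth
from .spots import SpotSet


@dataclass
class MatchResult:
    """Detected-vs-true spot matching within a tolerance radius."""

    n_true: int
    n_detected: int
    n_matched: int
    position_errors: np.ndarray  # per matched pair, lateral Euclidean px

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else np.nan

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else np.nan

    @property
    def rmse(self) -> float:
        return (
            float(np.sqrt(np.mean(self.position_errors**2)))
            if self.position_errors.size
            else np.nan
        )


def match_spots(
    detected: SpotSet, truth: GroundTruth, tol_px: float = 1.0
) -> MatchResult:
    """Greedy nearest-pair matching of detected to true (y, x) positions.

    Pairs are matched closest-first; each spot matches at most once, and
    only pairs within ``tol_px`` count as true positives.
    """
    det = detected.positions()
    tru = truth.positions()[:, 1:]  # (y, x)
    if det.size == 0 or tru.size == 0:
        return MatchResult(len(tru), len(det), 0, np.array([]))
    d = np.sqrt(((det[:, None, :] - tru[None, :, :]) ** 2).sum(axis=2))
    pairs = np.argwhere(d <= tol_px)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]])
    used_det: set[int] = set()
    used_tru: set[int] = set()
    errors = []
    for i, j in pairs[order]:
        if i in used_det or j in used_tru:
            continue
        used_det.add(int(i))
        used_tru.add(int(j))
        errors.append(d[i, j])
    return MatchResult(len(tru), len(det), len(errors), np.asarray(errors))


def per_cell_unit_errors(
    counts_total: dict[str, int], truth: GroundTruth
) -> np.ndarray:
    """Relative error of measured per-cell unit totals vs ground truth."""
    true_totals = truth.cell_unit_totals()
    errs = []
    for cid, true_total in true_totals.items():
        measured = counts_total.get(cid, 0)
        errs.append(abs(measured - true_total) / true_total)
    return np.asarray(errs)
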