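"""Condition-level summaries, Welch t-tests, significance stars, and
box-plot rendering for per-cell localization fractions.

The unit of analysis is the cell (typically 25 cells drawn from five
embryos per condition).  Box plots follow the ggplot2-style convention:
median line, first/third quartile hinges, whiskers (Tukey 1.5×IQR by
default, min/max optionally), individual cells as jittered dots, and
the mean as a red dot.  Group differences use Welch's unequal-variance
t-test, one- or two-tailed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)


@dataclass
class ConditionSummary:
    condition: str
    stage: str
    n_cells: int
    n_embryos: int
    mean: float
    stdev: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles out of order")
        if not self.whisker_low <= self.q1 or not self.whisker_high >= self.q3:
            raise ValueError("whiskers must bracket the box")


def validate_fraction_table(table: pd.DataFrame) -> None:
    """Check the long-format per-cell fraction table invariants."""
    required = {"embryo_id", "cell_id", "condition", "stage",
                "fraction_percent", "mode"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"fraction table missing columns {sorted(missing)}")
    vals = table["fraction_percent"].dropna()
    if ((vals < 0) | (vals > 100)).any():
        raise ValueError("fraction_percent outside [0, 100]")
    keys = table[["embryo_id", "cell_id", "condition", "stage", "mode"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (embryo, cell, condition, stage, mode) keys")


def summarize_condition(
    table: pd.DataFrame,
    condition: str,
    stage: str | None = None,
    whiskers: str = "tukey",
) -> ConditionSummary:
    """Box-plot summary of one condition (and optionally stage).

    Quartiles use the linear-interpolation convention
    (``numpy.percentile`` default).  ``whiskers="tukey"`` extends to the
    most extreme data point within 1.5×IQR of the hinges (the ggplot2
    default); ``whiskers="minmax"`` uses the data extremes.
    """
    sel = table[table["condition"] == condition]
    if stage is not None:
        sel = sel[sel["stage"] == stage]
    vals = sel["fraction_percent"].dropna().to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError(
            f"condition {condition!r}: need >= 2 cells, have {len(vals)}"
        )
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    if whiskers == "tukey":
        iqr = q3 - q1
        lo_candidates = vals[vals >= q1 - 1.5 * iqr]
        hi_candidates = vals[vals <= q3 + 1.5 * iqr]
        wlo = float(lo_candidates.min())
        whi = float(hi_candidates.max())
    elif whiskers == "minmax":
        wlo, whi = float(vals.min()), float(vals.max())
    else:
        raise ValueError(f"unknown whisker rule {whiskers!r}")
    return ConditionSummary(
        condition=condition,
        stage=stage if stage is not None else "",
        n_cells=int(len(vals)),
        n_embryos=int(sel["embryo_id"].nunique()) if "embryo_id" in sel else 0,
        mean=float(vals.mean()),
        stdev=float(vals.std(ddof=1)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=min(wlo, float(q1)),
        whisker_high=max(whi, float(q3)),
    )


def t_test(
    group_a,
    group_b,
    tails: int = 2,
    direction: str = "greater",
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns ``(t, df, p)``.

    The statistic is ``(mean_a - mean_b) / sqrt(s2a/na + s2b/nb)`` with
    Welch–Satterthwaite degrees of freedom.  For ``tails=1``,
    ``direction`` names the alternative for group A ("greater" or
    "less"); ``tails=2`` doubles the tail.  Two groups with zero
    variance and equal means return ``(0, df, 1)`` by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = float(na + nb - 2)
        if a.mean() == b.mean():
            logger.info("zero variance in both groups with equal means: p=1")
            return 0.0, df, 1.0
        t = np.inf if a.mean() > b.mean() else -np.inf
    else:
        se2 = va / na + vb / nb
        t = float((a.mean() - b.mean()) / np.sqrt(se2))
        df = float(
            se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        )
    if tails == 2:
        p = 2.0 * float(t_dist.sf(abs(t), df))
    else:
        p = float(t_dist.sf(t if direction == "greater" else -t, df))
    return float(t), df, min(p, 1.0)


def significance_stars(p: float) -> str:
    """Star label for a p-value: 0.05 / 0.01 / 0.001 thresholds, strict
    inequalities (p = 0.05 is not significant)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def compare_conditions(
    table: pd.DataFrame,
    comparisons: list[dict],
    stage: str | None = None,
) -> pd.DataFrame:
    """Run the requested pairwise Welch tests on a fraction table.

    Each comparison is a mapping with keys ``a``, ``b`` (condition
    labels), optional ``tails`` (default 2) and ``direction`` (default
    "greater", meaning the alternative is a > b).
    """
    rows = []
    conditions = set(table["condition"])
    for comp in comparisons:
        a_label, b_label = comp["a"], comp["b"]
        for lbl in (a_label, b_label):
            if lbl not in conditions:
                raise ValueError(f"comparison references unknown condition {lbl!r}")
        sel = table if stage is None else table[table["stage"] == stage]
        a = sel.loc[sel["condition"] == a_label, "fraction_percent"].dropna()
        b = sel.loc[sel["condition"] == b_label, "fraction_percent"].dropna()
        t, df, p = t_test(
            a, b, tails=int(comp.get("tails", 2)),
            direction=comp.get("direction", "greater"),
        )
        rows.append(
            {
                "condition_a": a_label,
                "condition_b": b_label,
                "tails": int(comp.get("tails", 2)),
                "direction": comp.get("direction", "greater"),
                "t": t,
                "df": df,
                "p": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)


def render_boxplot(
    table: pd.DataFrame,
    comparisons: list[dict] | None = None,
    out_figure=None,
    out_csv=None,
    stage: str | None = None,
    whiskers: str = "tukey",
    seed: int = 0,
    ylabel: str = "localized mRNA (% of total)",
):
    """Dot-plot-with-box-plot figure and its regenerable summary CSV.

    One box per condition with jittered per-cell dots, the mean as a red
    dot, and star annotations for the requested pairwise comparisons.
    The summary CSV holds exactly the :func:`summarize_condition` numbers
    the figure draws, so the figure is fully regenerable from it.
    Returns ``(summaries, tests)``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    validate_fraction_table(table)
    sel = table if stage is None else table[table["stage"] == stage]
    order = list(dict.fromkeys(sel["condition"]))
    if not order:
        raise ValueError("no conditions to plot")
    summaries = [summarize_condition(sel, c, stage=None, whiskers=whiskers)
                 for c in order]
    tests = compare_conditions(sel, comparisons or [], stage=None)

    fig, ax = plt.subplots(figsize=(1.6 + 1.2 * len(order), 4.0))
    rng = np.random.default_rng(seed)
    for i, (cond, summ) in enumerate(zip(order, summaries)):
        vals = sel.loc[sel["condition"] == cond, "fraction_percent"].dropna()
        ax.add_patch(
            plt.Rectangle((i - 0.3, summ.q1), 0.6, summ.q3 - summ.q1,
                          fill=False, color="black"),
        )
        ax.hlines(summ.median, i - 0.3, i + 0.3, color="black", lw=2.5)
        ax.vlines(i, summ.whisker_low, summ.q1, color="black")
        ax.vlines(i, summ.q3, summ.whisker_high, color="black")
        jitter = rng.uniform(-0.18, 0.18, size=len(vals))
        ax.plot(i + jitter, vals, "o", ms=3, color="0.4", alpha=0.7, zorder=3)
        ax.plot([i], [summ.mean], "o", ms=6, color="red", zorder=4)
    y_top = max(s.whisker_high for s in summaries)
    for k, row in tests.iterrows():
        ia, ib = order.index(row["condition_a"]), order.index(row["condition_b"])
        y = y_top + 6 + 8 * k
        ax.plot([ia, ia, ib, ib], [y - 1.5, y, y, y - 1.5], color="black", lw=0.8)
        ax.text((ia + ib) / 2, y + 0.5, row["stars"], ha="center", fontsize=9)
    ax.set_xticks(range(len(order)), order, rotation=20, ha="right")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if out_figure is not None:
        fig.savefig(out_figure, dpi=150)
    plt.close(fig)

    summary_df = pd.DataFrame([asdict(s) for s in summaries])
    if out_csv is not None:
        summary_df.to_csv(out_csv, index=False)
    return summaries, tests
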