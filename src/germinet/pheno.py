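"""Germination-vigor statistics from time-stamped detections.

Two standard indicators quantify seed vigor per dish:

* germination rate = N_t / N x 100%, the cumulative fraction of the N
  seeds that have germinated by day t — the headline viability number;
* germination index = Σ_t G_t / D_t, where G_t seeds newly germinate on
  day D_t — early germination counts more, so the index captures vigor,
  not just the endpoint.

Detections are reduced to per-seed events by snapping each box to the
nearest dish-grid cell: a seed counts as germinated from the first time
any root-class detection above the confidence threshold lands in its
cell, and stays germinated (repeated or re-emerging detections of the
same radicle never double-count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class GerminationSeries:
    """Cumulative germination observations for one dish.

    ``observations`` holds (day D_t, cumulative N_t, newly germinated G_t),
    time-ordered."""

    dish_id: str
    treatment: float | str
    n_seeds: int
    observations: list[tuple[float, int, int]] = field(default_factory=list)

    def __post_init__(self):
        prev_day, prev_n = 0.0, 0
        for day, n_t, g_t in self.observations:
            if day <= prev_day:
                raise ValueError("days must be strictly increasing and >= 1" if day <= 0
                                 else "days must be strictly increasing")
            if day < 1:
                raise ValueError("day numbers start at 1")
            if n_t < prev_n or n_t > self.n_seeds:
                raise ValueError("cumulative counts must be non-decreasing and <= N")
            if g_t != n_t - prev_n:
                raise ValueError("G_t must equal N_t - N_{t-1}")
            prev_day, prev_n = day, n_t

    @classmethod
    def from_cumulative(cls, dish_id, treatment, n_seeds, day_counts):
        """Build from (day, cumulative count) pairs."""
        obs, prev = [], 0
        for day, n_t in day_counts:
            obs.append((float(day), int(n_t), int(n_t) - prev))
            prev = int(n_t)
        return cls(dish_id, treatment, n_seeds, obs)

    @property
    def final_count(self) -> int:
        return self.observations[-1][1] if self.observations else 0


def germination_rate(n_t: int, n: int) -> float:
    """Cumulative germination percentage, 100 * N_t / N."""
    if n <= 0:
        raise ValueError("total seed count N must be positive")
    if not 0 <= n_t <= n:
        raise ValueError(f"N_t must lie in [0, N]; got {n_t} of {n}")
    return 100.0 * n_t / n


def germination_index(series: GerminationSeries) -> float:
    """Σ G_t / D_t over the observation days (early germination weighs more)."""
    total = 0.0
    for day, _, g_t in series.observations:
        if day <= 0:
            raise ValueError("day numbers must be positive")
        total += g_t / day
    return total


def detections_to_series(records, grid: tuple[int, int], n_seeds: int,
                         confidence_threshold: float = 0.5,
                         dish_id: str = "dish", treatment: float | str = 0.0
                         ) -> GerminationSeries:
    """Reduce time-stamped detections to a per-dish germination series.

    ``records`` is an iterable of (day, detections) pairs; each detection
    is (box, class_id, confidence) with a normalized box (or an object
    with those attributes).  Boxes centered outside the unit square are
    logged and dropped.  Seed identity is the nearest grid-cell center
    (ties go to the lower row-major index); germination is latched.
    """
    from .evaluation import _det

    rows, cols = grid
    centers = np.array([
        [(c + 0.5) / cols, (r + 0.5) / rows] for r in range(rows) for c in range(cols)
    ])
    if n_seeds > rows * cols:
        raise ValueError("more seeds than grid cells")
    germinated = np.zeros(rows * cols, dtype=bool)
    day_counts = []
    records = sorted(records, key=lambda rec: rec[0])
    for day, dets in records:
        for d in dets:
            box, cls, conf = _det(d)
            if conf < confidence_threshold:
                continue
            cx, cy = box[0], box[1]
            if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
                log.warning("dropping detection outside dish bounds: %s", box)
                continue
            dist = ((centers - np.array([cx, cy])) ** 2).sum(axis=1)
            germinated[int(np.argmin(dist))] = True
        day_counts.append((day, int(germinated.sum())))
    return GerminationSeries.from_cumulative(dish_id, treatment, n_seeds, day_counts)


def stress_report(series_list, out_dir=None) -> pd.DataFrame:
    """Per-dish final germination rate and index, plus optional CSV/plots.

    Returns a DataFrame with one row per series; with ``out_dir`` set,
    writes ``stress_report.csv`` and a germination-rate-over-days plot."""
    if not series_list:
        raise ValueError("need at least one series")
    ns = {s.n_seeds for s in series_list}
    if len(ns) > 1:
        import warnings
        warnings.warn("mixed total seed counts across dishes; rates are per-dish")
    rows = []
    for s in series_list:
        rows.append({
            "dish_id": s.dish_id,
            "treatment": s.treatment,
            "n_seeds": s.n_seeds,
            "final_germination_rate_pct": germination_rate(s.final_count, s.n_seeds),
            "germination_index": germination_index(s),
        })
    df = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "stress_report.csv", index=False)
        fig, ax = plt.subplots(figsize=(6, 4))
        for s in series_list:
            days = [o[0] for o in s.observations]
            rates = [germination_rate(o[1], s.n_seeds) for o in s.observations]
            ax.plot(days, rates, marker="o", label=f"{s.treatment}")
        ax.set_xlabel("day")
        ax.set_ylabel("germination rate (%)")
        ax.legend(title="treatment", fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "germination_rate.png", dpi=120)
        plt.close(fig)
    return df
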