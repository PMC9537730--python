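"""Recovery reports: bucketed heatmaps, Pareto fronts, random baselines.

Given the full property tables of a library (available in benchmark or
precomputed mode) and the index set a screen evaluated, these routines
answer the questions a screener asks afterwards: what fraction of each
property bucket did the screen sample, how much of the jointly-desirable
set did it recover at what budget, and how do the sampled property
distributions compare with uniform random sampling of the same size.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

DEFAULT_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)

#: default desirability rules on the raw property scales used for real
#: screens: strong binding, drug-like LogP window, easily synthesizable
DEFAULT_DESIRABLE = {
    "affinity": (-np.inf, -8.0),
    "logp": (0.0, 5.0),
    "sas": (-np.inf, 2.0),
}

#: default bucket widths per property for the recovery heatmaps
DEFAULT_BUCKET_WIDTH = {"affinity": 1.0, "logp": 1.0, "sas": 0.5}


@dataclass(frozen=True)
class BucketGrid:
    """2-D histogram of the library vs the sampled set over two properties.

    Values beyond the outermost edges land in open end-buckets, so
    ``counts_total`` always sums to the library size.
    """

    axes: tuple[str, str]
    edges: tuple[np.ndarray, np.ndarray]
    counts_total: np.ndarray
    counts_sampled: np.ndarray

    @property
    def fraction(self) -> np.ndarray:
        """Sampled fraction per bucket; NaN where the bucket is empty."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.counts_total > 0,
                            self.counts_sampled / self.counts_total, np.nan)

    def write_csv(self, path: str | os.PathLike) -> None:
        import pandas as pd

        rows = []
        nx, ny = self.counts_total.shape
        for i in range(nx):
            for j in range(ny):
                rows.append({
                    f"{self.axes[0]}_bin": i,
                    f"{self.axes[1]}_bin": j,
                    "total": int(self.counts_total[i, j]),
                    "sampled": int(self.counts_sampled[i, j]),
                    "fraction": self.fraction[i, j],
                })
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class RecoveryReport:
    """Headline numbers of a screen against ground truth."""

    desirable_total: int
    desirable_found: int
    recovery: float
    budget_used: float
    per_bucket: tuple[BucketGrid, ...] = ()
    distribution_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "desirable_total": self.desirable_total,
            "desirable_found": self.desirable_found,
            "recovery": self.recovery,
            "budget_used": self.budget_used,
            "distribution_summary": self.distribution_summary,
        }

    def write_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _digitize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bucket edges must be strictly increasing")
    return np.digitize(values, edges)  # 0 and len(edges) are open end-buckets


def bucket_recovery(values_x: np.ndarray, values_y: np.ndarray,
                    sampled: np.ndarray, edges_x: np.ndarray,
                    edges_y: np.ndarray,
                    axes: tuple[str, str] = ("x", "y")) -> BucketGrid:
    """Count library and sampled molecules per 2-D property bucket."""
    values_x = np.asarray(values_x, dtype=float)
    values_y = np.asarray(values_y, dtype=float)
    if values_x.shape != values_y.shape:
        raise ValueError("property vectors must align")
    bx = _digitize(values_x, edges_x)
    by = _digitize(values_y, edges_y)
    nx = len(np.asarray(edges_x)) + 1
    ny = len(np.asarray(edges_y)) + 1
    flat = bx * ny + by
    total = np.bincount(flat, minlength=nx * ny).reshape(nx, ny)
    sampled = np.asarray(sampled, dtype=int)
    samp = np.bincount(flat[sampled], minlength=nx * ny).reshape(nx, ny)
    return BucketGrid(axes=axes,
                      edges=(np.asarray(edges_x, dtype=float),
                             np.asarray(edges_y, dtype=float)),
                      counts_total=total, counts_sampled=samp)


def pareto_front(values: np.ndarray) -> np.ndarray:
    """Indices of the non-dominated rows of ``values`` (all maximized).

    A row is dominated when some other row is >= in every coordinate and
    strictly greater in at least one; exact duplicates of a front point are
    all kept. Simple-cull over a best-first ordering, so typical cost is
    far below the quadratic worst case.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    n = values.shape[0]
    order = np.argsort(-values.sum(axis=1), kind="stable")
    front_rows: list[np.ndarray] = []
    front_idx: list[int] = []
    for idx in order:
        row = values[idx]
        if front_rows:
            fr = np.asarray(front_rows)
            dominated = np.any(np.all(fr >= row, axis=1)
                               & np.any(fr > row, axis=1))
            if dominated:
                continue
        front_rows.append(row)
        front_idx.append(int(idx))
    return np.sort(np.asarray(front_idx, dtype=int))


def compare_to_random(library_values: Mapping[str, np.ndarray],
                      sampled: np.ndarray, n_random_draws: int = 20,
                      seed: int = 0,
                      directions: Mapping[str, str] | None = None) -> dict:
    """Quantiles of sampled vs same-size uniform random draws, per property.

    ``directions`` labels the desirable side per property: ``"lower"``,
    ``"higher"`` or ``"near:<center>"``. The returned flag per property says
    whether the sampled distribution is shifted toward that side relative
    to the random baseline ("toward", "away", or "flat" for degenerate
    properties).
    """
    sampled = np.asarray(sampled, dtype=int)
    if sampled.size == 0:
        raise ValueError("sampled set is empty")
    directions = dict(directions or {})
    rng = np.random.default_rng(seed)
    n = len(next(iter(library_values.values())))
    qs = np.asarray(DEFAULT_QUANTILES)
    summary: dict[str, dict] = {}
    draws = [rng.choice(n, size=sampled.size, replace=False)
             for _ in range(n_random_draws)]
    for name, vals in library_values.items():
        vals = np.asarray(vals, dtype=float)
        sq = np.quantile(vals[sampled], qs)
        rq = np.mean([np.quantile(vals[d], qs) for d in draws], axis=0)
        direction = directions.get(name)
        if np.ptp(vals) == 0:
            flag = "flat"
        elif direction is None:
            flag = "unspecified"
        else:
            if direction.startswith("near:"):
                center = float(direction.split(":", 1)[1])
                s_stat = float(np.median(np.abs(vals[sampled] - center)))
                r_stat = float(np.mean([
                    np.median(np.abs(vals[d] - center)) for d in draws]))
                flag = "toward" if s_stat < r_stat else "away"
            else:
                s_med, r_med = float(sq[2]), float(rq[2])
                if direction == "lower":
                    flag = "toward" if s_med < r_med else "away"
                else:
                    flag = "toward" if s_med > r_med else "away"
        summary[name] = {
            "quantile_levels": [float(q) for q in qs],
            "sampled_quantiles": [float(v) for v in sq],
            "random_quantiles": [float(v) for v in rq],
            "direction": flag,
        }
    return summary


def recovery(desirable: np.ndarray, sampled: np.ndarray) -> float:
    """Fraction of the ground-truth desirable set present in ``sampled``."""
    desirable = np.asarray(desirable, dtype=int)
    if desirable.size == 0:
        return float("nan")
    found = np.intersect1d(desirable, np.asarray(sampled, dtype=int))
    return found.size / desirable.size


def recovery_report(desirable: np.ndarray, sampled: np.ndarray, n: int,
                    library_values: Mapping[str, np.ndarray] | None = None,
                    bucket_axes: Sequence[tuple[str, str]] = (),
                    bucket_width: Mapping[str, float] | None = None,
                    n_random_draws: int = 20, seed: int = 0,
                    directions: Mapping[str, str] | None = None
                    ) -> RecoveryReport:
    """Assemble the full report: recovery, budget, bucket grids, baselines."""
    desirable = np.asarray(desirable, dtype=int)
    sampled = np.asarray(sampled, dtype=int)
    found = np.intersect1d(desirable, sampled).size
    grids: list[BucketGrid] = []
    summary: dict = {}
    if library_values is not None:
        widths = dict(DEFAULT_BUCKET_WIDTH)
        widths.update(bucket_width or {})
        for ax, ay in bucket_axes:
            ex = _default_edges(np.asarray(library_values[ax]),
                                widths.get(ax, 1.0))
            ey = _default_edges(np.asarray(library_values[ay]),
                                widths.get(ay, 1.0))
            grids.append(bucket_recovery(library_values[ax],
                                         library_values[ay], sampled,
                                         ex, ey, axes=(ax, ay)))
        if sampled.size:
            summary = compare_to_random(library_values, sampled,
                                        n_random_draws, seed, directions)
    return RecoveryReport(
        desirable_total=int(desirable.size),
        desirable_found=int(found),
        recovery=found / desirable.size if desirable.size else float("nan"),
        budget_used=sampled.size / n,
        per_bucket=tuple(grids),
        distribution_summary=summary,
    )


def _default_edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = math.floor(values.min() / width) * width
    hi = math.ceil(values.max() / width) * width
    return np.arange(lo, hi + width / 2, width)
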