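"""Controller-confidence metrics on a 2-D evaluation grid.

Two grid-level metrics summarise how trustworthy a controller's parameter
landscape is for a given patient:

* **Local extrema ratio** ``C_l = |E_l| / |T|`` — the number of strict
  local minima of the error surface over the table size.  Many isolated
  minima mean small parameter changes can move the patient between
  disconnected "good" settings, i.e. unpredictable fine-tuning; lower is
  better.

* **Global extremum spread** ``C_s = |S| / |T|`` — the size of the
  connected region of top-quality cells around the global minimum,
  found by breadth-first search from the global extremum through
  neighbouring cells whose error ranks within the best 20 % (the
  goodness-scale 80th percentile).  For a single-basin surface the ideal
  value is 0.2: the entire top quintile is reachable from the optimum.

Both metrics operate on the *error* scale (lower = better, global
extremum = minimum) and use 8-connectivity.  Qualification for the spread
region is rank-based: the ``floor(0.2 |T|)`` cells with the smallest
errors qualify, ties broken by row-major index, and the global extremum
itself always belongs to the region.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patient import CATEGORIES

__all__ = [
    "ConfidenceReport",
    "find_local_extrema",
    "local_extrema_ratio",
    "spread_region",
    "global_extremum_spread",
    "confidence_report",
    "summarize_by_category",
]

#: 8-connected neighbourhood offsets.
NEIGHBOURS = tuple((di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                   if (di, dj) != (0, 0))


def _as_array(grid) -> np.ndarray:
    values = getattr(grid, "values", grid)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("confidence metrics require a grid of at least 2x2")
    if not np.all(np.isfinite(values)):
        raise ValueError("grid contains non-finite values")
    return values


def find_local_extrema(grid) -> list[tuple[int, int]]:
    """Strict local minima of the error surface (8-neighbourhood).

    A cell qualifies when its error is strictly smaller than every
    existing neighbour's; edge and corner cells are compared against
    their in-grid neighbours only.  Flat plateaus contain no extrema.
    """
    v = _as_array(grid)
    nrow, ncol = v.shape
    out = []
    for i in range(nrow):
        for j in range(ncol):
            c = v[i, j]
            if all(c < v[i + di, j + dj]
                   for di, dj in NEIGHBOURS
                   if 0 <= i + di < nrow and 0 <= j + dj < ncol):
                out.append((i, j))
    return out


def local_extrema_ratio(grid) -> float:
    """``C_l = |E_l| / |T|``: fraction of cells that are strict local minima."""
    v = _as_array(grid)
    return len(find_local_extrema(v)) / v.size


def _global_extremum(v: np.ndarray) -> tuple[int, int]:
    # smallest error; ties resolved to the smallest row-major index
    flat_idx = int(np.argmin(v))
    return divmod(flat_idx, v.shape[1])


def spread_region(grid, q: float = 0.2) -> set[tuple[int, int]]:
    """Connected best-quantile region around the global extremum.

    The qualifying set holds the ``floor(q * |T|)`` cells with the
    smallest errors (stable rank: ties broken by row-major index) — the
    top-*q* fraction on the goodness scale.  The region is the BFS
    closure of the global extremum within the qualifying set under
    8-connectivity; the extremum itself is always included.
    """
    v = _as_array(grid)
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    nrow, ncol = v.shape
    x0 = _global_extremum(v)
    k = math.floor(q * v.size)
    order = np.argsort(v.ravel(), kind="stable")[:k]
    qualifying = {divmod(int(f), ncol) for f in order}
    qualifying.add(x0)

    region = {x0}
    queue = deque([x0])
    while queue:
        i, j = queue.popleft()
        for di, dj in NEIGHBOURS:
            nb = (i + di, j + dj)
            if (0 <= nb[0] < nrow and 0 <= nb[1] < ncol
                    and nb in qualifying and nb not in region):
                region.add(nb)
                queue.append(nb)
    return region


def global_extremum_spread(grid, q: float = 0.2) -> float:
    """``C_s = |S| / |T|``: relative size of the global-extremum region."""
    v = _as_array(grid)
    return len(spread_region(v, q)) / v.size


@dataclass
class ConfidenceReport:
    """Both confidence metrics plus the cells they were computed from."""

    C_l: float
    C_s: float
    extrema_cells: list
    global_cell: tuple
    spread_cells: list

    def to_json(self, path=None) -> str:
        payload = {
            "C_l": self.C_l,
            "C_s": self.C_s,
            "extrema_cells": [list(c) for c in self.extrema_cells],
            "global_cell": list(self.global_cell),
            "spread_cells": [list(c) for c in self.spread_cells],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def confidence_report(grid, q: float = 0.2) -> ConfidenceReport:
    """Compute both metrics and the supporting cell sets for one grid."""
    v = _as_array(grid)
    extrema = find_local_extrema(v)
    spread = spread_region(v, q)
    return ConfidenceReport(
        C_l=len(extrema) / v.size,
        C_s=len(spread) / v.size,
        extrema_cells=extrema,
        global_cell=_global_extremum(v),
        spread_cells=sorted(spread),
    )


def summarize_by_category(reports: dict[str, ConfidenceReport]) -> pd.DataFrame:
    """Per-category mean (SD) of both metrics over a cohort of reports.

    ``reports`` maps patient ids of the form ``"category#NNN"`` to their
    reports.  Returns rows for each category plus ``"all"`` with columns
    ``C_l_mean, C_l_sd, C_s_mean, C_s_sd`` (fractions, not percent).
    """
    rows = []
    frame = pd.DataFrame(
        [(pid.split("#")[0], r.C_l, r.C_s) for pid, r in reports.items()],
        columns=["category", "C_l", "C_s"])
    groups = [(c, frame[frame.category == c]) for c in CATEGORIES
              if (frame.category == c).any()]
    groups.append(("all", frame))
    for name, g in groups:
        rows.append({
            "category": name,
            "C_l_mean": g.C_l.mean(), "C_l_sd": g.C_l.std(ddof=1),
            "C_s_mean": g.C_s.mean(), "C_s_sd": g.C_s.std(ddof=1),
        })
    return pd.DataFrame(rows).set_index("category")
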