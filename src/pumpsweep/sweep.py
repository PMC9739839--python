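"""Cartesian-product parameter sweeps over the virtual-patient cohort.

Each controller parameter *i* is discretised into a vector
``P_i = {L_i, L_i + S_i, L_i + 2 S_i, ..., U_i}`` and the evaluation
table ``T = P_1 x P_2 x ... x P_n`` is their Cartesian product.  For the
two built-in controllers the swept axes are (default basal *b*,
suspension threshold theta) for LGS — 57 x 14 = 798 cells — and
(*b*, insulin sensitivity *s*) for the oref-like controller —
47 x 35 = 1645 cells.  Every cell is one closed-loop day scored by the
average-error metric.
"""

from __future__ import annotations

import itertools
import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .patient import PatientParams
from .simulation import Scenario, average_error, run_closed_loop

__all__ = [
    "ParameterAxis",
    "EvaluationGrid",
    "TABLE2_AXES",
    "axis_values",
    "build_table",
    "evaluate_grid",
    "grid_to_csv",
    "grid_from_csv",
    "grid_cells",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterAxis:
    """One swept parameter: name, lower/upper bounds and increment."""

    name: str
    L: float
    U: float
    S: float

    def __post_init__(self):
        if self.S <= 0:
            raise ValueError("increment S must be > 0")
        if self.U < self.L:
            raise ValueError("upper bound must be >= lower bound")

    def __len__(self) -> int:
        return int(round((self.U - self.L) / self.S)) + 1


#: Published sweep bounds/increments for the two built-in controllers.
TABLE2_AXES = {
    "lgs": (ParameterAxis("b", 0.2, 3.0, 0.05),
            ParameterAxis("theta", 1.0, 7.5, 0.5)),
    "oref_like": (ParameterAxis("b", 0.2, 2.5, 0.05),
                  ParameterAxis("s", 0.1, 1.8, 0.05)),
}


def axis_values(axis: ParameterAxis) -> list[float]:
    """The ordered parameter vector ``{L, L+S, ..., U}``.

    Values are built as ``L + k*S`` by integer index (never repeated
    addition) so the value count is exact and the last value equals U to
    within 1e-9.
    """
    count = len(axis)
    values = [axis.L + k * axis.S for k in range(count)]
    if abs(values[-1] - axis.U) > 1e-9 * max(1.0, abs(axis.U)):
        raise ValueError(
            f"axis {axis.name!r}: U - L = {axis.U - axis.L} is not an "
            f"integer multiple of S = {axis.S}")
    return values


def build_table(axes) -> list[tuple]:
    """Row-major Cartesian product of the axis value vectors."""
    axes = list(axes)
    if not axes:
        raise ValueError("at least one axis is required")
    return list(itertools.product(*(axis_values(a) for a in axes)))


@dataclass
class EvaluationGrid:
    """Evaluation table for one patient/controller: one error value per cell.

    ``values[i, j]`` is the average-error score at the i-th value of
    ``axes[0]`` and j-th value of ``axes[1]`` (row-major, matching
    :func:`axis_values` ordering).
    """

    axes: tuple
    values: np.ndarray
    patient_id: str
    controller: str

    def __post_init__(self):
        expected = tuple(len(a) for a in self.axes)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} does not "
                             f"match axis counts {expected}")

    @property
    def size(self) -> int:
        return int(self.values.size)


def _evaluate_cell(args):
    patient, controller_name, fixed, names, combo, scenario, cell_seed = args
    params = dict(fixed)
    params.update(zip(names, combo))
    sc = replace(scenario, seed=cell_seed)
    trace = run_closed_loop(patient, (controller_name, params), sc)
    return average_error(trace)


def _cell_seed(base_seed: int, i: int, j: int) -> int:
    # stable per-cell stream, independent of evaluation order
    ss = np.random.SeedSequence([max(0, base_seed), i, j])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def evaluate_grid(patient: PatientParams, controller_name: str, axes,
                  scenario: Scenario, workers: int = 1,
                  fixed_params: dict | None = None) -> EvaluationGrid:
    """Score every cell of the 2-D evaluation table for one patient.

    Each cell runs one closed-loop day with the swept parameters bound to
    the axis values and returns the average-error metric.  Results are
    identical regardless of ``workers`` (each cell draws its CGM noise
    from a seed derived from the scenario seed and the cell index).
    """
    axes = tuple(axes)
    if len(axes) != 2:
        raise ValueError("grid evaluation supports exactly 2 axes")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    fixed = dict(fixed_params or {})
    names = tuple(a.name for a in axes)
    v1, v2 = axis_values(axes[0]), axis_values(axes[1])

    tasks = [(patient, controller_name, fixed, names, (a, b), scenario,
              _cell_seed(scenario.seed, i, j))
             for i, a in enumerate(v1) for j, b in enumerate(v2)]
    log.info("evaluating %d x %d grid for %s / %s (%d workers)",
             len(v1), len(v2), patient.id, controller_name, workers)

    if workers == 1:
        flat = [_evaluate_cell(t) for t in tasks]
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            flat = list(pool.map(_evaluate_cell, tasks, chunksize=8))

    values = np.asarray(flat, dtype=float).reshape(len(v1), len(v2))
    if not np.all(np.isfinite(values)):
        raise RuntimeError("grid contains non-finite cells")
    return EvaluationGrid(axes=axes, values=values,
                          patient_id=patient.id, controller=controller_name)


def grid_cells(grid: EvaluationGrid) -> np.ndarray:
    """Flatten a grid to (x, y, error) triples in row-major cell order."""
    v1 = axis_values(grid.axes[0])
    v2 = axis_values(grid.axes[1])
    xx, yy = np.meshgrid(v1, v2, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), grid.values.ravel()])


# ---------------------------------------------------------------------------
# Persistence: CSV matrix + JSON sidecar

def grid_to_csv(grid: EvaluationGrid, csv_path, sidecar_path=None) -> None:
    """Write the grid as a CSV matrix plus a JSON sidecar.

    CSV layout: header row of axis-2 values, first column axis-1 values,
    cells = error.  The sidecar records axes, patient and controller.
    """
    df = pd.DataFrame(grid.values,
                      index=axis_values(grid.axes[0]),
                      columns=axis_values(grid.axes[1]))
    df.index.name = grid.axes[0].name
    df.to_csv(csv_path)
    if sidecar_path is None:
        sidecar_path = str(csv_path).rsplit(".", 1)[0] + ".json"
    meta = {
        "patient_id": grid.patient_id,
        "controller": grid.controller,
        "axes": [{"name": a.name, "L": a.L, "U": a.U, "S": a.S}
                 for a in grid.axes],
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def grid_from_csv(csv_path, sidecar_path=None) -> EvaluationGrid:
    """Load a grid written by :func:`grid_to_csv`."""
    if sidecar_path is None:
        sidecar_path = str(csv_path).rsplit(".", 1)[0] + ".json"
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    axes = tuple(ParameterAxis(**a) for a in meta["axes"])
    try:
        df = pd.read_csv(csv_path, index_col=0)
    except Exception as exc:  # pragma: no cover - defensive
        raise ValueError(f"malformed grid CSV {csv_path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    return EvaluationGrid(axes=axes, values=values,
                          patient_id=meta["patient_id"],
                          controller=meta["controller"])
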