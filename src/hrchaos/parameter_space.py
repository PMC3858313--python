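"""Scans of the (I, r) parameter plane.

Two map products: ISI bifurcation diagrams along straight line segments
(with run-length scenario extraction), and a gridded largest-Lyapunov-
exponent map over the rectangle 2.3 <= I <= 3.42, 0.001 <= r <= 0.035
with connected-component labeling of the chaotic (LLE > threshold)
regions.  On this rectangle the model shows two disjoint chaotic regions:
the well-known comb-shaped one toward high I / low r and a second,
narrow one lying between the period-1 and period-2 bands around
(I, r) = (2.53, 0.0245).

Named line presets (BL1-BL4, TL1-TL4, ML0, SL1) are shipped as data in
``data/line_presets.json``; each preset records the regime sequence its
scan is expected to traverse and how its endpoints were chosen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
from skimage.measure import label as _cc_label

from .errors import IntegrationBlowUpError
from .hr_model import (
    DEFAULT_DT,
    DEFAULT_INITIAL,
    DEFAULT_TRANSIENT,
    HRParams,
    ISISeries,
    State,
    largest_lyapunov,
    simulate_isis,
)
from .regimes import (
    APERIODIC,
    DEFAULT_K_MAX,
    DEFAULT_LLE_THRESHOLD,
    DEFAULT_REL_TOL,
    RegimeLabel,
    classify_period,
)

__all__ = [
    "ParameterLine",
    "BifurcationDiagram",
    "ScenarioStep",
    "LLEMap",
    "ChaoticRegionSet",
    "ScanConfig",
    "LINE_PRESETS",
    "FIG_RECTANGLE",
    "scan_line",
    "extract_scenario",
    "compute_lle_map",
    "label_chaotic_regions",
]

#: (I_min, I_max, r_min, r_max) of the standard two-parameter map.
FIG_RECTANGLE = (2.3, 3.42, 0.001, 0.035)


@dataclass(frozen=True)
class ParameterLine:
    """A straight segment in the (I, r) plane, scanned start -> end."""

    name: str
    start: tuple  # (I, r)
    end: tuple
    n_points: int = 150

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.n_points > 1 and tuple(self.start) == tuple(self.end):
            raise ValueError("start and end coincide but n_points > 1")

    def points(self) -> np.ndarray:
        """(n_points, 2) array of (I, r) pairs from start to end."""
        t = np.linspace(0.0, 1.0, self.n_points) if self.n_points > 1 else np.array([0.0])
        I = self.start[0] + t * (self.end[0] - self.start[0])
        r = self.start[1] + t * (self.end[1] - self.start[1])
        return np.column_stack([I, r])

    def with_points(self, n_points: int) -> "ParameterLine":
        return ParameterLine(self.name, self.start, self.end, n_points)


def _load_presets() -> dict:
    text = resources.files("hrchaos").joinpath("data/line_presets.json").read_text()
    raw = json.loads(text)
    return {
        name: ParameterLine(name=name, start=tuple(d["start"]), end=tuple(d["end"]),
                            n_points=d.get("n_points", 150))
        for name, d in raw["lines"].items()
    }


#: Named scan lines; endpoints chosen so each line traverses its
#: documented regime sequence (see data/line_presets.json provenance).
LINE_PRESETS: dict = _load_presets()


@dataclass
class ScanConfig:
    """Per-point simulation and classification settings for line scans."""

    n_isis: int = 120
    keep_isis: int = 60
    dt: float = DEFAULT_DT
    transient: float = DEFAULT_TRANSIENT
    t_end: float = 6000.0
    rel_tol: float = DEFAULT_REL_TOL
    k_max: int = DEFAULT_K_MAX
    lle_threshold: float = DEFAULT_LLE_THRESHOLD
    lle_t_average: float = 5000.0
    initial: tuple = DEFAULT_INITIAL
    continuation: bool = True  # warm-start each point from the previous one
    base_params: HRParams = field(default_factory=HRParams)


@dataclass
class BifurcationDiagram:
    """Per-point ISI sets and regime labels along a parameter line."""

    line: ParameterLine
    points: np.ndarray            # (n, 2) of (I, r)
    isi_sets: list                # list of 1-D arrays (tail ISIs)
    labels: list                  # list of RegimeLabel

    def __post_init__(self) -> None:
        n = len(self.points)
        if not (len(self.isi_sets) == n and len(self.labels) == n):
            raise ValueError("points, isi_sets and labels must have equal length")

    def to_frame(self):
        """Long-format table: one row per (parameter point, ISI)."""
        import pandas as pd

        rows = []
        for i, (pt, isis) in enumerate(zip(self.points, self.isi_sets)):
            for isi in isis:
                rows.append((i, pt[0], pt[1], isi))
        return pd.DataFrame(rows, columns=["param_index", "I", "r", "isi"])


@dataclass
class ScenarioStep:
    """One regime stretch of a scenario, with its parameter extent."""

    label: RegimeLabel
    start_index: int
    end_index: int      # half-open
    start_point: tuple  # (I, r) boundary (midpoint to previous step)
    end_point: tuple

    def to_dict(self) -> dict:
        d = self.label.to_dict()
        d.update(start_index=int(self.start_index), end_index=int(self.end_index),
                 start_point=list(map(float, self.start_point)),
                 end_point=list(map(float, self.end_point)))
        return d


@dataclass
class LLEMap:
    """Gridded largest Lyapunov exponent over an (I, r) rectangle."""

    I_axis: np.ndarray
    r_axis: np.ndarray
    values: np.ndarray  # shape (len(r_axis), len(I_axis)); NaN = blow-up

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.r_axis), len(self.I_axis)):
            raise ValueError("values must have shape (n_r, n_I)")

    def nearest_cell(self, I: float, r: float) -> tuple:
        """(row, col) of the grid node nearest to (I, r)."""
        return (int(np.argmin(np.abs(self.r_axis - r))),
                int(np.argmin(np.abs(self.I_axis - I))))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.r_axis, columns=self.I_axis)


@dataclass
class ChaoticRegionSet:
    """Disjoint connected components of the LLE > threshold mask."""

    threshold: float
    min_cells: int
    regions: list  # list of (k, 2) int arrays of (row, col) cells
    shape: tuple

    @property
    def count(self) -> int:
        return len(self.regions)

    def region_containing(self, cell: tuple) -> Optional[int]:
        """Index of the region containing (row, col), or None."""
        for i, cells in enumerate(self.regions):
            if np.any((cells[:, 0] == cell[0]) & (cells[:, 1] == cell[1])):
                return i
        return None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "min_cells": self.min_cells,
            "count": self.count,
            "regions": [cells.tolist() for cells in self.regions],
        }


def _label_point(params: HRParams, isis: ISISeries, final: State,
                 cfg: ScanConfig) -> RegimeLabel:
    evidence: dict = {"n_isis": len(isis)}
    if len(isis) < 1:
        return RegimeLabel("quiescent", evidence=evidence)
    if len(isis) < 4 * cfg.k_max:
        return RegimeLabel("unclassified", evidence=evidence)
    evidence["period_tol_used"] = cfg.rel_tol
    k = classify_period(isis, rel_tol=cfg.rel_tol, k_max=cfg.k_max,
                        tail=max(4 * cfg.k_max, len(isis) // 2))
    if k != APERIODIC:
        return RegimeLabel("periodic", period=k, evidence=evidence)
    lle = largest_lyapunov(params, t_transient=0.0, t_average=cfg.lle_t_average,
                           dt=cfg.dt, initial=final.to_array())
    evidence["lle"] = lle
    return RegimeLabel("chaotic" if lle > cfg.lle_threshold else "unclassified",
                       evidence=evidence)


def scan_line(line: ParameterLine, config: Optional[ScanConfig] = None) -> BifurcationDiagram:
    """Simulate and classify every point of ``line`` in order.

    Each point's initial state is the previous point's final state
    (continuation), mirroring the slow parameter drift of the underlying
    experiments; the first point starts from the configured initial
    state.  A blow-up at one point is recorded as unclassified (with an
    error flag) and the scan continues cold from the default state.
    """
    cfg = config if config is not None else ScanConfig()
    pts = line.points()
    isi_sets: list = []
    labels: list = []
    state = np.asarray(cfg.initial, dtype=float)
    for I, r in pts:
        params = cfg.base_params.with_point(I=float(I), r=float(r))
        try:
            isis, final = simulate_isis(
                params, n_isis=cfg.n_isis, t_end=cfg.t_end, dt=cfg.dt,
                transient=cfg.transient,
                initial=state if cfg.continuation else cfg.initial,
                return_final_state=True)
            label = _label_point(params, isis, final, cfg)
            state = final.to_array()
        except IntegrationBlowUpError as exc:
            isis = ISISeries(np.empty(0))
            label = RegimeLabel("unclassified",
                                evidence={"error": "blowup", "blowup_time": exc.time})
            state = np.asarray(cfg.initial, dtype=float)
        isi_sets.append(np.asarray(isis.isis[-cfg.keep_isis:]))
        labels.append(label)
    return BifurcationDiagram(line=line, points=pts, isi_sets=isi_sets, labels=labels)


def extract_scenario(diagram: BifurcationDiagram, min_run: int = 2) -> list[ScenarioStep]:
    """Run-length encode the diagram's labels into an ordered scenario.

    Runs shorter than ``min_run`` points are absorbed into the longer
    neighbouring run; regime boundaries are reported as midpoints between
    the adjacent differing parameter points.
    """
    labels = diagram.labels
    if not labels:
        raise ValueError("empty diagram")
    runs: list[list] = []  # [label, start, end)
    start = 0
    for i in range(1, len(labels)):
        if not labels[i].same_regime(labels[start]):
            runs.append([labels[start], start, i])
            start = i
    runs.append([labels[start], start, len(labels)])

    while len(runs) > 1:
        lengths = [rn[2] - rn[1] for rn in runs]
        j = int(np.argmin(lengths))
        if lengths[j] >= min_run:
            break
        if j == 0:
            runs[1][1] = runs[0][1]
            runs.pop(0)
        elif j == len(runs) - 1:
            runs[-2][2] = runs[-1][2]
            runs.pop()
        else:
            if (runs[j - 1][2] - runs[j - 1][1]) >= (runs[j + 1][2] - runs[j + 1][1]):
                runs[j - 1][2] = runs[j][2]
            else:
                runs[j + 1][1] = runs[j][1]
            runs.pop(j)
        merged = [runs[0]]
        for rn in runs[1:]:
            if rn[0].same_regime(merged[-1][0]):
                merged[-1][2] = rn[2]
            else:
                merged.append(rn)
        runs = merged

    pts = diagram.points
    steps = []
    for label, i0, i1 in runs:
        p_start = tuple(pts[i0] if i0 == 0 else 0.5 * (pts[i0 - 1] + pts[i0]))
        p_end = tuple(pts[i1 - 1] if i1 == len(pts) else 0.5 * (pts[i1 - 1] + pts[i1]))
        steps.append(ScenarioStep(label=label, start_index=i0, end_index=i1,
                                  start_point=p_start, end_point=p_end))
    return steps


def compute_lle_map(
    rectangle: tuple = FIG_RECTANGLE,
    n_I: int = 112,
    n_r: int = 70,
    *,
    dt: float = DEFAULT_DT,
    t_transient: float = DEFAULT_TRANSIENT,
    t_average: float = 5000.0,
    renorm_interval: float = 1.0,
    initial: tuple = DEFAULT_INITIAL,
    base_params: Optional[HRParams] = None,
    progress: bool = False,
) -> LLEMap:
    """Largest Lyapunov exponent on an n_r x n_I grid over ``rectangle``.

    Rows (fixed r) are evaluated left to right with state continuation;
    blow-up cells are stored as NaN.  Deterministic for a fixed
    configuration.
    """
    if n_I < 2 or n_r < 2:
        raise ValueError("grid must be at least 2x2")
    I_min, I_max, r_min, r_max = rectangle
    I_axis = np.linspace(I_min, I_max, n_I)
    r_axis = np.linspace(r_min, r_max, n_r)
    base = base_params if base_params is not None else HRParams()
    values = np.empty((n_r, n_I))
    for j, r in enumerate(r_axis):
        state = np.asarray(initial, dtype=float)
        for i, I in enumerate(I_axis):
            params = base.with_point(I=float(I), r=float(r))
            try:
                lle, final = largest_lyapunov(
                    params, t_transient=t_transient, t_average=t_average,
                    renorm_interval=renorm_interval, dt=dt, initial=state,
                    return_final_state=True)
                values[j, i] = lle
                state = final.to_array()
            except IntegrationBlowUpError:
                values[j, i] = np.nan
                state = np.asarray(initial, dtype=float)
        if progress:
            print(f"  lle-map row {j + 1}/{n_r} (r={r:.4f}) done", flush=True)
    return LLEMap(I_axis=I_axis, r_axis=r_axis, values=values)


def label_chaotic_regions(
    lle_map: LLEMap,
    threshold: float = 0.002,
    min_cells: int = 4,
    connectivity: int = 2,
) -> ChaoticRegionSet:
    """Connected components of cells with LLE above ``threshold``.

    Components smaller than ``min_cells`` cells are discarded (grid noise
    at the resolutions used here).  ``connectivity`` follows skimage: 2
    (default) joins diagonal neighbours, which keeps the thin oblique
    chaos bands around the comb's interior period windows in one piece at
    coarse grids; 1 restricts to 4-neighbourhoods.
    """
    mask = np.nan_to_num(lle_map.values, nan=-np.inf) > threshold
    labeled = _cc_label(mask, connectivity=connectivity)
    regions = []
    for lab in range(1, labeled.max() + 1):
        cells = np.argwhere(labeled == lab)
        if len(cells) >= min_cells:
            regions.append(cells)
    return ChaoticRegionSet(threshold=threshold, min_cells=min_cells,
                            regions=regions, shape=lle_map.values.shape)
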