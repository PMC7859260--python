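"""Bilayer equilibration diagnostics: area per lipid, thickness, convergence.

These diagnostics justify the choice of analysis window: self-assembly
statistics are collected only after the membrane has equilibrated, which in
the TNFR bundle systems happens within the first 3 microseconds (the
standard fluid-bilayer values being ~0.73 nm^2 per lipid and ~3.6 nm
thickness).

The area per lipid is the projected box area divided by lipids per leaflet;
no correction is applied for the area occupied by protein, which biases the
value slightly upward in crowded patches (reported alongside the number).
Thickness is the distance between the mean head-bead z of the two leaflets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MembraneTimeseries",
    "area_per_lipid",
    "bilayer_thickness",
    "convergence_check",
]


@dataclass
class MembraneTimeseries:
    times: np.ndarray  # ns
    apl: np.ndarray  # nm^2
    thickness: np.ndarray  # nm
    n_lipids_per_leaflet: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.apl = np.asarray(self.apl, dtype=float)
        self.thickness = np.asarray(self.thickness, dtype=float)
        if not (len(self.times) == len(self.apl) == len(self.thickness)):
            raise ValueError("time series must have equal lengths")
        if np.any(self.apl <= 0) or np.any(self.thickness <= 0):
            raise ValueError("area per lipid and thickness must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ns": self.times, "apl_nm2": self.apl,
             "thickness_nm": self.thickness}
        )


def area_per_lipid(box_xy: tuple[float, float], n_lipids_total: int) -> float:
    """Projected area per lipid: 2 * box_x * box_y / n_lipids_total (nm^2)."""
    if n_lipids_total <= 0:
        raise ValueError("lipid count must be positive")
    if n_lipids_total % 2:
        raise ValueError("lipid count must be even (two leaflets)")
    bx, by = box_xy
    return 2.0 * bx * by / n_lipids_total


def bilayer_thickness(
    headgroup_z: np.ndarray, box: np.ndarray | None = None
) -> float:
    """Leaflet-mean head-bead separation (nm).

    Head beads are assigned to leaflets by their z relative to the bilayer
    midplane (the median head z).  Raises if every bead falls in one leaflet.
    """
    z = np.asarray(headgroup_z, dtype=float)
    if z.ndim != 1 or z.size < 2:
        raise ValueError("need a 1D array of at least two head-bead z coordinates")
    mid = np.median(z)
    upper, lower = z[z > mid], z[z < mid]
    if upper.size == 0 or lower.size == 0:
        raise ValueError("all head beads fall in one leaflet")
    return float(abs(upper.mean() - lower.mean()))


def convergence_check(
    times: np.ndarray,
    values: np.ndarray,
    window_ns: float,
    rel_tol: float = 0.02,
    k_windows: int = 3,
) -> float | None:
    """Earliest time after which the series has settled, or None.

    The series is chopped into consecutive windows of ``window_ns``; it is
    converged from the start of the first window of a run of ``k_windows``
    windows whose means differ pairwise by less than ``rel_tol`` (relative
    to their overall mean).  Returns the start time of that first window.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size:
        raise ValueError("times and values must align")
    span = times[-1] - times[0]
    if span < (k_windows + 1) * window_ns:
        raise ValueError(
            f"insufficient data: series spans {span} ns but needs at least "
            f"{(k_windows + 1) * window_ns} ns for {k_windows} windows"
        )
    edges = np.arange(times[0], times[-1] + 1e-9, window_ns)
    means, starts = [], []
    for lo, hi in zip(edges, edges[1:]):
        mask = (times >= lo) & (times < hi)
        if np.any(mask):
            means.append(values[mask].mean())
            starts.append(lo)
    means_arr = np.array(means)
    for i in range(len(means_arr) - k_windows + 1):
        run = means_arr[i : i + k_windows]
        scale = abs(run.mean())
        if scale == 0:
            scale = 1.0
        if (run.max() - run.min()) / scale < rel_tol:
            return float(starts[i])
    return None
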