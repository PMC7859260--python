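"""Oligomer census: dimers, trimers, association lifetimes, radial-cluster
Markov transitions.

Pairs of helices are classified from their in-plane geometry: the centroid
separation, the angular position alpha of the neighbour in the reference
body frame, and the relative orientation beta (counterclockwise angle from
the reference orientation vector to the neighbour's, mod 360).  Adjacent
protomers of an ideal Cn-symmetric assembly satisfy beta = 360/n exactly:
180 degrees for a C2 dimer, 120/240 degrees for a C3 trimer.  A closed
trimer is a 3-cycle of C3-compatible pairs whose signed betas are cyclically
consistent (they sum to 0 mod 360); this closure test is what distinguishes
a true three-fold ring from three accidentally co-oriented pairs.

Default thresholds: first-orbit distance 1.5 nm; angular tolerance 25
degrees, which keeps the 120/180/240 windows disjoint (gaps of 60 > 2 x 25).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import BundleFrame, Trajectory, minimum_image
from .radial_geometry import (
    HelixFrameDescriptor,
    RadialCloud,
    _rotation_to_frame,
    _strided_frames,
    frame_descriptor,
)

__all__ = [
    "CensusParams",
    "PairGeometry",
    "FrameCensus",
    "AssociationRecord",
    "SpotCluster",
    "TransitionMatrix",
    "pair_geometry",
    "census_frame",
    "census_trajectory",
    "association_records",
    "association_summary",
    "cluster_spots",
    "markov_transitions",
]


def circular_difference(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Smallest absolute angular difference in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.minimum(d, 360.0 - d)


@dataclass(frozen=True)
class CensusParams:
    """Geometric thresholds of the oligomer census."""

    d_max: float = 1.5  # nm, first orbit
    beta_tol: float = 25.0  # degrees

    def __post_init__(self) -> None:
        if self.beta_tol > 30.0:
            raise ValueError(
                "beta_tol > 30 deg makes the C2 (180) and C3 (120/240) windows overlap"
            )


@dataclass(frozen=True)
class PairGeometry:
    """In-plane geometry of an ordered (reference, neighbour) helix pair."""

    ref: int
    neighbor: int
    time: float  # ns
    distance: float  # nm, XY minimum-image centroid distance
    alpha: float  # degrees [0, 360), position of neighbour in ref frame
    beta: float  # degrees [0, 360), relative orientation, CCW


@dataclass
class FrameCensus:
    """Oligomer classification of one frame."""

    time: float
    c2_pairs: set[frozenset[int]]
    c3_pairs: set[frozenset[int]]
    trimers: set[frozenset[int]]

    @property
    def counts(self) -> dict[str, int]:
        return {"C2": len(self.c2_pairs), "C3_pair": len(self.c3_pairs),
                "trimer": len(self.trimers)}


@dataclass
class AssociationRecord:
    """Contiguous qualification intervals of one member set in one category."""

    members: frozenset[int]
    category: str  # "C2" | "C3_pair" | "trimer"
    intervals: list[tuple[float, float]]  # (t_on, t_off) ns, t_off exclusive

    @property
    def accumulated_time(self) -> float:
        return sum(t1 - t0 for t0, t1 in self.intervals)

    @property
    def longest(self) -> float:
        return max(t1 - t0 for t0, t1 in self.intervals)

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)


@dataclass
class SpotCluster:
    """One first-orbit spot isolated by density clustering."""

    label: int
    centroid: tuple[float, float]  # nm, reference body frame
    alpha: float  # degrees
    mean_distance: float  # nm
    n_points: int
    betas: np.ndarray  # degrees, distribution over member points
    point_indices: np.ndarray  # indices into the source RadialCloud


@dataclass
class TransitionMatrix:
    """Row-stochastic transitions between radial clusters (+ "outside")."""

    states: list[str]
    counts: np.ndarray  # (S, S) integers
    probabilities: np.ndarray  # rows sum to 1 where counts exist
    empty_rows: np.ndarray  # bool mask of rows with zero outgoing counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probabilities, index=self.states,
                            columns=self.states)

    def self_transition(self, state: str) -> float:
        i = self.states.index(state)
        return float(self.probabilities[i, i])


def pair_geometry(
    ref_desc: HelixFrameDescriptor,
    nbr_desc: HelixFrameDescriptor,
    box: np.ndarray | None = None,
) -> PairGeometry:
    """Distance, radial location (alpha) and relative orientation (beta)."""
    if not (ref_desc.valid and nbr_desc.valid):
        raise ValueError("both helix descriptors must be valid")
    delta = minimum_image(nbr_desc.centroid - ref_desc.centroid, box)
    xy = _rotation_to_frame(ref_desc.orientation_xy) @ delta[:2]
    alpha = float(np.degrees(np.arctan2(xy[1], xy[0])) % 360.0)
    u, v = ref_desc.orientation_xy, nbr_desc.orientation_xy
    beta = float(np.degrees(np.arctan2(u[0] * v[1] - u[1] * v[0], u @ v)) % 360.0)
    return PairGeometry(
        ref=ref_desc.helix_id,
        neighbor=nbr_desc.helix_id,
        time=ref_desc.time,
        distance=float(np.hypot(*xy)),
        alpha=alpha,
        beta=beta,
    )


def census_frame(
    descriptors: Sequence[HelixFrameDescriptor],
    params: CensusParams = CensusParams(),
    box: np.ndarray | None = None,
) -> FrameCensus:
    """Classify C2 pairs, C3-compatible pairs and closed trimers in one frame.

    A pair is C2 when within the first orbit with beta within ``beta_tol``
    of 180; C3-compatible when beta is within tolerance of 120 or 240.  A
    closed trimer is a 3-cycle of C3-compatible pairs whose signed betas sum
    to 0 mod 360 within 3 x ``beta_tol``.
    """
    valid = [d for d in descriptors if d.valid]
    if len(valid) < 2:
        raise ValueError("need at least two valid helix descriptors")
    time = valid[0].time
    c2: set[frozenset[int]] = set()
    c3: set[frozenset[int]] = set()
    beta_of: dict[tuple[int, int], float] = {}
    for a, b in itertools.combinations(valid, 2):
        g = pair_geometry(a, b, box)
        if g.distance > params.d_max:
            continue
        beta_of[(a.helix_id, b.helix_id)] = g.beta
        beta_of[(b.helix_id, a.helix_id)] = (360.0 - g.beta) % 360.0
        key = frozenset((a.helix_id, b.helix_id))
        if circular_difference(g.beta, 180.0) <= params.beta_tol:
            c2.add(key)
        if (circular_difference(g.beta, 120.0) <= params.beta_tol
                or circular_difference(g.beta, 240.0) <= params.beta_tol):
            c3.add(key)

    trimers: set[frozenset[int]] = set()
    nodes = sorted({h for pair in c3 for h in pair})
    for trio in itertools.combinations(nodes, 3):
        a, b, c = trio
        if not ({frozenset((a, b)), frozenset((b, c)), frozenset((a, c))} <= c3):
            continue
        total = (beta_of[(a, b)] + beta_of[(b, c)] + beta_of[(c, a)]) % 360.0
        if min(total, 360.0 - total) <= 3 * params.beta_tol:
            trimers.add(frozenset(trio))
    return FrameCensus(time=time, c2_pairs=c2, c3_pairs=c3, trimers=trimers)


def census_trajectory(
    traj: Trajectory,
    center_residue: int,
    params: CensusParams = CensusParams(),
    stride_ns: float = 0.0,
    window: tuple[float, float] | None = None,
) -> list[FrameCensus]:
    """Per-frame census over a (strided, windowed) trajectory."""
    frames = _strided_frames(traj, stride_ns, window)
    out = []
    for frame in frames:
        box = frame.box if frame.periodic else None
        descs = [frame_descriptor(frame, h, center_residue)
                 for h in range(frame.n_helices)]
        out.append(census_frame(descs, params, box))
    return out


def _category_sets(c: FrameCensus, category: str) -> set[frozenset[int]]:
    return {"C2": c.c2_pairs, "C3_pair": c.c3_pairs, "trimer": c.trimers}[category]


def association_records(
    census: Sequence[FrameCensus],
    dt: float,
    gap_tolerance: int = 0,
    categories: Iterable[str] = ("C2", "C3_pair", "trimer"),
) -> list[AssociationRecord]:
    """Association intervals of every member set that ever qualifies.

    An interval opens when a member set first qualifies in its category and
    closes once it fails for more than ``gap_tolerance`` consecutive strides;
    bridged gaps count toward the interval duration.  Census frames must be
    equally strided with spacing ``dt`` (ns).
    """
    records: list[AssociationRecord] = []
    n = len(census)
    for category in categories:
        presence: dict[frozenset[int], np.ndarray] = {}
        for idx, frame in enumerate(census):
            for members in _category_sets(frame, category):
                presence.setdefault(members, np.zeros(n, dtype=bool))[idx] = True
        for members, mask in sorted(presence.items(), key=lambda kv: sorted(kv[0])):
            intervals: list[tuple[float, float]] = []
            start = None
            last_on = None
            for idx in range(n):
                if mask[idx]:
                    if start is None:
                        start = idx
                    last_on = idx
                elif start is not None and idx - last_on > gap_tolerance:
                    intervals.append((start * dt, (last_on + 1) * dt))
                    start = None
            if start is not None:
                intervals.append((start * dt, (last_on + 1) * dt))
            records.append(AssociationRecord(members, category, intervals))
    return records


def association_summary(records: Sequence[AssociationRecord],
                        category: str | None = None) -> dict[str, float]:
    """Aggregate association statistics, optionally for one category.

    Reports accumulated time over all records, the longest single interval,
    the mean per-record accumulated time, and how many distinct member sets
    and distinct helices were involved.
    """
    recs = [r for r in records if category is None or r.category == category]
    if not recs:
        return {"n_records": 0, "n_distinct_helices": 0, "accumulated_ns": 0.0,
                "longest_ns": 0.0, "mean_ns": 0.0}
    acc = [r.accumulated_time for r in recs]
    return {
        "n_records": len(recs),
        "n_distinct_helices": len({h for r in recs for h in r.members}),
        "accumulated_ns": float(np.sum(acc)),
        "longest_ns": float(max(r.longest for r in recs)),
        "mean_ns": float(np.mean(acc)),
    }


def cluster_spots(
    cloud: RadialCloud,
    first_orbit: float = 1.5,
    eps: float = 0.25,
    min_fraction: float = 0.01,
) -> list[SpotCluster]:
    """Density-based clustering of first-orbit radial-cloud points.

    Points with radius < ``first_orbit`` are clustered with DBSCAN
    (radius ``eps``, minimum cluster seed size max(5, min_fraction x
    points)); each spot reports its centroid, angular position alpha, mean
    distance and the beta distribution of its member pairs.  Noise points
    stay unlabelled ("outside").
    """
    from sklearn.cluster import DBSCAN

    if len(cloud) == 0:
        raise ValueError("empty radial cloud")
    inside = np.nonzero(cloud.radius < first_orbit)[0]
    if inside.size == 0:
        return []
    pts = np.column_stack([cloud.x[inside], cloud.y[inside]])
    min_samples = max(5, int(round(min_fraction * inside.size)))
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(pts)
    clusters = []
    for label in sorted(set(labels) - {-1}):
        idx = inside[labels == label]
        cx, cy = float(cloud.x[idx].mean()), float(cloud.y[idx].mean())
        clusters.append(
            SpotCluster(
                label=int(label),
                centroid=(cx, cy),
                alpha=float(np.degrees(np.arctan2(cy, cx)) % 360.0),
                mean_distance=float(cloud.radius[idx].mean()),
                n_points=int(idx.size),
                betas=cloud.beta[idx],
                point_indices=idx,
            )
        )
    return clusters


def markov_transitions(
    cloud: RadialCloud,
    clusters: Sequence[SpotCluster],
    outside_label: str = "outside",
) -> TransitionMatrix:
    """Markov transition matrix of pair trajectories over radial clusters.

    The state of each ordered (reference, neighbour) pair at each strided
    frame is the label of the cluster containing its radial point, or
    "outside".  Transitions are counted between consecutive strides of the
    same pair and each row is normalised; rows with no outgoing transitions
    are flagged instead of normalised.
    """
    times = np.unique(cloud.time)
    if times.size < 2:
        raise ValueError("need at least two strided frames")
    states = [f"spot{c.label}" for c in clusters] + [outside_label]
    state_index = {s: i for i, s in enumerate(states)}
    point_state = np.full(len(cloud), len(states) - 1, dtype=int)
    for c in clusters:
        point_state[c.point_indices] = state_index[f"spot{c.label}"]

    time_index = {t: i for i, t in enumerate(times)}
    S = len(states)
    counts = np.zeros((S, S), dtype=int)
    series: dict[tuple[int, int], np.ndarray] = {}
    for k in range(len(cloud)):
        key = (int(cloud.ref[k]), int(cloud.neighbor[k]))
        series.setdefault(key, np.full(times.size, -1, dtype=int))[
            time_index[cloud.time[k]]
        ] = point_state[k]
    for seq in series.values():
        ok = seq >= 0
        for a, b in zip(seq[:-1][ok[:-1] & ok[1:]], seq[1:][ok[:-1] & ok[1:]]):
            counts[a, b] += 1

    row_sums = counts.sum(axis=1)
    empty = row_sums == 0
    probs = np.zeros_like(counts, dtype=float)
    probs[~empty] = counts[~empty] / row_sums[~empty, None]
    return TransitionMatrix(states=states, counts=counts, probabilities=probs,
                            empty_rows=empty)
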