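"""Ground-truth-labelled synthetic helix-bundle trajectories.

The generator emulates the geometry of the simulated TNFR systems — 36
coarse-grained helices evenly spaced in a 25 x 25 nm membrane plane,
randomly oriented about the membrane normal — with planted C2 dimers, C3
trimers and dimers of trimers whose composition, position and on/off
schedule are known exactly.  Helices are ideal alpha-helix bead curves
moved as rigid bodies: per-frame Gaussian positional jitter plus bounded
(uniform) rotational noise about each helix axis.  There is no physics in
it — no interactions, no diffusion — so it validates the analysis chain,
not the simulations it stands in for.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core import BundleFrame, Trajectory

__all__ = [
    "PlantedAssembly",
    "SyntheticSpec",
    "GroundTruth",
    "ideal_helix",
    "place_assembly",
    "generate_trajectory",
    "membrane_fixture",
    "plan_assemblies",
]

# Canonical alpha-helix geometry for the BB bead curve.
RISE_PER_RESIDUE = 0.15  # nm
TWIST_PER_RESIDUE = 100.0  # degrees
HELIX_RADIUS = 0.23  # nm
MIN_SEPARATION = 0.5  # nm, placements closer than this are rejected


def _rz(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class PlantedAssembly:
    """One planted oligomer: members, placement and optional on/off schedule.

    ``schedule`` lists half-open frame-index intervals [on, off) during which
    the assembly is formed; None means always on.  While off, the members sit
    at their own grid slots like any other helix.
    """

    kind: str  # "C2" | "C3" | "C3x2"
    members: tuple[int, ...]
    center: tuple[float, float]  # nm, membrane plane
    phase: float = 0.0  # degrees
    pair_distance: float = 1.0  # nm, adjacent axis separation
    schedule: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        expected = {"C2": 2, "C3": 3, "C3x2": 6}
        if self.kind not in expected:
            raise ValueError(f"unknown assembly kind {self.kind!r}")
        if len(self.members) != expected[self.kind]:
            raise ValueError(
                f"{self.kind} assembly needs {expected[self.kind]} members"
            )

    def is_on(self, frame: int) -> bool:
        if self.schedule is None:
            return True
        return any(on <= frame < off for on, off in self.schedule)


@dataclass
class SyntheticSpec:
    """Full recipe of a synthetic bundle trajectory (deterministic per seed)."""

    n_helices: int = 36
    n_residues: int = 30
    box: tuple[float, float, float] = (25.0, 25.0, 10.0)
    assemblies: tuple[PlantedAssembly, ...] = ()
    jitter_sigma: float = 0.0  # nm, per-frame rigid displacement
    orientation_noise: float = 0.0  # degrees, uniform in +/- this bound
    n_frames: int = 1
    dt: float = 100.0  # ns between stored frames
    seed: int = 0
    # wandering close pairs: two helices kept within the first orbit of each
    # other but re-oriented at random and radially wobbled every frame — a
    # stand-in for unassigned neighbour spots that drift rather than bind
    wanderer_pairs: tuple[tuple[int, int], ...] = ()
    wanderer_distance: float = 1.35  # nm
    wanderer_sigma: float = 0.08  # nm, per-frame XY wobble

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0 or self.orientation_noise < 0:
            raise ValueError("noise amplitudes must be non-negative")
        members = [m for a in self.assemblies for m in a.members]
        members += [m for p in self.wanderer_pairs for m in p]
        if len(members) != len(set(members)):
            raise ValueError("assembly member ids overlap")
        if members and (min(members) < 0 or max(members) >= self.n_helices):
            raise ValueError("assembly member id out of range")


@dataclass
class GroundTruth:
    """Planted census per frame plus true rigid-body poses."""

    c2_pairs: list[set[frozenset[int]]]
    c3_pairs: list[set[frozenset[int]]]
    trimers: list[set[frozenset[int]]]
    axis_positions: np.ndarray  # (n_frames, H, 3) nm, true helix axis points
    phases: np.ndarray  # (n_frames, H) degrees, true azimuthal pose


def ideal_helix(
    n_residues: int,
    rise_per_res: float = RISE_PER_RESIDUE,
    twist_deg: float = TWIST_PER_RESIDUE,
    radius: float = HELIX_RADIUS,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> np.ndarray:
    """BB beads of an ideal alpha helix, axis along the pose Z.

    Beads sit on the canonical helix curve (rise 0.15 nm, twist 100 degrees,
    radius 0.23 nm per residue), centred on the axis midpoint, then rotated
    and translated by the pose.
    """
    if n_residues < 3:
        raise ValueError("a helix needs at least three residues")
    k = np.arange(n_residues)
    theta = np.radians(twist_deg * k)
    local = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta),
         (k - (n_residues - 1) / 2.0) * rise_per_res]
    )
    if rotation is not None:
        local = local @ np.asarray(rotation, dtype=float).T
    if translation is not None:
        local = local + np.asarray(translation, dtype=float)
    return local


def place_assembly(
    kind: str,
    center: tuple[float, float] = (0.0, 0.0),
    pair_distance: float = 1.0,
    phase: float = 0.0,
    z: float = 0.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rigid poses (rotation, translation) of the members of a Cn assembly.

    C2: two poses related by a 180-degree rotation about the vertical axis
    through the midpoint.  C3: three poses related by 120-degree rotations,
    adjacent axis separation ``pair_distance``.  C3x2 (dimer of trimers):
    two C3 units related by a 180-degree rotation about the assembly centre,
    facing protomers forming a C2 interface at ``pair_distance``.
    """
    cx, cy = center
    c3d = np.array([cx, cy, z])
    if kind == "C2":
        n, ring_radius = 2, pair_distance / 2.0
    elif kind == "C3":
        n, ring_radius = 3, pair_distance / (2.0 * np.sin(np.pi / 3.0))
    elif kind == "C3x2":
        ring_radius = pair_distance / (2.0 * np.sin(np.pi / 3.0))
        half_gap = pair_distance / 2.0 + ring_radius
        unit_a = place_assembly(
            "C3",
            center=(cx - half_gap * np.cos(np.radians(phase)),
                    cy - half_gap * np.sin(np.radians(phase))),
            pair_distance=pair_distance,
            phase=phase,
            z=z,
        )
        flip = _rz(180.0)
        unit_b = [
            (flip @ rot, flip @ (trans - c3d) + c3d) for rot, trans in unit_a
        ]
        return unit_a + unit_b
    else:
        raise ValueError(f"unknown assembly kind {kind!r}")

    poses = []
    for k in range(n):
        rot = _rz(phase + k * 360.0 / n)
        trans = c3d + rot @ np.array([ring_radius, 0.0, 0.0])
        poses.append((rot, trans))
    return poses


def _grid_positions(n_helices: int, box: tuple[float, float, float]) -> np.ndarray:
    """Evenly spaced XY slots (one per helix) in the membrane plane."""
    side = int(round(np.sqrt(n_helices)))
    if side * side != n_helices:
        raise ValueError(f"{n_helices} helices do not form a square grid")
    sx, sy = box[0] / side, box[1] / side
    ij = np.array(list(itertools.product(range(side), range(side))))
    return np.column_stack(
        [(ij[:, 0] + 0.5) * sx, (ij[:, 1] + 0.5) * sy]
    )


def plan_assemblies(
    n_c2: int = 0,
    n_c3: int = 0,
    n_c3x2: int = 0,
    n_helices: int = 36,
    box: tuple[float, float, float] = (25.0, 25.0, 10.0),
    pair_distance: float = 1.0,
    phases: float | list[float] = 0.0,
) -> tuple[PlantedAssembly, ...]:
    """Assign member ids and centres for a set of planted assemblies.

    Members get consecutive helix ids; each assembly is centred on the grid
    slot of its first member, which keeps assemblies separated by at least
    one grid spacing from every other occupied slot.
    """
    grid = _grid_positions(n_helices, box)
    kinds = ["C2"] * n_c2 + ["C3"] * n_c3 + ["C3x2"] * n_c3x2
    sizes = {"C2": 2, "C3": 3, "C3x2": 6}
    if isinstance(phases, (int, float)):
        phases = [float(phases)] * len(kinds)
    assemblies = []
    next_id = 0
    for kind, phase in zip(kinds, phases):
        members = tuple(range(next_id, next_id + sizes[kind]))
        if members[-1] >= n_helices:
            raise ValueError("not enough helices for the requested assemblies")
        assemblies.append(
            PlantedAssembly(
                kind=kind,
                members=members,
                center=tuple(grid[members[0]]),
                phase=phase,
                pair_distance=pair_distance,
            )
        )
        next_id = members[-1] + 1
    return tuple(assemblies)


def _planted_census(
    assembly: PlantedAssembly,
) -> tuple[set[frozenset[int]], set[frozenset[int]], set[frozenset[int]]]:
    m = assembly.members
    if assembly.kind == "C2":
        return {frozenset(m)}, set(), set()
    if assembly.kind == "C3":
        pairs = {frozenset(p) for p in itertools.combinations(m, 2)}
        return set(), pairs, {frozenset(m)}
    # C3x2: two trimers plus the facing C2 interface (first member of each unit)
    t1, t2 = m[:3], m[3:]
    pairs = {frozenset(p) for t in (t1, t2) for p in itertools.combinations(t, 2)}
    return {frozenset((t1[0], t2[0]))}, pairs, {frozenset(t1), frozenset(t2)}


def generate_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Build the synthetic trajectory and its exact ground truth.

    Deterministic for a given spec (seed included).  Unplanted helices sit
    at their grid slots with a fresh random orientation each frame; planted
    assemblies follow their schedule.  All helices receive independent
    per-frame rigid jitter (Gaussian displacement of ``jitter_sigma``,
    uniform axis rotation within ``orientation_noise`` degrees).

    Raises if two helix axes come closer than 0.5 nm, naming the offenders.
    """
    rng = np.random.default_rng(spec.seed)
    H, N = spec.n_helices, spec.n_residues
    box = np.asarray(spec.box, dtype=float)
    grid = _grid_positions(H, box)
    z_mid = box[2] / 2.0
    member_pose: dict[int, list] = {}

    planted_ids = {m for a in spec.assemblies for m in a.members}
    frames: list[BundleFrame] = []
    gt_c2, gt_c3, gt_tri = [], [], []
    axis_positions = np.zeros((spec.n_frames, H, 3))
    phases = np.zeros((spec.n_frames, H))

    assembly_poses = {
        id(a): place_assembly(a.kind, a.center, a.pair_distance, a.phase, z=z_mid)
        for a in spec.assemblies
    }

    for f in range(spec.n_frames):
        rot = np.zeros((H, 3, 3))
        pos = np.zeros((H, 3))
        pose_phase = np.zeros(H)
        # free helices (and off-schedule members) at their grid slots
        for h in range(H):
            angle = rng.uniform(0.0, 360.0)
            rot[h] = _rz(angle)
            pos[h] = np.array([grid[h, 0], grid[h, 1], z_mid])
            pose_phase[h] = angle
        for a_id, b_id in spec.wanderer_pairs:
            center = np.array([grid[a_id, 0], grid[a_id, 1], z_mid])
            half = np.array([spec.wanderer_distance / 2.0, 0.0, 0.0])
            for m_id, offset in ((a_id, half), (b_id, -half)):
                wob = np.append(rng.normal(0.0, spec.wanderer_sigma, 2), 0.0)
                pos[m_id] = center + offset + wob
        c2: set[frozenset[int]] = set()
        c3: set[frozenset[int]] = set()
        tri: set[frozenset[int]] = set()
        for a in spec.assemblies:
            if not a.is_on(f):
                continue
            for member, (r, t) in zip(a.members, assembly_poses[id(a)]):
                rot[member] = r
                pos[member] = t
                pose_phase[member] = np.degrees(np.arctan2(r[1, 0], r[0, 0]))
            pc2, pc3, ptri = _planted_census(a)
            c2 |= pc2
            c3 |= pc3
            tri |= ptri

        # reject overlapping placements before jitter
        d = np.linalg.norm(pos[:, None, :2] - pos[None, :, :2], axis=-1)
        np.fill_diagonal(d, np.inf)
        bad = np.argwhere(d < MIN_SEPARATION)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"helices {i} and {j} placed {d[i, j]:.3f} nm apart "
                f"(< {MIN_SEPARATION} nm) at frame {f}"
            )

        coords = np.zeros((H, N, 3))
        for h in range(H):
            r, t = rot[h], pos[h].copy()
            if spec.orientation_noise > 0:
                wobble = rng.uniform(-spec.orientation_noise,
                                     spec.orientation_noise)
                r = _rz(wobble) @ r
            if spec.jitter_sigma > 0:
                t = t + rng.normal(0.0, spec.jitter_sigma, size=3)
            coords[h] = ideal_helix(N, rotation=r, translation=t)
        frames.append(
            BundleFrame(time=f * spec.dt, box=box, coords=coords, periodic=True)
        )
        gt_c2.append(c2)
        gt_c3.append(c3)
        gt_tri.append(tri)
        axis_positions[f] = pos
        phases[f] = pose_phase

    traj = Trajectory(
        frames=frames,
        variant="synthetic",
        residue_numbers=np.arange(1, N + 1),
        residue_names=["GLY"] * N,
        sources=("synthetic",),
    )
    truth = GroundTruth(gt_c2, gt_c3, gt_tri, axis_positions, phases)
    return traj, truth


def membrane_fixture(
    n_lipids: int = 1700,
    box: tuple[float, float, float] = (25.0, 25.0, 10.0),
    thickness: float = 3.6,
    species_ratio: tuple[int, int] = (7, 3),
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Flat two-leaflet arrangement of lipid head beads.

    Head beads sit at z = mid +/- thickness / 2 on jittered XY grids, half
    per leaflet, labelled DOPC/DLPC in the given ratio (7:3 emulates the
    fluid-membrane composition of the reference systems).  Returns head-bead
    coordinates (nm) and per-lipid species labels.
    """
    if n_lipids % 2:
        raise ValueError("lipid count must be even (two leaflets)")
    rng = np.random.default_rng(seed)
    per_leaflet = n_lipids // 2
    side = int(np.ceil(np.sqrt(per_leaflet)))
    xs = (np.arange(side) + 0.5) * box[0] / side
    ys = (np.arange(side) + 0.5) * box[1] / side
    gx, gy = np.meshgrid(xs, ys)
    slots = np.column_stack([gx.ravel(), gy.ravel()])[:per_leaflet]
    z_mid = box[2] / 2.0
    coords = np.zeros((n_lipids, 3))
    for leaflet, sign in enumerate((1.0, -1.0)):
        sl = slice(leaflet * per_leaflet, (leaflet + 1) * per_leaflet)
        coords[sl, :2] = slots + rng.normal(0.0, 0.05, size=slots.shape)
        coords[sl, 2] = z_mid + sign * thickness / 2.0
    n_major = int(round(n_lipids * species_ratio[0] / sum(species_ratio)))
    species = ["DOPC"] * n_major + ["DLPC"] * (n_lipids - n_major)
    return coords, species
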