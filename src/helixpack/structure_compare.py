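"""Rigid superposition and symmetry-aware RMSD decomposition.

Assemblies extracted from coarse-grained trajectories are compared against
NMR reference structures at the backbone-bead level: a Kabsch least-squares
superposition gives the total RMSD, a chain-permutation search handles the
arbitrary protomer labelling of symmetric oligomers, and deviations can be
decomposed about a fitted Cn symmetry axis into radial, tangential and
axial components (R^2 + T^2 + A^2 = RMSD^2, an exact identity because the
cylindrical basis is orthonormal at every bead).

Comparisons are between CG backbone beads, not backmapped all-atom
structures, so absolute RMSD values are not interchangeable with all-atom
figures; the decomposition and relative comparisons are.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import BundleFrame, Trajectory

__all__ = [
    "Superposition",
    "RTADecomposition",
    "kabsch_superpose",
    "ensemble_average",
    "best_oligomer_match",
    "fit_cn_axis",
    "rta_rmsd",
]

NM_TO_ANGSTROM = 10.0


@dataclass
class Superposition:
    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,), applied after rotation
    rmsd: float  # nm
    n_atoms: int
    permutation: tuple[int, ...] | None = None  # chain correspondence, if searched

    @property
    def rmsd_angstrom(self) -> float:
        return self.rmsd * NM_TO_ANGSTROM

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class CnAxis:
    point: np.ndarray  # (3,) nm, on the axis (assembly centroid)
    direction: np.ndarray  # (3,) unit vector
    order: int
    azimuths: np.ndarray  # degrees, one per protomer
    max_gap_deviation: float  # degrees, max |azimuth gap - 360/n|


@dataclass
class RTADecomposition:
    axis: CnAxis
    radial_rmsd: float  # nm
    tangential_rmsd: float  # nm
    axial_rmsd: float  # nm
    total_rmsd: float  # nm
    n_excluded: int  # beads on the axis (radial basis undefined)


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> Superposition:
    """Optimal least-squares rigid superposition of mobile onto reference.

    Coordinates are corresponding (n, 3) arrays in nm.  Raises on fewer than
    three beads or a degenerate (collinear) configuration.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have the same shape")
    if mobile.shape[0] < 3:
        raise ValueError("need at least three corresponding beads")

    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    P, Q = mobile - mc, reference - rc
    sing = np.linalg.svd(P, compute_uv=False)
    if sing[1] < 1e-9 * max(sing[0], 1.0):
        raise ValueError("degenerate (collinear) bead configuration")

    U, _, Vt = np.linalg.svd(P.T @ Q)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = P @ R.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    translation = rc - R @ mc
    return Superposition(rotation=R, translation=translation, rmsd=rmsd,
                         n_atoms=mobile.shape[0])


def ensemble_average(traj: Trajectory) -> tuple[BundleFrame, np.ndarray]:
    """Average structure of a multi-model ensemble plus per-bead spread.

    Every model is superposed onto model 0 (all beads of all helices used as
    the correspondence), coordinates are averaged, and the spread is the
    per-bead RMS deviation about the mean.
    """
    if len(traj) < 2:
        raise ValueError("ensemble average needs at least two models")
    shape = traj.frames[0].coords.shape
    ref = traj.frames[0].coords.reshape(-1, 3)
    aligned = [ref]
    for frame in traj.frames[1:]:
        sup = kabsch_superpose(frame.coords.reshape(-1, 3), ref)
        aligned.append(sup.apply(frame.coords.reshape(-1, 3)))
    stack = np.stack(aligned)
    mean = stack.mean(axis=0)
    spread = np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0))
    frame = BundleFrame(
        time=0.0, box=traj.frames[0].box, coords=mean.reshape(shape),
        periodic=False,
    )
    return frame, spread.reshape(shape[:2])


def best_oligomer_match(
    mobile_assembly: np.ndarray, reference_assembly: np.ndarray
) -> Superposition:
    """Minimum-RMSD superposition over chain correspondences.

    Both assemblies are (n_helices, n_residues, 3) arrays with equal shapes.
    All chain permutations are tried (exhaustive; assemblies here have at
    most six protomers) and the winning correspondence is reported.
    """
    mobile_assembly = np.asarray(mobile_assembly, dtype=float)
    reference_assembly = np.asarray(reference_assembly, dtype=float)
    if mobile_assembly.shape != reference_assembly.shape:
        raise ValueError(
            f"assembly size mismatch: {mobile_assembly.shape} vs "
            f"{reference_assembly.shape}"
        )
    n = mobile_assembly.shape[0]
    if n > 6:
        raise ValueError("permutation search supports assemblies of up to 6 helices")
    ref_flat = reference_assembly.reshape(-1, 3)
    best: Superposition | None = None
    for perm in itertools.permutations(range(n)):
        sup = kabsch_superpose(mobile_assembly[list(perm)].reshape(-1, 3), ref_flat)
        if best is None or sup.rmsd < best.rmsd:
            best = sup
            best.permutation = perm
    assert best is not None
    return best


def fit_cn_axis(assembly: np.ndarray, n: int) -> CnAxis:
    """Fit an n-fold symmetry axis to an assembly of helices.

    The axis passes through the assembly centroid along the principal
    direction of the bead cloud most aligned with the membrane normal (Z).
    When the assembly holds more than n helices (e.g. a trimer of dimers
    with n = 3), consecutive groups of equal size form the protomers.  The
    deviation reported is the largest |azimuth gap - 360/n| over cyclically
    consecutive protomer azimuths.
    """
    assembly = np.asarray(assembly, dtype=float)
    if n < 2:
        raise ValueError("symmetry order must be at least 2")
    n_helices = assembly.shape[0]
    if n_helices % n:
        raise ValueError(f"{n_helices} helices not divisible by symmetry order {n}")

    flat = assembly.reshape(-1, 3)
    centroid = flat.mean(axis=0)
    centered = flat - centroid
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    direction = Vt[np.argmax(np.abs(Vt[:, 2]))]
    if direction[2] < 0:
        direction = -direction
    if np.linalg.norm(direction) < 1e-12:
        raise ValueError("degenerate assembly geometry")

    group = n_helices // n
    protomer_centroids = assembly.reshape(n, group, -1, 3).mean(axis=(1, 2))
    # azimuths in the plane perpendicular to the axis
    e1 = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.array([1.0, 0.0, 0.0])
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    rel = protomer_centroids - centroid
    az = np.degrees(np.arctan2(rel @ e2, rel @ e1)) % 360.0
    order = np.argsort(az)
    gaps = np.diff(np.concatenate([az[order], [az[order][0] + 360.0]]))
    deviation = float(np.max(np.abs(gaps - 360.0 / n)))
    return CnAxis(point=centroid, direction=direction, order=n,
                  azimuths=az, max_gap_deviation=deviation)


def rta_rmsd(
    mobile: np.ndarray, reference: np.ndarray, axis: CnAxis
) -> RTADecomposition:
    """Decompose per-bead deviations into radial/tangential/axial RMSDs.

    ``mobile`` must already be superposed onto ``reference`` (same shapes).
    At each reference bead the orthonormal cylindrical basis about the axis
    is (radial away from the axis, tangential = axis x radial, axial along
    the axis); beads lying on the axis have no radial direction and are
    excluded from all three components (and counted).
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mobile.shape != reference.shape:
        raise ValueError("shape mismatch")
    dev = mobile - reference

    a = axis.direction / np.linalg.norm(axis.direction)
    rel = reference - axis.point
    radial = rel - np.outer(rel @ a, a)
    norms = np.linalg.norm(radial, axis=1)
    ok = norms > 1e-9
    n_excluded = int(np.count_nonzero(~ok))
    if not np.any(ok):
        raise ValueError("every bead lies on the symmetry axis")
    r_hat = radial[ok] / norms[ok, None]
    t_hat = np.cross(a, r_hat)
    d = dev[ok]
    r_comp = np.einsum("ij,ij->i", d, r_hat)
    t_comp = np.einsum("ij,ij->i", d, t_hat)
    a_comp = d @ a
    return RTADecomposition(
        axis=axis,
        radial_rmsd=float(np.sqrt(np.mean(r_comp**2))),
        tangential_rmsd=float(np.sqrt(np.mean(t_comp**2))),
        axial_rmsd=float(np.sqrt(np.mean(a_comp**2))),
        total_rmsd=float(np.sqrt(np.mean(np.sum(d**2, axis=1)))),
        n_excluded=n_excluded,
    )
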