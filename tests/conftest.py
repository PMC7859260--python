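import numpy as np
import pytest

from helixpack.core import BundleFrame, Trajectory
from helixpack.radial_geometry import frame_descriptor
from helixpack.synthetic import ideal_helix, place_assembly

BOX = (25.0, 25.0, 10.0)


def assembly_frame(kind: str, center=(12.0, 12.0), phase=0.0, n_residues=30,
                   pair_distance=1.0, time=0.0) -> BundleFrame:
    """One frame holding a single ideal planted assembly."""
    poses = place_assembly(kind, center=center, pair_distance=pair_distance,
                           phase=phase, z=BOX[2] / 2)
    coords = np.stack([ideal_helix(n_residues, rotation=r, translation=t)
                       for r, t in poses])
    return BundleFrame(time=time, box=BOX, coords=coords)


def descriptors(frame: BundleFrame, center_residue: int | None = None):
    cr = center_residue if center_residue is not None else frame.n_residues // 2
    return [frame_descriptor(frame, h, cr) for h in range(frame.n_helices)]


def random_bundle(rng, n_helices=4, n_residues=12, box=BOX, spread=6.0,
                  periodic=True, n_frames=1) -> Trajectory:
    """Randomly posed ideal helices packed into a small patch."""
    frames = []
    for f in range(n_frames):
        coords = []
        for _ in range(n_helices):
            angle = rng.uniform(0, 360)
            a = np.radians(angle)
            rot = np.array([[np.cos(a), -np.sin(a), 0],
                            [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
            t = np.array([rng.uniform(2, 2 + spread), rng.uniform(2, 2 + spread),
                          box[2] / 2])
            coords.append(ideal_helix(n_residues, rotation=rot, translation=t))
        frames.append(BundleFrame(time=float(f), box=box,
                                  coords=np.stack(coords), periodic=periodic))
    return Trajectory(frames=frames, variant="synthetic",
                      residue_numbers=np.arange(1, n_residues + 1),
                      residue_names=["GLY"] * n_residues)


def brute_force_contact_matrix(traj, cutoff):
    """O(H^2 N^2) reference: explicit loops, explicit minimum image."""
    N = traj.n_residues
    counts = np.zeros((N, N))
    for frame in traj.frames:
        box = frame.box if frame.periodic else None
        H = frame.n_helices
        for K in range(H):
            for Hh in range(H):
                if K == Hh:
                    continue
                for i in range(N):
                    for j in range(N):
                        d = frame.coords[K, i] - frame.coords[Hh, j]
                        if box is not None:
                            d = d - box * np.round(d / box)
                        if np.linalg.norm(d) <= cutoff:
                            counts[i, j] += 1
    return counts


@pytest.fixture
def rng():
    return np.random.default_rng(20260402)


@pytest.fixture
def trimer_frame():
    return assembly_frame("C3")


@pytest.fixture
def dimer_frame():
    return assembly_frame("C2")
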