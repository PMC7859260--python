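"""Core containers for helix-bundle trajectories.

A *bundle* is a set of transmembrane helices in one membrane patch, each
represented by the ordered backbone (BB) beads of its residues.  All
coordinates are stored in nanometres; times in nanoseconds.  Boxes are
orthorhombic; frames read from NMR ensembles are flagged non-periodic so
distance code skips the minimum-image convention for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "BackboneBead",
    "BundleFrame",
    "Trajectory",
    "minimum_image",
    "minimum_image_distance",
]

#: Default box (nm) assigned to frames that carry no cell information.
DEFAULT_BOX = (25.0, 25.0, 10.0)


@dataclass(frozen=True)
class BackboneBead:
    """One coarse-grained backbone bead (one residue).

    ``residue_index`` is sequence-local and 0-based; ``residue_number`` keeps
    the author numbering from the source structure for reporting.
    """

    helix_id: int
    residue_index: int
    residue_number: int
    residue_name: str
    position: np.ndarray  # (3,) nm

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("bead position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class BundleFrame:
    """One time point of a helix bundle.

    ``coords`` has shape (n_helices, n_residues, 3): every helix of a frame
    shares the residue count (one peptide variant per bundle).
    """

    time: float  # ns
    box: np.ndarray  # (3,) nm
    coords: np.ndarray  # (H, N, 3) nm
    periodic: bool = True

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be a positive 3-vector (nm)")
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_helices, n_residues, 3)")

    @property
    def n_helices(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


@dataclass
class Trajectory:
    """Time-ordered bundle frames plus residue metadata.

    ``residue_numbers`` / ``residue_names`` apply to every helix (all helices
    of a bundle carry the same peptide variant).  ``helix_pairs`` optionally
    records covalent pairing metadata (e.g. disulphide-linked dimers); the
    pairing is bookkeeping only and never merges helices.
    """

    frames: list[BundleFrame]
    variant: str = ""
    residue_numbers: np.ndarray | None = None
    residue_names: list[str] | None = None
    sources: tuple[str, ...] = ()
    helix_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        times = [f.time for f in self.frames]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be non-decreasing")
        h = {f.n_helices for f in self.frames}
        if len(h) != 1:
            raise ValueError("helix count must be constant across frames")
        if self.residue_numbers is not None:
            self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[BundleFrame]:
        return iter(self.frames)

    @property
    def n_helices(self) -> int:
        return self.frames[0].n_helices

    @property
    def n_residues(self) -> int:
        return self.frames[0].n_residues

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def beads(self, frame_index: int, helix_id: int) -> list[BackboneBead]:
        """Materialise the BackboneBead view of one helix in one frame."""
        frame = self.frames[frame_index]
        nums = (
            self.residue_numbers
            if self.residue_numbers is not None
            else np.arange(frame.n_residues)
        )
        names = self.residue_names or ["UNK"] * frame.n_residues
        return [
            BackboneBead(helix_id, i, int(nums[i]), names[i], frame.coords[helix_id, i])
            for i in range(frame.n_residues)
        ]

    def window(self, t_start: float, t_end: float) -> "Trajectory":
        """Sub-trajectory with frame times in [t_start, t_end]."""
        frames = [f for f in self.frames if t_start <= f.time <= t_end]
        if not frames:
            raise ValueError(
                f"window [{t_start}, {t_end}] ns selects no frames "
                f"(trajectory spans [{self.frames[0].time}, {self.frames[-1].time}] ns)"
            )
        return replace(self, frames=frames)


def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the primary image of an orthorhombic box.

    ``delta`` may have any shape (..., d) with d <= 3; ``box`` is broadcast
    against the last axis.  ``box=None`` returns ``delta`` unchanged
    (non-periodic frame).
    """
    delta = np.asarray(delta, dtype=float)
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)[..., : delta.shape[-1]]
    return delta - box * np.round(delta / box)


def minimum_image_distance(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Euclidean distance under the minimum-image convention (plain when box is None)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    return np.linalg.norm(minimum_image(a - b, box), axis=-1)
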