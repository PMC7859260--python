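"""Run configuration: validated parameter schema shared by CLI and scripts.

Defaults follow the reference analysis of the TNFR systems: paired contact
cut-offs of 0.5 and 0.8 nm, an analysis window opening at 3000 ns (after
membrane convergence), a 100 ns stride for radial maps, and per-variant
reference residues for the body frame (the middle residue of the
centroid/orientation triplet): I259 for p75, L182 for Fas, T219 for DR5
trimer analysis and G217 for DR5 dimer analysis.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, Field, field_validator

from .io_structures import peptide_registry

__all__ = ["RunConfig", "CensusSection", "ClusterSection", "SynthSection",
           "default_center_residue", "load_config"]

# Author-numbered central residue of the orientation triplet, per variant
# family.  "DR5 dimer" is the alternative reference used to isolate the
# dimeric spot.
_DEFAULT_CENTER = {
    "p75": 259,  # S258, I259, L260
    "Fas": 182,  # L181, L182, P183
    "DR5": 219,  # V218, T219, V220
    "DR5 dimer": 217,  # G217, dimer-face reference
}


def default_center_residue(variant: str, mode: str = "trimer") -> int:
    """Default author-numbered reference residue for a peptide variant."""
    if variant.startswith("DR5") and mode == "dimer":
        return _DEFAULT_CENTER["DR5 dimer"]
    for family, resnum in _DEFAULT_CENTER.items():
        if variant.startswith(family):
            return resnum
    raise KeyError(f"no default reference residue for variant {variant!r}")


class CensusSection(BaseModel):
    d_max: float = Field(1.5, gt=0, description="first-orbit radius, nm")
    beta_tol: float = Field(25.0, gt=0, le=30.0,
                            description="angular tolerance, degrees")
    gap_tolerance: int = Field(0, ge=0)


class ClusterSection(BaseModel):
    first_orbit: float = Field(1.5, gt=0)
    eps: float = Field(0.25, gt=0)
    min_fraction: float = Field(0.01, ge=0)


class SynthSection(BaseModel):
    n_helices: int = 36
    n_residues: int = 30
    box: tuple[float, float, float] = (25.0, 25.0, 10.0)
    n_c2: int = 0
    n_c3: int = 0
    n_c3x2: int = 0
    jitter_sigma: float = 0.0
    orientation_noise: float = 0.0
    n_frames: int = 1
    dt: float = 100.0


class RunConfig(BaseModel):
    """Validated configuration of one analysis run."""

    variant: str = "synthetic"
    # inputs: either a multi-model structure, or topology (+ trajectory)
    structure: Optional[Path] = None
    topology: Optional[Path] = None
    trajectory: Optional[Path] = None
    bb_selection: str = "name BB"
    helix_grouping: Optional[int | list[tuple[int, int]]] = None
    head_selection: str = "name PO4"
    n_lipids: Optional[int] = None

    center_residue: Optional[int] = None  # author numbering
    cutoffs: list[float] = [0.5, 0.8]
    window: tuple[float, Optional[float]] = (3000.0, None)
    stride_ns: float = 100.0
    census: CensusSection = CensusSection()
    cluster: ClusterSection = ClusterSection()
    synth: SynthSection = SynthSection()
    seed: int = 0
    box_default: tuple[float, float, float] = (25.0, 25.0, 10.0)

    @field_validator("cutoffs")
    @classmethod
    def _positive_cutoffs(cls, v: list[float]) -> list[float]:
        if not v or any(c <= 0 for c in v):
            raise ValueError("cutoffs must be positive")
        return v

    @field_validator("variant")
    @classmethod
    def _known_variant(cls, v: str) -> str:
        if v not in ("synthetic", ""):
            peptide_registry(v)  # raises with the list of valid names
        return v

    def resolve_center_index(self, residue_numbers) -> int:
        """Sequence-local index of the reference residue for this run."""
        import numpy as np

        if self.center_residue is not None:
            target = self.center_residue
        elif self.variant == "synthetic":
            return int(len(residue_numbers) // 2)
        else:
            target = default_center_residue(self.variant)
        idx = np.nonzero(np.asarray(residue_numbers) == target)[0]
        if idx.size == 0:
            raise ValueError(
                f"reference residue {target} not present in the loaded sequence"
            )
        return int(idx[0])


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) config file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
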