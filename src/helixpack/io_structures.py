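"""Readers and writers for helix bundles, plus the TNFR peptide registry.

Multi-model PDB ensembles (NMR structures such as 2mic, 2na7, 6nhw) are read
with each model treated as one trajectory snapshot.  Coarse-grained GRO/XTC
trajectories are read through MDAnalysis.  The backbone bead of a residue in
an NMR model is proxied by its CA atom: the Martini BB bead sits at the
backbone centre of mass, within ~0.07 nm of CA, an accepted approximation
since no coarse-graining step is performed here.

Internally everything is nanometres and nanoseconds; PDB angstroms are
converted on read/write.  PDB models are numbered 0..M-1 with time equal to
the ordinal.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import DEFAULT_BOX, BundleFrame, Trajectory

__all__ = [
    "PeptideRecord",
    "peptide_registry",
    "load_multimodel_structure",
    "load_cg_trajectory",
    "write_pdb",
    "write_gro",
    "write_trajectory",
]

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass(frozen=True)
class PeptideRecord:
    """One transmembrane peptide variant: sequence and author numbering."""

    name: str
    sequence: str  # 1-letter codes
    start_number: int
    notes: str = ""

    @property
    def end_number(self) -> int:
        return self.start_number + len(self.sequence) - 1

    def residue_number(self, index: int) -> int:
        return self.start_number + index

    def one_letter(self, residue_number: int) -> str:
        return self.sequence[residue_number - self.start_number]


# TNFR transmembrane peptide variants: the three receptors solved by NMR
# (p75NTR, Fas, DR5) plus the simulated mutants.  "NMR" rows are the peptide
# constructs of the deposited ensembles; the others are the simulated
# variants.
_REGISTRY: dict[str, PeptideRecord] = {
    r.name: r
    for r in [
        PeptideRecord(
            "p75 NMR (2mic)",
            "MTRGTTDNLIPVYCSILAAVVVGLVAYIAFKRWNSSKQNKQ",
            244,
            "disulphide-linked dimer construct",
        ),
        PeptideRecord("p75 dimer (SS)", "TTDNLIPVYCSILAAVVVGLVAYIAFKRWNSS", 248,
                      "covalent dimer via C257"),
        PeptideRecord("p75 (SH)", "TTDNLIPVYCSILAAVVVGLVAYIAFKRWNSS", 248,
                      "reduced form, free C257"),
        PeptideRecord(
            "p75 NMR (2mjo)",
            "MTRGTTDNLIPVYASILAAVVVGLVAYIAFKRWNSSKQNKQ",
            244,
            "C257A construct",
        ),
        PeptideRecord("p75 (C257A)", "TTDNLIPVYASILAAVVVGLVAYIAFKRWNSS", 248,
                      "C257A, functionally inactive mutant"),
        PeptideRecord("Fas NMR (2na7)", "RSNLGWLSLLLLPIPLIVWVKRKEVQKT", 171,
                      "C178S construct"),
        PeptideRecord("Fas wt", "RSNLGWLCLLLLPIPLIVWVKRKE", 171, "wild type"),
        PeptideRecord("Fas C178S", "RSNLGWLSLLLLPIPLIVWVKRKE", 171,
                      "NMR-matched mutation"),
        PeptideRecord("Fas C178R", "RSNLGWLRLLLLPIPLIVWVKRKE", 171,
                      "pathogenic mutation"),
        PeptideRecord(
            "DR5 NMR (6nhw)",
            "MPGSLSGIIIGVTVAAVVLIVAVFVCKSLLWKKVL",
            207,
            "C209G construct",
        ),
        PeptideRecord("DR5 wt", "SPCSLSGIIIGVTVAAVVLIVAVFVCKSLLWKKVL", 207,
                      "wild type"),
        PeptideRecord("DR5 A222Y", "SPCSLSGIIIGVTVAYVVLIVAVFVCKSLLWKKVL", 207,
                      "trimer-disrupting mutation"),
        PeptideRecord("DR5 G217Y", "SPCSLSGIIIYVTVAAVVLIVAVFVCKSLLWKKVL", 207,
                      "dimer-disrupting mutation"),
    ]
}


def peptide_registry(name: str) -> PeptideRecord:
    """Look up a peptide variant by its registry name.

    Raises KeyError with the list of valid names for unknown variants.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        valid = ", ".join(sorted(_REGISTRY))
        raise KeyError(f"unknown peptide variant {name!r}; valid names: {valid}") from None


def registry_names() -> list[str]:
    return sorted(_REGISTRY)


def _three_letter(one: str) -> str:
    from Bio.SeqUtils import seq3

    return seq3(one).upper()


def _parse_cryst1(path: str | Path) -> np.ndarray | None:
    """Box edge lengths (nm) from a CRYST1 record, if one is present and real."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                try:
                    abc = np.array([float(line[6:15]), float(line[15:24]),
                                    float(line[24:33])]) / 10.0
                except ValueError:
                    return None
                # placeholder 1 A x 1 A x 1 A cells mean "no cell"
                if np.all(abc > 0.2):
                    return abc
                return None
    return None


def load_multimodel_structure(
    path: str | Path,
    helix_assignment: Mapping[str, int] | None = None,
    variant: str = "",
    default_box: Sequence[float] = DEFAULT_BOX,
) -> Trajectory:
    """Read a (multi-)model PDB file into a Trajectory, one frame per model.

    ``helix_assignment`` maps chain IDs to 0-based helix indices; by default
    every chain of the first model becomes a helix, in chain-ID order.  The
    BB bead position is taken from the CA atom of each residue.  Frame time
    is the model ordinal (a structural ensemble has no physical time axis).

    Raises ValueError naming the chain and model if a mapped chain is absent
    from any model, or listing missing residue numbers on numbering gaps.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("bundle", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")

    if helix_assignment is None:
        chains = sorted(c.id for c in models[0])
        helix_assignment = {c: i for i, c in enumerate(chains)}
    order = sorted(helix_assignment, key=lambda c: helix_assignment[c])

    box = _parse_cryst1(path)
    if box is None:
        box = np.asarray(default_box, dtype=float)

    frames: list[BundleFrame] = []
    residue_numbers: np.ndarray | None = None
    residue_names: list[str] | None = None
    for m_idx, model in enumerate(models):
        present = {c.id for c in model}
        helices = []
        for chain_id in order:
            if chain_id not in present:
                raise ValueError(
                    f"{path}: chain {chain_id!r} missing from model {m_idx}"
                )
            chain = model[chain_id]
            residues = [r for r in chain if "CA" in r or "BB" in r]
            if not residues:
                raise ValueError(
                    f"{path}: chain {chain_id!r} model {m_idx} has no CA/BB atoms"
                )
            nums = np.array([r.id[1] for r in residues])
            gaps = [
                n
                for lo, hi in zip(nums, nums[1:])
                for n in range(lo + 1, hi)
            ]
            if gaps:
                raise ValueError(
                    f"{path}: chain {chain_id!r} model {m_idx} has residue gaps: {gaps}"
                )
            atom = lambda r: r["BB"] if "BB" in r else r["CA"]
            coords = np.array([atom(r).coord for r in residues]) / 10.0  # A -> nm
            if residue_numbers is None:
                residue_numbers = nums
                residue_names = [r.get_resname() for r in residues]
            helices.append(coords)
        lengths = {len(h) for h in helices}
        if len(lengths) != 1:
            raise ValueError(f"{path}: helices have unequal residue counts {lengths}")
        frames.append(
            BundleFrame(time=float(m_idx), box=box, coords=np.stack(helices),
                        periodic=False)
        )

    return Trajectory(
        frames=frames,
        variant=variant,
        residue_numbers=residue_numbers,
        residue_names=residue_names,
        sources=(str(path),),
    )


def load_cg_trajectory(
    topology: str | Path,
    trajectory: str | Path | None = None,
    bb_selection: str = "name BB",
    helix_grouping: int | Sequence[tuple[int, int]] | None = None,
    variant: str = "",
    covalent_pairs: str | Sequence[tuple[int, int]] | None = None,
) -> Trajectory:
    """Read a coarse-grained GRO (+ XTC/TRR) trajectory into a Trajectory.

    ``bb_selection`` is an MDAnalysis selection picking the backbone beads.
    ``helix_grouping`` partitions the selected beads into helices: either an
    integer (split into that many equal consecutive runs) or a list of
    author residue-number ranges ``(lo, hi)``, one per helix.  Defaults to
    one helix per segment.

    ``covalent_pairs="consecutive"`` records helices (0,1), (2,3), ... as
    covalently linked (e.g. disulphide-bonded dimers analysed as separate
    helices with pair metadata).
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = (
            mda.Universe(str(topology))
            if trajectory is None
            else mda.Universe(str(topology), str(trajectory))
        )
    sel = u.select_atoms(bb_selection)
    if len(sel) == 0:
        raise ValueError(f"selection {bb_selection!r} resolves to 0 beads")

    if helix_grouping is None:
        groups = [sel.intersection(seg.atoms) for seg in u.segments]
        groups = [g for g in groups if len(g) > 0]
    elif isinstance(helix_grouping, int):
        if len(sel) % helix_grouping:
            raise ValueError(
                f"{len(sel)} beads cannot be split into {helix_grouping} equal helices"
            )
        n = len(sel) // helix_grouping
        groups = [sel[i * n : (i + 1) * n] for i in range(helix_grouping)]
    else:
        groups = [
            sel.select_atoms(f"resid {lo}:{hi}") for lo, hi in helix_grouping
        ]
        if any(len(g) == 0 for g in groups):
            raise ValueError("a residue range in helix_grouping selects no beads")

    lengths = {len(g) for g in groups}
    if len(lengths) != 1:
        raise ValueError(f"unequal helix lengths: {sorted(lengths)}")

    first = groups[0]
    residue_numbers = first.resids.copy()
    residue_names = [str(r) for r in first.resnames]

    frames = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Reader has no dt information")
        for ts in u.trajectory:
            coords = np.stack([g.positions for g in groups]) / 10.0  # A -> nm
            box = np.asarray(ts.dimensions[:3], dtype=float) / 10.0
            frames.append(
                BundleFrame(time=float(ts.time) / 1000.0, box=box, coords=coords)
            )

    pairs: list[tuple[int, int]] = []
    if covalent_pairs == "consecutive":
        pairs = [(i, i + 1) for i in range(0, len(groups) - 1, 2)]
    elif covalent_pairs is not None:
        pairs = [tuple(p) for p in covalent_pairs]  # type: ignore[misc]

    srcs = (str(topology),) if trajectory is None else (str(topology), str(trajectory))
    return Trajectory(
        frames=frames,
        variant=variant,
        residue_numbers=residue_numbers,
        residue_names=residue_names,
        sources=srcs,
        helix_pairs=pairs,
    )


def _as_universe(traj: Trajectory):
    """Build an in-memory MDAnalysis Universe mirroring a Trajectory."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    H, N = traj.n_helices, traj.n_residues
    n_atoms = H * N
    u = mda.Universe.empty(
        n_atoms,
        n_residues=n_atoms,
        n_segments=H,
        atom_resindex=np.arange(n_atoms),
        residue_segindex=np.repeat(np.arange(H), N),
        trajectory=False,
    )
    u.add_TopologyAttr("names", ["BB"] * n_atoms)
    resnames = traj.residue_names or ["GLY"] * N
    u.add_TopologyAttr("resnames", list(resnames) * H)
    nums = (
        traj.residue_numbers
        if traj.residue_numbers is not None
        else np.arange(1, N + 1)
    )
    u.add_TopologyAttr("resids", np.tile(nums, H))
    u.add_TopologyAttr("segids", [f"H{h:02d}" for h in range(H)])
    u.add_TopologyAttr(
        "chainIDs",
        np.repeat([_CHAIN_IDS[h % len(_CHAIN_IDS)] for h in range(H)], N),
    )

    coords = np.stack([f.coords.reshape(n_atoms, 3) for f in traj.frames]) * 10.0
    dims = np.array(
        [[*(f.box * 10.0), 90.0, 90.0, 90.0] for f in traj.frames]
    )
    u.load_new(coords, format=MemoryReader, dimensions=dims)
    return u


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB (one MODEL per frame)."""
    import MDAnalysis as mda

    u = _as_universe(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, n_atoms=len(u.atoms)) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_gro(traj: Trajectory, path: str | Path, frame: int = 0) -> None:
    """Write one frame as a GRO coordinate file."""
    u = _as_universe(traj)
    u.trajectory[frame]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, gro_path: str | Path, xtc_path: str | Path) -> None:
    """Write a GRO topology frame plus an XTC trajectory."""
    import MDAnalysis as mda

    u = _as_universe(traj)
    write_gro(traj, gro_path)
    times_ps = traj.times * 1000.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(xtc_path), n_atoms=len(u.atoms)) as w:
            for i, ts in enumerate(u.trajectory):
                ts.time = times_ps[i]
                w.write(u.atoms)
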