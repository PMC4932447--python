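"""Structures, trajectories, and atom selections.

The in-memory model is deliberately small: a :class:`TrajectorySegment` is a
``frames x atoms x 3`` coordinate array in nanometres plus a flat list of
:class:`AtomRecord` metadata and an explicit frame spacing in picoseconds.
Everything downstream (PCA, descriptors, distance maps) consumes this type.

File formats are handled by established readers: PDB via biotite, XTC/DCD via
MDAnalysis.  All Å-native interfaces convert to nanometres at the boundary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ArgumentError,
    EmptyInputError,
    FormatError,
    ParseError,
    SelectionError,
    TopologyError,
)

ANGSTROM_PER_NM = 10.0

#: DSSP-style three-letter names for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class AtomRecord:
    """Identity of one atom: name, element, residue, chain.

    ``residue_index`` is 1-based within its chain, matching the residue labels
    used throughout the analysis (e.g. "residues 82-83 and 86-87").
    """

    atom_index: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def is_calpha(self) -> bool:
        return self.atom_name == "CA" and self.element.upper() == "C"


@dataclass
class TrajectorySegment:
    """A contiguous block of frames: coordinates (nm) + atom metadata.

    Represents the time series X(t) = (X1(t), ..., X3N(t)) in 3N-dimensional
    configuration space; ``flat()`` exposes exactly that layout with degrees of
    freedom interleaved as (x1, y1, z1, x2, ...).
    """

    coords: np.ndarray          # (n_frames, n_atoms, 3), nanometres
    atoms: list[AtomRecord]
    frame_interval: float       # picoseconds between consecutive frames
    origin_time: float = 0.0    # picoseconds of the first frame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ArgumentError(
                f"coords must be (frames, atoms, 3); got {self.coords.shape}")
        if self.coords.shape[0] < 1 or self.coords.shape[1] < 1:
            raise EmptyInputError("trajectory needs >= 1 frame and >= 1 atom")
        if self.coords.shape[1] != len(self.atoms):
            raise TopologyError(
                f"{self.coords.shape[1]} coordinate columns vs "
                f"{len(self.atoms)} atom records")
        if not self.frame_interval > 0:
            raise ArgumentError("frame_interval must be > 0 ps")
        if not np.all(np.isfinite(self.coords)):
            raise ArgumentError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def duration(self) -> float:
        """Segment duration in ps (frame count x spacing)."""
        return self.n_frames * self.frame_interval

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def flat(self) -> np.ndarray:
        """View of shape (n_frames, 3N), DOFs interleaved x1,y1,z1,x2,..."""
        return self.coords.reshape(self.n_frames, 3 * self.n_atoms)

    def frame_times(self) -> np.ndarray:
        return self.origin_time + self.frame_interval * np.arange(self.n_frames)

    def subset(self, mask: "SelectionMask") -> "TrajectorySegment":
        """New segment restricted to the selected atoms (re-indexed 0..m-1)."""
        atoms = [replace(self.atoms[i], atom_index=k)
                 for k, i in enumerate(mask.indices)]
        return TrajectorySegment(self.coords[:, mask.indices, :].copy(), atoms,
                                 self.frame_interval, self.origin_time)


@dataclass(frozen=True)
class SelectionMask:
    """Ordered, unique, in-range atom indices with a human-readable label."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx) or list(idx) != sorted(idx):
            raise SelectionError("selection indices must be unique and ascending")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


def select(segment: TrajectorySegment,
           criterion: str | Iterable[int]) -> SelectionMask:
    """Build a :class:`SelectionMask` from a criterion.

    ``"heavy"`` excludes hydrogens, ``"calpha"`` keeps CA atoms,
    ``"chain:<id>"`` keeps one chain, ``"all"`` keeps everything; an iterable
    of integers is taken as an explicit index list.  Raises
    :class:`SelectionError` when the result is empty.
    """
    atoms = segment.atoms
    if isinstance(criterion, str):
        if criterion == "heavy":
            idx = [a.atom_index for a in atoms if a.is_heavy]
        elif criterion == "calpha":
            idx = [a.atom_index for a in atoms if a.is_calpha]
        elif criterion == "all":
            idx = [a.atom_index for a in atoms]
        elif criterion.startswith("chain:"):
            cid = criterion.split(":", 1)[1]
            idx = [a.atom_index for a in atoms if a.chain_id == cid]
        else:
            raise SelectionError(f"unknown selection criterion {criterion!r}")
        label = criterion
    else:
        idx = sorted(int(i) for i in criterion)
        if idx and (idx[0] < 0 or idx[-1] >= segment.n_atoms):
            raise SelectionError("custom index list out of range")
        label = "custom"
    if not idx:
        raise SelectionError(f"selection {label!r} matched no atoms")
    return SelectionMask(tuple(idx), label)


def slice_segments(segment: TrajectorySegment, window: float,
                   take_last: float) -> list[TrajectorySegment]:
    """Cut the trailing ``take_last`` ps into contiguous ``window``-ps segments.

    Mirrors the segment-averaging protocol (e.g. fifty 0.2-ns segments from
    the last 10 ns).  ``window`` must divide ``take_last`` evenly and both must
    be whole numbers of frames; no silent truncation.
    """
    dt = segment.frame_interval
    if window <= 0 or take_last <= 0:
        raise ArgumentError("window and take_last must be positive")
    if window > take_last:
        raise ArgumentError(f"window {window} ps exceeds take_last {take_last} ps")
    if take_last > segment.duration + 1e-9:
        raise ArgumentError(
            f"take_last {take_last} ps exceeds trajectory duration "
            f"{segment.duration} ps")
    n_seg_f = take_last / window
    if abs(n_seg_f - round(n_seg_f)) > 1e-9:
        raise ArgumentError("window must divide take_last evenly")
    frames_per_window = window / dt
    if abs(frames_per_window - round(frames_per_window)) > 1e-9:
        raise ArgumentError("window must be a whole number of frames")
    n_seg = int(round(n_seg_f))
    fpw = int(round(frames_per_window))
    total = n_seg * fpw
    start = segment.n_frames - total
    out = []
    for s in range(n_seg):
        lo = start + s * fpw
        out.append(TrajectorySegment(
            segment.coords[lo:lo + fpw].copy(), segment.atoms, dt,
            origin_time=segment.origin_time + lo * dt))
    return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _atom_records_from_array(arr) -> list[AtomRecord]:
    """biotite AtomArray annotations -> AtomRecord list (validated)."""
    records = []
    last_res: dict[str, int] = {}
    for i in range(arr.array_length()):
        cid = str(arr.chain_id[i]) or "A"
        rid = int(arr.res_id[i])
        if cid in last_res and rid < last_res[cid]:
            raise ParseError(
                f"residue numbering decreases within chain {cid} at atom {i}")
        last_res[cid] = rid
        element = str(arr.element[i]).capitalize() or "X"
        records.append(AtomRecord(
            atom_index=i,
            atom_name=str(arr.atom_name[i]),
            element=element,
            residue_index=rid,
            residue_name=str(arr.res_name[i]),
            chain_id=cid,
        ))
    return records


def _scan_for_bad_line(path: Path) -> str:
    """Best-effort location of the first malformed ATOM record."""
    try:
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except (ValueError, IndexError):
                    return f" (first malformed record at line {lineno})"
    except OSError:
        pass
    return ""


def _read_pdb(path: Path, model: int | None):
    import biotite.structure.io.pdb as pdb

    try:
        f = pdb.PDBFile.read(str(path))
        structure = f.get_structure(model=model, altloc="first")
    except Exception as exc:  # biotite raises a mix of error types
        raise ParseError(
            f"could not parse PDB file {path}{_scan_for_bad_line(path)}: {exc}"
        ) from exc
    return structure


def _strip_to_protein(arr):
    import biotite.structure as struc

    if np.any(arr.ins_code != ""):
        raise ParseError("insertion codes are not supported")
    keep = ~arr.hetero & struc.filter_amino_acids(arr)
    return arr[..., keep] if arr.coord.ndim == 3 else arr[keep]


def read_structure(path: str | Path, format: str = "pdb") -> TrajectorySegment:
    """Read a single-model structure file into a one-frame segment.

    Only protein ATOM records are kept (waters, ions and other HETATM groups
    are dropped); coordinates are converted Å -> nm.
    """
    path = Path(path)
    if format != "pdb":
        raise FormatError(f"unsupported structure format {format!r}")
    arr = _strip_to_protein(_read_pdb(path, model=1))
    if arr.array_length() == 0:
        raise EmptyInputError(f"{path} contains no protein atoms")
    coords = arr.coord[None, :, :] / ANGSTROM_PER_NM
    return TrajectorySegment(coords, _atom_records_from_array(arr),
                             frame_interval=1.0)


def read_trajectory(path: str | Path, topology: str | Path | None = None,
                    format: str | None = None,
                    frame_interval: float | None = None) -> TrajectorySegment:
    """Read a trajectory (multi-model PDB, XTC, or DCD).

    Multi-model PDB carries no time metadata, so ``frame_interval`` (ps) is
    required for it; XTC/DCD use the file's own time step unless overridden.
    ``topology`` (a PDB) provides atom metadata for XTC/DCD and is checked for
    atom-count agreement in every case.
    """
    path = Path(path)
    if format is None:
        format = {".pdb": "pdb", ".xtc": "xtc", ".dcd": "dcd"}.get(
            path.suffix.lower())
        if format is None:
            raise FormatError(f"cannot infer trajectory format of {path}")

    if format in ("pdb", "multi-model-pdb"):
        if frame_interval is None:
            raise ArgumentError(
                "frame_interval (ps) is required for multi-model PDB input")
        stack = _strip_to_protein(_read_pdb(path, model=None))
        coord = stack.coord
        if coord.ndim == 2:  # single model
            coord = coord[None]
        if coord.shape[1] == 0:
            raise EmptyInputError(f"{path} contains no protein atoms")
        first = stack[0] if coord.ndim == 3 and hasattr(stack, "stack_depth") \
            else stack
        atoms = _atom_records_from_array(first)
        if topology is not None:
            top = read_structure(topology)
            if top.n_atoms != coord.shape[1]:
                raise TopologyError(
                    f"topology has {top.n_atoms} atoms, trajectory has "
                    f"{coord.shape[1]}")
            atoms = top.atoms
        return TrajectorySegment(coord / ANGSTROM_PER_NM, atoms, frame_interval)

    if format in ("xtc", "dcd"):
        if topology is None:
            raise TopologyError(f"{format} input requires a PDB topology")
        import MDAnalysis as mda

        top = read_structure(topology)
        try:
            u = mda.Universe(str(topology), str(path))
        except Exception as exc:
            raise FormatError(f"could not read {format} file {path}: {exc}") \
                from exc
        if len(u.atoms) != top.n_atoms:
            raise TopologyError(
                f"topology has {top.n_atoms} protein atoms but the "
                f"trajectory reader sees {len(u.atoms)}")
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        dt = frame_interval if frame_interval is not None \
            else float(u.trajectory.dt)
        return TrajectorySegment(frames / ANGSTROM_PER_NM, top.atoms, dt)

    raise FormatError(f"unsupported trajectory format {format!r}")


def write_trajectory(segment: TrajectorySegment, path: str | Path) -> None:
    """Write a (possibly multi-model) PDB file; Å at 3 decimals."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = segment.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = segment.coords[0] * ANGSTROM_PER_NM
    arr.chain_id = np.array([a.chain_id for a in segment.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_index for a in segment.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in segment.atoms], dtype="U5")
    arr.atom_name = np.array([a.atom_name for a in segment.atoms], dtype="U6")
    arr.element = np.array([a.element.upper() for a in segment.atoms], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    if segment.n_frames == 1:
        out = arr
    else:
        out = struc.stack([arr] * segment.n_frames)
        out.coord = segment.coords * ANGSTROM_PER_NM
    f = pdb.PDBFile()
    f.set_structure(out)
    f.write(str(path))


def chain_sequences(segment: TrajectorySegment) -> dict[str, str]:
    """One-letter sequence of each chain (from CA atoms, file order)."""
    seqs: dict[str, list[str]] = {}
    for a in segment.atoms:
        if a.is_calpha:
            seqs.setdefault(a.chain_id, []).append(
                THREE_TO_ONE.get(a.residue_name, "X"))
    return {c: "".join(s) for c, s in seqs.items()}


def write_fasta(segment: TrajectorySegment, path: str | Path,
                name: str = "chain") -> None:
    """Per-chain FASTA of the segment's sequences."""
    with open(path, "w") as fh:
        for cid, seq in chain_sequences(segment).items():
            fh.write(f">{name}_{cid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def alpha_synuclein_sequence() -> str:
    """The packaged 140-residue human α-synuclein sequence (PDB 1XQ8)."""
    text = (importlib.resources.files("ecdyn.data")
            / "alpha_synuclein.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines()
                   if not line.startswith(">"))
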