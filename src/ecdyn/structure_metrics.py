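"""Supporting trajectory analyses: distance maps, RMSD, secondary structure.

* Mean shortest-distance maps: for every residue pair, the per-frame minimum
  distance between the residues' selected atoms, averaged over frames.
* RMSD traces: per-frame root-mean-square deviation from a reference after
  optimal rigid superposition.
* Secondary-structure occupancy: per-frame one-letter assignment tables
  (produced externally, e.g. by DSSP) are parsed into a timeline; occupancy
  over a trailing analysis window drives the stability rules used to report
  persistent elements — a residue's β-strand (E) is "stable" when present
  strictly more than 80% of the window, a helix class (H, G, or I) when
  present strictly more than 50%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import (
    ArgumentError,
    ConfigError,
    ConsistencyError,
    ParseError,
    SelectionError,
)
from .ecd_core import superpose_frames
from .traj_model import AtomRecord, SelectionMask, TrajectorySegment, select

#: The 8-letter secondary-structure alphabet (coil written as "C").
SS_CODES = "HGIEBTSC"
#: Codes that count as helix, per class.
HELIX_CODES = {"H": "alpha", "G": "3_10", "I": "pi"}

#: Named residue regions of α-synuclein used to annotate stable elements.
DEFAULT_REGIONS = {
    "N-terminal": (1, 60),
    "NAC": (61, 95),
    "amyloidogenic-core": (71, 82),
    "C-terminal": (96, 140),
}


@dataclass
class DistanceMap:
    """Mean over frames of the shortest inter-residue atom distance (nm)."""

    matrix: np.ndarray                    # (n_res, n_res)
    residues: list[tuple[str, int, str]]  # (chain, residue_index, res_name)


@dataclass
class SSTimeline:
    """frames x residues one-letter secondary-structure codes."""

    codes: np.ndarray                     # (n_frames, n_res), dtype <U1
    frame_times: np.ndarray               # ps
    residues: list[tuple[str, int]]       # (chain, residue_index)

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    @property
    def n_residues(self) -> int:
        return self.codes.shape[1]

    @property
    def frame_interval(self) -> float:
        t = self.frame_times
        return float(t[1] - t[0]) if len(t) > 1 else 1.0


@dataclass
class StableElement:
    """A maximal contiguous run of residues stable in one structure class."""

    chain_id: str
    start: int
    stop: int
    ss_class: str                         # code letter
    regions: tuple[str, ...] = ()


@dataclass
class OccupancyTable:
    """Per-residue occupancy fractions and stability flags.

    ``occupancy`` is a DataFrame indexed by (chain, residue) with one column
    per code letter; flags follow the strict-inequality reading of the
    stability thresholds ("more than 80%" / "more than 50%").
    """

    occupancy: pd.DataFrame
    stable_beta: np.ndarray               # per residue
    stable_helix: dict[str, np.ndarray]   # code letter -> per-residue flags
    elements: list[StableElement]
    window_frames: int


# ---------------------------------------------------------------------------
# Distance maps
# ---------------------------------------------------------------------------

def mean_shortest_distance_map(segment: TrajectorySegment,
                               selection: SelectionMask | None = None,
                               ) -> DistanceMap:
    """Frame-averaged minimum atom-atom distance for every residue pair.

    Every residue of the segment must contribute at least one selected atom.
    The diagonal is zero by definition.
    """
    if selection is None:
        selection = select(segment, "heavy")
    atoms = [segment.atoms[i] for i in selection.indices]
    residues: list[tuple[str, int, str]] = []
    res_of_atom = []
    for a in atoms:
        key = (a.chain_id, a.residue_index, a.residue_name)
        if not residues or residues[-1] != key:
            residues.append(key)
        res_of_atom.append(len(residues) - 1)
    present = {(a.chain_id, a.residue_index) for a in segment.atoms}
    covered = {(c, r) for c, r, _ in residues}
    missing = {(c, r) for c, r in present} - covered
    if missing:
        raise SelectionError(
            f"{len(missing)} residues have no selected atoms "
            f"(e.g. {sorted(missing)[:3]})")

    res_of_atom = np.array(res_of_atom)
    starts = np.flatnonzero(np.r_[1, np.diff(res_of_atom)])
    n_res = len(residues)
    idx = np.array(selection.indices)
    acc = np.zeros((n_res, n_res))
    for t in range(segment.n_frames):
        d = cdist(segment.coords[t, idx], segment.coords[t, idx])
        # two-stage minimum reduction over residue blocks (atoms are grouped)
        d = np.minimum.reduceat(d, starts, axis=0)
        d = np.minimum.reduceat(d, starts, axis=1)
        acc += d
    acc /= segment.n_frames
    np.fill_diagonal(acc, 0.0)
    return DistanceMap(acc, residues)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def rmsd_trace(segment: TrajectorySegment, reference,
               fit_selection: SelectionMask | None = None,
               measure_selection: SelectionMask | None = None) -> np.ndarray:
    """Per-frame RMSD (nm) from a reference after optimal superposition.

    ``reference`` is a frame index, an (n_atoms, 3) array, or a one-frame
    :class:`TrajectorySegment`.  Frames are fitted on ``fit_selection`` and
    measured on ``measure_selection`` (both default to all atoms).
    """
    if isinstance(reference, TrajectorySegment):
        if reference.n_atoms != segment.n_atoms:
            raise ConsistencyError("reference atom count differs from segment")
        ref = reference.coords[0]
    elif isinstance(reference, (int, np.integer)):
        ref = segment.coords[int(reference)]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (segment.n_atoms, 3):
            raise ConsistencyError(
                f"reference shape {ref.shape} != ({segment.n_atoms}, 3)")
    fit_idx = np.array(fit_selection.indices if fit_selection is not None
                       else range(segment.n_atoms))
    meas_idx = np.array(measure_selection.indices
                        if measure_selection is not None
                        else range(segment.n_atoms))
    from .ecd_core import _check_fit_geometry, _fit_frames

    _check_fit_geometry(ref[fit_idx])
    fitted = _fit_frames(segment.coords, ref, fit_idx)
    diff = fitted[:, meas_idx, :] - ref[meas_idx]
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1))


# ---------------------------------------------------------------------------
# Secondary-structure timelines
# ---------------------------------------------------------------------------

def _normalise_code(c: str, where: str) -> str:
    if c in (" ", "-", "~", "C"):
        return "C"
    if c in SS_CODES:
        return c
    raise ParseError(f"unknown secondary-structure code {c!r} {where}")


def parse_ss_table(source, frame_interval: float = 1.0,
                   residues: Sequence[tuple[str, int]] | None = None,
                   ) -> SSTimeline:
    """Parse a frames x residues code table into a timeline.

    ``source`` is a path to a text file (one line per frame, one character
    per residue; ``#`` comments allowed) or an iterable of per-frame strings.
    Blanks, ``-`` and ``~`` map to coil.  All frames must cover the same
    residues; ``residues`` labels default to chain A, 1..n.
    """
    if isinstance(source, (str, Path)):
        lines = [ln for ln in Path(source).read_text().splitlines()
                 if ln.strip() and not ln.startswith("#")]
    else:
        lines = [str(ln).rstrip("\n") for ln in source]
    if not lines:
        raise ParseError("empty secondary-structure table")
    width = len(lines[0])
    rows = []
    for f, line in enumerate(lines):
        if len(line) != width:
            raise ConsistencyError(
                f"frame {f} covers {len(line)} residues, frame 0 covers "
                f"{width}: residue sets drift across frames")
        rows.append([_normalise_code(c, f"at frame {f}") for c in line])
    codes = np.array(rows, dtype="U1")
    if residues is None:
        residues = [("A", i + 1) for i in range(width)]
    elif len(residues) != width:
        raise ConsistencyError("residue labels do not match table width")
    times = frame_interval * np.arange(len(lines))
    return SSTimeline(codes, times, list(residues))


def parse_dssp_timeline(paths_or_table, frame_interval: float = 1.0,
                        residues=None) -> SSTimeline:
    """Timeline from one table file or a list of per-frame code files."""
    if isinstance(paths_or_table, (list, tuple)) and paths_or_table and \
            isinstance(paths_or_table[0], (str, Path)):
        lines = []
        for p in paths_or_table:
            content = [ln for ln in Path(p).read_text().splitlines()
                       if ln.strip() and not ln.startswith("#")]
            if len(content) != 1:
                raise ParseError(
                    f"per-frame file {p} must hold exactly one code line")
            lines.append(content[0])
        return parse_ss_table(lines, frame_interval, residues)
    return parse_ss_table(paths_or_table, frame_interval, residues)


def write_ss_table(timeline: SSTimeline, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in timeline.codes:
            fh.write("".join(row) + "\n")


# ---------------------------------------------------------------------------
# Occupancy and stability
# ---------------------------------------------------------------------------

def ss_occupancy(timeline: SSTimeline,
                 window: float | None = None) -> OccupancyTable:
    """Occupancy fractions over the trailing ``window`` ps and stability flags.

    ``window=None`` uses the whole timeline.  Occupancies over the 8 disjoint
    classes sum to 1 per residue.  Stable runs are reported as maximal
    contiguous residue ranges per class, the form the analysis tables use.
    """
    if window is None:
        n_win = timeline.n_frames
    else:
        n_win = int(round(window / timeline.frame_interval))
        if n_win < 1:
            raise ArgumentError("analysis window contains no frames")
        if n_win > timeline.n_frames:
            raise ArgumentError("window exceeds timeline duration")
    codes = timeline.codes[-n_win:]
    occ = {c: (codes == c).mean(axis=0) for c in SS_CODES}
    df = pd.DataFrame(occ, index=pd.MultiIndex.from_tuples(
        timeline.residues, names=["chain", "residue"]))

    stable_beta = df["E"].to_numpy() > 0.8
    stable_helix = {c: df[c].to_numpy() > 0.5 for c in HELIX_CODES}

    elements: list[StableElement] = []
    flags_by_class = {"E": stable_beta, **stable_helix}
    for code, flags in flags_by_class.items():
        run_start = None
        for i in range(len(timeline.residues) + 1):
            boundary = (i == len(timeline.residues)
                        or not flags[i]
                        or (i > 0 and run_start is not None
                            and timeline.residues[i][0]
                            != timeline.residues[i - 1][0]))
            if run_start is not None and boundary:
                chain, start = timeline.residues[run_start]
                stop = timeline.residues[i - 1][1]
                elements.append(StableElement(chain, start, stop, code))
                run_start = None
            if i < len(timeline.residues) and flags[i] and run_start is None:
                run_start = i
    elements.sort(key=lambda e: (e.chain_id, e.start, e.ss_class))
    return OccupancyTable(df, stable_beta, stable_helix, elements, n_win)


def annotate_regions(table: OccupancyTable,
                     regions: dict[str, tuple[int, int]] | None = None,
                     ) -> OccupancyTable:
    """Label every stable element with the named residue regions it overlaps.

    Region names must be unique; defaults are the canonical α-synuclein
    regions (N-terminal 1-60, NAC 61-95, amyloidogenic core 71-82,
    C-terminal 96-140).  Returns the same table with elements annotated.
    """
    if regions is None:
        items = list(DEFAULT_REGIONS.items())
    elif isinstance(regions, dict):
        items = list(regions.items())
    else:  # list of (name, (lo, hi)) pairs — may carry duplicates
        items = [(str(n), (int(lo), int(hi))) for n, (lo, hi) in regions]
    names = [n for n, _ in items]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate region names")
    for el in table.elements:
        labels = [name for name, (lo, hi) in items
                  if el.start <= hi and el.stop >= lo]
        el.regions = tuple(labels)
    return table


def occupancy_report(table: OccupancyTable) -> pd.DataFrame:
    """Tabular view of stable elements (chain, range, class, occupancy, regions)."""
    rows = []
    for el in table.elements:
        sub = table.occupancy.loc[
            [(el.chain_id, r) for r in range(el.start, el.stop + 1)],
            el.ss_class]
        rows.append({
            "chain": el.chain_id, "start": el.start, "stop": el.stop,
            "class": el.ss_class,
            "mean_occupancy": float(sub.mean()),
            "regions": ",".join(el.regions),
        })
    return pd.DataFrame(rows, columns=["chain", "start", "stop", "class",
                                       "mean_occupancy", "regions"])
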