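"""Deterministic unfolded starting geometries: monomer, dimers, tetramer.

Chains are built fully extended with every Cα exactly on a straight line (the
chain axis).  Dimers place a second chain 14 Å away (axis-to-axis); head-to-
head (HH) keeps the two N->C directions parallel, head-to-tail (HT) reverses
the second chain, and the "#2" variants additionally roll the second chain by
180° about its own main-chain axis, which by construction changes only the
off-axis atoms (backbone pleat and side chains), never the Cα positions.  The
tetramer stacks two copies of a base dimer (default HT2) along a direction
orthogonal to the dimer separation, giving a 2x2 bundle with equal
nearest-neighbour spacing.

Bond lengths are ideal (N-CA 1.458 Å, CA-C 1.525 Å, peptide C-N 1.329 Å,
Cα-Cα rise 3.7537 Å); keeping the Cα atoms exactly collinear opens the
N-CA-C angle relative to its ideal value.  Carbonyl-O and side-chain heavy
atoms come from idealized residue templates (the chemical component
dictionary bundled with biotite) rigidly superposed onto each built N/CA/C
frame, so their internal geometry is exact.  The result is a plausible,
fully deterministic starting geometry for fluctuation synthesis and
geometric classification — not a physical conformer.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import AmbiguityError, ArgumentError, SequenceError, SpecError
from .traj_model import (
    ANGSTROM_PER_NM,
    AtomRecord,
    ONE_TO_THREE,
    TrajectorySegment,
)

# Ideal bond lengths (Å) and the derived extended-chain geometry.
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_PLEAT = 0.6                       # off-axis pleat amplitude (Å)
_AX_N = float(np.sqrt(_B_N_CA ** 2 - _PLEAT ** 2))   # 1.32882 Å
_AX_C = float(np.sqrt(_B_CA_C ** 2 - _PLEAT ** 2))   # 1.40201 Å
#: Cα-Cα rise per residue along the chain axis (Å); fixed by the exact
#: peptide-bond length given the pleat amplitude.
CA_RISE = _AX_N + _AX_C + float(np.sqrt(_B_C_N ** 2 - 2 * _PLEAT ** 2))

_CHAIN_LETTERS = "ABCD"
DIMER_ARRANGEMENTS = ("HH1", "HH2", "HT1", "HT2")


@dataclass(frozen=True)
class ConstructSpec:
    """What to build: oligomer kind, chain arrangement, spacing, sequence."""

    kind: str                         # monomer | dimer | tetramer
    sequence: str
    dimer_arrangement: str | None = None
    separation: float = 14.0          # Å, axis-to-axis
    tetramer_base: str = "HT2"

    def __post_init__(self) -> None:
        if self.kind not in ("monomer", "dimer", "tetramer"):
            raise SpecError(f"unknown construct kind {self.kind!r}")
        if not self.sequence:
            raise SequenceError("sequence must be non-empty")
        bad = set(self.sequence) - set(ONE_TO_THREE)
        if bad:
            raise SequenceError(f"unknown residue letters: {sorted(bad)}")
        if not self.separation > 0:
            raise SpecError("separation must be > 0 Å")
        if self.kind == "monomer" and self.dimer_arrangement is not None:
            raise SpecError("dimer_arrangement is meaningless for a monomer")
        if self.kind == "dimer":
            if self.dimer_arrangement not in DIMER_ARRANGEMENTS:
                raise SpecError(
                    f"dimer needs an arrangement in {DIMER_ARRANGEMENTS}")
        if self.kind == "tetramer" and self.tetramer_base not in \
                DIMER_ARRANGEMENTS:
            raise SpecError(f"tetramer_base must be in {DIMER_ARRANGEMENTS}")


@dataclass
class ConstructModel:
    """A built multi-chain geometry with per-chain axes and pair alignments.

    ``chain_axes`` maps chain id -> (point, unit N->C direction) in nm;
    ``alignment_table`` maps each unordered chain pair (as a sorted id tuple)
    to "HH" (parallel) or "HT" (antiparallel).
    """

    structure: TrajectorySegment
    chain_axes: dict[str, tuple[np.ndarray, np.ndarray]]
    alignment_table: dict[tuple[str, str], str]

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chain_axes)

    def chain_calpha_coords(self, chain_id: str) -> np.ndarray:
        """(n_res, 3) Cα coordinates of one chain, N->C order, nm."""
        seg = self.structure
        idx = [a.atom_index for a in seg.atoms
               if a.chain_id == chain_id and a.is_calpha]
        return seg.coords[0, idx, :]


@lru_cache(maxsize=32)
def _residue_template(res_name: str):
    """Heavy-atom idealized template (names, coords Å) for one residue type."""
    import biotite.structure.info as info

    res = info.residue(res_name)
    keep = (res.element != "H") & (res.atom_name != "OXT")
    res = res[keep]
    return list(res.atom_name), res.coord.copy()


def _fit_template(names: list[str], coords: np.ndarray,
                  n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Rigidly map a template onto a built N/CA/C frame; return all coords (Å)."""
    from scipy.spatial.transform import Rotation

    tri = {nm: i for i, nm in enumerate(names)}
    src = coords[[tri["N"], tri["CA"], tri["C"]]]
    dst = np.array([n, ca, c])
    src_c, dst_c = src.mean(axis=0), dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - dst_c, src - src_c)
    return rot.apply(coords - src_c) + dst_c


def build_extended_chain(sequence: str, chain_id: str = "A") -> ConstructModel:
    """Build one extended chain along +x with Cα atoms exactly on the axis.

    Residue i (1-based) has Cα at ((i-1)·3.7537 Å, 0, 0); backbone N and C
    alternate the pleat side with residue parity.  Deterministic: identical
    input gives identical coordinates.
    """
    spec = ConstructSpec(kind="monomer", sequence=sequence)  # validates letters
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    for i, letter in enumerate(spec.sequence):
        res_name = ONE_TO_THREE[letter]
        s = 1.0 if i % 2 == 0 else -1.0
        ca = np.array([i * CA_RISE, 0.0, 0.0])
        n = ca + np.array([-_AX_N, s * _PLEAT, 0.0])
        c = ca + np.array([_AX_C, 0.0, s * _PLEAT])
        names, tpl = _residue_template(res_name)
        fitted = _fit_template(names, tpl, n, ca, c)
        for name, xyz in zip(names, fitted):
            exact = {"N": n, "CA": ca, "C": c}.get(name)
            coords.append(exact if exact is not None else xyz)
            records.append(AtomRecord(
                atom_index=len(records), atom_name=name,
                element=name[0], residue_index=i + 1,
                residue_name=res_name, chain_id=chain_id))
    seg = TrajectorySegment(np.array(coords)[None] / ANGSTROM_PER_NM,
                            records, frame_interval=1.0)
    axes = {chain_id: (np.zeros(3), np.array([1.0, 0.0, 0.0]))}
    return ConstructModel(seg, axes, {})


def _transform_chain(coords: np.ndarray, axis, *, flip: bool, roll: bool,
                     shift: np.ndarray, ca_mid: float):
    """Apply HT flip / 180° roll / translation to one chain built at origin.

    ``ca_mid`` is the x midpoint of the Cα span; flipping about it keeps the
    reversed chain's Cα atoms on the same x positions (residue i of the
    flipped chain sits opposite residue n+1-i of an unflipped one).
    """
    point, direction = np.array(axis[0]), np.array(axis[1])
    out = coords.copy()
    if flip:  # 180° about the z-parallel axis through the Cα midpoint
        out[:, 0] = 2 * ca_mid - out[:, 0]
        out[:, 1] = -out[:, 1]
        direction = -direction
    if roll:  # 180° about the chain's own axis (the x axis here)
        out[:, 1] = -out[:, 1]
        out[:, 2] = -out[:, 2]
    out += shift
    return out, (point + shift, direction)


def assemble_construct(spec: ConstructSpec) -> ConstructModel:
    """Assemble the requested construct from copies of one extended chain.

    Chain 1 lies at the origin; chain 2 is translated by ``separation`` along
    +y.  HT arrangements reverse chain 2's N->C direction; "#2" variants roll
    chain 2 by 180° about its own main-chain axis.  The tetramer stacks two
    copies of the base dimer (chains 3,4 above 1,2) along +z at the same
    separation.  The alignment table covers every unordered chain pair.
    """
    base = build_extended_chain(spec.sequence, chain_id="A")
    base_coords = base.structure.coords[0] * ANGSTROM_PER_NM  # work in Å
    base_axis = (np.zeros(3), np.array([1.0, 0.0, 0.0]))
    ca_x = base.chain_calpha_coords("A")[:, 0] * ANGSTROM_PER_NM
    ca_mid = float((ca_x.min() + ca_x.max()) / 2.0)
    sep = spec.separation

    if spec.kind == "monomer":
        n_chains = 1
        placements = [dict(flip=False, roll=False, shift=np.zeros(3))]
    else:
        arr = spec.dimer_arrangement if spec.kind == "dimer" \
            else spec.tetramer_base
        flip = arr.startswith("HT")
        roll = arr.endswith("2")
        second = dict(flip=flip, roll=roll, shift=np.array([0.0, sep, 0.0]))
        if spec.kind == "dimer":
            n_chains = 2
            placements = [dict(flip=False, roll=False, shift=np.zeros(3)),
                          second]
        else:
            n_chains = 4
            lift = np.array([0.0, 0.0, sep])
            placements = [
                dict(flip=False, roll=False, shift=np.zeros(3)),
                second,
                dict(flip=False, roll=False, shift=lift),
                dict(flip=flip, roll=roll, shift=second["shift"] + lift),
            ]

    all_coords, all_records = [], []
    axes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for k, pl in enumerate(placements):
        cid = _CHAIN_LETTERS[k]
        coords, axis = _transform_chain(base_coords, base_axis, ca_mid=ca_mid,
                                        **pl)
        axes[cid] = (axis[0] / ANGSTROM_PER_NM, axis[1])
        for rec in base.structure.atoms:
            all_records.append(AtomRecord(
                atom_index=len(all_records), atom_name=rec.atom_name,
                element=rec.element, residue_index=rec.residue_index,
                residue_name=rec.residue_name, chain_id=cid))
        all_coords.append(coords)

    seg = TrajectorySegment(
        np.concatenate(all_coords)[None] / ANGSTROM_PER_NM,
        all_records, frame_interval=1.0)
    model = ConstructModel(seg, axes, {})
    for i in range(n_chains):
        for j in range(i + 1, n_chains):
            a, b = _CHAIN_LETTERS[i], _CHAIN_LETTERS[j]
            model.alignment_table[(a, b)] = classify_pair_alignment(model, a, b)
    _check_adjacent_separation(model, sep)
    return model


def _check_adjacent_separation(model: ConstructModel, sep: float) -> None:
    """Assert nearest-neighbour axis separations equal the spec (1e-6 Å)."""
    ids = model.chain_ids
    if len(ids) == 1:
        return
    dists = sorted(axis_separation(model, a, b) * ANGSTROM_PER_NM
                   for i, a in enumerate(ids) for b in ids[i + 1:])
    n_adjacent = {2: 1, 4: 4}[len(ids)]
    for d in dists[:n_adjacent]:
        if abs(d - sep) > 1e-6:
            raise SpecError(
                f"adjacent axis separation {d:.8f} Å != spec {sep} Å")


def axis_separation(model: ConstructModel, chain_a: str, chain_b: str) -> float:
    """Perpendicular distance (nm) between two parallel/antiparallel axes."""
    pa, da = model.chain_axes[chain_a]
    pb, _ = model.chain_axes[chain_b]
    delta = pb - pa
    perp = delta - np.dot(delta, da) * da
    return float(np.linalg.norm(perp))


def _resolve_chain_id(model: ConstructModel, chain) -> str:
    if isinstance(chain, str):
        if chain not in model.chain_axes:
            raise ArgumentError(f"no chain {chain!r} in construct")
        return chain
    idx = int(chain) - 1  # 1-based chain numbers
    ids = model.chain_ids
    if not 0 <= idx < len(ids):
        raise ArgumentError(f"no chain number {chain} in construct")
    return ids[idx]


def classify_pair_alignment(model: ConstructModel, chain_a, chain_b) -> str:
    """"HH" if the two N->C axis directions are parallel, "HT" if antiparallel.

    Chains may be given as ids ("A".."D") or 1-based numbers.  Perpendicular
    axes have no head/tail relation and raise :class:`AmbiguityError`.
    """
    a = _resolve_chain_id(model, chain_a)
    b = _resolve_chain_id(model, chain_b)
    if a == b:
        raise ArgumentError("cannot classify a chain against itself")
    da, db = model.chain_axes[a][1], model.chain_axes[b][1]
    dot = float(np.dot(da, db))
    if abs(dot) < 1e-9:
        raise AmbiguityError("chain axes are perpendicular; HH/HT undefined")
    return "HH" if dot > 0 else "HT"
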