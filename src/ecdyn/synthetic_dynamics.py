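"""Harmonic-network Langevin trajectories with known correlation structure.

One site per Cα carries an isotropic spring network: the potential is
``E = 1/2 * sum_springs k_ij |u_i - u_j|^2`` over site displacements u from
the reference geometry, so the Hessian is the weighted graph Laplacian L
(times the 3x3 identity per axis) and the stationary covariance of the
overdamped dynamics is ``kT * pinv(L)`` per Cartesian axis — a closed form
against which every PCA-based descriptor can be validated exactly.

The block plan mirrors what the analysis is meant to detect in real
trajectories: densely sprung "rigid" residue blocks that move as coherent
units, softly and sequentially sprung linkers, and explicit inter-chain
couplings between residue ranges.  Optionally every heavy atom of the source
construct rides its residue's Cα site with small independent Gaussian jitter
("satellite" atoms), which exercises the all-heavy-atom PCA path without
pretending to model side-chain physics.

Only translations are unrestrained by this potential (infinitesimal rotations
stretch springs), so the Laplacian of a connected graph has exactly one zero
mode per axis; it is projected out, which removes rigid-body drift by
construction.  The default integrator samples each Laplacian eigenmode as an
exact Ornstein-Uhlenbeck process (unconditionally stable, exact stationary
law); ``method="euler"`` provides a plain Euler-Maruyama integrator with
sub-stepping for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .construct_builder import ConstructModel
from .ecd_core import CovarianceModel, _fix_eigenvector_signs, _order_degenerate
from .errors import ArgumentError, ModelError, StabilityError
from .traj_model import AtomRecord, SelectionMask, TrajectorySegment

#: kT at 310 K in kJ/mol (the simulation temperature of the source protocol).
KT_310K = 2.577


@dataclass(frozen=True)
class BlockSpec:
    """One residue range of a chain with a dynamical role."""

    chain_id: str
    start: int                 # 1-based residue, inclusive
    stop: int                  # inclusive
    role: str = "rigid-block"  # rigid-block | linker


@dataclass(frozen=True)
class CouplingSpec:
    """All-pairs springs between two residue ranges of two chains."""

    chain_a: str
    range_a: tuple[int, int]
    chain_b: str
    range_b: tuple[int, int]
    stiffness: float           # kJ/mol/nm^2 per residue pair


@dataclass(frozen=True)
class BlockPlan:
    """Spring-assignment rules applied to a construct's Cα sites."""

    blocks: tuple[BlockSpec, ...]
    couplings: tuple[CouplingSpec, ...] = ()
    k_block: float = 1000.0    # kJ/mol/nm^2, dense within-block springs
    k_linker: float = 50.0     # kJ/mol/nm^2, chain-sequential linker springs
    cutoff: float = 1.0        # nm, within-block spring cutoff
    decorate_heavy: bool = False
    jitter_sigma: float = 0.005  # nm, satellite-atom jitter


@dataclass
class HarmonicNetworkModel:
    """Sites, springs, and thermodynamic parameters of the network."""

    reference: np.ndarray          # (n_sites, 3) nm
    springs: np.ndarray            # (m, 3): i, j, stiffness
    atoms: list[AtomRecord]        # Cα records of the sites
    kT: float = KT_310K            # kJ/mol
    friction: float = 50.0         # kJ/mol/nm^2 * ps; mode relax time = friction/lambda
    satellites: "SatelliteSet | None" = None

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        if self.kT < 0 or self.friction <= 0:
            raise ModelError("kT must be >= 0 and friction > 0")
        if len(self.springs) and np.any(np.asarray(self.springs)[:, 2] <= 0):
            raise ModelError("spring stiffness must be > 0")

    @property
    def n_sites(self) -> int:
        return self.reference.shape[0]

    def laplacian(self) -> np.ndarray:
        """Weighted graph Laplacian (n_sites x n_sites)."""
        n = self.n_sites
        L = np.zeros((n, n))
        for i, j, k in self.springs:
            i, j = int(i), int(j)
            L[i, i] += k
            L[j, j] += k
            L[i, j] -= k
            L[j, i] -= k
        return L

    def _eig(self):
        vals, vecs = np.linalg.eigh(self.laplacian())
        zero_tol = 1e-9 * max(vals[-1], 1.0)
        n_null = int(np.sum(np.abs(vals) < zero_tol))
        if n_null != 1:
            raise ModelError(
                f"spring graph has {n_null} zero modes per axis (expected 1: "
                "overall translation); the network is disconnected or "
                "degenerate")
        return vals, vecs


@dataclass
class SatelliteSet:
    """Heavy atoms riding their residue's Cα site with iso Gaussian jitter."""

    atoms: list[AtomRecord]        # full decorated atom table
    parent_site: np.ndarray        # (n_atoms,) site index per atom
    offsets: np.ndarray            # (n_atoms, 3) nm, offset from parent Cα
    is_site: np.ndarray            # (n_atoms,) True for the Cα atoms
    sigma: float                   # nm


@dataclass(frozen=True)
class SimulationConfig:
    """Length, spacing, burn-in, and seed of one synthetic trajectory."""

    n_frames: int
    frame_interval: float = 0.1    # ps
    burn_in_frames: int = 0
    seed: int = 0
    method: str = "exact"          # exact | euler
    substeps: int | None = None    # euler only; None = auto for stability

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ArgumentError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ArgumentError("frame_interval must be > 0 ps")
        if self.method not in ("exact", "euler"):
            raise ArgumentError(f"unknown integrator {self.method!r}")


def model_from_construct(model: ConstructModel, plan: BlockPlan,
                         kT: float = KT_310K,
                         friction: float = 50.0) -> HarmonicNetworkModel:
    """Assign springs to a construct's Cα sites according to a block plan.

    Within each rigid block, every site pair closer than ``plan.cutoff``
    receives a ``k_block`` spring (dense local bracing); linker residues and
    residues not covered by any block get chain-sequential ``k_linker``
    springs only.  Couplings add all-pairs springs between the named residue
    ranges regardless of distance.  A disconnected spring graph is an error.
    """
    seg = model.structure
    site_atoms = [a for a in seg.atoms if a.is_calpha]
    site_of = {(a.chain_id, a.residue_index): s
               for s, a in enumerate(site_atoms)}
    ref = seg.coords[0, [a.atom_index for a in site_atoms], :]

    role = {}  # site -> "rigid-block" | "linker"
    block_id = {}
    for b, blk in enumerate(plan.blocks):
        if blk.role not in ("rigid-block", "linker"):
            raise ArgumentError(f"unknown block role {blk.role!r}")
        for r in range(blk.start, blk.stop + 1):
            key = (blk.chain_id, r)
            if key not in site_of:
                raise ArgumentError(
                    f"block range {blk.chain_id}:{blk.start}-{blk.stop} "
                    "outside the construct's residues")
            role[site_of[key]] = blk.role
            block_id[site_of[key]] = b

    springs: dict[tuple[int, int], float] = {}

    def add(i: int, j: int, k: float) -> None:
        if i == j:
            return
        key = (min(i, j), max(i, j))
        springs[key] = max(springs.get(key, 0.0), k)

    # chain-sequential backbone springs
    for s in range(len(site_atoms) - 1):
        a, b = site_atoms[s], site_atoms[s + 1]
        if a.chain_id != b.chain_id:
            continue
        same_block = (role.get(s) == role.get(s + 1) == "rigid-block"
                      and block_id.get(s) == block_id.get(s + 1))
        add(s, s + 1, plan.k_block if same_block else plan.k_linker)

    # dense within-block springs under the cutoff
    for b in range(len(plan.blocks)):
        if plan.blocks[b].role != "rigid-block":
            continue
        members = [s for s in block_id if block_id[s] == b]
        for ii, s1 in enumerate(members):
            for s2 in members[ii + 1:]:
                if np.linalg.norm(ref[s1] - ref[s2]) <= plan.cutoff:
                    add(s1, s2, plan.k_block)

    # explicit inter-chain couplings (no cutoff)
    for cp in plan.couplings:
        for ra in range(cp.range_a[0], cp.range_a[1] + 1):
            for rb in range(cp.range_b[0], cp.range_b[1] + 1):
                try:
                    add(site_of[(cp.chain_a, ra)], site_of[(cp.chain_b, rb)],
                        cp.stiffness)
                except KeyError as exc:
                    raise ArgumentError(
                        f"coupling range outside construct: {exc}") from exc

    spring_arr = np.array([(i, j, k) for (i, j), k in sorted(springs.items())])
    satellites = _build_satellites(model, site_atoms, plan) \
        if plan.decorate_heavy else None
    net = HarmonicNetworkModel(ref, spring_arr, site_atoms, kT=kT,
                               friction=friction, satellites=satellites)
    net._eig()  # connectivity check (raises ModelError if disconnected)
    return net


def _build_satellites(model: ConstructModel, site_atoms: list[AtomRecord],
                      plan: BlockPlan) -> SatelliteSet:
    seg = model.structure
    site_of = {(a.chain_id, a.residue_index): s
               for s, a in enumerate(site_atoms)}
    parent, offsets, is_site = [], [], []
    ca_pos = {(a.chain_id, a.residue_index): seg.coords[0, a.atom_index]
              for a in site_atoms}
    for a in seg.atoms:
        key = (a.chain_id, a.residue_index)
        parent.append(site_of[key])
        offsets.append(seg.coords[0, a.atom_index] - ca_pos[key])
        is_site.append(a.is_calpha)
    return SatelliteSet(list(seg.atoms), np.array(parent), np.array(offsets),
                        np.array(is_site), plan.jitter_sigma)


# ---------------------------------------------------------------------------
# Closed-form covariance
# ---------------------------------------------------------------------------

def equilibrium_covariance(net: HarmonicNetworkModel,
                           include_satellites: bool = False) -> CovarianceModel:
    """Exact stationary covariance ``kT * pinv(L)`` per Cartesian axis.

    The translational null mode is projected out.  With
    ``include_satellites`` the covariance is extended to the decorated atom
    table: satellites share their parent site's covariance plus independent
    isotropic jitter ``sigma^2 I`` on the diagonal.
    """
    vals, vecs = net._eig()
    inv = np.zeros_like(vals)
    nz = np.abs(vals) >= 1e-9 * max(vals[-1], 1.0)
    inv[nz] = 1.0 / vals[nz]
    site_cov = (vecs * (net.kT * inv)) @ vecs.T      # (n, n) per axis

    if include_satellites:
        if net.satellites is None:
            raise ArgumentError("model has no satellite decoration")
        sat = net.satellites
        p = sat.parent_site
        cov_sites = site_cov[np.ix_(p, p)]
        jitter = np.where(~sat.is_site, sat.sigma ** 2, 0.0)
        cov_sites = cov_sites + np.diag(jitter)
        mean = net.reference[p] + sat.offsets
        atoms = sat.atoms
        per_axis = cov_sites
    else:
        mean = net.reference
        atoms = net.atoms
        per_axis = site_cov

    n = per_axis.shape[0]
    full = np.zeros((3 * n, 3 * n))
    for d in range(3):
        full[d::3, d::3] = per_axis
    evals, evecs = np.linalg.eigh(full)
    evals, evecs = evals[::-1].copy(), evecs[:, ::-1].copy()
    evecs = _order_degenerate(evals, _fix_eigenvector_signs(evecs))
    mask = SelectionMask(tuple(range(n)), "network")
    return CovarianceModel(mean, full, evals, evecs, mask, list(atoms))


# ---------------------------------------------------------------------------
# Trajectory synthesis
# ---------------------------------------------------------------------------

def _simulate_modes_exact(vals, rng, kT, friction, dt, n_total):
    """Exact OU recursion per non-null Laplacian mode, vectorized in time."""
    n_modes = vals.size
    a = np.exp(-vals * dt / friction)                       # (modes,)
    std_eq = np.sqrt(kT / vals)
    std_step = std_eq * np.sqrt(1.0 - a ** 2)
    c0 = rng.standard_normal((n_modes, 3)) * std_eq[:, None]
    noise = rng.standard_normal((n_modes, 3, n_total)) * std_step[:, None, None]
    out = np.empty_like(noise)
    for m in range(n_modes):  # lfilter is per-scalar-coefficient; loop modes
        out[m] = lfilter([1.0], [1.0, -a[m]], noise[m], axis=-1) \
            + (a[m] ** np.arange(1, n_total + 1)) * c0[m, :, None]
    return out  # (modes, 3, n_total)


def _simulate_modes_euler(vals, rng, kT, friction, dt, n_total, substeps):
    if substeps is None:
        # keep h*lambda_max/friction <= 0.05: stable and the Euler-Maruyama
        # stationary-variance bias 1/(1 - h*lambda/2) stays under ~3%
        lam_max = float(vals.max())
        substeps = max(1, int(np.ceil(dt * lam_max / (0.05 * friction))))
    h = dt / substeps / friction
    n_modes = vals.size
    c = rng.standard_normal((n_modes, 3)) * np.sqrt(kT / vals)[:, None]
    decay = 1.0 - vals * h                                  # (modes,)
    out = np.empty((n_modes, 3, n_total))
    amp = np.sqrt(2.0 * kT * h)
    for t in range(n_total):
        for _ in range(substeps):
            c = decay[:, None] * c + amp * rng.standard_normal(c.shape)
        out[:, :, t] = c
        if np.any(np.abs(c) > 1e3):
            raise StabilityError(
                "integrator blow-up (>1000 nm displacement); use a smaller "
                "frame_interval, more substeps, or softer springs")
    return out


def simulate(net: HarmonicNetworkModel,
             config: SimulationConfig) -> TrajectorySegment:
    """Sample a stationary fluctuation trajectory of the network.

    The initial condition is drawn from the exact stationary distribution, so
    the trajectory is equilibrated from frame 0; ``burn_in_frames`` are still
    generated and discarded if requested.  Reproducible given the seed.  With
    satellite decoration the output carries every heavy atom of the source
    construct; otherwise one atom per Cα site.
    """
    rng = np.random.default_rng(config.seed)
    vals, vecs = net._eig()
    nz = np.abs(vals) >= 1e-9 * max(vals[-1], 1.0)
    vals_nz, vecs_nz = vals[nz], vecs[:, nz]
    n_total = config.n_frames + config.burn_in_frames

    if net.kT == 0.0:
        disp = np.zeros((config.n_frames, net.n_sites, 3))
    else:
        if config.method == "exact":
            modes = _simulate_modes_exact(vals_nz, rng, net.kT, net.friction,
                                          config.frame_interval, n_total)
        else:
            modes = _simulate_modes_euler(vals_nz, rng, net.kT, net.friction,
                                          config.frame_interval, n_total,
                                          config.substeps)
        modes = modes[:, :, config.burn_in_frames:]
        # coordinates: u[t, i, d] = sum_m vecs[i, m] * modes[m, d, t]
        disp = np.einsum("im,mdt->tid", vecs_nz, modes)

    if net.satellites is None:
        coords = net.reference[None] + disp
        atoms = list(net.atoms)
        atoms = [replace(a, atom_index=i) for i, a in enumerate(atoms)]
    else:
        sat = net.satellites
        base = net.reference[sat.parent_site] + sat.offsets    # (n_atoms, 3)
        coords = base[None] + disp[:, sat.parent_site, :]
        if net.kT > 0 and sat.sigma > 0:
            jit = rng.standard_normal(coords.shape) * sat.sigma
            jit[:, sat.is_site, :] = 0.0
            coords = coords + jit
        atoms = list(sat.atoms)
    if np.any(np.abs(coords) > 1e3):
        raise StabilityError(
            "coordinates exceeded 1000 nm; reduce the step or stiffness")
    seg = TrajectorySegment(coords, atoms, config.frame_interval,
                            origin_time=0.0)
    seg.metadata.update(seed=config.seed, method=config.method,
                        burn_in_frames=config.burn_in_frames)
    return seg


# ---------------------------------------------------------------------------
# Canonical study conditions
# ---------------------------------------------------------------------------

def default_two_chain_plan(n_residues: int = 40, arrangement: str = "HH1",
                           separation: float = 14.0):
    """The package's reference two-chain block+linker system.

    Two 40-residue chains (the N-terminal stretch of the packaged
    α-synuclein sequence) in an HH1 arrangement at 14 Å separation; each
    chain carries two rigid blocks (residues 1-16 and 25-40) joined by a
    flexible linker (17-24), with an inter-chain coupling between residues
    5-12 of both chains.  Heavy-atom decoration is on, so the system
    exercises the all-heavy-atom PCA path.  Stiffnesses (block 1000,
    linker 50, coupling 10 kJ/mol/nm^2, kT at 310 K) put the network in the
    collective regime the analysis assumes: a handful of soft block/linker
    modes dominate the displacement variance, as expected of an equilibrated
    fluctuation segment.

    Returns ``(construct_spec, block_plan)``.
    """
    from .construct_builder import ConstructSpec
    from .traj_model import alpha_synuclein_sequence

    seq = alpha_synuclein_sequence()[:n_residues]
    spec = ConstructSpec(kind="dimer", sequence=seq,
                         dimer_arrangement=arrangement, separation=separation)
    third = max(n_residues // 3, 2)
    b1_end = 16 if n_residues == 40 else third
    link_end = 24 if n_residues == 40 else min(2 * third, n_residues - 2)
    blocks = tuple(
        BlockSpec(c, a, b, role)
        for c in "AB"
        for a, b, role in [(1, b1_end, "rigid-block"),
                           (b1_end + 1, link_end, "linker"),
                           (link_end + 1, n_residues, "rigid-block")])
    lo, hi = min(5, b1_end), min(12, b1_end)
    couplings = (CouplingSpec("A", (lo, hi), "B", (lo, hi), 10.0),)
    plan = BlockPlan(blocks, couplings, k_block=1000.0, k_linker=50.0,
                     cutoff=1.0, decorate_heavy=True, jitter_sigma=0.005)
    return spec, plan
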