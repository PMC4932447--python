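"""Essential collective dynamics: segment PCA, images, descriptors.

The analysis chain is

1. covariance of the 3N Cartesian coordinate time series over one short
   trajectory segment, ``C_ij = <(X_i - <X_i>)(X_j - <X_j>)>``, usually after
   least-squares superposition of every frame onto the segment mean;
2. eigendecomposition of C, eigenpairs sorted by decreasing eigenvalue;
3. per-atom "images": for atom i, the vector r_i of length 3*k_max obtained by
   concatenating the (x, y, z) components of atom i in each of the top k_max
   eigenvectors;
4. descriptors in image space — main-chain flexibility F(i) = |r_i - eps|
   with eps the centroid over Cα images, and pair correlations
   d_ij = |r_i - r_j|.  Small d_ij means atoms i and j move coherently;
   d_ij is a metric because it is a Euclidean distance.

Segment averaging (e.g. fifty 0.2-ns segments from a trailing 10-ns window)
runs the full chain per segment and averages the descriptors elementwise,
retaining per-element standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import (
    ArgumentError,
    ConsistencyError,
    DataError,
    GeometryError,
    RankError,
    SelectionError,
)
from .traj_model import AtomRecord, SelectionMask, TrajectorySegment, select

#: Relative threshold under which an eigenvalue counts as zero.
_EIG_ZERO_RTOL = 1e-10
#: Relative gap under which adjacent eigenvalues count as degenerate.
_DEGENERACY_RTOL = 1e-8


@dataclass
class CovarianceModel:
    """Mean structure + 3N x 3N covariance with sorted, sign-fixed eigenpairs.

    Degrees of freedom are interleaved (x1, y1, z1, x2, ...).  Eigenvectors
    are orthonormal columns; each is flipped so its largest-magnitude
    component is positive (ties broken by lowest index), and exactly
    degenerate eigenpairs are ordered lexicographically by eigenvector so the
    decomposition is deterministic.
    """

    mean_coords: np.ndarray      # (n_sel, 3) nm
    covariance: np.ndarray       # (3n, 3n) nm^2
    eigenvalues: np.ndarray      # descending
    eigenvectors: np.ndarray     # columns
    selection: SelectionMask
    atoms: list[AtomRecord]      # the selected atoms, in selection order

    @property
    def total_variance(self) -> float:
        return float(np.trace(self.covariance))

    @property
    def rank(self) -> int:
        """Number of strictly positive eigenvalues."""
        if self.eigenvalues.size == 0:
            return 0
        tol = _EIG_ZERO_RTOL * max(self.eigenvalues[0], 0.0)
        return int(np.sum(self.eigenvalues > max(tol, 0.0)))

    def degenerate_clusters(self) -> list[tuple[int, int]]:
        """Half-open index ranges of (near-)equal eigenvalues."""
        ev = self.eigenvalues
        if ev.size == 0:
            return []
        scale = max(abs(ev[0]), 1e-300)
        clusters, start = [], 0
        for i in range(1, ev.size):
            if abs(ev[i - 1] - ev[i]) > _DEGENERACY_RTOL * scale:
                clusters.append((start, i))
                start = i
        clusters.append((start, ev.size))
        return clusters


@dataclass
class ProjectedImage:
    """Per-atom image vectors in the space of the top k_max components."""

    k_max: int
    images: np.ndarray           # (n_sel, 3*k_max)
    atoms: list[AtomRecord]
    selection: SelectionMask


@dataclass
class FlexibilityProfile:
    """F(i) = |r_i - eps| over Cα atoms; low F = coupled to collective motion."""

    values: np.ndarray           # (n_calpha,)
    atoms: list[AtomRecord]      # Cα records
    centroid: np.ndarray         # eps, (3*k_max,)
    sd: np.ndarray | None = None  # segment-to-segment standard deviation

    def residue_labels(self) -> list[tuple[str, int]]:
        return [(a.chain_id, a.residue_index) for a in self.atoms]

    def chain_values(self, chain_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(residue indices, F values) for one chain."""
        idx = [i for i, a in enumerate(self.atoms) if a.chain_id == chain_id]
        if not idx:
            raise SelectionError(f"no Cα atoms in chain {chain_id!r}")
        res = np.array([self.atoms[i].residue_index for i in idx])
        return res, self.values[idx]


@dataclass
class CorrelationMap:
    """Symmetric matrix of image distances d_ij over a selection."""

    matrix: np.ndarray           # (m, m)
    atoms: list[AtomRecord]
    sd: np.ndarray | None = None

    def residue_labels(self) -> list[tuple[str, int]]:
        return [(a.chain_id, a.residue_index) for a in self.atoms]


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _check_fit_geometry(ref_fit: np.ndarray) -> None:
    if ref_fit.shape[0] < 3:
        raise GeometryError("superposition needs >= 3 fit atoms")
    centered = ref_fit - ref_fit.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] <= 1e-10 * max(svals[0], 1e-300):
        raise GeometryError("fit selection is (near-)collinear")


def _fit_frames(coords: np.ndarray, ref: np.ndarray,
                fit_idx: np.ndarray) -> np.ndarray:
    """Least-squares rigid fit of every frame onto ``ref`` over ``fit_idx``.

    Batched Kabsch: per frame, SVD of the 3x3 cross-covariance between the
    centred mobile and reference fit atoms gives the optimal proper rotation
    (reflections removed via the determinant correction).
    """
    ref_fit = ref[fit_idx]
    ref_c = ref_fit.mean(axis=0)
    q = ref_fit - ref_c                                   # (m, 3)
    mob = coords[:, fit_idx, :]
    mob_c = mob.mean(axis=1, keepdims=True)               # (T, 1, 3)
    p = mob - mob_c
    h = np.einsum("tmi,mj->tij", p, q)                    # cross-covariance
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("tji,tkj->tik", vt, u)))
    vt[:, 2, :] *= d[:, None]
    rot = np.einsum("tji,tkj->tik", vt, u)                # R = V' U^T
    return np.einsum("tij,tmj->tmi", rot, coords - mob_c) + ref_c


def superpose_frames(segment: TrajectorySegment,
                     reference: str = "segment-mean",
                     fit_selection: SelectionMask | None = None,
                     ) -> TrajectorySegment:
    """Remove rigid-body motion by least-squares fitting every frame.

    ``reference`` is ``"segment-mean"`` (fit, recompute the mean, refit,
    iterated to a fixed point so the operation is idempotent) or
    ``"first-frame"``.  Fitting uses ``fit_selection`` (default: all atoms);
    the optimal rotation is computed on the fit atoms and applied to all.
    """
    fit_idx = np.array(fit_selection.indices if fit_selection is not None
                       else range(segment.n_atoms), dtype=int)
    coords = segment.coords
    if reference == "first-frame":
        ref = coords[0]
        _check_fit_geometry(ref[fit_idx])
        fitted = _fit_frames(coords, ref, fit_idx)
    elif reference == "segment-mean":
        ref = coords.mean(axis=0)
        _check_fit_geometry(ref[fit_idx])
        fitted = _fit_frames(coords, ref, fit_idx)
        # iterate fit -> recompute mean -> refit to a fixed point, so the
        # operation is idempotent
        for _ in range(100):
            refitted = _fit_frames(fitted, fitted.mean(axis=0), fit_idx)
            delta = float(np.abs(refitted - fitted).max())
            fitted = refitted
            if delta < 1e-13:
                break
    else:
        raise ArgumentError(f"unknown superposition reference {reference!r}")
    return TrajectorySegment(fitted, segment.atoms, segment.frame_interval,
                             segment.origin_time)


# ---------------------------------------------------------------------------
# Covariance and eigenpairs
# ---------------------------------------------------------------------------

def _fix_eigenvector_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|.| component is positive.

    Ties (equal magnitudes) resolve to the lowest index.  A global sign flip
    of an eigenvector reflects every atom triplet simultaneously, so image
    DIFFERENCES (hence d_ij and F) are unaffected; the convention only makes
    the decomposition reproducible bit-for-bit.
    """
    out = vecs.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        lead = int(np.argmax(np.abs(col)))
        if col[lead] < 0:
            out[:, k] = -col
    return out


def _order_degenerate(vals: np.ndarray, vecs: np.ndarray) -> np.ndarray:
    """Within exactly-degenerate clusters, sort columns lexicographically."""
    scale = max(abs(vals[0]) if vals.size else 0.0, 1e-300)
    i = 0
    while i < vals.size:
        j = i + 1
        while j < vals.size and abs(vals[j] - vals[i]) <= \
                _DEGENERACY_RTOL * scale:
            j += 1
        if j - i > 1:
            order = np.lexsort(vecs[::-1, i:j])  # rows as keys, first row major
            vecs[:, i:j] = vecs[:, i:j][:, order]
        i = j
    return vecs


def compute_covariance(segment: TrajectorySegment,
                       selection: SelectionMask | None = None,
                       ) -> CovarianceModel:
    """Time-average covariance of the selected coordinates, eigendecomposed.

    Plain population normalisation (1/T).  One frame is allowed and yields the
    zero matrix.  The full symmetric matrix is decomposed exactly (dense
    ``eigh``); eigenvalues descend, eigenvectors are sign-fixed.
    """
    if selection is None:
        selection = select(segment, "all")
    sub = segment.coords[:, selection.indices, :]
    if not np.all(np.isfinite(sub)):
        raise DataError("non-finite coordinates in segment")
    n_sel = sub.shape[1]
    flat = sub.reshape(segment.n_frames, 3 * n_sel)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / segment.n_frames
    cov = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(cov)
    vals, vecs = vals[::-1].copy(), vecs[:, ::-1].copy()
    vecs = _order_degenerate(vals, _fix_eigenvector_signs(vecs))
    atoms = [segment.atoms[i] for i in selection.indices]
    return CovarianceModel(mean.reshape(n_sel, 3), cov, vals, vecs,
                           selection, atoms)


def variance_captured(model: CovarianceModel, k: int) -> float:
    """Fraction of total displacement variance in the top k components."""
    n = model.eigenvalues.size
    if not 1 <= k <= n:
        raise ArgumentError(f"k must be in [1, {n}]")
    total = float(model.eigenvalues.sum())
    if total <= 0:
        raise DataError("total variance is zero; fraction undefined")
    return float(np.clip(model.eigenvalues[:k].sum() / total, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Images and descriptors
# ---------------------------------------------------------------------------

def project_images(model: CovarianceModel, k_max: int = 20) -> ProjectedImage:
    """Build per-atom images from the top ``k_max`` eigenvectors.

    Image of atom i = concatenated triplets (E^k_ix, E^k_iy, E^k_iz) for
    k = 1..k_max.  Eigenvector orthonormality forces sum_i |r_i|^2 = k_max.
    Warns when the cut falls inside a degenerate eigenvalue cluster (the
    split is then basis-dependent up to rotations within the cluster).
    """
    rank = model.rank
    if not 1 <= k_max <= rank:
        raise RankError(
            f"k_max={k_max} exceeds the positive spectrum (rank {rank})")
    for lo, hi in model.degenerate_clusters():
        if lo < k_max < hi:
            warnings.warn(
                f"k_max={k_max} splits a degenerate eigenvalue cluster "
                f"[{lo}, {hi}); descriptors may depend on basis choice",
                stacklevel=2)
            break
    n = len(model.atoms)
    top = model.eigenvectors[:, :k_max]          # (3n, k)
    images = np.transpose(top.reshape(n, 3, k_max), (0, 2, 1)).reshape(
        n, 3 * k_max)
    return ProjectedImage(k_max, images, list(model.atoms), model.selection)


def flexibility_profile(image: ProjectedImage) -> FlexibilityProfile:
    """Distance of each Cα image from the centroid of all Cα images."""
    idx = [i for i, a in enumerate(image.atoms) if a.is_calpha]
    if not idx:
        raise SelectionError("no Cα atoms in the projected image")
    r = image.images[idx]
    eps = r.mean(axis=0)
    values = np.linalg.norm(r - eps, axis=1)
    return FlexibilityProfile(values, [image.atoms[i] for i in idx], eps)


def pair_correlations(image: ProjectedImage,
                      selection: SelectionMask | None = None,
                      ) -> CorrelationMap:
    """Full symmetric matrix of image distances d_ij over a selection.

    ``selection`` indexes the original segment atoms and must be a subset of
    the atoms the image was built on; default is every image atom.
    """
    if selection is None:
        rows = np.arange(len(image.atoms))
    else:
        pos = {a.atom_index: i for i, a in enumerate(image.atoms)}
        missing = [i for i in selection.indices if i not in pos]
        if missing:
            raise SelectionError(
                f"selection atoms {missing[:5]} not present in the image")
        rows = np.array([pos[i] for i in selection.indices])
    r = image.images[rows]
    mat = squareform(pdist(r)) if len(rows) > 1 else np.zeros((1, 1))
    return CorrelationMap(mat, [image.atoms[i] for i in rows])


# ---------------------------------------------------------------------------
# Segment averaging
# ---------------------------------------------------------------------------

def _segment_descriptor(segment: TrajectorySegment, selection: SelectionMask,
                        k_max: int, which: str, fit: bool,
                        descriptor_selection: SelectionMask | None):
    seg = superpose_frames(segment, "segment-mean", selection) if fit \
        else segment
    model = compute_covariance(seg, selection)
    image = project_images(model, k_max)
    if which == "flexibility":
        return flexibility_profile(image)
    if which == "correlation":
        return pair_correlations(image, descriptor_selection)
    raise ArgumentError(f"unknown descriptor {which!r}")


def average_descriptors(segments: Sequence[TrajectorySegment],
                        selection: SelectionMask, k_max: int, which: str,
                        fit: bool = True,
                        descriptor_selection: SelectionMask | None = None):
    """Per-segment pipeline, then unweighted elementwise mean across segments.

    Each segment is superposed (optional), PCA'd on ``selection``, projected
    to ``k_max`` components, and reduced to the requested descriptor; the
    segment-to-segment standard deviation is retained.  All segments must
    share the atom table.
    """
    if not segments:
        raise ArgumentError("need at least one segment")
    first_atoms = segments[0].atoms
    for s in segments[1:]:
        if s.atoms != first_atoms:
            raise ConsistencyError("segments do not share an atom table")
    results = [_segment_descriptor(s, selection, k_max, which, fit,
                                   descriptor_selection) for s in segments]
    if which == "flexibility":
        stack = np.array([r.values for r in results])
        return FlexibilityProfile(stack.mean(axis=0), results[0].atoms,
                                  np.mean([r.centroid for r in results],
                                          axis=0),
                                  sd=stack.std(axis=0, ddof=0))
    stack = np.array([r.matrix for r in results])
    return CorrelationMap(stack.mean(axis=0), results[0].atoms,
                          sd=stack.std(axis=0, ddof=0))
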