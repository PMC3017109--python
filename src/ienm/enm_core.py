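"""Elastic network model construction, energetics, and normal mode analysis.

The model is the classic Cα network: every residue pair closer than a cutoff
``R_c`` in the reference structure is joined by a Hookean spring whose rest
length is the reference distance. Chemically bonded neighbours (sequential
residues on the same chain) always carry a stiff spring ``k_bonded`` (default
10) regardless of the cutoff; all other pairs get ``k_nonbonded`` (default 1).
Force-constant units are arbitrary — energies are reported in "model units",
and every downstream quantity used for interpretation (pathways, fractional
progress) is unit-free.

    E(x) = sum_springs  k_ij/2 (d_ij - d0_ij)^2

Normal modes are eigenpairs of the 3N x 3N Hessian at the reference, after
discarding the six rigid-body (translation/rotation) zero modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .structures_io import Structure

log = logging.getLogger(__name__)

__all__ = [
    "ENMModel",
    "ModeSet",
    "DisconnectedNetworkError",
    "build_enm",
    "bonded_pairs",
    "enm_energy_gradient",
    "enm_hessian",
    "spring_hessian",
    "normal_modes",
    "rigid_body_basis",
    "overlap",
    "cumulative_overlap",
    "displace_along_mode",
    "difference_vector",
    "scan_cutoff",
    "modes_to_frame",
]

#: ratio by which the 7th eigenvalue must exceed the 6th for the rigid-body
#: null space to be considered exactly six-dimensional
RIGID_GAP_RATIO = 1e6


class DisconnectedNetworkError(ValueError):
    """Raised when the spring network has more than one connected component."""

    def __init__(self, labels: np.ndarray):
        self.component_labels = labels
        n_comp = int(labels.max()) + 1
        sizes = np.bincount(labels)
        super().__init__(
            f"spring network has {n_comp} connected components "
            f"(sizes {sizes.tolist()}); mask or cutoff severed the model"
        )


@dataclass(frozen=True)
class ENMModel:
    """Spring list plus reference coordinates.

    ``i < j`` for every spring; ``bonded`` flags sequential same-chain pairs.
    """

    reference: Structure
    i: np.ndarray
    j: np.ndarray
    d0: np.ndarray
    k: np.ndarray
    bonded: np.ndarray
    cutoff: float
    k_bonded: float
    k_nonbonded: float

    @property
    def n_atoms(self) -> int:
        return self.reference.n_atoms

    @property
    def n_springs(self) -> int:
        return self.i.size

    def pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.i.tolist(), self.j.tolist()))


@dataclass(frozen=True)
class ModeSet:
    """Non-rigid normal modes, ascending by eigenvalue.

    ``eigenvectors[m]`` is a unit 3N-vector; the first component of each with
    magnitude above 1e-8 is made positive so results are sign-reproducible.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_excluded_rigid: int = 6

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size


def bonded_pairs(structure: Structure) -> np.ndarray:
    """(n, 2) array of sequential same-chain residue pairs (|Δresnum| = 1)."""
    same_chain = structure.chain_ids[:-1] == structure.chain_ids[1:]
    seq = np.abs(structure.resnums[1:] - structure.resnums[:-1]) == 1
    idx = np.flatnonzero(same_chain & seq)
    return np.column_stack([idx, idx + 1])


def build_enm(
    structure: Structure,
    cutoff: float = 10.0,
    k_bonded: float = 10.0,
    k_nonbonded: float = 1.0,
    masked_pairs=None,
    nonbonded_scope: np.ndarray | None = None,
) -> ENMModel:
    """Construct the ENM spring list for a reference structure.

    Parameters
    ----------
    masked_pairs
        Optional set of (i, j) global-index pairs whose **non-bonded** springs
        are omitted (perturbation analysis). Bonded springs are never severed;
        a bonded pair matching the mask is kept and logged.
    nonbonded_scope
        Optional boolean mask over atoms; non-bonded springs are restricted to
        pairs with both members in scope (used to drop the unaligned residues
        from an end-conformation well, whose open-form positions are unknown).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = structure.n_atoms
    mask = {tuple(sorted(p)) for p in masked_pairs} if masked_pairs else set()

    tree = cKDTree(structure.coords)
    cand = tree.query_pairs(cutoff, output_type="ndarray")  # i < j, strict <

    bp = bonded_pairs(structure)
    bonded_set = {tuple(p) for p in bp.tolist()}

    scope_ok = np.ones(n, dtype=bool) if nonbonded_scope is None else np.asarray(nonbonded_scope, bool)

    rows = []
    for i, j in cand.tolist():
        pair = (i, j)
        if pair in bonded_set:
            continue
        if pair in mask:
            continue
        if not (scope_ok[i] and scope_ok[j]):
            continue
        rows.append((i, j, k_nonbonded, False))
    for i, j in bp.tolist():
        if (i, j) in mask:
            log.warning("bonded pair (%d, %d) matches mask; backbone spring kept", i, j)
        rows.append((i, j, k_bonded, True))
    if not rows:
        log.warning("ENM has an empty spring list")
        empty = np.empty(0, dtype=int)
        return ENMModel(structure, empty, empty, np.empty(0), np.empty(0),
                        np.empty(0, dtype=bool), cutoff, k_bonded, k_nonbonded)

    rows.sort(key=lambda r: (r[0], r[1]))
    ii = np.array([r[0] for r in rows], dtype=int)
    jj = np.array([r[1] for r in rows], dtype=int)
    kk = np.array([r[2] for r in rows], dtype=float)
    bb = np.array([r[3] for r in rows], dtype=bool)
    d0 = np.linalg.norm(structure.coords[jj] - structure.coords[ii], axis=1)
    if np.any(d0 <= 0):
        raise ValueError("coincident connected atoms in reference")
    return ENMModel(structure, ii, jj, d0, kk, bb, cutoff, k_bonded, k_nonbonded)


# ---------------------------------------------------------------------------
# energetics
# ---------------------------------------------------------------------------


def _spring_geometry(model: ENMModel, coords: np.ndarray):
    coords = np.asarray(coords, dtype=float).reshape(model.n_atoms, 3)
    dvec = coords[model.j] - coords[model.i]
    d = np.linalg.norm(dvec, axis=1)
    if np.any(d == 0):
        raise ValueError("coincident connected atoms")
    return coords, dvec, d


def enm_energy_gradient(model: ENMModel, coords: np.ndarray):
    """Energy (model units) and analytic gradient, shape (N, 3)."""
    coords, dvec, d = _spring_geometry(model, coords)
    stretch = d - model.d0
    energy = float(0.5 * np.sum(model.k * stretch**2))
    # dE/dx_j = k (d - d0) * unit(j - i); dE/dx_i = -that
    f = (model.k * stretch / d)[:, None] * dvec
    grad = np.zeros_like(coords)
    np.add.at(grad, model.j, f)
    np.add.at(grad, model.i, -f)
    return energy, grad


def spring_hessian(
    n_atoms: int,
    i: np.ndarray,
    j: np.ndarray,
    d0: np.ndarray,
    k: np.ndarray,
    coords: np.ndarray,
) -> sp.csr_matrix:
    """Sparse 3N x 3N Hessian of a list of harmonic springs at `coords`.

    Per spring, the off-diagonal 3x3 super-element is
    ``-(k u u^T + k (1 - d0/d)(I - u u^T))`` with ``u`` the unit bond vector,
    and diagonal blocks accumulate the opposite sign — the standard block
    pattern touching (i,i), (j,j), (i,j), (j,i) only.
    """
    coords = np.asarray(coords, dtype=float).reshape(n_atoms, 3)
    dvec = coords[j] - coords[i]
    d = np.linalg.norm(dvec, axis=1)
    if np.any(d == 0):
        raise ValueError("coincident connected atoms")
    u = dvec / d[:, None]
    uu = u[:, :, None] * u[:, None, :]                    # (S, 3, 3)
    eye = np.broadcast_to(np.eye(3), uu.shape)
    block = k[:, None, None] * (uu + (1.0 - d0 / d)[:, None, None] * (eye - uu))

    S = i.size
    off = np.arange(3)
    rows3 = np.repeat(off, 3)[None, :]                    # (1, 9)
    cols3 = np.tile(off, 3)[None, :]
    data = np.concatenate([block, block, -block, -block], axis=0).reshape(-1)
    bi = 3 * np.concatenate([i, j, i, j])
    bj = 3 * np.concatenate([i, j, j, i])
    rows = (bi[:, None] + np.tile(rows3, (4 * S, 1))).reshape(-1)
    cols = (bj[:, None] + np.tile(cols3, (4 * S, 1))).reshape(-1)
    H = sp.coo_matrix((data, (rows, cols)), shape=(3 * n_atoms, 3 * n_atoms))
    return H.tocsr()


def enm_hessian(model: ENMModel, coords: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse Hessian of the ENM at `coords` (default: the reference)."""
    if coords is None:
        coords = model.reference.coords
    return spring_hessian(model.n_atoms, model.i, model.j, model.d0, model.k, coords)


# ---------------------------------------------------------------------------
# normal modes
# ---------------------------------------------------------------------------


def _check_connected(model: ENMModel) -> None:
    n = model.n_atoms
    adj = sp.coo_matrix(
        (np.ones(model.n_springs), (model.i, model.j)), shape=(n, n)
    )
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    if n_comp > 1:
        raise DisconnectedNetworkError(labels)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    out = vecs.copy()
    for m in range(out.shape[0]):
        nz = np.flatnonzero(np.abs(out[m]) > 1e-8)
        if nz.size and out[m, nz[0]] < 0:
            out[m] = -out[m]
    return out


def normal_modes(model: ENMModel, n_modes: int, dense_threshold: int = 1200) -> ModeSet:
    """Lowest `n_modes` non-rigid normal modes of the ENM at its reference.

    Uses a dense symmetric eigensolver for small systems and shift-invert
    sparse Lanczos above `dense_threshold` degrees of freedom. The six
    smallest-magnitude eigenvalues are identified as rigid-body modes; the
    seventh must exceed the sixth by a factor of ``RIGID_GAP_RATIO`` or the
    network is reported disconnected.
    """
    _check_connected(model)
    H = enm_hessian(model)
    dof = H.shape[0]
    want = min(n_modes + 6, dof)
    if dof <= dense_threshold or want > dof // 2:
        vals, vecs = np.linalg.eigh(H.toarray())
        vals, vecs = vals[:want], vecs[:, :want]
    else:
        vals, vecs = spla.eigsh(H, k=want, sigma=-1e-6, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]

    gap6 = max(abs(vals[5]), 1e-300)
    if vals.size > 6 and vals[6] < RIGID_GAP_RATIO * gap6 and vals[6] < 1e-8:
        # degenerate near-zero modes beyond six: treat as disconnected
        raise DisconnectedNetworkError(np.zeros(model.n_atoms, dtype=int))
    vals, vecs = vals[6:], vecs[:, 6:]
    vecs = vecs / np.linalg.norm(vecs, axis=0)
    return ModeSet(np.clip(vals, 0.0, None), _fix_signs(vecs.T))


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal (6, 3N) basis of rigid translations and rotations about
    the centroid."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    c = coords - coords.mean(axis=0)
    basis = np.zeros((6, n, 3))
    for a in range(3):
        basis[a, :, a] = 1.0
    for a, axis in enumerate(np.eye(3)):
        basis[3 + a] = np.cross(axis, c)
    flat = basis.reshape(6, -1)
    q, _ = np.linalg.qr(flat.T)
    return q.T


# ---------------------------------------------------------------------------
# overlaps and displacements
# ---------------------------------------------------------------------------


def difference_vector(begin: Structure, end_superposed: Structure) -> np.ndarray:
    """Flattened 3N displacement from begin to (pre-superposed) end."""
    if begin.n_atoms != end_superposed.n_atoms:
        raise ValueError("structures differ in size")
    return (end_superposed.coords - begin.coords).reshape(-1)


def overlap(mode: np.ndarray, delta: np.ndarray) -> float:
    """Normalized absolute projection of one mode onto a displacement."""
    mode = np.asarray(mode, dtype=float).reshape(-1)
    delta = np.asarray(delta, dtype=float).reshape(-1)
    nd = np.linalg.norm(delta)
    if nd == 0:
        raise ValueError("zero displacement vector")
    return float(abs(mode @ delta) / (np.linalg.norm(mode) * nd))


def cumulative_overlap(modes: ModeSet, delta: np.ndarray, M: int | None = None) -> float:
    """Quadrature sum of mode overlaps: sqrt(sum_{m<=M} overlap_m^2)."""
    M = modes.n_modes if M is None else M
    if M > modes.n_modes:
        raise ValueError(f"M={M} exceeds available modes ({modes.n_modes})")
    ov = np.array([overlap(modes.eigenvectors[m], delta) for m in range(M)])
    return float(np.sqrt(np.sum(ov**2)))


def displace_along_mode(structure: Structure, mode: np.ndarray, target_rmsd: float) -> Structure:
    """Displace the Cα set along a mode direction by a prescribed RMSD.

    With a unit 3N mode vector the amplitude is ``target_rmsd * sqrt(N)``.
    """
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be non-negative")
    mode = np.asarray(mode, dtype=float).reshape(-1)
    norm = np.linalg.norm(mode)
    if abs(norm - 1.0) > 1e-8:
        log.warning("mode vector not unit (|v| = %.6g); renormalizing", norm)
        mode = mode / norm
    n = structure.n_atoms
    new = structure.coords.reshape(-1) + target_rmsd * np.sqrt(n) * mode
    return structure.with_coords(new.reshape(n, 3))


def scan_cutoff(
    structure: Structure,
    end_superposed: Structure,
    n_modes: int,
    cutoffs=np.arange(8.0, 16.5, 1.0),
    k_bonded: float = 10.0,
    k_nonbonded: float = 1.0,
) -> pd.DataFrame:
    """Cumulative overlap of the lowest `n_modes` modes vs. spring cutoff.

    Supports choosing the cutoff that best captures an observed transition;
    no particular optimum is assumed.
    """
    delta = difference_vector(structure, end_superposed)
    rows = []
    for rc in np.asarray(cutoffs, dtype=float):
        model = build_enm(structure, cutoff=rc, k_bonded=k_bonded, k_nonbonded=k_nonbonded)
        try:
            modes = normal_modes(model, n_modes)
        except DisconnectedNetworkError:
            rows.append((rc, np.nan))
            continue
        rows.append((rc, cumulative_overlap(modes, delta)))
    return pd.DataFrame(rows, columns=["cutoff", "cumulative_overlap"])


def modes_to_frame(modes: ModeSet, delta: np.ndarray | None = None) -> pd.DataFrame:
    """Tabulate modes as (mode, eigenvalue[, overlap, cumulative_overlap])."""
    df = pd.DataFrame(
        {"mode": np.arange(1, modes.n_modes + 1), "eigenvalue": modes.eigenvalues}
    )
    if delta is not None:
        ov = np.array([overlap(v, delta) for v in modes.eigenvectors])
        df["overlap"] = ov
        df["cumulative_overlap"] = np.sqrt(np.cumsum(ov**2))
    return df
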