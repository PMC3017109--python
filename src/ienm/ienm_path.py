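"""Saddle-point transition pathways on an interpolated double-well potential.

Given two endpoint conformations, two single-well ENM potentials ``E1`` and
``E2`` are anchored at them. The saddle points of *any* double-well
combination of the two wells lie on the solution curve of

    lambda * grad E1(x) + (1 - lambda) * grad E2(x) + grad E_coll(x) = 0

as the interpolation parameter lambda sweeps from 1 to 0 — equivalently the
minima of the linearly interpolated potential
``lambda E1 + (1-lambda) E2 + E_coll``. The curve is therefore independent of
the functional form used to mix the two wells, which is the method's central
robustness property. ``E_coll`` is a short-range steric penalty that switches
on only when two non-bonded Cα atoms approach closer than ``d_c``, the
smallest non-bonded Cα–Cα distance seen in either endpoint (so both endpoints
are penalty-free by construction).

Each point on the sweep is found by a damped Newton iteration warm-started
from the previous lambda, with a small diagonal shift to regularize the
rigid-body null space, and re-superposed onto the begin conformation to
remove rigid drift.

The exact algebraic body of the collision term is a smooth one-sided
quadratic, ``sum k_coll/2 (d - d_c)^2`` over non-bonded pairs with
``d < d_c``; it vanishes with continuous first derivative at ``d = d_c``.
For well-separated endpoint pairs the term is diagnostic rather than
decisive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from . import enm_core
from .enm_core import ENMModel, build_enm, bonded_pairs, enm_energy_gradient, enm_hessian
from .structures_io import AlignmentMap, Pathway, Structure, identity_alignment, kabsch, superpose

log = logging.getLogger(__name__)

__all__ = [
    "DoubleWellSpec",
    "SolverSettings",
    "ConvergenceError",
    "make_double_well",
    "min_nonbonded_distance",
    "collision_energy_gradient",
    "collision_hessian",
    "interpolated_minimize",
    "solve_pathway",
    "pathway_energy_profile",
]


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the gradient tolerance."""

    def __init__(self, lam: float, residual: float, max_iter: int):
        self.lam, self.residual = lam, residual
        super().__init__(
            f"Newton did not converge at lambda={lam:.6g} "
            f"(residual {residual:.3g} after {max_iter} iterations)"
        )


@dataclass(frozen=True)
class DoubleWellSpec:
    """The two endpoint wells plus the steric-collision term.

    ``model_begin`` is a full ENM at the begin conformation. ``model_end`` is
    anchored at the alignment-completed end target (in begin atom order):
    non-bonded springs exist only between aligned residues, while bonded
    springs always exist — those touching an unaligned residue inherit their
    rest length from the begin conformation, keeping the chain intact where
    the end-state position is unknown. ``bonded`` pairs are excluded from the
    collision sum.
    """

    model_begin: ENMModel
    model_end: ENMModel
    end_target: np.ndarray          # (N, 3), begin indexing
    aligned_mask: np.ndarray        # (N,) bool, True where end position known
    k_coll: float
    d_c: float
    bonded_set: frozenset

    @property
    def n_atoms(self) -> int:
        return self.model_begin.n_atoms

    @property
    def begin_coords(self) -> np.ndarray:
        return self.model_begin.reference.coords


@dataclass(frozen=True)
class SolverSettings:
    """Sweep schedule and Newton controls.

    ``lambda_schedule=None`` means `n_lambda` uniform steps from 1 to 0;
    whenever consecutive solutions move more than ``2 * sampling_increment``
    (all-atom RMSD) the interval is bisected adaptively, so the subsampled
    pathway is effectively schedule-independent.
    """

    lambda_schedule: np.ndarray | None = None
    n_lambda: int = 201
    newton_tolerance: float = 1e-8
    max_newton_iterations: int = 200
    sampling_increment: float = 0.1
    diagonal_shift_scale: float = 1e-8
    max_bisection_depth: int = 12

    def schedule(self) -> np.ndarray:
        if self.lambda_schedule is not None:
            s = np.asarray(self.lambda_schedule, dtype=float)
            if s[0] != 1.0 or s[-1] != 0.0 or np.any(np.diff(s) >= 0):
                raise ValueError("lambda schedule must run strictly from 1 to 0")
            return s
        return np.linspace(1.0, 0.0, self.n_lambda)


# ---------------------------------------------------------------------------
# spec construction
# ---------------------------------------------------------------------------


def min_nonbonded_distance(structure: Structure) -> float:
    """Smallest Cα–Cα distance between non-bonded residues."""
    coords = structure.coords
    bset = {tuple(p) for p in bonded_pairs(structure).tolist()}
    tree = cKDTree(coords)
    # widen the query until some non-bonded pair is found
    r = 5.0
    while True:
        pairs = tree.query_pairs(r, output_type="ndarray")
        nb = [p for p in pairs.tolist() if tuple(p) not in bset]
        if nb:
            nb = np.array(nb)
            return float(np.min(np.linalg.norm(coords[nb[:, 1]] - coords[nb[:, 0]], axis=1)))
        r *= 2.0
        if r > 1e4:
            raise ValueError("no non-bonded pairs found")


def make_double_well(
    begin: Structure,
    end: Structure,
    amap: AlignmentMap | None = None,
    cutoff: float = 10.0,
    k_bonded: float = 10.0,
    k_nonbonded: float = 1.0,
    k_coll: float = 10.0,
    d_c: float | None = None,
    masked_pairs=None,
    mask_wells: str = "both",
) -> DoubleWellSpec:
    """Assemble the double-well specification for a begin→end transition.

    The end structure is rigid-body superposed onto the begin structure over
    the aligned pairs; unaligned begin residues keep their begin positions in
    the end target (their open-form coordinates are unknown) and contribute
    no non-bonded springs to the end well.

    ``masked_pairs`` (begin indexing) removes non-bonded springs for
    perturbation analysis from both wells, or from only one with
    ``mask_wells`` in {"both", "begin", "end"}.
    """
    if amap is None:
        amap = identity_alignment(begin, end)
    if mask_wells not in ("both", "begin", "end"):
        raise ValueError("mask_wells must be 'both', 'begin' or 'end'")
    end_sup, _ = superpose(end, begin, _swap(amap))

    n = begin.n_atoms
    aligned_mask = np.zeros(n, dtype=bool)
    aligned_mask[amap.begin_indices] = True
    end_target = begin.coords.copy()
    end_target[amap.begin_indices] = end_sup.coords[amap.end_indices]

    mask_b = masked_pairs if mask_wells in ("both", "begin") else None
    mask_e = masked_pairs if mask_wells in ("both", "end") else None

    model_begin = build_enm(begin, cutoff, k_bonded, k_nonbonded, masked_pairs=mask_b)
    end_struct = begin.with_coords(end_target, label=f"{end.label}|completed")
    model_end = build_enm(
        end_struct, cutoff, k_bonded, k_nonbonded,
        masked_pairs=mask_e, nonbonded_scope=aligned_mask,
    )
    # bonded springs touching an unaligned residue: rest length from begin
    touch_un = ~(aligned_mask[model_end.i] & aligned_mask[model_end.j])
    fix = model_end.bonded & touch_un
    if np.any(fix):
        d0 = model_end.d0.copy()
        d0[fix] = np.linalg.norm(
            begin.coords[model_end.j[fix]] - begin.coords[model_end.i[fix]], axis=1
        )
        model_end = replace(model_end, d0=d0)

    if d_c is None:
        d_c = min(min_nonbonded_distance(begin), min_nonbonded_distance(end_struct))
    if d_c <= 0:
        raise ValueError("collision distance must be positive")

    bset = frozenset(tuple(p) for p in bonded_pairs(begin).tolist())
    return DoubleWellSpec(model_begin, model_end, end_target, aligned_mask, k_coll, float(d_c), bset)


def _swap(amap: AlignmentMap) -> AlignmentMap:
    return AlignmentMap(amap.pairs[:, ::-1], amap.unaligned_end, amap.unaligned_begin)


# ---------------------------------------------------------------------------
# collision term
# ---------------------------------------------------------------------------


def _colliding_pairs(spec: DoubleWellSpec, coords: np.ndarray) -> np.ndarray:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(spec.d_c, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    keep = [p for p in pairs.tolist() if tuple(p) not in spec.bonded_set]
    return np.array(keep, dtype=int).reshape(-1, 2)


def collision_energy_gradient(spec: DoubleWellSpec, coords: np.ndarray):
    """One-sided quadratic steric penalty and its analytic gradient."""
    coords = np.asarray(coords, dtype=float).reshape(spec.n_atoms, 3)
    pairs = _colliding_pairs(spec, coords)
    grad = np.zeros_like(coords)
    if pairs.shape[0] == 0:
        return 0.0, grad
    dvec = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    d = np.linalg.norm(dvec, axis=1)
    if np.any(d == 0):
        raise ValueError("coincident non-bonded atoms in collision term")
    pen = d - spec.d_c  # negative for active pairs
    energy = float(0.5 * spec.k_coll * np.sum(pen**2))
    f = (spec.k_coll * pen / d)[:, None] * dvec
    np.add.at(grad, pairs[:, 1], f)
    np.add.at(grad, pairs[:, 0], -f)
    return energy, grad


def collision_hessian(spec: DoubleWellSpec, coords: np.ndarray) -> sp.csr_matrix:
    coords = np.asarray(coords, dtype=float).reshape(spec.n_atoms, 3)
    pairs = _colliding_pairs(spec, coords)
    n3 = 3 * spec.n_atoms
    if pairs.shape[0] == 0:
        return sp.csr_matrix((n3, n3))
    k = np.full(pairs.shape[0], spec.k_coll)
    d0 = np.full(pairs.shape[0], spec.d_c)
    return enm_core.spring_hessian(spec.n_atoms, pairs[:, 0], pairs[:, 1], d0, k, coords)


# ---------------------------------------------------------------------------
# Newton sweep
# ---------------------------------------------------------------------------


def _residual(spec: DoubleWellSpec, lam: float, coords: np.ndarray):
    e1, g1 = enm_energy_gradient(spec.model_begin, coords)
    e2, g2 = enm_energy_gradient(spec.model_end, coords)
    ec, gc = collision_energy_gradient(spec, coords)
    g = lam * g1 + (1.0 - lam) * g2 + gc
    e = lam * e1 + (1.0 - lam) * e2 + ec
    return e, g


def _resuperpose(spec: DoubleWellSpec, coords: np.ndarray) -> np.ndarray:
    # aligned atoms only: the frame must not be dragged by unaligned
    # residues, which relax freely in the end well
    m = spec.aligned_mask
    R, t, _ = kabsch(coords[m], spec.begin_coords[m])
    return coords @ R.T + t


def interpolated_minimize(
    spec: DoubleWellSpec,
    lam: float,
    start_coords: np.ndarray,
    settings: SolverSettings = SolverSettings(),
) -> np.ndarray:
    """Minimize the lambda-interpolated potential by damped Newton iteration.

    Returns coordinates satisfying the saddle-point equation
    ``|lam*gradE1 + (1-lam)*gradE2 + gradE_coll|_inf <= newton_tolerance``,
    re-superposed rigidly onto the begin conformation.
    """
    x = np.asarray(start_coords, dtype=float).reshape(spec.n_atoms, 3).copy()
    _, g = _residual(spec, lam, x)
    res = float(np.max(np.abs(g)))
    for _ in range(settings.max_newton_iterations):
        if res <= settings.newton_tolerance:
            return _resuperpose(spec, x)
        H = (
            lam * enm_hessian(spec.model_begin, x)
            + (1.0 - lam) * enm_hessian(spec.model_end, x)
            + collision_hessian(spec, x)
        ).tocsc()
        shift = settings.diagonal_shift_scale * max(float(H.diagonal().max()), 1.0)
        H = H + shift * sp.identity(H.shape[0], format="csc")
        try:
            step = spla.spsolve(H, -g.reshape(-1)).reshape(spec.n_atoms, 3)
        except RuntimeError:
            # singular factorization: larger logged shift
            log.warning("singular Newton system at lambda=%.4g; shift increased", lam)
            H = H + (1e6 * shift) * sp.identity(H.shape[0], format="csc")
            step = spla.spsolve(H, -g.reshape(-1)).reshape(spec.n_atoms, 3)
        # backtracking on the residual norm keeps the iteration in basin
        alpha = 1.0
        for _bt in range(30):
            xn = x + alpha * step
            _, gn = _residual(spec, lam, xn)
            rn = float(np.max(np.abs(gn)))
            if rn < res or rn <= settings.newton_tolerance:
                break
            alpha *= 0.5
        x, g, res = xn, gn, rn
    if res <= settings.newton_tolerance:
        return _resuperpose(spec, x)
    raise ConvergenceError(lam, res, settings.max_newton_iterations)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def solve_pathway(spec: DoubleWellSpec, settings: SolverSettings = SolverSettings()) -> Pathway:
    """Sweep lambda from 1 to 0 and return the sampled transition pathway.

    The sweep is warm-started (each solve begins from the previous solution),
    bisected adaptively where the path moves faster than twice the sampling
    increment, and subsampled so consecutive retained conformations are at
    least ``sampling_increment`` apart (begin and end always retained).
    Deterministic: no randomness anywhere.
    """
    base = settings.schedule()
    sols: list[tuple[float, np.ndarray]] = []
    x = spec.begin_coords.copy()

    def solve_at(lam: float, start: np.ndarray) -> np.ndarray:
        return interpolated_minimize(spec, lam, start, settings)

    def advance(lam_prev, x_prev, lam_next, depth: int):
        x_next = solve_at(lam_next, x_prev)
        if (
            depth < settings.max_bisection_depth
            and _rmsd(x_next, x_prev) > 2.0 * settings.sampling_increment
        ):
            mid = 0.5 * (lam_prev + lam_next)
            x_mid = advance(lam_prev, x_prev, mid, depth + 1)
            sols.append((mid, x_mid))
            x_next = advance(mid, x_mid, lam_next, depth + 1)
        return x_next

    sols.append((1.0, solve_at(1.0, x)))
    for a, b in zip(base[:-1], base[1:]):
        xb = advance(a, sols[-1][1], b, 0)
        sols.append((b, xb))

    lams = np.array([s[0] for s in sols])
    confs = np.array([s[1] for s in sols])

    keep = [0]
    for m in range(1, len(sols) - 1):
        if _rmsd(confs[m], confs[keep[-1]]) >= settings.sampling_increment:
            keep.append(m)
    if len(sols) > 1:
        keep.append(len(sols) - 1)
    return Pathway(confs[keep], lams[keep])


def pathway_energy_profile(spec: DoubleWellSpec, pathway: Pathway) -> pd.DataFrame:
    """Per-conformation energy diagnostics along a pathway.

    Along a well-behaved sweep ``E1`` is non-decreasing and ``E2``
    non-increasing as lambda falls; this is reported, not enforced.
    """
    rows = []
    for m in range(pathway.n_conformations):
        coords = pathway.conformations[m]
        e1, _ = enm_energy_gradient(spec.model_begin, coords)
        e2, _ = enm_energy_gradient(spec.model_end, coords)
        ec, _ = collision_energy_gradient(spec, coords)
        rows.append((m, pathway.lambdas[m], pathway.cumulative_length[m], e1, e2, ec))
    return pd.DataFrame(
        rows, columns=["conformation", "lambda", "cumulative_length", "E1", "E2", "E_coll"]
    )
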