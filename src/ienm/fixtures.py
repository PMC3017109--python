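"""Synthetic two-state assemblies with known motional order.

Three topologies stand in for real closed/open structure pairs so every
analysis runs without downloads:

* ``hinge-dimer`` — a static stalk chain plus an arm chain that rotates about
  a hinge; stalk residues barely move (crossover undefined), arm residues all
  move.
* ``two-phase-chain`` — two chains displaced rigidly; a constructed two-phase
  pathway (chain A moves first, then chain B) has closed-form crossover
  values, giving an exact truth for the motional-order machinery.
* ``c5-barrel`` — five helices arranged with exact five-fold symmetry around
  the z axis; the end state is a radial expansion, exercising symmetry
  preservation and pore profiling.

Backbones are idealized Cα helices (rise 1.5 Å, 100° twist, radius 2.3 Å):
the elastic network needs plausible neighbour distances, not chemistry.
All generators are deterministic for a fixed spec; `seed` only drives the
optional coordinate jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures_io import Pathway, Structure, identity_alignment

__all__ = ["FixtureSpec", "make_two_state", "two_phase_pathway", "helix_coords"]

_TOPOLOGIES = ("hinge-dimer", "two-phase-chain", "c5-barrel")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic two-state pair.

    ``phase_split`` is the fraction of the constructed two-phase pathway in
    which the early group completes its motion. ``late_scale`` scales the
    late group's displacement relative to the early group (1.0 keeps the
    closed-form crossovers at phase_split/2 and (1+phase_split)/2).
    """

    topology: str = "c5-barrel"
    n_residues_per_chain: int = 30
    n_chains: int = 5
    phase_split: float = 0.5
    hinge_angle_deg: float = 30.0
    displacement: float = 6.0
    late_scale: float = 1.0
    barrel_radius: float = 8.0
    expansion: float = 2.0
    helix_rise: float = 1.5
    helix_twist_deg: float = 100.0
    helix_radius: float = 2.3
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"topology must be one of {_TOPOLOGIES}")
        if self.n_residues_per_chain < 4:
            raise ValueError("need at least 4 residues per chain")
        if not 0 < self.phase_split < 1:
            raise ValueError("phase_split must lie in (0, 1)")
        if self.barrel_radius <= 0 or self.helix_radius <= 0:
            raise ValueError("geometric radii must be positive")


def helix_coords(n: int, rise: float = 1.5, twist_deg: float = 100.0, radius: float = 2.3) -> np.ndarray:
    """Idealized Cα helix along +z, first residue at angle 0."""
    ang = np.deg2rad(twist_deg) * np.arange(n)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * np.arange(n)])


def _chain(spec: FixtureSpec, chain_id: str, coords: np.ndarray, resnum_start: int = 1) -> Structure:
    n = coords.shape[0]
    return Structure(
        np.full(n, chain_id, dtype=object),
        np.arange(resnum_start, resnum_start + n),
        np.full(n, "ALA", dtype=object),
        coords,
    )


def _concat(chains: list[Structure], label: str) -> Structure:
    return Structure(
        np.concatenate([c.chain_ids for c in chains]),
        np.concatenate([c.resnums for c in chains]),
        np.concatenate([c.resnames for c in chains]),
        np.vstack([c.coords for c in chains]),
        label,
    )


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _jitter(coords: np.ndarray, spec: FixtureSpec) -> np.ndarray:
    if spec.jitter == 0:
        return coords
    rng = np.random.default_rng(spec.seed)
    return coords + spec.jitter * rng.standard_normal(coords.shape)


def make_two_state(spec: FixtureSpec, delete_from_end: int = 0):
    """Build a (begin, end, alignment, truth) tuple for the requested topology.

    `truth` is a dict describing the constructed ground-truth motional order
    (see each topology below). ``delete_from_end`` removes that many trailing
    residues of the first chain from the end structure, populating the
    alignment's unaligned sets.
    """
    n, rise, twist, hr = (
        spec.n_residues_per_chain,
        spec.helix_rise,
        spec.helix_twist_deg,
        spec.helix_radius,
    )
    base = helix_coords(n, rise, twist, hr)

    if spec.topology == "hinge-dimer":
        # stalk A along +z; arm B continues above, rotated about the hinge in
        # the end state -> stalk static, arm moving
        stalk = base
        arm0 = base + np.array([0.0, 0.0, rise * n])
        hinge = np.array([0.0, 0.0, rise * n])
        arm1 = (arm0 - hinge) @ _rot_y(spec.hinge_angle_deg).T + hinge
        begin = _concat([_chain(spec, "A", stalk), _chain(spec, "B", arm0)], "hinge-begin")
        end = _concat([_chain(spec, "A", stalk), _chain(spec, "B", arm1)], "hinge-end")
        truth = {"static_chain": "A", "moving_chain": "B"}

    elif spec.topology == "two-phase-chain":
        # two parallel rigid chains displacing in opposite x directions, so
        # the transition is not a global rigid motion
        off = np.array([spec.displacement, 0.0, 0.0])
        a0, b0 = base, base + np.array([0.0, 10.0, 0.0])
        a1 = a0 + off
        b1 = b0 - off * spec.late_scale
        begin = _concat([_chain(spec, "A", a0), _chain(spec, "B", b0)], "two-phase-begin")
        end = _concat([_chain(spec, "A", a1), _chain(spec, "B", b1)], "two-phase-end")
        s, r = spec.phase_split, spec.late_scale
        # constructed two-phase path: A moves fully during [0, s], B during
        # [s, 1]; with n_A = n_B the arc-length fractions give closed-form
        # crossovers f_A = (d_A/2) / (d_A + d_B), f_B = (d_A + d_B/2) / (...)
        f_a = 0.5 / (1.0 + r)
        f_b = (1.0 + 0.5 * r) / (1.0 + r)
        truth = {"early_chain": "A", "late_chain": "B", "f_cross_early": f_a, "f_cross_late": f_b}

    else:  # c5-barrel
        chains = []
        chains_end = []
        ids = [chr(ord("A") + k) for k in range(spec.n_chains)]
        for k, cid in enumerate(ids):
            R = _rot_z(360.0 * k / spec.n_chains)
            c0 = (base + np.array([spec.barrel_radius, 0.0, 0.0])) @ R.T
            c1 = (base + np.array([spec.barrel_radius + spec.expansion, 0.0, 0.0])) @ R.T
            chains.append(_chain(spec, cid, c0))
            chains_end.append(_chain(spec, cid, c1))
        begin = _concat(chains, "barrel-begin")
        end = _concat(chains_end, "barrel-end")
        truth = {"symmetry": spec.n_chains, "radial_expansion": spec.expansion}

    begin = begin.with_coords(_jitter(begin.coords, spec), begin.label)
    end = end.with_coords(_jitter(end.coords, spec), end.label)

    if delete_from_end:
        first = end.chains[0]
        keep = np.ones(end.n_atoms, dtype=bool)
        idx = np.flatnonzero(end.chain_ids == first)[-delete_from_end:]
        keep[idx] = False
        end = end.select(keep)
    amap = identity_alignment(begin, end)
    return begin, end, amap, truth


def two_phase_pathway(
    begin: Structure,
    end: Structure,
    early_chain: str = "A",
    phase_split: float = 0.5,
    n_steps: int = 41,
) -> Pathway:
    """Constructed (not solved) pathway where `early_chain` moves during the
    first `phase_split` fraction of steps and everything else afterwards."""
    early = begin.chain_ids == early_chain
    delta = end.coords - begin.coords
    ts = np.linspace(0.0, 1.0, n_steps)
    confs = np.empty((n_steps, begin.n_atoms, 3))
    for m, t in enumerate(ts):
        w_early = np.clip(t / phase_split, 0.0, 1.0)
        w_late = np.clip((t - phase_split) / (1.0 - phase_split), 0.0, 1.0)
        w = np.where(early, w_early, w_late)
        confs[m] = begin.coords + w[:, None] * delta
    return Pathway(confs, 1.0 - ts)
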