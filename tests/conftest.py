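import numpy as np
import pytest

from ienm import (
    FixtureSpec,
    SolverSettings,
    make_double_well,
    make_two_state,
    solve_pathway,
)

FAST_SETTINGS = SolverSettings(n_lambda=101)


@pytest.fixture(scope="session")
def barrel_pair():
    """Small C5 barrel two-state pair (begin, end, map, truth)."""
    return make_two_state(FixtureSpec(topology="c5-barrel", n_residues_per_chain=12))


@pytest.fixture(scope="session")
def hinge_pair():
    return make_two_state(FixtureSpec(topology="hinge-dimer", n_residues_per_chain=12))


@pytest.fixture(scope="session")
def two_phase_pair():
    return make_two_state(FixtureSpec(topology="two-phase-chain", n_residues_per_chain=12))


@pytest.fixture(scope="session")
def barrel_solution(barrel_pair):
    """Solved double-well spec + pathway for the barrel pair (shared)."""
    begin, end, amap, _ = barrel_pair
    spec = make_double_well(begin, end, amap)
    pathway = solve_pathway(spec, FAST_SETTINGS)
    return spec, pathway


@pytest.fixture(scope="session")
def hinge_solution(hinge_pair):
    begin, end, amap, _ = hinge_pair
    spec = make_double_well(begin, end, amap)
    pathway = solve_pathway(spec, FAST_SETTINGS)
    return spec, pathway


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random rotation from a QR decomposition."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
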