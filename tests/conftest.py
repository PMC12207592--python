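"""Shared fixtures: toy systems, reference ensembles and long biased runs.

The expensive session fixtures (a converged WT-MetaD run and the five-seed
protocol runs used by the acceptance checks) are built lazily, once per
session, and shared by every test that consumes them.
"""

import numpy as np
import pytest
from scipy.special import logsumexp

from cvrefine.biasing import FESProfile, WallSpec, WTMetaDState
from cvrefine.toys import make_two_state_system, run_biased_langevin, sample_iid
from cvrefine.workflow import ProtocolConfig, initial_coordinate, run_protocol


# ---------------------------------------------------------------------------
# light fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def system6():
    """The standard mirror-symmetric 6-particle system (~6 kT barrier)."""
    return make_two_state_system(N=6, seed=1, barrier_kT=6.0,
                                 mirror_symmetric=True)


@pytest.fixture(scope="session")
def iid_sample(system6):
    """1500 exact i.i.d. frames from the mixture with generator labels."""
    return sample_iid(system6, 1500, seed=7)


@pytest.fixture(scope="session")
def state_frames(iid_sample):
    """(A, B) coordinate arrays split by generator label."""
    X = iid_sample.frames.coords
    return X[iid_sample.labels == 0], X[iid_sample.labels == 1]


@pytest.fixture(scope="session")
def initial_coord(state_frames):
    A, B = state_frames
    return initial_coordinate(A, B)


# ---------------------------------------------------------------------------
# oracle helpers
# ---------------------------------------------------------------------------

def linearized_cv_fes(system, coordinate, grid):
    """Closed-form FES of the linearized coordinate l_lin = v_c.x - v.mu_ref.

    The on-the-fly coordinate includes a configuration-dependent rotation;
    its linearization (rotation frozen at the identity) is a linear
    functional of x, whose Boltzmann marginal is an exact Gaussian mixture.
    """
    v = coordinate.coefficients
    vc = v - v.mean(axis=0)
    c0 = float(np.sum(v * coordinate.ref_mean))
    logps = []
    for j in range(system.n_states):
        mj = float(np.sum(vc * system.means[j])) - c0
        var = sum(float(vc[:, a] @ system.covariances_N[j] @ vc[:, a])
                  for a in range(3))
        logps.append(np.log(system.mixture_weights[j])
                     - 0.5 * np.log(2.0 * np.pi * var)
                     - 0.5 * (grid - mj) ** 2 / var)
    F = -system.kT * logsumexp(np.stack(logps), axis=0)
    return FESProfile(grid=np.asarray(grid, dtype=float), free_energy=F,
                      kT=system.kT)


def minima_gap(fes):
    """|F(min_A) - F(min_B)| with minima taken over each half of the grid."""
    g = fes.grid
    left = np.nanmin(fes.free_energy[g < 0])
    right = np.nanmin(fes.free_energy[g >= 0])
    return float(abs(left - right))


# ---------------------------------------------------------------------------
# heavy session fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def wtmetad_run(system6, initial_coord):
    """A 400k-step WT-MetaD run biased along the initial coordinate.

    Returns a dict with the trajectory, the final bias state, the walls,
    the CV grid and the closed-form linearized-CV reference profile.
    """
    lo, hi = initial_coord.value_range
    span = hi - lo
    state = WTMetaDState(h0=0.7, sigma=0.05 * span, gamma=8.0,
                         kT=system6.kT, pace=500)
    walls = WallSpec(lower=lo - 10.0, upper=hi + 10.0, kappa=125.0)
    traj, state = run_biased_langevin(system6, coordinate=initial_coord,
                                      bias_state=state, walls=walls,
                                      steps=400_000, seed=11, save_every=10)
    grid = np.linspace(lo - 0.5, hi + 0.5, 81)
    return {
        "trajectory": traj,
        "state": state,
        "walls": walls,
        "grid": grid,
        "coordinate": initial_coord,
        "exact": linearized_cv_fes(system6, initial_coord, grid),
    }


ACCEPTANCE_CONFIG = ProtocolConfig(scheme="wtmetad", gamma=8.0, pace=500,
                                   max_iterations=2, min_round_trips=10,
                                   max_steps=500_000)


@pytest.fixture(scope="session")
def acceptance_runs(system6):
    """Five-seed protocol runs used by the symmetry and transit checks."""
    return [run_protocol(system6, ACCEPTANCE_CONFIG, seed=seed)
            for seed in range(1, 6)]
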