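"""Synthetic two-state Gaussian-mixture systems and overdamped Langevin dynamics.

The generator builds a particle system whose Boltzmann density is exactly a
two-component Gaussian mixture in Cartesian coordinates,

    U(x) = -kT ln sum_j pi_j N(x | mu_j, Sigma_Nj (x) I_3),

so every downstream stage — clustering, discriminant analysis, biasing and
free-energy estimation — has closed-form oracles.  In the mirror-symmetric
configuration the second mean is the reflection of the first (a chiral
helix-like arrangement reflected through the xy plane) with an identical
covariance and equal mixture weight, so the two states are exact mirror
images of equal statistical likelihood — the analog of left- and
right-handed helices of an achiral peptide — and the free-energy profile
along the inter-state axis is exactly symmetric.

Dynamics use the first-order (overdamped) Langevin update

    x <- x - (dt/friction) grad(U + V(l(x))) + sqrt(2 kT dt / friction) eta,

whose stationary density at temperature kT is the mixture itself; the bias
force propagates through the collective variable's analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from cvrefine.biasing import OPESState, WallSpec, WTMetaDState, FESProfile
from cvrefine.errors import IntegrationError, InvalidInputError
from cvrefine.geometry import FrameEnsemble, random_rotation
from cvrefine.lda import LDACoordinate, evaluate_ld


# ---------------------------------------------------------------------------
# system definition
# ---------------------------------------------------------------------------

@dataclass
class ToyTwoStateSystem:
    """A Gaussian-mixture particle system with Boltzmann density = shape GMM.

    ``means`` is (2, N, 3) in angstroms, ``covariances_N`` is (2, N, N) in
    square angstroms (full covariance of state j is the Kronecker product
    with the 3x3 identity), ``mixture_weights`` the state populations.
    ``kT`` is in kcal/mol; ``friction`` and ``dt`` parameterize the
    overdamped integrator.
    """

    mixture_weights: np.ndarray
    means: np.ndarray
    covariances_N: np.ndarray
    kT: float = 1.0
    friction: float = 1.0
    dt: float = 0.01
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.mixture_weights = np.asarray(self.mixture_weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances_N = np.asarray(self.covariances_N, dtype=float)
        if abs(self.mixture_weights.sum() - 1.0) > 1e-10:
            raise InvalidInputError("mixture weights must sum to 1")
        for j, cov in enumerate(self.covariances_N):
            evals = np.linalg.eigvalsh(cov)
            if evals.min() <= 0:
                raise InvalidInputError(f"covariance {j} not positive definite")

    @property
    def particle_count(self) -> int:
        return self.means.shape[1]

    @property
    def n_states(self) -> int:
        return len(self.mixture_weights)

    def _params(self):
        if "prec" not in self._cache:
            prec, logconst, chol = [], [], []
            N = self.particle_count
            for cov in self.covariances_N:
                P = np.linalg.inv(cov)
                sign, ld = np.linalg.slogdet(cov)
                prec.append(P)
                logconst.append(-0.5 * 3 * N * np.log(2 * np.pi) - 1.5 * ld)
                chol.append(np.linalg.cholesky(cov))
            self._cache["prec"] = np.asarray(prec)
            self._cache["logconst"] = np.asarray(logconst)
            self._cache["chol"] = np.asarray(chol)
        return (self._cache["prec"], self._cache["logconst"],
                self._cache["chol"])

    def _state_logps(self, x):
        prec, logconst, _ = self._params()
        d = x[None] - self.means                     # (K, N, 3)
        Pd = prec @ d                                # batched matmul
        quad = np.einsum("kia,kia->k", d, Pd)
        return np.log(self.mixture_weights) + logconst - 0.5 * quad

    def potential(self, x) -> float:
        """U(x) = -kT ln(mixture density), kcal/mol."""
        x = np.asarray(x, dtype=float)
        return -self.kT * float(logsumexp(self._state_logps(x)))

    def potential_and_grad(self, x):
        """U(x) and its analytic (N, 3) gradient in one pass."""
        x = np.asarray(x, dtype=float)
        prec, logconst, _ = self._params()
        d = x[None] - self.means
        Pd = prec @ d
        quad = np.einsum("kia,kia->k", d, Pd)
        logp = np.log(self.mixture_weights) + logconst - 0.5 * quad
        m = logp.max()
        g = np.exp(logp - m)
        Z = g.sum()
        U = -self.kT * (m + np.log(Z))
        grad = self.kT * np.tensordot(g / Z, Pd, axes=(0, 0))
        return U, grad

    def grad_potential(self, x) -> np.ndarray:
        """Analytic (N, 3) gradient of the mixture potential."""
        return self.potential_and_grad(x)[1]

    def inter_state_axis(self) -> np.ndarray:
        """Unit 3N vector along mu_2 - mu_1 (the known reaction direction)."""
        d = (self.means[1] - self.means[0]).ravel()
        return d / np.linalg.norm(d)

    def reference_cv(self, frames) -> np.ndarray:
        """Projection of frames on the inter-state axis, zero at the midpoint."""
        X = np.asarray(frames.coords if isinstance(frames, FrameEnsemble)
                       else frames, dtype=float)
        if X.ndim == 2:
            X = X[None]
        mid = 0.5 * (self.means[0] + self.means[1])
        d = self.inter_state_axis()
        return (X - mid).reshape(X.shape[0], -1) @ d

    def state_cv_centers(self) -> tuple:
        """Reference-CV values of the two state centers (-m, +m)."""
        s = self.reference_cv(self.means)
        return float(s[0]), float(s[1])


@dataclass
class Trajectory:
    """Saved frames with per-frame CV value, bias energy and state labels."""

    frames: FrameEnsemble
    cv_values: np.ndarray = None
    bias_at_frame: np.ndarray = None
    labels: np.ndarray = None

    def __post_init__(self):
        M = self.frames.frame_count
        for name in ("cv_values", "bias_at_frame", "labels"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != M:
                raise InvalidInputError(f"{name} length differs from frames")


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _chiral_template(N: int, rng: np.random.Generator):
    """A chiral arrangement: ring in xy plus an out-of-plane puckering mode.

    Returns the centered xy part (mirror-neutral) and the unit-amplitude z
    displacement pattern (the chirality carrier, flipped by reflection).
    The z pattern is orthogonalized against rigid tilts (the constant and
    the in-plane coordinate columns): a z displacement proportional to an
    in-plane coordinate is just a small rotation of the whole structure,
    which optimal superposition would absorb, collapsing the two mirror
    states onto each other.
    """
    k = np.arange(N)
    theta = 2.0 * np.pi * k / N
    xy = np.zeros((N, 3))
    xy[:, 0] = 2.0 * np.cos(theta)
    xy[:, 1] = 2.0 * np.sin(theta)
    # small seeded in-plane perturbation keeps the structure generic while
    # remaining exactly mirror-neutral (z untouched)
    xy[:, :2] += 0.3 * rng.standard_normal((N, 2))
    xy -= xy.mean(axis=0)
    z = np.cos(2.0 * theta) + 0.5 * np.sin(2.0 * theta) \
        + 0.1 * rng.standard_normal(N)
    tilt_basis = np.column_stack([np.ones(N), xy[:, 0], xy[:, 1]])
    q, _ = np.linalg.qr(tilt_basis)
    z = z - q @ (q.T @ z)
    norm = np.linalg.norm(z)
    if norm < 1e-8:  # pragma: no cover - pathological perturbation draw
        z = np.cos(2.0 * theta)
        z -= q @ (q.T @ z)
        norm = np.linalg.norm(z)
    return xy, z / norm


def _aniso_covariance(N: int, spread: float, anisotropy: float,
                      rng: np.random.Generator) -> np.ndarray:
    """SPD particle covariance with eigenvalue spread set by ``anisotropy``."""
    evals = spread ** 2 * np.exp(
        rng.uniform(-np.log(anisotropy), np.log(anisotropy), size=N))
    Q, _ = np.linalg.qr(rng.standard_normal((N, N)))
    return Q @ np.diag(evals) @ Q.T


def _marginal_barrier(m: float, sigma: float, kT: float) -> float:
    """Barrier of the symmetric 1D two-Gaussian marginal with means +-m."""
    def f(s):
        return -kT * logsumexp([-0.5 * ((s - m) / sigma) ** 2,
                                -0.5 * ((s + m) / sigma) ** 2])
    return f(0.0) - f(m)


def make_two_state_system(separation: float = None, spread: float = 0.5,
                          anisotropy: float = 2.0, N: int = 6,
                          kT: float = 1.0, seed: int = 0,
                          mirror_symmetric: bool = True,
                          barrier_kT: float = 6.0,
                          friction: float = 1.0,
                          dt: float = 0.01) -> ToyTwoStateSystem:
    """Build a two-state Gaussian-mixture particle system.

    With ``mirror_symmetric`` (default) the second state is the exact
    reflection of the first through the xy plane with identical covariance
    and equal mixture weight, so the inter-state free-energy profile is
    exactly symmetric.  ``separation`` is the Euclidean distance between
    the two mean structures in angstroms; when omitted it is calibrated so
    the free-energy barrier along the inter-state axis equals
    ``barrier_kT`` (in units of kT), using the exact one-dimensional
    Gaussian-mixture marginal.
    """
    if N < 3:
        raise InvalidInputError("need at least 3 particles")
    if spread <= 0 or anisotropy < 1:
        raise InvalidInputError("spread must be > 0 and anisotropy >= 1")
    rng = np.random.default_rng(seed)
    xy, z_unit = _chiral_template(N, rng)
    cov = _aniso_covariance(N, spread, anisotropy, rng)

    # the inter-state axis is purely along the z pattern: sigma along it
    sigma_axis = float(np.sqrt(z_unit @ cov @ z_unit))
    if separation is None:
        if barrier_kT is None or barrier_kT <= 0:
            raise InvalidInputError("need separation or positive barrier_kT")
        target = barrier_kT * kT
        lo, hi = 1e-3 * sigma_axis, 100.0 * sigma_axis
        m = brentq(lambda mm: _marginal_barrier(mm, sigma_axis, kT) - target,
                   lo, hi)
        separation = 2.0 * m
    if separation <= 0:
        raise InvalidInputError("separation must be positive")

    amp = separation / 2.0
    mu1 = xy.copy()
    mu1[:, 2] = amp * z_unit
    if mirror_symmetric:
        mirror = np.diag([1.0, 1.0, -1.0])
        mu2 = mu1 @ mirror.T
        cov2 = cov
        weights = np.array([0.5, 0.5])
    else:
        mu2 = mu1.copy()
        mu2[:, 2] = -amp * z_unit
        mu2[:, :2] += 0.2 * spread * rng.standard_normal((N, 2))
        mu2 -= mu2.mean(axis=0)
        cov2 = _aniso_covariance(N, spread, anisotropy, rng)
        weights = np.array([0.5, 0.5])
    return ToyTwoStateSystem(mixture_weights=weights,
                             means=np.stack([mu1, mu2]),
                             covariances_N=np.stack([cov, cov2]),
                             kT=kT, friction=friction, dt=dt)


def mirror_frame(frame: np.ndarray) -> np.ndarray:
    """Apply the system's mirror operation (reflection through the xy plane)."""
    return np.asarray(frame, dtype=float) @ np.diag([1.0, 1.0, -1.0])


def barrier_height(system: ToyTwoStateSystem, n_points: int = 201) -> float:
    """Potential barrier along the straight line between the two means."""
    t = np.linspace(0.0, 1.0, n_points)
    line = [(1 - ti) * system.means[0] + ti * system.means[1] for ti in t]
    U = np.array([system.potential(x) for x in line])
    return float(U.max() - U.min())


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_iid(system: ToyTwoStateSystem, M: int, seed: int = 0,
               rigid_jitter: bool = False) -> Trajectory:
    """Exact i.i.d. samples from the mixture Boltzmann density.

    Draws a component per frame (probabilities pi_j) and then a Gaussian
    configuration with the component's Kronecker covariance; with
    ``rigid_jitter`` each frame is additionally scrambled by a random
    rigid-body transform (uniform rotation, normal translation).
    """
    if M < 1:
        raise InvalidInputError("need at least one sample")
    rng = np.random.default_rng(seed)
    _, _, chol = system._params()
    N = system.particle_count
    labels = rng.choice(system.n_states, size=M, p=system.mixture_weights)
    X = np.empty((M, N, 3))
    for i, j in enumerate(labels):
        X[i] = system.means[j] + chol[j] @ rng.standard_normal((N, 3))
    # the reference CV needs two states to define an inter-state axis
    cv = system.reference_cv(X) if system.n_states >= 2 else np.full(M, np.nan)
    if rigid_jitter:
        for i in range(M):
            X[i] = X[i] @ random_rotation(rng).T + rng.normal(scale=5.0, size=3)
    return Trajectory(frames=FrameEnsemble(X), cv_values=cv,
                      bias_at_frame=np.zeros(M), labels=labels)


def analytic_fes_linear(system: ToyTwoStateSystem, direction, grid,
                        origin=None) -> FESProfile:
    """Exact free energy along a linear coordinate s = d . (x - origin).

    Linear marginals of Gaussians are Gaussian, so
    F(s) = -kT ln sum_j pi_j N(s | d.mu_j, d^T Sigma_j d) in closed form,
    min-shifted on the grid.  ``direction`` is a unit 3N vector (or (N, 3)
    array); ``origin`` defaults to zero.
    """
    d = np.asarray(direction, dtype=float).ravel()
    if abs(np.linalg.norm(d) - 1.0) > 1e-8:
        raise InvalidInputError("direction must have unit norm")
    grid = np.asarray(grid, dtype=float)
    D = d.reshape(-1, 3)
    origin = np.zeros(3 * D.shape[0]) if origin is None \
        else np.asarray(origin, dtype=float).ravel()
    logps = []
    for j in range(system.n_states):
        mj = d @ (system.means[j].ravel() - origin)
        var = float(np.einsum("nm,na,ma->", system.covariances_N[j], D, D))
        logps.append(np.log(system.mixture_weights[j])
                     - 0.5 * np.log(2 * np.pi * var)
                     - 0.5 * (grid - mj) ** 2 / var)
    F = -system.kT * logsumexp(np.stack(logps), axis=0)
    return FESProfile(grid=grid, free_energy=F, kT=system.kT)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def run_biased_langevin(system: ToyTwoStateSystem,
                        coordinate: LDACoordinate = None,
                        bias_state=None, walls: WallSpec = None,
                        steps: int = 10000, seed: int = 0,
                        x0: np.ndarray = None, save_every: int = 10,
                        sanity_bound: float = 1.0e3):
    """Overdamped Langevin trajectory, optionally biased along a CV.

    ``bias_state`` is a live :class:`WTMetaDState` or :class:`OPESState`
    (mutated in place: one deposit every ``state.pace`` integration steps);
    ``coordinate`` supplies the biased CV and its analytic gradient.  Frames
    are saved every ``save_every`` steps together with the CV value and the
    bias energy at the save time.  Returns ``(Trajectory, bias_state)``.

    Raises
    ------
    IntegrationError
        If any coordinate exceeds ``sanity_bound`` (numerical blow-up).
    InvalidInputError
        If the time step is too large for the stiffest curvature
        (dt * max curvature / friction must stay below 0.5).
    """
    prec, _, _ = system._params()
    max_curv = system.kT * max(np.linalg.eigvalsh(P).max() for P in prec)
    if system.dt * max_curv / system.friction >= 0.5:
        raise InvalidInputError(
            f"unstable time step: dt*curvature/friction = "
            f"{system.dt * max_curv / system.friction:.3f} >= 0.5")
    if (bias_state is not None) and coordinate is None:
        raise InvalidInputError("biasing requires a coordinate")

    rng = np.random.default_rng(seed)
    x = np.array(system.means[0] if x0 is None else x0, dtype=float)
    mob = system.dt / system.friction
    noise_scale = np.sqrt(2.0 * system.kT * system.dt / system.friction)
    pace = getattr(bias_state, "pace", 0)

    frames, cvs, biases = [], [], []
    for step in range(steps):
        _, force_grad = system.potential_and_grad(x)
        V = 0.0
        if coordinate is not None:
            l, gl = evaluate_ld(x, coordinate, return_grad=True)
            if bias_state is not None:
                Vb, dVb = bias_state.potential(np.asarray(l))
                V = float(Vb)
                dV = float(dVb)
            else:
                dV = 0.0
            if walls is not None:
                Vw, dVw = walls.potential(l)
                V += float(Vw)
                dV += float(dVw)
            force_grad = force_grad + dV * gl
            if bias_state is not None and pace and (step + 1) % pace == 0:
                bias_state.deposit(l)
        # save before updating so frame, CV and bias describe the same
        # configuration (reweighting pairs the CV with the saved frame)
        if (step + 1) % save_every == 0:
            frames.append(x.copy())
            cvs.append(l if coordinate is not None else np.nan)
            biases.append(V)
        x = x - mob * force_grad + noise_scale * rng.standard_normal(x.shape)
        if np.abs(x).max() > sanity_bound:
            raise IntegrationError("trajectory blew up", step=step)
    traj = Trajectory(frames=FrameEnsemble(np.asarray(frames)),
                      cv_values=np.asarray(cvs),
                      bias_at_frame=np.asarray(biases))
    return traj, bias_state
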