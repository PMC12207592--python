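"""Frame-weighted linear discriminant analysis on aligned positions.

Given frames aligned into a common reference frame and class labels, the
weighted scatter matrices over the flattened 3N coordinates are

    S_W = sum_j sum_{i in N_j} w_i (x_i - mu_j)(x_i - mu_j)^T
    S_B = sum_j W_j (mu_j - mu)(mu_j - mu)^T

with weighted class means mu_j, weighted global mean mu and class totals
W_j = sum_{i in N_j} w_i.  The discriminant directions maximize
Tr[(G^T S_W G)^{-1} G^T S_B G]; positional scatter matrices are always
singular (translation/rotation null space), so the solver whitens S_W
through its eigendecomposition and solves in the subspace above a relative
spectral cutoff instead of inverting.

The resulting coordinate is evaluated on the fly as

    l(x) = v . (R(t) (x(t) - xi(t)) - mu_ref)

where xi(t) is the geometric-mean shift and R(t) the rotation minimizing
the Mahalanobis distance to the stored alignment reference.  l is invariant
under rigid-body transforms of x, and its analytic derivative (including
the rotation's dependence on x, via the stationarity of the Procrustes
objective) is available for biased dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cvrefine.errors import InvalidInputError, NoDiscriminantError
from cvrefine.geometry import (_procrustes_rotation, _weight_vector,
                               regularized_precision)

#: relative spectral floor applied to the within-class spectrum
SPECTRAL_FLOOR = 1.0e-10


@dataclass
class ScatterPair:
    """Weighted within- and between-class scatter matrices (3N x 3N)."""

    S_W: np.ndarray
    S_B: np.ndarray
    class_weights: np.ndarray
    class_means: np.ndarray = None     # (K, 3N)
    global_mean: np.ndarray = None     # (3N,)

    def __post_init__(self):
        self.S_W = np.asarray(self.S_W, dtype=float)
        self.S_B = np.asarray(self.S_B, dtype=float)
        for name, S in (("S_W", self.S_W), ("S_B", self.S_B)):
            if not np.allclose(S, S.T, atol=1e-10):
                raise InvalidInputError(f"{name} must be symmetric")


@dataclass
class LDACoordinate:
    """A linear positional reaction coordinate with its alignment reference.

    ``coefficients`` is the unit-norm (N, 3) vector v; ``ref_mean`` and
    ``ref_covariance_N`` define the rigid alignment applied before the dot
    product; ``value_range`` records the (min, max) of l on training data.
    """

    coefficients: np.ndarray
    ref_mean: np.ndarray
    ref_covariance_N: np.ndarray
    value_range: tuple = None
    _precision: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.ref_mean = np.asarray(self.ref_mean, dtype=float)
        self.ref_covariance_N = np.asarray(self.ref_covariance_N, dtype=float)
        if self.coefficients.shape != self.ref_mean.shape:
            raise InvalidInputError("coefficients and ref_mean shapes differ")
        norm = np.linalg.norm(self.coefficients)
        if abs(norm - 1.0) > 1e-10:
            raise InvalidInputError("coefficient vector must have unit norm")
        if np.abs(self.ref_mean.mean(axis=0)).max() > 1e-6:
            raise InvalidInputError("ref_mean must be centered")

    @property
    def precision(self) -> np.ndarray:
        if self._precision is None:
            self._precision = regularized_precision(self.ref_covariance_N)
        return self._precision

    @property
    def _precision_mean(self) -> np.ndarray:
        """Cached precision @ ref_mean, the hot product of on-the-fly evaluation."""
        if not hasattr(self, "_pm") or self._pm is None:
            self._pm = self.precision @ self.ref_mean
        return self._pm


# ---------------------------------------------------------------------------
# scatter matrices and solver
# ---------------------------------------------------------------------------

def weighted_scatter_matrices(aligned_frames, labels, weights=None,
                              equal_state_weights: bool = False) -> ScatterPair:
    """Weighted within- and between-class scatter of aligned frames.

    ``aligned_frames`` is (M, N, 3) or (M, 3N); ``labels`` are integer class
    ids.  With ``equal_state_weights`` each class's weights are renormalized
    to an equal share (total 1/K per class) before the sums, enforcing equal
    contributions from the states regardless of how much sampling each
    received.
    """
    X = np.asarray(aligned_frames, dtype=float)
    if X.ndim == 3:
        X = X.reshape(X.shape[0], -1)
    labels = np.asarray(labels)
    M, D = X.shape
    w = _weight_vector(weights, M).copy()
    classes = np.unique(labels)
    K = len(classes)
    if equal_state_weights:
        for c in classes:
            mask = labels == c
            total = w[mask].sum()
            if total <= 0:
                raise InvalidInputError(f"class {c} has zero total weight")
            w[mask] *= (1.0 / K) / total
    S_W = np.zeros((D, D))
    class_means = np.zeros((K, D))
    W_j = np.zeros(K)
    for k, c in enumerate(classes):
        mask = labels == c
        if not np.any(mask):
            raise InvalidInputError(f"class {c} is empty")
        wk = w[mask]
        W_j[k] = wk.sum()
        if W_j[k] <= 0:
            raise InvalidInputError(f"class {c} has zero total weight")
        mu_k = (wk[:, None] * X[mask]).sum(axis=0) / W_j[k]
        class_means[k] = mu_k
        dev = X[mask] - mu_k
        S_W += (wk[:, None] * dev).T @ dev
    mu = (W_j[:, None] * class_means).sum(axis=0) / W_j.sum()
    dev_b = class_means - mu
    S_B = (W_j[:, None] * dev_b).T @ dev_b
    S_W = 0.5 * (S_W + S_W.T)
    S_B = 0.5 * (S_B + S_B.T)
    return ScatterPair(S_W=S_W, S_B=S_B, class_weights=W_j,
                       class_means=class_means, global_mean=mu)


def wlda_solve(scatter: ScatterPair, n_components: int = 1) -> np.ndarray:
    """Discriminant directions maximizing the weighted Fisher criterion.

    Whitens S_W through its eigendecomposition, discarding directions whose
    eigenvalue falls below a relative spectral cutoff (the rigid-body gauge
    and rank-deficiency null space of positional data, whose eigenvectors
    are numerically arbitrary), then diagonalizes the whitened S_B in the
    retained subspace.  Returns an (n_components, 3N) array of unit-norm
    directions ordered by decreasing discriminability; each direction's
    sign is fixed so its largest-magnitude coefficient is positive.
    """
    S_W, S_B = scatter.S_W, scatter.S_B
    if np.abs(S_B).max() <= 1e-300 or np.allclose(S_B, 0.0, atol=1e-14):
        raise NoDiscriminantError("between-class scatter is zero")
    evals, evecs = np.linalg.eigh(S_W)
    cutoff = SPECTRAL_FLOOR * max(evals.max(), 1e-300)
    keep = evals > cutoff
    if not np.any(keep):
        raise NoDiscriminantError("within-class scatter is numerically zero")
    whiten = evecs[:, keep] / np.sqrt(evals[keep])
    B = whiten.T @ S_B @ whiten
    B = 0.5 * (B + B.T)
    bvals, bvecs = np.linalg.eigh(B)
    order = np.argsort(bvals)[::-1][:n_components]
    V = whiten @ bvecs[:, order]
    V /= np.linalg.norm(V, axis=0)
    for k in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, k]))
        if V[i, k] < 0:
            V[:, k] = -V[:, k]
    return V.T


def fisher_ratio(direction: np.ndarray, scatter: ScatterPair) -> float:
    """v^T S_B v / v^T S_W v for a flattened direction."""
    v = np.asarray(direction, dtype=float).ravel()
    return float(v @ scatter.S_B @ v) / float(v @ scatter.S_W @ v)


# ---------------------------------------------------------------------------
# on-the-fly evaluation
# ---------------------------------------------------------------------------

def _hat(w):
    return np.array([[0.0, -w[2], w[1]],
                     [w[2], 0.0, -w[0]],
                     [-w[1], w[0], 0.0]])


def evaluate_ld(frame: np.ndarray, coordinate: LDACoordinate,
                return_grad: bool = False):
    """Evaluate l(x) = v . (R (x - xi) - mu_ref), optionally with dl/dx.

    The frame is shifted by its geometric mean relative to the (centered)
    reference and rotated by the Mahalanobis-optimal rotation before the dot
    product, making l invariant under rigid transforms of the input.  With
    ``return_grad`` the (N, 3) derivative is returned as well; the rotation's
    response to the coordinates is included analytically by implicit
    differentiation of the Procrustes stationarity condition (skew(R A) = 0
    with A = x_c^T P mu).
    """
    x = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("frame has non-finite coordinates")
    v = coordinate.coefficients
    mu = coordinate.ref_mean
    Pmu = coordinate._precision_mean
    xc = x - x.mean(axis=0)
    A = xc.T @ Pmu
    R = _procrustes_rotation(A)
    y = xc @ R.T
    value = float(np.sum(v * (y - mu)))
    if not return_grad:
        return value
    # translation/rotation-aware gradient (verified against finite differences)
    T = R @ A                                   # symmetric at the optimum
    C = v.T @ y
    a = np.array([C[1, 2] - C[2, 1], C[2, 0] - C[0, 2], C[0, 1] - C[1, 0]])
    Mmat = np.trace(T) * np.eye(3) - T
    b = 2.0 * np.linalg.solve(Mmat, a)
    G = v @ R + 0.5 * (Pmu @ (_hat(b).T @ R))
    G = G - G.mean(axis=0)                      # centering projector
    return value, G


def evaluate_ld_batch(frames, coordinate: LDACoordinate) -> np.ndarray:
    """Vectorized l(x) over an (M, N, 3) stack of frames."""
    X = np.asarray(frames, dtype=float)
    if X.ndim == 2:
        X = X[None]
    mu = coordinate.ref_mean
    v = coordinate.coefficients
    Xc = X - X.mean(axis=1, keepdims=True)
    A = np.einsum("mia,ib->mab", Xc, coordinate._precision_mean)
    from cvrefine.geometry import _procrustes_rotation_batch
    R = _procrustes_rotation_batch(A)
    Y = np.einsum("mia,mba->mib", Xc, R)
    return np.einsum("ia,mia->m", v, Y - mu)
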