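"""Translation removal and optimal rigid-body superposition.

A particle configuration is an N x 3 matrix of Cartesian coordinates (in
angstroms), and two configurations are physically equivalent when they
differ only by a rigid-body transform: the feature clustered by the rest of
the package is the orbit of a configuration under translation and proper
rotation.  This module removes translations by centering on the geometric
mean and solves for optimal rotations under two metrics:

* uniform (Kabsch): minimize the plain summed squared deviation;
* Kronecker Mahalanobis: minimize ``tr[(xR^T - mu)^T Sigma_N^{-1}
  (xR^T - mu)]`` where ``Sigma_N`` is an N x N particle covariance and the
  full 3N covariance is ``Sigma_N (x) I_3``.

Because the Kronecker structure weights particles but not Cartesian axes,
both problems are weighted orthogonal Procrustes problems, linear in the
rotation, and are solved exactly by an SVD with a determinant correction
that excludes reflections (the smallest singular direction is flipped when
needed so that det R = +1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cvrefine.errors import ConvergenceError, InvalidInputError

#: Tikhonov regularization added to Sigma_N before inversion (A^2).  The
#: particle covariance of centered configurations is always rank deficient
#: (row sums vanish), so a small diagonal shift is required.
COVAR_REGULARIZATION = 1.0e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FrameEnsemble:
    """A stack of particle configurations.

    Parameters
    ----------
    coords
        Array of shape (M, N, 3) in angstroms; M frames of N particles.
    """

    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InvalidInputError(
                f"coords must have shape (M, N, 3), got {self.coords.shape}")
        if self.coords.shape[1] < 3:
            raise InvalidInputError("need at least 3 particles (N >= 3)")
        if self.coords.shape[0] < 1:
            raise InvalidInputError("need at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidInputError("coordinates must be finite")

    @property
    def frame_count(self) -> int:
        return self.coords.shape[0]

    @property
    def particle_count(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.frame_count

    def __getitem__(self, idx) -> np.ndarray:
        return self.coords[idx]


@dataclass
class RigidTransform:
    """A rigid-body transform ``x -> (x - translation) @ rotation.T``.

    ``rotation`` is special orthogonal; ``translation`` is the geometric-mean
    shift removed before rotating.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise InvalidInputError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise InvalidInputError("rotation must be proper (det = +1)")

    def apply(self, frame: np.ndarray) -> np.ndarray:
        """Apply the transform to an (N, 3) frame."""
        return (np.asarray(frame, dtype=float) - self.translation) @ self.rotation.T


@dataclass
class AlignmentResult:
    """Frames aligned to a common reference, with per-frame bookkeeping."""

    aligned: FrameEnsemble
    transforms: list = field(default_factory=list)
    mahalanobis: np.ndarray = None


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def remove_translation(frames):
    """Center every frame so its geometric mean sits at the origin.

    Returns ``(centered, translations)`` where ``translations`` has shape
    (M, 3) and records the removed per-frame geometric means.
    """
    ens = frames if isinstance(frames, FrameEnsemble) else FrameEnsemble(frames)
    translations = ens.coords.mean(axis=1)
    centered = ens.coords - translations[:, None, :]
    return FrameEnsemble(centered), translations


def _procrustes_rotation(A: np.ndarray) -> np.ndarray:
    """Rotation maximizing tr(R @ A) over SO(3), by SVD with det correction."""
    U, s, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0.0:  # pragma: no cover - fully degenerate input
        d = 1.0
    return Vt.T @ np.diag([1.0, 1.0, d]) @ U.T


def _procrustes_rotation_batch(A: np.ndarray) -> np.ndarray:
    """Batched version of :func:`_procrustes_rotation` for (M, 3, 3) input."""
    U, s, Vt = np.linalg.svd(A)
    V = np.swapaxes(Vt, -1, -2)
    Ut = np.swapaxes(U, -1, -2)
    d = np.sign(np.linalg.det(V @ Ut))
    d[d == 0.0] = 1.0
    D = np.zeros_like(A)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    return V @ D @ Ut


def kabsch_rotation(frame: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Optimal proper rotation of ``frame`` onto ``reference`` (uniform metric).

    Both inputs must be centered (N, 3) arrays.  The returned rotation
    minimizes the summed squared deviation over SO(3); reflections are
    excluded by determinant correction.  Near-degenerate (collinear)
    configurations trigger a warning and a best-effort rotation.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    _check_centered_pair(frame, reference)
    A = frame.T @ reference
    s = np.linalg.svd(A, compute_uv=False)
    if s[1] < 1e-10 * max(s[0], 1.0):
        warnings.warn("near-collinear configuration: rotation is ill-determined",
                      RuntimeWarning, stacklevel=2)
    R = _procrustes_rotation(A)
    return RigidTransform(rotation=R, translation=np.zeros(3))


def kronecker_rotation(frame: np.ndarray, mean: np.ndarray,
                       precision_N: np.ndarray) -> RigidTransform:
    """Rotation minimizing the Kronecker Mahalanobis distance to ``mean``.

    Minimizes ``tr[(frame @ R.T - mean).T @ precision_N @ (frame @ R.T -
    mean)]`` over proper rotations; exact single-shot weighted Procrustes
    solve (the objective is linear in R).
    """
    frame = np.asarray(frame, dtype=float)
    mean = np.asarray(mean, dtype=float)
    precision_N = np.asarray(precision_N, dtype=float)
    _check_centered_pair(frame, mean)
    if not np.allclose(precision_N, precision_N.T, atol=1e-8):
        raise InvalidInputError("precision_N must be symmetric")
    A = frame.T @ precision_N @ mean
    R = _procrustes_rotation(A)
    return RigidTransform(rotation=R, translation=np.zeros(3))


def _check_centered_pair(frame, reference):
    if frame.shape != reference.shape:
        raise InvalidInputError(
            f"shape mismatch: {frame.shape} vs {reference.shape}")
    for name, arr in (("frame", frame), ("reference", reference)):
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"{name} has non-finite coordinates")
        if np.abs(arr.mean(axis=0)).max() > 1e-6:
            raise InvalidInputError(f"{name} is not centered at the origin")


def regularized_precision(covariance_N: np.ndarray,
                          delta: float = COVAR_REGULARIZATION) -> np.ndarray:
    """Invert ``covariance_N + delta*I`` (symmetric positive definite)."""
    covariance_N = np.asarray(covariance_N, dtype=float)
    if not np.allclose(covariance_N, covariance_N.T, atol=1e-8):
        raise InvalidInputError("covariance_N must be symmetric")
    n = covariance_N.shape[0]
    return np.linalg.inv(covariance_N + delta * np.eye(n))


# ---------------------------------------------------------------------------
# ensemble alignment
# ---------------------------------------------------------------------------

def _align_batch(centered: np.ndarray, mean: np.ndarray,
                 precision_N) -> tuple:
    """Rotate each centered frame onto ``mean``; returns (aligned, rotations)."""
    if precision_N is None:
        A = np.einsum("mia,ib->mab", centered, mean)
    else:
        A = np.einsum("mia,ij,jb->mab", centered, precision_N, mean)
    R = _procrustes_rotation_batch(A)
    aligned = np.einsum("mia,mba->mib", centered, R)
    return aligned, R


def _mahalanobis_sq(aligned: np.ndarray, mean: np.ndarray, precision_N):
    dev = aligned - mean
    if precision_N is None:
        return np.einsum("mia,mia->m", dev, dev)
    return np.einsum("mia,ij,mja->m", dev, precision_N, dev)


def align_ensemble(frames, mean: np.ndarray = None,
                   covariance_N=None, weights=None,
                   uniform: bool = False, max_passes: int = 1000,
                   tol: float = 1.0e-10):
    """Align an ensemble to a reference structure.

    With ``mean`` given, every frame is centered and rotated onto it in one
    pass (Kronecker Mahalanobis metric when ``covariance_N`` is supplied,
    uniform Kabsch metric otherwise).  With ``mean=None`` the reference is
    determined self-consistently: starting from the first frame, alternate
    (weight-averaged mean, weighted particle covariance) estimation and
    realignment until the mean drifts by less than ``tol`` angstroms between
    passes.  ``weights`` are per-frame statistical weights (uniform when
    omitted).

    Returns an :class:`AlignmentResult`; the self-consistent variant
    additionally attaches ``mean`` and ``covariance_N`` attributes on the
    result.

    Raises
    ------
    ConvergenceError
        If the self-consistent mean does not settle within ``max_passes``;
        the exception carries the last iterate.
    """
    ens = frames if isinstance(frames, FrameEnsemble) else FrameEnsemble(frames)
    centered, translations = remove_translation(ens)
    X = centered.coords
    M, N, _ = X.shape
    w = _weight_vector(weights, M)

    if mean is not None:
        mean = np.asarray(mean, dtype=float)
        if np.abs(mean.mean(axis=0)).max() > 1e-6:
            raise InvalidInputError("reference mean must be centered")
        precision = None
        if covariance_N is not None and not uniform:
            precision = regularized_precision(covariance_N)
        aligned, R = _align_batch(X, mean, precision)
        maha = _mahalanobis_sq(aligned, mean, precision)
        transforms = [RigidTransform(rotation=R[i], translation=translations[i])
                      for i in range(M)]
        return AlignmentResult(aligned=FrameEnsemble(aligned),
                               transforms=transforms, mahalanobis=maha)

    # self-consistent reference; the initial mean is the weighted average of
    # the centered frames, making the result independent of frame order.
    # When orientations are scrambled the average can collapse toward zero;
    # fall back to the largest-norm frame (still order-invariant) in that case.
    aligned = X.copy()
    mu = (w[:, None, None] * aligned).sum(axis=0)
    rms = np.sqrt((w * np.einsum("mia,mia->m", X, X)).sum())
    if np.linalg.norm(mu) < 1e-2 * rms:
        mu = X[int(np.argmax(np.einsum("mia,mia->m", X, X)))].copy()
    mu -= mu.mean(axis=0)
    R_total = np.tile(np.eye(3), (M, 1, 1))
    for _ in range(max_passes):
        precision = None
        if not uniform:
            dev = aligned - (w[:, None, None] * aligned).sum(axis=0)
            cov = np.einsum("m,mia,mja->ij", w, dev, dev) / 3.0
            precision = regularized_precision(cov)
        aligned, R = _align_batch(aligned, mu, precision)
        R_total = R @ R_total
        mu_new = (w[:, None, None] * aligned).sum(axis=0)
        mu_new -= mu_new.mean(axis=0)
        drift = np.abs(mu_new - mu).max()
        mu = mu_new
        if drift < tol:
            break
    else:
        raise ConvergenceError(
            f"self-consistent alignment did not converge in {max_passes} passes",
            last_iterate=(mu, aligned))
    if uniform:
        cov = None
        precision = None
    maha = _mahalanobis_sq(aligned, mu, precision)
    transforms = [RigidTransform(rotation=R_total[i], translation=translations[i])
                  for i in range(M)]
    result = AlignmentResult(aligned=FrameEnsemble(aligned),
                             transforms=transforms, mahalanobis=maha)
    result.mean = mu
    result.covariance_N = cov
    return result


def _weight_vector(weights, M: int) -> np.ndarray:
    """Normalize ``weights`` (FrameWeights, array, or None) to a length-M array."""
    if weights is None:
        return np.full(M, 1.0 / M)
    w = np.asarray(getattr(weights, "values", weights), dtype=float)
    if w.shape != (M,):
        raise InvalidInputError(f"weights must have length {M}")
    if np.any(w < 0):
        raise InvalidInputError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise InvalidInputError("weights sum to zero")
    return w / total


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
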