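"""Frame-weighted Gaussian mixture modeling of aligned particle positions.

Each mixture component is a multivariate Gaussian over the 3N Cartesian
coordinates of a configuration with a Kronecker-structured covariance
``Sigma_N (x) I_3`` — anisotropic across particles, isotropic across axes —
and the density of a frame is evaluated at the rigid-body transform that
minimizes the component's Mahalanobis distance.  Per-frame statistical
weights ``w_i`` (summing to one) enter the EM estimate through the
posterior responsibilities:

    gamma_i(j) = w_i * phi_j N(x_i | mu_j, Sigma_j) / sum_k phi_k N(x_i | mu_k, Sigma_k)

so that the maximization step produces weighted averages and the weighted
log-likelihood per frame is  sum_i w_i ln sum_j phi_j N(x_i | mu_j, Sigma_j).
With uniform weights the procedure reduces exactly to unweighted EM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from cvrefine.errors import (ConvergenceError, EmptyComponentError,
                             InvalidInputError)
from cvrefine.geometry import (COVAR_REGULARIZATION, FrameEnsemble,
                               _align_batch, _mahalanobis_sq, _weight_vector,
                               align_ensemble, regularized_precision,
                               remove_translation)

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FrameWeights:
    """Normalized per-frame statistical weights (nonnegative, summing to 1)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidInputError("weights must be one-dimensional")
        if np.any(self.values < 0):
            raise InvalidInputError("weights must be nonnegative")
        if abs(self.values.sum() - 1.0) > 1e-12:
            raise InvalidInputError("weights must sum to 1 (use from_unnormalized)")

    @classmethod
    def uniform(cls, M: int) -> "FrameWeights":
        return cls(np.full(M, 1.0 / M))

    @classmethod
    def from_unnormalized(cls, raw) -> "FrameWeights":
        raw = np.asarray(raw, dtype=float)
        total = raw.sum()
        if total <= 0:
            raise InvalidInputError("weights sum to zero")
        w = raw / total
        w = w / w.sum()  # second pass tightens rounding to the 1e-12 contract
        return cls(w)

    def __len__(self):
        return len(self.values)


@dataclass
class ShapeGMMModel:
    """A fitted K-component shape Gaussian mixture.

    Attributes
    ----------
    phi : (K,) mixture weights summing to one.
    means : (K, N, 3) centered mean structures, angstroms.
    covariances_N : (K, N, N) particle covariance factors, square angstroms
        (the full covariance of component j is ``covariances_N[j] (x) I_3``).
    train_log_likelihood : weighted log-likelihood per frame at the optimum.
    """

    phi: np.ndarray
    means: np.ndarray
    covariances_N: np.ndarray
    train_log_likelihood: float = np.nan
    converged: bool = True
    n_iter: int = 0
    ll_history: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances_N = np.asarray(self.covariances_N, dtype=float)
        if np.any(self.phi < -1e-12):
            raise InvalidInputError("mixture weights must be nonnegative")
        if abs(self.phi.sum() - 1.0) > 1e-10:
            raise InvalidInputError("mixture weights must sum to 1")
        for j, cov in enumerate(self.covariances_N):
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise InvalidInputError(f"covariance {j} is not symmetric")

    @property
    def K(self) -> int:
        return len(self.phi)

    @property
    def particle_count(self) -> int:
        return self.means.shape[1]


@dataclass
class Responsibilities:
    """Weighted posterior membership gamma with rows summing to w_i."""

    gamma: np.ndarray

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        if np.any(self.gamma < -1e-12):
            raise InvalidInputError("responsibilities must be nonnegative")


# ---------------------------------------------------------------------------
# density plumbing
# ---------------------------------------------------------------------------

def _component_logdens_and_alignment(model, centered):
    """Per-component optimal alignment and log-density of each frame.

    Returns (logdens (K, M), aligned (K, M, N, 3)).
    """
    X = centered
    M, N, _ = X.shape
    K = model.K
    logdens = np.empty((K, M))
    aligned = np.empty((K, M, N, 3))
    log2pi = np.log(2.0 * np.pi)
    for j in range(K):
        cov = model.covariances_N[j] + COVAR_REGULARIZATION * np.eye(N)
        prec = np.linalg.inv(cov)
        sign, logdet_N = np.linalg.slogdet(cov)
        if sign <= 0:
            raise InvalidInputError(f"covariance {j} not positive definite")
        y, _ = _align_batch(X, model.means[j], prec)
        maha = _mahalanobis_sq(y, model.means[j], prec)
        logdens[j] = -0.5 * maha - 0.5 * (3 * N) * log2pi - 1.5 * logdet_N
        aligned[j] = y
    return logdens, aligned


def _estep_arrays(model, centered, w):
    """Responsibilities, per-component aligned frames, and weighted LL."""
    logdens, aligned = _component_logdens_and_alignment(model, centered)
    logphi = np.log(np.clip(model.phi, 1e-300, None))
    lognum = logphi[:, None] + logdens              # (K, M)
    lognorm = logsumexp(lognum, axis=0)             # (M,)
    if not np.all(np.isfinite(lognorm)):
        bad = int(np.flatnonzero(~np.isfinite(lognorm))[0])
        raise InvalidInputError(
            f"density underflow could not be resolved for frame {bad}")
    gamma = w * np.exp(lognum - lognorm)            # (K, M)
    ll = float(np.dot(w, lognorm))
    return gamma.T, aligned, ll


# ---------------------------------------------------------------------------
# spec operations
# ---------------------------------------------------------------------------

def weighted_e_step(model: ShapeGMMModel, frames, weights=None) -> Responsibilities:
    """Weighted posterior responsibilities gamma_i(j), rows summing to w_i.

    Frames are centered and aligned to each component (Mahalanobis-optimal
    rigid transform) before the density is evaluated; all arithmetic is in
    log space.
    """
    ens = frames if isinstance(frames, FrameEnsemble) else FrameEnsemble(frames)
    centered, _ = remove_translation(ens)
    w = _weight_vector(weights, ens.frame_count)
    gamma, _, _ = _estep_arrays(model, centered.coords, w)
    return Responsibilities(gamma=gamma)


def weighted_m_step(responsibilities, aligned_per_component) -> ShapeGMMModel:
    """Maximization step from responsibilities and per-component aligned frames.

    ``aligned_per_component`` has shape (K, M, N, 3): frame i aligned to
    component j.  Returns the model with phi_j = sum_i gamma_ij, weighted
    means, and weighted particle covariances (axis-averaged outer products).
    """
    gamma = responsibilities.gamma if isinstance(responsibilities, Responsibilities) \
        else np.asarray(responsibilities, dtype=float)
    Y = np.asarray(aligned_per_component, dtype=float)
    if Y.ndim == 3:  # single shared alignment for all components
        Y = np.broadcast_to(Y, (gamma.shape[1],) + Y.shape)
    K = gamma.shape[1]
    phi = gamma.sum(axis=0)
    if np.any(phi < 1e-12):
        j = int(np.argmin(phi))
        raise EmptyComponentError(
            f"component {j} has total responsibility {phi[j]:.3e}; "
            "reduce K or reseed")
    means = np.einsum("jm,jmna->jna", gamma.T, Y) / phi[:, None, None]
    means = means - means.mean(axis=1, keepdims=True)
    dev = Y - means[:, None]
    covs = np.einsum("jm,jmna,jmpa->jnp", gamma.T, dev, dev) \
        / (3.0 * phi[:, None, None])
    total = phi.sum()
    return ShapeGMMModel(phi=phi / total, means=means, covariances_N=covs)


def weighted_log_likelihood(model: ShapeGMMModel, frames, weights=None) -> float:
    """Weighted log-likelihood per frame, sum_i w_i ln sum_j phi_j N_j(x_i)."""
    ens = frames if isinstance(frames, FrameEnsemble) else FrameEnsemble(frames)
    centered, _ = remove_translation(ens)
    w = _weight_vector(weights, ens.frame_count)
    _, _, ll = _estep_arrays(model, centered.coords, w)
    return ll


def _kmeanspp_init(centered, w, K, rng):
    """Hard k-means++-style seeding on uniformly self-aligned frames."""
    res = align_ensemble(FrameEnsemble(centered), weights=w, uniform=True)
    flat = res.aligned.coords.reshape(len(centered), -1)
    M = flat.shape[0]
    centers = [int(rng.choice(M, p=w))]
    d2 = np.sum((flat - flat[centers[0]]) ** 2, axis=1)
    for _ in range(1, K):
        p = w * d2
        if p.sum() <= 0:
            p = w
        centers.append(int(rng.choice(M, p=p / p.sum())))
        d2 = np.minimum(d2, np.sum((flat - flat[centers[-1]]) ** 2, axis=1))
    dists = np.stack([np.sum((flat - flat[c]) ** 2, axis=1) for c in centers])
    labels = np.argmin(dists, axis=0)
    gamma = np.zeros((M, K))
    gamma[np.arange(M), labels] = w
    return gamma, res.aligned.coords


def weighted_em_fit(frames, weights=None, K: int = 2, seeds=(0, 1, 2),
                    max_iter: int = 200, tol: float = 1.0e-6) -> ShapeGMMModel:
    """Fit a K-component weighted shape GMM by EM with per-component alignment.

    Multiple random initializations (``seeds``) are run to completion and
    the model with the best final weighted log-likelihood is returned.
    Convergence is declared when the change in weighted log-likelihood drops
    below ``tol``.

    Raises
    ------
    ConvergenceError
        If every seed fails (e.g. all collapse to an empty component).
    """
    ens = frames if isinstance(frames, FrameEnsemble) else FrameEnsemble(frames)
    if ens.frame_count <= K:
        raise InvalidInputError("need more frames than components (M > K)")
    centered, _ = remove_translation(ens)
    X = centered.coords
    w = _weight_vector(weights, ens.frame_count)

    best = None
    failures = {}
    for seed in np.atleast_1d(seeds):
        rng = np.random.default_rng(int(seed))
        try:
            gamma0, aligned0 = _kmeanspp_init(X, w, K, rng)
            model = weighted_m_step(Responsibilities(gamma0), aligned0)
            ll_prev = -np.inf
            history = []
            converged = False
            n_iter = 0
            for n_iter in range(1, max_iter + 1):
                gamma, aligned, ll = _estep_arrays(model, X, w)
                model = weighted_m_step(Responsibilities(gamma), aligned)
                history.append(ll)
                if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol:
                    converged = True
                    break
                ll_prev = ll
            ll_final = weighted_log_likelihood(model, centered, w)
            model.train_log_likelihood = ll_final
            model.converged = converged
            model.n_iter = n_iter
            model.ll_history = np.asarray(history)
            if best is None or ll_final > best.train_log_likelihood:
                best = model
        except (EmptyComponentError, InvalidInputError) as exc:
            failures[int(seed)] = str(exc)
    if best is None:
        raise ConvergenceError("no EM seed converged", diagnostics=failures)
    return best


def predict_assignments(model: ShapeGMMModel, frames):
    """Hard labels and unweighted posterior responsibilities per frame.

    Labels are the argmax of the unweighted posterior; exact ties resolve to
    the lowest component index.
    """
    ens = frames if isinstance(frames, FrameEnsemble) else FrameEnsemble(frames)
    centered, _ = remove_translation(ens)
    gamma, _, _ = _estep_arrays(model, centered.coords,
                                np.ones(ens.frame_count))
    posteriors = gamma  # unit weights: rows sum to 1
    labels = np.argmax(posteriors, axis=1)
    return labels, posteriors


def scan_num_clusters(frames, weights=None, K_range=(1, 2, 3),
                      train_frac: float = 0.9, seeds=(0, 1, 2),
                      em_seeds=(0,), max_iter: int = 200,
                      tol: float = 1.0e-6) -> pd.DataFrame:
    """Cross-validated scan over candidate numbers of clusters.

    For every (K, seed) pair the frames are split into train and held-out
    subsets (fractions ``train_frac`` / ``1 - train_frac``, permuted by
    ``seed``), a weighted GMM is fitted on the train split, and the weighted
    log-likelihood is reported on both splits with each split's weights
    renormalized to sum to one.  Errors for a particular row (e.g. K larger
    than the train split) are recorded in the ``error`` column and the scan
    continues.
    """
    ens = frames if isinstance(frames, FrameEnsemble) else FrameEnsemble(frames)
    M = ens.frame_count
    w = _weight_vector(weights, M)
    n_train = int(round(train_frac * M))
    if n_train < 1 or n_train > M:
        raise InvalidInputError("train_frac leaves an empty split")
    rows = []
    for seed in np.atleast_1d(seeds):
        rng = np.random.default_rng(int(seed))
        perm = rng.permutation(M)
        tr, cv = perm[:n_train], perm[n_train:]
        w_tr = FrameWeights.from_unnormalized(w[tr])
        w_cv = FrameWeights.from_unnormalized(w[cv]) if len(cv) else None
        for K in np.atleast_1d(K_range):
            row = {"K": int(K), "seed": int(seed),
                   "train_ll": np.nan, "cv_ll": np.nan, "error": None}
            try:
                model = weighted_em_fit(ens.coords[tr], w_tr, K=int(K),
                                        seeds=em_seeds, max_iter=max_iter,
                                        tol=tol)
                row["train_ll"] = model.train_log_likelihood
                if w_cv is not None:
                    row["cv_ll"] = weighted_log_likelihood(
                        model, ens.coords[cv], w_cv)
            except (InvalidInputError, ConvergenceError,
                    EmptyComponentError) as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
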