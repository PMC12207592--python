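"""Bhattacharyya-distance matching of fitted clusters to reference states.

After re-clustering biased data, the new mixture components must be mapped
back onto the two original reference states so that the next discriminant
is built between the "same" physical states.  Similarity is measured by the
Bhattacharyya distance between Gaussian states,

    D_B = (1/8) dmu^T Sbar^{-1} dmu
        + (1/2) ln( det Sbar / sqrt(det Sa det Sb) ),   Sbar = (Sa + Sb)/2

evaluated on the N x N Kronecker covariance factors (determinant exponents
x3, quadratic form summed over the three Cartesian axes).  Before the
evaluation the second state's mean is rotated onto the first under the
pooled covariance metric, so distances live in a shared aligned frame; with
the Kronecker structure the covariance factors are rotation-invariant, and
the resulting distance is symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from cvrefine.errors import InvalidInputError
from cvrefine.geometry import (COVAR_REGULARIZATION, kronecker_rotation,
                               regularized_precision)

logger = logging.getLogger(__name__)


@dataclass
class GaussianState:
    """A Gaussian metastable state: centered mean (N, 3) and N x N covariance."""

    mean: np.ndarray
    covariance_N: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance_N = np.asarray(self.covariance_N, dtype=float)
        if not np.allclose(self.covariance_N, self.covariance_N.T, atol=1e-8):
            raise InvalidInputError("covariance_N must be symmetric")


@dataclass
class MatchResult:
    """Selected cluster indices for the two references plus the full table."""

    index_A: int
    index_B: int
    distance_table: np.ndarray   # (K, 2)


def bhattacharyya_distance(a: GaussianState, b: GaussianState,
                           align: bool = True) -> float:
    """Bhattacharyya distance between two Gaussian states (Kronecker form).

    With ``align`` (default) state b's mean is first rotated onto a's under
    the pooled-covariance Mahalanobis metric.  Both states must describe the
    same particle set.  Nonnegative; zero iff the states coincide.
    """
    if a.mean.shape != b.mean.shape:
        raise InvalidInputError("states are defined on different particle sets")
    n = a.covariance_N.shape[0]
    eye = np.eye(n)
    Sa = a.covariance_N + COVAR_REGULARIZATION * eye
    Sb = b.covariance_N + COVAR_REGULARIZATION * eye
    Sbar = 0.5 * (Sa + Sb)
    prec = np.linalg.inv(Sbar)
    mean_a = a.mean - a.mean.mean(axis=0)
    mean_b = b.mean - b.mean.mean(axis=0)
    if align:
        t = kronecker_rotation(mean_b, mean_a, prec)
        mean_b = t.apply(mean_b)
    d = mean_a - mean_b
    quad = float(np.einsum("ia,ij,ja->", d, prec, d))
    sign, ld_bar = np.linalg.slogdet(Sbar)
    sign_a, ld_a = np.linalg.slogdet(Sa)
    sign_b, ld_b = np.linalg.slogdet(Sb)
    if min(sign, sign_a, sign_b) <= 0:
        raise InvalidInputError("covariance not positive definite "
                                "after regularization")
    # determinants of the full 3N x 3N Kronecker covariances: logdet x3
    log_term = 0.5 * (3.0 * ld_bar - 1.5 * ld_a - 1.5 * ld_b)
    return 0.125 * quad + log_term


def _distance_table(model, ref_A: GaussianState,
                    ref_B: GaussianState) -> np.ndarray:
    table = np.empty((model.K, 2))
    for j in range(model.K):
        state = GaussianState(mean=model.means[j],
                              covariance_N=model.covariances_N[j],
                              label=f"cluster{j}")
        table[j, 0] = bhattacharyya_distance(state, ref_A)
        table[j, 1] = bhattacharyya_distance(state, ref_B)
    return table


def match_states(model, ref_A: GaussianState, ref_B: GaussianState) -> MatchResult:
    """Select the fitted clusters closest to each reference state.

    Picks the cluster minimizing D_B to ``ref_A`` and, among the remaining
    clusters, the minimizer for ``ref_B``.  If a single cluster is closest
    to both references, it is assigned to the reference with the smaller
    distance and the other reference takes its runner-up (logged warning).
    """
    if model.K < 2:
        raise InvalidInputError("state matching requires K >= 2")
    table = _distance_table(model, ref_A, ref_B)
    best_A = int(np.argmin(table[:, 0]))
    best_B = int(np.argmin(table[:, 1]))
    if best_A != best_B:
        return MatchResult(index_A=best_A, index_B=best_B,
                           distance_table=table)
    logger.warning("cluster %d is closest to both references; "
                   "assigning by smaller distance", best_A)
    if table[best_A, 0] <= table[best_B, 1]:
        masked = table[:, 1].copy()
        masked[best_A] = np.inf
        best_B = int(np.argmin(masked))
    else:
        masked = table[:, 0].copy()
        masked[best_B] = np.inf
        best_A = int(np.argmin(masked))
    return MatchResult(index_A=best_A, index_B=best_B, distance_table=table)
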