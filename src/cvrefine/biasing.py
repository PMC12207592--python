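"""Metadynamics-style bias bookkeeping along a scalar collective variable.

Two bias schemes are provided:

* **Well-tempered metadynamics (WT-MetaD)**: a history-dependent sum of
  Gaussian hills deposited at the visited CV values.  Each new hill is
  scaled by ``exp(-V(s)/kB*DeltaT)`` with effective temperature
  ``DeltaT = (gamma - 1) T``, so revisited regions receive geometrically
  shrinking hills and the bias converges to ``-(1 - 1/gamma) F(s)``.

* **OPES-MetaD**: a bias built from an on-the-fly kernel density estimate
  of the (reweighted) CV probability,
  ``V(s) = kT (1 - 1/gamma) ln(P(s)/Z + eps)`` with
  ``eps = exp(-DeltaE / (kT (1 - 1/gamma)))`` chosen so the magnitude of
  the bias can never exceed the cap DeltaE.

Both support quadratic restraining walls, free-energy estimation from the
final bias, F(s) = -(gamma/(gamma-1)) V(s), and reweighting factors
``w_i ∝ exp(+V(s_i)/kT)`` that recover unbiased expectations.

Energies are in kcal/mol; kT is carried explicitly (kT = kB*T in
kcal/mol), and the CV is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cvrefine.errors import InvalidInputError
from cvrefine.shapegmm import FrameWeights


# ---------------------------------------------------------------------------
# walls
# ---------------------------------------------------------------------------

@dataclass
class WallSpec:
    """Quadratic restraining walls: V = kappa*(s - bound)^2 beyond each bound."""

    lower: float
    upper: float
    kappa: float = 125.0

    def __post_init__(self):
        if not self.lower < self.upper:
            raise InvalidInputError("lower wall must sit below upper wall")
        if self.kappa < 0:
            raise InvalidInputError("kappa must be nonnegative")

    def potential(self, s):
        s = np.asarray(s, dtype=float)
        lo = np.minimum(s - self.lower, 0.0)
        hi = np.maximum(s - self.upper, 0.0)
        V = self.kappa * (lo ** 2 + hi ** 2)
        dV = 2.0 * self.kappa * (lo + hi)
        return V, dV


# ---------------------------------------------------------------------------
# WT-MetaD
# ---------------------------------------------------------------------------

@dataclass
class WTMetaDState:
    """Well-tempered metadynamics hill list and bias-factor bookkeeping.

    Parameters
    ----------
    h0 : initial hill height, kcal/mol.
    sigma : hill width in CV units.
    gamma : bias factor (> 1); the effective hill-tempering temperature is
        DeltaT = (gamma - 1) T, i.e. kB*DeltaT = (gamma - 1) * kT.
    kT : thermal energy, kcal/mol.
    pace : intended steps between deposits (bookkeeping only; the caller
        drives the deposit schedule).
    """

    h0: float = 1.0
    sigma: float = 0.1
    gamma: float = 8.0
    kT: float = 1.0
    pace: int = 500
    centers: list = field(default_factory=list)
    heights: list = field(default_factory=list)
    _arrays: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.gamma <= 1:
            raise InvalidInputError("bias factor gamma must exceed 1")
        if self.h0 <= 0 or self.sigma <= 0 or self.kT <= 0:
            raise InvalidInputError("h0, sigma and kT must be positive")

    @property
    def delta_T_energy(self) -> float:
        """kB * DeltaT = (gamma - 1) * kT, kcal/mol."""
        return (self.gamma - 1.0) * self.kT

    def potential(self, s):
        """Hill-sum bias V(s) and derivative dV/ds (vectorized over s)."""
        s = np.asarray(s, dtype=float)
        if not self.centers:
            return np.zeros_like(s), np.zeros_like(s)
        if self._arrays is None or len(self._arrays[0]) != len(self.centers):
            self._arrays = (np.asarray(self.centers), np.asarray(self.heights))
        c, h = self._arrays
        d = s[..., None] - c
        g = h * np.exp(-0.5 * (d / self.sigma) ** 2)
        V = g.sum(axis=-1)
        dV = (-d / self.sigma ** 2 * g).sum(axis=-1)
        return V, dV

    def deposit(self, s: float):
        """Add a hill at s with height h0 * exp(-V(s)/kB*DeltaT)."""
        if not np.isfinite(s):
            raise InvalidInputError("CV value must be finite")
        V, _ = self.potential(np.asarray(float(s)))
        height = self.h0 * np.exp(-float(V) / self.delta_T_energy)
        self.centers.append(float(s))
        self.heights.append(float(height))


def wtmetad_update(state: WTMetaDState, s: float) -> WTMetaDState:
    """Deposit one WT-MetaD hill at the current CV value; returns the state."""
    state.deposit(s)
    return state


# ---------------------------------------------------------------------------
# OPES-MetaD
# ---------------------------------------------------------------------------

@dataclass
class OPESState:
    """On-the-fly probability enhanced sampling bias bookkeeping.

    Kernels of fixed ``bandwidth`` are accumulated at the visited CV values
    with on-the-fly reweighting heights ``exp(V(s)/kT)`` (bias at deposit
    time), giving a kernel density estimate of the unbiased CV distribution.
    The normalization Z is the mean of the estimate over kernel centers.
    The regularizer ``eps = exp(-DeltaE/(kT (1 - 1/gamma)))`` caps the bias
    magnitude at DeltaE everywhere.
    """

    gamma: float = 8.0
    deltaE: float = 10.0
    kT: float = 1.0
    bandwidth: float = 0.1
    pace: int = 500
    centers: list = field(default_factory=list)
    log_heights: list = field(default_factory=list)
    _arrays: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.gamma <= 1:
            raise InvalidInputError("bias factor gamma must exceed 1")
        if self.deltaE <= 0 or self.kT <= 0 or self.bandwidth <= 0:
            raise InvalidInputError("deltaE, kT and bandwidth must be positive")

    @property
    def prefactor(self) -> float:
        """kT * (1 - 1/gamma), kcal/mol."""
        return self.kT * (1.0 - 1.0 / self.gamma)

    @property
    def epsilon(self) -> float:
        return np.exp(-self.deltaE / self.prefactor)

    def _prob_unnormalized(self, s):
        s = np.asarray(s, dtype=float)
        if self._arrays is None or len(self._arrays[0]) != len(self.centers):
            logh = np.asarray(self.log_heights)
            self._arrays = (np.asarray(self.centers), logh - logh.max())
        c, logh = self._arrays[0], self._arrays[1]
        d = s[..., None] - c
        kern = np.exp(logh) * np.exp(-0.5 * (d / self.bandwidth) ** 2)
        p = kern.sum(axis=-1)
        dp = (-d / self.bandwidth ** 2 * kern).sum(axis=-1)
        return p, dp

    @property
    def Z(self) -> float:
        """Normalization: mean of the probability estimate over kernel centers."""
        if self._arrays is not None and len(self._arrays) == 3 \
                and len(self._arrays[0]) == len(self.centers):
            return self._arrays[2]
        p, _ = self._prob_unnormalized(np.asarray(self.centers))
        Z = float(p.mean())
        self._arrays = self._arrays[:2] + (Z,)
        return Z

    def potential(self, s):
        """OPES bias V(s) = kT (1 - 1/gamma) ln(P(s)/Z + eps) and dV/ds."""
        s = np.asarray(s, dtype=float)
        if not self.centers:
            return np.zeros_like(s), np.zeros_like(s)
        p, dp = self._prob_unnormalized(s)
        Z = self.Z
        arg = p / Z + self.epsilon
        V = self.prefactor * np.log(arg)
        dV = self.prefactor * (dp / Z) / arg
        return V, dV

    def deposit(self, s: float):
        """Add a kernel at s with on-the-fly reweighting height exp(V(s)/kT)."""
        if not np.isfinite(s):
            raise InvalidInputError("CV value must be finite")
        V, _ = self.potential(np.asarray(float(s)))
        self.centers.append(float(s))
        self.log_heights.append(float(V) / self.kT)


def opes_update(state: OPESState, s: float) -> OPESState:
    """Deposit one OPES kernel at the current CV value; returns the state."""
    state.deposit(s)
    return state


# ---------------------------------------------------------------------------
# combined bias and FES estimators
# ---------------------------------------------------------------------------

def bias_potential(state, walls: WallSpec = None, s=None):
    """Total bias energy and derivative at s: hill/kernel sum plus walls."""
    s = np.asarray(s, dtype=float)
    V, dV = state.potential(s)
    if walls is not None:
        Vw, dVw = walls.potential(s)
        V = V + Vw
        dV = dV + dVw
    return V, dV


@dataclass
class FESProfile:
    """A gridded one-dimensional free-energy profile, min-shifted to zero.

    ``free_energy`` is in kcal/mol with NaN marking unsampled (missing)
    bins; ``grid`` holds strictly increasing bin centers in CV units.
    """

    grid: np.ndarray
    free_energy: np.ndarray
    kT: float = 1.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise InvalidInputError("grid must be strictly increasing")
        finite = np.isfinite(self.free_energy)
        if finite.any():
            self.free_energy = self.free_energy - self.free_energy[finite].min()


def fes_from_bias(state, grid) -> FESProfile:
    """FES estimate from the accumulated bias: F(s) = -(gamma/(gamma-1)) V(s)."""
    grid = np.asarray(grid, dtype=float)
    V, _ = state.potential(grid)
    factor = state.gamma / (state.gamma - 1.0)
    return FESProfile(grid=grid, free_energy=-factor * V, kT=state.kT)


def weights_from_bias(state, s_values, kT: float = None) -> FrameWeights:
    """Normalized reweighting factors w_i ∝ exp(+V(s_i)/kT) from the final bias."""
    s_values = np.asarray(s_values, dtype=float)
    if not np.all(np.isfinite(s_values)):
        raise InvalidInputError("CV values must be finite")
    kT = state.kT if kT is None else kT
    V, _ = state.potential(s_values)
    logw = V / kT
    logw = logw - logw.max()
    return FrameWeights.from_unnormalized(np.exp(logw))


def reweighted_fes(values, weights, grid, kT: float = 1.0) -> FESProfile:
    """FES from a weighted histogram: F = -kT ln(sum of weights per bin).

    ``grid`` gives bin centers (uniform spacing assumed); empty bins are
    returned as NaN (missing).  ``values`` may be the biased CV itself or
    any other scalar observable evaluated on the same frames.
    """
    values = np.asarray(values, dtype=float)
    w = np.asarray(getattr(weights, "values", weights), dtype=float)
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 2:
        raise InvalidInputError("grid needs at least two bins")
    spacing = np.diff(grid)
    edges = np.concatenate([[grid[0] - spacing[0] / 2],
                            grid[:-1] + spacing / 2,
                            [grid[-1] + spacing[-1] / 2]])
    hist, _ = np.histogram(values, bins=edges, weights=w)
    if not np.any(hist > 0):
        raise InvalidInputError("no samples fall inside the grid")
    with np.errstate(divide="ignore"):
        F = np.where(hist > 0, -kT * np.log(np.where(hist > 0, hist, 1.0)),
                     np.nan)
    return FESProfile(grid=grid, free_energy=F, kT=kT)


def fes_mae(a: FESProfile, b: FESProfile, cutoff: float = 7.5) -> float:
    """Mean absolute FES error over bins where the reference stays below cutoff.

    ``b`` is the reference profile; bins with reference free energy at or
    above ``cutoff`` kcal/mol, or missing in either profile, are excluded.
    """
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise InvalidInputError("profiles must share a common grid")
    mask = (np.isfinite(a.free_energy) & np.isfinite(b.free_energy)
            & (b.free_energy < cutoff))
    if not np.any(mask):
        raise InvalidInputError("no qualifying bins below the cutoff")
    return float(np.mean(np.abs(a.free_energy[mask] - b.free_energy[mask])))
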