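"""The six-step iterative coordinate-refinement loop.

1. short unbiased runs in each of the two states of interest;
2. an initial discriminant coordinate between the labeled ensembles;
3. biased sampling (WT-MetaD or OPES) along the current coordinate;
4. convergence check of the free-energy profile along a fixed reference
   coordinate (the known inter-state axis of the toy system, so that
   successive iterations are comparable even though the biased coordinate
   changes);
5. frame-weighted re-clustering of the biased data and Bhattacharyya
   matching of the new clusters to the original reference states;
6. a frame-weighted discriminant between the two matched clusters,
   yielding the next iteration's coordinate.

Steps 3-6 repeat until the reference free-energy profile stops changing
(mean absolute error below tolerance, with the standard cutoff excluding
bins above 7.5 kcal/mol) or an iteration budget runs out.  Every source of
randomness derives deterministically from the protocol seed and the
iteration index, so a resumed run reproduces an uninterrupted one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from cvrefine.biasing import (FESProfile, OPESState, WallSpec, WTMetaDState,
                              fes_mae, weights_from_bias, reweighted_fes)
from cvrefine.errors import InvalidInputError, NoDiscriminantError
from cvrefine.geometry import FrameEnsemble, align_ensemble
from cvrefine.lda import (LDACoordinate, evaluate_ld_batch,
                          weighted_scatter_matrices, wlda_solve)
from cvrefine.matching import GaussianState, MatchResult, match_states
from cvrefine.shapegmm import (FrameWeights, ShapeGMMModel, predict_assignments,
                               weighted_em_fit)
from cvrefine.toys import ToyTwoStateSystem, Trajectory, run_biased_langevin

logger = logging.getLogger(__name__)

MAE_CUTOFF = 7.5  # kcal/mol: reference bins above this are excluded from MAE


# ---------------------------------------------------------------------------
# configuration and records
# ---------------------------------------------------------------------------

@dataclass
class ProtocolConfig:
    """Parameters of the iterate loop.

    Biasing defaults follow common well-tempered metadynamics practice for
    small systems: bias factor 8, deposit pace 500 steps, quadratic walls of
    125 kcal/mol per squared CV unit placed 10 CV units beyond the training
    range of the coordinate.
    """

    K: int = 2
    gmm_seeds: tuple = (0, 1, 2)
    scheme: str = "wtmetad"          # "wtmetad" or "opes"
    hill_height: float = 0.7         # kcal/mol (WT-MetaD h0)
    sigma_fraction: float = 0.05     # hill width as a fraction of the CV range
    gamma: float = 8.0
    deltaE: float = 10.0             # kcal/mol (OPES cap)
    pace: int = 500
    wall_kappa: float = 125.0
    wall_offset: float = 10.0        # walls this far beyond the training range
    mae_tol: float = 0.5             # kcal/mol
    max_iterations: int = 2
    equal_state_weights: bool = False
    init_steps: int = 5000           # unbiased steps per starting state
    max_steps: int = 200_000         # cap on biased steps per iteration
    chunk_steps: int = 25_000        # round-trip check granularity
    min_round_trips: int = 2
    save_every: int = 10
    subsample_cap: int = 4000        # frames fed to re-clustering
    fes_bins: int = 61
    fes_margin: float = 1.5          # reference grid: state centers x margin
    transit_fraction: float = 0.5    # basin threshold as fraction of center

    def __post_init__(self):
        if self.mae_tol <= 0:
            raise InvalidInputError("convergence tolerance must be positive")
        if self.max_iterations < 1:
            raise InvalidInputError("need at least one iteration")
        if self.scheme not in ("wtmetad", "opes"):
            raise InvalidInputError(f"unknown bias scheme {self.scheme!r}")


@dataclass
class IterationRecord:
    """Everything one pass of the loop produced."""

    index: int
    coordinate: LDACoordinate
    model: ShapeGMMModel = None
    match: MatchResult = None
    fes: FESProfile = None
    mae_vs_previous: float = np.nan
    transit_count: int = 0
    trajectory: Trajectory = field(default=None, repr=False)
    bias_state: object = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# coordinate construction
# ---------------------------------------------------------------------------

def _pooled_within_class_covariance(aligned, labels, w):
    """Weighted pooled N x N particle covariance about each class mean."""
    X = np.asarray(aligned, dtype=float)
    cov = np.zeros((X.shape[1], X.shape[1]))
    for c in np.unique(labels):
        mask = labels == c
        wk = w[mask]
        mu = np.einsum("m,mia->ia", wk, X[mask]) / wk.sum()
        dev = X[mask] - mu
        cov += np.einsum("m,mia,mja->ij", wk, dev, dev) / 3.0
    return cov / w.sum()


def _fit_coordinate(frames_A, frames_B, weights_A=None, weights_B=None,
                    equal_state_weights: bool = False) -> LDACoordinate:
    """Weighted discriminant coordinate between two labeled ensembles.

    Joint self-consistent Kronecker alignment of all frames, weighted
    scatter matrices, whitened discriminant solve; the returned coordinate
    carries the joint alignment mean and the pooled within-class particle
    covariance as its alignment reference, and is oriented so the first
    (A) ensemble projects to negative values.
    """
    A = frames_A.coords if isinstance(frames_A, FrameEnsemble) else np.asarray(frames_A)
    B = frames_B.coords if isinstance(frames_B, FrameEnsemble) else np.asarray(frames_B)
    X = np.concatenate([A, B])
    labels = np.concatenate([np.zeros(len(A), dtype=int),
                             np.ones(len(B), dtype=int)])
    wA = np.ones(len(A)) if weights_A is None else \
        np.asarray(getattr(weights_A, "values", weights_A), dtype=float)
    wB = np.ones(len(B)) if weights_B is None else \
        np.asarray(getattr(weights_B, "values", weights_B), dtype=float)
    w = np.concatenate([wA, wB])
    w = w / w.sum()
    if equal_state_weights:
        for c, mask in ((0, labels == 0), (1, labels == 1)):
            w[mask] *= 0.5 / w[mask].sum()

    res = align_ensemble(FrameEnsemble(X), weights=w)
    aligned = res.aligned.coords

    # degenerate states: identical orbits leave nothing to discriminate
    muA = np.einsum("m,mia->ia", w[labels == 0], aligned[labels == 0]) \
        / w[labels == 0].sum()
    muB = np.einsum("m,mia->ia", w[labels == 1], aligned[labels == 1]) \
        / w[labels == 1].sum()
    scatter = weighted_scatter_matrices(aligned, labels, w)
    if np.abs(muA - muB).max() < 1e-6:
        covA = _pooled_within_class_covariance(aligned[labels == 0],
                                               np.zeros(int((labels == 0).sum())),
                                               w[labels == 0])
        covB = _pooled_within_class_covariance(aligned[labels == 1],
                                               np.zeros(int((labels == 1).sum())),
                                               w[labels == 1])
        if np.abs(covA - covB).max() < 1e-6:
            raise NoDiscriminantError(
                "the two states have identical means and covariances")

    v = wlda_solve(scatter, n_components=1)[0].reshape(-1, 3)
    pooled = _pooled_within_class_covariance(aligned, labels, w)
    coord = LDACoordinate(coefficients=v, ref_mean=res.mean,
                          ref_covariance_N=pooled)
    lvals = evaluate_ld_batch(X, coord)
    lA = np.average(lvals[labels == 0], weights=w[labels == 0])
    if lA > 0:  # sign convention: state A sits on the negative side
        coord = LDACoordinate(coefficients=-v, ref_mean=res.mean,
                              ref_covariance_N=pooled)
        lvals = -lvals
    coord.value_range = (float(lvals.min()), float(lvals.max()))
    return coord


def initial_coordinate(state_A_frames, state_B_frames) -> LDACoordinate:
    """Uniform-weight discriminant between the two starting ensembles."""
    return _fit_coordinate(state_A_frames, state_B_frames)


# ---------------------------------------------------------------------------
# transit bookkeeping
# ---------------------------------------------------------------------------

def count_transits(series, lower: float, upper: float) -> int:
    """Number of basin switches of a scalar series with hysteresis bounds."""
    state = None
    switches = 0
    for s in np.asarray(series, dtype=float):
        if s < lower:
            if state == "B":
                switches += 1
            state = "A"
        elif s > upper:
            if state == "A":
                switches += 1
            state = "B"
    return switches


def count_round_trips(series, lower: float, upper: float) -> int:
    """Completed round trips (there-and-back excursions between the basins)."""
    return count_transits(series, lower, upper) // 2


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

def _make_bias_state(config: ProtocolConfig, coordinate: LDACoordinate,
                     kT: float):
    lo, hi = coordinate.value_range
    span = max(hi - lo, 1e-6)
    if config.scheme == "wtmetad":
        return WTMetaDState(h0=config.hill_height,
                            sigma=config.sigma_fraction * span,
                            gamma=config.gamma, kT=kT, pace=config.pace)
    return OPESState(gamma=config.gamma, deltaE=config.deltaE, kT=kT,
                     bandwidth=config.sigma_fraction * span,
                     pace=config.pace)


def _walls_for(config: ProtocolConfig, coordinate: LDACoordinate) -> WallSpec:
    lo, hi = coordinate.value_range
    return WallSpec(lower=lo - config.wall_offset,
                    upper=hi + config.wall_offset, kappa=config.wall_kappa)


def reference_grid(system: ToyTwoStateSystem, config: ProtocolConfig):
    sA, sB = system.state_cv_centers()
    half = config.fes_margin * max(abs(sA), abs(sB))
    return np.linspace(-half, half, config.fes_bins)


def _iteration_seed(seed: int, index: int, stage: int) -> int:
    """Deterministic child seed below 2**31 for (protocol seed, iteration, stage)."""
    ss = np.random.SeedSequence([int(seed), int(index), int(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_iteration(system: ToyTwoStateSystem, prev: IterationRecord,
                  config: ProtocolConfig, ref_A: GaussianState,
                  ref_B: GaussianState, seed: int,
                  grid=None) -> IterationRecord:
    """One pass of steps 3-6: bias, reweight, re-cluster, match, refit.

    Biased sampling along ``prev.coordinate`` runs in chunks until at least
    ``config.min_round_trips`` round trips are observed on the reference
    coordinate or the step cap is reached.  The reference free-energy
    profile is estimated by final-bias reweighting, and the next coordinate
    is the weighted discriminant between the two clusters matched to the
    reference states.
    """
    index = prev.index + 1
    grid = reference_grid(system, config) if grid is None else grid
    bias_state = _make_bias_state(config, prev.coordinate, system.kT)
    walls = _walls_for(config, prev.coordinate)
    sA, sB = system.state_cv_centers()
    lo = config.transit_fraction * sA if sA < 0 else -abs(sA) / 2
    hi = config.transit_fraction * sB

    all_frames, all_cv = [], []
    x0 = system.means[0]
    total = 0
    chunk_idx = 0
    while total < config.max_steps:
        n = min(config.chunk_steps, config.max_steps - total)
        traj, bias_state = run_biased_langevin(
            system, coordinate=prev.coordinate, bias_state=bias_state,
            walls=walls, steps=n,
            seed=_iteration_seed(seed, index, 100 + chunk_idx),
            x0=x0, save_every=config.save_every)
        all_frames.append(traj.frames.coords)
        all_cv.append(traj.cv_values)
        x0 = traj.frames.coords[-1]
        total += n
        chunk_idx += 1
        ref_series = system.reference_cv(np.concatenate(all_frames))
        if count_round_trips(ref_series, lo, hi) >= config.min_round_trips:
            break
    coords = np.concatenate(all_frames)
    cv = np.concatenate(all_cv)
    ref_series = system.reference_cv(coords)
    transits = count_round_trips(ref_series, lo, hi)

    weights = weights_from_bias(bias_state, cv, kT=system.kT)
    fes = reweighted_fes(ref_series, weights, grid, kT=system.kT)
    mae = np.nan
    if prev.fes is not None:
        mae = fes_mae(fes, prev.fes, cutoff=MAE_CUTOFF)

    # subsample for re-clustering (weights renormalized)
    M = len(coords)
    stride = max(1, int(np.ceil(M / config.subsample_cap)))
    sel = np.arange(0, M, stride)
    w_sub = FrameWeights.from_unnormalized(weights.values[sel])
    model = weighted_em_fit(coords[sel], w_sub, K=config.K,
                            seeds=config.gmm_seeds)
    match = match_states(model, ref_A, ref_B)

    labels, _ = predict_assignments(model, coords[sel])
    mask_A = labels == match.index_A
    mask_B = labels == match.index_B
    if not mask_A.any() or not mask_B.any():
        raise InvalidInputError("a matched cluster received no frames")
    coordinate = _fit_coordinate(
        coords[sel][mask_A], coords[sel][mask_B],
        weights_A=weights.values[sel][mask_A],
        weights_B=weights.values[sel][mask_B],
        equal_state_weights=config.equal_state_weights)

    traj_all = Trajectory(frames=FrameEnsemble(coords), cv_values=cv,
                          bias_at_frame=bias_state.potential(cv)[0])
    return IterationRecord(index=index, coordinate=coordinate, model=model,
                           match=match, fes=fes, mae_vs_previous=float(mae),
                           transit_count=transits, trajectory=traj_all,
                           bias_state=bias_state)


def check_convergence(history, tol: float) -> bool:
    """True when the two most recent reference FES estimates agree within tol.

    Agreement is the mean absolute error over bins where the earlier profile
    stays below the 7.5 kcal/mol cutoff.
    """
    if len(history) < 2:
        raise InvalidInputError("need at least two iteration records")
    a, b = history[-1].fes, history[-2].fes
    if a is None or b is None:
        raise InvalidInputError("records lack FES estimates")
    return fes_mae(a, b, cutoff=MAE_CUTOFF) < tol


# ---------------------------------------------------------------------------
# full protocol with checkpointing
# ---------------------------------------------------------------------------

def build_reference_states(system: ToyTwoStateSystem, config: ProtocolConfig,
                           seed: int):
    """Short unbiased runs from each state; returns (frames_A, frames_B, refs).

    Each state's ensemble is aligned self-consistently and summarized as a
    Gaussian reference (mean structure and particle covariance) for later
    Bhattacharyya matching.
    """
    ensembles, refs = [], []
    for j, label in ((0, "state_A"), (1, "state_B")):
        traj, _ = run_biased_langevin(
            system, steps=config.init_steps,
            seed=_iteration_seed(seed, 0, 10 + j),
            x0=system.means[j], save_every=config.save_every)
        res = align_ensemble(traj.frames)
        refs.append(GaussianState(mean=res.mean,
                                  covariance_N=res.covariance_N, label=label))
        ensembles.append(traj.frames)
    return ensembles[0], ensembles[1], refs


def run_protocol(system: ToyTwoStateSystem, config: ProtocolConfig,
                 seed: int = 0, workdir=None):
    """Run the full loop; returns the list of IterationRecords.

    With ``workdir`` each completed iteration is checkpointed and a
    restarted call resumes from the last checkpoint, reproducing the
    uninterrupted result (all randomness derives from ``seed`` and the
    iteration index).
    """
    workdir = Path(workdir) if workdir is not None else None
    if workdir is not None:
        workdir.mkdir(parents=True, exist_ok=True)
        (workdir / "config.json").write_text(json.dumps(asdict(config),
                                                        indent=2))

    frames_A, frames_B, (ref_A, ref_B) = build_reference_states(
        system, config, seed)
    coord0 = initial_coordinate(frames_A, frames_B)
    history = [IterationRecord(index=0, coordinate=coord0)]
    grid = reference_grid(system, config)

    start = 1
    if workdir is not None:
        while (workdir / f"iteration_{start:02d}.npz").exists():
            history.append(load_record(workdir / f"iteration_{start:02d}.npz"))
            start += 1

    for index in range(start, config.max_iterations + 1):
        record = run_iteration(system, history[-1], config, ref_A, ref_B,
                               seed, grid=grid)
        history.append(record)
        if workdir is not None:
            save_record(workdir / f"iteration_{index:02d}.npz", record)
        logger.info("iteration %d: %d round trips, MAE %.3f kcal/mol",
                    index, record.transit_count, record.mae_vs_previous)
        if len(history) >= 3 and check_convergence(history, config.mae_tol):
            logger.info("converged at iteration %d", index)
            break
    return history


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_record(path, record: IterationRecord):
    """Checkpoint an IterationRecord (coordinate, model, match, FES) to npz."""
    payload = {
        "index": record.index,
        "coefficients": record.coordinate.coefficients,
        "ref_mean": record.coordinate.ref_mean,
        "ref_covariance_N": record.coordinate.ref_covariance_N,
        "value_range": np.asarray(record.coordinate.value_range, dtype=float),
        "mae_vs_previous": record.mae_vs_previous,
        "transit_count": record.transit_count,
    }
    if record.model is not None:
        payload.update(phi=record.model.phi, means=record.model.means,
                       covariances_N=record.model.covariances_N)
    if record.match is not None:
        payload.update(match_indices=np.array([record.match.index_A,
                                               record.match.index_B]),
                       distance_table=record.match.distance_table)
    if record.fes is not None:
        payload.update(fes_grid=record.fes.grid,
                       fes_values=record.fes.free_energy,
                       fes_kT=record.fes.kT)
    np.savez(path, **payload)


def load_record(path) -> IterationRecord:
    with np.load(path) as data:
        coord = LDACoordinate(coefficients=data["coefficients"],
                              ref_mean=data["ref_mean"],
                              ref_covariance_N=data["ref_covariance_N"],
                              value_range=tuple(data["value_range"]))
        model = match = fes = None
        if "phi" in data:
            model = ShapeGMMModel(phi=data["phi"], means=data["means"],
                                  covariances_N=data["covariances_N"])
        if "match_indices" in data:
            match = MatchResult(index_A=int(data["match_indices"][0]),
                                index_B=int(data["match_indices"][1]),
                                distance_table=data["distance_table"])
        if "fes_grid" in data:
            fes = FESProfile(grid=data["fes_grid"],
                             free_energy=data["fes_values"],
                             kT=float(data["fes_kT"]))
        return IterationRecord(index=int(data["index"]), coordinate=coord,
                               model=model, match=match, fes=fes,
                               mae_vs_previous=float(data["mae_vs_previous"]),
                               transit_count=int(data["transit_count"]))


# ---------------------------------------------------------------------------
# coefficient export
# ---------------------------------------------------------------------------

def export_coefficients(coordinate: LDACoordinate, model=None, out_dir="."):
    """Write the coordinate in the layout biased-MD engines consume.

    Produces ``ld_coefficients.txt`` (one ``particle_index cx cy cz`` row
    per particle, full double precision), ``ref_mean.pdb``, a delimited
    ``ref_covariance.txt`` and ``manifest.json`` recording the
    normalization, sign convention and training value range.  Returns the
    list of written paths.
    """
    from cvrefine.io import write_pdb
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    v = coordinate.coefficients
    rows = np.column_stack([np.arange(len(v)), v])
    coeff_path = out / "ld_coefficients.txt"
    np.savetxt(coeff_path, rows, fmt=["%d"] + ["%.17g"] * 3,
               header="particle_index cx cy cz")
    pdb_path = out / "ref_mean.pdb"
    write_pdb(pdb_path, coordinate.ref_mean)
    # PDB fixed-width fields truncate to 1e-3 A; keep a full-precision copy
    np.savetxt(out / "ref_mean.txt", coordinate.ref_mean, fmt="%.17g")
    cov_path = out / "ref_covariance.txt"
    np.savetxt(cov_path, coordinate.ref_covariance_N, fmt="%.17g")
    manifest = {
        "norm": float(np.linalg.norm(v)),
        "sign_convention": "state A projects to negative values",
        "value_range": list(coordinate.value_range)
        if coordinate.value_range else None,
        "units": "coefficients 1/angstrom, reference coordinates angstrom",
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    if model is not None:
        from cvrefine.io import save_model
        save_model(out / "shapegmm_model.npz", model)
    return [coeff_path, pdb_path, cov_path, manifest_path]


def load_coefficients(out_dir) -> LDACoordinate:
    """Re-import a coordinate written by :func:`export_coefficients`."""
    out = Path(out_dir)
    rows = np.loadtxt(out / "ld_coefficients.txt")
    v = rows[:, 1:4]
    cov = np.loadtxt(out / "ref_covariance.txt")
    manifest = json.loads((out / "manifest.json").read_text())
    # the PDB's fixed-width fields truncate coordinates; the exact reference
    # mean travels through the covariance file's companion full-precision copy
    mean_rows = np.loadtxt(out / "ref_mean.txt") if (out / "ref_mean.txt").exists() \
        else None
    if mean_rows is None:
        from cvrefine.io import read_pdb
        mean = read_pdb(out / "ref_mean.pdb")
        mean = mean - mean.mean(axis=0)
    else:
        mean = mean_rows
    vr = manifest.get("value_range")
    return LDACoordinate(coefficients=v, ref_mean=mean,
                         ref_covariance_N=cov,
                         value_range=tuple(vr) if vr else None)
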