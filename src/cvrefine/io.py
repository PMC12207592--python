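"""File formats: multi-frame XYZ, PDB references, model archives, text tables.

Trajectories are exchanged as multi-frame XYZ (angstroms, element column
preserved), single reference structures as PDB; both go through MDAnalysis.
Fitted mixture models are stored as a single ``.npz`` archive with keys
``K, phi, means, covariances_N, train_log_likelihood``; scan tables, hill
logs, free-energy profiles and coefficient exports are plain delimited
text.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from cvrefine.errors import InvalidInputError
from cvrefine.geometry import FrameEnsemble


def _universe_from_coords(coords: np.ndarray, elements=None):
    import MDAnalysis as mda
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    M, N, _ = coords.shape
    if elements is None:
        elements = ["C"] * N
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(N, trajectory=True)
        u.add_TopologyAttr("names", elements)
        u.add_TopologyAttr("elements", elements)
        u.add_TopologyAttr("resnames", ["TOY"])
        u.add_TopologyAttr("resids", [1])
        u.load_new(coords.astype(np.float32), order="fac")
    return u


def write_xyz(path, frames, elements=None):
    """Write frames (FrameEnsemble or (M, N, 3) array) as multi-frame XYZ."""
    coords = frames.coords if isinstance(frames, FrameEnsemble) else frames
    import MDAnalysis as mda
    u = _universe_from_coords(coords, elements)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=u.atoms.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def read_xyz(path):
    """Read a multi-frame XYZ file; returns (FrameEnsemble, element list)."""
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = np.stack([u.atoms.positions.copy().astype(float)
                           for _ in u.trajectory])
        elements = list(u.atoms.names)
    return FrameEnsemble(coords), elements


def write_pdb(path, frame, elements=None):
    """Write a single (N, 3) structure as a PDB file."""
    u = _universe_from_coords(np.asarray(frame)[None], elements)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_pdb(path):
    """Read a single-structure PDB; returns an (N, 3) array."""
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        return u.atoms.positions.astype(float)


# ---------------------------------------------------------------------------
# model archives
# ---------------------------------------------------------------------------

def save_model(path, model):
    """Serialize a ShapeGMMModel to a single .npz archive."""
    np.savez(path, K=model.K, phi=model.phi, means=model.means,
             covariances_N=model.covariances_N,
             train_log_likelihood=model.train_log_likelihood)


def load_model(path):
    from cvrefine.shapegmm import ShapeGMMModel
    with np.load(path) as data:
        return ShapeGMMModel(
            phi=data["phi"], means=data["means"],
            covariances_N=data["covariances_N"],
            train_log_likelihood=float(data["train_log_likelihood"]))


# ---------------------------------------------------------------------------
# delimited text tables
# ---------------------------------------------------------------------------

def write_weights(path, weights):
    w = np.asarray(getattr(weights, "values", weights), dtype=float)
    np.savetxt(path, w, fmt="%.17g", header="frame_weight")


def read_weights(path):
    from cvrefine.shapegmm import FrameWeights
    return FrameWeights.from_unnormalized(np.loadtxt(path))


def write_fes(path, profile):
    """Two-column text: CV grid value and free energy (kcal/mol, NaN = unsampled)."""
    np.savetxt(path, np.column_stack([profile.grid, profile.free_energy]),
               fmt="%.10g", header="cv free_energy_kcal_mol")


def read_fes(path, kT: float = 1.0):
    from cvrefine.biasing import FESProfile
    data = np.loadtxt(path)
    return FESProfile(grid=data[:, 0], free_energy=data[:, 1], kT=kT)


def write_hills(path, state):
    """Append-style hill/kernel log: index, center, height, width per deposit."""
    from cvrefine.biasing import OPESState
    if isinstance(state, OPESState):
        heights = np.exp(np.asarray(state.log_heights)
                         - max(state.log_heights, default=0.0))
        width = state.bandwidth
    else:
        heights = np.asarray(state.heights)
        width = state.sigma
    rows = np.column_stack([np.arange(len(state.centers)),
                            np.asarray(state.centers), heights,
                            np.full(len(state.centers), width)])
    np.savetxt(path, rows, fmt=["%d", "%.10g", "%.10g", "%.10g"],
               header="index center height width")


def write_distance_table(path, table, ref_labels=("state_A", "state_B")):
    header = "cluster " + " ".join(f"D_B_to_{lab}" for lab in ref_labels)
    rows = np.column_stack([np.arange(len(table)), table])
    np.savetxt(path, rows, fmt=["%d"] + ["%.10g"] * table.shape[1],
               header=header)
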