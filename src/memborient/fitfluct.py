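"""Rigid-body superposition (Kabsch) and RMSD/RMSF trajectory analyses.

RMSD is computed per frame after least-squares superposition of the fit
selection onto a reference frame; RMSF is the per-residue fluctuation
about the mean position after the same superposition, matching the usual
"fit to first frame, fluctuate about the mean" semantics of MD viewers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import MolecularSystem, SelectionError, Trajectory


class FitGeometryError(ValueError):
    """Superposition undefined (too few or collinear points)."""


@dataclass
class FitResult:
    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # nm
    rmsd: float  # nm

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Optimal proper rotation + translation mapping mobile onto reference.

    SVD-based Kabsch with the reflection branch forced to a proper rotation
    (det = +1). ``weights`` defaults to unit weights; pass masses for a
    mass-weighted fit.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise FitGeometryError("need at least 3 points to superpose")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    ref_c = reference - (w[:, None] * reference).sum(axis=0)
    h = (w[:, None] * mob_c).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    # collinear sets have (at least) two vanishing covariance singular values
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise FitGeometryError("points are collinear: rotation ill-determined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    ref_centroid = (w[:, None] * reference).sum(axis=0)
    mob_centroid = (w[:, None] * mobile).sum(axis=0)
    trans = ref_centroid - rot @ mob_centroid
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt((w * ((moved - reference) ** 2).sum(axis=1)).sum()))
    return FitResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_series(
    traj: Trajectory,
    atom_idx: np.ndarray,
    reference_frame: int = 0,
    weights: np.ndarray | None = None,
    skip_frames: int = 0,
) -> np.ndarray:
    """Per-frame RMSD (nm) of a selection after superposition onto a reference.

    ``skip_frames`` drops the first frames (equilibration window) from the
    returned series; the reference frame index refers to the full trajectory.
    """
    atom_idx = np.asarray(atom_idx, dtype=int)
    if atom_idx.size == 0:
        raise SelectionError("empty selection for RMSD")
    if not (0 <= reference_frame < traj.n_frames):
        raise IndexError(f"reference frame {reference_frame} out of range")
    ref = traj.coords[reference_frame][atom_idx]
    out = np.empty(traj.n_frames - skip_frames)
    for i, f in enumerate(range(skip_frames, traj.n_frames)):
        if f == reference_frame:
            out[i] = 0.0
            continue
        out[i] = kabsch_superpose(traj.coords[f][atom_idx], ref, weights).rmsd
    return out


def rmsf_per_residue(
    traj: Trajectory,
    system: MolecularSystem,
    fit_idx: np.ndarray,
    rmsf_idx: np.ndarray | None = None,
    reference_frame: int = 0,
    weights: np.ndarray | None = None,
    skip_frames: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF (nm) after superposing each frame onto a reference.

    Frames are fitted on ``fit_idx`` (e.g. G-domain Cα); fluctuations are
    then measured on ``rmsf_idx`` (defaults to the fit selection) about the
    mean superposed position: rmsf_i = sqrt(<|r_i(t) - <r_i>|^2>). Atom
    values are averaged within each residue. Returns (resids, rmsf).
    """
    fit_idx = np.asarray(fit_idx, dtype=int)
    if fit_idx.size == 0:
        raise SelectionError("empty fit selection")
    rmsf_idx = fit_idx if rmsf_idx is None else np.asarray(rmsf_idx, dtype=int)
    frames = range(skip_frames, traj.n_frames)
    if len(frames) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    ref = traj.coords[reference_frame][fit_idx]
    fitted = np.empty((len(frames), rmsf_idx.size, 3))
    for i, f in enumerate(frames):
        fit = kabsch_superpose(traj.coords[f][fit_idx], ref, weights)
        fitted[i] = fit.apply(traj.coords[f][rmsf_idx])
    mean_pos = fitted.mean(axis=0)
    per_atom = np.sqrt(((fitted - mean_pos) ** 2).sum(axis=2).mean(axis=0))

    resids = system.resids[rmsf_idx]
    order: list[int] = []
    seen: set[int] = set()
    for r in resids:
        if r not in seen:
            seen.add(r)
            order.append(r)
    rmsf = np.array([per_atom[resids == r].mean() for r in order])
    return np.array(order), rmsf
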