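"""Membrane-orientation observables of a lipid-anchored G domain.

Two scalars describe how the catalytic domain sits on the bilayer:

* the pivot angle ``theta`` between the membrane normal ``n`` and the
  G-domain direction vector ``G`` (90 deg = domain lying parallel to the
  membrane surface), and
* the torsion ``phi`` of the switch-region vector ``S`` about the domain
  axis ``G`` measured from the membrane normal. ``phi`` = 180 deg is the
  "syn" conformation (switch regions facing the membrane), ``phi`` near
  0/360 deg the solvent-exposed "anti" conformation.

``G`` is taken as the longest principal axis of the G-domain Cα cloud with
a continuity sign convention; ``S`` points from the G-domain Cα centroid to
the combined switch I + switch II Cα centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .structio import MolecularSystem, RegionSet, SelectionError, Trajectory


class DegeneracyError(ValueError):
    """Direction vector undefined (near-spherical point cloud)."""


class UndefinedTorsionError(ValueError):
    """Torsion undefined because two defining vectors are (anti)parallel."""


#: classification windows (deg); syn is closed, anti is open as written
DEFAULT_THRESHOLDS = {"syn": (120.0, 240.0), "anti": (60.0, 300.0)}


@dataclass
class OrientationVectors:
    n: np.ndarray
    G: np.ndarray
    S: np.ndarray
    frame: int


def _unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError(f"{name} must be non-zero")
    return v / norm


def g_vector(
    coords: np.ndarray,
    ca_idx: np.ndarray,
    previous: np.ndarray | None = None,
    degeneracy_tol: float = 0.01,
) -> np.ndarray:
    """Longest principal axis of the selected Cα cloud, sign-fixed.

    At frame 0 (``previous`` is None) the sign is chosen so the axis points
    away from the membrane (positive z component); afterwards the sign
    follows the previous frame (dot >= 0), which keeps the axis continuous
    through tilted orientations where the z component changes sign.
    """
    pts = np.asarray(coords, dtype=float)[np.asarray(ca_idx, dtype=int)]
    if pts.shape[0] < 4:
        raise DegeneracyError("need at least 4 points for a direction vector")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[2] <= 0:
        raise DegeneracyError("degenerate point cloud")
    if (evals[2] - evals[1]) / evals[2] < degeneracy_tol:
        raise DegeneracyError(
            "two largest principal-axis eigenvalues within "
            f"{degeneracy_tol:.0%}: direction ill-defined"
        )
    axis = evecs[:, 2]
    ref = np.array([0.0, 0.0, 1.0]) if previous is None else np.asarray(previous, float)
    if np.dot(axis, ref) < 0:
        axis = -axis
    return axis


def s_vector(coords: np.ndarray, switch_ca_idx: np.ndarray,
             g_ca_idx: np.ndarray) -> np.ndarray:
    """Unit vector from the G-domain Cα centroid to the switch Cα centroid."""
    switch_ca_idx = np.asarray(switch_ca_idx, dtype=int)
    g_ca_idx = np.asarray(g_ca_idx, dtype=int)
    if switch_ca_idx.size == 0:
        raise SelectionError("switch selection is empty")
    if g_ca_idx.size == 0:
        raise SelectionError("G-domain selection is empty")
    coords = np.asarray(coords, dtype=float)
    vec = coords[switch_ca_idx].mean(axis=0) - coords[g_ca_idx].mean(axis=0)
    return _unit(vec, "switch-position vector")


def pivot_angle(n: np.ndarray, G: np.ndarray) -> float:
    """Angle between membrane normal and G-domain axis, degrees in [0, 180]."""
    n = _unit(n, "membrane normal")
    G = _unit(G, "G-domain vector")
    return float(np.degrees(np.arccos(np.clip(np.dot(n, G), -1.0, 1.0))))


def torsion_phi(n: np.ndarray, G: np.ndarray, S: np.ndarray,
                parallel_tol_deg: float = 0.5) -> float:
    """Torsion of S about the axis G measured from the membrane normal.

    Equals the four-point dihedral over (p+n, p, p+G, p+G+S) mapped to
    [0, 360): 180 deg when S points along -n (switch regions toward the
    membrane, "syn"), 0 deg when S points along +n ("anti").
    """
    n = _unit(n, "membrane normal")
    G = _unit(G, "G-domain vector")
    S = _unit(S, "switch vector")
    lim = np.cos(np.radians(parallel_tol_deg))
    if abs(np.dot(n, G)) >= lim:
        raise UndefinedTorsionError("G parallel to membrane normal: torsion undefined")
    if abs(np.dot(G, S)) >= lim:
        raise UndefinedTorsionError("G parallel to S: torsion undefined")
    a = np.cross(n, G)
    b = np.cross(G, S)
    x = -np.dot(a, b)
    y = -np.dot(np.cross(a, b), G)
    phi = float(np.degrees(np.arctan2(y, x)) % 360.0)
    # a tiny negative angle can wrap to exactly 360.0 in floating point
    return 0.0 if phi >= 360.0 else phi


def classify(theta: float, phi: float,
             thresholds: dict | None = None) -> str:
    """syn / anti / intermediate label from the torsion angle.

    syn for phi in the closed window [120, 240]; anti for phi < 60 or
    phi > 300 (open); everything else intermediate.
    """
    th = thresholds or DEFAULT_THRESHOLDS
    syn_lo, syn_hi = th["syn"]
    anti_lo, anti_hi = th["anti"]
    if not (0.0 <= theta <= 180.0):
        raise ValueError("theta outside [0, 180]")
    if not (0.0 <= phi < 360.0):
        raise ValueError("phi outside [0, 360)")
    if syn_lo <= phi <= syn_hi:
        return "syn"
    if phi < anti_lo or phi > anti_hi:
        return "anti"
    return "intermediate"


def orientation_records(
    traj: Trajectory,
    system: MolecularSystem,
    regions: RegionSet,
    normal: np.ndarray | None = None,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Per-frame (theta, phi, label) table over a trajectory.

    Frames where the torsion is undefined (G within 0.5 deg of the normal
    or of S) are flagged rather than fatal: phi is NaN and the label is
    "undefined".
    """
    n = np.array([0.0, 0.0, 1.0]) if normal is None else _unit(np.asarray(normal))
    g_idx = regions.ca_atoms(system, "g_domain")
    s1 = regions.ca_atoms(system, "switch1")
    s2 = regions.ca_atoms(system, "switch2")
    switch_idx = np.union1d(s1, s2)
    rows = []
    # The principal axis has an arbitrary sign. Frame 0 points it away from
    # the membrane (+z, upright start); the Cα quartile at its far end then
    # becomes a structural reference group, and later frames orient the
    # axis toward that group's centroid. Unlike chaining the sign frame to
    # frame, this stays correct when consecutive frames are far apart.
    G0 = g_vector(traj.coords[0], g_idx, previous=None)
    proj = (traj.coords[0][g_idx] - traj.coords[0][g_idx].mean(axis=0)) @ G0
    ref_group = g_idx[proj >= np.quantile(proj, 0.75)]
    for f in range(traj.n_frames):
        ref_dir = (traj.coords[f][ref_group].mean(axis=0)
                   - traj.coords[f][g_idx].mean(axis=0))
        G = g_vector(traj.coords[f], g_idx,
                     previous=None if f == 0 else ref_dir)
        S = s_vector(traj.coords[f], switch_idx, g_idx)
        theta = pivot_angle(n, G)
        try:
            phi = torsion_phi(n, G, S)
            label = classify(theta, phi, thresholds)
            flagged = False
        except UndefinedTorsionError:
            phi, label, flagged = np.nan, "undefined", True
        rows.append({"frame": f, "theta": theta, "phi": phi,
                     "label": label, "flagged": flagged})
    return pd.DataFrame(rows)


def population_summary(records: pd.DataFrame, hist_bins: int = 36) -> dict:
    """Label fractions, per-label circular statistics and a (theta, phi) 2-D histogram.

    Flagged (undefined-torsion) frames are excluded from the fractions and
    counted separately. Circular statistics are used for phi; theta lives on
    [0, 180] and gets plain moments.
    """
    valid = records[~records["flagged"]]
    if len(valid) == 0:
        raise ValueError("no valid frames to summarise")
    fractions = {
        lab: float((valid["label"] == lab).mean())
        for lab in ("syn", "anti", "intermediate")
    }
    per_label = {}
    for lab, grp in valid.groupby("label"):
        phi = np.radians(grp["phi"].to_numpy())
        per_label[lab] = {
            "n": int(len(grp)),
            "theta_mean": float(grp["theta"].mean()),
            "theta_sd": float(grp["theta"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "phi_circmean": float(np.degrees(stats.circmean(phi))),
            "phi_circstd": float(np.degrees(stats.circstd(phi))) if len(grp) > 1 else 0.0,
        }
    phi_all = np.radians(valid["phi"].to_numpy())
    hist, theta_edges, phi_edges = np.histogram2d(
        valid["theta"].to_numpy(), valid["phi"].to_numpy(),
        bins=hist_bins, range=[[0, 180], [0, 360]],
    )
    return {
        "n_valid": int(len(valid)),
        "n_flagged": int(records["flagged"].sum()),
        "fractions": fractions,
        "per_label": per_label,
        "theta_mean": float(valid["theta"].mean()),
        "phi_circmean": float(np.degrees(stats.circmean(phi_all))),
        "phi_circstd": float(np.degrees(stats.circstd(phi_all))),
        "histogram": {
            "counts": hist.astype(int).tolist(),
            "theta_edges": theta_edges.tolist(),
            "phi_edges": phi_edges.tolist(),
        },
    }
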