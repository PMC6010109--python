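"""Protein-membrane proximity: phosphate planes, per-residue distance maps
and anchor insertion depth.

The proximal (upper) phosphate plane of the bilayer is the reference
surface for all protein distances; signed distances are negative when a
residue centre drops below it. The anchor insertion depth is measured from
the phosphates laterally neighbouring the anchor down to the deepest
anchor-chain carbon; positive depth means membrane penetration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .structio import MolecularSystem, SelectionError, Trajectory

logger = logging.getLogger("memborient")


class GeometryError(ValueError):
    """Not enough atoms to define the requested geometry."""


@dataclass
class PhosphatePlane:
    leaflet: str  # "upper" | "lower"
    mean_z: float  # nm
    members: np.ndarray  # atom indices
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))


@dataclass
class DistanceProfile:
    """residue x frame matrix of signed z-distances to the upper phosphate plane."""

    distances: np.ndarray  # (n_residues, n_frames) nm
    resids: np.ndarray
    frames: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format (residue, frame, distance) table."""
        res, frm = np.meshgrid(self.resids, self.frames, indexing="ij")
        return pd.DataFrame({
            "residue": res.ravel(),
            "frame": frm.ravel(),
            "distance": self.distances.ravel(),
        })


def phosphate_plane(
    coords: np.ndarray,
    phosphate_idx: np.ndarray,
    mode: str = "box-z",
) -> tuple[PhosphatePlane, PhosphatePlane]:
    """Split phosphates into leaflets and fit the reference planes.

    Leaflet assignment is by z relative to the phosphate median. In
    ``box-z`` mode the normal is the z axis; ``plane-fit`` fits a
    least-squares plane per leaflet and orients its normal toward +z.
    """
    phosphate_idx = np.asarray(phosphate_idx, dtype=int)
    if phosphate_idx.size < 6:
        raise GeometryError("need at least 3 phosphates per leaflet")
    pts = np.asarray(coords, dtype=float)[phosphate_idx]
    median_z = np.median(pts[:, 2])
    upper_mask = pts[:, 2] >= median_z
    planes = []
    for leaflet, mask in (("upper", upper_mask), ("lower", ~upper_mask)):
        members = phosphate_idx[mask]
        if members.size < 3:
            raise GeometryError(f"fewer than 3 phosphates in {leaflet} leaflet")
        sub = pts[mask]
        if mode == "plane-fit":
            centered = sub - sub.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            normal = vt[2]
            if normal[2] < 0:
                normal = -normal
        elif mode == "box-z":
            normal = np.array([0.0, 0.0, 1.0])
        else:
            raise ValueError(f"unknown plane mode: {mode}")
        planes.append(PhosphatePlane(
            leaflet=leaflet,
            mean_z=float(sub[:, 2].mean()),
            members=members,
            normal=normal,
        ))
    upper, lower = planes
    return upper, lower


def residue_centres(coords: np.ndarray, system: MolecularSystem,
                    atom_idx: np.ndarray, mass_weighted: bool = True
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue centre (mass-weighted by default) over a selection.

    Returns (resids, centres); residues ordered by first appearance.
    """
    atom_idx = np.asarray(atom_idx, dtype=int)
    if atom_idx.size == 0:
        raise SelectionError("empty selection")
    resids = system.resids[atom_idx]
    order = []
    seen = set()
    for r in resids:
        if r not in seen:
            seen.add(r)
            order.append(r)
    coords = np.asarray(coords, dtype=float)
    weights = system.masses[atom_idx] if mass_weighted else np.ones(atom_idx.size)
    centres = np.empty((len(order), 3))
    for i, r in enumerate(order):
        m = resids == r
        w = weights[m]
        if w.sum() <= 0:
            raise ValueError(f"residue {r} has zero total mass")
        centres[i] = (coords[atom_idx[m]] * w[:, None]).sum(axis=0) / w.sum()
    return np.array(order), centres


def residue_distance_profile(
    traj: Trajectory,
    system: MolecularSystem,
    protein_atom_idx: np.ndarray,
    phosphate_idx: np.ndarray,
    mode: str = "box-z",
    mass_weighted: bool = True,
) -> DistanceProfile:
    """Signed z-distance of each residue centre to the upper phosphate plane.

    distance = z(residue centre) - mean z(upper-leaflet phosphates);
    negative values mean the residue centre sits below the plane (inserted).
    """
    all_res = None
    cols = []
    for f in range(traj.n_frames):
        upper, _ = phosphate_plane(traj.coords[f], phosphate_idx, mode=mode)
        resids, centres = residue_centres(
            traj.coords[f], system, protein_atom_idx, mass_weighted
        )
        if all_res is None:
            all_res = resids
        cols.append(centres[:, 2] - upper.mean_z)
    return DistanceProfile(
        distances=np.column_stack(cols),
        resids=all_res,
        frames=np.arange(traj.n_frames),
    )


def anchor_insertion_depth(
    coords: np.ndarray,
    anchor_idx: np.ndarray,
    phosphate_idx: np.ndarray,
    lateral_cutoff: float = 1.0,
) -> float:
    """Insertion depth of the lipid anchor below the local phosphate plane.

    depth = mean z of upper-leaflet phosphates within ``lateral_cutoff`` nm
    (in xy) of the anchor carbons' lateral centroid, minus the minimum z
    over the anchor carbons. Positive = inserted. Falls back to the whole
    upper leaflet (with a warning) when no phosphate lies inside the cutoff.
    """
    anchor_idx = np.asarray(anchor_idx, dtype=int)
    if anchor_idx.size == 0:
        raise SelectionError("anchor selection is empty")
    coords = np.asarray(coords, dtype=float)
    upper, _ = phosphate_plane(coords, phosphate_idx)
    anchor = coords[anchor_idx]
    centroid_xy = anchor[:, :2].mean(axis=0)
    p = coords[upper.members]
    lateral = np.linalg.norm(p[:, :2] - centroid_xy, axis=1)
    local = p[lateral <= lateral_cutoff]
    if local.shape[0] == 0:
        logger.warning(
            "no phosphate within %.2f nm of the anchor centroid; "
            "falling back to the whole upper leaflet", lateral_cutoff,
        )
        local = p
    return float(local[:, 2].mean() - anchor[:, 2].min())


def depth_series(
    traj: Trajectory,
    anchor_idx: np.ndarray,
    phosphate_idx: np.ndarray,
    lateral_cutoff: float = 1.0,
) -> np.ndarray:
    """Per-frame anchor insertion depth over a trajectory (nm)."""
    return np.array([
        anchor_insertion_depth(traj.coords[f], anchor_idx, phosphate_idx,
                               lateral_cutoff)
        for f in range(traj.n_frames)
    ])


def depth_summary(values: np.ndarray, n_bins: int = 30) -> dict:
    """Mean, sd, Shapiro-Wilk normality and a histogram of depth values.

    With fewer than 8 values (or a constant series) the normality statistic
    is reported as undefined; mean and sd are always returned.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty depth series")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if sd < 1e-12 * max(1.0, abs(mean)):  # numerically constant series
        sd = 0.0
    if values.size >= 8 and sd > 0:
        w, p = stats.shapiro(values)
        shapiro_w, shapiro_p = float(w), float(p)
        degenerate = False
    else:
        shapiro_w = shapiro_p = None
        degenerate = sd == 0
    counts, edges = np.histogram(values, bins=n_bins)
    return {
        "n": int(values.size),
        "mean": mean,
        "sd": sd,
        "shapiro_w": shapiro_w,
        "shapiro_p": shapiro_p,
        "degenerate": bool(degenerate),
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
    }
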