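"""Shrake-Rupley solvent-accessible surface area and relative accessibility.

Per-atom SASA is computed by rolling a probe sphere (default radius 1.4 Å)
over the van der Waals surface: each atom carries a deterministic
generalized-spiral point set on its expanded sphere, a point is buried if
it falls strictly inside any neighbour's expanded sphere, and the exposed
fraction scales the analytic sphere area. Per-residue areas are normalized
against the maximum accessibility of residue X in an extended Gly-X-Gly
tripeptide (the Miller et al. reference areas), so a normalized SASA of 1
means the residue is essentially fully water-accessible.

Areas are in the square of whatever unit the coordinates/radii are given
in -- Å² throughout this package; region totals are reported in nm²
(1 nm² = 100 Ų).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import MolecularSystem, RegionSet

#: maximum accessible surface areas (Ų) of residue X in extended Gly-X-Gly
#: tripeptides (Miller et al. reference set), probe radius 1.4 Å.
MILLER_REFERENCE_AREAS: dict[str, float] = {
    "ALA": 113.0, "ARG": 241.0, "ASN": 158.0, "ASP": 151.0, "CYS": 140.0,
    "GLN": 189.0, "GLU": 183.0, "GLY": 85.0, "HIS": 194.0, "ILE": 182.0,
    "LEU": 180.0, "LYS": 211.0, "MET": 204.0, "PHE": 218.0, "PRO": 143.0,
    "SER": 122.0, "THR": 146.0, "TRP": 259.0, "TYR": 229.0, "VAL": 160.0,
}


@dataclass
class SasaConfig:
    probe_radius: float = 1.4  # Å
    n_points: int = 960
    reference_areas: dict[str, float] = field(
        default_factory=lambda: dict(MILLER_REFERENCE_AREAS)
    )

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.n_points < 32:
            raise ValueError("need at least 32 sphere points")


def sphere_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral (golden-angle) points on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    config: SasaConfig | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible area; units follow the input (Å -> Ų)."""
    config = config or SasaConfig()
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or radii.shape != (coords.shape[0],):
        raise ValueError("coords must be (n, 3) with matching radii")
    if (radii <= 0).any():
        raise ValueError("all radii must be positive")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")

    n = coords.shape[0]
    expanded = radii + config.probe_radius
    unit = sphere_points(config.n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(n)
    for i in range(n):
        r_i = expanded[i]
        nbrs = tree.query_ball_point(coords[i], r_i + expanded.max())
        nbrs = [j for j in nbrs if j != i]
        if nbrs:
            nbr_pos = coords[nbrs]
            nbr_r2 = expanded[nbrs] ** 2
            pts = coords[i] + r_i * unit  # (P, 3)
            d2 = ((pts[:, None, :] - nbr_pos[None, :, :]) ** 2).sum(axis=2)
            exposed = ~(d2 < nbr_r2[None, :] - 1e-12).any(axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * r_i * r_i * frac
    return areas


def residue_sasa_normalized(
    atom_areas: np.ndarray,
    system: MolecularSystem,
    atom_idx: np.ndarray | None = None,
    reference: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Aggregate per-atom areas to residues and normalize against the
    tripeptide reference table.

    ``atom_areas`` is indexed like ``atom_idx`` (defaults to all atoms).
    Residues absent from the reference table (lipid-modified cysteines,
    pseudo-residues) get NaN normalized area and ``flagged`` True; values
    slightly above 1 are reported as computed, not clipped.
    """
    reference = MILLER_REFERENCE_AREAS if reference is None else reference
    atom_idx = (np.arange(system.n_atoms) if atom_idx is None
                else np.asarray(atom_idx, dtype=int))
    atom_areas = np.asarray(atom_areas, dtype=float)
    if atom_areas.shape != (atom_idx.size,):
        raise ValueError("atom_areas must align with atom_idx")
    resids = system.resids[atom_idx]
    resnames = system.resnames[atom_idx]
    rows = []
    seen: set[int] = set()
    for r in resids:
        if r in seen:
            continue
        seen.add(r)
        m = resids == r
        area = float(atom_areas[m].sum())
        name = str(resnames[m][0])
        ref = reference.get(name)
        rows.append({
            "residue": int(r),
            "resname": name,
            "area_A2": area,
            "normalized": area / ref if ref else np.nan,
            "flagged": ref is None,
        })
    return pd.DataFrame(rows)


def region_sasa_total(
    atom_areas: np.ndarray,
    regions: RegionSet,
    region_names: list[str] | None = None,
    atom_idx: np.ndarray | None = None,
) -> dict[str, float]:
    """Per-region SASA totals in nm² plus the whole-selection total.

    Overlapping regions (e.g. a combined switch total) are summed over the
    union of atoms so no atom is double-counted.
    """
    atom_areas = np.asarray(atom_areas, dtype=float)
    atom_idx = (np.arange(atom_areas.size) if atom_idx is None
                else np.asarray(atom_idx, dtype=int))
    lookup = dict(zip(atom_idx.tolist(), atom_areas.tolist()))
    names = region_names or list(regions.atoms)
    totals: dict[str, float] = {}
    for name in names:
        sel = regions[name]
        totals[name] = sum(lookup.get(int(a), 0.0) for a in sel) / 100.0
    switch_union = np.union1d(regions["switch1"], regions["switch2"]) \
        if "switch1" in regions.atoms and "switch2" in regions.atoms else np.array([], int)
    if switch_union.size:
        totals["switch_total"] = sum(lookup.get(int(a), 0.0) for a in switch_union) / 100.0
    totals["all"] = float(atom_areas.sum()) / 100.0
    return totals


def trajectory_sasa(
    traj,
    system: MolecularSystem,
    atom_idx: np.ndarray | None = None,
    config: SasaConfig | None = None,
    skip_frames: int = 0,
    stride: int = 1,
    occluder_idx: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Time-averaged per-residue SASA over a trajectory.

    Areas are computed for ``atom_idx`` (default: all atoms) with
    ``occluder_idx`` atoms (default: all atoms) acting as additional
    burial partners -- membrane lipids occlude protein residues this way.
    Coordinates are converted nm -> Å so areas come out in Ų. Returns the
    averaged per-residue table and the per-frame atom-area matrix.
    """
    config = config or SasaConfig()
    atom_idx = (np.arange(system.n_atoms) if atom_idx is None
                else np.asarray(atom_idx, dtype=int))
    occluder_idx = (np.arange(system.n_atoms) if occluder_idx is None
                    else np.asarray(occluder_idx, dtype=int))
    scope = np.union1d(atom_idx, occluder_idx)
    pos_in_scope = {int(a): k for k, a in enumerate(scope)}
    sel = np.array([pos_in_scope[int(a)] for a in atom_idx])
    frames = range(skip_frames, traj.n_frames, stride)
    per_frame = np.empty((len(list(frames)), atom_idx.size))
    for row, f in enumerate(range(skip_frames, traj.n_frames, stride)):
        areas = atom_sasa(
            traj.coords[f][scope] * 10.0, system.radii[scope], config
        )
        per_frame[row] = areas[sel]
    mean_atom = per_frame.mean(axis=0)
    table = residue_sasa_normalized(mean_atom, system, atom_idx,
                                    config.reference_areas)
    return table, per_frame
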