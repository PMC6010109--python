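"""Synthetic membrane-anchored GTPase fixtures and rigid-body trajectories.

This module emulates the study system -- a 215-residue Rab5-like protein
carrying two 20-carbon geranylgeranyl pseudo-chains on Cys212/Cys213,
anchored to a symmetric six-lipid-type early-endosome model bilayer -- at
pseudo-atomic (Cα + bead) resolution. Every downstream observable of the
pipeline (distance maps, insertion depth, pivot/torsion orientation,
SASA, RMSD/RMSF) is computable from Cα, phosphate and anchor-carbon
positions, so an all-atom model is unnecessary; Cα spheres carry inflated
radii (3.3 Å) so burial patterns remain non-trivial for SASA.

Trajectories are generated by rigid-body posing of the G domain at pivot
and torsion angles drawn from wrapped-Gaussian mixtures, with the anchor
pinned at a sampled insertion depth below the local phosphate plane, the
hypervariable linker interpolated between the two, and isotropic Gaussian
thermal noise on top (extra noise on the switch residues). All output is a
pure function of (spec, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import orientation as _orient
from .membrane import phosphate_plane
from .structio import (
    DEFAULT_REGION_INTERVALS,
    MolecularSystem,
    RegionSet,
    Trajectory,
    resolve_regions,
)


class ParameterError(ValueError):
    """Invalid generator parameters."""


class MembraneGeometryError(ValueError):
    """Lipids do not fit the requested lateral area."""


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

#: per-leaflet lipid counts of the early-endosome model membrane
DEFAULT_LEAFLET_COUNTS: dict[str, int] = {
    "POPC": 90, "CHOL": 150, "PSM": 50, "POPE": 135, "POPS": 55, "PI3P": 25,
}


@dataclass
class MembraneSpec:
    """Symmetric bilayer: identical per-leaflet composition, planar leaflets."""

    leaflet_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LEAFLET_COUNTS))
    lx: float = 16.9  # nm
    ly: float = 16.6  # nm
    thickness: float = 4.0  # phosphate-plane to phosphate-plane, nm
    jitter: float = 0.1  # positional sigma, nm

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.leaflet_counts.values()):
            raise ParameterError("lipid counts must be non-negative")
        if self.lx <= 0 or self.ly <= 0 or self.thickness <= 0:
            raise ParameterError("membrane dimensions must be positive")
        if self.jitter < 0:
            raise ParameterError("jitter must be >= 0")

    @property
    def n_per_leaflet(self) -> int:
        return sum(self.leaflet_counts.values())


@dataclass
class AngleMixture:
    """Mixture of wrapped-Gaussian components: (mean deg, sigma deg, weight)."""

    components: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.components)
        if not np.isclose(w, 1.0):
            raise ParameterError("mixture weights must sum to 1")
        for mean, sigma, weight in self.components:
            if sigma < 0 or weight < 0:
                raise ParameterError("sigma and weight must be >= 0")
            if not (0.0 <= mean < 360.0):
                raise ParameterError("mean angles must lie in [0, 360)")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        weights = np.array([c[2] for c in self.components])
        which = rng.choice(len(self.components), size=n, p=weights)
        means = np.array([c[0] for c in self.components])[which]
        sigmas = np.array([c[1] for c in self.components])[which]
        return (rng.normal(means, sigmas)) % 360.0


@dataclass
class TrajectoryParams:
    n_frames: int = 500
    seed: int = 0
    theta: AngleMixture = field(
        default_factory=lambda: AngleMixture([(95.0, 7.5, 1.0)]))
    phi: AngleMixture = field(
        default_factory=lambda: AngleMixture([(80.0, 10.0, 0.5),
                                              (190.0, 10.0, 0.5)]))
    depth_mean: float = 1.74  # nm
    depth_sigma: float = 0.10  # nm
    thermal_sigma: float = 0.090  # per-atom isotropic noise, nm
    switch_sigma: float = 0.050  # extra noise on switch residues, nm

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ParameterError("need at least 1 frame")
        for name in ("depth_sigma", "thermal_sigma", "switch_sigma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.depth_mean <= 0:
            raise ParameterError("depth_mean must be positive")


#: activation-state presets. The inactive (GDP-like) state keeps the pivot
#: angle near 90 deg with torsion populations near 80 and 190 deg and mean
#: anchor depth 1.74 nm; the active (GTP-like) state samples a broader pivot
#: range with solvent-exposed torsions (0-90 and 280-360 deg windows) and
#: depth 1.71 nm. Thermal-noise sigmas are calibrated so the G-domain RMSD
#: plateaus near 0.24 nm (GDP-like) / 0.17 nm (GTP-like).
PRESETS: dict[str, TrajectoryParams] = {
    "gdp": TrajectoryParams(
        theta=AngleMixture([(95.0, 7.5, 1.0)]),
        phi=AngleMixture([(80.0, 10.0, 0.5), (190.0, 10.0, 0.5)]),
        depth_mean=1.74, depth_sigma=0.10,
        thermal_sigma=0.090, switch_sigma=0.050,
    ),
    "gtp": TrajectoryParams(
        theta=AngleMixture([(115.0, 25.0, 1.0)]),
        phi=AngleMixture([(45.0, 20.0, 0.5), (320.0, 20.0, 0.5)]),
        depth_mean=1.71, depth_sigma=0.10,
        thermal_sigma=0.066, switch_sigma=0.040,
    ),
}


def preset_params(state: str, n_frames: int, seed: int) -> TrajectoryParams:
    if state.lower() not in PRESETS:
        raise ParameterError(f"unknown activation state preset: {state}")
    return replace(PRESETS[state.lower()], n_frames=n_frames, seed=seed)


# ---------------------------------------------------------------------------
# composition arithmetic
# ---------------------------------------------------------------------------

def composition_percentages(spec: MembraneSpec) -> pd.DataFrame:
    """Per-leaflet composition table: count and percentage (1 decimal)."""
    total = spec.n_per_leaflet
    if total == 0:
        raise ParameterError("composition undefined for zero lipids")
    rows = [
        {"lipid": name, "count": count,
         "percent": round(100.0 * count / total, 1)}
        for name, count in spec.leaflet_counts.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# protein fixture
# ---------------------------------------------------------------------------

N_RESIDUES = 215
GG_CARBONS = 20
ELLIPSOID_LONG = 2.2  # nm, semi-axis along the domain axis (2:1 prolate)
ELLIPSOID_SHORT = 1.1  # nm
CA_RADIUS = 3.3  # Å, inflated to mimic residue bulk
CA_MASS = 12.011
STEP = 0.38  # Cα-Cα distance, nm


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _grow_chain(rng: np.random.Generator, start: np.ndarray, n: int,
                bias: np.ndarray, existing: np.ndarray,
                min_dist: float = 0.30) -> np.ndarray:
    """Self-avoiding biased random walk with Cα-sized steps."""
    pts: list[np.ndarray] = []
    pos = np.asarray(start, dtype=float)
    placed = existing
    for _ in range(n):
        cand = pos + STEP * bias  # fallback if every attempt clashes
        for _attempt in range(200):
            d = rng.normal(size=3)
            d = d / np.linalg.norm(d) + 1.5 * bias
            d /= np.linalg.norm(d)
            trial = pos + STEP * d
            if np.min(np.linalg.norm(placed - trial, axis=1)) >= min_dist:
                cand = trial
                break
        pts.append(cand)
        placed = np.vstack([placed, cand])
        pos = cand
    return np.array(pts)


def build_protein_fixture(seed: int = 0) -> tuple[MolecularSystem, np.ndarray]:
    """Cα-only 215-residue pseudo-protein with two 20-carbon anchor chains.

    The G domain (residues 15-184) sits on the surface of a 2:1 prolate
    ellipsoid whose long axis is the body-frame z axis; the switch residues
    (44-66 and 75-91) occupy the +x face. Residues 1-14 and 185-215 are
    self-avoiding chains; residues 212/213 each carry a 20-carbon
    geranylgeranyl pseudo-chain extending toward -z. Deterministic for a
    given seed; coordinates are in nm, body frame, ellipsoid centred at the
    origin.
    """
    rng = np.random.default_rng(seed)
    g_lo, g_hi = DEFAULT_REGION_INTERVALS["g_domain"]
    g_resids = list(range(g_lo, g_hi + 1))
    sw1 = range(*DEFAULT_REGION_INTERVALS["switch1"])
    sw2 = range(*DEFAULT_REGION_INTERVALS["switch2"])
    switch = (set(range(DEFAULT_REGION_INTERVALS["switch1"][0],
                        DEFAULT_REGION_INTERVALS["switch1"][1] + 1))
              | set(range(DEFAULT_REGION_INTERVALS["switch2"][0],
                          DEFAULT_REGION_INTERVALS["switch2"][1] + 1)))
    del sw1, sw2

    pts = _fibonacci_sphere(len(g_resids)) * np.array(
        [ELLIPSOID_SHORT, ELLIPSOID_SHORT, ELLIPSOID_LONG])
    order = np.argsort(-pts[:, 0])  # +x face first
    switch_resids = sorted(r for r in g_resids if r in switch)
    other_resids = sorted(r for r in g_resids if r not in switch)
    pos_by_resid: dict[int, np.ndarray] = {}
    for k, r in enumerate(switch_resids):
        pos_by_resid[r] = pts[order[k]]
    for k, r in enumerate(other_resids):
        pos_by_resid[r] = pts[order[len(switch_resids) + k]]

    g_coords = np.array([pos_by_resid[r] for r in g_resids])

    # N-terminal tail grows radially away from residue 15's surface point
    start = pos_by_resid[g_lo]
    bias = start / np.linalg.norm(start)
    n_term = _grow_chain(rng, start, 14, bias, g_coords)[::-1]  # resid 1..14
    for k, r in enumerate(range(1, 15)):
        pos_by_resid[r] = n_term[k]

    # hypervariable linker grows downward from residue 184 toward the anchor
    start = pos_by_resid[g_hi]
    bias = start / np.linalg.norm(start) * 0.5 + np.array([0.0, 0.0, -1.0])
    bias /= np.linalg.norm(bias)
    existing = np.vstack([g_coords, n_term])
    hvr = _grow_chain(rng, start, 27, bias, existing)  # resid 185..211
    for k, r in enumerate(range(185, 212)):
        pos_by_resid[r] = hvr[k]

    # anchor cysteines and their geranylgeranyl pseudo-chains
    ca212 = hvr[-1] + np.array([0.0, -0.19, -0.33])
    ca213 = ca212 + np.array([0.0, 0.38, 0.0])
    pos_by_resid[212] = ca212
    pos_by_resid[213] = ca213
    # short C-terminal tail past the anchor cysteines
    pos_by_resid[214] = ca213 + np.array([0.30, 0.15, 0.15])
    pos_by_resid[215] = pos_by_resid[214] + np.array([0.30, -0.15, 0.15])

    names, elements, resids, resnames = [], [], [], []
    coords: list[np.ndarray] = []
    masses, radii = [], []

    def add_atom(name: str, element: str, resid: int, resname: str,
                 xyz: np.ndarray, radius: float) -> None:
        names.append(name)
        elements.append(element)
        resids.append(resid)
        resnames.append(resname)
        coords.append(np.asarray(xyz, dtype=float))
        masses.append(CA_MASS)
        radii.append(radius)

    for r in range(1, N_RESIDUES + 1):
        resname = "CYG" if r in (212, 213) else "ALA"
        add_atom("CA", "C", r, resname, pos_by_resid[r], CA_RADIUS)
        if r in (212, 213):
            base = pos_by_resid[r] + np.array([0.0, 0.0, -0.15])
            for j in range(GG_CARBONS):
                off = np.array([0.05 * (-1.0) ** j, 0.0, -0.125 * (j + 1)])
                add_atom(f"C{j + 1:02d}", "C", r, resname, base + off, 1.70)

    system = MolecularSystem(
        names=np.array(names),
        elements=np.array(elements),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames),
        chains=np.full(len(names), "A"),
        masses=np.array(masses),
        radii=np.array(radii),
        metadata={"kind": "synthetic-protein", "seed": int(seed)},
    )
    return system, np.array(coords)


# ---------------------------------------------------------------------------
# membrane fixture
# ---------------------------------------------------------------------------

MIN_LIPID_SPACING = 0.4  # nm
LIPID_ATOMS = ("head", "tail1", "tail2")


def build_membrane_fixture(
    spec: MembraneSpec | None = None, seed: int = 0,
) -> tuple[MolecularSystem, np.ndarray, dict]:
    """Two planar leaflets of pseudo-lipids on a jittered grid.

    Each lipid is one residue with a head particle at z = +/- thickness/2
    (a phosphate named "P", except cholesterol which gets "O3") and two
    tail particles stepping toward the bilayer midplane. Returns (system,
    coordinates in nm, summary) where the summary reports the realized
    area per lipid and phosphate-plane thickness. The bilayer is centred
    at z = 0 and laterally spans [0, lx] x [0, ly].
    """
    spec = spec or MembraneSpec()
    rng = np.random.default_rng(seed)
    n = spec.n_per_leaflet
    if n == 0:
        raise ParameterError("membrane needs at least one lipid per leaflet")
    nx = int(np.ceil(np.sqrt(n * spec.lx / spec.ly)))
    ny = int(np.ceil(n / nx))
    sx, sy = spec.lx / nx, spec.ly / ny
    if min(sx, sy) < MIN_LIPID_SPACING:
        raise MembraneGeometryError(
            f"lateral area {spec.lx:.1f} x {spec.ly:.1f} nm too small for "
            f"{n} lipids at {MIN_LIPID_SPACING} nm spacing"
        )
    sites = np.array([((i + 0.5) * sx, (j + 0.5) * sy)
                      for j in range(ny) for i in range(nx)])[:n]

    types = [name for name, cnt in spec.leaflet_counts.items() for _ in range(cnt)]

    names, elements, resids, resnames, chains = [], [], [], [], []
    coords, masses, radii = [], [], []
    resid = 0
    half = spec.thickness / 2.0
    for leaflet_sign in (+1.0, -1.0):
        type_order = rng.permutation(n)
        for k in range(n):
            resid += 1
            lipid = types[type_order[k]]
            x0, y0 = sites[k]
            head_name = "O3" if lipid == "CHOL" else "P"
            head_el = "O" if lipid == "CHOL" else "P"
            zs = leaflet_sign * np.array([half, half - 0.5, half - 1.0])
            for name, z in zip(("", "C1", "C2"), zs):
                jit = rng.normal(0.0, spec.jitter, size=3) if spec.jitter else 0.0
                pos = np.array([x0, y0, z]) + jit
                atom_name = head_name if name == "" else name
                names.append(atom_name)
                elements.append(head_el if name == "" else "C")
                resids.append(resid)
                resnames.append(lipid)
                chains.append("M")
                coords.append(pos)
                masses.append(30.974 if atom_name == "P" else
                              (15.999 if atom_name == "O3" else 12.011))
                radii.append(1.80 if atom_name == "P" else
                             (1.52 if atom_name == "O3" else 1.70))

    coords = np.array(coords)
    names = np.array(names)
    system = MolecularSystem(
        names=names,
        elements=np.array(elements),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames),
        chains=np.array(chains),
        masses=np.array(masses),
        radii=np.array(radii),
        metadata={"kind": "synthetic-membrane", "seed": int(seed)},
    )
    p_mask = names == "P"
    pz = coords[p_mask, 2]
    summary = {
        "n_lipids_per_leaflet": n,
        "n_lipids_total": 2 * n,
        "area_per_lipid_nm2": spec.lx * spec.ly / n,
        "thickness_nm": float(pz[pz > 0].mean() - pz[pz < 0].mean()),
    }
    return system, coords, summary


def combine_systems(
    protein: MolecularSystem, membrane: MolecularSystem,
) -> MolecularSystem:
    """Concatenate protein (chain A) and membrane (chain M) topologies."""
    return MolecularSystem(
        names=np.concatenate([protein.names, membrane.names]),
        elements=np.concatenate([protein.elements, membrane.elements]),
        resids=np.concatenate([protein.resids, membrane.resids]),
        resnames=np.concatenate([protein.resnames, membrane.resnames]),
        chains=np.concatenate([protein.chains, membrane.chains]),
        masses=np.concatenate([protein.masses, membrane.masses]),
        radii=np.concatenate([protein.radii, membrane.radii]),
        metadata={"kind": "synthetic-system",
                  **{f"protein_{k}": v for k, v in protein.metadata.items()},
                  **{f"membrane_{k}": v for k, v in membrane.metadata.items()}},
    )


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

G_CLEARANCE = 0.5  # nm between the lowest G-domain/N-term atom and the plane
BOX_HEIGHT = 16.0  # nm
LATERAL_CUTOFF = 1.0  # nm, local phosphate plane around the anchor


@dataclass
class SyntheticRun:
    system: MolecularSystem
    trajectory: Trajectory
    regions: RegionSet
    truth: pd.DataFrame  # frame, theta, phi, depth (generator ground truth)
    membrane_summary: dict


def _rot_y(theta_rad: float) -> np.ndarray:
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(psi_rad: float) -> np.ndarray:
    c, s = np.cos(psi_rad), np.sin(psi_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _local_plane_z(membrane_coords: np.ndarray, phosphate_local: np.ndarray,
                   centroid_xy: np.ndarray) -> float:
    """Mean z of upper-leaflet phosphates near a lateral centroid."""
    upper, _ = phosphate_plane(membrane_coords, phosphate_local)
    p = membrane_coords[upper.members]
    d = np.linalg.norm(p[:, :2] - centroid_xy, axis=1)
    local = p[d <= LATERAL_CUTOFF]
    if local.shape[0] == 0:
        local = p
    return float(local[:, 2].mean())


def generate_trajectory(
    protein: MolecularSystem,
    protein_coords: np.ndarray,
    membrane: MolecularSystem,
    membrane_coords: np.ndarray,
    params: TrajectoryParams,
    spec: MembraneSpec | None = None,
    membrane_summary: dict | None = None,
) -> SyntheticRun:
    """Rigid-body trajectory with prescribed orientation/depth statistics.

    Frame 0 is the upright start (G-domain axis along the membrane normal,
    pivot angle 0); every later frame poses the G domain at (theta, phi)
    drawn from the wrapped-Gaussian mixtures, pins the lowest anchor carbon
    at the sampled depth below the local phosphate plane, interpolates the
    hypervariable linker, and adds thermal noise. The sampled (theta, phi,
    depth) per frame are returned as ground truth.
    """
    spec = spec or MembraneSpec()
    half = spec.thickness / 2.0
    if params.depth_mean >= half:
        raise ParameterError(
            f"requested depth {params.depth_mean} nm exceeds the leaflet "
            f"half-thickness {half} nm"
        )
    rng = np.random.default_rng(params.seed)
    system = combine_systems(protein, membrane)
    regions = resolve_regions(system)
    n_prot = protein.n_atoms

    coords0 = np.vstack([protein_coords, membrane_coords])
    box = np.array([spec.lx, spec.ly, BOX_HEIGHT])
    centre_xy = np.array([spec.lx / 2.0, spec.ly / 2.0])

    g_ca = regions.ca_atoms(system, "g_domain")
    sw_ca = np.union1d(regions.ca_atoms(system, "switch1"),
                       regions.ca_atoms(system, "switch2"))
    gn_atoms = regions.protein_atoms[
        system.resids[regions.protein_atoms] <= 184]  # G domain + N-term
    hvr_ca = regions.ca_atoms(system, "hvr")
    # the anchor block (cysteines + their chains + the short C-tail past
    # them) moves rigidly with the membrane-inserted anchor
    anchor_atoms = regions.protein_atoms[
        system.resids[regions.protein_atoms] >= 212]
    anchor_carbons = regions.anchor_carbons
    ca184 = regions.protein_atoms[
        (system.resids[regions.protein_atoms] == 184)
        & (system.names[regions.protein_atoms] == "CA")][0]
    ca212 = anchor_atoms[(system.resids[anchor_atoms] == 212)
                         & (system.names[anchor_atoms] == "CA")][0]
    switch_mask_prot = np.isin(
        np.arange(n_prot), sw_ca)  # switch CAs within protein block
    phosphates_mem = regions.membrane_phosphates - n_prot  # membrane-local

    # body-frame basis: e3 = domain long axis, e1 = switch-face direction
    body = protein_coords
    e3 = _orient.g_vector(body, g_ca, previous=None)
    s_full = body[sw_ca].mean(axis=0) - body[g_ca].mean(axis=0)
    e1 = s_full - np.dot(s_full, e3) * e3
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(e3, e1)
    b_t = np.array([e1, e2, e3])  # maps body -> canonical (g -> z, s_perp -> x)

    nrm = np.array([0.0, 0.0, 1.0])

    nf = params.n_frames
    thetas = params.theta.sample(rng, nf)
    # fold onto the polar range and keep the torsion defined
    thetas = np.abs((thetas + 180.0) % 360.0 - 180.0)
    thetas = np.clip(thetas, 1.0, 179.0)
    phis = params.phi.sample(rng, nf)
    depths = np.clip(rng.normal(params.depth_mean, params.depth_sigma, nf),
                     0.05, half - 0.05)
    thetas[0], phis[0], depths[0] = 0.0, np.nan, params.depth_mean

    frames = np.empty((nf, system.n_atoms, 3))
    truth_rows = []
    for f in range(nf):
        theta, phi_t, depth_t = thetas[f], phis[f], depths[f]
        if f == 0:
            rot = b_t
        else:
            r_y = _rot_y(np.radians(theta))
            # torsion is linear in the spin psi about the domain axis
            g_pose = r_y @ np.array([0.0, 0.0, 1.0])
            s0 = r_y @ _rot_z(0.0) @ (b_t @ s_full)
            phi0 = _orient.torsion_phi(nrm, g_pose, s0)
            s1 = r_y @ _rot_z(np.radians(10.0)) @ (b_t @ s_full)
            phi1 = _orient.torsion_phi(nrm, g_pose, s1)
            sense = 1.0 if np.isclose((phi1 - phi0) % 360.0, 10.0, atol=1e-6) else -1.0
            psi = sense * (phi_t - phi0)
            rot = r_y @ _rot_z(np.radians(psi)) @ b_t

        crd = coords0.copy()
        # pose G domain + N-terminus
        posed = crd[gn_atoms] @ rot.T
        g_xy = posed[np.isin(gn_atoms, g_ca)][:, :2].mean(axis=0)
        posed[:, :2] += centre_xy - g_xy
        upper, _ = phosphate_plane(membrane_coords, phosphates_mem)
        posed[:, 2] += (upper.mean_z + G_CLEARANCE) - posed[:, 2].min()
        crd[gn_atoms] = posed

        # anchor block: keep body orientation, drop to the sampled depth
        anchor = coords0[anchor_atoms].copy()
        carbons_local = np.isin(anchor_atoms, anchor_carbons)
        anchor[:, :2] += centre_xy - anchor[carbons_local][:, :2].mean(axis=0)
        local_z = _local_plane_z(membrane_coords, phosphates_mem,
                                 anchor[carbons_local][:, :2].mean(axis=0))
        anchor[:, 2] += (local_z - depth_t) - anchor[carbons_local][:, 2].min()
        crd[anchor_atoms] = anchor

        # hypervariable linker: straight interpolation Cα184 -> Cα212
        a, b = crd[ca184], crd[ca212]
        ts = (np.arange(1, hvr_ca.size + 1) / (hvr_ca.size + 1))[:, None]
        crd[hvr_ca] = a + ts * (b - a)

        # thermal noise (protein only; membrane is static scaffolding)
        if params.thermal_sigma > 0:
            crd[:n_prot] += rng.normal(0.0, params.thermal_sigma, (n_prot, 3))
        if params.switch_sigma > 0:
            crd[:n_prot][switch_mask_prot] += rng.normal(
                0.0, params.switch_sigma, (int(switch_mask_prot.sum()), 3))
        # The sampled depth is the per-frame ground truth: after noise has
        # moved the carbons (and hence the lateral centroid that selects the
        # local phosphate plane), re-pin the chain minimum against the plane
        # the analysis will actually see.
        carbons = regions.anchor_carbons
        local_z_post = _local_plane_z(membrane_coords, phosphates_mem,
                                      crd[carbons][:, :2].mean(axis=0))
        delta = (local_z_post - depth_t) - crd[carbons][:, 2].min()
        crd[carbons, 2] += delta

        frames[f] = crd
        truth_rows.append({"frame": f, "theta": theta, "phi": phi_t,
                           "depth": depth_t})

    traj = Trajectory(
        coords=frames,
        box=np.tile(box, (nf, 1)),
        times=np.arange(nf, dtype=float),
    )
    return SyntheticRun(
        system=system,
        trajectory=traj,
        regions=regions,
        truth=pd.DataFrame(truth_rows),
        membrane_summary=membrane_summary or {},
    )


def synthesize(
    state: str = "gdp",
    n_frames: int = 500,
    seed: int = 0,
    spec: MembraneSpec | None = None,
    params: TrajectoryParams | None = None,
) -> SyntheticRun:
    """One-call fixture + trajectory generation for an activation state."""
    spec = spec or MembraneSpec()
    if params is None:
        params = preset_params(state, n_frames, seed)
    protein, prot_coords = build_protein_fixture(seed)
    membrane, mem_coords, summary = build_membrane_fixture(spec, seed + 1)
    return generate_trajectory(protein, prot_coords, membrane, mem_coords,
                               params, spec, summary)
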