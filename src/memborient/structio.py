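"""Structure/trajectory I/O, atom selection and region resolution.

All coordinates are handled internally in nm (PDB Å are converted on read);
residue numbers are 1-based inclusive, atom indices 0-based. File parsing
and writing is delegated to MDAnalysis; masses and vdW radii always come
from the packaged element table so results do not depend on what a given
PDB dialect stores.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .elements import DEFAULT_RADIUS, element_from_name, mass_radius

logger = logging.getLogger("memborient")

ANGSTROM_PER_NM = 10.0


class StructureError(ValueError):
    """Malformed or empty structure input."""


class TopologyError(ValueError):
    """Trajectory does not match the system topology."""


class RegionConfigError(ValueError):
    """Region definition references residues outside the system."""


class SelectionError(ValueError):
    """An analysis was asked to run on an empty selection."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MolecularSystem:
    """Static topology: names, residues, masses and radii for each atom.

    Atom indices are implicit (0 .. n_atoms-1, file order). ``radii`` are in
    Å (the natural unit of the packaged vdW table), ``masses`` in Da.
    """

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    masses: np.ndarray
    radii: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "resids", "resnames", "chains", "masses", "radii"):
            if len(getattr(self, attr)) != n:
                raise StructureError(f"field {attr!r} length != n_atoms")
        if n and (np.asarray(self.masses) <= 0).any():
            raise StructureError("all atoms must have positive mass")
        if n and (np.asarray(self.radii) <= 0).any():
            raise StructureError("all atoms must have positive radius")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_residues(self) -> int:
        return len(np.unique(np.stack([self.chains.astype(str), self.resids.astype(str)]), axis=1).T)

    def atoms_of_chain(self, chain: str) -> np.ndarray:
        return np.flatnonzero(self.chains == chain)


@dataclass
class Trajectory:
    """Ordered coordinate frames in nm with per-frame box dimensions."""

    coords: np.ndarray  # (n_frames, n_atoms, 3) nm
    box: np.ndarray  # (n_frames, 3) nm
    times: np.ndarray | None = None  # ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError("coords must have shape (n_frames, n_atoms, 3)")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (self.n_frames, 3):
            raise TopologyError("box must have shape (n_frames, 3)")
        if self.n_frames and (self.box <= 0).any():
            raise TopologyError("box dimensions must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


#: the Rab5 residue intervals used throughout (1-based inclusive)
DEFAULT_REGION_INTERVALS: dict[str, tuple[int, int]] = {
    "g_domain": (15, 184),
    "switch1": (44, 66),
    "switch2": (75, 91),
    "hvr": (185, 211),
    "n_term": (1, 14),
    "anchor_cys": (212, 213),
}

DEFAULT_REGION_CONFIG: dict = {
    "regions": dict(DEFAULT_REGION_INTERVALS),
    "protein_chain": "A",
    "phosphate_name": "P",
    "anchor_carbon_pattern": r"C\d+",
}


@dataclass
class RegionSet:
    """Concrete atom-index selections for each named region.

    ``residue_regions`` keeps the resolved interval per region; ``atoms``
    maps region name -> sorted atom-index array. ``membrane_phosphates`` and
    ``anchor_carbons`` are atom-name based selections.
    """

    atoms: dict[str, np.ndarray]
    residue_regions: dict[str, tuple[int, int]]
    membrane_phosphates: np.ndarray
    anchor_carbons: np.ndarray
    protein_atoms: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        if name == "membrane_phosphates":
            return self.membrane_phosphates
        if name == "anchor_carbons":
            return self.anchor_carbons
        return self.atoms[name]

    def ca_atoms(self, system: MolecularSystem, name: str) -> np.ndarray:
        idx = self[name]
        return idx[system.names[idx] == "CA"]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _system_from_universe(u, default_radius: float, source: str) -> MolecularSystem:
    atoms = u.atoms
    if len(atoms) == 0:
        raise StructureError(f"no ATOM records in {source}")
    names = atoms.names.astype(str)
    if hasattr(atoms, "elements"):
        elements = np.array([e if e.strip() else element_from_name(n)
                             for e, n in zip(atoms.elements, names)])
    else:
        elements = np.array([element_from_name(n) for n in names])
    masses = np.empty(len(atoms))
    radii = np.empty(len(atoms))
    unknown: set[str] = set()
    for i, el in enumerate(elements):
        m, r, known = mass_radius(el, default_radius)
        masses[i] = m
        radii[i] = r
        if not known:
            unknown.add(el or "?")
    if unknown:
        logger.warning(
            "unknown element(s) %s: default radius %.2f Å assigned",
            sorted(unknown), default_radius,
        )
    chains = (atoms.chainIDs.astype(str) if hasattr(atoms, "chainIDs")
              else np.full(len(atoms), "A"))
    return MolecularSystem(
        names=names,
        elements=elements.astype(str),
        resids=atoms.resids.astype(int),
        resnames=atoms.resnames.astype(str),
        chains=chains,
        masses=masses,
        radii=radii,
        metadata={"source": source},
    )


def read_structure(
    path: str | Path,
    format: str = "pdb",
    default_radius: float = DEFAULT_RADIUS,
) -> tuple[MolecularSystem, np.ndarray]:
    """Read a PDB structure; returns (system, first-frame coordinates in nm)."""
    path = Path(path)
    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format: {format}")
    if not path.exists():
        raise IOError(f"structure file not found: {path}")
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format="PDB")
        except Exception as exc:  # zero ATOM records etc.
            raise StructureError(f"could not parse {path} as PDB: {exc}") from exc
    system = _system_from_universe(u, default_radius, str(path))
    coords = u.atoms.positions.astype(float) / ANGSTROM_PER_NM
    return system, coords


def read_trajectory(
    path: str | Path,
    format: str,
    system: MolecularSystem,
) -> Trajectory:
    """Read a DCD/XTC/multi-model-PDB trajectory against a known topology.

    Coordinates come back in nm whatever the on-disk unit convention.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"trajectory file not found: {path}")
    fmt = format.lower()
    if fmt not in {"dcd", "xtc", "pdb"}:
        raise ValueError(f"unsupported trajectory format: {format}")
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(system.n_atoms, trajectory=True)
        try:
            u.load_new(str(path), format=fmt.upper())
        except (ValueError, IOError) as exc:
            msg = str(exc)
            if "atoms" in msg or "shape" in msg:
                raise TopologyError(
                    f"{path}: atom count does not match system ({system.n_atoms})"
                ) from exc
            raise
        frames = []
        boxes = []
        times = []
        try:
            for i, ts in enumerate(u.trajectory):
                if ts.positions.shape[0] != system.n_atoms:
                    raise TopologyError(
                        f"{path}: frame {i} has {ts.positions.shape[0]} atoms, "
                        f"expected {system.n_atoms}"
                    )
                frames.append(ts.positions.astype(float) / ANGSTROM_PER_NM)
                dims = ts.dimensions
                if dims is None or not np.all(dims[:3] > 0):
                    boxes.append(np.full(3, np.nan))
                else:
                    boxes.append(np.asarray(dims[:3], dtype=float) / ANGSTROM_PER_NM)
                times.append(ts.time / 1000.0)  # ps -> ns
        except EOFError as exc:
            raise IOError(f"{path}: truncated at frame {len(frames)}") from exc
    box = np.array(boxes)
    if np.isnan(box).any():
        box = np.where(np.isnan(box), 100.0, box)  # effectively unbounded
    return Trajectory(coords=np.array(frames), box=box, times=np.array(times))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _universe_from_system(system: MolecularSystem, coords_nm: np.ndarray):
    mda = _mda()
    # residue partition in file order
    key = np.stack([system.chains.astype(str), system.resids.astype(str)])
    change = np.ones(system.n_atoms, dtype=bool)
    change[1:] = (key[:, 1:] != key[:, :-1]).any(axis=0)
    resindex = np.cumsum(change) - 1
    n_res = int(resindex[-1]) + 1 if system.n_atoms else 0
    first = np.flatnonzero(change)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            system.n_atoms, n_residues=n_res, atom_resindex=resindex, trajectory=True
        )
        u.add_TopologyAttr("names", system.names)
        u.add_TopologyAttr("elements", system.elements)
        u.add_TopologyAttr("resids", system.resids[first])
        u.add_TopologyAttr("resnames", system.resnames[first])
        u.add_TopologyAttr("chainIDs", system.chains)
        u.atoms.positions = np.asarray(coords_nm, dtype=float) * ANGSTROM_PER_NM
    return u


def write_structure(system: MolecularSystem, coords_nm: np.ndarray,
                    path: str | Path, box_nm: Sequence[float] | None = None) -> Path:
    """Write a single-model PDB (coordinates given in nm)."""
    path = Path(path)
    mda = _mda()
    u = _universe_from_system(system, coords_nm)
    if box_nm is not None:
        u.dimensions = [*(np.asarray(box_nm) * ANGSTROM_PER_NM), 90, 90, 90]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path)) as w:
            w.write(u.atoms)
    return path


def write_trajectory(system: MolecularSystem, traj: Trajectory,
                     path: str | Path, format: str | None = None) -> Path:
    """Write a trajectory as multi-model PDB, DCD or XTC (by extension)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"pdb", "dcd", "xtc"}:
        raise ValueError(f"unsupported trajectory format: {fmt}")
    if traj.n_atoms != system.n_atoms:
        raise TopologyError("trajectory atom count does not match system")
    mda = _mda()
    u = _universe_from_system(system, traj.coords[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kwargs = {"multiframe": True} if fmt == "pdb" else {"n_atoms": system.n_atoms}
        with mda.Writer(str(path), **kwargs) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f] * ANGSTROM_PER_NM
                u.dimensions = [*(traj.box[f] * ANGSTROM_PER_NM), 90, 90, 90]
                if traj.times is not None:
                    u.trajectory.ts.time = traj.times[f] * 1000.0
                w.write(u.atoms)
    return path


def write_table(records, path: str | Path, format: str | None = None) -> Path:
    """Write stage output (DataFrame / list of mappings / mapping) to CSV or JSON.

    Column order is deterministic (input order) and floats are rendered at
    6 significant digits.
    """
    if records is None:
        raise ValueError("records must not be None")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if isinstance(records, pd.DataFrame):
        df = records
    elif isinstance(records, Mapping):
        df = None
    else:
        records = list(records)
        df = pd.DataFrame.from_records(
            [r if isinstance(r, Mapping) else vars(r) for r in records]
        )
    if fmt == "csv":
        if df is None:
            df = pd.DataFrame([dict(records)])
        df.to_csv(path, index=False, float_format="%.6g")
    elif fmt == "json":
        obj = _jsonable(dict(records) if df is None else df.to_dict(orient="records"))
        path.write_text(json.dumps(obj, indent=1, sort_keys=False) + "\n")
    else:
        raise ValueError(f"unsupported table format: {fmt}")
    return path


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return float(f"{v:.6g}") if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# region resolution
# ---------------------------------------------------------------------------

def resolve_regions(system: MolecularSystem, config: Mapping | None = None) -> RegionSet:
    """Turn residue-interval definitions into concrete atom-index sets.

    The default config encodes the Rab5 intervals (G domain 15-184,
    switch I 44-66, switch II 75-91, anchor cysteines 212-213).
    """
    cfg = dict(DEFAULT_REGION_CONFIG)
    if config:
        cfg.update({k: v for k, v in config.items() if k != "regions"})
        if "regions" in config:
            cfg["regions"] = {k: tuple(v) for k, v in config["regions"].items()}
    chain = cfg["protein_chain"]
    protein = system.atoms_of_chain(chain)
    if protein.size == 0:
        # single-chain files often carry no chain ID; fall back to everything
        protein = np.arange(system.n_atoms)
    prot_resids = system.resids[protein]
    max_resid = int(prot_resids.max()) if protein.size else 0

    atoms: dict[str, np.ndarray] = {}
    intervals: dict[str, tuple[int, int]] = {}
    for name, bounds in cfg["regions"].items():
        lo, hi = int(bounds[0]), int(bounds[1])
        if lo < 1 or hi > max_resid or lo > hi:
            raise RegionConfigError(
                f"region {name!r} interval [{lo}, {hi}] outside residues [1, {max_resid}]"
            )
        mask = (prot_resids >= lo) & (prot_resids <= hi)
        atoms[name] = protein[mask]
        intervals[name] = (lo, hi)

    phos_name = cfg["phosphate_name"]
    non_protein = np.setdiff1d(np.arange(system.n_atoms), protein, assume_unique=False)
    phosphates = non_protein[system.names[non_protein] == phos_name]

    pattern = re.compile(cfg["anchor_carbon_pattern"])
    if "anchor_cys" in atoms:
        cand = atoms["anchor_cys"]
        mask = np.array([bool(pattern.fullmatch(n)) for n in system.names[cand]])
        anchor_carbons = cand[mask] if cand.size else cand
    else:
        anchor_carbons = np.array([], dtype=int)

    return RegionSet(
        atoms=atoms,
        residue_regions=intervals,
        membrane_phosphates=phosphates,
        anchor_carbons=anchor_carbons,
        protein_atoms=protein,
    )
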