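"""End-to-end pipeline: generate (or load) -> analyze -> report.

A run is fully determined by its config and seed: every stage consumes the
same trajectory, stage outputs land in a fixed file layout, and replicate
runs draw child seeds from the master seed. The headline summary in
``report.json`` (orientation fractions, depth mean +/- sd, switch SASA,
RMSD plateau) is recomputable from the stage CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitfluct import rmsd_series, rmsf_per_residue
from .membrane import depth_series, depth_summary, residue_distance_profile
from .orientation import orientation_records, population_summary
from .sasa import SasaConfig, region_sasa_total, trajectory_sasa
from .structio import (
    DEFAULT_REGION_CONFIG,
    MolecularSystem,
    RegionSet,
    Trajectory,
    read_structure,
    read_trajectory,
    resolve_regions,
    write_table,
)
from .synthetic import SyntheticRun, synthesize

logger = logging.getLogger("memborient")

#: production protocol emulated by the replicate machinery: three
#: independent runs of 450 ns each per activation state
N_REPLICAS = 3
RUN_LENGTH_NS = 450.0


def production_time_us(n_runs: int = N_REPLICAS,
                       run_length_ns: float = RUN_LENGTH_NS) -> float:
    """Total production simulation time per state, in microseconds."""
    return n_runs * run_length_ns / 1000.0


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    state: str = "gdp"  # activation-state preset (synthetic mode)
    n_frames: int = 300
    seed: int = 0
    replicates: int = 1
    structure_path: str | None = None  # files mode
    trajectory_path: str | None = None
    trajectory_format: str = "xtc"
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGION_CONFIG))
    plane_mode: str = "box-z"
    lateral_cutoff: float = 1.0  # nm
    probe_radius: float = 1.4  # Å
    sasa_points: int = 960
    sasa_stride: int = 0  # 0 -> auto (~25 frames)
    skip_fraction: float = 0.1  # equilibration window dropped from averages
    outdir: str = "memborient_run"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files" and not (self.structure_path and self.trajectory_path):
            raise ValueError("files mode needs structure_path and trajectory_path")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if "regions" in self.regions:  # normalize intervals for YAML round trips
            self.regions = {
                **self.regions,
                "regions": {k: [int(v[0]), int(v[1])]
                            for k, v in self.regions["regions"].items()},
            }

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        """Hash of the scientific content of the config (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failed; the partial manifest records where."""


def _load_inputs(config: RunConfig, seed: int
                 ) -> tuple[MolecularSystem, Trajectory, RegionSet, dict]:
    if config.mode == "synthetic":
        run: SyntheticRun = synthesize(
            state=config.state, n_frames=config.n_frames, seed=seed)
        extra = {"membrane_summary": run.membrane_summary,
                 "truth_available": True}
        return run.system, run.trajectory, run.regions, extra
    system, _ = read_structure(config.structure_path)
    traj = read_trajectory(config.trajectory_path, config.trajectory_format,
                           system)
    regions = resolve_regions(system, config.regions)
    return system, traj, regions, {}


def _analyze(system: MolecularSystem, traj: Trajectory, regions: RegionSet,
             config: RunConfig, outdir: Path) -> dict:
    """Run every analysis stage on one trajectory; returns the summary."""
    outdir.mkdir(parents=True, exist_ok=True)
    skip = int(round(config.skip_fraction * traj.n_frames))
    manifest: dict[str, str] = {}
    t_start = time.time()

    g_ca = regions.ca_atoms(system, "g_domain")
    prot_ca = regions.protein_atoms[system.names[regions.protein_atoms] == "CA"]

    # -- RMSD / RMSF ------------------------------------------------------
    series = rmsd_series(traj, g_ca, reference_frame=0)
    fluct = pd.DataFrame({"frame": np.arange(traj.n_frames), "rmsd": series})
    write_table(fluct, outdir / "fluct.csv")
    manifest["fluct"] = "fluct.csv"
    plateau = float(series[skip:].mean()) if traj.n_frames > skip else float("nan")

    resids, rmsf = rmsf_per_residue(traj, system, g_ca, rmsf_idx=prot_ca,
                                    skip_frames=skip)
    write_table(pd.DataFrame({"residue": resids, "rmsf": rmsf}),
                outdir / "rmsf.csv")
    manifest["rmsf"] = "rmsf.csv"

    # -- membrane proximity ----------------------------------------------
    profile = residue_distance_profile(
        traj, system, regions.protein_atoms, regions.membrane_phosphates,
        mode=config.plane_mode)
    write_table(profile.to_frame(), outdir / "distances.csv")
    manifest["distances"] = "distances.csv"

    depths = depth_series(traj, regions.anchor_carbons,
                          regions.membrane_phosphates, config.lateral_cutoff)
    dsum = depth_summary(depths[skip:] if len(depths) > skip + 8 else depths)
    write_table(dsum, outdir / "depth.json")
    manifest["depth"] = "depth.json"

    # -- orientation ------------------------------------------------------
    records = orientation_records(traj, system, regions)
    write_table(records, outdir / "orientation.csv")
    manifest["orientation"] = "orientation.csv"
    pops = population_summary(records.iloc[skip:] if len(records) > skip + 1
                              else records)
    write_table(pops, outdir / "populations.json")
    manifest["populations"] = "populations.json"

    # -- SASA -------------------------------------------------------------
    stride = config.sasa_stride or max(1, (traj.n_frames - skip) // 25)
    sasa_cfg = SasaConfig(probe_radius=config.probe_radius,
                          n_points=config.sasa_points)
    table, per_frame = trajectory_sasa(
        traj, system, atom_idx=regions.protein_atoms, config=sasa_cfg,
        skip_frames=skip, stride=stride)
    write_table(table, outdir / "sasa.csv")
    manifest["sasa"] = "sasa.csv"
    totals = region_sasa_total(per_frame.mean(axis=0), regions,
                               region_names=["switch1", "switch2", "g_domain"],
                               atom_idx=regions.protein_atoms)
    switch_norm = table[
        table["residue"].isin(_switch_residues(regions))]["normalized"]

    summary = {
        "rmsd_plateau_nm": plateau,
        "depth_mean_nm": dsum["mean"],
        "depth_sd_nm": dsum["sd"],
        "fractions": pops["fractions"],
        "theta_mean_deg": pops["theta_mean"],
        "phi_circmean_deg": pops["phi_circmean"],
        "switch_sasa_nm2": totals["switch_total"],
        "protein_sasa_nm2": totals["all"],
        "switch_normalized_sasa_mean": float(switch_norm.mean()),
        "n_frames": traj.n_frames,
        "skip_frames": skip,
    }
    logger.info("stages finished in %.1f s", time.time() - t_start)
    return {"manifest": manifest, "summary": summary}


def _switch_residues(regions: RegionSet) -> list[int]:
    out: set[int] = set()
    for name in ("switch1", "switch2"):
        lo, hi = regions.residue_regions[name]
        out.update(range(lo, hi + 1))
    return sorted(out)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages for every replicate; returns the run report.

    Child seeds are spawned deterministically from the master seed. With
    one replicate the stage files land directly in the output directory;
    with more, each replicate gets a ``repNN/`` subdirectory and the report
    carries the pooled (averaged) summary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(config.seed).spawn(config.replicates)]
    if config.replicates == 1:
        seeds = [config.seed]

    replica_reports = []
    manifest: dict = {"config": "config.yaml"}
    try:
        for i, seed in enumerate(seeds):
            rep_dir = outdir if config.replicates == 1 else outdir / f"rep{i + 1:02d}"
            logger.info("replicate %d/%d (seed %d)", i + 1, len(seeds), seed)
            system, traj, regions, extra = _load_inputs(config, seed)
            result = _analyze(system, traj, regions, config, rep_dir)
            result["seed"] = seed
            result.update(extra)
            replica_reports.append(result)
            prefix = "" if config.replicates == 1 else f"rep{i + 1:02d}/"
            for key, fname in result["manifest"].items():
                manifest[f"{key}_{i + 1}" if config.replicates > 1 else key] = \
                    prefix + fname
    except Exception as exc:
        report = {
            "version": __version__,
            "config_hash": config.digest(),
            "seed": config.seed,
            "failed": True,
            "error": f"{type(exc).__name__}: {exc}",
            "manifest": manifest,
            "replicates": replica_reports,
        }
        write_table(report, outdir / "report.json")
        raise PipelineError(str(exc)) from exc

    pooled = _pool([r["summary"] for r in replica_reports])
    report = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "state": config.state if config.mode == "synthetic" else "files",
        "failed": False,
        "manifest": manifest,
        "summary": pooled,
        "replicates": replica_reports,
        "regions": {k: list(v) for k, v in
                    (config.regions.get("regions")
                     or DEFAULT_REGION_CONFIG["regions"]).items()},
    }
    write_table(report, outdir / "report.json")
    return report


def _pool(summaries: list[dict]) -> dict:
    """Average replicate summaries (final per-replica values, then mean)."""
    if len(summaries) == 1:
        return dict(summaries[0])
    pooled: dict = {}
    for key in summaries[0]:
        vals = [s[key] for s in summaries]
        if key == "fractions":
            pooled[key] = {lab: float(np.mean([v[lab] for v in vals]))
                           for lab in vals[0]}
        elif isinstance(vals[0], (int, float)) and key not in ("n_frames", "skip_frames"):
            pooled[key] = float(np.mean(vals))
        else:
            pooled[key] = vals[0]
    return pooled


HEADLINE_KEYS = [
    "rmsd_plateau_nm", "depth_mean_nm", "depth_sd_nm", "theta_mean_deg",
    "phi_circmean_deg", "switch_sasa_nm2", "protein_sasa_nm2",
    "switch_normalized_sasa_mean",
]


def compare_states(report_a: dict, report_b: dict) -> pd.DataFrame:
    """Side-by-side comparison of two run reports (e.g. GDP vs GTP presets)."""
    if report_a.get("regions") != report_b.get("regions"):
        raise ValueError("reports use different region configs; not comparable")
    rows = []
    sa, sb = report_a["summary"], report_b["summary"]
    for lab in ("syn", "anti", "intermediate"):
        rows.append({"metric": f"fraction_{lab}",
                     "a": sa["fractions"][lab], "b": sb["fractions"][lab],
                     "diff": sa["fractions"][lab] - sb["fractions"][lab]})
    for key in HEADLINE_KEYS:
        rows.append({"metric": key, "a": sa[key], "b": sb[key],
                     "diff": sa[key] - sb[key]})
    return pd.DataFrame(rows)


def load_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
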