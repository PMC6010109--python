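# memborient

Membrane-orientation analysis of lipid-anchored small GTPases.

Peripheral membrane proteins of the Ras superfamily — Rab5 is the system
this package is built around — attach to bilayers through C-terminal
lipid anchors, and their catalytic G domain then tilts and rotates on the
membrane surface. Whether the nucleotide-sensitive switch regions end up
facing the membrane ("syn", buried, effector-inaccessible) or the solvent
("anti", accessible) depends on the activation state, and quantifying
that from trajectories takes a small zoo of observables. `memborient`
computes all of them behind one pipeline:

* **Distance maps** — per-residue signed z-distance between each residue's
  centre of mass and the proximal phosphate plane (negative = inserted).
* **Anchor insertion depth** — mean z of the phosphates laterally
  neighbouring the anchor minus the deepest anchor-chain carbon, with
  mean/sd, Shapiro–Wilk normality and a histogram over the trajectory.
* **Orientation** — the pivot angle θ = arccos(**n**·**G**) between the
  membrane normal **n** and the G-domain long axis **G** (θ = 90° means
  the domain lies parallel to the surface), and the torsion φ of the
  switch-position vector **S** about **G** measured from **n**
  (φ = 180° is syn — switches facing the membrane; φ ≈ 0°/360° is anti),
  with per-frame syn/anti/intermediate labels and circular population
  statistics.
* **SASA** — Shrake–Rupley solvent-accessible surface area (1.4 Å probe,
  deterministic spiral point sets), normalized per residue by its maximum
  accessibility in an extended Gly-X-Gly tripeptide, plus region totals
  in nm² with lipids acting as occluders.
* **RMSD/RMSF** — Kabsch superposition of the G-domain Cα atoms onto a
  reference frame, per-frame RMSD and per-residue fluctuation about the
  mean structure.

Because µs-scale production trajectories of such systems are rarely
shareable, the package also ships a **synthetic trajectory generator**: a
215-residue Cα-resolution protein with two 20-carbon geranylgeranyl
pseudo-chains on a symmetric six-lipid early-endosome model bilayer
(POPC/CHOL/PSM/POPE/POPS/PI(3)P, 505 lipids per leaflet, 16.9 × 16.6 nm),
rigid-body posed frame by frame with θ, φ and insertion depth drawn from
prescribed distributions. The sampled values are returned as ground
truth, so every analyzer can be tested for exact recovery; GDP-like and
GTP-like presets encode the two activation states' orientation
populations and depths. See `docs/methods.md` for the model and all
numerical conventions.

## Worked example

Run the two activation-state presets and compare them:

```bash
memborient run --state gdp --frames 200 --seed 1 --outdir runs/gdp
memborient run --state gtp --frames 200 --seed 1 --outdir runs/gtp
memborient compare runs/gdp/report.json runs/gtp/report.json
```

The first command prints (exact numbers for `--seed 1`):

```
  rmsd_plateau_nm: 0.23190361627398712
  depth_mean_nm: 1.7434357367896585
  depth_sd_nm: 0.0954619854290967
  fractions: {'syn': 0.494..., 'anti': 0.022..., 'intermediate': 0.483...}
  theta_mean_deg: 94.2486803500989
  phi_circmean_deg: 132.2130811141976
  switch_sasa_nm2: 15.399301034543221
  protein_sasa_nm2: 86.09483631386016
  switch_normalized_sasa_mean: 0.3406925007642306
```

and the comparison table ends with:

```
                     metric          a          b        diff
               fraction_syn   0.494444   0.000000    0.494444
              fraction_anti   0.022222   0.755556   -0.733334
            rmsd_plateau_nm   0.231904   0.170962    0.060942
              depth_mean_nm   1.743440   1.713820    0.029620
switch_normalized_sasa_mean   0.340693   0.348475   -0.007782
```

Reading it: the GDP-like run spends half its frames in the syn
orientation (the 190° torsion population) and essentially never in anti,
while the GTP-like run is three-quarters anti and never syn; the anchor
sits ~1.74 vs ~1.71 nm deep; the G-domain RMSD plateaus near 0.23 vs
0.17 nm; and the switch regions are slightly less solvent-accessible in
the GDP-like run, where the syn pose buries them against the bilayer.
Each run directory holds the full stage outputs (`fluct.csv`, `rmsf.csv`,
`distances.csv`, `depth.json`, `orientation.csv`, `populations.json`,
`sasa.csv`, `report.json`) — re-running with the same config and seed
reproduces them byte for byte.

The same stages run on your own files:

```bash
memborient orient --structure system.pdb --trajectory traj.xtc
memborient membrane --structure system.pdb --trajectory traj.xtc --cutoff 1.0
memborient sasa --structure system.pdb --trajectory traj.xtc --probe 1.4
```

or from Python via `memborient.synthesize`, `orientation_records`,
`depth_series`, `trajectory_sasa`, `rmsd_series` etc.

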