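# Methods

## Scope and model system

`memborient` analyses how a lipid-anchored small GTPase sits on a membrane.
The concrete system it is built around is Rab5: a 215-residue protein whose
catalytic G domain (residues 15–184) carries the nucleotide-sensitive
switch I (44–66) and switch II (75–91) loops, a ~30-residue hypervariable
C-terminal linker (HVR, 185–211), and two geranylgeranyl (GG) 20-carbon
chains attached to Cys212/Cys213 that insert into the bilayer. The package
computes, over a trajectory of such a system:

* per-residue signed z-distances to the proximal phosphate plane
  (distance maps),
* the GG-anchor insertion depth below the local phosphate plane,
* two orientation observables — the pivot angle θ between the membrane
  normal **n** and the G-domain direction vector **G**, and the torsion φ
  of the switch-position vector **S** about **G** measured from **n** —
  with syn/anti classification,
* Shrake–Rupley solvent-accessible surface area (SASA), normalized per
  residue against Gly-X-Gly tripeptide reference areas, and
* RMSD/RMSF after Kabsch superposition of the G-domain Cα atoms.

All lengths are handled internally in nm (PDB Å converted on read); SASA is
computed in Ų and region totals reported in nm² (1 nm² = 100 Ų). Residue
numbers are 1-based; atom indices 0-based.

## Orientation observables

**G** is the principal axis of largest variance (longest geometric axis) of
the G-domain Cα cloud. The axis itself is sign-ambiguous; the convention
used by `orientation_records` is: at frame 0 the axis points away from the
membrane (positive dot with +z, matching an upright starting pose), the Cα
quartile at the far end of that axis is then remembered as a structural
reference group, and in every frame the axis is oriented toward that
group's centroid. For a continuous trajectory this is equivalent to
chaining the sign frame-to-frame, but it remains correct when consecutive
frames are orientationally far apart (as in resampled or subsampled data),
where a frame-to-frame chain can lock into a mirrored branch after a
single >90° jump. A near-spherical Cα cloud (two largest principal
eigenvalues within 1%) makes the direction ill-defined and raises an error.

**S** points from the G-domain Cα centroid to the combined
switch I + switch II Cα centroid. Projecting out the component along **G**
is unnecessary because the torsion is computed about **G**.

θ = arccos(**n**·**G**) ∈ [0°, 180°]; 90° means the domain lies parallel
to the membrane surface. φ is the four-point dihedral over
(p+**n**, p, p+**G**, p+**G**+**S**) mapped to [0°, 360°): φ = 180° when
**S** points straight at the membrane (the "syn" switch orientation),
φ near 0°/360° when the switches are solvent-exposed ("anti"). Frames
where **G** is within 0.5° of **n** or of **S** have undefined torsion;
they are flagged and excluded from population statistics rather than
failing the run. Classification windows: syn for φ ∈ [120°, 240°] (closed),
anti for φ < 60° or φ > 300° (open), intermediate otherwise; the anchor
values are the geometric ones (180° exactly syn, 0° exactly anti), the
window widths are package choices and configurable. Circular statistics
(circular mean/σ) are used for φ; θ lives on the bounded interval
[0°, 180°] and gets ordinary moments.

The membrane normal defaults to the box z-axis (appropriate for a planar,
equilibrated bilayer); a least-squares plane-fit mode exists for tilted
fixtures.

## Membrane proximity

Phosphate atoms are split into leaflets about their median z; the upper
(protein-side) leaflet's mean z is the reference plane. Residue–membrane
distance is z(residue centre of mass) − mean z(upper phosphates), negative
below the plane. Residue centres are mass-weighted by default (a
geometric-centre flag exists; the two coincide on Cα-only models).

Anchor insertion depth = mean z of upper-leaflet phosphates within a
1.0 nm lateral cutoff of the anchor carbons' lateral centroid, minus the
minimum z over the anchor carbons; positive = inserted. The local cutoff
models "the neighbouring lipid P atoms"; when no phosphate falls inside
the cutoff the whole upper leaflet is used and a warning logged. For
exactly coplanar phosphates the local and global definitions coincide.
Depth series are summarised by mean, sd, a Shapiro–Wilk normality test
(reported as undefined below 8 samples or for constant series) and an
equal-width histogram.

No periodic-image handling is done in z: the protein is assumed whole and
on one side of the bilayer, which the generator guarantees and typical
production setups satisfy after unwrapping.

## Superposition and fluctuations

Kabsch superposition is the SVD solution with the reflection branch forced
to a proper rotation (det = +1); degenerate inputs (< 3 points, collinear
sets) raise. Unit weights are the default for Cα selections;
mass-weighting is available. RMSD is reported per frame after fitting the
selection onto a reference frame. RMSF is computed about the *mean*
superposed position (not the reference frame): after fitting every frame
onto the reference on the fit selection, rmsf_i = √⟨|r_i(t) − ⟨r_i⟩|²⟩,
averaged within residues. The first 10% of frames are treated as an
equilibration window and excluded from plateau/RMSF averages by default
(`skip_fraction`). When several replicates are run, per-replica RMSF
profiles are computed first and averaged afterwards.

## SASA

Shrake–Rupley with a deterministic generalized-spiral (golden-angle) point
set — no RNG, so results are bit-reproducible — at 960 points/atom and a
1.4 Å probe by default. A point on atom i's expanded sphere (r_i + probe)
is buried if strictly inside any neighbour's expanded sphere; neighbours
come from a k-d tree query. Van der Waals radii come from a packaged
Bondi-style element table (the table is swappable; normalized values are
only comparable within one radii set). Per-residue areas are divided by
the residue's maximum accessibility in an extended Gly-X-Gly tripeptide
(packaged Miller-style reference areas, Ų); values slightly above 1 are
reported as computed. Residues without a reference entry (the
GG-modified cysteines, pseudo-residues) are flagged and left
unnormalized. On trajectories, per-residue areas are averaged over frames
after the skip window, optionally strided (the pipeline default samples
~25 frames). Lipid atoms are included as occluders, so membrane burial of
switch residues shows up in the normalized values.

Numerical behaviour: an isolated sphere reproduces the analytic area to
<0.5% at 960 points; agreement with a 10⁶-point Monte-Carlo surface
integration is within 2% on small clusters. Because the spiral point set
is anisotropic, totals vary by up to ~1% under rigid rotation at 960
points (~0.2% at 3840), and per-atom areas of strongly buried atoms
converge in absolute rather than relative terms as the point count grows.

## Synthetic trajectory generator

The generator replaces unavailable production MD with a pseudo-atomic
stand-in whose *statistics* are prescribed, so analyzers can be tested for
exact recovery.

**Protein fixture** (Cα + bead resolution): the G domain is 170 Cα
pseudo-atoms on a 2:1 prolate ellipsoid (semi-axes 2.2/1.1 nm) via a
Fibonacci spiral, with the 40 switch residues assigned to the +x face;
the N-terminus (1–14) and HVR (185–211) are self-avoiding biased random
walks with 0.38 nm steps; residues 212/213 each carry a 20-carbon GG
pseudo-chain extending downward; a 2-residue C-tail follows. Cα spheres
carry inflated 3.3 Å radii so Cα-only burial patterns are non-trivial for
SASA; every other observable needs only Cα/P/anchor-carbon positions,
which is why an all-atom model would add nothing the analyses can see.
All protein residues are labelled ALA (the reference-area contract is
tested separately with synthetic tables); the anchor cysteines are
labelled CYG and deliberately absent from the reference table.

**Membrane fixture**: a symmetric bilayer with per-leaflet composition
POPC 90, CHOL 150, PSM 50, POPE 135, POPS 55, PI(3)P 25 (505 lipids per
leaflet) on a 16.9 × 16.6 nm jittered grid — the early-endosome model
composition. Each lipid is a head particle (phosphate "P"; cholesterol
gets "O3" instead, so it never enters phosphate-plane fits) at
±thickness/2 plus two tail beads toward the midplane. The
phosphate-plane-to-phosphate-plane thickness defaults to 4.0 nm, a
typical P–P distance for such mixtures; positional jitter σ = 0.1 nm.
The build summary reports realized area per lipid (lateral area / 505)
and realized P–P thickness, standing in for the usual equilibration
monitoring. Lipids do not diffuse and the membrane has no undulations —
the membrane is static scaffolding for the protein's rigid-body motion.

**Trajectory**: frame 0 is the upright start (θ = 0, domain axis along
the normal). Each later frame draws θ and φ from wrapped-Gaussian
mixtures, poses the G domain (+ N-terminus) rigidly at that orientation
above the membrane with a 0.5 nm clearance between its lowest atom and
the phosphate plane, draws an insertion depth from N(mean, σ), pins the
anchor block under the domain with the deepest GG carbon at that depth
below the *local* phosphate plane, linearly interpolates the HVR between
Cα184 and Cα212, and finally adds isotropic Gaussian thermal noise
(extra noise on switch residues). After noise the anchor minimum is
re-pinned against the local plane defined by the *noised* carbon
centroid, so the sampled depth is exactly the quantity the depth analyzer
measures; without the re-pin, the minimum over 40 noisy carbons would be
biased deep by roughly two thermal σ and the sampled depths would stop
being ground truth. θ samples are folded onto [0°, 180°] and kept 1° away
from the poles so the torsion stays defined. Everything is a pure
function of (spec, params, seed).

**Presets** encode the two activation states. GDP-like (inactive):
θ ~ N(95°, 7.5°) (covering the observed 80–110° band), φ an equal-weight
mixture at 80° and 190° (σ = 10°), depth N(1.74, 0.10) nm. GTP-like
(active): θ ~ N(115°, 25°) (broad, ~50–180°), φ an equal-weight mixture
at 45° and 320° (σ = 20°, i.e. the solvent-exposed 0–90°/280–360°
windows), depth N(1.71, 0.10) nm. Only the population locations, θ ranges
and depth means are literature-anchored; component σ's, weights and the
depth σ are package choices (no variances are published for these
distributions). Thermal noise σ (0.090 nm GDP-like / 0.066 nm GTP-like,
switch extra 0.050/0.040 nm) is calibrated so the G-domain RMSD plateaus
near 0.24 / 0.17 nm: with both the frame and the reference carrying
independent noise, the plateau is ≈ √(6σ² + 6σ_sw²·f_sw) with f_sw the
switch fraction of fitted atoms.

**What the generator does and does not emulate.** It reproduces the
*observables'* statistics — orientation populations, depth distribution,
fluctuation magnitudes, membrane burial of the switch face — not the
physics behind them: there is no force field, no correlated dynamics
(frames are i.i.d. draws), no internal G-domain deformation, no lipid
motion, no nucleotide atoms (activation state is a preset label). Tests
passing on synthetic data therefore validate the *analysis machinery*
(geometry, statistics, bookkeeping, recovery of known ground truth), not
any claim about real membrane–protein systems.

## Pipeline and reproducibility

`run_pipeline` executes RMSD/RMSF → distance map → insertion depth →
orientation → SASA on one trajectory (synthetic or loaded from
PDB + DCD/XTC/multi-model-PDB files) and writes a fixed layout:
`config.yaml, fluct.csv, rmsf.csv, distances.csv, depth.json,
orientation.csv, populations.json, sasa.csv, report.json`. Replicates
draw child seeds from the master seed (SeedSequence spawning, kept below
2³¹); per-replica outputs go to `repNN/` subdirectories and the report
pools final per-replica summaries. Config + seed determine every output
byte (the one exception is the output path recorded inside
`config.yaml`); floats are written at 6 significant digits. A stage
failure halts the run and leaves a partial manifest with the error in
`report.json`.

Default problem sizes (300 frames per run, ~25 SASA frames, 960 sphere
points) keep a full two-state comparison in the few-minute range on one
core while leaving all estimators comfortably inside their statistical
tolerances; every size is a config field.

## Known limitations

* The exact atoms defining **G** and **S** in published analyses of this
  kind vary; results here are reported under the definitions above, and
  normalized SASA values are only comparable within one radii/reference
  set.
* The N-terminal numbering relative to deposited G-domain crystal
  structures is not standardized; the default region config assumes
  uniform 1–215 numbering.
* The distance map uses the upper-leaflet mean plane, not a local plane
  per residue; only the anchor depth uses a local plane.
* `files` mode expects whole (unwrapped) proteins on one side of the
  bilayer and orthorhombic boxes.
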