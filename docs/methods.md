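# Methods

lipidmap maps state-dependent protein–lipid interactions around a pentameric
ligand-gated ion channel (pLGIC) embedded in an asymmetric membrane: which
lipid species accumulate where around the receptor, for how long individual
lipids stay bound to each residue, and how both change between the inactive
(closed) and active (open) conformational states.  The package analyzes
coarse-grained coordinate/trajectory files (GRO/PDB + XTC/DCD) and ships a
synthetic membrane + toy lipid-dynamics generator with planted ground truth,
so every statistic can be validated against known answers.

## The membrane model

The default composition is a five-species simplification of a human neuronal
plasma membrane, asymmetric across leaflets (mole percents):

| species | extracellular | intracellular |
|---------|--------------:|--------------:|
| POPC    | 24.4          | 13.7          |
| POPE    | 11.1          | 21.5          |
| DOPS    | 0             | 16.9          |
| SM      | 19.9          | 3.0           |
| CHOL    | 44.7          | 44.9          |

Counts are apportioned per type by round-half-up,
`count_i = round(percent_i × n / 100)`.  We chose this rule over
largest-remainder normalization because the extracellular column sums to
100.1%, and per-type rounding reproduces the printed one-decimal mole
percents exactly (at a nominal 1000 lipids per leaflet the extracellular
leaflet holds 1001 lipids, 44.7% of them cholesterol).  Leaflet totals are
therefore allowed to deviate from the nominal count.

Lipids are placed uniformly at random in their leaflet's plane (minimum
spacing 0.45 nm, excluded from a disc around the protein), with anchor-bead
z at the leaflet plane ±1.8 nm from the midplane plus Gaussian noise
(σ = 0.05 nm).  Each lipid is a small rigid bead cluster in Martini-style
naming: choline/ammonium headgroup bead (NC3/NH3), phosphate (PO4), two tail
beads for phospholipids; hydroxyl (ROH) plus two tail beads for cholesterol.
The simulation cell is a hexagonal prism, represented as a triclinic lattice
with vectors (a,0,0), (−a/2, a√3/2, 0), (0,0,c); all wrapping and
minimum-image arithmetic use this basis.

## The pentamer model

The protein is a static, exactly C5-symmetric pseudo-pentamer: five
identical subunits, each built from four straight transmembrane
pseudo-helices at α-helical residue rise (19 residues over the 2.8 nm TM
span, ≈0.15 nm/residue) — a pore-lining inner helix (M2-like, r = 1.0 nm),
two middle helices (M1/M3-like, r = 1.6 nm, ±20° from the subunit axis) and
a lipid-facing outer helix (M4-like, r = 2.2 nm).  Each residue carries a
backbone and a sidechain bead.  Straight helix columns matter for the
contact statistic: a lipid bound at the protein surface must face protein
beads at every depth in the membrane, otherwise continuous contacts break on
bead-geometry artifacts rather than on actual unbinding.  Subunits B–E are
exact 72° rotations of subunit A, so the C5 deviation of the model is at
machine precision.  The protein never moves during the toy dynamics,
emulating position-restrained production runs; the two conformational states
differ only through which planted binding sites are available, never through
protein coordinates.

Because GRO files carry no chain identifiers, subunit identity is encoded in
residue numbering (`resid = subunit_index × 1000 + local_index`); PDB export
carries chain IDs A–E.

## Toy lipid dynamics

Lipids undergo overdamped Brownian motion in the membrane plane:

    x(t+dt) = x(t) + D F(x) dt + √(2 D dt) ξ,  F = −∇U,
    U(x) = − Σ_s depth_s · exp(−|x − x_s|² / (2 width_s²)),

with energies in kT units at an implicit single temperature (no thermostat
concept).  Each planted site is restricted to one lipid type, one leaflet
and a set of states; wedge-anchored sites (subunit interfaces) replicate
five-fold so the planted truth stays C5-symmetric.  A hard reflective disc
(default radius 1.4 nm) around the pore axis stands in for the protein's
excluded volume.  Cholesterol flips between leaflets as a Poisson process
(default rate 10⁻⁴ events/ns per molecule) implemented as an instantaneous
z-teleport to the other leaflet plane — only the fact of exchange is
modelled, not transit kinetics.  Other species never change leaflet.
z-coordinates are otherwise static; the model has no undulations, curvature,
solvent or force-field realism.

Default lateral diffusion is 0.005 nm²/ns (5 µm²/s, the order observed for
coarse-grained lipids).  The integrator refuses steps whose RMS displacement
exceeds half the narrowest site width.  Randomness is one counter-based
Philox stream per molecule keyed by (seed, molecule id), so changing the
molecule count does not reshuffle the noise of unrelated molecules, and
identical seeds give bit-identical trajectories.

A Monte-Carlo residence oracle provides ground truth for contact-duration
recovery: a single lipid starts at a site anchor and diffuses in the
isolated site potential until it first leaves twice the site width.  At zero
depth it agrees with an independent free random walk, and it scales as 1/D.

## Analysis protocol

Frames are analyzed over the last half of each run at 10 ns spacing (the
standard production protocol this package targets: last 20 µs of 40 µs,
dt = 10 ns, 10 repeats per state, 5-subunit averaging).  The window keeps
frames with `t > (1 − last_fraction) · T_end` — half-open, so a frame
exactly at the boundary is excluded — then subsamples from the first kept
frame; a 40 µs run at 10 ns spacing windowed at 0.5 yields exactly 2000
frames on (20 µs, 40 µs].

**Leaflet assignment.**  Per frame, the midplane z* is the mean z of all
lipid anchor beads (phosphate for phospholipids, hydroxyl for cholesterol);
a lipid is extracellular iff its anchor sits above z*.  Assignments may
change across frames (flip-flop).

**Densities.**  2D leaflet densities count one anchor bead per molecule per
frame into bins (default 0.2 nm); 3D densities bin selected beads (default
voxel 0.1 nm) with selectors for cationic-headgroup, phosphate, hydroxyl and
tail beads.  Units are absolute time-averaged number densities
(molecules/nm² and molecules/nm³); a probability-density color map is a
normalization of the same field.  Every grid satisfies
`Σ values × cell_volume = time-averaged selected count` to machine
precision.  Grid extents derive from the box alone (padded by 0.6 nm for
beads of molecule-whole-wrapped lipids that overhang the cell), so grids
from different repeats and states are commensurate by construction and can
be subtracted exactly.

**Equal-composition isovalue reweighting.**  To compare species of very
different abundance on one figure, each species' isosurface is drawn at
`reference_iso × fraction × n_types`, i.e. as if the membrane consisted of
equal amounts of each lipid type.  A species at exactly 1/n_types abundance
keeps the reference isovalue; a 44.8% cholesterol shown at reference 6.7
molecules/nm³ is drawn at 15 molecules/nm³.

**C5 symmetrization and deviation.**  Around a C5-symmetric receptor the
converged densities must be five-fold symmetric, so the distance from
symmetry is a convergence diagnostic.  We implement symmetrization as an
exact orbit-average projection: grid cells are keyed by (z slice, radial
bin, angular bin within a 72° sector) about the pore axis and each orbit is
replaced by its mean.  We chose this over rotation + interpolation averaging
because a projection is exactly idempotent and mass-conserving — the
deviation of a symmetrized grid is zero at machine precision — whereas
repeated interpolation is not.  The price is bin-level granularity: sector
masses of a symmetrized feature agree to ~5% at default resolution.  The
deviation metric is the normalized L1 distance `Σ|g − S(g)| / (2 Σ g)`
∈ [0, 1]: 0 for symmetric grids, 0.8 for mass confined to a single sector.
Averaging repeats reduces sampling noise, so the deviation of a repeat-mean
grid falls below the median single-repeat deviation — the package's
quantitative form of the visual per-repeat convergence check.

**Contact durations.**  A residue and a lipid molecule are in contact in a
frame when any bead of one lies within 0.6 nm (the first lipid shell) of any
bead of the other, under minimum-image distances.  A continuous contact is a
maximal run of consecutive contact frames; a single non-contact frame ends a
run (an optional gap tolerance exists but defaults to 0, the literal
reading of "continuous").  Runs touching the window edges count at their
observed length; no censoring correction is applied and the choice is
recorded in the table metadata so the (downward) bias on long contacts is
auditable.  Per (residue, lipid type), event durations are pooled across
molecules, repeats and — by default — the five aligned subunit copies, and
the mean is over pooled events, weighting evidence by event count;
per-molecule mean-of-means averaging is available behind a flag.  Occupancy
is the fraction of frames with at least one molecule of the type in
contact.  The accelerated distance search uses a neighbor-grid method
(float32); the brute-force all-pairs scan is retained as the test oracle.
Lipid types are ranked by the maximum per-residue mean duration or by the
mean of the top-20 residues.

**Site overlap and state contrasts.**  Ligand sites come from user-supplied
reference structures (e.g. an allosteric-modulator pose between the (+)M3
and (−)M1 helices, or an anionic-lipid pocket) already registered to the
trajectory frame — the package validates overlap but performs no structural
alignment.  Site regions are vertical cylinders (in-plane distance to any
ligand atom ≤ radius, default 0.7 nm, within the z slab spanned by the
ligand): in a thin-slab toy membrane a spherical region would weight voxel
layers unequally in z and bias the enrichment of even a laterally uniform
density by ~1.5×, while the cylinder makes uniform lateral density score
exactly 1.  The bulk reference shares the slab, lies beyond twice the
protein footprint radius from the pore axis, and is clipped to the periodic
cell (the grid's bounding rectangle has empty corners outside the hexagonal
cell that would otherwise dilute the bulk mean).  Enrichment is mean site
density over mean bulk density; the site integral is also reported in
molecules.  Interface penetration depth is `R_footprint − r_min` per 72°
wedge, where r_min is the smallest radius at which wedge density exceeds a
threshold; state pairs share one threshold (25% of the wedge-density
maximum across the pair, a half-max-style criterion robust to Poisson noise
in sparse voxels).

## Validation scenarios (planted truth)

The scenarios in `lipidmap.scenarios` fix the study conditions used by the
test-suite and the acceptance script; their parameters were set once from
the considerations below and are not tuned per run.

* Geometry: hexagonal cell a = 11 nm, c = 6 nm; 150 lipids per leaflet
  (≈10⁵ analyzed lipid-frames per run at 660 frames of 10 ns); integration
  step 0.5 ns.
* **Hierarchy recovery**: annular sites on each subunit's outer helix
  (radius 2.45 nm, width 0.25 nm) with depths CHOL 6 kT > PS 4 kT >
  PC = PE = SM 1 kT.  Narrow wells centered on the lipid-facing helix keep a
  bound lipid well inside the contact shell, so measured contact durations
  track well depth (≈320, 100 and 35 ns respectively) instead of saturating
  at the local dwell time.  Recovery means CHOL first and PS second by both
  ranking statistics, in 3/3 seeds.
* **State dependence**: one interface CHOL site (wedge-anchored, depth 6 kT,
  width 0.35 nm, radius 1.8 nm) available only in the active state; paired
  common-seed runs give site enrichment ≈20–30 (active) versus ≈0.5–0.9
  (inactive) and mean penetration depth ≈0.7 nm versus 0.
* **C5 convergence**: ten short repeats of a symmetric interface site
  (depth 3 kT); the repeat-average density is more symmetric (deviation
  ≈0.21) than the median single repeat (≈0.33).
* **Flip-flop**: 90 cholesterol molecules over 20 µs at λ = 10⁻⁴/ns;
  the observed flip count sits within 4√(λNT) of λNT = 180.

What passing these scenarios does *not* show: the generator has no
force-field energetics, no membrane deformation, no protein flexibility, no
solvent, and its binding sites are isotropic Gaussian wells — so agreement
here validates the *analysis machinery* (windowing, leaflet logic, density
normalization, run-length statistics, symmetry metrics, site geometry), not
the realism of any particular simulation.

## Numerical choices and degenerate inputs

* Coordinates in nm throughout (GRO native; PDB converted from Å on read);
  GRO precision 0.001 nm bounds round-trip error; XTC uses the standard
  lossy 0.001 nm precision.
* Minimum-image distances reduce the displacement to the nearest lattice
  point and then search the 27 neighboring images — exhaustive for any
  separation; contact cutoffs must stay below half the shortest box vector
  (enforced).
* Empty selections raise rather than returning zero grids, so misconfigured
  residue or bead names fail loudly; all-zero grids make the symmetry
  deviation undefined (error), as does exporting an empty grid.
* Windows at stride finer than the native frame spacing are rejected;
  windowing is idempotent at equal parameters.
* Grid subtraction requires exactly commensurate grids; there is no silent
  resampling.
* Exact ties in the lipid hierarchy keep input order and set a tie flag.
* The residence oracle raises a budget error carrying its partial estimate
  when walkers fail to exit within the step budget.

## Known limitations

* The toy model cannot reproduce printed system sizes of any specific study
  (how the insane tool resolved the 100.1% extracellular column into its
  289-lipid system is not recoverable); compositions are exact in mole
  percent, not in absolute counts.
* Published per-figure isovalues are consistent with the
  fraction-proportional reweighting rule only to ±1 in the last digit; the
  exact reference isovalue per figure is not recoverable, so the rule — not
  any specific printed isovalue — is the tested surface.
* Boundary-touching contact runs bias long mean durations downward
  (uncensored); survival-curve koff estimation is deliberately out of scope.
* Lipids are analyzed per-bead after molecule-whole wrapping, which can
  differ from per-bead wrapping at box edges.
* The orbit-average symmetrization is exact as a projection but has
  bin-level angular granularity; quantitative sector comparisons are good to
  ~5% at the default 0.2 nm bins.
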