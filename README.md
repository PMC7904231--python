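# lipidmap

State-dependent protein–lipid interaction mapping for membrane proteins,
built around the analysis workflow used for coarse-grained simulations of
pentameric ligand-gated ion channels (pLGICs) in asymmetric neuronal
membranes.

Membrane lipids are not a passive solvent: cholesterol, anionic lipids and
sphingomyelin form specific, state-dependent interactions with receptors
like the glycine receptor, accumulating at subunit interfaces and known
modulator pockets.  lipidmap quantifies these interactions from
coordinate/trajectory files (GRO/PDB + XTC/DCD):

* **leaflet-resolved densities** — 2D per-leaflet maps and 3D grids of each
  lipid species around the protein, with bead-role selectors (choline/
  ammonium headgroup, phosphate, hydroxyl, tail) and equal-composition
  isovalue reweighting so species of very different abundance can be
  compared on one figure;
* **continuous contact durations** — for every residue and lipid species,
  the mean length of unbroken contact runs at a 0.6 nm (first lipid shell)
  cutoff, pooled over molecules, repeats and the five subunits; plus a
  ranking of lipid species by interaction duration;
* **C5 symmetry diagnostics** — an exact orbit-average symmetrization and a
  normalized deviation metric that turns "the converged density should be
  five-fold symmetric" into a quantitative convergence check across repeats;
* **ligand-site overlap** — enrichment of a lipid's density inside
  structurally defined sites (e.g. an ivermectin pose or a PIP2 pocket from
  a user-supplied PDB), exact state-difference grids, and the radial
  penetration depth of density into the five subunit-interface wedges;
* **a synthetic generator** — an asymmetric five-species membrane
  (POPC/POPE/DOPS/SM/CHOL), a static C5 pentamer, and Brownian toy lipid
  dynamics with planted, state-gated binding sites and cholesterol
  flip-flop, providing ground truth for every statistic above.

The contact statistic is the mean continuous contact duration: with frames
at spacing dt, a maximal run of L consecutive contact frames between a lipid
molecule and a residue contributes one event of duration L·dt, and the
per-residue mean pools events across molecules, repeats and subunits.
Densities are absolute time-averaged number densities (molecules/nm²,
molecules/nm³) satisfying Σ values × cell volume = time-averaged molecule
count exactly.  See `docs/methods.md` for the full model description.

## Worked example

Recover a planted lipid hierarchy from the built-in synthetic study: sites
on each subunit's lipid-facing outer helix with well depths CHOL 6 kT >
PS 4 kT > PC = PE = SM 1 kT, 150 lipids per leaflet, 6.6 µs of toy dynamics
analyzed over the last half at 10 ns frames:

```python
from lipidmap.scenarios import run_hierarchy, run_state_pair

res = run_hierarchy(seed=1)
print("ranking by max:   ", " > ".join(res["by_max"]))
print("ranking by top-20:", " > ".join(res["by_top20"]))

sp = run_state_pair(seed=1)
print(f"CHOL interface enrichment: active {sp['enrichment']['active']:.1f}, "
      f"inactive {sp['enrichment']['inactive']:.2f}")
print(f"mean penetration depth: active "
      f"{sp['penetration']['active']['depth_nm'].mean():.2f} nm, inactive "
      f"{sp['penetration']['inactive']['depth_nm'].mean():.2f} nm")
```

prints

```
ranking by max:    CHOL > DOPS > SM > POPE > POPC
ranking by top-20: CHOL > DOPS > POPC > POPE > SM
CHOL interface enrichment: active 20.7, inactive 0.77
mean penetration depth: active 0.73 nm, inactive 0.00 nm
```

Both ranking statistics put cholesterol first and the anionic lipid (DOPS)
second, matching the planted well depths; the three 1 kT species are
statistically interchangeable, so their internal order varies.  The second
block probes a cholesterol site at the subunit interfaces that exists only
in the active state: cholesterol density inside the site region is ~21×
bulk in the active run but indistinguishable from bulk (<1.2×) in the
paired inactive run, and supra-threshold density reaches 0.73 nm deeper
into the interface wedges.

The same stages run from the command line on a YAML configuration
(schema in `docs/config.md`), against either synthetic or user-supplied
trajectories:

```bash
lipidmap all -c run.yaml --seed 1 --state active
lipidmap contacts -c run.yaml        # re-run one stage from intermediates
```

Outputs are CSV tables (contacts, hierarchy, site reports, symmetry),
OpenDX volumes (3D densities, loadable in VMD/PyMOL/ChimeraX), CSV matrices
(2D maps), a B-factor-colored PDB export for structure mapping, and a
manifest recording version, seed and config hash.  Identical config + seed
give byte-identical outputs.

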