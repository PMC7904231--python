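# Run configuration schema

A run is described by one YAML file.  Exactly one of `synthetic` or
`inputs` must be present; unknown keys are rejected with every offending
key named.  CLI flags `--seed`, `--state`, `--repeats` override the
corresponding keys.

```yaml
# --- input mode 1: built-in synthetic generator -------------------------
synthetic:
  nominal_per_leaflet: 150      # lipids per leaflet before apportionment
  box_a_nm: 11.0                # hexagonal cell edge
  box_c_nm: 6.0                 # cell height
  n_frames: 200                 # trajectory frames to produce
  step_dt_ns: 0.5               # integration step
  frame_dt_ns: 10.0             # frame spacing (write interval)
  flipflop_rate_per_ns: 1.0e-4  # cholesterol leaflet-exchange rate
  diffusion_nm2_per_ns: {}      # per-type override, default 0.005
  protein_core_radius_nm: 1.4   # hard reflective disc around the pore axis
  sites:                        # planted binding sites (ground truth)
    - name: interface-chol
      leaflet: extracellular    # extracellular | intracellular
      selectivity: CHOL         # POPC | POPE | DOPS | SM | CHOL
      well_depth_kt: 6.0
      width_nm: 0.35
      radius_nm: 1.8            # radial distance from the pore axis
      wedge: 0                  # subunit interface 0-4 (5-fold replicated)
      # angle_deg: 18.0         # ... or an explicit polar anchor instead
      available_in: [active]    # states in which the site exists

# --- input mode 2: user-supplied files ----------------------------------
# inputs:
#   coordinates: system.gro     # GRO or PDB
#   trajectory: traj.xtc        # XTC or DCD (optional: single-frame run)
#   naming_config: naming.yaml  # residue/bead naming overrides (optional)

state: inactive                 # inactive | active
window:
  last_fraction: 0.5            # analyze the last half of the run
  stride_dt_ns: 10.0            # frame spacing after subsampling
cutoff_nm: 0.6                  # protein-lipid contact cutoff
bin2d_nm: 0.2                   # 2D density bin size
voxel3d_nm: 0.1                 # 3D density voxel size
repeats: 1                      # repeat count; repeat r uses seed + r
seed: 0
outdir: results

sites:                          # ligand sites to score (optional)
  - name: ivermectin            # from a reference structure ...
    pdb: 5vdh_aligned.pdb       # user-aligned to the trajectory frame
    ligand: IVM
    radius_nm: 0.7
  - name: interface             # ... or a subunit-interface wedge
    wedge: 0
    wedge_half_width_deg: 25.0
    leaflet: extracellular
```

The naming config maps residue names to lipid types and bead names to
roles; the defaults cover Martini names (POPC/POPE/DOPS/DPSM/CHOL; beads
NC3/NH3/PO4/ROH/CNO, tails `C*`/`D*`, protein BB/`SC*`).  Override any
subset:

```yaml
lipid_types: {DPPC: POPC}         # treat DPPC as the PC species
bead_roles: {AM1: cationic-headgroup}
anchors: {POPC: PO4}
subunit_resid_stride: 1000        # resid = subunit_index * stride + local
```
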