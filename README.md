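# phantomkit

Engineering and dosimetry toolkit for polygon-mesh, tetrahedral-mesh and
voxel computational human phantoms, with a desk-scale kerma-approximation
Monte Carlo photon transport for anterior-posterior (AP) parallel-beam
irradiation.

What it does:

* **Phantom I/O** (`phantomkit.phantom_io`) — region-tagged Wavefront OBJ
  surfaces, TetGen-dialect ELE/NODE tetrahedral meshes, whitespace ASCII
  voxel rasters, plus TSV material libraries and region catalogs.  All
  round-trips preserve region identity and per-region volume.
* **Geometry QA and conversion** (`phantomkit.geometry_qa`) —
  watertightness and self-intersection checks, divergence-theorem volumes,
  mass-targeted uniform scaling (cube-root law), radiosensitive shell-layer
  extraction by inward vertex-normal offsetting (e.g. a 50–100 µm skin
  basal layer), voxel→surface, surface→tetrahedra (Delaunay with
  innermost-region assignment) and surface→voxel (innermost-wins
  rasterization) conversion.
* **Skeletal materials** (`phantomkit.skeleton_materials`) — packaged
  20-anatomical-region inventories of active/inactive marrow, hard bone and
  endosteum for an adult male ("jpm") and female ("jpf") model,
  mass-weighted homogenization of bone-component mixtures, and mixture mass
  energy-absorption coefficients on a packaged elemental table.
* **Photon transport** (`phantomkit.photon_transport`) — vectorized analog
  Monte Carlo on voxel phantoms: Woodcock delta-tracking, exact
  Klein–Nishina incoherent scattering, photoelectric absorption, pair
  production, 1 keV cutoff, per-region track-length fluence spectra and
  deposited energy per unit incident fluence, batch-based fractional
  standard deviations, exact per-batch energy balance and bit-reproducible
  seeding.  One-voxel-wide "column" phantoms get an exact per-segment
  track-length tally, which resolves micrometre-thin layers.
* **Dosimetry** (`phantomkit.dosimetry`) — marrow/endosteum doses from
  fluence spectra below 1 MeV and from mass-proportional energy partition
  at and above it, mass-weighted whole-body component doses, organ absorbed
  doses in pGy·cm², equivalent doses (w_R = 1 for photons/electrons) and
  ICRP-103 sex-averaged effective dose with the remainder-tissue rule.
* **Synthetic phantoms** (`phantomkit.synthetic_phantoms`) — deterministic
  stylized fixtures: a layered ellipsoid body (full skin shell, 50–100 µm
  sensitive sublayer, breast analog, optional bone slab), a mass-targeted
  eye with an anterior-sensitive / posterior-insensitive lens split, and a
  perforated-voxel-skin generator that mimics resolution-limited voxel
  membranes.

The elemental photon coefficients in `phantomkit/data/photon_coefficients.tsv`
are generated by an internally consistent analytic model (exact
Klein–Nishina, calibrated photoelectric power law, Bethe–Heitler-style pair
production; no coherent scattering, no shell edges, no radiative losses).
They track evaluated data to within a few percent over 0.01–10 MeV for
light elements and are intended for verification and trend studies, not for
production dosimetry.  Regenerate with
`python scripts/generate_photon_tables.py`.

## CLI

```bash
phantom synth eye --sex male --out eye.obj     # stylized fixtures
phantom synth body --sex female --pitch 2 --out out/
phantom qa eye.obj                             # watertightness report
phantom mass eye.obj --catalog catalog.tsv     # volume/mass accounting
phantom layer body.obj --lo 50 --hi 100 --region 2 --out layer.obj
phantom scale eye.obj --region 10 --density 1.05 --target-mass 0.012 --out s.obj
phantom convert body.obj --to voxel --pitch 1.0 --out body.vox

dose transport --phantom eye.obj --pitch 1.0 --energy 0.05 \
    --histories 100000 --seed 1 --out tally.json
dose bone --tallies tally.json --inventory jpm --component active_marrow
dose effective --male male.tsv --female female.tsv
```

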