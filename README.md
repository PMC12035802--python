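# memtk

Membrane trajectory analysis toolkit for lipid-bilayer molecular dynamics
data under rectangular **and hexagonal** periodic boundaries:

- **Leaflet assignment** robust to membrane curvature (periodic proximity
  graph on phosphorus atoms, not a z-threshold).
- **Per-lipid areas** from the periodic Voronoi diagram (dual of the
  Delaunay triangulation) with exact area conservation per leaflet.
- **2D raster maps** (default 512 x 512) of membrane thickness and
  area-per-lipid over the unit cell, with nanoparticle outline projection.
- **Acyl-chain deuterium order parameters** (|S_CD|), **mass-density
  profiles** along the membrane normal, polymer **radius of gyration /
  end-to-end / COM trajectories**.
- **Release-state classification** of probe molecules (k-means, k = 3, on
  the standard deviation of the probe-to-nanoparticle COM distance):
  immobile / released / escaped by ascending dispersion.
- A **synthetic-data module** that generates bilayer + polymer-blob +
  probe trajectories with planted, recoverable ground truth (per-lipid
  area, thickness, Gaussian bump deformation, C-H bond angles, COM drift,
  probe mobility classes), used throughout the test suite.

Internal units are nm and ns. Structures are read from GRO/PDB and
trajectories from XTC/TRR (via MDAnalysis) or from a versioned plain-JSON
dialect (documented in `memtk/core_model/io.py`) so fixtures stay text-only.

## CLI

All commands are driven by a single YAML config:

```yaml
# config.yaml
seed: 1
generate:            # or: structure: system.gro / trajectory: traj.xtc
  kind: flat         # flat | bump | blob
  n_per_leaflet: 178
  apl: 0.64          # nm^2
  thickness: 3.93    # nm
  cell_kind: hexagonal
  jitter: 0.05       # nm
  n_frames: 100
grid: 512            # raster resolution
map_window_ns: 10    # map averaging window (end of trajectory)
summary_window_ns: 50
leaflet_cutoff: 1.2  # nm
```

```sh
memtk generate -c config.yaml -o fixtures/   # JSON + GRO + ground truth
memtk all      -c config.yaml -o out/        # every applicable stage
memtk maps     -c config.yaml -o out/        # (leaflets|maps|metrics|release)
```

Outputs are CSVs and plain-text grid files plus `manifest.json` recording
the package version, seed, and a SHA-256 of the config; identical config +
seed gives byte-identical outputs. Exit code 2 marks configuration errors,
1 computation errors.

## Layout

```
src/memtk/core_model/   cells, minimum image, ghost replication, I/O
src/memtk/synthetic_data.py  generators with planted ground truth
src/memtk/leaflets.py   curved-leaflet assignment
src/memtk/surface_maps.py    Voronoi APL, thickness/APL rasters, outlines
src/memtk/chain_metrics.py   S_CD, density profiles, R_g, d_ee, COM z
src/memtk/release.py    distance series, dispersion feature, k-means
src/memtk/cli_pipeline.py    config, pipeline driver, CLI
tests/                  unit + property + acceptance suites
```
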