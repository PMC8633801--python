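# vasctree

Constructive synthesis of arterial trees in 3-D perfusion domains, with a
partitioned concurrent growth mode: a sequentially grown baseline tree is
shared by disjoint subdomains that are vascularized independently (frozen
outside outflows, midpoint-resident parent sets), their insertion logs are
replayed onto the baseline with an exact-coordinate lookup, and the merged
network is rescaled once under Poiseuille haemodynamics with
diameter-dependent (Fåhræus–Lindqvist type) blood viscosity.

## Features

- **Domains** (`vasctree.domain_geometry`): axis-aligned boxes and watertight
  triangle meshes (ASCII OBJ/STL/PLY), uniform rejection sampling, disjoint
  axis-aligned partitions with function-valued point labelling, allometric
  inlet scaling (Q ∝ V, r₀ ∝ V^{3/8}).
- **Tree model** (`vasctree.vessel_tree`): strict binary trees of rigid
  cylindrical segments, terminal insertion by parent splitting, uniform or
  mixed terminal-outflow policies, radius propagation under the branching
  power law r_p^γ = r_l^γ + r_r^γ with the equal-terminal-pressure closure.
- **Haemodynamics** (`vasctree.hemodynamics`): Poiseuille resistances (CGS in,
  mmHg out), pressure marching verified against an independent sparse linear
  solve, constant and diameter-dependent viscosity models coupled to radius
  rescaling by fixed-point iteration.
- **Sequential growth** (`vasctree.dcco_growth`): volumetric and sprouting
  cost functionals, neighbourhood search, barycentric-lattice trial
  bifurcations, geometric/haemodynamic validity constraints, exact full-tree
  δF evaluation (numba-accelerated), multi-stage driver.
- **Partitioned growth** (`vasctree.pdcco`): per-subdomain growth from a
  shared baseline, insertion-record logging (JSON-lines), coordinate-keyed
  merge with deferred radius scaling; serial and threaded execution produce
  bit-identical results.
- **Morphometry** (`vasctree.morphometry`): generation-wise box-plot
  profiles, radius–length histograms, Strahler orders with connectivity
  matrices, lumen areas, subtended volumes, relative-volume agreement
  statistics.
- **I/O + CLI** (`vasctree.io`, `vasctree.cli`): lossless CSV edge tables,
  legacy VTK polydata (ASCII or bit-exact binary), YAML/JSON run configs with
  strict schemas.

## CLI

```bash
vasctree grow   -c config.yaml -o out/          # sequential multi-stage growth
vasctree pgrow  -c config.yaml -o out/ --seed 1 # baseline + subdomains + merge
vasctree merge  --baseline out/baseline.csv --records out/records-0.jsonl \
                --records out/records-1.jsonl -o merged/
vasctree flow   --tree out/tree.csv --model diameter -o flow/
vasctree analyze --tree out/tree.csv -o tables/
vasctree export --tree out/tree.csv -o net.vtk --binary
vasctree experiment --name baseline-sensitivity -o experiments/
```

A minimal config:

```yaml
domain: {type: box, corners: [[0, 0, 0], [4, 1, 1]], seed: 0}
partition: {counts: [4, 1, 1]}
inlet: {x_p: [0, 0.5, 0.5], x_d: [0.4, 0.5, 0.5], r0: 0.075, Q_in: 0.002}
stages:
  - {name: base, N: 499, seed: 1}
subdomain_stages:
  - {name: s0, N: 200, seed: 0}
  - {name: s1, N: 200, seed: 0}
  - {name: s2, N: 200, seed: 0}
  - {name: s3, N: 200, seed: 0}
seed: 1
```

## Notes

- All randomness flows through explicit seeds; rerunning any config +
  seed reproduces artifacts bit-identically.
- The first import compiles the numba kernels (~15 s, cached afterwards).
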