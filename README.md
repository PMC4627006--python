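# greennet

Landscape-pattern metrics and ecological-network analysis for urban
green-space planning.

Urban planners and landscape ecologists evaluate green-space plans with two
complementary toolkits: **landscape pattern metrics** computed on categorical
land-cover rasters, and **graph-structure indices** computed on ecological
networks whose nodes are important green-space patches and whose links are
planned green corridors. `greennet` implements the complete chain —
FRAGSTATS-style raster metrics, network indices, and the corridor-overlay
experiment that quantifies how a planned corridor network changes the
landscape — as a tested, reproducible Python package with a CLI.

## What it computes

**Class and landscape pattern metrics** on integer rasters (patches are
connected components of same-class cells under 4- or 8-adjacency):

- CA — total class area (ha), `Σ a_ij / 10⁴`
- PD — patch density (patches per 100 ha), `N/A × 10⁶`
- ED — edge density (m/ha), `E/A × 10⁴`
- MPS — mean patch size (ha); at landscape level `A/N/10⁴`, so `PD × MPS ≡ 100`
- MPFD — mean patch fractal dimension, mean of `2 ln(0.25 P_ij)/ln(a_ij)`
- LSI — landscape shape index, `0.25 E/√A`
- SHDI / SHEI — Shannon diversity `−Σ P_k ln P_k` of class-area proportions
  and its evenness normalization `SHDI/ln n`
- ENN — Euclidean nearest-neighbour distance between same-class patches,
  shortest edge-cell center to edge-cell center (m)
- CONNECT — connectance, the percentage of same-class patch pairs within a
  user-chosen threshold distance

**Network structure indices** of a corridor network with `v` nodes, `l`
links and total corridor length `d` (km):

- α = (l − v + 1)/(2v − 5) — circuitry (loops present / loops possible)
- β = l/v — links per node (<1 dendroid, =1 single loop, >1 complex)
- γ = l/(3(v − 2)) — links over the planar maximum
- cost ratio = 1 − l/d — an efficiency proxy
- corridor density = d / district area (km/km²)

**Corridor overlay**: corridors are normalized to a fixed width (default
40 m), rasterized (a cell joins a corridor iff its center lies within
half-width of a polyline), burned onto the plan raster as green space while
all other uses collapse to one non-green class, and the landscape metrics
are recomputed before/after with signed deltas.

A **synthetic-data module** generates random-cluster neutral landscapes
(tunable class proportions and fragmentation) and random spatial networks,
plus frozen reference networks carrying the published node/corridor counts
of Nanchang's two districts.

## Worked example

```python
from greennet import (LandscapeSpec, generate_landscape, landscape_report,
                      network_report, reference_networks)

# Graph indices of the Changnan district network (74 nodes, 109 corridors,
# 197.15 km of corridor):
rec = network_report(reference_networks()["Changnan"])
print(rec["display"])
# {'length_km': 197.15, 'alpha': 0.25, 'beta': 1.47, 'gamma': 0.5,
#  'cost_ratio': 0.45}

# Landscape metrics of a synthetic two-class landscape:
spec = LandscapeSpec(rows=40, cols=40, proportions={1: 0.25, 2: 0.15},
                     clumping=4, seed=3)
rep = landscape_report(generate_landscape(spec), connect_threshold_m=100.0)
print(rep.to_frame().to_string(index=False))
```

prints

```
    level class  metric      value   units
landscape   all      PD  37.500000 n/100ha
landscape   all      ED 242.500000    m/ha
landscape   all     MPS   2.666667      ha
landscape   all     LSI   2.425000
landscape   all    SHDI   0.937637
landscape   all    SHEI   0.853474
landscape   all    MPFD   1.126699
landscape   all     ENN  78.360740       m
landscape   all CONNECT  28.571429      %
```

α = 0.25 says a quarter of the possible loops are present; β = 1.47 marks a
complex (multi-loop) network; the cost ratio 0.45 trades corridor count
against built length. In the raster report, PD × MPS = 37.5 × 2.667 = 100
(an identity of the definitions), and SHEI = SHDI/ln 3 since three patch
types (two green classes + background) share the mosaic.

The same computations are available from the shell:

```bash
greennet metrics --raster landscape.asc --out-dir out/
greennet network --nodes nodes.geojson --links links.geojson --out-dir out/
greennet overlay --raster plan.asc --corridors corridors.geojson --out-dir out/
greennet simulate --config spec.json --out-dir out/
```

## Layout

- `src/greennet/grid.py` — raster container, ESRI ASCII grid I/O, reclassification
- `src/greennet/patches.py` — patch delineation, CA/PD/ED/MPS/MPFD
- `src/greennet/landscape.py` — SHDI/SHEI/LSI/ENN/CONNECT and full reports
- `src/greennet/network.py` — ecological networks, α/β/γ/cost ratio, GeoJSON I/O
- `src/greennet/overlay.py` — corridor rasterization, overlay, plan comparison
- `src/greennet/synthetic.py` — neutral landscapes, random networks, fixtures
- `src/greennet/cli.py` — `greennet` command-line interface
- `docs/methods.md` — models, conventions, parameter choices, limitations
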