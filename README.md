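# rangeconnect

Dams fragment rivers, and fragmented rivers strand fish: barriers block
the migrations that many freshwater species need for spawning and feeding,
and they slice resident species' ranges into isolated patches.
`rangeconnect` quantifies this for individual species on a dendritic
subbasin mesh.  It is aimed at freshwater ecologists and conservation
planners who want a species-specific, scenario-aware fragmentation measure
— which basins and which species lose the most connectivity if the planned
wave of hydropower dams is built?

## The Connectivity Index

Each species *s* gets a Connectivity Index (CI, 0–100%) per main
hydrologic basin *b* (a basin draining to the sea or an internal sink).
Dams split the basin into patches *i* = 1..*n*, patch 1 holding the
outlet.  Subbasin areas *a* are converted to river-length proxies by
Hack's law *l* = β·*a*^α (α = 0.55 by default; β cancels).  With
*L_i* the α-length of the species' range in patch *i* and *L* = Σ *L_i*:

* nondiadromous species (lifecycle completed in freshwater):
  **CI^N = 100 · Σ_i L_i² / L²**
* diadromous species (migrating between river and sea):
  **CI^D = 100 · L₁ / L**

CI is 100 when the range is unfragmented, drops as dams carve it up, and
for diadromous fish collapses whenever a downstream dam cuts the range off
from the sea.  Two scenarios come from one dam table: `present` (existing
dams) and `future` (plus dams under construction or planned).  Aggregation
utilities produce species-level area-weighted means, basin and subbasin
means, trait-group summaries, and present-vs-future deltas.  A synthetic
data generator supplies download-free test worlds with the same structure
as global hydrography, range, and dam inventories.

## Worked example

```python
import pandas as pd
from rangeconnect import SynthConfig, simulate, compute_ci_table, species_mean_ci

ds = simulate(SynthConfig(seed=42, n_units=500, n_basins=8, n_species=60,
                          diadromous_fraction=0.15,
                          n_dams_existing=25, n_dams_future=8))
tables = [compute_ci_table(ds.network, ds.dams, ds.ranges, s)
          for s in ("present", "future")]
sp = species_mean_ci(pd.concat(tables, ignore_index=True))
print(sp.groupby(["diadromy", "scenario"])["ci_percent"]
        .agg(["mean", "std", "count"]).round(1))
```

```text
                        mean   std  count
diadromy      scenario
diadromous    future    89.1  25.3      7
              present   89.7  25.5      7
nondiadromous future    82.1  22.1     53
              present   84.5  20.2     53
```

The 53 nondiadromous species average 84.5% range connectivity under the 25
existing dams; completing the 8 future dams lowers the mean by 2.4
percentage points.  The 7 diadromous species stay near 90% because, in
this world, few of the new dams land downstream of their outlet-anchored
ranges — a single well-placed mainstem dam would change that sharply,
which is exactly the asymmetry CI^D is designed to expose.

The same pipeline runs from the shell:

```sh
rangeconnect simulate --seed 42 --out data/
rangeconnect compute-ci --network data/network.csv --dams data/dams.csv \
    --ranges data/ranges.csv --species data/species.csv \
    --scenario future --out out/ci_future.csv
rangeconnect aggregate --ci out/ci_future.csv --species data/species.csv \
    --group-by climate_zone --out out/summary.csv
```

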