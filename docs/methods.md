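# Methods

## The model

`rangeconnect` quantifies how dams fragment the geographic ranges of
riverine (lotic) fish.  The spatial template is a mesh of subbasin units
forming a forest of rooted trees: each unit drains into exactly one
downstream unit or is the terminus of its *main hydrologic basin* (an
outlet to the sea or an internal sink).  A species' range is the set of
units it occupies; a dam assigned to unit *j* severs the edge from *j* to
its downstream neighbour, so the dammed unit is the most downstream member
of its upstream patch.  Removing all severed edges partitions each basin
into *patches* — maximal sets of units mutually reachable without crossing
a dam — with patch 1 containing the basin terminus.

Ranges are areas, not vectorized rivers, so each unit's area *a* (km²) is
converted to a river-length proxy by Hack's law, *l* = β·*a*^α.  The shape
factor β cancels in every index ratio and is never an input; α defaults to
0.55, the centre of its empirical 0.5–0.6 band (values outside the band
warn, non-positive values are rejected).

For species *s* in basin *b*, let *L_i* be the sum of *a*^α over the range
units in patch *i* and *L* = Σ*_i L_i* (both sums range-restricted):

* **Nondiadromous** (resident and within-river migrants):
  CI^N = 100 · Σ*_i L_i*² / *L*² — the length-weighted probability that
  two random points of the range remain mutually reachable.
* **Diadromous** (migrants between river and sea):
  CI^D = 100 · *L*₁ / *L* — the fraction of the range still connected to
  the basin terminus, so the most downstream dam dominates.

CI = 100 exactly iff the whole range (within that basin) lies in one
patch; both indices are monotonically non-increasing under added dams and
invariant to rescaling all areas by a common factor.

Two scenarios are composed from one dam table: **present** (existing dams)
and **future** (existing + under construction + planned), so future ⊇
present and CI never rises from present to future.

## Assumptions and semantics

* Barriers are fully impassable; no fish-pass passability, no
  upstream/downstream asymmetry, no natural barriers (waterfalls are
  treated as evolutionary background, not fragmentation).
* Range gaps do not fragment: only dams and basin boundaries delimit
  patches.  Two disconnected range fragments inside one patch count as one
  patch contribution.
* Multiple dams in one unit collapse to one cut — the unit-resolution mesh
  cannot represent within-unit fragmentation.
* A dam in an outlet unit has no edge to sever.  By default it is recorded
  but ignored; with `strict_outlet_dams` the diadromous sea-connected
  patch is truncated to the outlet unit itself.  The default reflects that
  no rule is defensible at unit resolution; strict mode bounds the effect.
* The mesh does not distinguish sea outlets from internal sinks, so
  diadromous CI in an endorheic basin is computed against the
  sink-containing patch.  Interpret diadromous values in endorheic basins
  with care; the package cannot flag them.

## Aggregation

* **Species level**: mean of basin CIs weighted by the species' range area
  (sum of occupied unit areas) per basin.
* **Basin level**: unweighted mean across species occurring in the basin.
* **Subbasin level**: unweighted mean, across species occupying a unit, of
  each species' CI in that unit's basin; unoccupied units are absent.
* **Trait groups**: descriptive summaries (mean, SD with ddof = 1 — a
  single-member group reports SD 0 — median, quartiles, and 2.5/97.5
  empirical percentiles with linear interpolation) by climate zone, IUCN
  status, commercial relevance, taxonomic order (orders with fewer than 20
  species merge into "other"), body length (default bin edges 5, 10, 20,
  40, 80 cm; only the first edge is canonical, the rest are configurable
  defaults), and range area (log₁₀ bins at integer edges by default).
* Climate-zone membership is single (never fractional): each species gets
  the zone with the largest precomputed range overlap, ties broken in
  fixed order A, B, C, D, E.
* Scenario deltas are reported in percentage points (present − future).

## Range compilation from occurrence records

Species ranges may arrive pre-mapped at fine resolution, or be compiled
from point occurrence records referenced to coarse units: a species keeps
the set of distinct coarse units holding ≥ 1 record, and species with
fewer than 10 raw records in total are dropped (records are deliberately
not deduplicated before the threshold; the count is of raw records).
Coarse units nest fine units exactly, so refinement to the fine mesh is a
union of block members.  Lotic/extant filtering is upstream data curation:
inputs are assumed already filtered.

## Synthetic data: what it emulates, and what it does not

The generator produces download-free worlds with the structure the
analysis assumes.  Defaults define the study conditions used by the
acceptance script:

| parameter | default | rationale |
|---|---|---|
| `n_units` / `n_basins` | 4000 / 25 | desk-scale stand-in for a global mesh of ~10⁶ units |
| areas | lognormal, median 100 km², σ = 1 | fine subbasin units average ~100 km² |
| `coarse_block` | 10 | fine units per coarse unit, contiguous along a depth-first order (guarantees nesting) |
| `n_species` | 300 | enough for stable group summaries |
| `diadromous_fraction` | 0.05 | matches the observed diadromous share (~490/9794) |
| range size | 1 + NegBin, mean 40 units | contiguous ranges spanning a few coarse units |
| `n_dams_existing` | 160 | ~4% of units dammed, the global large-dam density |
| `n_dams_future` | 15 | future/existing ratio ≈ 3,681/39,912 |
| future status | P(under construction) = 574/3681 | observed share in the future-dam inventory |
| records/species | 1 + NegBin, mean 30, r = 0.8 | heavy left tail exercises the 10-record filter |

Trees grow by uniform random attachment.  CI depends only on topology,
areas, and cuts, so realistic branching statistics (Hortonian ratios,
basin shape) are unnecessary for correctness testing — but this is also
the key limitation: passing tests demonstrate the *computation* is right,
not that synthetic CI magnitudes match any real region.  Real-data
features the generator omits: spatial autocorrelation of dam placement
(dams cluster on mainstems), range shapes driven by ecology rather than
random expansion, multi-basin species (generated ranges are connected,
hence single-basin; multi-basin aggregation is exercised by unit tests
instead), and any geographic coordinates or climate rasters (climate
zones are labels, one per basin).

Diadromous ranges are grown from basin outlets, so every diadromous
species starts sea-connected (CI^D = 100 pre-damming) and declines are
attributable to dams, not range position.

All randomness derives from one integer seed through
`numpy.random.SeedSequence` spawns; identical configurations give
byte-identical CSV outputs.

## Numerical choices

* α-lengths accumulate in double precision; no compensated summation (the
  relative error at realistic patch sizes is ≪ the 1e-9 testing
  tolerance).
* A range whose basin intersection lies in one patch returns 100.0 exactly
  (short-circuit), and a fully fragmented equal-area chain of *n* units
  returns exactly 100/*n*; intermediate cases round normally.
* Patch indexing: patch 1 is the terminus patch; remaining patches are
  ordered by their most downstream unit's edge-count distance to the
  outlet, ties by unit id.  Neither index depends on the ordering beyond
  "terminus first" — the rule exists for reproducible output.
* Patch decomposition is computed once per (basin, scenario) and shared
  across species; an independent oracle (`ci_oracle`, flood fill via
  networkx + literal formulas) guards the equivalence in tests.
* Equality tolerance for conservation/oracle checks: 1e-9 relative.

## Known limitations

* Unit-resolution hydrography: within-unit river length is approximated by
  *a*^α, not measured; headwater and intermittent-reach mapping problems
  are inherited from any upstream mesh, not addressed here.
* No partial passability or directional asymmetry.
* The occurrence pathway counts raw records against the 10-record
  threshold; deduplication before thresholding would retain slightly fewer
  species (a sensitivity worth testing when real record tables are noisy).
* Whether the dammed unit's area belongs to the upstream or downstream
  patch is a genuine unit-resolution ambiguity; upstream-inclusive is
  implemented (the dammed unit heads its upstream patch).
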