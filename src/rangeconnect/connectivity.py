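"""Range Connectivity Index (CI) for riverine fish.

The CI adapts the dendritic connectivity framework of Cote et al. to species
geographic ranges mapped on subbasin units.  Because ranges are areas rather
than vectorized rivers, each subbasin's area *a* is converted to a river
length proxy via Hack's law, ``l = β·a^α``; the shape factor β cancels in
every CI ratio, so only ``a^α`` is ever computed.  α defaults to 0.55, the
central value of its empirical 0.5–0.6 range.

For a species *s* in main basin *b*, with the basin split into patches
*i = 1..n* by dams (patch 1 contains the outlet) and ``L_i`` the sum of
``a^α`` over range units in patch *i* and ``L = Σ L_i``:

* nondiadromous:  ``CI^N = 100 · Σ_i L_i² / L²`` — the probability that two
  random range locations are mutually reachable, length-weighted;
* diadromous:     ``CI^D = 100 · L_1 / L`` — the range fraction still
  connected to the sea, so the most downstream dam dominates.

Both sums run over the species' range only (numerator and denominator),
and only dams and basin boundaries delimit patches: disconnected range
fragments within one patch count as a single patch contribution.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import pandas as pd

from .dams import (
    DamScenario,
    PatchDecomposition,
    cut_edges,
    decompose_patches,
    outlet_dam_units,
    select_scenario,
)
from .errors import ComputationError, SchemaError
from .network import SubbasinNetwork
from .ranges import SpeciesRange

__all__ = [
    "HackParams",
    "CIRecord",
    "CI_COLUMNS",
    "effective_length",
    "ci_nondiadromous",
    "ci_diadromous",
    "compute_ci_table",
    "ci_oracle",
]

CI_COLUMNS = [
    "species_id", "main_basin_id", "scenario", "diadromy",
    "ci_percent", "range_area_km2",
]


@dataclass(frozen=True)
class HackParams:
    """Hack's-law exponent α relating channel length to drainage area.

    α is empirically constrained to [0.5, 0.6]; values outside that band
    are accepted with a warning, non-positive values are rejected.  The
    prefactor β never appears: it cancels in the CI ratios.
    """

    alpha: float = 0.55

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise SchemaError(f"alpha must be > 0, got {self.alpha}")
        if not 0.5 <= self.alpha <= 0.6:
            warnings.warn(
                f"alpha={self.alpha} is outside the empirical range [0.5, 0.6]",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CIRecord:
    """Connectivity index of one species in one main basin under one scenario."""

    species: str
    main_basin: str
    scenario: str
    ci: float
    diadromy: str
    range_area_in_basin: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci <= 100.0 + 1e-9:
            raise ComputationError(f"CI out of [0, 100]: {self.ci}")
        if not self.range_area_in_basin > 0:
            raise ComputationError(
                f"range area in basin must be > 0, got {self.range_area_in_basin}"
            )


def effective_length(area: float, params: HackParams = HackParams()) -> float:
    """Dimensionless river-length proxy of a subbasin: ``area ** alpha``."""
    if not area > 0:
        raise SchemaError(f"area must be > 0, got {area}")
    return area ** params.alpha


def _patch_lengths(
    patches: PatchDecomposition,
    range_units: Iterable[str],
    areas: Mapping[str, float],
    params: HackParams,
) -> dict[int, float]:
    """α-length of the species range within each patch (absent patches omitted)."""
    lengths: dict[int, float] = {}
    for u in range_units:
        p = patches.patch_of.get(u)
        if p is None:
            continue
        lengths[p] = lengths.get(p, 0.0) + effective_length(areas[u], params)
    return lengths


def ci_nondiadromous(
    patches: PatchDecomposition,
    range_units: Iterable[str],
    areas: Mapping[str, float],
    params: HackParams = HackParams(),
) -> float:
    """CI for species completing their lifecycle in freshwater.

    ``100 · Σ_i L_i² / (Σ_i L_i)²`` over the patches intersecting the range;
    100 exactly when the whole range lies in one patch.
    """
    lengths = _patch_lengths(patches, range_units, areas, params)
    if not lengths:
        raise ComputationError(
            f"range does not intersect basin {patches.main_basin!r}"
        )
    if len(lengths) == 1:
        return 100.0  # whole range in one patch: fully connected, exactly
    total = sum(lengths.values())
    return 100.0 * sum(v * v for v in lengths.values()) / (total * total)


def ci_diadromous(
    patches: PatchDecomposition,
    range_units: Iterable[str],
    areas: Mapping[str, float],
    params: HackParams = HackParams(),
    strict_outlet_dams: bool = False,
) -> float:
    """CI for species migrating between river and sea.

    ``100 · L_1 / L``: only the most downstream patch retains a connection
    to the marine environment, so the index is 0 when the range misses
    patch 1 entirely.  In strict mode a dam sitting in the outlet unit
    additionally truncates the sea-connected patch to the outlet unit
    itself.
    """
    lengths = _patch_lengths(patches, range_units, areas, params)
    if not lengths:
        raise ComputationError(
            f"range does not intersect basin {patches.main_basin!r}"
        )
    total = sum(lengths.values())
    if strict_outlet_dams and patches.outlet_dams:
        # basin mouth blocked: only the outlet unit itself stays sea-connected
        outlet_units = patches.outlet_dams & set(range_units)
        connected = sum(effective_length(areas[u], params) for u in outlet_units)
        return 100.0 if connected == total else 100.0 * connected / total
    downstream = lengths.get(patches.outlet_patch, 0.0)
    return 100.0 if downstream == total else 100.0 * downstream / total


def compute_ci_table(
    network: SubbasinNetwork,
    dam_table: pd.DataFrame,
    ranges: Iterable[SpeciesRange],
    scenario: str,
    params: HackParams = HackParams(),
    strict_outlet_dams: bool = False,
) -> pd.DataFrame:
    """CI of every (species, main basin) pair under one scenario.

    Patch structure is computed once per basin and shared across species
    (results are identical to per-species decomposition, since patches do
    not depend on ranges).  Nondiadromous species are scored with the
    two-way reachability index, diadromous species with the sea-connection
    index.  Diadromous species in endorheic basins are scored against the
    sink-containing patch, with a warning.

    Returns a DataFrame with columns ``species_id, main_basin_id, scenario,
    diadromy, ci_percent, range_area_km2`` sorted by (species, basin).
    """
    ranges = sorted(ranges, key=lambda r: r.species)
    for r in ranges:
        r.validate_against(network)
    scen = select_scenario(dam_table, scenario)
    cuts = cut_edges(network, scen)
    odams = outlet_dam_units(network, scen)

    basin_of = {uid: u.main_basin for uid, u in network.units.items()}
    # which basins any species touches, to avoid decomposing empty ones
    needed: set[str] = set()
    species_basins: list[tuple[SpeciesRange, dict[str, set[str]]]] = []
    for r in ranges:
        per_basin: dict[str, set[str]] = {}
        for u in r.units:
            per_basin.setdefault(basin_of[u], set()).add(u)
        needed |= per_basin.keys()
        species_basins.append((r, per_basin))

    decomp: dict[str, PatchDecomposition] = {}
    for b in needed:
        basin_cuts = {(u, d) for (u, d) in cuts if basin_of[u] == b}
        decomp[b] = decompose_patches(network, basin_cuts, b, outlet_dams=odams)

    areas = {uid: u.area for uid, u in network.units.items()}
    records: list[CIRecord] = []
    for r, per_basin in species_basins:
        for b in sorted(per_basin):
            units_b = per_basin[b]
            if r.diadromy == "diadromous":
                # the mesh does not distinguish sea outlets from internal
                # sinks: patch 1 is the terminus-containing patch either way
                ci = ci_diadromous(
                    decomp[b], units_b, areas, params,
                    strict_outlet_dams=strict_outlet_dams,
                )
            else:
                ci = ci_nondiadromous(decomp[b], units_b, areas, params)
            records.append(
                CIRecord(
                    species=r.species,
                    main_basin=b,
                    scenario=scenario,
                    ci=ci,
                    diadromy=r.diadromy,
                    range_area_in_basin=sum(areas[u] for u in units_b),
                )
            )

    return pd.DataFrame(
        [
            {
                "species_id": rec.species,
                "main_basin_id": rec.main_basin,
                "scenario": rec.scenario,
                "diadromy": rec.diadromy,
                "ci_percent": rec.ci,
                "range_area_km2": rec.range_area_in_basin,
            }
            for rec in records
        ],
        columns=CI_COLUMNS,
    )


def ci_oracle(
    network: SubbasinNetwork,
    dam_table: pd.DataFrame,
    ranges: Iterable[SpeciesRange],
    scenario: str,
    params: HackParams = HackParams(),
) -> pd.DataFrame:
    """Naive independent re-computation of :func:`compute_ci_table`.

    Rebuilds patches per species by connected components of the dam-cut
    undirected basin graph (via networkx) and evaluates the two index
    formulas literally.  Quadratic and deliberately simple; used only for
    verification in tests.
    """
    import networkx as nx

    scen = select_scenario(dam_table, scenario)
    cuts = cut_edges(network, scen)

    g = nx.Graph()
    g.add_nodes_from(network.units)
    g.add_edges_from(e for e in network.edges() if e not in cuts)

    rows = []
    areas = {uid: u.area for uid, u in network.units.items()}
    basin_of = {uid: u.main_basin for uid, u in network.units.items()}
    components = [set(c) for c in nx.connected_components(g)]

    for r in sorted(ranges, key=lambda r: r.species):
        for b in sorted({basin_of[u] for u in r.units}):
            in_basin = {u for u in r.units if basin_of[u] == b}
            outlet = network.outlets[b]
            patch_sums = []
            outlet_sum = 0.0
            for comp in components:
                if not comp & {u for u in network.units if basin_of[u] == b}:
                    continue
                s = sum(areas[u] ** params.alpha for u in comp & in_basin)
                if s > 0:
                    patch_sums.append(s)
                if outlet in comp:
                    outlet_sum = s
            total = sum(patch_sums)
            if r.diadromy == "diadromous":
                ci = 100.0 * (outlet_sum / total)
            else:
                ci = 100.0 * (sum(s * s for s in patch_sums) / total ** 2)
            rows.append({
                "species_id": r.species,
                "main_basin_id": b,
                "scenario": scenario,
                "diadromy": r.diadromy,
                "ci_percent": ci,
                "range_area_km2": sum(areas[u] for u in in_basin),
            })
    return pd.DataFrame(rows, columns=CI_COLUMNS)
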