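"""Dam scenarios and dam-delimited patch decomposition.

A dam assigned to subbasin *j* severs the downstream edge *j → next_down(j)*:
the dammed unit becomes the most downstream member of its upstream patch.
Removing the severed edges from a basin's tree partitions it into connected
patches; the patch containing the outlet/sink carries index 1 and is the only
patch connected to the sea (or to the basin terminus, for endorheic basins).

Two scenarios are composed from one dam table: ``present`` (existing dams
only) and ``future`` (existing plus under-construction plus planned), so the
future scenario always contains the present one.

A dam sitting in an outlet unit has no downstream edge to sever.  By default
it is only recorded on the decomposition (``outlet_dams``); an optional
strict mode lets the diadromous index treat the basin mouth as blocked.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError
from .network import SubbasinNetwork, basin_units

__all__ = [
    "Dam",
    "DamScenario",
    "PatchDecomposition",
    "DAM_STATUSES",
    "SCENARIOS",
    "select_scenario",
    "cut_edges",
    "outlet_dam_units",
    "decompose_patches",
    "read_dams_csv",
    "write_dams_csv",
]

DAM_STATUSES = ("existing", "under_construction", "planned")
SCENARIOS = ("present", "future")

#: Statuses active under each scenario label.
_SCENARIO_STATUSES = {
    "present": frozenset({"existing"}),
    "future": frozenset(DAM_STATUSES),
}


@dataclass(frozen=True)
class Dam:
    """A dam assigned to one subbasin unit."""

    id: str
    subbasin: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in DAM_STATUSES:
            raise SchemaError(
                f"dam {self.id!r}: unknown status {self.status!r} "
                f"(expected one of {DAM_STATUSES})"
            )


@dataclass(frozen=True)
class DamScenario:
    """A named set of dams active under one scenario."""

    name: str
    dams: tuple[Dam, ...]

    @property
    def dammed_units(self) -> frozenset[str]:
        return frozenset(d.subbasin for d in self.dams)


@dataclass
class PatchDecomposition:
    """Partition of one basin's units into dam-delimited patches.

    ``patch_of`` is total over the basin's units; patch 1 contains the
    outlet.  Remaining patches are indexed in increasing order of their most
    downstream unit's edge-count distance to the outlet, ties broken by unit
    id, a rule that exists only for reproducible output (neither index
    depends on the ordering beyond "outlet first").
    """

    main_basin: str
    patch_of: dict[str, int]
    n_patches: int
    outlet_patch: int = 1
    outlet_dams: frozenset[str] = field(default_factory=frozenset)

    def units_of(self, patch: int) -> set[str]:
        return {u for u, p in self.patch_of.items() if p == patch}


def _coerce_dam_table(dam_table: pd.DataFrame | Iterable[Mapping]) -> pd.DataFrame:
    if not isinstance(dam_table, pd.DataFrame):
        dam_table = pd.DataFrame(list(dam_table))
    if dam_table.empty and not len(dam_table.columns):
        dam_table = pd.DataFrame(columns=["dam_id", "unit_id", "status"])
    df = dam_table.rename(columns={"id": "dam_id", "subbasin": "unit_id"})
    missing = {"dam_id", "unit_id", "status"} - set(df.columns)
    if missing:
        raise SchemaError(f"dam table missing columns: {sorted(missing)}")
    return df


def select_scenario(
    dam_table: pd.DataFrame | Iterable[Mapping], scenario: str
) -> DamScenario:
    """Compose a :class:`DamScenario` from a dam table.

    ``present`` keeps existing dams only; ``future`` keeps all three
    statuses (existing, under construction, planned).
    """
    if scenario not in _SCENARIO_STATUSES:
        raise SchemaError(
            f"unknown scenario {scenario!r} (expected one of {SCENARIOS})"
        )
    df = _coerce_dam_table(dam_table)
    active = _SCENARIO_STATUSES[scenario]
    all_dams = [
        Dam(id=str(r.dam_id), subbasin=str(r.unit_id), status=str(r.status))
        for r in df.itertuples(index=False)
    ]
    return DamScenario(name=scenario, dams=tuple(d for d in all_dams if d.status in active))


def cut_edges(
    network: SubbasinNetwork, scenario: DamScenario
) -> set[tuple[str, str]]:
    """Edges severed by a scenario's dams.

    One cut per dammed subbasin that has a downstream neighbor; multiple
    dams in one unit collapse to a single cut (the unit-resolution mesh
    cannot represent within-unit fragmentation).  Dams in outlet units
    yield no cut; see :func:`outlet_dam_units`.
    """
    unknown = sorted(d.id for d in scenario.dams if d.subbasin not in network)
    if unknown:
        raise SchemaError(f"dams reference unknown subbasins: {unknown}")
    cuts: set[tuple[str, str]] = set()
    for unit in scenario.dammed_units:
        nd = network.units[unit].next_down
        if nd is not None:
            cuts.add((unit, nd))
    return cuts


def outlet_dam_units(network: SubbasinNetwork, scenario: DamScenario) -> frozenset[str]:
    """Dammed units that are basin outlets (no downstream edge to sever)."""
    return frozenset(
        u for u in scenario.dammed_units
        if u in network and network.units[u].next_down is None
    )


def _distance_to_outlet(network: SubbasinNetwork, unit: str) -> int:
    d = 0
    u = unit
    while (nd := network.units[u].next_down) is not None:
        u = nd
        d += 1
    return d


def decompose_patches(
    network: SubbasinNetwork,
    cuts: Iterable[tuple[str, str]],
    main_basin: str,
    outlet_dams: Iterable[str] = (),
) -> PatchDecomposition:
    """Decompose one basin into connected patches given severed edges.

    Every cut must be an edge of the requested basin.  The number of patches
    is exactly ``len(cuts) + 1``.
    """
    members = basin_units(network, main_basin)
    cuts = set(cuts)
    for u, d in cuts:
        if u not in members or network.units[u].next_down != d:
            raise SchemaError(
                f"cut edge ({u!r}, {d!r}) is not an edge of basin {main_basin!r}"
            )

    # roots: outlet first, then dammed units ordered by distance to outlet
    outlet = network.outlets[main_basin]
    upstream_roots = sorted(
        (u for u, _ in cuts), key=lambda u: (_distance_to_outlet(network, u), u)
    )

    patch_of: dict[str, int] = {}
    for idx, root in enumerate([outlet, *upstream_roots], start=1):
        patch_of[root] = idx
        frontier = [root]
        while frontier:
            nxt: list[str] = []
            for u in frontier:
                for c in network.children[u]:
                    if (c, u) in cuts:
                        continue  # c starts its own patch
                    patch_of[c] = idx
                    nxt.append(c)
            frontier = nxt

    assert len(patch_of) == len(members)
    return PatchDecomposition(
        main_basin=main_basin,
        patch_of=patch_of,
        n_patches=len(cuts) + 1,
        outlet_dams=frozenset(outlet_dams) & frozenset(members),
    )


def read_dams_csv(path) -> pd.DataFrame:
    """Read a dam table (columns ``dam_id,unit_id,status``) and validate labels."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"dam_id", "unit_id", "status"} - set(df.columns)
    if missing:
        raise SchemaError(f"dams CSV {path}: missing columns {sorted(missing)}")
    bad = df.loc[~df["status"].isin(DAM_STATUSES), "status"]
    if not bad.empty:
        raise SchemaError(f"dams CSV {path}: unknown status {bad.iloc[0]!r}")
    return df


def write_dams_csv(dam_table: pd.DataFrame, path) -> None:
    _coerce_dam_table(dam_table)[["dam_id", "unit_id", "status"]].to_csv(
        path, index=False
    )
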