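"""Dendritic subbasin networks.

The spatial template of the whole analysis is a forest of rooted trees: each
subbasin unit drains into exactly one downstream unit (``next_down``) or is
the terminus of its main hydrologic basin (outlet to the sea or internal
sink).  Units carry a surface area in km² and two memberships: the main
basin they belong to and an optional coarser parent unit used when species
ranges are compiled at a coarser resolution and later refined.

Identifiers are opaque strings; no hierarchical basin-coding arithmetic is
implemented or assumed.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError

__all__ = [
    "Subbasin",
    "SubbasinNetwork",
    "build_network",
    "upstream_set",
    "basin_units",
    "read_network_csv",
    "write_network_csv",
]

#: Column order of the network CSV interface.
NETWORK_COLUMNS = ["unit_id", "next_down", "area_km2", "main_basin_id", "coarse_id"]


@dataclass(frozen=True)
class Subbasin:
    """One hydrological unit of the mesh.

    Parameters
    ----------
    id : str
        Opaque unit identifier, unique within the network.
    area : float
        Surface area in km²; strictly positive.
    next_down : str or None
        Identifier of the immediately downstream unit; ``None`` marks the
        basin outlet/sink.
    main_basin : str
        Identifier of the containing main hydrologic basin.
    coarse_parent : str or None
        Identifier of the containing coarse unit, when ranges are supplied
        at a coarser resolution.  Optional.
    """

    id: str
    area: float
    next_down: str | None
    main_basin: str
    coarse_parent: str | None = None

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise SchemaError(f"subbasin {self.id!r}: area must be > 0, got {self.area}")
        if self.next_down == self.id:
            raise SchemaError(f"subbasin {self.id!r} drains into itself")


@dataclass
class SubbasinNetwork:
    """Validated forest of subbasins with eager downstream/upstream indexes.

    Attributes
    ----------
    units : dict
        Mapping unit id → :class:`Subbasin`.
    children : dict
        Mapping unit id → sorted tuple of immediately upstream unit ids;
        the exact inverse of the ``next_down`` relation.
    outlets : dict
        Mapping main-basin id → id of its unique terminal unit.
    """

    units: dict[str, Subbasin]
    children: dict[str, tuple[str, ...]] = field(repr=False)
    outlets: dict[str, str] = field(repr=False)
    _basin_members: dict[str, frozenset[str]] = field(repr=False)

    def __len__(self) -> int:
        return len(self.units)

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self.units

    @property
    def basins(self) -> tuple[str, ...]:
        return tuple(sorted(self.outlets))

    def area_of(self, unit_id: str) -> float:
        return self.units[unit_id].area

    def edges(self) -> Iterable[tuple[str, str]]:
        """All (unit, next_down) pairs of the forest."""
        for u in self.units.values():
            if u.next_down is not None:
                yield (u.id, u.next_down)

    def coarse_members(self) -> dict[str, frozenset[str]]:
        """Mapping coarse id → fine unit ids, over units with a coarse parent."""
        out: dict[str, set[str]] = {}
        for u in self.units.values():
            if u.coarse_parent is not None:
                out.setdefault(u.coarse_parent, set()).add(u.id)
        return {k: frozenset(v) for k, v in out.items()}


def build_network(units_table: pd.DataFrame | Iterable[Mapping]) -> SubbasinNetwork:
    """Build and validate a :class:`SubbasinNetwork` from tabular records.

    Parameters
    ----------
    units_table : DataFrame or iterable of mappings
        Must provide columns/keys ``id``, ``area``, ``next_down`` (nullable),
        ``main_basin``, and optionally ``coarse_parent``.  The CSV column
        names (``unit_id``, ``area_km2``, ...) are accepted as aliases.

    Raises
    ------
    SchemaError
        On duplicate ids, non-positive areas, dangling or self downstream
        references, downstream edges crossing basin boundaries, cycles, or
        basins without exactly one terminal unit.
    """
    if not isinstance(units_table, pd.DataFrame):
        units_table = pd.DataFrame(list(units_table))
    df = units_table.rename(
        columns={
            "unit_id": "id",
            "area_km2": "area",
            "main_basin_id": "main_basin",
            "coarse_id": "coarse_parent",
        }
    )
    required = {"id", "area", "next_down", "main_basin"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"units table missing columns: {sorted(missing)}")
    if "coarse_parent" not in df.columns:
        df = df.assign(coarse_parent=None)

    ids = df["id"].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicate unit id {dup.iloc[0]!r}")

    units: dict[str, Subbasin] = {}
    for row in df.itertuples(index=False):
        nd = row.next_down
        nd = None if pd.isna(nd) or nd == "" else str(nd)
        cp = row.coarse_parent
        cp = None if pd.isna(cp) or cp == "" else str(cp)
        sb = Subbasin(
            id=str(row.id),
            area=float(row.area),
            next_down=nd,
            main_basin=str(row.main_basin),
            coarse_parent=cp,
        )
        units[sb.id] = sb

    children: dict[str, list[str]] = {uid: [] for uid in units}
    outlets: dict[str, str] = {}
    for u in units.values():
        if u.next_down is None:
            if u.main_basin in outlets:
                raise SchemaError(
                    f"basin {u.main_basin!r} has multiple terminal units: "
                    f"{outlets[u.main_basin]!r} and {u.id!r}"
                )
            outlets[u.main_basin] = u.id
        else:
            down = units.get(u.next_down)
            if down is None:
                raise SchemaError(
                    f"subbasin {u.id!r} references missing downstream unit {u.next_down!r}"
                )
            if down.main_basin != u.main_basin:
                raise SchemaError(
                    f"edge {u.id!r}->{u.next_down!r} crosses main-basin boundary "
                    f"({u.main_basin!r} -> {down.main_basin!r})"
                )
            children[u.next_down].append(u.id)

    _check_acyclic(units)

    basin_members: dict[str, set[str]] = {}
    for u in units.values():
        basin_members.setdefault(u.main_basin, set()).add(u.id)
    for basin in basin_members:
        if basin not in outlets:
            raise SchemaError(f"basin {basin!r} has no terminal unit")

    return SubbasinNetwork(
        units=units,
        children={uid: tuple(sorted(ch)) for uid, ch in children.items()},
        outlets=outlets,
        _basin_members={b: frozenset(m) for b, m in basin_members.items()},
    )


def _check_acyclic(units: dict[str, Subbasin]) -> None:
    """Reject cycles in the next_down relation, reporting one cycle."""
    state: dict[str, int] = {}  # 0 in progress on current walk, 1 proven acyclic
    for start in units:
        if start in state:
            continue
        path: list[str] = []
        u: str | None = start
        while u is not None and u not in state:
            state[u] = 0
            path.append(u)
            u = units[u].next_down
        if u is not None and state[u] == 0:
            cycle = path[path.index(u):] + [u]
            raise SchemaError(f"cycle in next_down relation: {' -> '.join(cycle)}")
        for v in path:
            state[v] = 1


def upstream_set(network: SubbasinNetwork, unit: str) -> set[str]:
    """All units whose flow path passes through ``unit``, including itself.

    Breadth-first traversal of the upstream (children) index; O(subtree).
    """
    if unit not in network.units:
        raise SchemaError(f"unknown unit id {unit!r}")
    out = {unit}
    frontier = [unit]
    while frontier:
        nxt: list[str] = []
        for u in frontier:
            for c in network.children[u]:
                out.add(c)
                nxt.append(c)
        frontier = nxt
    return out


def basin_units(network: SubbasinNetwork, main_basin: str) -> set[str]:
    """All unit ids of one main hydrologic basin."""
    try:
        return set(network._basin_members[main_basin])
    except KeyError:
        raise SchemaError(f"unknown main basin id {main_basin!r}") from None


def write_network_csv(network: SubbasinNetwork, path) -> None:
    """Write the network to the CSV interface (UTF-8, header, empty
    ``next_down`` marks the outlet/sink)."""
    rows = [
        {
            "unit_id": u.id,
            "next_down": u.next_down if u.next_down is not None else "",
            "area_km2": u.area,
            "main_basin_id": u.main_basin,
            "coarse_id": u.coarse_parent if u.coarse_parent is not None else "",
        }
        for u in sorted(network.units.values(), key=lambda s: s.id)
    ]
    pd.DataFrame(rows, columns=NETWORK_COLUMNS).to_csv(path, index=False)


def read_network_csv(path) -> SubbasinNetwork:
    """Read a network from the CSV interface and validate it."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(NETWORK_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"network CSV {path}: missing columns {sorted(missing)}")
    df["area_km2"] = pd.to_numeric(df["area_km2"], errors="coerce")
    if df["area_km2"].isna().any():
        bad = df.loc[df["area_km2"].isna(), "unit_id"].iloc[0]
        raise SchemaError(f"network CSV {path}: non-numeric area for unit {bad!r}")
    return build_network(df)
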