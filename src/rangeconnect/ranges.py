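"""Species geographic ranges on the subbasin mesh.

Ranges can be supplied directly as sets of fine subbasin units (the
polygon-overlay pathway, pre-intersected upstream), or compiled from point
occurrence records referenced to coarse units and then refined to the fine
mesh through the guaranteed coarse→fine nesting.  Species with fewer than 10
occurrence records are dropped from the compiled pathway; raw (undeduplicated)
records are counted against that threshold.

Each species carries a diadromy flag — diadromous fish migrate between
freshwater and the sea, so their connectivity hinges on the link to the basin
mouth — plus optional trait metadata (taxonomic order, maximum body length,
IUCN threat status, commercial relevance, main climate zone) used only for
group-level summaries.  Trait values outside the closed vocabularies are
treated as missing, mirroring incomplete metadata in real species tables.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError
from .network import SubbasinNetwork

__all__ = [
    "SpeciesRange",
    "OccurrenceRecord",
    "DIADROMY_LABELS",
    "IUCN_STATUSES",
    "COMMERCIAL_LABELS",
    "CLIMATE_ZONES",
    "compile_range_from_occurrences",
    "refine_range",
    "assign_climate_zone",
    "read_ranges_csv",
    "write_ranges_csv",
    "read_species_metadata_csv",
    "write_species_metadata_csv",
    "read_occurrences_csv",
    "write_occurrences_csv",
]

DIADROMY_LABELS = ("diadromous", "nondiadromous")
IUCN_STATUSES = ("CR", "EN", "VU", "NT", "LC", "DD")
COMMERCIAL_LABELS = ("Com.", "HCom.", "MCom.", "NonInt.", "Subs.")
#: Köppen–Geiger main zones: A equatorial, B arid, C warm temperate,
#: D snow, E polar.  The tuple order is also the tie-break order.
CLIMATE_ZONES = ("A", "B", "C", "D", "E")

_TRAIT_VOCAB = {
    "iucn_status": set(IUCN_STATUSES),
    "commercial": set(COMMERCIAL_LABELS),
    "climate_zone": set(CLIMATE_ZONES),
}


@dataclass(frozen=True)
class SpeciesRange:
    """A species' occupied fine-unit set plus diadromy and optional traits."""

    species: str
    units: frozenset[str]
    diadromy: str
    traits: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.units:
            raise SchemaError(f"species {self.species!r}: empty range")
        if self.diadromy not in DIADROMY_LABELS:
            raise SchemaError(
                f"species {self.species!r}: diadromy must be one of "
                f"{DIADROMY_LABELS}, got {self.diadromy!r}"
            )

    def validate_against(self, network: SubbasinNetwork) -> None:
        unknown = sorted(self.units - network.units.keys())
        if unknown:
            raise SchemaError(
                f"species {self.species!r}: range references unknown units "
                f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}"
            )


@dataclass(frozen=True)
class OccurrenceRecord:
    """One point occurrence, referenced to the coarse unit containing it."""

    species: str
    coarse_unit: str


def compile_range_from_occurrences(
    records: Iterable[OccurrenceRecord] | pd.DataFrame,
    min_records: int = 10,
) -> dict[str, frozenset[str]]:
    """Compile per-species coarse-unit ranges from point occurrence records.

    A species' range is the set of distinct coarse units holding at least
    one of its records.  Species with fewer than ``min_records`` raw records
    in total are dropped entirely (the compiled-range quality threshold);
    dropping is silent at this level and reported by callers.
    """
    if isinstance(records, pd.DataFrame):
        missing = {"species_id", "coarse_id"} - set(records.columns)
        if missing:
            raise SchemaError(f"occurrence table missing columns: {sorted(missing)}")
        pairs = [(str(r.species_id), str(r.coarse_id)) for r in records.itertuples(index=False)]
    else:
        pairs = [(r.species, r.coarse_unit) for r in records]
    if not pairs:
        raise SchemaError("no occurrence records supplied")

    counts: dict[str, int] = {}
    units: dict[str, set[str]] = {}
    for sp, cu in pairs:
        counts[sp] = counts.get(sp, 0) + 1
        units.setdefault(sp, set()).add(cu)
    return {
        sp: frozenset(us) for sp, us in units.items() if counts[sp] >= min_records
    }


def refine_range(
    coarse_units: Iterable[str], network: SubbasinNetwork
) -> frozenset[str]:
    """Refine a coarse-unit range to all nested fine units.

    Coarse units nest fine units exactly, so refinement is the union of each
    coarse unit's fine members.  Coarse ids matching no fine unit are
    rejected.
    """
    members = network.coarse_members()
    coarse_units = set(coarse_units)
    unknown = sorted(coarse_units - members.keys())
    if unknown:
        raise SchemaError(f"coarse ids match no fine unit: {unknown}")
    fine: set[str] = set()
    for cu in coarse_units:
        fine |= members[cu]
    return frozenset(fine)


def assign_climate_zone(overlaps: Mapping[str, float]) -> str:
    """Main climate zone of a species: the zone with the largest range
    overlap area, ties broken in fixed zone order A, B, C, D, E."""
    unknown = sorted(set(overlaps) - set(CLIMATE_ZONES))
    if unknown:
        raise SchemaError(f"unknown climate zones: {unknown}")
    if any(v < 0 for v in overlaps.values()):
        raise SchemaError("overlap areas must be >= 0")
    if not any(v > 0 for v in overlaps.values()):
        raise SchemaError("all-zero climate overlaps: no zone can be assigned")
    return max(CLIMATE_ZONES, key=lambda z: (overlaps.get(z, 0.0), ))


# ---------------------------------------------------------------------------
# CSV interfaces

def write_ranges_csv(ranges: Iterable[SpeciesRange], path) -> None:
    """Long-format ranges CSV: one row per occupied fine unit."""
    rows = [
        {"species_id": r.species, "unit_id": u}
        for r in sorted(ranges, key=lambda r: r.species)
        for u in sorted(r.units)
    ]
    pd.DataFrame(rows, columns=["species_id", "unit_id"]).to_csv(path, index=False)


def write_species_metadata_csv(ranges: Iterable[SpeciesRange], path) -> None:
    cols = [
        "species_id", "diadromy", "order", "max_length_cm",
        "iucn_status", "commercial", "climate_zone",
    ]
    rows = []
    for r in sorted(ranges, key=lambda r: r.species):
        t = r.traits or {}
        rows.append({
            "species_id": r.species,
            "diadromy": r.diadromy,
            "order": t.get("order", ""),
            "max_length_cm": t.get("max_length_cm", ""),
            "iucn_status": t.get("iucn_status", ""),
            "commercial": t.get("commercial", ""),
            "climate_zone": t.get("climate_zone", ""),
        })
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_ranges_csv(
    ranges_path, metadata_path, network: SubbasinNetwork | None = None
) -> list[SpeciesRange]:
    """Read the long-format ranges CSV plus the species metadata CSV.

    Diadromy is required for every species appearing in the ranges table;
    other traits are optional, and values outside the closed vocabularies
    become missing.
    """
    long_df = pd.read_csv(ranges_path, dtype=str, keep_default_na=False)
    missing = {"species_id", "unit_id"} - set(long_df.columns)
    if missing:
        raise SchemaError(f"ranges CSV {ranges_path}: missing columns {sorted(missing)}")
    meta = read_species_metadata_csv(metadata_path)

    out: list[SpeciesRange] = []
    grouped = long_df.groupby("species_id", sort=True)["unit_id"]
    for sp, units in grouped:
        if sp not in meta.index:
            raise SchemaError(f"species {sp!r} in ranges but not in metadata")
        row = meta.loc[sp]
        traits = {
            k: row[k]
            for k in ("order", "max_length_cm", "iucn_status", "commercial", "climate_zone")
            if pd.notna(row[k])
        }
        sr = SpeciesRange(
            species=str(sp),
            units=frozenset(units.astype(str)),
            diadromy=str(row["diadromy"]),
            traits=traits,
        )
        if network is not None:
            sr.validate_against(network)
        out.append(sr)
    return out


def read_species_metadata_csv(path) -> pd.DataFrame:
    """Species metadata indexed by species id; vocabulary-invalid trait
    values are mapped to missing (NaN)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"species_id", "diadromy"} - set(df.columns)
    if missing:
        raise SchemaError(f"species CSV {path}: missing columns {sorted(missing)}")
    bad = df.loc[~df["diadromy"].isin(DIADROMY_LABELS), "diadromy"]
    if not bad.empty:
        raise SchemaError(f"species CSV {path}: invalid diadromy {bad.iloc[0]!r}")
    for col in ("order", "max_length_cm", "iucn_status", "commercial", "climate_zone"):
        if col not in df.columns:
            df[col] = pd.NA
    df = df.set_index("species_id")
    df["max_length_cm"] = pd.to_numeric(df["max_length_cm"], errors="coerce")
    df["order"] = df["order"].replace("", pd.NA)
    for col, vocab in _TRAIT_VOCAB.items():
        df.loc[~df[col].isin(vocab), col] = pd.NA
    return df


def read_occurrences_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"species_id", "coarse_id"} - set(df.columns)
    if missing:
        raise SchemaError(f"occurrences CSV {path}: missing columns {sorted(missing)}")
    return df


def write_occurrences_csv(records: pd.DataFrame, path) -> None:
    records[["species_id", "coarse_id"]].to_csv(path, index=False)
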