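"""Aggregation of species×basin CI values.

Four summary levels mirror how the index is reported:

* per species — area-weighted mean over the main basins the species
  occupies, weighted by the species' range area within each basin;
* per basin — unweighted mean over species occurring in the basin;
* per subbasin — unweighted mean, over species occupying the unit, of each
  species' CI in the basin containing that unit;
* per trait group — descriptive summaries (mean, SD, median, quartiles,
  2.5/97.5 percentiles) of species-level CI by climate zone, range-area or
  body-length bin, IUCN status, commercial relevance, or taxonomic order.

Scenario deltas (present − future, in percentage points) and paired
comparisons between two dam datasets round out the reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import HackParams, compute_ci_table
from .errors import SchemaError

__all__ = [
    "SUMMARY_COLUMNS",
    "species_mean_ci",
    "basin_mean_ci",
    "subbasin_mean_ci",
    "group_mean_ci",
    "delta_ci",
    "compare_dam_sets",
    "DamSetComparison",
]

SUMMARY_COLUMNS = [
    "grouping", "category", "scenario", "n_species",
    "mean", "sd", "median", "q25", "q75", "p2_5", "p97_5",
]

#: Default body-length bin edges (cm); the first bin is "<5".
DEFAULT_LENGTH_EDGES = (5.0, 10.0, 20.0, 40.0, 80.0)

#: Taxonomic orders with fewer species than this merge into "other".
SMALL_ORDER_THRESHOLD = 20


def species_mean_ci(ci_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-basin CI records to one CI per species and scenario.

    The species CI is the mean of its basin CIs weighted by the species'
    range area within each basin; a species occupying a single basin keeps
    that basin's CI unchanged.  The output also carries the species' total
    range area (summed over basins), used downstream for range-area binning.
    """
    if ci_table.empty:
        return pd.DataFrame(
            columns=["species_id", "scenario", "diadromy", "ci_percent", "range_area_km2"]
        )
    if (ci_table["range_area_km2"] <= 0).any():
        raise SchemaError("range_area_km2 weights must be > 0")

    def _one(g: pd.DataFrame) -> pd.Series:
        w = g["range_area_km2"].to_numpy(float)
        return pd.Series({
            "diadromy": g["diadromy"].iloc[0],
            "ci_percent": float(np.average(g["ci_percent"].to_numpy(float), weights=w)),
            "range_area_km2": float(w.sum()),
        })

    out = (
        ci_table.groupby(["species_id", "scenario"], sort=True)
        .apply(_one, include_groups=False)
        .reset_index()
    )
    return out


def basin_mean_ci(ci_table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean CI across the species occurring in each basin."""
    out = (
        ci_table.groupby(["main_basin_id", "scenario"], sort=True)
        .agg(n_species=("species_id", "nunique"), mean_ci=("ci_percent", "mean"))
        .reset_index()
    )
    return out


def subbasin_mean_ci(
    ci_table: pd.DataFrame, ranges, scenario: str, network
) -> pd.Series:
    """Mean CI per subbasin unit over the species occupying it.

    Each species contributes its basin-level CI for the basin containing
    the unit.  Units occupied by no species are absent from the result
    (range-less areas carry no index).
    """
    sub = ci_table[ci_table["scenario"] == scenario]
    ci_lookup = {
        (r.species_id, r.main_basin_id): r.ci_percent
        for r in sub.itertuples(index=False)
    }
    basin_of = {uid: u.main_basin for uid, u in network.units.items()}
    total: dict[str, float] = {}
    count: dict[str, int] = {}
    for r in ranges:
        for u in r.units:
            ci = ci_lookup.get((r.species, basin_of[u]))
            if ci is None:
                continue
            total[u] = total.get(u, 0.0) + ci
            count[u] = count.get(u, 0) + 1
    out = pd.Series(
        {u: total[u] / count[u] for u in total}, name="mean_ci", dtype=float
    )
    out.index.name = "unit_id"
    return out.sort_index()


def group_mean_ci(
    species_ci: pd.DataFrame,
    metadata: pd.DataFrame,
    grouping: str,
    bins: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Descriptive CI summaries per trait category or numeric bin.

    Supported groupings: ``climate_zone``, ``iucn_status``, ``commercial``,
    ``order`` (categories with fewer than 20 species merge into "other"),
    ``max_length_cm`` (binned; default edges 5, 10, 20, 40, 80 cm), and
    ``range_area_km2`` (binned on log10 area; default integer edges).
    Species with missing metadata for the requested trait are excluded from
    that grouping.  Whiskers are the empirical 2.5–97.5 percentiles with
    linear interpolation.
    """
    known = {"climate_zone", "iucn_status", "commercial", "order",
             "max_length_cm", "range_area_km2"}
    if grouping not in known:
        raise SchemaError(f"unknown grouping {grouping!r} (expected one of {sorted(known)})")

    df = species_ci.copy()
    if grouping == "range_area_km2":
        logs = np.log10(df["range_area_km2"].to_numpy(float))
        if bins is None:
            lo, hi = int(np.floor(logs.min())), int(np.ceil(logs.max()))
            bins = tuple(range(lo + 1, hi))  # interior integer edges
        df["category"] = _bin_labels(logs, bins, fmt="10^{:g}")
    else:
        meta_col = metadata[grouping] if grouping in metadata.columns else None
        if meta_col is None:
            raise SchemaError(f"metadata has no column {grouping!r}")
        df = df.join(meta_col, on="species_id")
        df = df[df[grouping].notna()]
        if grouping == "max_length_cm":
            if bins is None:
                bins = DEFAULT_LENGTH_EDGES
            df["category"] = _bin_labels(
                df["max_length_cm"].to_numpy(float), bins, fmt="{:g}"
            )
        else:
            df["category"] = df[grouping].astype(str)
            if grouping == "order":
                counts = df.groupby("category")["species_id"].nunique()
                small = set(counts[counts < SMALL_ORDER_THRESHOLD].index)
                df.loc[df["category"].isin(small), "category"] = "other"

    rows = []
    for (cat, scen), g in df.groupby(["category", "scenario"], sort=True,
                                     observed=True):
        ci = g["ci_percent"].to_numpy(float)
        q = np.percentile(ci, [2.5, 25, 50, 75, 97.5])
        rows.append({
            "grouping": grouping,
            "category": cat,
            "scenario": scen,
            "n_species": int(g["species_id"].nunique()),
            "mean": float(ci.mean()),
            "sd": float(ci.std(ddof=1)) if len(ci) > 1 else 0.0,
            "median": float(q[2]),
            "q25": float(q[1]),
            "q75": float(q[3]),
            "p2_5": float(q[0]),
            "p97_5": float(q[4]),
        })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def _bin_labels(values: np.ndarray, edges: tuple[float, ...], fmt: str) -> pd.Categorical:
    """Half-open bins (-inf, e1), [e1, e2), ..., [ek, inf) with readable labels."""
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise SchemaError(f"bin edges must be strictly increasing: {edges}")
    labels = [f"<{fmt.format(edges[0])}"]
    labels += [
        f"{fmt.format(a)}-{fmt.format(b)}" for a, b in zip(edges, edges[1:])
    ]
    labels += [f">={fmt.format(edges[-1])}"]
    idx = np.searchsorted(edges, values, side="right")
    return pd.Categorical([labels[i] for i in idx], categories=labels, ordered=True)


def delta_ci(present: pd.DataFrame, future: pd.DataFrame) -> pd.DataFrame:
    """Per-key drop in CI between scenarios, in percentage points.

    Inputs are CI tables (or species-level tables) sharing key columns;
    the result carries ``delta = present − future``, nonnegative whenever
    the future dam set contains the present one.  Mismatched keys are
    rejected.
    """
    keys = [c for c in ("species_id", "main_basin_id") if c in present.columns]
    if not keys:
        raise SchemaError("no key columns (species_id/main_basin_id) found")
    p = present.set_index(keys)["ci_percent"]
    f = future.set_index(keys)["ci_percent"]
    if set(p.index) != set(f.index):
        only_p = sorted(set(p.index) - set(f.index))[:3]
        only_f = sorted(set(f.index) - set(p.index))[:3]
        raise SchemaError(
            f"key mismatch between scenarios: only-present {only_p}, only-future {only_f}"
        )
    out = pd.DataFrame({
        "ci_present": p,
        "ci_future": f.reindex(p.index),
    })
    out["delta"] = out["ci_present"] - out["ci_future"]
    return out.reset_index()


@dataclass(frozen=True)
class DamSetComparison:
    """Paired species CI under two dam sets plus the mean difference."""

    per_species: pd.DataFrame  # species_id, diadromy, ci_a, ci_b, delta
    mean_delta: float


def compare_dam_sets(
    network,
    ranges,
    dams_a: pd.DataFrame,
    dams_b: pd.DataFrame,
    params: HackParams = HackParams(),
) -> DamSetComparison:
    """Species-level CI under two alternative dam datasets.

    Both tables are treated as complete barrier sets (all statuses active,
    i.e. the ``future`` composition), matching how alternative dam datasets
    are contrasted — e.g. large dams only versus large plus small dams.
    ``delta = ci_a − ci_b`` per species; the mean delta summarizes the
    additional fragmentation attributable to set B's extra barriers.
    """
    ranges = list(ranges)
    sp_a = species_mean_ci(compute_ci_table(network, dams_a, ranges, "future", params))
    sp_b = species_mean_ci(compute_ci_table(network, dams_b, ranges, "future", params))
    a = sp_a.set_index("species_id")
    b = sp_b.set_index("species_id")
    if set(a.index) != set(b.index):
        raise SchemaError("species sets differ between the two dam-set runs")
    paired = pd.DataFrame({
        "diadromy": a["diadromy"],
        "ci_a": a["ci_percent"],
        "ci_b": b["ci_percent"].reindex(a.index),
    })
    paired["delta"] = paired["ci_a"] - paired["ci_b"]
    paired = paired.reset_index()
    return DamSetComparison(per_species=paired, mean_delta=float(paired["delta"].mean()))
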