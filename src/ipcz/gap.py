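"""Conservation-gap analysis: fishing effort, effort hotspots, MPA coverage.

Fishing records are classified by gear into mollusk-targeting, non-mollusk
and ambiguous effort, aggregated into monthly class totals and per-cell
annual grids (with the ln(1+x) transform used for mapping — monotone, so it
never changes a quantile hotspot set). Effort hotspots are the top 20% of
cells by annual intensity, with the quantile computed over cells that have
positive effort (including the empty ocean would make the threshold
trivially low; a flag restores the all-cells variant). Closed-season
statistics compare May–July against the year. MPA coverage of the priority
mask is the area-weighted fraction of priority-cell boxes intersected by the
MPA union under the planar 111 km/degree approximation; a binary
any-intersection variant is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box, shape
from shapely.ops import unary_union

from .grid import GridSpec, assign_cells
from .hotspots import PriorityMask
from .synthetic import DEFAULT_GEARS

EFFORT_CLASSES = ("mollusk", "non_mollusk", "ambiguous")
CLOSED_SEASON = (5, 7)  # May through July, inclusive


@dataclass
class GearClassification:
    """Total mapping from gear strings to effort classes (unknown → ambiguous)."""

    mapping: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GEARS))

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.mapping.items() if c not in EFFORT_CLASSES}
        if bad:
            raise ValueError(f"unknown effort classes in gear mapping: {bad}")

    def classify(self, gear: pd.Series) -> pd.Series:
        return gear.map(self.mapping).fillna("ambiguous")

    @classmethod
    def from_csv(cls, path) -> "GearClassification":
        df = pd.read_csv(path)
        return cls(dict(zip(df["gear"], df["effort_class"])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gear": list(self.mapping), "effort_class": list(self.mapping.values())}
        )


@dataclass
class EffortGrid:
    """Per-cell annual hours by effort class for one focal year."""

    year: int
    hours: pd.DataFrame  # index cell_id, one column per effort class
    log_hours: pd.DataFrame  # ln(1 + hours)

    def annual_cell_totals(self, effort_class: str = "mollusk") -> pd.Series:
        return self.hours[effort_class]


def latest_complete_year(monthly: pd.DataFrame) -> int:
    """The most recent year with all 12 months present in the monthly totals."""
    months_per_year = monthly.groupby("year")["month"].nunique()
    complete = months_per_year[months_per_year == 12]
    if complete.empty:
        raise ValueError("no year has all 12 months of effort data")
    return int(complete.index.max())


def classify_and_aggregate(
    effort: pd.DataFrame,
    gears: GearClassification | None = None,
    spec: GridSpec | None = None,
    focal_year: int | None = None,
) -> tuple[pd.DataFrame, EffortGrid, dict]:
    """Classify effort records by gear and aggregate.

    Returns (monthly class totals, per-cell annual EffortGrid for the focal
    year, log dict). Rows with negative hours are rejected and counted.
    """
    gears = gears or GearClassification()
    spec = spec or GridSpec()
    df = effort.copy()
    df["hours"] = pd.to_numeric(df["hours"], errors="coerce")
    bad = df["hours"].isna() | (df["hours"] < 0)
    log = {"n_input": len(df), "n_rejected_hours": int(bad.sum())}
    df = df[~bad]
    if not df["month"].between(1, 12).all():
        raise ValueError("effort months must lie in 1..12")
    df["effort_class"] = gears.classify(df["gear"])
    monthly = (
        df.groupby(["year", "month", "effort_class"], observed=True)["hours"]
        .sum()
        .reset_index()
    )
    year = focal_year if focal_year is not None else latest_complete_year(monthly)
    dfy = df[df["year"] == year].copy()
    dfy["cell_id"] = assign_cells(
        dfy["lat"].to_numpy(dtype=float), dfy["lon"].to_numpy(dtype=float), spec
    )
    dfy = dfy[dfy["cell_id"] >= 0]
    hours = (
        dfy.groupby(["cell_id", "effort_class"], observed=True)["hours"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(pd.RangeIndex(spec.n_cells, name="cell_id"), fill_value=0.0)
        .reindex(columns=list(EFFORT_CLASSES), fill_value=0.0)
    )
    grid = EffortGrid(year=year, hours=hours, log_hours=np.log1p(hours))
    log["focal_year"] = year
    return monthly, grid, log


def closed_season_stats(
    monthly: pd.DataFrame, window: tuple[int, int] = CLOSED_SEASON
) -> dict:
    """Seasonal effort shares for the closed-season window (default May–July).

    Shares are computed over classified effort only (ambiguous excluded).
    Missing months count as zero. Returns:

    * ``window_mollusk_share`` — mollusk share of classified effort inside
      the window;
    * ``annual_mollusk_share`` — same over the whole year;
    * ``mollusk_window_fraction`` — window mollusk hours / annual mollusk
      hours;
    * ``non_mollusk_window_fraction`` — likewise for non-mollusk effort.
    """
    m0, m1 = window
    classified = monthly[monthly["effort_class"].isin(("mollusk", "non_mollusk"))]
    in_window = classified["month"].between(m0, m1)

    def total(df: pd.DataFrame, effort_class: str | None = None) -> float:
        sel = df if effort_class is None else df[df["effort_class"] == effort_class]
        return float(sel["hours"].sum())

    win = classified[in_window]
    annual_mollusk = total(classified, "mollusk")
    annual_non = total(classified, "non_mollusk")
    win_total = total(win)
    return {
        "window": window,
        "window_mollusk_share": total(win, "mollusk") / win_total if win_total else 0.0,
        "annual_mollusk_share": (
            annual_mollusk / (annual_mollusk + annual_non)
            if annual_mollusk + annual_non
            else 0.0
        ),
        "mollusk_window_fraction": (
            total(win, "mollusk") / annual_mollusk if annual_mollusk else 0.0
        ),
        "non_mollusk_window_fraction": (
            total(win, "non_mollusk") / annual_non if annual_non else 0.0
        ),
    }


def effort_hotspots(
    cell_hours: pd.Series, q: float = 0.80, include_zero_cells: bool = False
) -> set[int]:
    """Cells in the top (1−q) tail of annual effort (ties at the threshold in).

    The quantile is computed over positive-effort cells unless
    ``include_zero_cells``; an all-zero grid yields the empty set.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    x = cell_hours[cell_hours > 0] if not include_zero_cells else cell_hours
    if x.empty or (x <= 0).all() and not include_zero_cells:
        return set()
    threshold = float(np.quantile(x.to_numpy(), q))
    eligible = cell_hours[cell_hours > 0] if not include_zero_cells else cell_hours
    return set(int(c) for c in eligible[eligible >= threshold].index)


def _validated_polygons(mpas: dict) -> list:
    polys = []
    for i, feature in enumerate(mpas.get("features", [])):
        geom = shape(feature["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid MPA geometry at feature index {i}")
        polys.append(geom)
    return polys


def mpa_coverage(
    mask: PriorityMask, mpas: dict, spec: GridSpec
) -> tuple[float, float, pd.Series]:
    """MPA coverage of the priority mask.

    Returns (area-weighted coverage fraction, binary any-intersection
    fraction, per-priority-cell covered fraction). All areas are planar in
    degrees — cells are equal-size squares under the 111 km/degree
    approximation, so the area-weighted mean is the mean per-cell fraction.
    """
    cells = mask.cells
    if cells.size == 0:
        return 0.0, 0.0, pd.Series(dtype=float)
    polys = _validated_polygons(mpas)
    union = unary_union(polys) if polys else None
    fractions = {}
    for c in cells:
        row, col = spec.rowcol(int(c))
        la0, la1, lo0, lo1 = spec.cell_bounds(row, col)
        cell_box = box(lo0, la0, lo1, la1)
        if union is None:
            fractions[int(c)] = 0.0
        else:
            fractions[int(c)] = cell_box.intersection(union).area / cell_box.area
    per_cell = pd.Series(fractions, name="covered_fraction")
    area_weighted = float(per_cell.mean())
    binary = float((per_cell > 0).mean())
    return area_weighted, binary, per_cell


@dataclass
class GapReport:
    """Coverage and fishing-pressure statistics for the priority mask."""

    focal_year: int
    n_priority_cells: int
    mpa_coverage_fraction: float  # area-weighted
    mpa_coverage_fraction_binary: float
    effort_hotspot_cells: set[int]
    priority_hotspot_cells: set[int]  # priority ∩ effort hotspots
    priority_covered_cells: set[int]  # priority ∩ MPA (any intersection)
    overlap_cells: set[int]  # priority ∩ MPA ∩ effort hotspots
    seasonal: dict

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        for k in ("effort_hotspot_cells", "priority_hotspot_cells", "priority_covered_cells", "overlap_cells"):
            d[k] = sorted(d[k])
        return d


def pressure_overlap(
    mask: PriorityMask,
    per_cell_coverage: pd.Series,
    hotspot_cells: set[int],
    seasonal: dict,
    focal_year: int,
) -> GapReport:
    """Combine MPA coverage and effort hotspots over the priority mask.

    The overlap set — priority cells that are MPA-covered *and* effort
    hotspots — is the "protected yet still under high fishing pressure" set.
    """
    priority = set(int(c) for c in mask.cells)
    covered = set(int(c) for c in per_cell_coverage[per_cell_coverage > 0].index) & priority
    hot_in_priority = priority & hotspot_cells
    return GapReport(
        focal_year=focal_year,
        n_priority_cells=len(priority),
        mpa_coverage_fraction=float(per_cell_coverage.mean()) if len(per_cell_coverage) else 0.0,
        mpa_coverage_fraction_binary=(
            float((per_cell_coverage > 0).mean()) if len(per_cell_coverage) else 0.0
        ),
        effort_hotspot_cells=hotspot_cells,
        priority_hotspot_cells=hot_in_priority,
        priority_covered_cells=covered,
        overlap_cells=covered & hot_in_priority,
        seasonal=seasonal,
    )
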