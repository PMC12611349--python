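"""Reading, validation, cleaning and threatened/non-threatened partitioning.

The cleaning contract for occurrence tables: rows with unparseable
coordinates or dates are dropped (and counted, per reason), rows outside the
configured temporal window or the study bounding box are dropped, and exact
duplicates on (species, lat, lon, event_date) — coordinates compared after
rounding to 4 decimals (~11 m) — are collapsed to one. Cleaning is
idempotent and order-invariant, and never mutates its input.

"Threatened" membership follows the union rule used in regional mollusk
assessments: a species is threatened if it carries any IUCN Red List
category from a configured set (by default all listed categories, including
LC and DD — mollusk conservation lists routinely include both) OR appears in
CITES Appendix I or II. Species absent from the lookup are non-threatened.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec

OCCURRENCE_COLUMNS = ("species", "taxon_class", "lat", "lon", "event_date", "source")

#: IUCN categories that qualify a species as threatened, by default.
DEFAULT_THREATENED_IUCN = frozenset({"CR", "EN", "VU", "NT", "LC", "DD"})
CITES_THREATENED = frozenset({"I", "II"})

DEFAULT_WINDOW = ("2000-01-01", "2024-12-31")

COORD_DECIMALS = 4


@dataclass
class CleaningLog:
    """Per-reason row counts from one cleaning pass."""

    n_input: int = 0
    n_bad_coords: int = 0
    n_bad_date: int = 0
    n_outside_window: int = 0
    n_outside_bounds: int = 0
    n_duplicates: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def clean_occurrences(
    raw: pd.DataFrame,
    window: tuple[str, str] = DEFAULT_WINDOW,
    bounds: GridSpec | None = None,
    allow_missing_date: bool = False,
) -> tuple[pd.DataFrame, CleaningLog]:
    """Clean an occurrence table; returns (kept rows, per-reason log).

    Raises ``ValueError`` if a required column is missing (fatal); bad rows
    are dropped and counted, never fatal.
    """
    bounds = bounds or GridSpec()
    missing = [c for c in OCCURRENCE_COLUMNS if c != "source" and c not in raw.columns]
    if missing:
        raise ValueError(f"occurrence table is missing required columns: {missing}")
    log = CleaningLog(n_input=len(raw))

    df = raw.copy()
    if "source" not in df.columns:
        df["source"] = ""
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    ok_coords = df["lat"].notna() & df["lon"].notna()
    ok_coords &= df["lat"].between(-90, 90) & (df["lon"] > -180) & (df["lon"] <= 180)
    log.n_bad_coords = int((~ok_coords).sum())
    df = df[ok_coords]

    dates = pd.to_datetime(df["event_date"], errors="coerce", format="mixed")
    if allow_missing_date:
        ok_date = np.ones(len(df), dtype=bool)
    else:
        ok_date = dates.notna().to_numpy()
    log.n_bad_date = int((~ok_date).sum())
    df = df[ok_date]
    dates = dates[ok_date]

    w0, w1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    in_window = (dates.isna() | ((dates >= w0) & (dates <= w1))).to_numpy()
    log.n_outside_window = int((~in_window).sum())
    df = df[in_window]

    in_bounds = (
        df["lat"].between(bounds.lat_min, bounds.lat_max)
        & df["lon"].between(bounds.lon_min, bounds.lon_max)
    ).to_numpy()
    log.n_outside_bounds = int((~in_bounds).sum())
    df = df[in_bounds]

    key = pd.DataFrame(
        {
            "species": df["species"],
            "lat": df["lat"].round(COORD_DECIMALS),
            "lon": df["lon"].round(COORD_DECIMALS),
            "event_date": pd.to_datetime(df["event_date"], errors="coerce", format="mixed"),
        }
    )
    # stable sort so the kept representative is input-order independent
    order = key.sort_values(["species", "lat", "lon", "event_date"], kind="mergesort").index
    dup = key.loc[order].duplicated().to_numpy()
    keep_idx = order[~dup].sort_values()
    log.n_duplicates = int(dup.sum())
    out = df.loc[keep_idx].reset_index(drop=True)
    out["event_date"] = pd.to_datetime(out["event_date"], format="mixed").dt.strftime("%Y-%m-%d")
    log.n_kept = len(out)
    return out, log


def load_status(path: str | Path) -> pd.DataFrame:
    """Load a threatened-status lookup CSV (species, iucn, cites_appendix)."""
    df = pd.read_csv(path)
    return validate_status(df)


def validate_status(status: pd.DataFrame) -> pd.DataFrame:
    for col in ("species", "iucn", "cites_appendix"):
        if col not in status.columns:
            raise ValueError(f"status table is missing column {col!r}")
    if status["species"].duplicated().any():
        dupes = status.loc[status["species"].duplicated(), "species"].tolist()
        raise ValueError(f"species listed more than once in status table: {dupes[:5]}")
    return status


def threatened_species(
    status: pd.DataFrame,
    iucn_set: frozenset[str] = DEFAULT_THREATENED_IUCN,
) -> set[str]:
    """The set of species the status table qualifies as threatened."""
    is_threatened = status["iucn"].isin(iucn_set) | status["cites_appendix"].isin(
        CITES_THREATENED
    )
    return set(status.loc[is_threatened, "species"])


def split_threatened(
    occ: pd.DataFrame,
    status: pd.DataFrame,
    iucn_set: frozenset[str] = DEFAULT_THREATENED_IUCN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition occurrences into (threatened, non-threatened) record tables.

    Species absent from the lookup count as non-threatened. The two outputs
    partition the input exactly.
    """
    thr = threatened_species(status, iucn_set) if len(status) else set()
    mask = occ["species"].isin(thr).to_numpy()
    return occ[mask].reset_index(drop=True), occ[~mask].reset_index(drop=True)


@dataclass
class ThreatCrosstab:
    """Cross-tabulation of threatened species by class, category and appendix.

    ``class_totals`` count each species once even when it is listed by both
    the IUCN Red List and CITES (dual listings are common for cephalopods).
    """

    by_iucn: pd.DataFrame  # IUCN category × taxon class species counts
    by_cites: pd.DataFrame  # CITES appendix × taxon class species counts
    class_totals: pd.Series  # per-class union species counts
    n_species: int
    n_records: int
    category_totals: pd.Series = field(default=None)  # per-IUCN-category totals
    appendix_totals: pd.Series = field(default=None)


def tabulate_threat_categories(
    status: pd.DataFrame,
    occ: pd.DataFrame | None = None,
    iucn_set: frozenset[str] = DEFAULT_THREATENED_IUCN,
) -> ThreatCrosstab:
    """Count threatened species per taxon class, IUCN category and CITES appendix.

    Only species present in ``occ`` are counted (pass None to count the whole
    lookup). A species listed by both the Red List and CITES contributes to
    both marginal tables but is counted once in the per-class totals.
    """
    st = status.copy()
    if "taxon_class" not in st.columns:
        if occ is None:
            raise ValueError("status table lacks taxon_class and no occurrences given")
        st = st.merge(
            occ[["species", "taxon_class"]].drop_duplicates("species"), on="species", how="left"
        )
    if occ is not None:
        present = set(occ["species"])
        st = st[st["species"].isin(present)]
        n_records = int(occ["species"].isin(threatened_species(status, iucn_set)).sum())
    else:
        n_records = 0

    iucn_listed = st[st["iucn"].isin(iucn_set)]
    cites_listed = st[st["cites_appendix"].isin(CITES_THREATENED)]
    union = st[st["iucn"].isin(iucn_set) | st["cites_appendix"].isin(CITES_THREATENED)]

    by_iucn = (
        iucn_listed.groupby(["iucn", "taxon_class"], observed=True)["species"]
        .nunique()
        .unstack(fill_value=0)
    )
    by_cites = (
        cites_listed.groupby(["cites_appendix", "taxon_class"], observed=True)["species"]
        .nunique()
        .unstack(fill_value=0)
    )
    class_totals = union.groupby("taxon_class")["species"].nunique()
    return ThreatCrosstab(
        by_iucn=by_iucn,
        by_cites=by_cites,
        class_totals=class_totals,
        n_species=int(union["species"].nunique()),
        n_records=n_records,
        category_totals=by_iucn.sum(axis=1) if len(by_iucn) else pd.Series(dtype=int),
        appendix_totals=by_cites.sum(axis=1) if len(by_cites) else pd.Series(dtype=int),
    )


def load_habitats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("habitat", "lat", "lon"):
        if col not in df.columns:
            raise ValueError(f"habitat table is missing column {col!r}")
    bad = ~df["habitat"].isin(("coral", "seagrass", "mangrove"))
    if bad.any():
        raise ValueError(f"unknown habitat labels: {sorted(df.loc[bad, 'habitat'].unique())}")
    if not np.isfinite(df[["lat", "lon"]].to_numpy(dtype=float)).all():
        raise ValueError("non-finite habitat coordinates")
    return df


def load_effort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("lat", "lon", "year", "month", "gear", "hours"):
        if col not in df.columns:
            raise ValueError(f"effort table is missing column {col!r}")
    return df


def load_mpas(path: str | Path) -> dict:
    """Load an MPA polygon layer from GeoJSON (WGS84)."""
    gj = json.loads(Path(path).read_text())
    if gj.get("type") != "FeatureCollection":
        raise ValueError("MPA file is not a GeoJSON FeatureCollection")
    return gj
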