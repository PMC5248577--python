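"""Photo-record ingestion and detection-history construction.

Camera-trap surveys produce timestamped species photographs per station.
Two analysis branches consume them differently:

* the occupancy branch collapses photos to daily detection/nondetection
  per station for one focal survey month per year (the month with the
  most records of the dominant species), with prey covariates measured
  as the proportion of surveyed days on which each prey was photographed;
* the activity branch keeps timestamps but thins them with a minimum
  inter-photo gap (default 1 h, per station per species) so events can be
  treated as independent.

Species vocabulary is closed: two predators (jaguar, puma) and three
prey (deer, peccary, calf).
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "PhotoRecordSet",
    "EventSet",
    "TwoSpeciesHistory",
    "load_photo_records",
    "write_photo_records",
    "select_focal_month",
    "collapse_daily",
    "filter_independent_events",
    "prey_covariate",
    "build_two_species_histories",
    "write_history_csv",
    "read_history_csv",
]

SPECIES = ("jaguar", "puma", "deer", "peccary", "calf")


@dataclass
class PhotoRecordSet:
    """Validated photo records plus the station table.

    ``records``: columns station, species, datetime, year (sorted by
    station then time). ``stations``: one row per station-year with
    columns station, lat, lon, road, year, active_from, active_to.
    """

    records: pd.DataFrame
    stations: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)

    def active_days(self, station: str, year: int) -> pd.DatetimeIndex:
        """Calendar days the station was operating in the given year."""
        rows = self.stations[
            (self.stations["station"] == station) & (self.stations["year"] == year)
        ]
        days: list[pd.Timestamp] = []
        for _, r in rows.iterrows():
            days.extend(pd.date_range(r["active_from"], r["active_to"], freq="D"))
        return pd.DatetimeIndex(sorted(set(days)))


@dataclass
class EventSet:
    """Independence-filtered activity events for one species."""

    species: str
    events: pd.DataFrame  # columns: station, datetime, year
    sun_times: np.ndarray | None = None  # radians in [0, 2*pi)

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class TwoSpeciesHistory:
    """Paired daily detection histories for species A and B.

    ``yA``/``yB`` are (n_sites, n_occasions) arrays with entries 0/1 and
    NaN where the occasion was not surveyed; both share one mask. Each
    row is a site-year unit described by ``sites`` (station, year, prey
    covariates in [0, 1], road flag).
    """

    yA: np.ndarray
    yB: np.ndarray
    sites: pd.DataFrame
    species_a: str = "jaguar"
    species_b: str = "puma"

    def __post_init__(self) -> None:
        if self.yA.shape != self.yB.shape:
            raise ValueError("yA and yB must have identical shape")
        if not np.array_equal(np.isnan(self.yA), np.isnan(self.yB)):
            raise ValueError("yA and yB must share one missing mask")
        for arr in (self.yA, self.yB):
            vals = arr[~np.isnan(arr)]
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("unmasked history entries must be 0 or 1")
        for cov in ("deer", "peccary", "calf"):
            if cov in self.sites and not self.sites[cov].between(0, 1).all():
                raise ValueError(f"covariate {cov} outside [0, 1]")

    @property
    def n_sites(self) -> int:
        return self.yA.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.yA.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """True where the occasion was surveyed."""
        return ~np.isnan(self.yA)


class NoDataError(ValueError):
    """Raised when a species/year combination has no records."""


def load_photo_records(path, station_table) -> PhotoRecordSet:
    """Read and validate the photo-record and station CSVs.

    The record CSV needs columns (station, species, datetime); the
    station table needs (station, lat, lon, road, year, active_from,
    active_to). Unknown species and unknown stations are rejected;
    unparseable datetimes are reported with their line numbers.
    """
    stations = pd.read_csv(station_table, comment="#")
    req = {"station", "lat", "lon", "road", "year", "active_from", "active_to"}
    if missing := req - set(stations.columns):
        raise ValueError(f"station table missing columns: {sorted(missing)}")
    stations["station"] = stations["station"].astype(str)
    for col in ("active_from", "active_to"):
        stations[col] = pd.to_datetime(stations[col])
    bad = stations[~stations["lat"].between(-90, 90) | ~stations["lon"].between(-180, 180)]
    if len(bad):
        raise ValueError(f"coordinates out of range for stations {bad['station'].tolist()}")

    rec = pd.read_csv(path, comment="#")
    if missing := {"station", "species", "datetime"} - set(rec.columns):
        raise ValueError(f"record CSV missing columns: {sorted(missing)}")
    rec["station"] = rec["station"].astype(str)

    parsed = pd.to_datetime(rec["datetime"], errors="coerce")
    if parsed.isna().any():
        lines = (rec.index[parsed.isna()] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"unparseable datetimes at lines {lines}")
    rec["datetime"] = parsed

    unknown = sorted(set(rec["species"]) - set(SPECIES))
    if unknown:
        raise ValueError(f"unknown species {unknown}; allowed: {list(SPECIES)}")
    orphan = sorted(set(rec["station"]) - set(stations["station"]))
    if orphan:
        raise ValueError(f"stations absent from station table: {orphan}")

    rec["year"] = rec["datetime"].dt.year
    rec = rec.sort_values(["station", "datetime"], kind="stable").reset_index(drop=True)
    prs = PhotoRecordSet(records=rec, stations=stations)

    # soft check: photos outside the station's active calendar are kept
    # (they may still feed the activity branch) but flagged
    n_outside = 0
    for (st, yr), grp in rec.groupby(["station", "year"]):
        active = set(prs.active_days(st, yr).date)
        n_outside += sum(d not in active for d in grp["datetime"].dt.date)
    if n_outside:
        warnings.warn(
            f"{n_outside} photos fall outside their station's active calendar",
            stacklevel=2,
        )
    return prs


def write_photo_records(prs: PhotoRecordSet, records_path, stations_path) -> None:
    """Write the record and station CSVs in the dialect `load_photo_records` reads."""
    out = prs.records[["station", "species", "datetime"]].copy()
    out["datetime"] = out["datetime"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(records_path, index=False)
    st = prs.stations.copy()
    for col in ("active_from", "active_to"):
        st[col] = pd.to_datetime(st[col]).dt.strftime("%Y-%m-%d")
    st.to_csv(stations_path, index=False)


def select_focal_month(prs: PhotoRecordSet, species: str, year: int) -> int:
    """Calendar month with the most records of `species` in `year`.

    Ties resolve to the earliest month, deterministically.
    """
    sel = prs.records[(prs.records["species"] == species) & (prs.records["year"] == year)]
    if sel.empty:
        raise NoDataError(f"no {species} records in {year}")
    counts = sel["datetime"].dt.month.value_counts().reindex(range(1, 13), fill_value=0)
    return int(counts.idxmax())  # idxmax returns the first (earliest) maximum


def collapse_daily(prs: PhotoRecordSet, species: str, year: int, month: int) -> pd.DataFrame:
    """Daily detection matrix (stations x days) for one species and month.

    Entry 1 iff at least one photo of the species on that station-day,
    0 for surveyed days without a photo, NaN for days outside the
    station's active calendar (photos on inactive days are not counted).
    Stations with no active day in the month are excluded.
    """
    start = pd.Timestamp(year, month, 1)
    days = pd.date_range(start, start + pd.offsets.MonthEnd(0), freq="D")
    sel = prs.records[
        (prs.records["species"] == species)
        & (prs.records["datetime"].dt.year == year)
        & (prs.records["datetime"].dt.month == month)
    ]
    photo_days = set(zip(sel["station"], sel["datetime"].dt.normalize()))

    rows, index = [], []
    for st in prs.stations.loc[prs.stations["year"] == year, "station"].unique():
        active = set(prs.active_days(st, year))
        month_active = [d for d in days if d in active]
        if not month_active:
            continue
        row = np.full(len(days), np.nan)
        for j, d in enumerate(days):
            if d in active:
                row[j] = 1.0 if (st, d) in photo_days else 0.0
        rows.append(row)
        index.append(st)
    return pd.DataFrame(rows, index=index, columns=days)


def filter_independent_events(
    prs: PhotoRecordSet, species: str, gap: float = 1.0
) -> EventSet:
    """Thin photos to independent events with a minimum inter-photo gap.

    Greedy forward scan per station: a photo is kept iff it is at least
    ``gap`` hours after the last kept photo of the same species at the
    same station. Idempotent by construction.
    """
    sel = prs.records[prs.records["species"] == species]
    kept_idx: list[int] = []
    gap_td = pd.Timedelta(hours=gap)
    for _, grp in sel.groupby("station"):
        last = None
        for idx, t in grp["datetime"].items():
            if last is None or t - last >= gap_td:
                kept_idx.append(idx)
                last = t
    events = (
        sel.loc[kept_idx, ["station", "datetime", "year"]]
        .sort_values(["station", "datetime"])
        .reset_index(drop=True)
    )
    return EventSet(species=species, events=events)


def prey_covariate(
    prs: PhotoRecordSet,
    prey: str,
    station: str,
    year: int,
    month: int,
    survey_days: int,
) -> float:
    """Proportion of surveyed days with at least one photo of `prey`."""
    if survey_days < 1:
        raise ValueError("survey_days must be >= 1")
    sel = prs.records[
        (prs.records["species"] == prey)
        & (prs.records["station"] == station)
        & (prs.records["datetime"].dt.year == year)
        & (prs.records["datetime"].dt.month == month)
    ]
    active = set(prs.active_days(station, year))
    n_days = len({d for d in sel["datetime"].dt.normalize() if d in active})
    return n_days / survey_days


def build_two_species_histories(
    prs: PhotoRecordSet,
    focal_months: dict[int, int],
    species_a: str = "jaguar",
    species_b: str = "puma",
    prey: tuple[str, ...] = ("deer", "peccary", "calf"),
) -> TwoSpeciesHistory:
    """Assemble paired detection histories with covariates per site-year.

    One focal month per year; each surveyed day is an occasion. Rows are
    station-year units. Stations with zero active days in a year's focal
    month are dropped with a warning. Prey covariates are the proportion
    of that station's surveyed days with a photo of the prey.
    """
    blocks: list[tuple[np.ndarray, np.ndarray]] = []
    site_rows: list[dict] = []
    road = prs.stations.drop_duplicates("station").set_index("station")["road"]

    for year in sorted(focal_months):
        month = focal_months[year]
        mA = collapse_daily(prs, species_a, year, month)
        mB = collapse_daily(prs, species_b, year, month)
        year_stations = prs.stations.loc[prs.stations["year"] == year, "station"].unique()
        dropped = sorted(set(year_stations) - set(mA.index))
        if dropped:
            warnings.warn(
                f"{len(dropped)} stations with no active day in {year}-{month:02d} "
                f"dropped: {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                stacklevel=2,
            )
        for st in mA.index:
            a, b = mA.loc[st].to_numpy(), mB.loc[st].to_numpy()
            blocks.append((a, b))
            n_active = int((~np.isnan(a)).sum())
            row = {"station": st, "year": year, "road": int(road[st])}
            for p in prey:
                row[p] = prey_covariate(prs, p, st, year, month, n_active)
            site_rows.append(row)

    n_occ = max(len(a) for a, _ in blocks)
    yA = np.full((len(blocks), n_occ), np.nan)
    yB = np.full((len(blocks), n_occ), np.nan)
    for i, (a, b) in enumerate(blocks):
        yA[i, : len(a)] = a
        yB[i, : len(b)] = b
    return TwoSpeciesHistory(
        yA=yA,
        yB=yB,
        sites=pd.DataFrame(site_rows),
        species_a=species_a,
        species_b=species_b,
    )


def write_history_csv(hist: TwoSpeciesHistory, path) -> None:
    """Wide-format detection-history CSV: dA_1..dA_J, dB_1..dB_J, covariates.

    Missing occasions are written as ".".
    """
    J = hist.n_occasions
    out = hist.sites.copy()
    for j in range(J):
        out[f"dA_{j + 1}"] = [_cell(v) for v in hist.yA[:, j]]
    for j in range(J):
        out[f"dB_{j + 1}"] = [_cell(v) for v in hist.yB[:, j]]
    out.to_csv(path, index=False)


def _cell(v: float) -> str:
    return "." if np.isnan(v) else str(int(v))


def read_history_csv(path) -> TwoSpeciesHistory:
    """Read a detection-history CSV written by :func:`write_history_csv`."""
    df = pd.read_csv(path, comment="#", dtype=str)
    a_cols = sorted((c for c in df.columns if c.startswith("dA_")), key=lambda c: int(c[3:]))
    b_cols = sorted((c for c in df.columns if c.startswith("dB_")), key=lambda c: int(c[3:]))
    if len(a_cols) != len(b_cols) or not a_cols:
        raise ValueError("history CSV must contain matching dA_*/dB_* columns")

    def parse(cols: list[str]) -> np.ndarray:
        arr = df[cols].to_numpy()
        return np.where(arr == ".", np.nan, arr).astype(float)

    sites = df[[c for c in df.columns if not c.startswith(("dA_", "dB_"))]].copy()
    for col in sites.columns:
        if col != "station":
            sites[col] = pd.to_numeric(sites[col])
    sites["year"] = sites["year"].astype(int)
    return TwoSpeciesHistory(yA=parse(a_cols), yB=parse(b_cols), sites=sites)
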