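"""Relative-abundance profiles: RRA, focal-observation rates, and
temporal/individual aggregation.

Profiles are held in a :class:`DietProfileMatrix` (rows = profile units,
columns = taxa) whose rows are either compositions (sum to 1) or daily
observation rates (sum <= 1); rates are renormalized to compositions only
when they enter compositional analyses.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DietBarcoderError, SampleTable

MONTH_LABELS = [f"{m:02d}" for m in range(1, 13)]


# ---------------------------------------------------------------------------
# season calendar
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeasonCalendar:
    """Ordered seasons, each starting mid-month (at ``boundary_day``).

    A season ``(name, start_month)`` begins on ``boundary_day`` of its start
    month and runs to the day before the next season's boundary; together the
    seasons partition the year.
    """

    seasons: tuple  # ((name, start_month), ...)
    boundary_day: int = 16

    def __post_init__(self):
        if len(self.seasons) < 1:
            raise DietBarcoderError("calendar needs at least one season")
        names = [n for n, _ in self.seasons]
        if len(set(names)) != len(names):
            raise DietBarcoderError("duplicate season names")
        starts = [m for _, m in self.seasons]
        if len(set(starts)) != len(starts):
            raise DietBarcoderError("duplicate season start months")
        if any(not 1 <= m <= 12 for m in starts):
            raise DietBarcoderError("start months must be in 1..12")

    @property
    def names(self) -> list:
        return [n for n, _ in self.seasons]

    def _halfmonth_map(self) -> dict:
        # half-month index: (month-1)*2 + (day >= boundary_day)
        starts = sorted(
            ((m - 1) * 2 + 1, name) for name, m in self.seasons
        )
        mapping = {}
        for i, (start_hm, name) in enumerate(starts):
            next_hm = starts[(i + 1) % len(starts)][0]
            hm = start_hm
            while hm % 24 != next_hm or hm == start_hm:
                mapping[hm % 24] = name
                hm += 1
                if hm - start_hm > 24:  # pragma: no cover - guarded by ctor
                    raise DietBarcoderError("calendar does not close")
        if len(starts) == 1:
            mapping = {h: starts[0][1] for h in range(24)}
        return mapping

    def season_of(self, date) -> str:
        """Season of a date; the mapping is total over the year."""
        date = as_date(date)
        hm = (date.month - 1) * 2 + (1 if date.day >= self.boundary_day else 0)
        return self._halfmonth_map()[hm]

    def days_in_season(self, season: str, year: int = 2018) -> list:
        """All calendar dates of a (non-leap-aware) reference year in a season."""
        days = []
        d = dt.date(year, 1, 1)
        while d.year == year:
            if self.season_of(d) == season:
                days.append(d)
            d += dt.timedelta(days=1)
        return days


#: mid-month austral calendar: Aug-Nov spring, Nov-Mar summer,
#: Mar-May autumn, May-Aug winter.
VERVET_CALENDAR = SeasonCalendar(
    (("spring", 8), ("summer", 11), ("autumn", 3), ("winter", 5))
)


def default_calendar(n_seasons: int) -> SeasonCalendar:
    if n_seasons == 4:
        return VERVET_CALENDAR
    if not 1 <= n_seasons <= 12:
        raise DietBarcoderError("n_seasons must be in 1..12")
    starts = [1 + round(12 * i / n_seasons) for i in range(n_seasons)]
    return SeasonCalendar(
        tuple((f"season{i + 1}", m) for i, m in enumerate(starts))
    )


def as_date(date) -> dt.date:
    if isinstance(date, dt.datetime):
        return date.date()
    if isinstance(date, dt.date):
        return date
    return dt.date.fromisoformat(str(date))


def season_of(date, calendar: SeasonCalendar) -> str:
    return calendar.season_of(date)


# ---------------------------------------------------------------------------
# focal logs
# ---------------------------------------------------------------------------


@dataclass
class FocalLog:
    """Dated feeding-event records plus per-day focal screening totals."""

    events: pd.DataFrame  # date, individual_id, item, level
    screenings: pd.DataFrame  # date, count

    def __post_init__(self):
        for col in ("date", "individual_id", "item", "level"):
            if col not in self.events.columns:
                raise DietBarcoderError(f"events missing column {col!r}")
        for col in ("date", "count"):
            if col not in self.screenings.columns:
                raise DietBarcoderError(f"screenings missing column {col!r}")
        if (self.screenings["count"] <= 0).any():
            raise DietBarcoderError("screening counts must be positive")
        known = set(self.screenings["date"].astype(str))
        missing = set(self.events["date"].astype(str)) - known
        if missing:
            raise DietBarcoderError(
                f"events on days without screenings: {sorted(missing)[:5]}"
            )

    def item_totals(self) -> pd.Series:
        return self.events.groupby("item").size().sort_values(ascending=False)


# ---------------------------------------------------------------------------
# profile matrices
# ---------------------------------------------------------------------------


@dataclass
class DietProfileMatrix:
    """Profile units x taxa; ``kind`` is 'composition' (rows sum to 1) or
    'rate' (daily observation rates, row sums <= 1)."""

    values: pd.DataFrame
    meta: pd.DataFrame
    kind: str = "composition"

    def __post_init__(self):
        if self.kind not in ("composition", "rate"):
            raise DietBarcoderError(f"unknown profile kind {self.kind!r}")
        if not self.values.index.equals(self.meta.index):
            raise DietBarcoderError("values and meta index differ")
        vals = self.values.to_numpy(dtype=float)
        if (vals < 0).any():
            raise DietBarcoderError("negative profile values")
        sums = vals.sum(axis=1)
        if "empty" not in self.meta.columns:
            self.meta = self.meta.assign(empty=sums == 0)
        if self.kind == "composition":
            bad = ~np.isclose(sums, 1.0, atol=1e-9) & (sums > 0)
            if bad.any():
                raise DietBarcoderError("nonempty composition rows must sum to 1")

    @property
    def taxa(self) -> list:
        return list(self.values.columns)

    def nonempty(self) -> "DietProfileMatrix":
        keep = ~self.meta["empty"].to_numpy(dtype=bool)
        return DietProfileMatrix(
            self.values.loc[keep], self.meta.loc[keep], self.kind
        )

    def renormalized(self) -> "DietProfileMatrix":
        """Rates -> compositions (drops empty rows)."""
        sub = self.nonempty()
        vals = sub.values.div(sub.values.sum(axis=1), axis=0)
        return DietProfileMatrix(vals, sub.meta, "composition")


def _close(values: pd.DataFrame) -> tuple:
    sums = values.sum(axis=1)
    out = values.copy().astype(float)
    nz = sums > 0
    out.loc[nz] = out.loc[nz].div(sums[nz], axis=0)
    return out, ~nz


def to_rra(samples: SampleTable, calendar: SeasonCalendar | None = None) -> DietProfileMatrix:
    """Relative read abundance: each sample's counts divided by its total."""
    values = samples.values.T  # samples x taxa
    closed, empty = _close(values)
    meta = pd.DataFrame(index=values.index)
    meta["individual_id"] = samples.samples.get("individual_id", "")
    meta["group_id"] = samples.samples.get("group_id", "")
    meta["date"] = samples.samples.get("collection_date", "")
    if calendar is not None:
        meta["season"] = [
            calendar.season_of(d) if str(d) else "" for d in meta["date"]
        ]
    else:
        meta["season"] = ""
    meta["source"] = "edna"
    meta["empty"] = empty.to_numpy()
    return DietProfileMatrix(closed, meta, "composition")


def normalize_focal(
    log: FocalLog,
    calendar: SeasonCalendar | None = None,
    min_item_occurrence: int = 2,
) -> DietProfileMatrix:
    """Daily observation rates: item events per day / focal screenings that day.

    Items seen fewer than ``min_item_occurrence`` times in the whole log are
    dropped before normalization.
    """
    totals = log.item_totals()
    keep_items = sorted(totals.index[totals >= min_item_occurrence])
    events = log.events[log.events["item"].isin(keep_items)]
    screenings = log.screenings.copy()
    screenings["date"] = screenings["date"].astype(str)
    per_day = screenings.groupby("date")["count"].sum()
    if (per_day <= 0).any():
        raise DietBarcoderError("zero screenings on a recorded day")
    counts = (
        events.assign(date=events["date"].astype(str))
        .groupby(["date", "item"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=per_day.index, columns=keep_items, fill_value=0)
    )
    missing = set(counts.index) - set(per_day.index)
    if missing:
        raise DietBarcoderError(f"events on days without screenings: {missing}")
    rates = counts.div(per_day, axis=0)
    meta = pd.DataFrame(index=rates.index)
    meta["individual_id"] = ""
    meta["group_id"] = ""
    meta["date"] = rates.index
    meta["season"] = (
        [calendar.season_of(d) for d in rates.index] if calendar is not None else ""
    )
    meta["source"] = "focal"
    return DietProfileMatrix(rates, meta, "rate")


def focal_individual_profiles(
    log: FocalLog,
    calendar: SeasonCalendar,
    min_item_occurrence: int = 2,
) -> DietProfileMatrix:
    """Per focal individual/season event compositions (rows sum to 1)."""
    totals = log.item_totals()
    keep_items = sorted(totals.index[totals >= min_item_occurrence])
    events = log.events[log.events["item"].isin(keep_items)].copy()
    events["season"] = [calendar.season_of(d) for d in events["date"]]
    counts = (
        events.groupby(["individual_id", "season", "item"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=keep_items, fill_value=0)
    )
    closed, empty = _close(counts)
    idx = [f"{i}|{s}" for i, s in counts.index]
    closed.index = idx
    meta = pd.DataFrame(index=pd.Index(idx))
    meta["individual_id"] = [i for i, _ in counts.index]
    meta["group_id"] = ""
    meta["date"] = ""
    meta["season"] = [s for _, s in counts.index]
    meta["source"] = "focal"
    meta["empty"] = empty.to_numpy()
    return DietProfileMatrix(closed, meta, "composition")


def aggregate_temporal(
    profiles: DietProfileMatrix,
    unit: str = "month",
    calendar: SeasonCalendar | None = None,
) -> DietProfileMatrix:
    """Unweighted mean profile per month or season, pooling years.

    Empty rows are excluded from the means so composition closure is kept.
    """
    if unit not in ("month", "season"):
        raise DietBarcoderError("unit must be 'month' or 'season'")
    sub = profiles.nonempty()
    if sub.values.shape[0] == 0:
        raise DietBarcoderError("no nonempty rows to aggregate")
    if unit == "month":
        keys = [f"{as_date(d).month:02d}" for d in sub.meta["date"]]
        order = MONTH_LABELS
    else:
        seasons = sub.meta["season"]
        if (seasons == "").any():
            if calendar is None:
                raise DietBarcoderError("season metadata absent and no calendar given")
            seasons = pd.Series(
                [calendar.season_of(d) for d in sub.meta["date"]], index=sub.meta.index
            )
        keys = list(seasons)
        order = calendar.names if calendar is not None else sorted(set(keys))
    grouped = sub.values.groupby(pd.Index(keys, name=unit)).mean()
    grouped = grouped.reindex([k for k in order if k in grouped.index])
    meta = pd.DataFrame(index=grouped.index)
    meta["individual_id"] = ""
    meta["group_id"] = ""
    meta["date"] = ""
    meta["season"] = grouped.index if unit == "season" else ""
    meta["source"] = sub.meta["source"].iloc[0] if len(sub.meta) else ""
    return DietProfileMatrix(grouped, meta, profiles.kind)


def individual_weighted(
    profiles: DietProfileMatrix,
    calendar: SeasonCalendar | None = None,
) -> DietProfileMatrix:
    """One renormalized row per individual/season, so every individual
    carries the same weight regardless of its number of samples."""
    sub = profiles.nonempty()
    meta = sub.meta
    if (meta["individual_id"] == "").all():
        raise DietBarcoderError("individual metadata required")
    seasons = meta["season"]
    if (seasons == "").any():
        if calendar is None:
            raise DietBarcoderError("season metadata absent and no calendar given")
        seasons = pd.Series(
            [calendar.season_of(d) for d in meta["date"]], index=meta.index
        )
    key = pd.MultiIndex.from_arrays(
        [meta["individual_id"], seasons], names=["individual_id", "season"]
    )
    mean = sub.values.groupby(key).mean()
    closed, empty = _close(mean)
    idx = [f"{i}|{s}" for i, s in mean.index]
    closed.index = idx
    out_meta = pd.DataFrame(index=pd.Index(idx))
    out_meta["individual_id"] = [i for i, _ in mean.index]
    out_meta["group_id"] = ""
    out_meta["date"] = ""
    out_meta["season"] = [s for _, s in mean.index]
    out_meta["source"] = meta["source"].iloc[0] if len(meta) else ""
    out_meta["empty"] = empty.to_numpy()
    return DietProfileMatrix(closed, out_meta, "composition")
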