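"""Camera-trap detection records, independent events and site-occasion response tables.

A camera records bursts of photographs; photographs of the same species class
at the same site are chained into *independent events* using a rolling time
gap (30 min by default).  Site-level use is summarised as the relative
detection frequency (RDF, events per 100 camera-trap days) and, for the
spatiotemporal model, as the per-occasion response rate (events per active
camera day, without the x100 factor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SPECIES_CLASSES = ("chimpanzee", "human", "other")


@dataclass(frozen=True)
class DetectionRecord:
    """A single classified camera-trap photograph."""

    site_id: str
    species_class: str
    timestamp: datetime


@dataclass(frozen=True)
class Event:
    """An independent detection event: a chain of photographs at one site."""

    site_id: str
    species_class: str
    start: datetime
    end: datetime
    n_photos: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("event start must not be after its end")


@dataclass(frozen=True)
class OccasionGrid:
    """Contiguous, non-overlapping sampling occasions aligned to phenology surveys.

    ``starts``/``ends`` are inclusive date bounds, one pair per occasion;
    ``phenology_dates[i]`` falls inside occasion ``i``.
    """

    starts: tuple[date, ...]
    ends: tuple[date, ...]
    phenology_dates: tuple[date, ...]

    def __post_init__(self) -> None:
        n = len(self.starts)
        if not (len(self.ends) == len(self.phenology_dates) == n):
            raise ValueError("starts, ends and phenology_dates must align")
        for i in range(n):
            if self.starts[i] > self.ends[i]:
                raise ValueError(f"occasion {i + 1} has start after end")
            if not (self.starts[i] <= self.phenology_dates[i] <= self.ends[i]):
                raise ValueError(f"phenology date outside occasion {i + 1}")
            if i and self.starts[i] != self.ends[i - 1] + timedelta(days=1):
                raise ValueError("occasions must be contiguous and non-overlapping")

    @property
    def n_occasions(self) -> int:
        return len(self.starts)

    def length_days(self, occasion: int) -> int:
        """Inclusive length in days of 1-based ``occasion``."""
        i = occasion - 1
        return (self.ends[i] - self.starts[i]).days + 1

    def occasion_of(self, when: date | datetime) -> int | None:
        """1-based occasion containing ``when``, or None if outside the grid."""
        d = when.date() if isinstance(when, datetime) else when
        for i in range(self.n_occasions):
            if self.starts[i] <= d <= self.ends[i]:
                return i + 1
        return None


def parse_records(table: pd.DataFrame) -> list[DetectionRecord]:
    """Build detection records from a dataframe with site_id / species_class / timestamp.

    Rows whose timestamp cannot be parsed as ISO-8601 are rejected with a
    logged warning rather than aborting the whole ingest.
    """
    out: list[DetectionRecord] = []
    ts = pd.to_datetime(table["timestamp"], errors="coerce")
    for (_, row), t in zip(table.iterrows(), ts):
        if pd.isna(t):
            logger.warning("rejecting record with unparseable timestamp: %r", row["timestamp"])
            continue
        out.append(DetectionRecord(str(row["site_id"]), str(row["species_class"]), t.to_pydatetime()))
    return out


def assign_events(
    records: Iterable[DetectionRecord], gap_minutes: float = 30.0
) -> list[Event]:
    """Chain photographs into independent events with a rolling gap rule.

    Within each site x species class, photographs are taken in time order and
    a photo joins the open event iff its gap to the event's *most recent*
    photo is strictly less than ``gap_minutes``; otherwise it opens a new
    event.  Timestamps are compared at minute resolution and photos falling
    in the same minute collapse into one burst member each (they still count
    towards ``n_photos``).

    Returns events sorted by (site, class, start).
    """
    if gap_minutes <= 0:
        raise ValueError("gap_minutes must be positive")
    gap = timedelta(minutes=gap_minutes)

    groups: dict[tuple[str, str], list[datetime]] = {}
    for r in records:
        t = r.timestamp.replace(second=0, microsecond=0)
        groups.setdefault((r.site_id, r.species_class), []).append(t)

    out: list[Event] = []
    for (site, cls), times in groups.items():
        times.sort()
        start = prev = times[0]
        n = 1
        for t in times[1:]:
            if t - prev < gap:
                prev = t
                n += 1
            else:
                out.append(Event(site, cls, start, prev, n))
                start = prev = t
                n = 1
        out.append(Event(site, cls, start, prev, n))
    out.sort(key=lambda e: (e.site_id, e.species_class, e.start))
    return out


def rdf(n_events: float, effort_days: float) -> float:
    """Relative detection frequency: events per 100 camera-trap days.

    A site-selection measure, deliberately not an abundance index.
    """
    if effort_days <= 0:
        raise ValueError("effort_days must be positive")
    return 100.0 * n_events / effort_days


def build_occasions(
    phenology_dates: Sequence[date],
    study_start: date,
    study_end: date,
    boundaries: Sequence[date] | None = None,
) -> OccasionGrid:
    """Cut the study window into occasions centred on phenology survey dates.

    Default rule: each occasion ends on the floor of the midpoint between its
    phenology date and the next one; the first starts at ``study_start`` and
    the last ends at ``study_end``.  An explicit ``boundaries`` list (the
    inclusive end date of every occasion except the last) overrides the rule.
    """
    dates = list(phenology_dates)
    if len(dates) < 2:
        raise ValueError("need at least two phenology dates to cut occasions")
    if any(b >= a for b, a in zip(dates, dates[1:])):
        raise ValueError("phenology dates must be strictly increasing")
    if dates[0] < study_start or dates[-1] > study_end:
        raise ValueError("phenology dates must lie inside the study window")

    if boundaries is not None:
        ends_mid = list(boundaries)
        if len(ends_mid) != len(dates) - 1:
            raise ValueError("need one boundary per occasion except the last")
    else:
        ends_mid = [d1 + timedelta(days=(d2 - d1).days // 2) for d1, d2 in zip(dates, dates[1:])]

    starts = [study_start] + [e + timedelta(days=1) for e in ends_mid]
    ends = ends_mid + [study_end]
    return OccasionGrid(tuple(starts), tuple(ends), tuple(dates))


def effort_from_daily(daily: pd.DataFrame, grid: OccasionGrid) -> pd.DataFrame:
    """Aggregate a per-day activity log into active days per site x occasion.

    ``daily`` has columns site_id, date, active (0/1 or bool).  Days outside
    the occasion grid are ignored.  Returns a site x occasion DataFrame of
    active-day counts (sites as index, occasions 1..T as columns), with
    unlisted days counting as inactive.
    """
    d = daily.copy()
    d["date"] = pd.to_datetime(d["date"]).dt.date
    d["occ"] = [grid.occasion_of(x) for x in d["date"]]
    d = d.dropna(subset=["occ"])
    d["occ"] = d["occ"].astype(int)
    tab = (
        d[d["active"].astype(bool)]
        .groupby(["site_id", "occ"])
        .size()
        .unstack(fill_value=0)
    )
    return tab.reindex(columns=range(1, grid.n_occasions + 1), fill_value=0)


def response_table(
    events: Sequence[Event],
    effort: pd.DataFrame,
    grid: OccasionGrid,
    na_inactive_days: float = 7,
    species_class: str = "chimpanzee",
) -> pd.DataFrame:
    """Per-occasion response rate y = events / active days, with the NA rule.

    ``effort`` is the site x occasion active-day table (as from
    :func:`effort_from_daily`).  A cell is set to missing (NaN) when the
    number of *inactive* days during the occasion strictly exceeds
    ``na_inactive_days`` — a camera out for more than a week gives an
    unreliable rate.  Exactly ``na_inactive_days`` inactive days is retained.

    Returns a DataFrame shaped like ``effort`` holding rates (or NaN).
    """
    counts = pd.DataFrame(0, index=effort.index, columns=effort.columns, dtype=float)
    for e in events:
        if e.species_class != species_class or e.site_id not in counts.index:
            continue
        occ = grid.occasion_of(e.start)
        if occ is not None:
            counts.loc[e.site_id, occ] += 1

    rates = pd.DataFrame(np.nan, index=effort.index, columns=effort.columns)
    for occ in effort.columns:
        occ_len = grid.length_days(int(occ))
        active = effort[occ].astype(float)
        inactive = occ_len - active
        ok = (inactive <= na_inactive_days) & (active > 0)
        rates.loc[ok, occ] = counts.loc[ok, occ] / active[ok]
    return rates


def compare_site_use(
    rdf_a: Sequence[float], rdf_b: Sequence[float], stratum: Sequence[str] | None = None
) -> dict:
    """Spearman correlation between two species' site RDFs, and a rank-sum test
    of one species' RDF between two strata (e.g. forest vs matrix).

    Returns {'spearman_rs', 'spearman_p'} and, when ``stratum`` labels with
    exactly two levels are given, {'wilcoxon_W', 'wilcoxon_p'} comparing
    ``rdf_a`` across strata (W is the rank-sum statistic as R's wilcox.test
    reports it).
    """
    a = np.asarray(rdf_a, dtype=float)
    b = np.asarray(rdf_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rdf vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 sites")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rs = stats.spearmanr(a, b)
    out = {"spearman_rs": float(rs.statistic), "spearman_p": float(rs.pvalue)}
    if stratum is not None:
        labels = pd.unique(np.asarray(stratum))
        if len(labels) != 2:
            raise ValueError("stratum must have exactly two levels")
        mask = np.asarray(stratum) == labels[0]
        mw = stats.mannwhitneyu(a[mask], a[~mask], alternative="two-sided")
        out["wilcoxon_W"] = float(mw.statistic)
        out["wilcoxon_p"] = float(mw.pvalue)
    return out


def events_to_frame(events: Sequence[Event]) -> pd.DataFrame:
    """Long-format event table, round-trippable through CSV."""
    return pd.DataFrame(
        {
            "site_id": [e.site_id for e in events],
            "species_class": [e.species_class for e in events],
            "start": [e.start.isoformat() for e in events],
            "end": [e.end.isoformat() for e in events],
            "n_photos": [e.n_photos for e in events],
        }
    )
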