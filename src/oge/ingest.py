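"""Readers, validators and inclusion filters for the four panel inputs.

The analysis consumes four kinds of external data, all as plain text:

* sentiment-labelled geotagged posts (CSV/TSV with columns
  ``post_id, date, city, sentiment[, text]``),
* city-level daily mobility (Apple-mobility wide dialect or a tidy long CSV),
* county-level cumulative epidemic counts (JHU-CSSE wide dialect) plus a
  county-to-city mapping,
* a policy-events configuration (YAML) with federal announcement dates and
  per-city shelter-in-place intervals.

Everything is returned as tidy :class:`pandas.DataFrame` panels keyed by
``(city, date)`` (policy events as a list of :class:`PolicyEvent`), so the
downstream statistics never touch file dialects.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Accepted sentiment classes for a post.
SENTIMENTS = ("positive", "neutral", "negative", "mixed")

#: Topic labels, "overall" first; the remaining five are the subtopics.
TOPICS = ("overall", "TA", "China", "distancing", "mask", "economy")

#: Default keyword sub-strings per subtopic.  Matching is plain lowercase
#: substring containment (stems such as "quarantin" are deliberate), so false
#: positives like "chinatown" -> China are an accepted consequence.
DEFAULT_KEYWORDS: dict[str, tuple[str, ...]] = {
    "TA": ("trump", "pence"),
    "China": ("china", "chinese", "wuhan"),
    "distancing": ("quarantin", "lockdown", "social distanc"),
    "mask": ("mask", "ppe"),
    "economy": ("econom", "stock market", "dow", "unemploy"),
}

#: Default federal policy announcement dates: declaration of national
#: emergency, extension of social distancing guidelines, release of state
#: reopening guidelines.
DEFAULT_FEDERAL_DATES = {
    1: dt.date(2020, 3, 13),
    2: dt.date(2020, 3, 29),
    3: dt.date(2020, 4, 16),
}

EVENT_NAMES = {
    1: "national_emergency",
    2: "distancing_extension",
    3: "reopening_guidelines",
    4: "shelter_in_place",
}

#: Label of the pseudo-city that pools posts from every location.
NATIONAL = "national"


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass(frozen=True)
class PolicyEvent:
    """A policy intervention used as an exogenous regressor.

    Events 1-3 are federal single-day impulses; event 4 is a per-city
    shelter-in-place step over ``[start, end]`` (``end`` of ``None`` means the
    order was still active at the end of the study window).
    """

    k: int
    kind: str  # "impulse" | "step"
    scope: str  # "federal" | "local"
    date: dt.date | None = None
    city: str | None = None
    start: dt.date | None = None
    end: dt.date | None = None

    def __post_init__(self) -> None:
        if self.k not in EVENT_NAMES:
            raise ValueError(f"unknown policy event key {self.k!r}")
        if self.kind not in ("impulse", "step"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "step" and self.start is None:
            raise ValueError("step events require a start date")
        if (
            self.kind == "step"
            and self.end is not None
            and self.end < self.start
        ):
            raise ValueError(
                f"shelter interval ends ({self.end}) before it starts ({self.start})"
            )

    @property
    def name(self) -> str:
        return EVENT_NAMES[self.k]


def _parse_date(value: object) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value).strip())


def read_posts(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read sentiment-labelled post records from a delimited text file.

    Parameters
    ----------
    path
        CSV (default) or TSV file with header columns
        ``post_id, date, city, sentiment`` and optionally ``text``.
    sep
        Field separator; inferred from the ``.tsv`` extension when omitted.

    Returns
    -------
    DataFrame with columns ``post_id, date, city, sentiment, text`` in the
    input row order.  Sentiment labels are case-folded; any label outside the
    four classes is an error, never a silent neutral.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"post_id", "date", "city", "sentiment"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if "text" not in df.columns:
        df["text"] = ""
    dates = []
    for i, raw in enumerate(df["date"]):
        try:
            dates.append(_parse_date(raw))
        except ValueError as exc:
            # +2: header line plus 1-based numbering
            raise FormatError(f"{path}, line {i + 2}: unparseable date {raw!r}") from exc
    df = df.assign(date=dates, sentiment=df["sentiment"].str.strip().str.lower())
    bad = ~df["sentiment"].isin(SENTIMENTS)
    if bad.any():
        first = df.index[bad][0]
        raise FormatError(
            f"{path}, line {first + 2}: unknown sentiment label "
            f"{df.loc[first, 'sentiment']!r}"
        )
    return df[["post_id", "date", "city", "sentiment", "text"]]


def write_posts(posts: pd.DataFrame, path: str | Path) -> None:
    """Write a posts table in the dialect :func:`read_posts` reads."""
    posts = posts.assign(date=[d.isoformat() for d in posts["date"]])
    sep = "\t" if Path(path).suffix.lower() == ".tsv" else ","
    posts.to_csv(path, sep=sep, index=False)


def read_mobility(path: str | Path, dialect: str = "apple_wide") -> pd.DataFrame:
    """Read city-level daily mobility series.

    ``apple_wide``: rows keyed by ``geo_type, region, transportation_type``
    with one column per date, values being relative request volume as a
    percent of a baseline day.  ``tidy_long``: columns
    ``city, date, mode, value``.  Only the ``driving`` and ``walking`` modes
    are retained; other modes (e.g. ``transit``) are dropped with a notice.

    Returns a tidy frame with columns ``city, mode, date, value``.
    """
    path = Path(path)
    if dialect == "apple_wide":
        df = pd.read_csv(path)
        meta = {"geo_type", "region", "transportation_type"}
        if not meta <= set(df.columns):
            raise FormatError(f"{path}: not an apple_wide file (missing {meta})")
        date_cols = [c for c in df.columns if c not in meta]
        long = df.melt(
            id_vars=sorted(meta),
            value_vars=date_cols,
            var_name="date",
            value_name="value",
        ).rename(columns={"region": "city", "transportation_type": "mode"})
        long = long[["city", "mode", "date", "value"]]
    elif dialect == "tidy_long":
        long = pd.read_csv(path)
        required = {"city", "date", "mode", "value"}
        if not required <= set(long.columns):
            raise FormatError(f"{path}: tidy_long requires columns {sorted(required)}")
        long = long[["city", "mode", "date", "value"]].copy()
    else:
        raise FormatError(f"unknown mobility dialect {dialect!r}")
    dropped = sorted(set(long["mode"]) - {"driving", "walking"})
    if dropped:
        logger.info("read_mobility: dropping modes %s", dropped)
        long = long[long["mode"].isin(["driving", "walking"])]
    long = long.assign(
        date=[_parse_date(d) for d in long["date"]],
        value=pd.to_numeric(long["value"]),
    )
    if long.duplicated(["city", "mode", "date"]).any():
        raise FormatError(f"{path}: duplicate (city, mode, date) cells")
    return long.sort_values(["city", "mode", "date"], kind="stable").reset_index(drop=True)


def write_mobility(
    mobility: pd.DataFrame, path: str | Path, dialect: str = "apple_wide"
) -> None:
    """Write a tidy mobility frame in either dialect :func:`read_mobility` reads."""
    mob = mobility.assign(date=[d.isoformat() for d in mobility["date"]])
    if dialect == "apple_wide":
        wide = (
            mob.pivot(index=["city", "mode"], columns="date", values="value")
            .reset_index()
            .rename(columns={"city": "region", "mode": "transportation_type"})
        )
        wide.insert(0, "geo_type", "city")
        wide.columns.name = None
        wide.to_csv(path, index=False)
    elif dialect == "tidy_long":
        mob.to_csv(path, index=False)
    else:
        raise FormatError(f"unknown mobility dialect {dialect!r}")


def read_epidemic(
    path: str | Path,
    county_to_city: Mapping[str, str],
    measure: str = "cases",
    on_unmapped: str = "skip",
    county_col: str = "county",
) -> pd.DataFrame:
    """Aggregate a county-level cumulative wide CSV to city daily series.

    The file has one row per county and one column per date holding
    cumulative counts.  Per-city cumulative series are sums over mapped
    counties; a ``national`` series sums every row regardless of mapping.
    Daily series are first differences of the cumulative ones (the first day
    has no predecessor and is reported as the cumulative value itself, i.e.
    the difference from an implicit zero).  Negative daily values caused by
    reporting corrections are retained as-is.

    ``on_unmapped`` is ``"skip"`` (drop with a warning) or ``"error"``.
    Returns a tidy frame ``city, measure, date, cumulative, daily`` where
    ``city`` includes the pseudo-city ``"national"``.
    """
    df = pd.read_csv(path)
    if county_col not in df.columns:
        raise FormatError(f"{path}: missing county column {county_col!r}")
    date_cols = [c for c in df.columns if c != county_col]
    unmapped = [c for c in df[county_col] if c not in county_to_city]
    if unmapped:
        if on_unmapped == "error":
            raise FormatError(f"{path}: counties not in map: {unmapped}")
        logger.warning("read_epidemic: skipping unmapped counties %s", unmapped)
    dates = [_parse_date(c) for c in date_cols]
    values = df[date_cols].apply(pd.to_numeric)
    out = []

    def _series(city: str, cumulative: pd.Series) -> pd.DataFrame:
        daily = cumulative.diff()
        daily.iloc[0] = cumulative.iloc[0]
        return pd.DataFrame(
            {
                "city": city,
                "measure": measure,
                "date": dates,
                "cumulative": cumulative.to_numpy(),
                "daily": daily.to_numpy(),
            }
        )

    cities = df[county_col].map(lambda c: county_to_city.get(c))
    for city, group in values.groupby(cities):
        out.append(_series(city, group.sum(axis=0)))
    out.append(_series(NATIONAL, values.sum(axis=0)))
    return pd.concat(out, ignore_index=True)


def read_county_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``county,city`` mapping CSV."""
    df = pd.read_csv(path, dtype=str)
    if not {"county", "city"} <= set(df.columns):
        raise FormatError(f"{path}: county map requires columns county,city")
    return dict(zip(df["county"], df["city"]))


def read_policy_config(path: str | Path) -> list[PolicyEvent]:
    """Read the policy-events configuration.

    YAML layout::

        federal:
          national_emergency: 2020-03-13
          distancing_extension: 2020-03-29
          reopening_guidelines: 2020-04-16
        shelter:
          "New York": {start: 2020-03-22, end: null}

    Federal dates omitted from the file fall back to the default announcement
    dates.  Shelter entries with no ``end`` are open intervals that run to the
    study-window end.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return policy_events_from_mapping(cfg)


def policy_events_from_mapping(cfg: Mapping) -> list[PolicyEvent]:
    """Build :class:`PolicyEvent` objects from a parsed configuration mapping."""
    name_to_k = {v: k for k, v in EVENT_NAMES.items()}
    federal = dict(cfg.get("federal") or {})
    unknown = set(federal) - set(name_to_k)
    if unknown:
        raise FormatError(f"unknown federal event key(s) {sorted(unknown)}")
    events: list[PolicyEvent] = []
    for k in (1, 2, 3):
        raw = federal.get(EVENT_NAMES[k])
        date = _parse_date(raw) if raw is not None else DEFAULT_FEDERAL_DATES[k]
        events.append(PolicyEvent(k=k, kind="impulse", scope="federal", date=date))
    for city, interval in (cfg.get("shelter") or {}).items():
        interval = interval or {}
        if "start" not in interval:
            raise FormatError(f"shelter entry for {city!r} lacks a start date")
        end = interval.get("end")
        events.append(
            PolicyEvent(
                k=4,
                kind="step",
                scope="local",
                city=city,
                start=_parse_date(interval["start"]),
                end=_parse_date(end) if end is not None else None,
            )
        )
    return events


def write_policy_config(events: Iterable[PolicyEvent], path: str | Path) -> None:
    """Write policy events in the YAML layout :func:`read_policy_config` reads."""
    cfg: dict = {"federal": {}, "shelter": {}}
    for ev in events:
        if ev.kind == "impulse":
            cfg["federal"][ev.name] = ev.date.isoformat()
        else:
            cfg["shelter"][ev.city] = {
                "start": ev.start.isoformat(),
                "end": ev.end.isoformat() if ev.end else None,
            }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def filter_cities(
    posts: pd.DataFrame,
    window: tuple[dt.date, dt.date],
    min_daily_avg: float = 500.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Apply the volume inclusion filter and restrict to the study window.

    A city is kept iff its average number of posts per day over the inclusive
    window ``[start, end]`` is at least ``min_daily_avg`` (the comparison is
    inclusive).  Returns the filtered posts (window-restricted) and the
    sorted list of kept cities.
    """
    start, end = window
    if end < start:
        raise ValueError(f"empty study window {start}..{end}")
    n_days = (end - start).days + 1
    in_window = posts[(posts["date"] >= start) & (posts["date"] <= end)]
    totals = in_window.groupby("city").size()
    kept = sorted(totals.index[totals / n_days >= min_daily_avg])
    return in_window[in_window["city"].isin(kept)].reset_index(drop=True), kept


def match_topics(
    text: str, keyword_map: Mapping[str, Iterable[str]] | None = None
) -> set[str]:
    """Return the subtopics whose keyword sub-strings occur in ``text``.

    Containment is plain substring search on the lowercased text; a post with
    no match belongs only to the implicit "overall" topic (not returned
    here).
    """
    keyword_map = DEFAULT_KEYWORDS if keyword_map is None else keyword_map
    return {
        topic
        for topic, keys in keyword_map.items()
        if any(key in text for key in keys)
    }


def daily_topic_counts(
    posts: pd.DataFrame,
    keyword_map: Mapping[str, Iterable[str]] | None = None,
    national_label: str = NATIONAL,
) -> pd.DataFrame:
    """Count posts per (city, date, topic) by sentiment class.

    For every topic a post matches — plus "overall", which every post counts
    toward once — the post increments ``P`` (positive), ``M`` (neutral or
    mixed pooled) or ``N`` (negative); ``T = P + M + N``.  A pseudo-city
    (default ``"national"``) pools all posts irrespective of location.
    Days with no matching post produce no row (missing, never zero).
    """
    keyword_map = DEFAULT_KEYWORDS if keyword_map is None else keyword_map
    topic_lists = [
        ["overall", *match_topics(t, keyword_map)] for t in posts["text"]
    ]
    expanded = posts.loc[posts.index.repeat([len(t) for t in topic_lists])].assign(
        topic=[topic for row in topic_lists for topic in row]
    )
    pooled = expanded.assign(city=national_label)
    both = pd.concat([expanded, pooled], ignore_index=True)
    both["klass"] = both["sentiment"].map(
        {"positive": "P", "neutral": "M", "mixed": "M", "negative": "N"}
    )
    counts = (
        both.groupby(["city", "date", "topic", "klass"], sort=True)
        .size()
        .unstack("klass", fill_value=0)
        .reindex(columns=["P", "M", "N"], fill_value=0)
        .reset_index()
    )
    counts.columns.name = None
    counts["T"] = counts["P"] + counts["M"] + counts["N"]
    return counts
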