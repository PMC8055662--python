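"""Synthetic city panels with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be exercised — and calibrated — without any
external download:

* a latent mean-sentiment path per (city, topic) following AR(1) dynamics
  with cross-city correlated innovations (tunable rho) and injectable
  impulse/step policy effects on the latent scale;
* daily post volumes drawn negative-binomially (overdispersed, like real
  daily tweet counts), split multinomially over subtopics, with per-post
  sentiment classes drawn through a bounded softmax link of the latent
  value;
* mobility series coupled to the latent sentiment at a known lag with AR(1)
  observation noise;
* monotone logistic epidemic curves with leading zeros before onset and
  optional reporting noise.

All generators are pure functions of ``(spec, seed)``.  The writers emit the
exact file dialects :mod:`oge.ingest` reads, so the full pipeline can run
from disk fixtures.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import (
    DEFAULT_FEDERAL_DATES,
    DEFAULT_KEYWORDS,
    PolicyEvent,
    write_mobility,
    write_policy_config,
    write_posts,
)

__all__ = [
    "PolicyEffectSpec",
    "ScenarioSpec",
    "latent_paths",
    "generate_counts",
    "generate_posts",
    "generate_policy_scenario",
    "generate_mobility",
    "generate_epidemic",
    "write_scenario",
]

SUBTOPICS = ("distancing", "China", "TA", "economy", "mask")


@dataclass(frozen=True)
class PolicyEffectSpec:
    """A ground-truth policy effect on the latent sentiment scale.

    ``kind`` defaults to "step" for k=4 and "impulse" otherwise; dates
    default to the standard federal announcement dates for k=1..3.
    """

    k: int
    effect: float
    kind: str | None = None
    date: dt.date | None = None
    start: dt.date | None = None
    end: dt.date | None = None

    @property
    def resolved_kind(self) -> str:
        return self.kind or ("step" if self.k == 4 else "impulse")


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions for a synthetic panel.

    Defaults mirror the real study setup: 49 cities observed daily from
    2020-02-26 to 2020-05-01, overdispersed daily volumes safely above the
    500-post inclusion threshold, moderately persistent latent sentiment
    with a negative mean (city sentiment was consistently negative), and
    substantial cross-city correlation.  Tests and calibration studies
    override sizes explicitly.
    """

    n_cities: int = 49
    start: dt.date = dt.date(2020, 2, 26)
    end: dt.date = dt.date(2020, 5, 1)
    topics: tuple[str, ...] = SUBTOPICS
    # latent dynamics
    ar: float = 0.5
    innovation_sd: float = 0.1
    latent_mean: float = -0.3
    cross_city_rho: float = 0.5
    # sentiment link: softmax of (a + b x, 0, a - b x)
    link_offset: float = 0.0
    link_scale: float = 1.0
    # volumes
    volume_mean: float = 600.0
    volume_dispersion: float = 10.0
    topic_share: float = 0.08
    mixed_fraction: float = 0.2
    # policy ground truth
    policy_effects: tuple[PolicyEffectSpec, ...] = ()
    # mobility coupling: M_t = baseline + coupling * latent_{t-lag} + AR(1) noise
    mobility_baseline: float = 100.0
    mobility_coupling: float = -20.0
    mobility_lag: int = 2
    mobility_noise_sd: float = 2.0
    mobility_noise_ar: float = 0.5
    # epidemic curves
    epidemic_onset_day: int = 14
    epidemic_rate: float = 0.15
    epidemic_ceiling: float = 20000.0
    epidemic_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("scenario window is empty")
        if not 0 <= self.cross_city_rho <= 1:
            raise ValueError("cross_city_rho must be in [0, 1]")
        if self.topic_share * len(self.topics) > 1:
            raise ValueError("topic shares exceed 1")
        if self.epidemic_rate < 0:
            raise ValueError("epidemic growth rate must be non-negative")
        for eff in self.policy_effects:
            if not np.isfinite(eff.effect):
                raise ValueError("policy effect sizes must be finite")

    @property
    def dates(self) -> list[dt.date]:
        n = (self.end - self.start).days + 1
        return [self.start + dt.timedelta(days=i) for i in range(n)]

    @property
    def cities(self) -> list[str]:
        return [f"city_{i:02d}" for i in range(self.n_cities)]


def link_probabilities(x, offset: float = 0.0, scale: float = 1.0) -> np.ndarray:
    """Softmax link from latent value(s) to (p_pos, p_neu, p_neg).

    Scores are ``(offset + scale*x, 0, offset - scale*x)``, so probabilities
    are bounded away from 0 and 1 for finite latent values and
    ``p_pos - p_neg`` is monotone in ``x``.
    """
    x = np.asarray(x, dtype=float)
    scores = np.stack(
        [offset + scale * x, np.zeros_like(x), offset - scale * x], axis=-1
    )
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=-1, keepdims=True)


def _resolve_effect_window(spec: ScenarioSpec, eff: PolicyEffectSpec):
    """Return the (start_idx, end_idx) day span an effect applies to."""
    dates = spec.dates
    if eff.resolved_kind == "impulse":
        date = eff.date or DEFAULT_FEDERAL_DATES.get(eff.k)
        if date is None:
            raise ValueError(f"impulse effect k={eff.k} needs a date")
        if not (spec.start <= date <= spec.end):
            raise ValueError(f"policy event on {date} outside scenario window")
        i = (date - spec.start).days
        return i, i
    if eff.start is None:
        raise ValueError(f"step effect k={eff.k} needs a start date")
    end = eff.end or spec.end
    if not (spec.start <= eff.start <= spec.end):
        raise ValueError(f"policy event on {eff.start} outside scenario window")
    return (eff.start - spec.start).days, (min(end, spec.end) - spec.start).days


def latent_paths(spec: ScenarioSpec, seed: int) -> dict[str, pd.DataFrame]:
    """Simulate latent sentiment per topic: a dates-by-cities frame each.

    Innovations share a common factor across cities with weight
    ``sqrt(rho)``, giving cross-city innovation correlation rho.  Paths
    start from the stationary distribution, and policy effects shift the
    latent of every topic over their day span.
    """
    rng = np.random.default_rng(seed)
    dates = spec.dates
    n, m = len(dates), spec.n_cities
    out: dict[str, pd.DataFrame] = {}
    spans = [_resolve_effect_window(spec, eff) for eff in spec.policy_effects]
    for topic in ("overall", *spec.topics):
        common = rng.standard_normal(n)
        idio = rng.standard_normal((n, m))
        e = spec.innovation_sd * (
            np.sqrt(spec.cross_city_rho) * common[:, None]
            + np.sqrt(1 - spec.cross_city_rho) * idio
        )
        u = np.empty((n, m))
        u[0] = e[0] / np.sqrt(1 - spec.ar**2) if abs(spec.ar) < 1 else e[0]
        for t in range(1, n):
            u[t] = spec.ar * u[t - 1] + e[t]
        x = spec.latent_mean + u
        for eff, (i0, i1) in zip(spec.policy_effects, spans):
            x[i0: i1 + 1] += eff.effect
        out[topic] = pd.DataFrame(x, index=pd.Index(dates, name="date"),
                                  columns=spec.cities)
    return out


def generate_counts(
    spec: ScenarioSpec, seed: int
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Draw daily sentiment counts per (city, date, topic) from the latents.

    Each city-day draws a negative-binomial volume, splits it multinomially
    into subtopic buckets plus a no-topic bucket, then draws each bucket's
    (positive, neutral-or-mixed, negative) counts from its topic's latent
    link.  The "overall" row pools every bucket.  Returns the counts table
    (columns ``city, date, topic, P, M, N, T``) and the latent paths.
    """
    latents = latent_paths(spec, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    dates = spec.dates
    shares = [spec.topic_share] * len(spec.topics)
    shares.append(1.0 - sum(shares))
    rows = []
    nb_n = spec.volume_dispersion
    nb_p = nb_n / (nb_n + spec.volume_mean)
    for ci, city in enumerate(spec.cities):
        volumes = rng.negative_binomial(nb_n, nb_p, size=len(dates))
        for di, date in enumerate(dates):
            buckets = rng.multinomial(volumes[di], shares)
            overall = np.zeros(3, dtype=int)
            for topic, size in zip((*spec.topics, "overall"), buckets):
                if size == 0:
                    continue
                probs = link_probabilities(
                    latents[topic].iloc[di, ci],
                    offset=spec.link_offset, scale=spec.link_scale,
                )
                pmn = rng.multinomial(size, probs)
                overall += pmn
                if topic != "overall":
                    rows.append((city, date, topic, *pmn))
            if overall.sum() > 0:
                rows.append((city, date, "overall", *overall))
    counts = pd.DataFrame(rows, columns=["city", "date", "topic", "P", "M", "N"])
    counts["T"] = counts[["P", "M", "N"]].sum(axis=1)
    return counts, latents


def generate_posts(spec: ScenarioSpec, seed: int) -> pd.DataFrame:
    """Expand synthetic counts into per-post records.

    Post text is minimal — the topic's first keyword plus a serial number —
    just enough for substring matching to recover the intended topic
    exactly; no-topic posts carry no keyword and count only toward
    "overall".  Neutral-class posts are split between the "neutral" and
    "mixed" labels.  Deterministic given the seed.
    """
    counts, _ = generate_counts(spec, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    recs: list[tuple] = []
    serial = 0
    for row in counts.itertuples(index=False):
        if row.topic == "overall":
            continue
        keyword = DEFAULT_KEYWORDS.get(row.topic, (row.topic.lower(),))[0]
        for sentiment, count in (("positive", row.P), ("neutral", row.M),
                                 ("negative", row.N)):
            for _ in range(count):
                label = sentiment
                if sentiment == "neutral" and rng.random() < spec.mixed_fraction:
                    label = "mixed"
                recs.append(
                    (f"p{serial:08d}", row.date, row.city, label,
                     f"{keyword} synthetic post {serial}")
                )
                serial += 1
    # no-topic posts: overall minus the sum of subtopic buckets
    sub = (
        counts[counts["topic"] != "overall"]
        .groupby(["city", "date"])[["P", "M", "N"]].sum()
    )
    overall = counts[counts["topic"] == "overall"].set_index(["city", "date"])
    for key, row in overall.iterrows():
        extra = row[["P", "M", "N"]] - (sub.loc[key] if key in sub.index else 0)
        city, date = key
        for sentiment, count in (("positive", extra["P"]), ("neutral", extra["M"]),
                                 ("negative", extra["N"])):
            for _ in range(int(count)):
                label = sentiment
                if sentiment == "neutral" and rng.random() < spec.mixed_fraction:
                    label = "mixed"
                recs.append(
                    (f"p{serial:08d}", date, city, label,
                     f"synthetic post {serial}")
                )
                serial += 1
    posts = pd.DataFrame(
        recs, columns=["post_id", "date", "city", "sentiment", "text"]
    )
    return posts.sort_values(["date", "city", "post_id"], kind="stable").reset_index(
        drop=True
    )


def scenario_events(spec: ScenarioSpec) -> list[PolicyEvent]:
    """Policy events matching the scenario's injected effects (plus federal defaults)."""
    events: list[PolicyEvent] = []
    have = {eff.k for eff in spec.policy_effects if eff.resolved_kind == "impulse"}
    for eff in spec.policy_effects:
        if eff.resolved_kind == "impulse":
            events.append(
                PolicyEvent(
                    k=eff.k, kind="impulse", scope="federal",
                    date=eff.date or DEFAULT_FEDERAL_DATES[eff.k],
                )
            )
        else:
            for city in spec.cities:
                events.append(
                    PolicyEvent(
                        k=4, kind="step", scope="local", city=city,
                        start=eff.start, end=eff.end,
                    )
                )
    for k in (1, 2, 3):
        if k not in have and spec.start <= DEFAULT_FEDERAL_DATES[k] <= spec.end:
            events.append(
                PolicyEvent(k=k, kind="impulse", scope="federal",
                            date=DEFAULT_FEDERAL_DATES[k])
            )
    return events


def generate_policy_scenario(
    spec: ScenarioSpec, seed: int
) -> tuple[pd.DataFrame, list[PolicyEvent]]:
    """Posts with injected policy effects plus the matching event list.

    The returned events let the intervention stage run blind against the
    known ground truth.
    """
    return generate_posts(spec, seed), scenario_events(spec)


def generate_mobility(
    spec: ScenarioSpec, latent: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Mobility series coupled to the latent sentiment at a known lag.

    ``M_t = baseline + coupling * latent_{t-lag} + AR(1) noise`` for both the
    driving and walking modes with independent noise; the pre-lag head reuses
    the first latent value.  Returns a tidy ``city, mode, date, value``
    frame.
    """
    if spec.mobility_lag >= len(latent):
        raise ValueError("mobility lag is not shorter than the series")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    dates = list(latent.index)
    n = len(dates)
    out = []
    for city in latent.columns:
        base = latent[city].to_numpy()
        lagged = np.concatenate(
            [np.full(spec.mobility_lag, base[0]), base[: n - spec.mobility_lag]]
        )
        for mode in ("driving", "walking"):
            e = rng.standard_normal(n) * spec.mobility_noise_sd
            noise = np.empty(n)
            noise[0] = e[0]
            for t in range(1, n):
                noise[t] = spec.mobility_noise_ar * noise[t - 1] + e[t]
            values = spec.mobility_baseline + spec.mobility_coupling * lagged + noise
            out.append(
                pd.DataFrame(
                    {"city": city, "mode": mode, "date": dates, "value": values}
                )
            )
    return pd.concat(out, ignore_index=True)


def generate_epidemic(
    spec: ScenarioSpec, seed: int, measure: str = "cases", scale: float = 1.0
) -> pd.DataFrame:
    """Cumulative logistic epidemic curves with leading zeros before onset.

    Cumulative counts are a rounded logistic curve (ceiling scaled by
    ``scale``) starting at ``epidemic_onset_day``; optional Gaussian
    reporting noise can introduce non-monotonicities, which downstream code
    retains as-is.  Returns ``city, measure, date, cumulative, daily``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    dates = spec.dates
    t = np.arange(len(dates), dtype=float)
    out = []
    for i, city in enumerate(spec.cities):
        onset = spec.epidemic_onset_day + (i % 3)  # slight stagger across cities
        mid = onset + 20
        curve = scale * spec.epidemic_ceiling / (1 + np.exp(-spec.epidemic_rate * (t - mid)))
        cumulative = np.where(t < onset, 0.0, np.maximum(np.round(curve), 1.0))
        if spec.epidemic_noise_sd > 0:
            noise = np.round(rng.standard_normal(len(t)) * spec.epidemic_noise_sd)
            cumulative = np.where(t < onset, 0.0, np.maximum(cumulative + noise, 0.0))
        daily = np.diff(cumulative, prepend=0.0)
        out.append(
            pd.DataFrame(
                {"city": city, "measure": measure, "date": dates,
                 "cumulative": cumulative.astype(int), "daily": daily.astype(int)}
            )
        )
    return pd.concat(out, ignore_index=True)


def write_scenario(spec: ScenarioSpec, outdir: str | Path, seed: int) -> dict[str, Path]:
    """Materialize a scenario as the on-disk dialects the readers consume.

    Writes ``posts.csv``, ``mobility.csv`` (apple_wide), ``cases.csv`` and
    ``deaths.csv`` (county-per-city wide cumulative), ``county_map.csv`` and
    ``policy.yaml``; returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    posts, events = generate_policy_scenario(spec, seed)
    _, latents = generate_counts(spec, seed)
    paths = {
        "posts": outdir / "posts.csv",
        "mobility": outdir / "mobility.csv",
        "cases": outdir / "cases.csv",
        "deaths": outdir / "deaths.csv",
        "county_map": outdir / "county_map.csv",
        "policy": outdir / "policy.yaml",
    }
    write_posts(posts, paths["posts"])
    write_mobility(
        generate_mobility(spec, latents["overall"], seed), paths["mobility"],
        dialect="apple_wide",
    )
    for measure, scale in (("cases", 1.0), ("deaths", 0.05)):
        epi = generate_epidemic(spec, seed, measure=measure, scale=scale)
        wide = epi.assign(
            county=epi["city"] + "_county",
            date=[d.isoformat() for d in epi["date"]],
        ).pivot(index="county", columns="date", values="cumulative")
        wide.columns.name = None
        wide.reset_index().to_csv(paths[measure], index=False)
    pd.DataFrame(
        {"county": [c + "_county" for c in spec.cities], "city": spec.cities}
    ).to_csv(paths["county_map"], index=False)
    write_policy_config(events, paths["policy"])
    return paths
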