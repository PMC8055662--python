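"""End-to-end orchestration: ingest -> measures -> intervention -> association.

A :class:`RunConfig` (usually parsed from a YAML file) fully determines a
run; given the same config and seed, outputs are byte-identical.  Inputs are
either file paths or a synthetic :class:`~oge.synthetic.ScenarioSpec`.
Every figure-analog table is written as tidy CSV:

================  =====================================================
artifact          contents
================  =====================================================
gms.csv           city, topic, date, P, M, N, T, gms
gms_ma.csv        7-day trailing moving averages of each GMS series
coherence.csv     date, phi_degrees, phi_ma, n_pairs (3-day smoothing)
pairwise_corr.csv per-topic city-pair Pearson r after joint differencing
pairwise_summary.csv  r percentiles and percent significant per topic
effects.csv       per (city, topic, event) standardized z-scores
response_counts.csv   per-city number of significant overall-GMS responses
effect_regressions.csv  OLS between effect sizes of paired policies
offline_corr.csv  GMS vs mobility / epidemic Pearson correlations
granger.csv       two-step Granger tests of mobility on lagged GMS
manifest.json     config echo, seed, versions, per-stage timing
================  =====================================================
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import association, ingest, intervention, measures, stationarity, synthetic

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """The run configuration failed validation."""


@dataclass
class RunConfig:
    """Everything a full analysis run needs.

    Either the four ``*_path`` inputs or ``scenario`` must be provided.
    Defaults mirror the study conventions: 0.05 significance, ARMA orders
    scanned over [0,7]^2, Granger lags up to 14, 500 posts/day inclusion
    threshold, 7-day GMS and 3-day coherence smoothing windows.
    """

    outdir: str = "oge_output"
    seed: int = 0
    window_start: dt.date | None = None
    window_end: dt.date | None = None
    # inputs
    posts_path: str | None = None
    mobility_path: str | None = None
    mobility_dialect: str = "apple_wide"
    cases_path: str | None = None
    deaths_path: str | None = None
    county_map_path: str | None = None
    policy_path: str | None = None
    scenario: synthetic.ScenarioSpec | None = None
    # analysis knobs
    min_daily_avg: float = 500.0
    keyword_map: dict | None = None
    alpha: float = 0.05
    p_max: int = 7
    q_max: int = 7
    granger_max_lag: int = 14
    max_diff_order: int = 3
    gms_ma_window: int = 7
    coherence_ma_window: int = 3
    topics_for_intervention: tuple[str, ...] | None = None
    stages: tuple[str, ...] = ("measures", "intervention", "association")

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.window_start and self.window_end and self.window_end < self.window_start:
            raise ConfigError("window start must precede window end")
        if self.scenario is None and self.posts_path is None:
            raise ConfigError("either a scenario or a posts_path is required")
        for name in ("p_max", "q_max", "granger_max_lag", "gms_ma_window",
                     "coherence_ma_window"):
            if getattr(self, name) < 0 or (name.endswith("window") and getattr(self, name) < 1):
                raise ConfigError(f"{name} out of range")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        scenario = raw.pop("scenario", None)
        if scenario is not None:
            for key in ("start", "end"):
                if key in scenario:
                    scenario[key] = dt.date.fromisoformat(str(scenario[key]))
            if "policy_effects" in scenario:
                effects = []
                for eff in scenario["policy_effects"]:
                    for key in ("date", "start", "end"):
                        if eff.get(key) is not None:
                            eff[key] = dt.date.fromisoformat(str(eff[key]))
                    effects.append(synthetic.PolicyEffectSpec(**eff))
                scenario["policy_effects"] = tuple(effects)
            scenario = synthetic.ScenarioSpec(**scenario)
        for key in ("window_start", "window_end"):
            if raw.get(key) is not None:
                raw[key] = dt.date.fromisoformat(str(raw[key]))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(scenario=scenario, **raw)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _config_digest(config: RunConfig) -> str:
    payload = json.dumps(
        dataclasses.asdict(config), default=str, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the result bundle under ``config.outdir``.

    Returns a manifest dict (also written as ``manifest.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": _config_digest(config),
        "stages": timings,
    }

    def stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
            def __exit__(self_, *exc):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                if exc[0] is not None:
                    logger.error("stage %r failed", name)
        return _T()

    # ---- ingest ---------------------------------------------------------
    with stage("ingest"):
        if config.scenario is not None:
            inputs = outdir / "inputs"
            paths = synthetic.write_scenario(config.scenario, inputs, config.seed)
            posts = ingest.read_posts(paths["posts"])
            mobility = ingest.read_mobility(paths["mobility"], dialect="apple_wide")
            county_map = ingest.read_county_map(paths["county_map"])
            cases = ingest.read_epidemic(paths["cases"], county_map, measure="cases")
            deaths = ingest.read_epidemic(paths["deaths"], county_map, measure="deaths")
            events = ingest.read_policy_config(paths["policy"])
        else:
            posts = ingest.read_posts(config.posts_path)
            mobility = (
                ingest.read_mobility(config.mobility_path, config.mobility_dialect)
                if config.mobility_path else pd.DataFrame(
                    columns=["city", "mode", "date", "value"])
            )
            county_map = (
                ingest.read_county_map(config.county_map_path)
                if config.county_map_path else {}
            )
            cases = (
                ingest.read_epidemic(config.cases_path, county_map, measure="cases")
                if config.cases_path else None
            )
            deaths = (
                ingest.read_epidemic(config.deaths_path, county_map, measure="deaths")
                if config.deaths_path else None
            )
            events = (
                ingest.read_policy_config(config.policy_path)
                if config.policy_path else []
            )
        window = (
            config.window_start or min(posts["date"]),
            config.window_end or max(posts["date"]),
        )
        posts, kept = ingest.filter_cities(posts, window, config.min_daily_avg)
        if not kept:
            raise ConfigError(
                "no city passes the volume filter; lower min_daily_avg")
        logger.info("kept %d cities over %s..%s", len(kept), *window)

    # ---- measures -------------------------------------------------------
    with stage("measures"):
        counts = ingest.daily_topic_counts(posts, config.keyword_map)
        gms = measures.gms_table(counts)
        _write(gms, outdir / "gms.csv")
        dates = pd.Index(
            [window[0] + dt.timedelta(days=i)
             for i in range((window[1] - window[0]).days + 1)],
            name="date",
        )
        ma_rows = []
        for (city, topic), grp in gms.groupby(["city", "topic"]):
            s = pd.Series(grp["gms"].to_numpy(), index=grp["date"]).reindex(dates)
            ma = measures.moving_average(s, config.gms_ma_window)
            ma_rows.append(pd.DataFrame(
                {"city": city, "topic": topic, "date": dates, "gms_ma": ma.to_numpy()}
            ))
        _write(pd.concat(ma_rows, ignore_index=True).dropna(subset=["gms_ma"]),
               outdir / "gms_ma.csv")
        coh = measures.coherence_series(gms, exclude=(ingest.NATIONAL,))
        coh_df = pd.DataFrame(
            {
                "date": coh.values.index,
                "phi_degrees": coh.values.to_numpy(),
                "phi_ma": measures.moving_average(
                    coh.values, config.coherence_ma_window).to_numpy(),
                "n_pairs": coh.n_pairs_used.to_numpy(),
            }
        )
        _write(coh_df, outdir / "coherence.csv")

    topics = list(config.topics_for_intervention or ingest.TOPICS)
    cities = [c for c in kept]
    run_intervention = "intervention" in config.stages
    run_association = "association" in config.stages

    # ---- intervention ---------------------------------------------------
    with stage("intervention"):
        effect_rows = []
        for city in (cities if run_intervention else []):
            for topic in topics:
                s = measures.gms_series(gms, city, topic, dates).dropna()
                try:
                    yd, order = stationarity.difference_to_stationary(
                        s, alpha=config.alpha, max_order=config.max_diff_order
                    )
                    z = intervention.build_policy_indicators(events, city, yd.index)
                    model = intervention.scan_armax(
                        yd, z, p_max=config.p_max, q_max=config.q_max
                    )
                    eff = intervention.intervention_zscores(model, city, topic)
                    eff["diff_order"] = order
                    effect_rows.append(eff)
                except (ValueError, stationarity.DegenerateSeriesError,
                        intervention.ScanError) as exc:
                    logger.warning("intervention (%s, %s) skipped: %s",
                                   city, topic, exc)
        effects = (
            pd.concat(effect_rows, ignore_index=True)
            if effect_rows else pd.DataFrame(
                columns=["city", "topic", "k", "event", "beta_hat", "se", "z",
                         "significant", "p", "q", "bic", "diff_order"])
        )
        _write(effects, outdir / "effects.csv")
        resp = pd.DataFrame(
            {
                "city": cities,
                "n_significant": [
                    intervention.count_significant_responses(effects, c, "overall")
                    for c in cities
                ],
            }
        )
        _write(resp, outdir / "response_counts.csv")
        reg_rows = []
        for topic, k_x, k_y in (("distancing", 1, 4), ("economy", 1, 4), ("TA", 3, 4)):
            try:
                slope, icpt, r, p, n = intervention.regress_effect_sizes(
                    effects, topic, k_x, k_y
                )
                reg_rows.append({"topic": topic, "k_x": k_x, "k_y": k_y,
                                 "slope": slope, "intercept": icpt, "r": r,
                                 "p_value": p, "n_used": n})
            except ValueError as exc:
                logger.warning("effect regression (%s, %d, %d) skipped: %s",
                               topic, k_x, k_y, exc)
        _write(pd.DataFrame(reg_rows), outdir / "effect_regressions.csv")

    # ---- association ----------------------------------------------------
    with stage("association"):
        corr_tables, summ_rows = [], []
        for topic in (topics if run_association else []):
            wide = pd.DataFrame(
                {c: measures.gms_series(gms, c, topic, dates) for c in cities}
            )
            wide = wide.dropna(axis=1, how="all")
            if wide.shape[1] < 2:
                continue
            try:
                table, summary = association.pairwise_city_correlations(
                    wide, alpha=config.alpha, max_order=config.max_diff_order
                )
            except ValueError as exc:
                logger.warning("pairwise correlations for %s skipped: %s", topic, exc)
                continue
            table.insert(0, "topic", topic)
            corr_tables.append(table)
            summ_rows.append({"topic": topic, **summary.pop("percentiles"),
                              **summary})
        _write(pd.concat(corr_tables, ignore_index=True) if corr_tables
               else pd.DataFrame(), outdir / "pairwise_corr.csv")
        _write(pd.DataFrame(summ_rows), outdir / "pairwise_summary.csv")

        offline = (
            _offline_series(mobility, cases, deaths, cities, dates)
            if run_association else []
        )
        off_rows = []
        gms_cache = {
            (c, t): measures.gms_series(gms, c, t, dates)
            for c in cities for t in topics
        }
        for (city, off_name, truncate), off_series in offline:
            for topic in topics:
                try:
                    res = association.gms_offline_correlation(
                        gms_cache[(city, topic)], off_series,
                        alpha=config.alpha, max_order=config.max_diff_order,
                        truncate_offline=truncate,
                        names=(f"{city}:{topic}", off_name),
                    )
                    off_rows.append(
                        {"city": city, "topic": topic, "offline": off_name,
                         "diff_order": res.diff_order, "r": res.r,
                         "p_value": res.p_value, "significant": res.significant,
                         "n_obs": res.n_obs}
                    )
                except (ValueError, stationarity.DegenerateSeriesError) as exc:
                    logger.warning("offline corr (%s, %s, %s) skipped: %s",
                                   city, topic, off_name, exc)
        _write(pd.DataFrame(off_rows), outdir / "offline_corr.csv")

        mob_dict = {
            f"{city}:{mode}": _mobility_series(mobility, city, mode, dates)
            for city in cities for mode in ("driving", "walking")
            if not mobility.empty
        }
        granger_rows = []
        for city in (cities if run_association else []):
            mob_city = {k: v for k, v in mob_dict.items()
                        if k.startswith(f"{city}:") and v.notna().sum() >= 10}
            gms_city = {f"{city}:{t}": gms_cache[(city, t)] for t in topics}
            if not mob_city:
                continue
            granger_rows.append(
                association.granger_matrix(
                    mob_city, gms_city, max_lag=config.granger_max_lag,
                    alpha=config.alpha, max_order=config.max_diff_order,
                )
            )
        _write(pd.concat(granger_rows, ignore_index=True) if granger_rows
               else pd.DataFrame(), outdir / "granger.csv")

    manifest["n_cities"] = len(cities)
    manifest["window"] = [str(window[0]), str(window[1])]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _mobility_series(mobility, city, mode, dates) -> pd.Series:
    sel = mobility[(mobility["city"] == city) & (mobility["mode"] == mode)]
    return pd.Series(sel["value"].to_numpy(), index=sel["date"]).reindex(dates)


def _offline_series(mobility, cases, deaths, cities, dates):
    """Yield ((city, offline_name, truncate_flag), series) pairs."""
    out = []
    for city in cities:
        if mobility is not None and not mobility.empty:
            for mode in ("driving", "walking"):
                s = _mobility_series(mobility, city, mode, dates)
                if s.notna().any():
                    out.append(((city, f"mobility_{mode}", False), s))
        for frame, measure in ((cases, "cases"), (deaths, "deaths")):
            if frame is None or frame.empty:
                continue
            for scope, label in ((city, "local"), (ingest.NATIONAL, "national")):
                sel = frame[frame["city"] == scope]
                if sel.empty:
                    continue
                s = pd.Series(sel["daily"].to_numpy(dtype=float),
                              index=sel["date"]).reindex(dates)
                out.append(((city, f"{label}_daily_{measure}", True), s))
    return out
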