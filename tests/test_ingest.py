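import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from oge import ingest
from oge.ingest import (
    DEFAULT_KEYWORDS,
    FormatError,
    PolicyEvent,
    daily_topic_counts,
    filter_cities,
    match_topics,
    policy_events_from_mapping,
    read_county_map,
    read_epidemic,
    read_mobility,
    read_policy_config,
    read_posts,
    write_mobility,
    write_policy_config,
    write_posts,
)


class TestReadPosts:
    def test_round_trip_preserves_records(self, posts_csv):
        posts = read_posts(posts_csv)
        assert len(posts) == 3
        assert list(posts["city"]) == ["Austin", "Austin", "Boston"]
        assert posts.loc[0, "date"] == dt.date(2020, 3, 1)

    def test_sentiment_labels_are_case_folded(self, posts_csv):
        posts = read_posts(posts_csv)
        assert posts.loc[0, "sentiment"] == "positive"

    def test_missing_city_column_is_a_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("post_id,date,sentiment\na,2020-03-01,positive\n")
        with pytest.raises(FormatError, match="city"):
            read_posts(path)

    def test_unknown_sentiment_label_is_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "post_id,date,city,sentiment\na,2020-03-01,Austin,angry\n"
        )
        with pytest.raises(FormatError, match="angry"):
            read_posts(path)

    def test_unparseable_date_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "post_id,date,city,sentiment\n"
            "a,2020-03-01,Austin,positive\n"
            "b,not-a-date,Austin,positive\n"
        )
        with pytest.raises(FormatError, match="line 3"):
            read_posts(path)

    def test_write_read_round_trip(self, posts_csv, tmp_path):
        posts = read_posts(posts_csv)
        out = tmp_path / "again.csv"
        write_posts(posts, out)
        again = read_posts(out)
        pd.testing.assert_frame_equal(posts, again)


class TestReadMobility:
    @pytest.fixture
    def apple_csv(self, tmp_path):
        path = tmp_path / "mob.csv"
        dates = [f"2020-03-0{i}" for i in range(1, 6)]
        lines = ["geo_type,region,transportation_type," + ",".join(dates)]
        for city in ("Austin", "Boston"):
            for mode, base in (("driving", 100), ("walking", 90)):
                vals = ",".join(str(base + i) for i in range(5))
                lines.append(f"city,{city},{mode},{vals}")
        lines.append("city,Austin,transit," + ",".join("50" for _ in range(5)))
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_apple_wide_fixture(self, apple_csv):
        mob = read_mobility(apple_csv, dialect="apple_wide")
        assert set(mob["mode"]) == {"driving", "walking"}  # transit dropped
        assert mob.groupby(["city", "mode"]).size().eq(5).all()
        assert len(mob) == 20

    def test_dialect_equivalence(self, apple_csv, tmp_path):
        mob = read_mobility(apple_csv, dialect="apple_wide")
        long_path = tmp_path / "long.csv"
        write_mobility(mob, long_path, dialect="tidy_long")
        again = read_mobility(long_path, dialect="tidy_long")
        pd.testing.assert_frame_equal(mob, again)

    def test_apple_round_trip(self, apple_csv, tmp_path):
        mob = read_mobility(apple_csv, dialect="apple_wide")
        out = tmp_path / "wide.csv"
        write_mobility(mob, out, dialect="apple_wide")
        pd.testing.assert_frame_equal(mob, read_mobility(out, dialect="apple_wide"))

    def test_unknown_dialect(self, apple_csv):
        with pytest.raises(FormatError, match="dialect"):
            read_mobility(apple_csv, dialect="parquet")

    def test_duplicate_cells_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "city,date,mode,value\n"
            "Austin,2020-03-01,driving,100\n"
            "Austin,2020-03-01,driving,101\n"
        )
        with pytest.raises(FormatError, match="duplicate"):
            read_mobility(path, dialect="tidy_long")


class TestReadEpidemic:
    @pytest.fixture
    def jhu_csv(self, tmp_path):
        path = tmp_path / "cases.csv"
        path.write_text(
            "county,2020-03-01,2020-03-02,2020-03-03\n"
            "Travis,0,1,3\n"
            "Williamson,0,0,2\n"
        )
        return path

    def test_county_aggregation_and_differencing(self, jhu_csv):
        epi = read_epidemic(jhu_csv, {"Travis": "Austin", "Williamson": "Austin"})
        city = epi[epi["city"] == "Austin"]
        assert list(city["cumulative"]) == [0, 1, 5]
        assert list(city["daily"]) == [0, 1, 4]

    def test_national_pools_all_counties(self, jhu_csv):
        epi = read_epidemic(jhu_csv, {}, on_unmapped="skip")
        assert set(epi["city"]) == {"national"}
        assert list(epi["cumulative"]) == [0, 1, 5]

    def test_unmapped_county_error_policy(self, jhu_csv):
        with pytest.raises(FormatError, match="Williamson"):
            read_epidemic(jhu_csv, {"Travis": "Austin"}, on_unmapped="error")

    def test_reporting_correction_gives_negative_daily(self, tmp_path):
        path = tmp_path / "corr.csv"
        path.write_text("county,2020-03-01,2020-03-02,2020-03-03\nTravis,5,3,6\n")
        epi = read_epidemic(path, {"Travis": "Austin"})
        city = epi[epi["city"] == "Austin"]
        assert list(city["daily"]) == [5, -2, 3]  # correction retained as-is

    def test_county_map_round_trip(self, tmp_path):
        path = tmp_path / "map.csv"
        path.write_text("county,city\nTravis,Austin\n")
        assert read_county_map(path) == {"Travis": "Austin"}


class TestPolicyConfig:
    def test_defaults_fill_missing_federal_dates(self, tmp_path):
        path = tmp_path / "policy.yaml"
        path.write_text("shelter:\n  Austin: {start: 2020-03-24, end: 2020-04-30}\n")
        events = read_policy_config(path)
        impulses = {e.k: e.date for e in events if e.kind == "impulse"}
        assert impulses == {
            1: dt.date(2020, 3, 13),
            2: dt.date(2020, 3, 29),
            3: dt.date(2020, 4, 16),
        }
        steps = [e for e in events if e.kind == "step"]
        assert len(steps) == 1 and steps[0].city == "Austin"

    def test_open_shelter_interval(self):
        events = policy_events_from_mapping(
            {"shelter": {"Austin": {"start": "2020-03-24"}}}
        )
        step = [e for e in events if e.kind == "step"][0]
        assert step.end is None

    def test_end_before_start_is_an_error(self):
        with pytest.raises(ValueError, match="before"):
            policy_events_from_mapping(
                {"shelter": {"Austin": {"start": "2020-04-01", "end": "2020-03-01"}}}
            )

    def test_unknown_event_key_is_an_error(self):
        with pytest.raises(FormatError, match="unknown"):
            policy_events_from_mapping({"federal": {"mask_mandate": "2020-04-01"}})

    def test_config_round_trip(self, tmp_path):
        events = policy_events_from_mapping(
            {"shelter": {"Austin": {"start": "2020-03-24", "end": None}}}
        )
        path = tmp_path / "policy.yaml"
        write_policy_config(events, path)
        assert read_policy_config(path) == events


class TestFilterCities:
    def _posts(self, per_city: dict[str, int], days: int = 10) -> pd.DataFrame:
        rows = []
        for city, total in per_city.items():
            for i in range(total):
                rows.append(
                    ("p%s%05d" % (city, i),
                     dt.date(2020, 3, 1) + dt.timedelta(days=i % days),
                     city, "neutral", "")
                )
        return pd.DataFrame(
            rows, columns=["post_id", "date", "city", "sentiment", "text"]
        )

    def test_threshold_is_inclusive(self):
        window = (dt.date(2020, 3, 1), dt.date(2020, 3, 10))
        posts = self._posts({"above": 65, "exact": 50, "below": 49})
        _, kept = filter_cities(posts, window, min_daily_avg=5)
        assert kept == ["above", "exact"]

    def test_empty_window_is_an_error(self):
        posts = self._posts({"a": 10})
        with pytest.raises(ValueError, match="window"):
            filter_cities(posts, (dt.date(2020, 3, 2), dt.date(2020, 3, 1)))


class TestMatchTopics:
    @pytest.mark.parametrize(
        "text,expected",
        [
            # "lockdown" also contains the economy keyword "dow" -- a literal
            # consequence of substring containment, like "chinatown" below
            ("trump extended the lockdown", {"TA", "distancing", "economy"}),
            ("trump extended the quarantine", {"TA", "distancing"}),
            ("nice weather today", set()),
            ("chinatown is quiet", {"China"}),  # substring false positive accepted
            ("social distancing and masks", {"distancing", "mask"}),
            ("", set()),
        ],
    )
    def test_keyword_containment(self, text, expected):
        assert match_topics(text) == expected

    @given(
        text=hst.text(alphabet="abcdefghijklmnopqrstuvwxyz ", max_size=60),
        suffix=hst.text(alphabet="xyz!? ", max_size=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_appending_nonmatching_text_never_removes_topics(self, text, suffix):
        before = match_topics(text)
        assert before <= match_topics(text + suffix)

    @given(text=hst.text(alphabet="abcdefghijklmnopqrstuvwxyz ", max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_adding_a_keyword_is_monotone(self, text):
        base = match_topics(text)
        extended = dict(DEFAULT_KEYWORDS)
        extended["economy"] = extended["economy"] + ("z",)
        assert base <= match_topics(text, extended)


class TestDailyTopicCounts:
    def test_sentiment_counting_with_mixed_pooled(self):
        posts = pd.DataFrame(
            {
                "post_id": [f"p{i}" for i in range(5)],
                "date": [dt.date(2020, 3, 1)] * 5,
                "city": ["Austin"] * 5,
                "sentiment": ["positive"] * 3 + ["mixed", "negative"],
                "text": ["wear a mask"] * 5,
            }
        )
        counts = daily_topic_counts(posts)
        row = counts[(counts["city"] == "Austin") & (counts["topic"] == "mask")]
        assert row[["P", "M", "N", "T"]].values.tolist() == [[3, 1, 1, 5]]

    def test_multi_topic_post_counts_once_per_topic_and_once_overall(self):
        posts = pd.DataFrame(
            {
                "post_id": ["p0"],
                "date": [dt.date(2020, 3, 1)],
                "city": ["Austin"],
                "sentiment": ["positive"],
                "text": ["trump extended the quarantine"],
            }
        )
        counts = daily_topic_counts(posts)
        austin = counts[counts["city"] == "Austin"]
        assert set(austin["topic"]) == {"overall", "TA", "distancing"}
        assert (austin["T"] == 1).all()

    def test_national_pseudo_city_pools_counts(self, tiny_posts):
        counts = daily_topic_counts(tiny_posts)
        national = counts[
            (counts["city"] == ingest.NATIONAL) & (counts["topic"] == "overall")
        ]["T"].sum()
        assert national == len(tiny_posts)

    def test_row_sums_and_total_record_count(self, tiny_posts):
        counts = daily_topic_counts(tiny_posts)
        assert (counts["T"] == counts["P"] + counts["M"] + counts["N"]).all()
        cities_only = counts[
            (counts["city"] != ingest.NATIONAL) & (counts["topic"] == "overall")
        ]
        assert cities_only["T"].sum() == len(tiny_posts)


def test_policy_event_validation():
    with pytest.raises(ValueError, match="unknown policy event key"):
        PolicyEvent(k=9, kind="impulse", scope="federal", date=dt.date(2020, 3, 1))
    with pytest.raises(ValueError, match="start"):
        PolicyEvent(k=4, kind="step", scope="local", city="x")
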