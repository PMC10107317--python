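import pandas as pd
import pytest

from conftest import sample_csv_text
from rivertrends import records, traits
from rivertrends.errors import FormatError, UsageError

KICK = records.KICK_METHOD


class TestParseSamples:
    def test_empty_file_with_valid_header(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text(sample_csv_text([]))
        df, report = records.parse_samples(path)
        assert len(df) == 0 and report.rows_rejected == 0

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("site_id,sample_id,date\n")
        with pytest.raises(FormatError):
            records.parse_samples(path)

    def test_bad_rows_rejected_with_line_numbers(self, tmp_path):
        rows = [
            ("s1", "k1", "2005-04-15", KICK, "Baetis", "genus", 3),
            ("s1", "k2", "not-a-date", KICK, "Baetis", "genus", 2),
            ("s1", "k3", "2006-09-01", KICK, "Baetis", "genus", -3),
            ("s1", "k4", "2006-10-01", KICK, "Baetis", "genus", 7),
            ("s1", "k5", "2007-04-02", KICK, "Baetis", "species", 1),
        ]
        path = tmp_path / "s.csv"
        path.write_text(sample_csv_text(rows))
        df, report = records.parse_samples(path)
        assert len(df) == 2
        assert report.rows_rejected == 3
        joined = " ".join(report.messages)
        assert "line 3" in joined and "line 4" in joined and "line 6" in joined


class TestAssignSeason:
    @pytest.mark.parametrize(
        "date,expected",
        [
            ("2005-04-15", "spring"),
            ("2010-09-01", "autumn"),
            ("2010-07-01", "other"),
            ("2003-03-01", "spring"),
            ("2003-11-30", "autumn"),
            ("2003-12-01", "other"),
        ],
    )
    def test_month_windows(self, date, expected):
        assert records.assign_season(date) == expected


def survey(rows):
    df = pd.DataFrame(
        rows,
        columns=["site_id", "sample_id", "date", "method", "taxon_name", "taxon_rank", "count"],
    )
    df["date"] = pd.to_datetime(df["date"])
    return df


def site_rows(site, year_seasons, method=KICK):
    out = []
    for i, (year, month) in enumerate(year_seasons):
        out.append(
            (site, f"{site}-{i}", f"{year}-{month:02d}-10", method, "Baetis", "genus", 5)
        )
    return out


class TestFilterRecords:
    def make_three_site_fixture(self):
        # qualifying: 3 years with both seasons; spring-only: 5 years;
        # short: both seasons but only 2 years.
        rows = []
        rows += site_rows(
            "good",
            [(2002, 4), (2002, 10), (2003, 4), (2003, 10), (2004, 4), (2004, 10)],
        )
        rows += site_rows(
            "springonly", [(y, 4) for y in range(2002, 2007)]
        )
        rows += site_rows(
            "short", [(2002, 4), (2002, 10), (2003, 4), (2003, 10)]
        )
        return survey(rows)

    def test_three_site_fixture_counts(self):
        df = self.make_three_site_fixture()
        kept, report = records.filter_records(df)
        assert set(kept["site_id"]) == {"good"}
        assert report.input_sites == 3
        assert report.input_records == 15
        assert report.after_method_year_records == 15
        assert report.retained_records == 6
        assert report.retained_sites == 1

    def test_min_years_monotone_shrinkage(self):
        df = self.make_three_site_fixture()
        previous = None
        for m in (1, 2, 3, 4):
            kept, _ = records.filter_records(
                df, records.FilterConfig(min_years_both_seasons=m)
            )
            sites = set(kept["site_id"])
            if previous is not None:
                assert sites.issubset(previous)
            previous = sites

    def test_idempotent(self):
        df = self.make_three_site_fixture()
        once, _ = records.filter_records(df)
        twice, _ = records.filter_records(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_non_kick_method_removed(self):
        rows = site_rows(
            "good",
            [(2002, 4), (2002, 10), (2003, 4), (2003, 10), (2004, 4), (2004, 10)],
            method="sweep net",
        )
        kept, report = records.filter_records(survey(rows))
        assert kept.empty and report.after_method_year_records == 0

    def test_out_of_window_years_removed(self):
        rows = site_rows(
            "good",
            [(2000, 4), (2000, 10), (2001, 4), (2001, 10), (2002, 4), (2002, 10)],
        )
        kept, _ = records.filter_records(survey(rows))
        assert kept.empty  # only one in-window both-season year remains

    def test_other_season_samples_kept_at_qualifying_sites(self):
        rows = self.make_three_site_fixture()
        extra = survey(site_rows("good", [(2003, 7)]))
        df = pd.concat([rows, extra], ignore_index=True)
        kept, _ = records.filter_records(df)
        assert (kept["season"] == "other").sum() == 1
        kept2, _ = records.filter_records(
            df, records.FilterConfig(spring_autumn_only=True)
        )
        assert (kept2["season"] == "other").sum() == 0


TAXONOMY = pd.DataFrame(
    {
        "taxon_name": ["Baetis", "Caenis", "Baetidae", "Caenidae", "Ephemeroptera"],
        "rank": ["genus", "genus", "family", "family", "higher-group"],
        "family": ["Baetidae", "Caenidae", "Baetidae", "Caenidae", ""],
        "group": ["Ephemeroptera"] * 5,
    }
)


class TestAggregateCounts:
    def sample(self, counts):
        rows = [
            ("s1", "k1", "2005-04-15", KICK, taxon, rank, c)
            for taxon, rank, c in counts
        ]
        df = survey(rows)
        df["year"] = df["date"].dt.year
        df["season"] = "spring"
        return df

    def test_group_level_additivity(self):
        df = self.sample([("Baetidae", "family", 10), ("Caenidae", "family", 5)])
        agg, unresolved = records.aggregate_counts(df, "group", taxonomy=TAXONOMY)
        assert unresolved == []
        assert agg.loc[agg["unit"] == "Ephemeroptera", "count"].tolist() == [15]

    def test_family_level_keeps_families_separate(self):
        df = self.sample([("Baetis", "genus", 7), ("Caenidae", "family", 5)])
        agg, _ = records.aggregate_counts(df, "family", taxonomy=TAXONOMY)
        out = dict(zip(agg["unit"], agg["count"]))
        assert out == {"Baetidae": 7, "Caenidae": 5}

    def test_higher_group_record_unresolvable_at_family_level(self):
        df = self.sample([("Ephemeroptera", "higher-group", 9)])
        agg, unresolved = records.aggregate_counts(df, "family", taxonomy=TAXONOMY)
        assert unresolved == ["Ephemeroptera"]
        assert agg.empty

    def test_absent_group_gives_no_row_without_zero_fill(self):
        df = self.sample([("Baetis", "genus", 4)])
        agg, _ = records.aggregate_counts(
            df, "group", taxonomy=TAXONOMY, materialize_zeros=False
        )
        assert set(agg["unit"]) == {"Ephemeroptera"}

    def test_zero_materialization_completes_sample_by_unit_grid(self):
        df = pd.concat(
            [
                self.sample([("Baetis", "genus", 4)]),
                self.sample([("Caenis", "genus", 2)]).assign(sample_id="k2"),
            ],
            ignore_index=True,
        )
        tax = TAXONOMY.copy()
        tax.loc[tax["taxon_name"] == "Caenis", "group"] = "molluscs"
        tax.loc[tax["taxon_name"] == "Caenidae", "group"] = "molluscs"
        agg, _ = records.aggregate_counts(df, "group", taxonomy=tax)
        assert len(agg) == 4  # 2 samples x 2 groups
        zeros = agg[agg["count"] == 0]
        assert len(zeros) == 2

    def test_multi_guild_taxon_counts_in_both_groups(self):
        df = self.sample([("Baetis", "genus", 7)])
        tmap = traits.TrophicMap(
            assignments={
                "Baetis": traits.TrophicAssignment(
                    "Baetis",
                    frozenset({"carnivore", "herbivore"}),
                    ("living_microphytes", "living_macroinvertebrates"),
                    3.0,
                )
            }
        )
        agg, _ = records.aggregate_counts(df, "trophic", trophic_map=tmap)
        out = dict(zip(agg["unit"], agg["count"]))
        assert out == {"carnivore": 7, "herbivore": 7}

    def test_conservation_at_group_level(self, tiny_survey):
        df = tiny_survey["records"]
        agg, unresolved = records.aggregate_counts(
            df, "group", taxonomy=tiny_survey["taxonomy"], materialize_zeros=False
        )
        assert unresolved == []
        assert agg["count"].sum() == df["count"].sum()

    def test_unknown_level_rejected(self):
        with pytest.raises(UsageError):
            records.aggregate_counts(self.sample([]), "order", taxonomy=TAXONOMY)
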