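import datetime

import numpy as np
import pandas as pd
import pytest

from dyadscan import scan_data as sd


def _write_roster(tmp_path, rows):
    path = tmp_path / "individuals.csv"
    pd.DataFrame(rows, columns=["id", "group", "sex", "age", "mother_id", "father_id"]).to_csv(
        path, index=False
    )
    return path


class TestReadIndividuals:
    def test_focal_threshold_at_seven_years(self, tmp_path):
        path = _write_roster(
            tmp_path, [("A", "g", "F", 12, "", ""), ("B", "g", "M", 5, "", "")]
        )
        inds = sd.read_individuals(path)
        assert [i.is_focal for i in inds] == [True, False]

    def test_missing_parents_are_none(self, tmp_path):
        path = _write_roster(tmp_path, [("A", "g", "F", 12, "", "")])
        (ind,) = sd.read_individuals(path)
        assert ind.mother_id is None and ind.father_id is None

    def test_duplicate_id_rejected(self, tmp_path):
        path = _write_roster(
            tmp_path, [("Kelele", "g", "F", 12, "", ""), ("Kelele", "g", "M", 9, "", "")]
        )
        with pytest.raises(sd.ValidationError, match="duplicate id.*Kelele"):
            sd.read_individuals(path)

    def test_unknown_sex_code_rejected(self, tmp_path):
        path = _write_roster(tmp_path, [("A", "g", "X", 12, "", "")])
        with pytest.raises(sd.ValidationError, match="sex"):
            sd.read_individuals(path)


def _events_files(tmp_path, event_rows, vis_rows):
    ev = tmp_path / "events.csv"
    vis = tmp_path / "visibility.csv"
    pd.DataFrame(
        event_rows,
        columns=["group", "day", "scan", "behaviour", "actor", "partner", "direction"],
    ).to_csv(ev, index=False)
    pd.DataFrame(vis_rows, columns=["group", "day", "scan", "visible_ids"]).to_csv(
        vis, index=False
    )
    return ev, vis


class TestReadScanEvents:
    def test_single_event_parsed(self, tmp_path):
        ev, vis = _events_files(
            tmp_path,
            [("g", "2020-01-01", 1, "close_proximity", "A", "B", "undirected")],
            [("g", "2020-01-01", 1, "A;B;C")],
        )
        table = sd.read_scan_events(ev, vis)
        assert len(table.events) == 1
        assert table.visibility[("g", datetime.date(2020, 1, 1), 1)] == {"A", "B", "C"}

    def test_proximity_exclusivity_enforced(self, tmp_path):
        ev, vis = _events_files(
            tmp_path,
            [
                ("g", "2020-01-01", 3, "close_proximity", "A", "B", "undirected"),
                ("g", "2020-01-01", 3, "distant_proximity", "B", "A", "undirected"),
            ],
            [("g", "2020-01-01", 3, "A;B")],
        )
        with pytest.raises(sd.ValidationError, match="scan 3"):
            sd.read_scan_events(ev, vis)

    def test_directional_grooming_retained(self, tmp_path):
        ev, vis = _events_files(
            tmp_path,
            [("g", "2020-01-01", 1, "grooming", "A", "B", "actor_grooms_partner")],
            [("g", "2020-01-01", 1, "A;B")],
        )
        table = sd.read_scan_events(ev, vis)
        assert table.events.iloc[0]["direction"] == "actor_grooms_partner"

    def test_actor_out_of_sight_rejected(self, tmp_path):
        ev, vis = _events_files(
            tmp_path,
            [("g", "2020-01-01", 1, "play", "A", "B", "undirected")],
            [("g", "2020-01-01", 1, "B")],
        )
        with pytest.raises(sd.ValidationError, match="'A'"):
            sd.read_scan_events(ev, vis)


def _simple_individuals():
    return [
        sd.Individual("A", "g", "F", 12.0),
        sd.Individual("B", "g", "M", 9.0),
        sd.Individual("C", "g", "F", 15.0),
    ]


def _table(event_rows, vis):
    ev = pd.DataFrame(
        event_rows,
        columns=["group", "day", "scan", "behaviour", "actor", "partner", "direction"],
    )
    ev["day"] = ev["day"].map(datetime.date.fromisoformat)
    visibility = {
        (g, datetime.date.fromisoformat(d), s): frozenset(ids) for (g, d, s), ids in vis.items()
    }
    return sd.ScanEventTable(events=ev, visibility=visibility)


class TestBuildDyadScanTable:
    def test_out_of_sight_partner_scored_zero(self):
        events = _table(
            [("g", "2020-01-01", 1, "close_proximity", "A", "B", "undirected")],
            {("g", "2020-01-01", 1): ["A", "B"]},  # C out of sight
        )
        table = sd.build_dyad_scan_table(events, _simple_individuals(), "close_proximity")
        got = {(r["i"], r["j"]): r["y"] for _, r in table.df.iterrows()}
        assert got == {("A", "B"): 1, ("A", "C"): 0, ("B", "C"): 0}

    def test_lag_within_day(self):
        events = _table(
            [
                ("g", "2020-01-01", 1, "play", "A", "B", "undirected"),
                ("g", "2020-01-01", 2, "play", "A", "B", "undirected"),
            ],
            {("g", "2020-01-01", 1): ["A", "B", "C"], ("g", "2020-01-01", 2): ["A", "B", "C"]},
        )
        table = sd.build_dyad_scan_table(events, _simple_individuals(), "play")
        ab = table.df[(table.df.i == "A") & (table.df.j == "B")].sort_values("scan")
        assert ab.y.tolist() == [1, 1]
        assert ab.y_prev.tolist() == [0, 1]

    def test_lag_resets_across_days(self):
        events = _table(
            [("g", "2020-01-01", 2, "play", "A", "B", "undirected")],
            {
                ("g", "2020-01-01", 1): ["A", "B"],
                ("g", "2020-01-01", 2): ["A", "B"],
                ("g", "2020-01-02", 1): ["A", "B"],
            },
        )
        table = sd.build_dyad_scan_table(events, _simple_individuals(), "play")
        ab = table.df[(table.df.i == "A") & (table.df.j == "B")].sort_values(["day", "scan"])
        # y=1 at last scan of day 1 does not carry into day 2
        assert ab.y.tolist() == [0, 1, 0]
        assert ab.y_prev.tolist() == [0, 0, 0]

    def test_both_out_of_sight_is_missing_not_zero(self):
        events = _table(
            [],
            {("g", "2020-01-01", 1): ["C"]},
        )
        table = sd.build_dyad_scan_table(events, _simple_individuals(), "play")
        # A-B dropped; A-C and B-C retained with y=0
        assert set(zip(table.df.i, table.df.j)) == {("A", "C"), ("B", "C")}

    def test_non_focal_dyads_excluded(self):
        inds = _simple_individuals() + [sd.Individual("D", "g", "F", 3.0)]
        inds[1] = sd.Individual("B", "g", "M", 4.0)  # B now juvenile
        events = _table([], {("g", "2020-01-01", 1): ["A", "B", "C", "D"]})
        table = sd.build_dyad_scan_table(events, inds, "play")
        pairs = set(zip(table.df.i, table.df.j))
        assert ("B", "D") not in pairs  # both juvenile
        assert ("A", "B") in pairs and ("A", "D") in pairs  # one focal suffices

    def test_unknown_behaviour_rejected(self):
        events = _table([], {("g", "2020-01-01", 1): ["A", "B"]})
        with pytest.raises(sd.ValidationError, match="unknown behaviour"):
            sd.build_dyad_scan_table(events, _simple_individuals(), "wrestling")

    def test_first_scan_of_each_dyad_day_has_zero_lag(self, tiny_table):
        df = tiny_table.df
        firsts = df.loc[df.groupby(["group", "i", "j", "day"])["scan"].idxmin()]
        assert (firsts.y_prev == 0).all()

    def test_grooming_table_doubles_undirected_rows(self, tiny_table, tiny_grooming_table):
        # same individuals, same visibility: one ordered pair per direction
        assert tiny_grooming_table.n_rows == 2 * tiny_table.n_rows

    def test_row_count_matches_brute_force_enumeration(self, tiny_dataset, tiny_table):
        events = tiny_dataset.events["close_proximity"]
        inds = tiny_dataset.individuals
        expected = 0
        focal = {i.id for i in inds if i.is_focal}
        by_group = {}
        for i in inds:
            by_group.setdefault(i.group, []).append(i.id)
        for (g, day, scan), vis in events.visibility.items():
            ids = sorted(by_group[g])
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    if ids[a] not in focal and ids[b] not in focal:
                        continue
                    if ids[a] in vis or ids[b] in vis:
                        expected += 1
        assert tiny_table.n_rows == expected


class TestRawRates:
    def test_dyad_and_individual_and_group_aggregation(self):
        rows = []
        # dyad A-B: 2/10 scans; dyad A-C: 3/10; dyad B-C: 0/10
        for s in range(10):
            rows.append(("g", "A", "B", datetime.date(2020, 1, 1), s + 1, int(s < 2), 0, 0.0, 0, 0, "FF"))
            rows.append(("g", "A", "C", datetime.date(2020, 1, 1), s + 1, int(s < 3), 0, 0.0, 0, 0, "FF"))
            rows.append(("g", "B", "C", datetime.date(2020, 1, 1), s + 1, 0, 0, 0.0, 0, 0, "FF"))
        df = pd.DataFrame(
            rows,
            columns=["group", "i", "j", "day", "scan", "y", "y_prev",
                     "age_diff", "maternal_kin", "paternal_kin", "sex_class"],
        )
        table = sd.DyadScanTable("close_proximity", False, df, _simple_individuals())
        rates = sd.compute_raw_rates(table)
        ab = rates.dyad_rates[(rates.dyad_rates.i == "A") & (rates.dyad_rates.j == "B")]
        assert float(ab.rate.iloc[0]) == pytest.approx(0.2)
        totals = dict(zip(rates.individual_totals.id, rates.individual_totals.total))
        assert totals["A"] == pytest.approx(0.5)  # 0.2 + 0.3
        g = rates.group_summary.iloc[0]
        assert g["mean"] == pytest.approx((0.5 + 0.2 + 0.3) / 3)

    def test_empty_table_rejected(self):
        df = pd.DataFrame(
            columns=["group", "i", "j", "day", "scan", "y", "y_prev",
                     "age_diff", "maternal_kin", "paternal_kin", "sex_class"]
        )
        table = sd.DyadScanTable("play", False, df, [])
        with pytest.raises(sd.ValidationError):
            sd.compute_raw_rates(table)


class TestEventWriterRoundTrip:
    def test_round_trip_preserves_table(self, tmp_path, tiny_dataset):
        events = tiny_dataset.events["close_proximity"]
        sd.write_events_csv(events, tmp_path / "ev.csv", tmp_path / "vis.csv")
        back = sd.read_scan_events(tmp_path / "ev.csv", tmp_path / "vis.csv")
        assert back.n_scans() == events.n_scans()
        assert len(back.events) == len(events.events)

    def test_conflicting_distant_event_dropped_on_write(self, tmp_path):
        events = _table(
            [("g", "2020-01-01", 1, "close_proximity", "A", "B", "undirected")],
            {("g", "2020-01-01", 1): ["A", "B"]},
        )
        # force a conflicting distant event into the in-memory frame
        clash = events.events.iloc[0].copy()
        clash["behaviour"] = "distant_proximity"
        events.events = pd.concat([events.events, clash.to_frame().T], ignore_index=True)
        sd.write_events_csv(events, tmp_path / "ev.csv", tmp_path / "vis.csv")
        back = pd.read_csv(tmp_path / "ev.csv")
        assert back.behaviour.tolist() == ["close_proximity"]
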