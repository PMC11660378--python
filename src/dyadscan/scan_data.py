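"""Domain types and ingestion for scan-sampled dyadic behaviour records.

Scan sampling records, at fixed instants, which visible group members are
engaged in a target behaviour with which partners.  The analysis operates on
a "dyad-scan" table: one binary outcome per eligible dyad per retained scan,
with a lagged outcome column carrying within-day autocorrelation and
dyad-level covariates (kinship, sex combination, age difference).

Conventions
-----------
* Behaviours: ``close_proximity`` (0-1 m), ``distant_proximity`` (1-2 m,
  mutually exclusive with close proximity within one scan), ``play``
  (undirected), ``grooming`` (directional: actor grooms partner).
* Focal individuals are those aged >= 7 years at study start; a dyad enters
  the analysis only if at least one member is focal.  Younger individuals
  appear only as partners of focal subjects.
* Out-of-sight handling: a dyad-scan with both members out of sight
  contributes no row (missing); with at least one member in sight and no
  recorded event, the outcome is 0 — an in-sight individual not seen
  interacting was by implication not interacting with anyone, visible or not.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BEHAVIOURS = ("close_proximity", "distant_proximity", "play", "grooming")

UNDIRECTED = "undirected"
ACTOR_GROOMS_PARTNER = "actor_grooms_partner"

FOCAL_AGE = 7.0

#: sex-class labels for undirected behaviours (female-female is reference)
SEX_CLASSES_UNDIRECTED = ("FF", "mixed", "MM")
#: sex-class labels for directional grooming (F grooms F is reference)
SEX_CLASSES_DIRECTED = ("FF", "MgroomsF", "FgroomsM", "MM")


class ValidationError(ValueError):
    """Raised when an input table violates the recording protocol."""


@dataclass(frozen=True)
class Individual:
    """A study subject.

    ``is_focal`` is derived: individuals aged 7 years or older at study
    start are treated as independent social actors; younger individuals are
    retained only as interaction partners.
    """

    id: str
    group: str
    sex: str  # 'F' or 'M'
    age_years: float
    mother_id: str | None = None
    father_id: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"unknown sex code {self.sex!r} for {self.id}")
        if self.age_years < 0:
            raise ValidationError(f"negative age for {self.id}")
        if self.mother_id == self.id or self.father_id == self.id:
            raise ValidationError(f"individual {self.id} listed as its own parent")

    @property
    def is_focal(self) -> bool:
        return self.age_years >= FOCAL_AGE


@dataclass
class ScanEventTable:
    """Raw per-scan behavioural events plus per-scan visibility.

    ``events`` columns: group, day (datetime.date), scan (int), behaviour,
    actor, partner, direction.  ``visibility`` maps (group, day, scan) to the
    frozenset of individual ids in sight at that scan; its keys enumerate the
    full scan universe, including scans at which nothing happened.
    """

    events: pd.DataFrame
    visibility: dict[tuple[str, _dt.date, int], frozenset[str]]

    def scans(self, group: str) -> list[tuple[_dt.date, int]]:
        """Chronologically ordered (day, scan) pairs recorded for a group."""
        keys = sorted((d, s) for (g, d, s) in self.visibility if g == group)
        return keys

    @property
    def groups(self) -> list[str]:
        return sorted({g for (g, _, _) in self.visibility})

    def n_scans(self, group: str | None = None) -> int:
        if group is None:
            return len(self.visibility)
        return sum(1 for (g, _, _) in self.visibility if g == group)


@dataclass
class DyadScanTable:
    """Likelihood input: one row per eligible dyad per retained scan.

    ``df`` columns: group, i, j, day, scan, y, y_prev, age_diff, maternal_kin,
    paternal_kin, sex_class.  For undirected behaviours rows are unordered
    pairs (i < j lexicographically); for grooming, ordered pairs with i the
    candidate groomer and j the candidate recipient, two rows per pair per
    scan.  ``age_diff`` is standardized across all dyads pooled over groups
    (absolute difference for undirected behaviour, signed groomer-minus-
    recipient for grooming).
    """

    behaviour: str
    directional: bool
    df: pd.DataFrame
    individuals: list[Individual]
    age_diff_mean: float = 0.0
    age_diff_sd: float = 1.0

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def groups(self) -> list[str]:
        return sorted(self.df["group"].unique())

    def to_csv(self, path) -> None:
        """Write the table for audit as plain CSV."""
        self.df.to_csv(path, index=False)


def _parse_day(value) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def read_individuals(path) -> list[Individual]:
    """Read the subject roster from CSV.

    Expected header: ``id,group,sex,age,mother_id,father_id``; sex coded
    F/M; empty parent fields mean unknown.  Duplicate ids within a group are
    an error.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"id", "group", "sex", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"individuals file missing columns: {sorted(missing)}")
    out: list[Individual] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        key = (row["group"], row["id"])
        if key in seen:
            raise ValidationError(f"duplicate id {row['id']!r} in group {row['group']!r}")
        seen.add(key)
        mother = row.get("mother_id")
        father = row.get("father_id")
        out.append(
            Individual(
                id=str(row["id"]),
                group=str(row["group"]),
                sex=str(row["sex"]),
                age_years=float(row["age"]),
                mother_id=None if pd.isna(mother) or mother == "" else str(mother),
                father_id=None if pd.isna(father) or father == "" else str(father),
            )
        )
    return out


def read_scan_events(
    events_path,
    visibility_path=None,
    *,
    individuals: Sequence[Individual] | None = None,
    assume_visible: bool = False,
) -> ScanEventTable:
    """Read scan events (and visibility) from CSV.

    ``events_path`` header: ``group,day,scan,behaviour,actor,partner,
    direction``.  ``visibility_path`` header: ``group,day,scan,visible_ids``
    with ids semicolon-separated; its rows enumerate every scan taken.

    With ``assume_visible=True`` (requires ``individuals``), scans missing
    from the visibility file are treated as having every group member in
    sight — the fallback for datasets that only list exceptions.
    """
    ev = pd.read_csv(events_path, dtype=str)
    required = {"group", "day", "scan", "behaviour", "actor", "partner", "direction"}
    missing = required - set(ev.columns)
    if missing:
        raise ValidationError(f"events file missing columns: {sorted(missing)}")
    ev["day"] = ev["day"].map(_parse_day)
    ev["scan"] = ev["scan"].astype(int)

    visibility: dict[tuple[str, _dt.date, int], frozenset[str]] = {}
    if visibility_path is not None:
        vis = pd.read_csv(visibility_path, dtype=str)
        vis["day"] = vis["day"].map(_parse_day)
        vis["scan"] = vis["scan"].astype(int)
        for _, row in vis.iterrows():
            ids = row["visible_ids"]
            members = frozenset() if pd.isna(ids) or ids == "" else frozenset(str(ids).split(";"))
            visibility[(row["group"], row["day"], row["scan"])] = members

    if assume_visible:
        if individuals is None:
            raise ValidationError("assume_visible requires the individuals roster")
        by_group: dict[str, frozenset[str]] = {}
        for ind in individuals:
            by_group.setdefault(ind.group, frozenset())
        for ind in individuals:
            by_group[ind.group] = by_group[ind.group] | {ind.id}
        for _, row in ev.iterrows():
            key = (row["group"], row["day"], row["scan"])
            if key not in visibility:
                visibility[key] = by_group.get(row["group"], frozenset())
    return _validate_events(ScanEventTable(events=ev, visibility=visibility))


def _validate_events(table: ScanEventTable) -> ScanEventTable:
    ev = table.events
    bad = set(ev["behaviour"]) - set(BEHAVIOURS)
    if bad:
        raise ValidationError(f"unknown behaviours: {sorted(bad)}")
    if (ev["scan"] < 1).any():
        raise ValidationError("scan indices must be positive")
    # close/distant proximity are mutually exclusive for a dyad in one scan
    prox = ev[ev["behaviour"].isin(["close_proximity", "distant_proximity"])].copy()
    if len(prox):
        prox["pair"] = [tuple(sorted(p)) for p in zip(prox["actor"], prox["partner"])]
        counts = prox.groupby(["group", "day", "scan", "pair"])["behaviour"].nunique()
        clash = counts[counts > 1]
        if len(clash):
            g, d, s, pair = clash.index[0]
            raise ValidationError(
                f"dyad {pair} recorded in both close and distant proximity at "
                f"scan {s} on {d} (group {g})"
            )
    # every actor/partner must be in the scan's visibility set
    for _, row in ev.iterrows():
        key = (row["group"], row["day"], row["scan"])
        vis = table.visibility.get(key)
        if vis is None:
            raise ValidationError(f"event at unknown scan {key}: no visibility record")
        for who in (row["actor"], row["partner"]):
            if who not in vis:
                raise ValidationError(
                    f"{who!r} recorded at scan {key} but not in its visibility set"
                )
    return table


def _maternal_kin(a: Individual, b: Individual) -> int:
    related = (
        a.mother_id == b.id
        or b.mother_id == a.id
        or (a.mother_id is not None and a.mother_id == b.mother_id)
    )
    return int(related)


def _paternal_kin(a: Individual, b: Individual) -> int:
    related = (
        a.father_id == b.id
        or b.father_id == a.id
        or (a.father_id is not None and a.father_id == b.father_id)
    )
    return int(related)


def _sex_class(a: Individual, b: Individual, directional: bool) -> str:
    if not directional:
        if a.sex == b.sex:
            return "FF" if a.sex == "F" else "MM"
        return "mixed"
    if a.sex == "M" and b.sex == "F":
        return "MgroomsF"
    if a.sex == "F" and b.sex == "M":
        return "FgroomsM"
    return "FF" if a.sex == "F" else "MM"


def eligible_dyads(
    individuals: Sequence[Individual], directional: bool
) -> list[tuple[Individual, Individual]]:
    """Same-group dyads with at least one focal member.

    Undirected: unordered pairs (id-sorted); grooming: both ordered pairs.
    """
    by_group: dict[str, list[Individual]] = {}
    for ind in individuals:
        by_group.setdefault(ind.group, []).append(ind)
    pairs: list[tuple[Individual, Individual]] = []
    for group in sorted(by_group):
        members = sorted(by_group[group], key=lambda x: x.id)
        for ia in range(len(members)):
            for ib in range(ia + 1, len(members)):
                a, b = members[ia], members[ib]
                if not (a.is_focal or b.is_focal):
                    continue
                if directional:
                    pairs.append((a, b))
                    pairs.append((b, a))
                else:
                    pairs.append((a, b))
    return pairs


def build_dyad_scan_table(
    events: ScanEventTable,
    individuals: Sequence[Individual],
    behaviour: str,
) -> DyadScanTable:
    """Construct the lagged binary dyad-scan table for one behaviour.

    Rules applied:

    * dyads require >= 1 focal member; both-juvenile pairs are excluded;
    * a dyad-scan with both members out of sight is dropped (missing);
    * otherwise y = 1 iff an event for this dyad (and, for grooming, this
      direction) was recorded at the scan, else 0;
    * ``y_prev`` is the previous retained scan's outcome within the same
      (dyad, day) block, 0 at the first retained scan of each day.
    """
    if behaviour not in BEHAVIOURS:
        raise ValidationError(f"unknown behaviour {behaviour!r}; expected one of {BEHAVIOURS}")
    directional = behaviour == "grooming"
    dyads = eligible_dyads(individuals, directional)

    ev = events.events
    ev_b = ev[ev["behaviour"] == behaviour]
    # map (group, day, scan) -> set of interacting (ordered or unordered) pairs
    active: dict[tuple, set[tuple[str, str]]] = {}
    for _, row in ev_b.iterrows():
        key = (row["group"], row["day"], row["scan"])
        pair: tuple[str, str]
        if directional:
            if row["direction"] != ACTOR_GROOMS_PARTNER:
                raise ValidationError(
                    f"grooming event without direction {ACTOR_GROOMS_PARTNER!r} at {key}"
                )
            pair = (row["actor"], row["partner"])
        else:
            pair = tuple(sorted((row["actor"], row["partner"])))  # type: ignore[assignment]
        active.setdefault(key, set()).add(pair)

    records: list[tuple] = []
    for a, b in dyads:
        group = a.group
        mk = _maternal_kin(a, b)
        pk = _paternal_kin(a, b)
        sc = _sex_class(a, b, directional)
        raw_age = (a.age_years - b.age_years) if directional else abs(a.age_years - b.age_years)
        prev = 0
        prev_day: _dt.date | None = None
        for day, scan in events.scans(group):
            vis = events.visibility[(group, day, scan)]
            if a.id not in vis and b.id not in vis:
                continue  # both out of sight: missing, not zero
            if day != prev_day:
                prev = 0
                prev_day = day
            y = int((a.id, b.id) in active.get((group, day, scan), ()))
            records.append((group, a.id, b.id, day, scan, y, prev, raw_age, mk, pk, sc))
            prev = y

    df = pd.DataFrame(
        records,
        columns=[
            "group", "i", "j", "day", "scan", "y", "y_prev",
            "age_diff", "maternal_kin", "paternal_kin", "sex_class",
        ],
    )
    # standardize age difference across unique dyads pooled over all groups
    mean, sd = 0.0, 1.0
    if len(df):
        per_dyad = df.drop_duplicates(["group", "i", "j"])["age_diff"].to_numpy(float)
        mean = float(per_dyad.mean())
        sd = float(per_dyad.std(ddof=0))
        if sd == 0.0:
            sd = 1.0
        df["age_diff"] = (df["age_diff"] - mean) / sd
    return DyadScanTable(
        behaviour=behaviour,
        directional=directional,
        df=df,
        individuals=list(individuals),
        age_diff_mean=mean,
        age_diff_sd=sd,
    )


@dataclass
class RawRates:
    """'Raw' descriptive rates: per-dyad proportions, per-individual totals,
    and per-group mean/SD of those totals."""

    dyad_rates: pd.DataFrame  # group, i, j, n_scans, rate
    individual_totals: pd.DataFrame  # group, id, total
    group_summary: pd.DataFrame  # group, mean, sd, n_individuals


def compute_raw_rates(table: DyadScanTable) -> RawRates:
    """Raw proportions of scans in which the behaviour occurred.

    Per dyad: (# scans with y=1) / (# retained scans).  Per individual: the
    sum of proportions over its dyads (for grooming, over both directions —
    total involvement).  Per group: mean and SD of individual totals.
    Dyads with zero retained scans are excluded with a warning.
    """
    if table.n_rows == 0:
        raise ValidationError("empty dyad-scan table")
    grp = table.df.groupby(["group", "i", "j"])["y"].agg(["sum", "count"]).reset_index()
    grp["rate"] = grp["sum"] / grp["count"]
    dyad_rates = grp.rename(columns={"count": "n_scans"})[["group", "i", "j", "n_scans", "rate"]]

    # individuals appearing in the table (focal-eligible dyad members)
    totals: dict[tuple[str, str], float] = {}
    for _, row in dyad_rates.iterrows():
        for who in (row["i"], row["j"]):
            totals[(row["group"], who)] = totals.get((row["group"], who), 0.0) + row["rate"]
    individual_totals = pd.DataFrame(
        [(g, i, t) for (g, i), t in sorted(totals.items())],
        columns=["group", "id", "total"],
    )
    zero_dyads = len(
        eligible_dyads(table.individuals, table.directional)
    ) - len(dyad_rates)
    if zero_dyads > 0:
        warnings.warn(
            f"{zero_dyads} dyad(s) with zero retained scans excluded from raw rates",
            stacklevel=2,
        )
    group_summary = (
        individual_totals.groupby("group")["total"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"std": "sd", "count": "n_individuals"})
    )
    return RawRates(dyad_rates, individual_totals, group_summary)


def write_events_csv(table: ScanEventTable, events_path, visibility_path) -> None:
    """Write a ScanEventTable back to the two-file CSV format.

    If close and distant proximity are ever recorded for the same dyad in
    the same scan (possible when independently simulated behaviours are
    merged), the distant-proximity event is dropped to honour the recording
    protocol's exclusivity rule.
    """
    ev = table.events.copy()
    prox = ev[ev["behaviour"].isin(["close_proximity", "distant_proximity"])]
    drop: list[int] = []
    if len(prox):
        keyed: dict[tuple, dict[str, int]] = {}
        for idx, row in prox.iterrows():
            pair = tuple(sorted((row["actor"], row["partner"])))
            key = (row["group"], row["day"], row["scan"], pair)
            keyed.setdefault(key, {})[row["behaviour"]] = idx
        for key, found in keyed.items():
            if len(found) > 1:
                drop.append(found["distant_proximity"])
    if drop:
        ev = ev.drop(index=drop)
    ev = ev.copy()
    ev["day"] = ev["day"].map(lambda d: d.isoformat())
    ev.to_csv(events_path, index=False)

    rows = [
        (g, d.isoformat(), s, ";".join(sorted(members)))
        for (g, d, s), members in sorted(table.visibility.items())
    ]
    pd.DataFrame(rows, columns=["group", "day", "scan", "visible_ids"]).to_csv(
        visibility_path, index=False
    )
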