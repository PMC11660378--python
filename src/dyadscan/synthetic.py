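"""Generative counterpart of the hierarchical dyadic model, with known truth.

Simulates multi-group scan-sampling studies: groups of individuals with
sex, age, and pedigree structure; per-dyad binary behaviour chains with
within-day Markov dependence on the previous scan; and per-scan visibility
censoring.  The defaults emulate the study design the model was built for:
six zoo-housed groups of 8-16 individuals sampled daily for about three
months (10 scans/day over 87 days, ~5220 scans in total), four behaviours,
and dyad-level kin/sex/age effects.

The outcome model run generatively is exactly the likelihood the sampler
fits:  y ~ Bernoulli(logit^-1(alpha + beta_last * y_prev + B_ijk + x'delta)),
with B_ijk the sum of group, individual (and grooming-recipient), and dyad
random effects drawn from their normal distributions.

Visibility censoring is applied after outcome generation and never flips an
outcome: each individual is independently in sight with probability
``visibility_prob`` per scan; an interaction whose members are all out of
sight is unobserved (event and dyad-scan row dropped), while an interaction
with at least one member in sight pulls the partner into the scan's
visibility set, as a live observer scoring the interaction would.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from dyadscan.scan_data import (
    ACTOR_GROOMS_PARTNER,
    BEHAVIOURS,
    UNDIRECTED,
    Individual,
    ScanEventTable,
    eligible_dyads,
)
import pandas as pd

START_DATE = _dt.date(2012, 1, 1)


@dataclass(frozen=True)
class TrueParameters:
    """Ground-truth parameters for one behaviour.

    ``delta`` maps covariate names (as produced by
    :func:`dyadscan.scan_data.build_dyad_scan_table` and consumed by the
    model) to log-odds coefficients; ``None`` means no covariate effects.
    """

    alpha: float = -4.0
    beta_last: float = 2.0
    sigma_group: float = 0.5
    sigma_ind: float = 0.5
    sigma_dyad: float = 1.0
    sigma_rec: float = 0.8
    delta: Mapping[str, float] | None = None


def default_true_parameters(behaviour: str) -> TrueParameters:
    """Study-condition defaults per behaviour.

    Baseline log-odds are low (raw dyadic rates of a few percent), the
    autocorrelation is strong (interaction bouts persist across successive
    scans), the dyad component dominates the individual one for proximity,
    and kin/sex/age effects take magnitudes of the order reported for
    captive bonobo groups (maternal kin several-fold more likely to
    interact; female dyads closer than mixed or male dyads; close proximity
    declining with age distance).
    """
    if behaviour == "grooming":
        return TrueParameters(
            alpha=-5.0,
            beta_last=2.0,
            sigma_group=0.4,
            sigma_ind=0.5,
            sigma_dyad=1.0,
            sigma_rec=0.9,
            delta={
                "age_diff": 0.0,
                "maternal_kin": float(np.log(15.8)),
                "paternal_kin": 0.2,
                "male_grooms_female": 0.0,
                "female_grooms_male": 0.0,
                "male_male": 0.0,
            },
        )
    deltas = {
        "close_proximity": {
            "age_diff": float(np.log(0.75)),
            "maternal_kin": float(np.log(6.1)),
            "paternal_kin": 0.1,
            "mixed_sex": float(-np.log(2.0)),
            "male_male": float(-np.log(2.9)),
        },
        "distant_proximity": {
            "age_diff": -0.15,
            "maternal_kin": float(np.log(3.5)),
            "paternal_kin": 0.1,
            "mixed_sex": float(-np.log(1.8)),
            "male_male": float(-np.log(2.8)),
        },
        "play": {
            "age_diff": 0.0,
            "maternal_kin": float(np.log(12.2)),
            "paternal_kin": float(np.log(1.49)),
            "mixed_sex": 0.0,
            "male_male": 0.0,
        },
    }
    return TrueParameters(
        alpha=-4.0,
        beta_last=2.0,
        sigma_group=0.5,
        sigma_ind=0.5,
        sigma_dyad=1.0,
        delta=deltas[behaviour],
    )


@dataclass
class SimulationConfig:
    """Configuration of a simulated multi-group scan-sampling study."""

    n_groups: int = 6
    group_sizes: Sequence[int] | None = None  # None: drawn uniform on 8..16
    female_fraction: float = 0.6
    age_range: tuple[float, float] = (7.0, 40.0)
    juvenile_fraction: float = 0.2  # individuals < 7 y, partners only
    maternal_kin_density: float = 0.3
    paternal_kin_density: float = 0.3
    days: int = 87
    scans_per_day: int = 10
    behaviours: Sequence[str] = BEHAVIOURS
    true_params: TrueParameters | Mapping[str, TrueParameters] | None = None
    visibility_prob: float = 0.9
    seed: int = 0

    def params_for(self, behaviour: str) -> TrueParameters:
        if self.true_params is None:
            return default_true_parameters(behaviour)
        if isinstance(self.true_params, TrueParameters):
            return self.true_params
        return self.true_params[behaviour]

    def validate(self) -> None:
        if self.scans_per_day < 1 or self.days < 1:
            raise ValueError("need at least one scan per day and one day")
        if not (0.0 < self.visibility_prob <= 1.0):
            raise ValueError("visibility_prob must be in (0, 1]")
        sizes = self.group_sizes
        if sizes is not None:
            if len(sizes) != self.n_groups:
                raise ValueError("group_sizes length must equal n_groups")
            if any(s < 2 for s in sizes):
                raise ValueError("every group needs at least 2 individuals")
        for b in self.behaviours:
            p = self.params_for(b)
            for name in ("sigma_group", "sigma_ind", "sigma_dyad", "sigma_rec"):
                if getattr(p, name) < 0:
                    raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticDataset:
    """A simulated study: roster, per-behaviour event tables, and the truth.

    ``truth`` records the generating parameters and every latent effect,
    keyed by group / individual / dyad labels, so that fitting stages can be
    checked against known ground truth.  The dataset is a pure function of
    its config (including the seed).
    """

    individuals: list[Individual]
    events: dict[str, ScanEventTable]
    truth: dict
    config: SimulationConfig

    def write(self, out_dir) -> list[str]:
        """Emit individuals.csv, per-behaviour events/visibility CSVs, and a
        truth.json sidecar; returns the file names written."""
        import pathlib

        from dyadscan.scan_data import write_events_csv

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        rows = [
            (i.id, i.group, i.sex, i.age_years, i.mother_id or "", i.father_id or "")
            for i in self.individuals
        ]
        pd.DataFrame(
            rows, columns=["id", "group", "sex", "age", "mother_id", "father_id"]
        ).to_csv(out / "individuals.csv", index=False)
        written.append("individuals.csv")
        for behaviour, table in self.events.items():
            ev_name = f"events_{behaviour}.csv"
            vis_name = f"visibility_{behaviour}.csv"
            write_events_csv(table, out / ev_name, out / vis_name)
            written.extend([ev_name, vis_name])
        truth = _jsonable(self.truth)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
        written.append("truth.json")
        return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _make_roster(config: SimulationConfig, rng: np.random.Generator) -> list[Individual]:
    sizes = config.group_sizes
    if sizes is None:
        sizes = rng.integers(8, 17, size=config.n_groups).tolist()
    individuals: list[Individual] = []
    for g in range(config.n_groups):
        group = f"G{g + 1}"
        n = int(sizes[g])
        sexes = np.where(rng.random(n) < config.female_fraction, "F", "M")
        juvenile = rng.random(n) < config.juvenile_fraction
        lo, hi = config.age_range
        ages = np.where(
            juvenile,
            rng.uniform(1.0, 7.0, size=n),
            rng.uniform(lo, hi, size=n),
        )
        # ensure at least two focal members so the group contributes dyads
        while (ages >= 7.0).sum() < 2:
            ages[int(np.argmin(ages))] = rng.uniform(lo, hi)
        members = [
            (f"{group}_I{k + 1:02d}", str(sexes[k]), float(ages[k])) for k in range(n)
        ]
        # pedigree: mother sampled among same-group females >= 12 years older
        for k, (iid, sex, age) in enumerate(members):
            mother = father = None
            mums = [m for m in members if m[1] == "F" and m[2] >= age + 12.0]
            dads = [m for m in members if m[1] == "M" and m[2] >= age + 12.0]
            if mums and rng.random() < config.maternal_kin_density:
                mother = mums[int(rng.integers(len(mums)))][0]
            if dads and rng.random() < config.paternal_kin_density:
                father = dads[int(rng.integers(len(dads)))][0]
            individuals.append(
                Individual(
                    id=iid, group=group, sex=sex, age_years=age,
                    mother_id=mother, father_id=father,
                )
            )
    return individuals


def _covariate_names(directional: bool) -> list[str]:
    if directional:
        return [
            "age_diff", "maternal_kin", "paternal_kin",
            "male_grooms_female", "female_grooms_male", "male_male",
        ]
    return ["age_diff", "maternal_kin", "paternal_kin", "mixed_sex", "male_male"]


def _dyad_covariates(a: Individual, b: Individual, directional: bool) -> dict[str, float]:
    from dyadscan.scan_data import _maternal_kin, _paternal_kin, _sex_class

    cov = {
        "maternal_kin": float(_maternal_kin(a, b)),
        "paternal_kin": float(_paternal_kin(a, b)),
    }
    sc = _sex_class(a, b, directional)
    if directional:
        cov["age_diff_raw"] = a.age_years - b.age_years
        cov["male_grooms_female"] = float(sc == "MgroomsF")
        cov["female_grooms_male"] = float(sc == "FgroomsM")
        cov["male_male"] = float(sc == "MM")
    else:
        cov["age_diff_raw"] = abs(a.age_years - b.age_years)
        cov["mixed_sex"] = float(sc == "mixed")
        cov["male_male"] = float(sc == "MM")
    return cov


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate a full study from the generative model.

    Deterministic under ``config.seed``: latent effects, outcome chains and
    visibility draws all come from one seeded generator, consumed in a fixed
    order (roster, then per behaviour in config order, then visibility).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    individuals = _make_roster(config, rng)
    groups = sorted({i.group for i in individuals})
    by_id = {i.id: i for i in individuals}

    n_scans = config.days * config.scans_per_day
    scan_days = np.repeat(np.arange(config.days), config.scans_per_day)
    scan_dates = [START_DATE + _dt.timedelta(days=int(d)) for d in range(config.days)]
    scan_index_in_day = np.tile(np.arange(1, config.scans_per_day + 1), config.days)

    truth: dict = {"groups": groups, "params": {}, "latents": {}}
    # per-behaviour simulated outcome matrices (n_scans, n_series)
    sim_y: dict[str, np.ndarray] = {}
    sim_pairs: dict[str, list[tuple[str, str]]] = {}

    for behaviour in config.behaviours:
        params = config.params_for(behaviour)
        directional = behaviour == "grooming"
        truth["params"][behaviour] = params

        pairs = eligible_dyads(individuals, directional)
        unordered = sorted({tuple(sorted((a.id, b.id))) for a, b in pairs})
        a_k = rng.normal(0.0, params.sigma_group, size=len(groups))
        b_i = rng.normal(0.0, params.sigma_ind, size=len(individuals))
        c_ij = rng.normal(0.0, params.sigma_dyad, size=len(unordered))
        d_j = rng.normal(0.0, params.sigma_rec, size=len(individuals)) if directional else None

        ind_ids = [i.id for i in individuals]
        gi = {g: k for k, g in enumerate(groups)}
        ii = {i: k for k, i in enumerate(ind_ids)}
        di = {p: k for k, p in enumerate(unordered)}
        truth["latents"][behaviour] = {
            "a": dict(zip(groups, a_k)),
            "b": dict(zip(ind_ids, b_i)),
            "c": {f"{p[0]}|{p[1]}": v for p, v in zip(unordered, c_ij)},
        }
        if directional:
            truth["latents"][behaviour]["d"] = dict(zip(ind_ids, d_j))

        # standardize age differences across unique (ordered) dyads, pooled
        raw_ages = np.array(
            [_dyad_covariates(a, b, directional)["age_diff_raw"] for a, b in pairs]
        )
        age_mean = float(raw_ages.mean())
        age_sd = float(raw_ages.std(ddof=0)) or 1.0

        delta = dict(params.delta or {})
        eta0 = np.empty(len(pairs))
        for idx, (a, b) in enumerate(pairs):
            cov = _dyad_covariates(a, b, directional)
            x_age = (cov.pop("age_diff_raw") - age_mean) / age_sd
            lin = params.alpha + a_k[gi[a.group]] + b_i[ii[a.id]] + c_ij[di[tuple(sorted((a.id, b.id)))]]
            lin += d_j[ii[b.id]] if directional else b_i[ii[b.id]]
            lin += delta.get("age_diff", 0.0) * x_age
            for name, val in cov.items():
                lin += delta.get(name, 0.0) * val
            eta0[idx] = lin
        p0 = expit(eta0)
        p1 = expit(eta0 + params.beta_last)

        y = np.zeros((n_scans, len(pairs)), dtype=np.int8)
        prev = np.zeros(len(pairs), dtype=np.int8)
        current_day = -1
        for s in range(n_scans):
            if scan_days[s] != current_day:
                prev = np.zeros(len(pairs), dtype=np.int8)
                current_day = scan_days[s]
            p = np.where(prev == 1, p1, p0)
            y[s] = (rng.random(len(pairs)) < p).astype(np.int8)
            prev = y[s].copy()
        sim_y[behaviour] = y
        sim_pairs[behaviour] = [(a.id, b.id) for a, b in pairs]

    # visibility: shared across behaviours (one scan universe per group)
    ind_ids = [i.id for i in individuals]
    base_visible = rng.random((n_scans, len(ind_ids))) < config.visibility_prob
    ii_all = {i: k for k, i in enumerate(ind_ids)}

    events_by_behaviour: dict[str, list[tuple]] = {b: [] for b in config.behaviours}
    visibility: dict[tuple[str, _dt.date, int], frozenset[str]] = {}
    members_of = {g: [i.id for i in individuals if i.group == g] for g in groups}

    for s in range(n_scans):
        day = scan_dates[int(scan_days[s])]
        scan_no = int(scan_index_in_day[s])
        # candidate interaction pairs at this scan, across behaviours
        candidates: list[tuple[str, str, str]] = []
        for behaviour in config.behaviours:
            ys = sim_y[behaviour][s]
            for idx in np.flatnonzero(ys):
                a_id, b_id = sim_pairs[behaviour][idx]
                candidates.append((behaviour, a_id, b_id))
        for g in groups:
            visible = {m for m in members_of[g] if base_visible[s, ii_all[m]]}
            group_cand = [c for c in candidates if by_id[c[1]].group == g]
            # an interaction with one member in sight reveals the partner
            changed = True
            retained: set[tuple[str, str, str]] = set()
            while changed:
                changed = False
                for cand in group_cand:
                    if cand in retained:
                        continue
                    _, a_id, b_id = cand
                    if a_id in visible or b_id in visible:
                        retained.add(cand)
                        if not {a_id, b_id} <= visible:
                            visible |= {a_id, b_id}
                            changed = True
            visibility[(g, day, scan_no)] = frozenset(visible)
            for behaviour, a_id, b_id in sorted(retained):
                direction = ACTOR_GROOMS_PARTNER if behaviour == "grooming" else UNDIRECTED
                events_by_behaviour[behaviour].append(
                    (g, day, scan_no, behaviour, a_id, b_id, direction)
                )

    columns = ["group", "day", "scan", "behaviour", "actor", "partner", "direction"]
    events = {
        behaviour: ScanEventTable(
            events=pd.DataFrame(rows, columns=columns), visibility=dict(visibility)
        )
        for behaviour, rows in events_by_behaviour.items()
    }
    return SyntheticDataset(
        individuals=individuals, events=events, truth=truth, config=config
    )


def simulate_party_scans(
    n_individuals: int = 8,
    n_scans: int = 200,
    base_rate: float = 0.04,
    party_prob: float = 0.15,
    party_rate: float = 0.6,
    seed: int = 0,
    behaviour: str = "play",
) -> tuple[list[Individual], ScanEventTable]:
    """Burst generator: dyads co-activate in latent "party" scans.

    With probability ``party_prob`` a scan is a party: every dyad is
    independently active with probability ``party_rate``; otherwise each
    dyad is active with ``base_rate``.  Marginal dyadic rates stay modest,
    but multi-individual components co-occur far more often than under
    dyadic independence — the alternative against which the clique
    posterior-predictive test is powered.  One group, full visibility.
    """
    rng = np.random.default_rng(seed)
    group = "G1"
    individuals = [
        Individual(
            id=f"{group}_I{k + 1:02d}",
            group=group,
            sex="F" if k % 2 == 0 else "M",
            age_years=10.0 + k,
        )
        for k in range(n_individuals)
    ]
    pairs = [(a.id, b.id) for a, b in eligible_dyads(individuals, False)]
    rows = []
    visibility = {}
    all_ids = frozenset(i.id for i in individuals)
    for s in range(n_scans):
        day = START_DATE + _dt.timedelta(days=s // 10)
        scan_no = s % 10 + 1
        rate = party_rate if rng.random() < party_prob else base_rate
        active = rng.random(len(pairs)) < rate
        visibility[(group, day, scan_no)] = all_ids
        for idx in np.flatnonzero(active):
            a_id, b_id = pairs[idx]
            rows.append((group, day, scan_no, behaviour, a_id, b_id, UNDIRECTED))
    events = pd.DataFrame(
        rows,
        columns=["group", "day", "scan", "behaviour", "actor", "partner", "direction"],
    )
    return individuals, ScanEventTable(events=events, visibility=visibility)


FIXTURES: dict[str, dict] = {
    "tiny": dict(
        n_groups=2,
        group_sizes=[4, 4],
        juvenile_fraction=0.0,
        days=4,
        scans_per_day=5,
        behaviours=("close_proximity", "grooming"),
        visibility_prob=1.0,
        seed=20_240_101,
    ),
    "paper_like": dict(
        n_groups=6,
        group_sizes=None,
        days=87,
        scans_per_day=10,
        seed=20_240_102,
    ),
    "null_group": dict(
        n_groups=6,
        group_sizes=[8] * 6,
        days=20,
        scans_per_day=10,
        behaviours=("close_proximity",),
        true_params=TrueParameters(
            alpha=-3.5, beta_last=1.5, sigma_group=0.0, sigma_ind=0.5, sigma_dyad=0.8
        ),
        seed=20_240_103,
    ),
    "strong_group": dict(
        n_groups=6,
        group_sizes=[8] * 6,
        days=20,
        scans_per_day=10,
        behaviours=("close_proximity",),
        true_params=TrueParameters(
            alpha=-3.5, beta_last=1.5, sigma_group=1.5, sigma_ind=0.5, sigma_dyad=0.5
        ),
        seed=20_240_104,
    ),
}


def make_fixture(name: str, **overrides) -> SyntheticDataset:
    """Canned simulation configs with documented seeds.

    ``tiny`` runs the whole pipeline in seconds; ``paper_like`` matches the
    emulated study scale (6 groups of 8-16, ~870 scans each, ~5220 total);
    ``null_group`` has no group-level variation (sigma_group = 0);
    ``strong_group`` has dominant group-level variation (sigma_group = 1.5).
    Keyword overrides (e.g. ``days=20``, ``seed=...``) adjust the config.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    cfg = dict(FIXTURES[name])
    cfg.update(overrides)
    return simulate_dataset(SimulationConfig(**cfg))
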