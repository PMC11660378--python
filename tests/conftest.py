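import numpy as np
import pandas as pd
import pytest

from dyadscan import scan_data as sd
from dyadscan import synthetic as syn
from dyadscan.model import ModelSpec, fit


@pytest.fixture(scope="session")
def tiny_dataset():
    return syn.make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_table(tiny_dataset):
    return sd.build_dyad_scan_table(
        tiny_dataset.events["close_proximity"], tiny_dataset.individuals, "close_proximity"
    )


@pytest.fixture(scope="session")
def tiny_grooming_table(tiny_dataset):
    return sd.build_dyad_scan_table(
        tiny_dataset.events["grooming"], tiny_dataset.individuals, "grooming"
    )


@pytest.fixture(scope="session")
def small_fit():
    """A modest but converged fit shared across network/clique/summary tests."""
    ds = syn.make_fixture(
        "paper_like",
        group_sizes=[8] * 6,
        days=15,
        scans_per_day=10,
        behaviours=("close_proximity",),
        seed=77,
    )
    table = sd.build_dyad_scan_table(
        ds.events["close_proximity"], ds.individuals, "close_proximity"
    )
    spec = ModelSpec(
        behaviour="close_proximity", include_covariates=True, iterations=1600, warmup=800, seed=5
    )
    return ds, table, fit(table, spec)


def random_dyad_table(rng: np.random.Generator, directional: bool = False) -> sd.DyadScanTable:
    """A small random dyad-scan table (valid structure, random contents)."""
    behaviour = "grooming" if directional else "close_proximity"
    n_groups = int(rng.integers(1, 3))
    rows = []
    for g in range(n_groups):
        group = f"g{g}"
        ids = [f"{group}_x{k}" for k in range(int(rng.integers(3, 5)))]
        pairs = [(a, b) for ai, a in enumerate(ids) for b in ids[ai + 1 :]]
        if directional:
            pairs = [(a, b) for a, b in pairs] + [(b, a) for a, b in pairs]
        for i, j in pairs:
            sex_class = (
                str(rng.choice(["FF", "MgroomsF", "FgroomsM", "MM"]))
                if directional
                else str(rng.choice(["FF", "mixed", "MM"]))
            )
            age = float(rng.normal())
            mk, pk = int(rng.random() < 0.3), int(rng.random() < 0.3)
            n_scans = int(rng.integers(1, 5))
            prev = 0
            for s in range(n_scans):
                y = int(rng.random() < 0.3)
                rows.append(
                    (group, i, j, pd.Timestamp("2020-01-01").date(), s + 1, y, prev,
                     age, mk, pk, sex_class)
                )
                prev = y
    df = pd.DataFrame(
        rows,
        columns=["group", "i", "j", "day", "scan", "y", "y_prev",
                 "age_diff", "maternal_kin", "paternal_kin", "sex_class"],
    )
    return sd.DyadScanTable(behaviour=behaviour, directional=directional, df=df, individuals=[])
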