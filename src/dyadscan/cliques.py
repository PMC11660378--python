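"""Clique formation beyond dyadic expectation (posterior-predictive test).

A "clique" here is a connected component of three or more simultaneously
interacting individuals within a single scan — chains are the observable
signature of multi-party congregation in pairwise scan records.  The test
compares the observed fraction of scans containing such a component with
its posterior-predictive distribution when every dyad switches on
independently at its model-estimated rate: an observed rate outside the
predictive interval indicates group-level co-activation (or avoidance)
beyond what dyadic rates explain.

A useful graph fact keeps the simulation cheap: an undirected graph has a
connected component with >= 3 vertices if and only if some vertex has
degree >= 2 (a path of three is already such a component, and any larger
component contains one).  The predictive simulation therefore only tracks
vertex degrees; :func:`scan_components` remains the general, explicit
component computation used on observed data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from dyadscan.networks import NetworkPosterior
from dyadscan.scan_data import ScanEventTable


def scan_components(pairs: Iterable[tuple[str, str]]) -> list[int]:
    """Sizes of connected components among one scan's interacting dyads.

    ``pairs`` are the dyads recorded as interacting within a single scan
    (grooming direction is ignored: edges are undirected).  Individuals not
    appearing in any pair form no component.
    """
    g = nx.Graph()
    g.add_edges_from(pairs)
    return sorted((len(comp) for comp in nx.connected_components(g)), reverse=True)


def observed_clique_rate(
    events: ScanEventTable,
    behaviour: str,
    group: str,
    min_visible: int = 3,
) -> tuple[float, list[int]]:
    """Observed fraction of scans containing a component of size >= 3.

    Only scans with at least ``min_visible`` individuals in sight can show
    a clique and are counted; the per-scan visible counts of those scans
    are returned alongside the rate so the predictive simulation can match
    them.  Raises on a group with no qualifying scans.
    """
    ev = events.events
    ev = ev[(ev["behaviour"] == behaviour) & (ev["group"] == group)]
    keyed: dict[tuple, list[tuple[str, str]]] = {}
    for _, row in ev.iterrows():
        keyed.setdefault((row["day"], row["scan"]), []).append((row["actor"], row["partner"]))
    scans = events.scans(group)
    if not scans:
        raise ValueError(f"no scans recorded for group {group!r}")
    hits = 0
    counted = 0
    visible_counts: list[int] = []
    for day, scan in scans:
        n_vis = len(events.visibility[(group, day, scan)])
        if n_vis < min_visible:
            continue
        counted += 1
        visible_counts.append(n_vis)
        sizes = scan_components(keyed.get((day, scan), []))
        if sizes and sizes[0] >= 3:
            hits += 1
    if counted == 0:
        raise ValueError(f"no scans with >= {min_visible} visible individuals in group {group!r}")
    return hits / counted, visible_counts


@dataclass
class PredictiveCliqueRate:
    """Posterior-predictive distribution of the per-study clique rate."""

    rates: np.ndarray  # one simulated study per entry
    mean: float
    interval: tuple[float, float]  # central 95% interval


def predictive_clique_rate(
    networks: NetworkPosterior,
    group: str,
    n_scans: int,
    n_sims: int = 500,
    seed: int = 0,
    visible_counts: Sequence[int] | None = None,
) -> PredictiveCliqueRate:
    """Clique rate expected under dyadic independence at posterior rates.

    Each simulation picks one posterior draw of the group's edge weights,
    switches every dyad on independently (Bernoulli at its weight) for
    ``n_scans`` scans, and records the fraction of scans with a component
    of size >= 3.  When ``visible_counts`` is given, each simulated scan
    restricts to a random node subset of the corresponding observed size,
    so predictive and observed rates face the same visibility regime.
    Grooming weights are combined as P(either direction active) =
    w_ij + w_ji - w_ij * w_ji.  Deterministic under ``seed``.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    rng = np.random.default_rng(seed)
    W_all = networks.weights[group]
    n_draws, n, _ = W_all.shape
    if networks.directed:
        W_all = W_all + np.transpose(W_all, (0, 2, 1)) - W_all * np.transpose(W_all, (0, 2, 1))
    iu, ju = np.triu_indices(n, k=1)
    edge_probs = W_all[:, iu, ju]  # (n_draws, n_edges)
    incidence = np.zeros((iu.size, n), dtype=np.int32)
    incidence[np.arange(iu.size), iu] = 1
    incidence[np.arange(ju.size), ju] = 1
    if visible_counts is not None:
        visible_counts = np.asarray(list(visible_counts), dtype=int)

    rates = np.empty(n_sims)
    for s in range(n_sims):
        t = int(rng.integers(n_draws))
        p = edge_probs[t]
        active = rng.random((n_scans, p.size)) < p[None, :]
        if visible_counts is not None:
            counts = visible_counts[rng.integers(len(visible_counts), size=n_scans)]
            # mask edges with an out-of-subset endpoint, per scan
            node_mask = np.zeros((n_scans, n), dtype=bool)
            for sc in range(n_scans):
                k = min(counts[sc], n)
                node_mask[sc, rng.permutation(n)[:k]] = True
            active &= node_mask[:, iu] & node_mask[:, ju]
        # component of size >= 3 exists iff some vertex degree >= 2
        deg = active.astype(np.int32) @ incidence
        rates[s] = float(np.mean((deg >= 2).any(axis=1)))
    lo, hi = np.percentile(rates, [2.5, 97.5])
    return PredictiveCliqueRate(rates=rates, mean=float(rates.mean()), interval=(float(lo), float(hi)))


@dataclass
class CliqueStatistics:
    """One group's clique test: observed vs dyadic-independence prediction."""

    group: str
    behaviour: str
    observed: float
    predictive_mean: float
    predictive_interval: tuple[float, float]
    excess: float
    evidence: bool


def clique_excess(
    observed: float,
    predictive: PredictiveCliqueRate,
    group: str = "",
    behaviour: str = "",
) -> CliqueStatistics:
    """Excess clique formation and its evidence flag.

    Excess = observed - predictive mean; evidence is flagged when the
    observed rate falls outside the central 95% predictive interval.
    """
    lo, hi = predictive.interval
    return CliqueStatistics(
        group=group,
        behaviour=behaviour,
        observed=float(observed),
        predictive_mean=predictive.mean,
        predictive_interval=predictive.interval,
        excess=float(observed) - predictive.mean,
        evidence=not (lo <= observed <= hi),
    )
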