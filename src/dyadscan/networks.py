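"""Posterior social networks and node/group-level metrics.

Edge weights are "association probabilities": the probability that a dyad
is engaged in the behaviour at a random point in time.  Because the model
is a lagged (two-state Markov) process on scans, that probability is the
stationary probability of the fitted chain, not the plain inverse-logit of
the linear predictor; the two coincide when the lag coefficient is zero.
Computing the weights per posterior draw propagates estimation uncertainty
into every derived metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit

from dyadscan.model import PosteriorSample
from dyadscan.summaries import evidence_flag, hpdi


def stationary_edge_prob(alpha, beta_last, B):
    """Long-run probability of being engaged, from the two-state chain.

    With p0 = P(y=1 | y_prev=0) = logit^-1(alpha + B) and
    p1 = P(y=1 | y_prev=1) = logit^-1(alpha + B + beta_last), the chain's
    stationary probability is p0 / (1 - p1 + p0).  Accepts scalars or
    arrays (broadcasting).
    """
    p0 = expit(np.asarray(alpha) + np.asarray(B))
    p1 = expit(np.asarray(alpha) + np.asarray(B) + np.asarray(beta_last))
    out = p0 / (1.0 - p1 + p0)
    if np.ndim(out) == 0:
        return float(out)
    return out


@dataclass
class NetworkPosterior:
    """Per-draw edge-weight matrices for every group.

    ``weights[group]`` has shape (n_draws, n, n) with nodes ordered as
    ``nodes[group]``; matrices are symmetric for undirected behaviours and
    directed (entry [i, j] = P(i grooms j)) for grooming.  Diagonals are 0.
    """

    weights: dict[str, np.ndarray]
    nodes: dict[str, list[str]]
    directed: bool

    @property
    def groups(self) -> list[str]:
        return sorted(self.weights)

    @property
    def n_draws(self) -> int:
        first = next(iter(self.weights.values()))
        return first.shape[0]

    def posterior_mean(self, group: str) -> np.ndarray:
        return self.weights[group].mean(axis=0)

    def edge_list(self, group: str) -> pd.DataFrame:
        """Posterior mean and 95% HPDI per edge, as a tidy frame."""
        W = self.weights[group]
        nodes = self.nodes[group]
        rows = []
        n = len(nodes)
        for i in range(n):
            js = range(n) if self.directed else range(i + 1, n)
            for j in js:
                if i == j:
                    continue
                draws = W[:, i, j]
                lo, hi = hpdi(draws) if draws.size >= 2 else (float(draws[0]),) * 2
                rows.append((nodes[i], nodes[j], float(draws.mean()), lo, hi))
        return pd.DataFrame(rows, columns=["i", "j", "mean", "hpdi_lo", "hpdi_hi"])


def derive_networks(
    sample: PosteriorSample,
    spec=None,
    covariate_values: pd.DataFrame | None = None,
    include_covariates: bool = True,
) -> NetworkPosterior:
    """Posterior association networks from a fitted model.

    Per draw and per modelled dyad, the edge weight is the stationary
    probability at alpha, beta_last and the dyad's linear predictor B_ijk
    (plus covariate contributions x'delta unless ``include_covariates`` is
    False, which reproduces the networks of the random-effects-only model).
    ``covariate_values`` may override the covariates stored with the fit
    (same columns as the dyad-scan table); every modelled dyad must appear.
    """
    if spec is None:
        spec = sample.spec
    meta = sample.dyad_meta
    if covariate_values is not None:
        merged = meta[["group", "i", "j"]].merge(covariate_values, on=["group", "i", "j"], how="left")
        if merged.isna().any().any():
            missing = merged[merged.isna().any(axis=1)][["group", "i", "j"]].iloc[0]
            raise ValueError(f"missing covariates for dyad {tuple(missing)}")
        work = sample_with_meta(sample, merged)
    else:
        work = sample
    B = work.dyad_linear_predictors(include_covariates=include_covariates)
    alpha = work.flat("alpha")[:, None]
    beta = work.flat("beta_last")[:, None]
    probs = stationary_edge_prob(alpha, beta, B)  # (n_draws, n_series)

    directed = bool(spec.directional)
    groups = sorted(meta["group"].unique())
    nodes = {
        g: sorted(set(meta.loc[meta["group"] == g, "i"]) | set(meta.loc[meta["group"] == g, "j"]))
        for g in groups
    }
    n_draws = probs.shape[0]
    weights = {g: np.zeros((n_draws, len(nodes[g]), len(nodes[g]))) for g in groups}
    for s, (_, row) in enumerate(meta.iterrows()):
        g = row["group"]
        node_index = {x: k for k, x in enumerate(nodes[g])}
        i = node_index[row["i"]]
        j = node_index[row["j"]]
        weights[g][:, i, j] = probs[:, s]
        if not directed:
            weights[g][:, j, i] = probs[:, s]
    return NetworkPosterior(weights=weights, nodes=nodes, directed=directed)


def sample_with_meta(sample: PosteriorSample, meta: pd.DataFrame) -> PosteriorSample:
    """A shallow copy of ``sample`` with replaced dyad covariate metadata."""
    import copy

    out = copy.copy(sample)
    out.dyad_meta = meta
    return out


def strength(matrix: np.ndarray, node: int, directed: bool | None = None) -> float:
    """Total connection of a node: sum of its edge weights.

    For directed grooming matrices, strength counts total involvement,
    out-edges plus in-edges (out-strength and in-strength are the two
    addends when needed separately).  With ``directed=None`` the mode is
    inferred from matrix symmetry.
    """
    matrix = np.asarray(matrix, dtype=float)
    if directed is None:
        directed = _is_directed(matrix)
    return float(matrix[node].sum() + (matrix[:, node].sum() if directed else 0.0))


def _is_directed(matrix: np.ndarray) -> bool:
    return not np.allclose(matrix, matrix.T)


def strength_vector(matrix: np.ndarray, directed: bool) -> np.ndarray:
    if directed:
        return matrix.sum(axis=1) + matrix.sum(axis=0)
    return matrix.sum(axis=1)


def cluster_coefficient(matrix: np.ndarray, node: int) -> float:
    """Probabilistic clustering coefficient of a node.

    Treating weights as independent edge probabilities,

        C_i = sum_{j != k != i} w_ij * w_jk * w_ik
              / sum_{j != k != i} w_ij * w_ik,

    the probability that two random "neighbours" (weighted by connection
    probability) are themselves connected.  Equals the binary clustering
    coefficient on 0/1 graphs.  Returns NaN (missing) when the denominator
    is zero (no pair of positively weighted neighbours).  Directed
    matrices are symmetrized as (W + W') / 2 first.
    """
    W = np.asarray(matrix, dtype=float)
    if np.any((W < 0) | (W > 1)):
        raise ValueError("edge weights must lie in [0, 1]")
    if W.shape[0] < 3:
        return float("nan")
    if _is_directed(W):
        W = np.clip((W + W.T) / 2.0, 0.0, 1.0)
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    w_i = W[node]
    num = float(w_i @ W @ w_i)  # j = k terms vanish with the zero diagonal
    den = float(w_i.sum() ** 2 - (w_i**2).sum())
    if den == 0.0:
        return float("nan")
    return num / den


def clustering_vector(matrix: np.ndarray) -> np.ndarray:
    return np.array([cluster_coefficient(matrix, k) for k in range(matrix.shape[0])])


@dataclass
class GroupMetricSummary:
    """Group means of a node metric with uncertainty, and all pairwise
    group contrasts with evidence flags (HPDI of the difference excluding
    zero)."""

    metric: str
    means: pd.DataFrame  # group, mean, hpdi_lo, hpdi_hi
    contrasts: pd.DataFrame  # group_a, group_b, mean_diff, hpdi_lo, hpdi_hi, evidence
    draws: dict[str, np.ndarray]  # per-group per-draw group means


def group_metric_posterior(networks: NetworkPosterior, metric: str) -> GroupMetricSummary:
    """Posterior of the group-average node metric, plus pairwise contrasts.

    Per draw: compute the metric for every node, average within the group.
    Clustering for groups of fewer than 3 nodes is flagged missing (NaN).
    """
    if metric not in ("strength", "clustering"):
        raise ValueError("metric must be 'strength' or 'clustering'")
    per_group: dict[str, np.ndarray] = {}
    for g in networks.groups:
        W = networks.weights[g]
        n_draws, n, _ = W.shape
        if metric == "strength":
            vals = np.array([strength_vector(W[t], networks.directed).mean() for t in range(n_draws)])
        else:
            if n < 3:
                vals = np.full(n_draws, np.nan)
            else:
                vals = np.array([np.nanmean(clustering_vector(W[t])) for t in range(n_draws)])
        per_group[g] = vals

    mrows = []
    for g, vals in per_group.items():
        if np.all(np.isnan(vals)):
            mrows.append((g, np.nan, np.nan, np.nan))
        else:
            lo, hi = hpdi(vals)
            mrows.append((g, float(np.mean(vals)), lo, hi))
    means = pd.DataFrame(mrows, columns=["group", "mean", "hpdi_lo", "hpdi_hi"])

    crows = []
    for ga, gb in combinations(networks.groups, 2):
        diff = per_group[ga] - per_group[gb]
        if np.all(np.isnan(diff)):
            crows.append((ga, gb, np.nan, np.nan, np.nan, False))
        else:
            lo, hi = hpdi(diff)
            crows.append((ga, gb, float(np.mean(diff)), lo, hi, not (lo <= 0.0 <= hi)))
    contrasts = pd.DataFrame(
        crows, columns=["group_a", "group_b", "mean_diff", "hpdi_lo", "hpdi_hi", "evidence"]
    )
    return GroupMetricSummary(metric=metric, means=means, contrasts=contrasts, draws=per_group)
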