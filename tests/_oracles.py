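"""Independent naive reference implementations used as test oracles.

Everything here is deliberately slow and literal: per-row loops, textbook
formulas, no shared code with the package internals beyond public data
containers.
"""

import math

from scipy.stats import norm


def naive_linear_predictor(state, row, directional, covariate_names):
    eta = state.alpha + state.beta_last * row["y_prev"]
    eta += state.a[state.group_labels.index(row["group"])]
    eta += state.b[state.individual_labels.index(row["i"])]
    if directional:
        eta += state.d[state.individual_labels.index(row["j"])]
    else:
        eta += state.b[state.individual_labels.index(row["j"])]
    pair = tuple(sorted((row["i"], row["j"])))
    eta += state.c[state.dyad_labels.index(pair)]
    for k, name in enumerate(covariate_names):
        if name in ("age_diff", "maternal_kin", "paternal_kin"):
            x = float(row[name])
        else:
            x = float(
                {
                    "mixed_sex": row["sex_class"] == "mixed",
                    "male_male": row["sex_class"] == "MM",
                    "male_grooms_female": row["sex_class"] == "MgroomsF",
                    "female_grooms_male": row["sex_class"] == "FgroomsM",
                }[name]
            )
        eta += state.delta[k] * x
    return eta


def naive_log_posterior(state, table, spec):
    """Per-row Bernoulli pmf summation plus explicit prior densities."""
    upper = spec.prior_sigma_upper
    sigmas = [state.sigma_group, state.sigma_ind, state.sigma_dyad]
    if spec.directional:
        sigmas.append(state.sigma_rec)
    for s in sigmas:
        if not (0.0 <= s <= upper):
            return -math.inf
    names = spec.covariate_names()
    total = 0.0
    for row in table.df.to_dict("records"):
        eta = naive_linear_predictor(state, row, spec.directional, names)
        p = 1.0 / (1.0 + math.exp(-eta))
        total += math.log(p) if row["y"] == 1 else math.log(1.0 - p)
    for x in state.a:
        total += norm.logpdf(x, scale=state.sigma_group)
    for x in state.b:
        total += norm.logpdf(x, scale=state.sigma_ind)
    for x in state.c:
        total += norm.logpdf(x, scale=state.sigma_dyad)
    if spec.directional:
        for x in state.d:
            total += norm.logpdf(x, scale=state.sigma_rec)
    total += norm.logpdf(state.alpha, scale=spec.prior_sd_fixed)
    total += norm.logpdf(state.beta_last, scale=spec.prior_sd_fixed)
    if names:
        for dk in state.delta:
            total += norm.logpdf(dk, scale=spec.prior_sd_fixed)
    total += -len(sigmas) * math.log(upper)
    return total


def naive_hpdi(draws, mass):
    """Exhaustive search over all windows of ceil(mass*n) sorted draws."""
    xs = sorted(float(v) for v in draws)
    n = len(xs)
    m = math.ceil(mass * n)
    best = None
    for lo in range(n - m + 1):
        width = xs[lo + m - 1] - xs[lo]
        if best is None or width < best[0]:
            best = (width, xs[lo], xs[lo + m - 1])
    return best[1], best[2]


def naive_cluster_coefficient(W, node):
    """Exhaustive enumeration over ordered triples (i, j, k)."""
    n = W.shape[0]
    num = 0.0
    den = 0.0
    for j in range(n):
        for k in range(n):
            if j == node or k == node or j == k:
                continue
            num += W[node, j] * W[j, k] * W[node, k]
            den += W[node, j] * W[node, k]
    if den == 0.0:
        return float("nan")
    return num / den


def random_parameter_state(rng, groups, individuals, dyads, directional, covariate_names):
    from dyadscan.model import ParameterState

    import numpy as np

    return ParameterState(
        alpha=float(rng.normal()),
        beta_last=float(rng.normal()),
        sigma_group=float(rng.uniform(0.2, 3.0)),
        sigma_ind=float(rng.uniform(0.2, 3.0)),
        sigma_dyad=float(rng.uniform(0.2, 3.0)),
        sigma_rec=float(rng.uniform(0.2, 3.0)) if directional else None,
        a=rng.normal(size=len(groups)),
        b=rng.normal(size=len(individuals)),
        c=rng.normal(size=len(dyads)),
        d=rng.normal(size=len(individuals)) if directional else None,
        delta=rng.normal(size=len(covariate_names)) if covariate_names else None,
        group_labels=list(groups),
        individual_labels=list(individuals),
        dyad_labels=[tuple(t) for t in dyads],
        covariate_names=list(covariate_names),
    )
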