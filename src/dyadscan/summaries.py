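"""Posterior summaries: HPD intervals, variance decompositions, odds effects.

All derived quantities (ratios, percent shares, odds multipliers) are
computed per posterior draw and then summarized — never as functions of
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dyadscan.model import ModelSpec, PosteriorSample


def hpdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Highest posterior density interval of a sample.

    The shortest contiguous interval of sorted draws containing
    ``ceil(mass * n)`` of them; among ties the leftmost window is returned
    (draws are discrete, so ties happen).  Requires at least 2 draws.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie strictly between 0 and 1")
    n = x.size
    if n < 2:
        raise ValueError("hpdi requires at least 2 draws")
    x = np.sort(x)
    m = int(np.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    lo = int(np.argmin(widths))  # argmin returns the first (leftmost) minimum
    return float(x[lo]), float(x[lo + m - 1])


def evidence_flag(draws_of_difference, reference: float = 0.0, mass: float = 0.95) -> bool:
    """True iff the HPD interval of the draws excludes the reference value.

    Used both for group contrasts (reference 0) and SD ratios (reference 1).
    """
    lo, hi = hpdi(draws_of_difference, mass)
    return not (lo <= reference <= hi)


def _summ(draws: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.mean(draws))
    if draws.size >= 2:
        lo, hi = hpdi(draws)
    else:
        lo = hi = float(draws[0])
    return mean, lo, hi


@dataclass
class VarianceSummary:
    """Posterior variance decomposition across model levels.

    ``table`` rows: sigma_group, sigma_ind, sigma_dyad, (sigma_rec),
    sigma_within, ratio_group (sigma_group / sigma_within), ratio_dyad
    (sigma_dyad / sigma_IND), each with posterior mean and 95% HPDI.
    ``percent`` rows: percent-of-total-variance shares per component
    (summing to 100 within each draw).  ``ratio_dyad_undefined`` flags
    draws where sigma_IND = 0 made the dyad/individual ratio infinite; the
    ratio is then reported as missing rather than crashing or truncating.
    """

    table: pd.DataFrame
    percent: pd.DataFrame
    directional: bool
    ratio_dyad_undefined: bool = False


def variance_summary(sample: PosteriorSample | dict, directional: bool | None = None) -> VarianceSummary:
    """Decompose posterior variance across group/individual/dyad levels.

    For undirected behaviours the individual component enters the total
    twice (once per member), so

        sigma_within = sqrt(2*sigma_ind^2 + sigma_dyad^2),
        sigma_IND    = sqrt(2) * sigma_ind,

    while for directional grooming the groomer and recipient components are
    distinct:

        sigma_within = sqrt(sigma_ind^2 + sigma_rec^2 + sigma_dyad^2),
        sigma_IND    = sqrt(sigma_ind^2 + sigma_rec^2).

    Accepts a fitted :class:`PosteriorSample` or a plain mapping of draw
    arrays (``sigma_group``, ``sigma_ind``, ``sigma_dyad``, optionally
    ``sigma_rec``).
    """
    if isinstance(sample, PosteriorSample):
        if directional is None:
            directional = bool(sample.spec.directional)
        get = lambda k: sample.flat(k)
        have_rec = "sigma_rec" in sample.draws
    else:
        if directional is None:
            raise ValueError("directional must be given with raw draw mappings")
        get = lambda k: np.atleast_1d(np.asarray(sample[k], dtype=float))
        have_rec = "sigma_rec" in sample
    if directional and not have_rec:
        raise ValueError("directional summary requires sigma_rec draws")

    sg = get("sigma_group")
    si = get("sigma_ind")
    sd = get("sigma_dyad")
    components = {"group": sg**2}
    if directional:
        sr = get("sigma_rec")
        within_var = si**2 + sr**2 + sd**2
        sigma_ind_combined = np.sqrt(si**2 + sr**2)
        components["individual"] = si**2
        components["recipient"] = sr**2
    else:
        within_var = 2 * si**2 + sd**2
        sigma_ind_combined = np.sqrt(2.0) * si
        components["individual"] = 2 * si**2
    components["dyad"] = sd**2

    sigma_within = np.sqrt(within_var)
    total_var = sg**2 + within_var
    ratio_group = np.where(sigma_within > 0, sg / np.where(sigma_within > 0, sigma_within, 1.0), np.inf)
    undefined = sigma_ind_combined == 0
    ratio_dyad = np.where(undefined, np.inf, sd / np.where(undefined, 1.0, sigma_ind_combined))
    ratio_dyad_undefined = bool(np.any(undefined))

    rows = [("sigma_group", *_summ(sg)), ("sigma_ind", *_summ(si)), ("sigma_dyad", *_summ(sd))]
    if directional:
        rows.append(("sigma_rec", *_summ(sr)))
    rows.append(("sigma_within", *_summ(sigma_within)))
    rows.append(("ratio_group", *_summ(ratio_group)))
    if ratio_dyad_undefined:
        rows.append(("ratio_dyad", np.nan, np.nan, np.nan))
    else:
        rows.append(("ratio_dyad", *_summ(ratio_dyad)))
    table = pd.DataFrame(rows, columns=["quantity", "mean", "hpdi_lo", "hpdi_hi"])

    prows = []
    for name, var in components.items():
        share = 100.0 * var / total_var
        prows.append((name, *_summ(share)))
    percent = pd.DataFrame(prows, columns=["component", "mean", "hpdi_lo", "hpdi_hi"])
    return VarianceSummary(
        table=table,
        percent=percent,
        directional=directional,
        ratio_dyad_undefined=ratio_dyad_undefined,
    )


@dataclass
class EffectSummary:
    """Odds-scale covariate effects: exp(delta) per draw, summarized."""

    table: pd.DataFrame  # covariate, multiplier, hpdi_lo, hpdi_hi, evidence

    def multiplier(self, covariate: str) -> float:
        row = self.table[self.table["covariate"] == covariate]
        if row.empty:
            raise KeyError(covariate)
        return float(row["multiplier"].iloc[0])


def odds_effects(sample: PosteriorSample, spec: ModelSpec | None = None) -> EffectSummary:
    """Back-transform covariate coefficients to the odds scale.

    For each coefficient delta the multiplier exp(delta) is computed per
    draw and summarized with its mean and 95% HPDI; the evidence flag marks
    intervals excluding 1 (no effect).
    """
    if spec is None:
        spec = sample.spec
    names = spec.covariate_names()
    if not names:
        raise ValueError("model was fitted without covariates")
    rows = []
    for name in names:
        key = f"delta_{name}"
        if key not in sample.draws:
            raise ValueError(f"covariate {name!r} absent from the posterior sample")
        mult = np.exp(sample.flat(key))
        mean, lo, hi = _summ(mult)
        rows.append((name, mean, lo, hi, not (lo <= 1.0 <= hi)))
    return EffectSummary(
        pd.DataFrame(rows, columns=["covariate", "multiplier", "hpdi_lo", "hpdi_hi", "evidence"])
    )
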