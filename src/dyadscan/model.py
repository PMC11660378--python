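"""Hierarchical Bernoulli model of dyadic scan outcomes, and its sampler.

Model
-----
For dyad (i, j) in group k at scan l on day m, the outcome is

    y ~ Bernoulli(p),   logit(p) = alpha + beta_last * y_prev + B_ijk + x'delta

with, for undirected behaviours,

    B_ijk = a_k + b_ik + b_jk + c_ijk

and for directional grooming (i the candidate groomer, j the recipient)

    B_ijk = a_k + b_ik + d_jk + c_ijk

where a_k ~ N(0, sigma_group^2) is a group effect, b_ik ~ N(0, sigma_ind^2)
an individual effect (propensity to groom, for grooming), d_jk ~
N(0, sigma_rec^2) a grooming-recipient effect, and c_ijk ~ N(0,
sigma_dyad^2) a dyad bond effect shared by both directions of a pair.
Priors are vague: N(0, 100^2) on alpha, beta_last and each covariate
coefficient; uniform(0, 10) on every SD.

Estimation is by Markov chain Monte Carlo (adaptive Metropolis-within-
Gibbs with interweaved centred/non-centred SD updates; see
``dyadscan._kernels``), with split-R-hat and effective-sample-size
diagnostics via ArviZ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from dyadscan.scan_data import DyadScanTable

COVARIATES_UNDIRECTED = ("age_diff", "maternal_kin", "paternal_kin", "mixed_sex", "male_male")
COVARIATES_DIRECTED = (
    "age_diff",
    "maternal_kin",
    "paternal_kin",
    "male_grooms_female",
    "female_grooms_male",
    "male_male",
)


class FitError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Configuration of one model fit."""

    behaviour: str = "close_proximity"
    directional: bool | None = None  # None: inferred (grooming is directional)
    include_covariates: bool = True
    include_male_male_grooming: bool = True
    prior_sd_fixed: float = 100.0  # N(0, 100^2) on alpha, beta_last, delta
    prior_sigma_upper: float = 10.0  # U(0, 10) on every SD
    chains: int = 2
    iterations: int = 2000  # total per chain, including warmup
    warmup: int = 1000
    thinning: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.directional is None:
            self.directional = self.behaviour == "grooming"
        if self.prior_sigma_upper <= 0:
            raise ValueError("prior_sigma_upper must be positive")
        if self.chains < 2:
            warnings.warn("fewer than 2 chains: convergence diagnostics unavailable")
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")

    def covariate_names(self) -> list[str]:
        if not self.include_covariates:
            return []
        names = list(COVARIATES_DIRECTED if self.directional else COVARIATES_UNDIRECTED)
        if self.directional and not self.include_male_male_grooming:
            names.remove("male_male")
        return names


@dataclass
class ParameterState:
    """One full set of model parameters, with labels for every effect."""

    alpha: float
    beta_last: float
    sigma_group: float
    sigma_ind: float
    sigma_dyad: float
    a: np.ndarray  # per group
    b: np.ndarray  # per individual
    c: np.ndarray  # per unordered dyad
    group_labels: list[str]
    individual_labels: list[str]
    dyad_labels: list[tuple[str, str]]
    sigma_rec: float | None = None
    d: np.ndarray | None = None  # per individual (grooming recipient)
    delta: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    @classmethod
    def zeros(
        cls,
        group_labels: Sequence[str],
        individual_labels: Sequence[str],
        dyad_labels: Sequence[tuple[str, str]],
        directional: bool = False,
        covariate_names: Sequence[str] = (),
        sigma: float = 1.0,
    ) -> "ParameterState":
        return cls(
            alpha=0.0,
            beta_last=0.0,
            sigma_group=sigma,
            sigma_ind=sigma,
            sigma_dyad=sigma,
            sigma_rec=sigma if directional else None,
            a=np.zeros(len(group_labels)),
            b=np.zeros(len(individual_labels)),
            c=np.zeros(len(dyad_labels)),
            d=np.zeros(len(individual_labels)) if directional else None,
            delta=np.zeros(len(covariate_names)) if covariate_names else None,
            group_labels=list(group_labels),
            individual_labels=list(individual_labels),
            dyad_labels=[tuple(t) for t in dyad_labels],
            covariate_names=list(covariate_names),
        )


def linear_predictor(state: ParameterState, row: Mapping, spec: ModelSpec) -> float:
    """Log-odds of interaction for one dyad-scan row.

    ``row`` must provide group, i, j, y_prev and — when the spec includes
    covariates — the covariate columns named by ``spec.covariate_names()``
    (sex combination via the ``sex_class`` token, as in the dyad-scan
    table).
    """
    gi = state.group_labels.index(row["group"])
    ii = state.individual_labels.index(row["i"])
    ji = state.individual_labels.index(row["j"])
    pair = tuple(sorted((row["i"], row["j"])))
    di = state.dyad_labels.index(pair)
    eta = state.alpha + state.beta_last * row["y_prev"] + state.a[gi] + state.b[ii] + state.c[di]
    if spec.directional:
        assert state.d is not None
        eta += state.d[ji]
    else:
        eta += state.b[ji]
    if spec.include_covariates and state.delta is not None:
        for k, name in enumerate(state.covariate_names):
            eta += state.delta[k] * _covariate_value(row, name)
    return float(eta)


def _covariate_value(row: Mapping, name: str) -> float:
    if name in ("age_diff", "maternal_kin", "paternal_kin"):
        return float(row[name])
    sex_class = row["sex_class"]
    mapping = {
        "mixed_sex": sex_class == "mixed",
        "male_male": sex_class == "MM",
        "male_grooms_female": sex_class == "MgroomsF",
        "female_grooms_male": sex_class == "FgroomsM",
    }
    return float(mapping[name])


@dataclass
class _Prepared:
    """Index arrays the sampler and the log posterior operate on."""

    y: np.ndarray
    y_prev: np.ndarray
    X: np.ndarray
    g_idx: np.ndarray
    i_idx: np.ndarray
    j_idx: np.ndarray
    dy_idx: np.ndarray
    groups: list[str]
    individuals: list[str]
    dyads: list[tuple[str, str]]
    covariate_names: list[str]
    dyad_meta: pd.DataFrame  # one row per modelled (ordered) dyad series


def _prepare(table: DyadScanTable, spec: ModelSpec) -> _Prepared:
    df = table.df
    groups = sorted(df["group"].unique())
    individuals = sorted(set(df["i"]) | set(df["j"]))
    pairs = sorted({tuple(sorted(t)) for t in zip(df["i"], df["j"])})
    gmap = {g: k for k, g in enumerate(groups)}
    imap = {i: k for k, i in enumerate(individuals)}
    dmap = {p: k for k, p in enumerate(pairs)}

    cov_names = spec.covariate_names()
    n = len(df)
    X = np.empty((n, len(cov_names)))
    for k, name in enumerate(cov_names):
        if name in ("age_diff", "maternal_kin", "paternal_kin"):
            X[:, k] = df[name].to_numpy(float)
        else:
            target = {
                "mixed_sex": "mixed",
                "male_male": "MM",
                "male_grooms_female": "MgroomsF",
                "female_grooms_male": "FgroomsM",
            }[name]
            X[:, k] = (df["sex_class"] == target).to_numpy(float)

    meta = df.drop_duplicates(["group", "i", "j"]).copy()
    meta = meta.drop(columns=["day", "scan", "y", "y_prev"]).reset_index(drop=True)

    return _Prepared(
        y=df["y"].to_numpy(float),
        y_prev=df["y_prev"].to_numpy(float),
        X=X,
        g_idx=df["group"].map(gmap).to_numpy(np.int64),
        i_idx=df["i"].map(imap).to_numpy(np.int64),
        j_idx=df["j"].map(imap).to_numpy(np.int64),
        dy_idx=np.array([dmap[tuple(sorted(t))] for t in zip(df["i"], df["j"])], dtype=np.int64),
        groups=groups,
        individuals=individuals,
        dyads=pairs,
        covariate_names=cov_names,
        dyad_meta=meta,
    )


def log_posterior(state: ParameterState, table: DyadScanTable, spec: ModelSpec) -> float:
    """Unnormalized log posterior density at ``state``.

    Bernoulli log likelihood at the logit of the linear predictor, plus
    normal log densities of every random effect given its SD, plus the
    fixed-effect normal priors and the uniform SD priors.  Returns ``-inf``
    (never raises) when any SD lies outside [0, upper].
    """
    upper = spec.prior_sigma_upper
    sigmas = [state.sigma_group, state.sigma_ind, state.sigma_dyad]
    if spec.directional:
        sigmas.append(state.sigma_rec)
    for s in sigmas:
        if s is None or not (0.0 <= s <= upper):
            return -np.inf

    prep = _prepare(table, spec)
    gmap = {g: k for k, g in enumerate(state.group_labels)}
    imap = {i: k for k, i in enumerate(state.individual_labels)}
    dmap = {p: k for k, p in enumerate(state.dyad_labels)}
    g = np.array([gmap[x] for x in prep.groups], dtype=int)
    i = np.array([imap[x] for x in prep.individuals], dtype=int)
    dpair = np.array([dmap[x] for x in prep.dyads], dtype=int)

    a = state.a[g][prep.g_idx]
    b_i = state.b[i][prep.i_idx]
    c = state.c[dpair][prep.dy_idx]
    eta = state.alpha + state.beta_last * prep.y_prev + a + b_i + c
    if spec.directional:
        assert state.d is not None
        eta = eta + state.d[i][prep.j_idx]
    else:
        eta = eta + state.b[i][prep.j_idx]
    if spec.include_covariates and state.delta is not None and prep.X.shape[1]:
        eta = eta + prep.X @ state.delta

    # Bernoulli log pmf: y*eta - log(1 + exp(eta))
    ll = float(np.sum(prep.y * eta - np.logaddexp(0.0, eta)))

    def _sum_norm(x, sd):
        if sd == 0.0:
            return 0.0 if np.allclose(x, 0.0) else -np.inf
        return float(np.sum(norm.logpdf(x, scale=sd)))

    lp = ll
    lp += _sum_norm(state.a, state.sigma_group)
    lp += _sum_norm(state.b, state.sigma_ind)
    lp += _sum_norm(state.c, state.sigma_dyad)
    if spec.directional:
        lp += _sum_norm(state.d, state.sigma_rec)
    lp += float(norm.logpdf(state.alpha, scale=spec.prior_sd_fixed))
    lp += float(norm.logpdf(state.beta_last, scale=spec.prior_sd_fixed))
    if spec.include_covariates and state.delta is not None:
        lp += float(np.sum(norm.logpdf(state.delta, scale=spec.prior_sd_fixed)))
    lp += -len(sigmas) * np.log(upper)  # uniform prior densities
    return lp


@dataclass
class PosteriorSample:
    """Retained MCMC draws with chain structure and effect labels.

    Scalar draws (``alpha``, ``beta_last``, ``delta_*``, ``sigma_*``) have
    shape (chains, draws); effect vectors (``a``, ``b``, ``c``, ``d``) have
    shape (chains, draws, n_effects).  ``dyad_meta`` carries one row per
    modelled dyad series (group, members, covariates) so that per-draw
    linear predictors B_ijk can be reconstructed.
    """

    draws: dict[str, np.ndarray]
    groups: list[str]
    individuals: list[str]
    dyads: list[tuple[str, str]]
    covariate_names: list[str]
    dyad_meta: pd.DataFrame
    spec: ModelSpec

    @property
    def n_chains(self) -> int:
        return self.draws["alpha"].shape[0]

    @property
    def n_draws(self) -> int:
        """Total retained draws across chains."""
        return int(np.prod(self.draws["alpha"].shape[:2]))

    def flat(self, name: str) -> np.ndarray:
        """Draws pooled across chains: (n_draws,) or (n_draws, k)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def scalar_names(self) -> list[str]:
        return [k for k, v in self.draws.items() if v.ndim == 2]

    def dyad_linear_predictors(self, include_covariates: bool = True) -> np.ndarray:
        """Per-draw B_ijk (+ x'delta) for every modelled dyad series.

        Returns (n_draws, n_series) log-odds offsets relative to
        alpha + beta_last*y_prev.
        """
        meta = self.dyad_meta
        imap = {x: k for k, x in enumerate(self.individuals)}
        gmap = {x: k for k, x in enumerate(self.groups)}
        dmap = {x: k for k, x in enumerate(self.dyads)}
        gi = np.array([gmap[g] for g in meta["group"]])
        ii = np.array([imap[i] for i in meta["i"]])
        ji = np.array([imap[j] for j in meta["j"]])
        di = np.array([dmap[tuple(sorted(t))] for t in zip(meta["i"], meta["j"])])

        a = self.flat("a")[:, gi]
        b = self.flat("b")
        c = self.flat("c")[:, di]
        B = a + b[:, ii] + c
        if self.spec.directional:
            B = B + self.flat("d")[:, ji]
        else:
            B = B + b[:, ji]
        if include_covariates and self.covariate_names:
            X = np.empty((len(meta), len(self.covariate_names)))
            for k, name in enumerate(self.covariate_names):
                X[:, k] = [_covariate_value(row, name) for _, row in meta.iterrows()]
            delta = np.column_stack([self.flat(f"delta_{n}") for n in self.covariate_names])
            B = B + delta @ X.T
        return B

    def to_inference_data(self):
        """Convert to an ArviZ InferenceData for diagnostics/plotting."""
        import arviz as az

        data = {}
        for name, arr in self.draws.items():
            data[name] = arr
        return az.from_dict(posterior=data)


def _build_csr(idx: np.ndarray, n_sites: int, extra: np.ndarray | None = None):
    row_ids = np.arange(idx.shape[0], dtype=np.int64)
    if extra is not None:
        cat_idx = np.concatenate([idx, extra])
        cat_rows = np.concatenate([row_ids, row_ids])
    else:
        cat_idx = idx
        cat_rows = row_ids
    order = np.argsort(cat_idx, kind="stable")
    rows_sorted = cat_rows[order].astype(np.int64)
    counts = np.bincount(cat_idx, minlength=n_sites)
    indptr = np.zeros(n_sites + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, rows_sorted


def fit(table: DyadScanTable, spec: ModelSpec) -> PosteriorSample:
    """Sample the posterior by MCMC; deterministic under (seed, spec).

    Chains run sequentially with seeds derived from ``spec.seed``.
    """
    from dyadscan import _kernels

    prep = _prepare(table, spec)
    if len(prep.groups) < 2:
        warnings.warn(
            "fewer than 2 groups: sigma_group is informed by the prior only",
            stacklevel=2,
        )
    n_rows = len(prep.y)
    if n_rows == 0:
        # no likelihood rows: the chain samples the priors (exact for SDs)
        warnings.warn("empty dyad-scan table: posteriors reproduce the priors", stacklevel=2)
    n_cov = prep.X.shape[1]
    directional = bool(spec.directional)

    # Collapse rows to sufficient-statistic cells: within a dyad series the
    # linear predictor varies only with y_prev, so the likelihood depends on
    # the data only through per-(series, lag) trial and success counts.
    series_key = prep.i_idx * len(prep.individuals) + prep.j_idx
    cell_key = series_key * 2 + prep.y_prev.astype(np.int64)
    _, first_idx, inverse = np.unique(cell_key, return_index=True, return_inverse=True)
    cell_k = np.bincount(inverse, weights=prep.y).astype(np.float64)
    cell_n = np.bincount(inverse).astype(np.float64)
    cell_yprev = prep.y_prev[first_idx]
    g_idx = prep.g_idx[first_idx]
    i_idx = prep.i_idx[first_idx]
    j_idx = prep.j_idx[first_idx]
    dy_idx = prep.dy_idx[first_idx]
    X_cell = prep.X[first_idx]
    n_cells = cell_k.shape[0]

    cells_all = np.arange(n_cells, dtype=np.int64)
    cells_lag = np.flatnonzero(cell_yprev == 1.0).astype(np.int64)

    g_indptr, g_cells = _build_csr(g_idx, len(prep.groups))
    if directional:
        b_indptr, b_cells = _build_csr(i_idx, len(prep.individuals))
        d_indptr, d_cells = _build_csr(j_idx, len(prep.individuals))
    else:
        b_indptr, b_cells = _build_csr(i_idx, len(prep.individuals), extra=j_idx)
        d_indptr = np.zeros(1, dtype=np.int64)
        d_cells = np.zeros(0, dtype=np.int64)
    c_indptr, c_cells = _build_csr(dy_idx, len(prep.dyads))

    # covariate <-> dyad-effect translation moves need covariates that are
    # constant across a dyad's series (both grooming directions, both lag
    # states); direction-specific indicators are excluded
    trc_ok = np.zeros(max(n_cov, 1), dtype=np.bool_)
    trc_entries: list[list[tuple[int, float]]] = []
    for q in range(n_cov):
        per_dyad: dict[int, float] = {}
        constant = True
        for t in range(n_cells):
            dyv = int(dy_idx[t])
            xv = float(X_cell[t, q])
            if dyv in per_dyad:
                if per_dyad[dyv] != xv:
                    constant = False
                    break
            else:
                per_dyad[dyv] = xv
        entries = (
            [(dyv, xv) for dyv, xv in sorted(per_dyad.items()) if xv != 0.0]
            if constant
            else []
        )
        trc_ok[q] = bool(entries)
        trc_entries.append(entries)
    trc_indptr = np.zeros(max(n_cov, 1) + 1, dtype=np.int64)
    for q in range(n_cov):
        trc_indptr[q + 1] = trc_indptr[q] + len(trc_entries[q])
    trc_dy = np.array(
        [dyv for entries in trc_entries for dyv, _ in entries], dtype=np.int64
    )
    trc_x = np.array(
        [xv for entries in trc_entries for _, xv in entries], dtype=np.float64
    )

    # individual -> unordered-dyad membership (for b/c translation moves)
    imap = {x: k for k, x in enumerate(prep.individuals)}
    i2dy_lists: list[list[int]] = [[] for _ in prep.individuals]
    for s, (u, v) in enumerate(prep.dyads):
        i2dy_lists[imap[u]].append(s)
        i2dy_lists[imap[v]].append(s)
    i2dy_indptr = np.zeros(len(prep.individuals) + 1, dtype=np.int64)
    for k, lst in enumerate(i2dy_lists):
        i2dy_indptr[k + 1] = i2dy_indptr[k] + len(lst)
    i2dy_list = np.array([s for lst in i2dy_lists for s in lst], dtype=np.int64)

    # group -> unordered-dyad membership (for a/c translation moves)
    ind_group = {ind_id: None for ind_id in prep.individuals}
    for row in prep.dyad_meta.itertuples():
        ind_group[row.i] = row.group
        ind_group[row.j] = row.group
    gmap = {g: k for k, g in enumerate(prep.groups)}
    g2dy_lists: list[list[int]] = [[] for _ in prep.groups]
    for s, (u, v) in enumerate(prep.dyads):
        g2dy_lists[gmap[ind_group[u]]].append(s)
    g2dy_indptr = np.zeros(len(prep.groups) + 1, dtype=np.int64)
    for k, lst in enumerate(g2dy_lists):
        g2dy_indptr[k + 1] = g2dy_indptr[k] + len(lst)
    g2dy_list = np.array([s for lst in g2dy_lists for s in lst], dtype=np.int64)

    # signed-age translation (grooming): enabled when the standardized age
    # covariate decomposes exactly as atilde_i - atilde_j over node ages
    age_q = -1
    atilde = np.zeros(len(prep.individuals))
    if directional and "age_diff" in prep.covariate_names:
        q = prep.covariate_names.index("age_diff")
        ages = {ind.id: ind.age_years for ind in table.individuals}
        if all(x in ages for x in prep.individuals) and table.age_diff_sd > 0:
            cand = np.array([ages[x] / table.age_diff_sd for x in prep.individuals])
            recon = cand[i_idx] - cand[j_idx]
            if n_cells and np.max(np.abs(recon - X_cell[:, q])) < 1e-9:
                age_q = q
                atilde = cand

    # sex-class translations (grooming): need all three indicators plus a
    # consistent node-sex labelling that reproduces the indicator columns
    sex_mgf_q = sex_fgm_q = sex_mm_q = -1
    male_idx = np.zeros(0, dtype=np.int64)
    sex_names = {"male_grooms_female", "female_grooms_male", "male_male"}
    if directional and sex_names <= set(prep.covariate_names):
        sexes = {ind.id: ind.sex for ind in table.individuals}
        if all(x in sexes for x in prep.individuals):
            male = np.array([sexes[x] == "M" for x in prep.individuals])
            q_mgf = prep.covariate_names.index("male_grooms_female")
            q_fgm = prep.covariate_names.index("female_grooms_male")
            q_mm = prep.covariate_names.index("male_male")
            ok = (
                np.array_equal(X_cell[:, q_mgf], (male[i_idx] & ~male[j_idx]).astype(float))
                and np.array_equal(X_cell[:, q_fgm], (~male[i_idx] & male[j_idx]).astype(float))
                and np.array_equal(X_cell[:, q_mm], (male[i_idx] & male[j_idx]).astype(float))
            )
            if ok:
                sex_mgf_q, sex_fgm_q, sex_mm_q = q_mgf, q_fgm, q_mm
                male_idx = np.flatnonzero(male).astype(np.int64)

    n_keep = (spec.iterations - spec.warmup + spec.thinning - 1) // spec.thinning
    n_sigma = 4 if directional else 3
    n_scalar = 2 + n_cov + n_sigma

    chains_scalar = []
    chains_a, chains_b, chains_c, chains_d = [], [], [], []
    if n_rows:
        ybar = float(np.clip(prep.y.mean(), 1e-4, 1 - 1e-4))
        alpha_init = float(np.log(ybar / (1 - ybar)))
    else:
        alpha_init = 0.0

    for chain in range(spec.chains):
        seed_chain = int(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(chain,)).generate_state(1)[0]
            % (2**31 - 1)
        )
        rng = np.random.default_rng(seed_chain)
        a0 = rng.normal(0.0, 0.1, len(prep.groups))
        b0 = rng.normal(0.0, 0.1, len(prep.individuals))
        c0 = rng.normal(0.0, 0.1, len(prep.dyads))
        d0 = (
            rng.normal(0.0, 0.1, len(prep.individuals))
            if directional
            else np.zeros(1)
        )
        sig0 = np.full(4, 1.0) * np.exp(rng.normal(0.0, 0.1, 4))
        if not np.isfinite(alpha_init):
            raise FitError("non-finite initialization for alpha (degenerate outcomes)")

        out_scalar = np.empty((n_keep, n_scalar))
        out_a = np.empty((n_keep, len(prep.groups)))
        out_b = np.empty((n_keep, len(prep.individuals)))
        out_c = np.empty((n_keep, len(prep.dyads)))
        out_d = np.empty((n_keep, len(prep.individuals) if directional else 1))

        kept = _kernels.run_chain(
            cell_k,
            cell_n,
            cell_yprev,
            cells_all,
            cells_lag,
            X_cell,
            g_idx,
            i_idx,
            j_idx,
            dy_idx,
            g_indptr,
            g_cells,
            b_indptr,
            b_cells,
            d_indptr,
            d_cells,
            c_indptr,
            c_cells,
            trc_ok,
            trc_indptr,
            trc_dy,
            trc_x,
            i2dy_indptr,
            i2dy_list,
            g2dy_indptr,
            g2dy_list,
            age_q,
            atilde,
            sex_mgf_q,
            sex_fgm_q,
            sex_mm_q,
            male_idx,
            directional,
            alpha_init,
            0.0,
            np.zeros(max(n_cov, 1))[:n_cov],
            a0,
            b0,
            c0,
            d0,
            sig0,
            float(spec.prior_sd_fixed),
            float(spec.prior_sigma_upper),
            int(spec.iterations),
            int(spec.warmup),
            int(spec.thinning),
            seed_chain,
            out_scalar,
            out_a,
            out_b,
            out_c,
            out_d,
        )
        if kept != n_keep:
            raise FitError(f"chain {chain} retained {kept} draws, expected {n_keep}")
        chains_scalar.append(out_scalar)
        chains_a.append(out_a)
        chains_b.append(out_b)
        chains_c.append(out_c)
        chains_d.append(out_d)

    scal = np.stack(chains_scalar)  # (C, D, n_scalar)
    names = ["alpha", "beta_last"]
    names += [f"delta_{n}" for n in prep.covariate_names]
    names += ["sigma_group", "sigma_ind", "sigma_dyad"]
    if directional:
        names.append("sigma_rec")
    draws: dict[str, np.ndarray] = {name: scal[:, :, k] for k, name in enumerate(names)}
    draws["a"] = np.stack(chains_a)
    draws["b"] = np.stack(chains_b)
    draws["c"] = np.stack(chains_c)
    if directional:
        draws["d"] = np.stack(chains_d)

    return PosteriorSample(
        draws=draws,
        groups=prep.groups,
        individuals=prep.individuals,
        dyads=prep.dyads,
        covariate_names=prep.covariate_names,
        dyad_meta=prep.dyad_meta,
        spec=spec,
    )


def save_posterior(sample: PosteriorSample, out_dir) -> None:
    """Persist draws as a columnar CSV plus a JSON manifest naming every
    parameter column, and the dyad metadata needed to rebuild networks."""
    import dataclasses
    import json
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols: dict[str, np.ndarray] = {}
    C, D = sample.draws["alpha"].shape
    cols["chain"] = np.repeat(np.arange(C), D)
    cols["draw"] = np.tile(np.arange(D), C)
    manifest_cols: dict[str, str] = {}
    for name, arr in sample.draws.items():
        if arr.ndim == 2:
            cols[name] = arr.reshape(-1)
            manifest_cols[name] = "scalar"
        else:
            labels = {
                "a": sample.groups,
                "b": sample.individuals,
                "c": [f"{i}|{j}" for i, j in sample.dyads],
                "d": sample.individuals,
            }[name]
            for k, lab in enumerate(labels):
                col = f"{name}[{lab}]"
                cols[col] = arr[:, :, k].reshape(-1)
                manifest_cols[col] = name
    pd.DataFrame(cols).to_csv(out / "draws.csv", index=False)
    sample.dyad_meta.to_csv(out / "dyad_meta.csv", index=False)
    manifest = {
        "columns": manifest_cols,
        "groups": sample.groups,
        "individuals": sample.individuals,
        "dyads": [list(t) for t in sample.dyads],
        "covariate_names": sample.covariate_names,
        "spec": dataclasses.asdict(sample.spec),
    }
    with open(out / "posterior_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_posterior(in_dir) -> PosteriorSample:
    import json
    import pathlib

    src = pathlib.Path(in_dir)
    with open(src / "posterior_manifest.json") as fh:
        manifest = json.load(fh)
    df = pd.read_csv(src / "draws.csv")
    C = int(df["chain"].max()) + 1
    D = int(df["draw"].max()) + 1
    draws: dict[str, np.ndarray] = {}
    for col, kind in manifest["columns"].items():
        if kind == "scalar":
            draws[col] = df[col].to_numpy().reshape(C, D)
    for vec, labels in (
        ("a", manifest["groups"]),
        ("b", manifest["individuals"]),
        ("c", [f"{i}|{j}" for i, j in manifest["dyads"]]),
        ("d", manifest["individuals"]),
    ):
        cols = [f"{vec}[{lab}]" for lab in labels if f"{vec}[{lab}]" in df.columns]
        if cols:
            draws[vec] = np.stack(
                [df[c].to_numpy().reshape(C, D) for c in cols], axis=2
            )
    spec = ModelSpec(**manifest["spec"])
    return PosteriorSample(
        draws=draws,
        groups=manifest["groups"],
        individuals=manifest["individuals"],
        dyads=[tuple(t) for t in manifest["dyads"]],
        covariate_names=manifest["covariate_names"],
        dyad_meta=pd.read_csv(src / "dyad_meta.csv"),
        spec=spec,
    )


def diagnostics(sample: PosteriorSample, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split-R-hat and bulk ESS per scalar parameter (vector effects are
    diagnosed element-wise).  Requires at least 2 chains."""
    import arviz as az

    if sample.n_chains < 2:
        raise ValueError("diagnostics require chains >= 2; refit with more chains")
    rows = []
    for name, arr in sample.draws.items():
        if arr.ndim == 2:
            entries = {name: arr}
        else:
            entries = {f"{name}[{k}]": arr[:, :, k] for k in range(arr.shape[2])}
        for label, x in entries.items():
            rhat = float(az.rhat(x.astype(float)))
            ess = float(az.ess(x.astype(float)))
            rows.append((label, rhat, ess, rhat > rhat_threshold))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess_bulk", "flagged"])
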