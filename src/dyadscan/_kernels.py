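"""Numba kernels for the Metropolis-within-Gibbs sampler.

Likelihood representation
-------------------------
Within one dyad series (an unordered pair, or an ordered pair for
grooming) every scan row shares the same linear predictor except for the
lag term, which is 0 or 1.  The Bernoulli likelihood therefore depends on
the data only through, per series and lag state, the number of trials n
and successes k:

    sum_rows [ y*eta - log(1+e^eta) ]  =  sum_cells [ k*eta_cell - n*log(1+e^eta_cell) ]

The sampler operates on these "cells" (at most two per series), which
makes every sweep O(#series) instead of O(#scans) with an exactly equal
posterior (the collapse is algebraic, not an approximation; the day-reset
rule is inherited from the y_prev column).

Update types per iteration:

* adaptive random-walk Metropolis on each fixed effect;
* adaptive single-site random-walk Metropolis on each random-effect
  vector, with an exact prior draw for sites appearing in no cell;
* a gridded Gibbs draw for each SD given its effect vector (the
  conditional under a uniform prior is one-dimensional; it is normalized
  on a fine grid over (0, upper) and sampled with within-cell jitter);
* a non-centred rescaling move per effect vector (propose a new SD, scale
  the whole vector, accept on the likelihood) — the half of an
  interweaving strategy that keeps the sampler mobile when an SD is small
  and the centred conditional degenerates;
* translation moves shifting mass between the intercept and the mean of
  each random-effect vector along the likelihood ridge (likelihood
  invariant; only the priors decide), decorrelating the intercept from
  the random-effect means.

Proposal scales adapt during warmup only (Robbins-Monro toward standard
acceptance targets), so retained draws come from a fixed kernel.
"""

import numpy as np
from numba import njit

ACC_TARGET_SCALAR = 0.44
ACC_TARGET_OTHER = 0.3
SIGMA_GRID = 1024


@njit(cache=False)
def _log1pexp(x):
    if x > 35.0:
        return x
    if x < -35.0:
        return np.exp(x)
    return np.log1p(np.exp(x))


@njit(cache=False)
def _update_scalar_cells(eta, k, n, cells, val, prior_sd, scale):
    """RW update of a scalar whose unit change shifts eta by 1 on `cells`."""
    new = val + scale * np.random.normal()
    sh = new - val
    dl = 0.0
    for t in range(cells.shape[0]):
        r = cells[t]
        e = eta[r]
        dl += k[r] * sh - n[r] * (_log1pexp(e + sh) - _log1pexp(e))
    dl += (val * val - new * new) / (2.0 * prior_sd * prior_sd)
    if np.log(np.random.random()) < dl:
        for t in range(cells.shape[0]):
            eta[cells[t]] += sh
        return new, 1.0
    return val, 0.0


@njit(cache=False)
def _update_scalar_x(eta, k, n, xcol, val, prior_sd, scale):
    """RW update of a coefficient on per-cell covariate column `xcol`."""
    new = val + scale * np.random.normal()
    d = new - val
    dl = 0.0
    for r in range(eta.shape[0]):
        xv = xcol[r]
        if xv != 0.0:
            sh = d * xv
            e = eta[r]
            dl += k[r] * sh - n[r] * (_log1pexp(e + sh) - _log1pexp(e))
    dl += (val * val - new * new) / (2.0 * prior_sd * prior_sd)
    if np.log(np.random.random()) < dl:
        for r in range(eta.shape[0]):
            if xcol[r] != 0.0:
                eta[r] += d * xcol[r]
        return new, 1.0
    return val, 0.0


@njit(cache=False)
def _update_sites(eta, k, n, indptr, cells_cat, vals, prior_sd, scale):
    """Single-site RW updates over one random-effect vector (CSR cells)."""
    acc = 0.0
    K = vals.shape[0]
    if K == 0:
        return 1.0
    for s in range(K):
        start = indptr[s]
        end = indptr[s + 1]
        old = vals[s]
        if end == start:
            # no likelihood cells: conditional is the prior
            vals[s] = prior_sd * np.random.normal()
            acc += 1.0
            continue
        new = old + scale * np.random.normal()
        sh = new - old
        dl = 0.0
        for t in range(start, end):
            r = cells_cat[t]
            e = eta[r]
            dl += k[r] * sh - n[r] * (_log1pexp(e + sh) - _log1pexp(e))
        dl += (old * old - new * new) / (2.0 * prior_sd * prior_sd)
        if np.log(np.random.random()) < dl:
            vals[s] = new
            for t in range(start, end):
                eta[cells_cat[t]] += sh
            acc += 1.0
    return acc / K


@njit(cache=False)
def _sigma_gibbs(vals, upper):
    """Gibbs draw of an SD given its effects, uniform prior on (0, upper).

    The conditional density is proportional to
    sigma^-m * exp(-S / (2 sigma^2)) on (0, upper), m the number of
    effects and S their sum of squares.
    """
    m = vals.shape[0]
    if m == 0:
        return upper * np.random.random()
    S = 0.0
    for s in range(m):
        S += vals[s] * vals[s]
    if S <= 0.0:
        S = 1e-12
    w = np.empty(SIGMA_GRID)
    mx = -1e300
    for i in range(SIGMA_GRID):
        sig = (i + 0.5) * upper / SIGMA_GRID
        lp = -m * np.log(sig) - S / (2.0 * sig * sig)
        w[i] = lp
        if lp > mx:
            mx = lp
    tot = 0.0
    for i in range(SIGMA_GRID):
        w[i] = np.exp(w[i] - mx)
        tot += w[i]
    u = np.random.random() * tot
    csum = 0.0
    for i in range(SIGMA_GRID):
        csum += w[i]
        if csum >= u:
            return (i + np.random.random()) * upper / SIGMA_GRID
    return (SIGMA_GRID - 0.5) * upper / SIGMA_GRID


@njit(cache=False)
def _ncp_sigma_move(eta, k, n, vals, idx1, idx2, use2, sig, upper, scale):
    """Non-centred SD move: rescale sigma and the whole effect vector.

    In (sigma, theta/sigma) coordinates the effect prior does not involve
    sigma, so acceptance uses only the likelihood, the uniform prior
    support and the log-RW proposal Jacobian.
    """
    z = np.random.normal()
    sigp = sig * np.exp(scale * z)
    if sigp >= upper:
        return sig, 0.0
    ratio = sigp / sig
    dl = 0.0
    nc = eta.shape[0]
    for t in range(nc):
        sh = (ratio - 1.0) * vals[idx1[t]]
        if use2:
            sh += (ratio - 1.0) * vals[idx2[t]]
        e = eta[t]
        dl += k[t] * sh - n[t] * (_log1pexp(e + sh) - _log1pexp(e))
    dl += np.log(ratio)
    if np.log(np.random.random()) < dl:
        for t in range(nc):
            sh = (ratio - 1.0) * vals[idx1[t]]
            if use2:
                sh += (ratio - 1.0) * vals[idx2[t]]
            eta[t] += sh
        for s in range(vals.shape[0]):
            vals[s] *= ratio
        return sigp, 1.0
    return sig, 0.0


@njit(cache=False)
def _translation(alpha, vals, sig, mult, prior_sd_fixed, scale):
    """Shift intercept and one effect vector along the likelihood ridge.

    alpha' = alpha + mult * d, vals' = vals - d; each cell contains the
    effect `mult` times, so eta (hence the likelihood) is unchanged and
    only the priors enter the acceptance ratio.
    """
    d = scale * np.random.normal()
    K = vals.shape[0]
    S1 = 0.0
    for s in range(K):
        S1 += vals[s]
    new_alpha = alpha + mult * d
    lr = (alpha * alpha - new_alpha * new_alpha) / (2.0 * prior_sd_fixed * prior_sd_fixed)
    lr -= (-2.0 * d * S1 + K * d * d) / (2.0 * sig * sig)
    if np.log(np.random.random()) < lr:
        for s in range(K):
            vals[s] -= d
        return new_alpha, 1.0
    return alpha, 0.0


@njit(cache=False)
def _translation_bc(b, c, i2dy_indptr, i2dy_list, sig_i, sig_c, scale):
    """Per-individual shift between b_i and the dyad effects of i's pairs.

    For undirected behaviours each of i's series contains b_i + c_ij once,
    so b_i' = b_i + d with c_ij' = c_ij - d leaves eta unchanged; only the
    normal priors enter.  (Invalid for grooming, where c is shared by both
    directions while b is not.)
    """
    acc = 0.0
    K = b.shape[0]
    if K == 0:
        return 1.0
    for i in range(K):
        d = scale * np.random.normal()
        new_b = b[i] + d
        lr = (b[i] * b[i] - new_b * new_b) / (2.0 * sig_i * sig_i)
        for t in range(i2dy_indptr[i], i2dy_indptr[i + 1]):
            cs = c[i2dy_list[t]]
            lr += (cs * cs - (cs - d) * (cs - d)) / (2.0 * sig_c * sig_c)
        if np.log(np.random.random()) < lr:
            b[i] = new_b
            for t in range(i2dy_indptr[i], i2dy_indptr[i + 1]):
                c[i2dy_list[t]] -= d
            acc += 1.0
    return acc / K


@njit(cache=False)
def _translation_bdc(b, d_vec, c, i2dy_indptr, i2dy_list, sig_i, sig_r, sig_c, scale):
    """Grooming analogue of the individual/dyad translation.

    Outgoing series hold b_i + c_ij, incoming ones d_i + c_ij; shifting
    b_i and d_i by +d while shifting every c of i's dyads by -d leaves all
    etas unchanged.
    """
    acc = 0.0
    K = b.shape[0]
    if K == 0:
        return 1.0
    for i in range(K):
        d = scale * np.random.normal()
        nb = b[i] + d
        nd = d_vec[i] + d
        lr = (b[i] * b[i] - nb * nb) / (2.0 * sig_i * sig_i)
        lr += (d_vec[i] * d_vec[i] - nd * nd) / (2.0 * sig_r * sig_r)
        for t in range(i2dy_indptr[i], i2dy_indptr[i + 1]):
            cs = c[i2dy_list[t]]
            lr += (cs * cs - (cs - d) * (cs - d)) / (2.0 * sig_c * sig_c)
        if np.log(np.random.random()) < lr:
            b[i] = nb
            d_vec[i] = nd
            for t in range(i2dy_indptr[i], i2dy_indptr[i + 1]):
                c[i2dy_list[t]] -= d
            acc += 1.0
    return acc / K


@njit(cache=False)
def _translation_age(delta_q, b, d_vec, atilde, sig_i, sig_r, prior_sd_fixed, scale):
    """Shift the signed-age coefficient against groomer/recipient effects.

    When the standardized age covariate decomposes as x_ij = a~_i - a~_j,
    delta' = delta + d with b_i' = b_i - d * a~_i and d_j' = d_j + d * a~_j
    leaves every eta unchanged; only the normal priors enter.
    """
    d = scale * np.random.normal()
    new_delta = delta_q + d
    lr = (delta_q * delta_q - new_delta * new_delta) / (2.0 * prior_sd_fixed * prior_sd_fixed)
    for i in range(b.shape[0]):
        nb = b[i] - d * atilde[i]
        lr += (b[i] * b[i] - nb * nb) / (2.0 * sig_i * sig_i)
    for j in range(d_vec.shape[0]):
        nd = d_vec[j] + d * atilde[j]
        lr += (d_vec[j] * d_vec[j] - nd * nd) / (2.0 * sig_r * sig_r)
    if np.log(np.random.random()) < lr:
        for i in range(b.shape[0]):
            b[i] -= d * atilde[i]
        for j in range(d_vec.shape[0]):
            d_vec[j] += d * atilde[j]
        return new_delta, 1.0
    return delta_q, 0.0


@njit(cache=False)
def _translation_ac(a, c, g2dy_indptr, g2dy_list, sig_g, sig_c, scale):
    """Per-group shift between a_k and the dyad effects of group k.

    Every series in group k contains a_k + c once, so a_k' = a_k + d with
    c' = c - d over the group's dyads leaves eta unchanged.
    """
    acc = 0.0
    K = a.shape[0]
    if K == 0:
        return 1.0
    for k in range(K):
        d = scale * np.random.normal()
        na = a[k] + d
        lr = (a[k] * a[k] - na * na) / (2.0 * sig_g * sig_g)
        for t in range(g2dy_indptr[k], g2dy_indptr[k + 1]):
            cs = c[g2dy_list[t]]
            lr += (cs * cs - (cs - d) * (cs - d)) / (2.0 * sig_c * sig_c)
        if np.log(np.random.random()) < lr:
            a[k] = na
            for t in range(g2dy_indptr[k], g2dy_indptr[k + 1]):
                c[g2dy_list[t]] -= d
            acc += 1.0
    return acc / K


@njit(cache=False)
def _translation_sex(delta, q1, q2, vec, male_idx, sig, prior_sd_fixed, scale):
    """Shift one side's male effects against the sex-class coefficients.

    For grooming, a +s shift of b (or d) over all male nodes adds s exactly
    to the series where the groomer (or recipient) is male — the series
    counted by the direction indicator q1 plus the male-male indicator q2 —
    so subtracting s from both coefficients leaves every eta unchanged.
    """
    s = scale * np.random.normal()
    n1 = delta[q1] - s
    n2 = delta[q2] - s
    lr = (delta[q1] * delta[q1] - n1 * n1) / (2.0 * prior_sd_fixed * prior_sd_fixed)
    lr += (delta[q2] * delta[q2] - n2 * n2) / (2.0 * prior_sd_fixed * prior_sd_fixed)
    for t in range(male_idx.shape[0]):
        v = vec[male_idx[t]]
        lr += (v * v - (v + s) * (v + s)) / (2.0 * sig * sig)
    if np.log(np.random.random()) < lr:
        delta[q1] = n1
        delta[q2] = n2
        for t in range(male_idx.shape[0]):
            vec[male_idx[t]] += s
        return 1.0
    return 0.0


@njit(cache=False)
def _translation_cov(delta_q, c, dy_list, x_list, sig_c, prior_sd_fixed, scale):
    """Shift a pair-constant covariate coefficient against the dyad effects.

    delta' = delta + d and c_s' = c_s - d * x_s for every dyad s with
    nonzero covariate value leaves every cell's eta unchanged (the
    covariate is constant within each dyad's series), so only the priors
    enter.  This decorrelates sparse dyad-level covariates (e.g. maternal
    kinship) from the dyad random effects.
    """
    d = scale * np.random.normal()
    new_delta = delta_q + d
    lr = (delta_q * delta_q - new_delta * new_delta) / (2.0 * prior_sd_fixed * prior_sd_fixed)
    Sxc = 0.0
    Sxx = 0.0
    for t in range(dy_list.shape[0]):
        Sxc += c[dy_list[t]] * x_list[t]
        Sxx += x_list[t] * x_list[t]
    lr -= (-2.0 * d * Sxc + d * d * Sxx) / (2.0 * sig_c * sig_c)
    if np.log(np.random.random()) < lr:
        for t in range(dy_list.shape[0]):
            c[dy_list[t]] -= d * x_list[t]
        return new_delta, 1.0
    return delta_q, 0.0


@njit(cache=False)
def run_chain(
    cell_k,
    cell_n,
    cell_yprev,
    cells_all,
    cells_lag,
    X,
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
    alpha0,
    beta0,
    delta0,
    a0,
    b0,
    c0,
    d0,
    sig0,
    prior_sd_fixed,
    sigma_upper,
    n_iter,
    n_warmup,
    thin,
    seed,
    out_scalar,
    out_a,
    out_b,
    out_c,
    out_d,
):
    """Run one MCMC chain; fills the ``out_*`` arrays with retained draws.

    ``out_scalar`` columns: alpha, beta_last, delta..., sigma_group,
    sigma_ind, sigma_dyad, sigma_rec (if directional).
    """
    np.random.seed(seed)
    n_cells = cell_k.shape[0]
    n_cov = X.shape[1]

    alpha = alpha0
    beta = beta0
    delta = delta0.copy()
    a = a0.copy()
    b = b0.copy()
    c = c0.copy()
    d = d0.copy()
    sig_g, sig_i, sig_c, sig_r = sig0[0], sig0[1], sig0[2], sig0[3]

    eta = np.empty(n_cells)
    for r in range(n_cells):
        e = alpha + beta * cell_yprev[r] + a[g_idx[r]] + b[i_idx[r]] + c[dy_idx[r]]
        if directional:
            e += d[j_idx[r]]
        else:
            e += b[j_idx[r]]
        for q in range(n_cov):
            e += X[r, q] * delta[q]
        eta[r] = e

    # adaptive proposal scales (log-space Robbins-Monro during warmup)
    s_alpha, s_beta = 0.1, 0.2
    s_delta = np.full(n_cov, 0.3)
    s_a, s_b, s_c, s_d = 0.5, 0.5, 0.5, 0.5
    s_nc = np.full(4, 0.3)  # non-centred sigma moves: group, ind, dyad, rec
    s_tr = np.full(4, 0.3)  # translation moves
    s_trc = np.full(max(n_cov, 1), 0.3)  # covariate/dyad-effect translations
    s_bc = 0.3  # individual/dyad-effect translations
    s_ac = 0.3  # group/dyad-effect translations
    s_age = 0.3  # signed-age/node-effect translation (grooming)
    s_sex = np.full(2, 0.3)  # sex-class/node-effect translations (grooming)

    keep = 0
    for it in range(n_iter):
        gam = 1.0 / (1.0 + 0.2 * it) ** 0.7 if it < n_warmup else 0.0

        alpha, acc = _update_scalar_cells(
            eta, cell_k, cell_n, cells_all, alpha, prior_sd_fixed, s_alpha
        )
        s_alpha *= np.exp(gam * (acc - ACC_TARGET_SCALAR))
        beta, acc = _update_scalar_cells(
            eta, cell_k, cell_n, cells_lag, beta, prior_sd_fixed, s_beta
        )
        s_beta *= np.exp(gam * (acc - ACC_TARGET_SCALAR))
        for q in range(n_cov):
            delta[q], acc = _update_scalar_x(
                eta, cell_k, cell_n, X[:, q], delta[q], prior_sd_fixed, s_delta[q]
            )
            s_delta[q] *= np.exp(gam * (acc - ACC_TARGET_SCALAR))

        for _ in range(2):  # two site sweeps per iteration: cheap, halves
            # the autocorrelation of the random-effect components
            acc = _update_sites(eta, cell_k, cell_n, g_indptr, g_cells, a, sig_g, s_a)
            s_a *= np.exp(gam * (acc - ACC_TARGET_SCALAR))
            acc = _update_sites(eta, cell_k, cell_n, b_indptr, b_cells, b, sig_i, s_b)
            s_b *= np.exp(gam * (acc - ACC_TARGET_SCALAR))
            if directional:
                acc = _update_sites(eta, cell_k, cell_n, d_indptr, d_cells, d, sig_r, s_d)
                s_d *= np.exp(gam * (acc - ACC_TARGET_SCALAR))
            acc = _update_sites(eta, cell_k, cell_n, c_indptr, c_cells, c, sig_c, s_c)
            s_c *= np.exp(gam * (acc - ACC_TARGET_SCALAR))

        sig_g = _sigma_gibbs(a, sigma_upper)
        sig_i = _sigma_gibbs(b, sigma_upper)
        sig_c = _sigma_gibbs(c, sigma_upper)
        if directional:
            sig_r = _sigma_gibbs(d, sigma_upper)

        sig_g, acc = _ncp_sigma_move(
            eta, cell_k, cell_n, a, g_idx, g_idx, False, sig_g, sigma_upper, s_nc[0]
        )
        s_nc[0] *= np.exp(gam * (acc - ACC_TARGET_OTHER))
        if directional:
            sig_i, acc = _ncp_sigma_move(
                eta, cell_k, cell_n, b, i_idx, i_idx, False, sig_i, sigma_upper, s_nc[1]
            )
            s_nc[1] *= np.exp(gam * (acc - ACC_TARGET_OTHER))
            sig_r, acc = _ncp_sigma_move(
                eta, cell_k, cell_n, d, j_idx, j_idx, False, sig_r, sigma_upper, s_nc[3]
            )
            s_nc[3] *= np.exp(gam * (acc - ACC_TARGET_OTHER))
        else:
            sig_i, acc = _ncp_sigma_move(
                eta, cell_k, cell_n, b, i_idx, j_idx, True, sig_i, sigma_upper, s_nc[1]
            )
            s_nc[1] *= np.exp(gam * (acc - ACC_TARGET_OTHER))
        sig_c, acc = _ncp_sigma_move(
            eta, cell_k, cell_n, c, dy_idx, dy_idx, False, sig_c, sigma_upper, s_nc[2]
        )
        s_nc[2] *= np.exp(gam * (acc - ACC_TARGET_OTHER))

        alpha, acc = _translation(alpha, a, sig_g, 1.0, prior_sd_fixed, s_tr[0])
        s_tr[0] *= np.exp(gam * (acc - ACC_TARGET_OTHER))
        b_mult = 1.0 if directional else 2.0
        alpha, acc = _translation(alpha, b, sig_i, b_mult, prior_sd_fixed, s_tr[1])
        s_tr[1] *= np.exp(gam * (acc - ACC_TARGET_OTHER))
        if directional:
            alpha, acc = _translation(alpha, d, sig_r, 1.0, prior_sd_fixed, s_tr[3])
            s_tr[3] *= np.exp(gam * (acc - ACC_TARGET_OTHER))
        alpha, acc = _translation(alpha, c, sig_c, 1.0, prior_sd_fixed, s_tr[2])
        s_tr[2] *= np.exp(gam * (acc - ACC_TARGET_OTHER))
        for q in range(n_cov):
            if trc_ok[q]:
                delta[q], acc = _translation_cov(
                    delta[q], c, trc_dy[trc_indptr[q] : trc_indptr[q + 1]],
                    trc_x[trc_indptr[q] : trc_indptr[q + 1]],
                    sig_c, prior_sd_fixed, s_trc[q],
                )
                s_trc[q] *= np.exp(gam * (acc - ACC_TARGET_OTHER))
        if directional:
            acc = _translation_bdc(
                b, d, c, i2dy_indptr, i2dy_list, sig_i, sig_r, sig_c, s_bc
            )
            s_bc *= np.exp(gam * (acc - ACC_TARGET_SCALAR))
        else:
            acc = _translation_bc(b, c, i2dy_indptr, i2dy_list, sig_i, sig_c, s_bc)
            s_bc *= np.exp(gam * (acc - ACC_TARGET_SCALAR))
        acc = _translation_ac(a, c, g2dy_indptr, g2dy_list, sig_g, sig_c, s_ac)
        s_ac *= np.exp(gam * (acc - ACC_TARGET_SCALAR))
        if age_q >= 0:
            delta[age_q], acc = _translation_age(
                delta[age_q], b, d, atilde, sig_i, sig_r, prior_sd_fixed, s_age
            )
            s_age *= np.exp(gam * (acc - ACC_TARGET_OTHER))
        if sex_mm_q >= 0:
            acc = _translation_sex(
                delta, sex_mgf_q, sex_mm_q, b, male_idx, sig_i, prior_sd_fixed, s_sex[0]
            )
            s_sex[0] *= np.exp(gam * (acc - ACC_TARGET_OTHER))
            acc = _translation_sex(
                delta, sex_fgm_q, sex_mm_q, d, male_idx, sig_r, prior_sd_fixed, s_sex[1]
            )
            s_sex[1] *= np.exp(gam * (acc - ACC_TARGET_OTHER))

        if it >= n_warmup and (it - n_warmup) % thin == 0:
            out_scalar[keep, 0] = alpha
            out_scalar[keep, 1] = beta
            for q in range(n_cov):
                out_scalar[keep, 2 + q] = delta[q]
            out_scalar[keep, 2 + n_cov] = sig_g
            out_scalar[keep, 3 + n_cov] = sig_i
            out_scalar[keep, 4 + n_cov] = sig_c
            if directional:
                out_scalar[keep, 5 + n_cov] = sig_r
            out_a[keep] = a
            out_b[keep] = b
            out_c[keep] = c
            if directional:
                out_d[keep] = d
            keep += 1
    return keep
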