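"""Numba kernel for the two-component mixture Gibbs sampler.

Single-site sweep per cycle: overall mean (flat prior), each SNP's
(indicator, effect) pair jointly with the effect integrated out of the
indicator draw, polygenic values one at a time through the sparse
pedigree A-inverse, then the variance components and the mixture
proportion from their closed-form conditionals. The running residual is
updated by add-back/subtract bookkeeping; its drift against a from-
scratch recomputation is tracked every ``check_every`` cycles.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1


@njit(cache=True)
def _chi2(df):
    return 2.0 * np.random.gamma(0.5 * df, 1.0)


@njit(cache=True)
def _beta(a, b):
    x = np.random.gamma(a, 1.0)
    y = np.random.gamma(b, 1.0)
    return x / (x + y)


@njit(cache=True)
def gibbs_kernel(
    Xt,            # (m, n) centred genotypes, C-contiguous
    y,             # (n,)
    w,             # (n,) record weights; residual var sigma2_e / w_i
    c,             # (m,) sum_i w_i * Xt[j,i]^2
    indptr, indices, data,  # CSR of A^{-1} (ignored if not has_poly)
    has_poly,      # bool
    ratio,         # sigma2_g1 / sigma2_g0 (100)
    beta_a, beta_b,  # Beta prior on pi0 (small-effect probability)
    n_cycles, burn_in, thin,
    seed,
    s2g0_max,
    prior_only,
    check_every,
    # outputs, preallocated with T = (n_cycles - burn_in) // thin rows
    g_out, delta_out, u_out,
    mu_out, s2g0_out, pi0_out, s2u_out, s2e_out,
):
    np.random.seed(seed)
    m, n = Xt.shape
    sw = w.sum()
    ym = 0.0
    for i in range(n):
        ym += w[i] * y[i]
    ym /= sw
    vary = 0.0
    for i in range(n):
        vary += w[i] * (y[i] - ym) ** 2
    vary /= n
    if vary <= 0.0:
        vary = 1.0

    mu = ym
    g = np.zeros(m)
    delta = np.zeros(m, dtype=np.uint8)
    u = np.zeros(n)
    s2e = 0.5 * vary
    s2u = 0.25 * vary if has_poly else 1.0
    cbar = max(c.sum() / max(m, 1) / max(n, 1), 1e-12)
    s2g0 = vary / (m * cbar * 2.0) + 1e-12
    pi0 = beta_a / (beta_a + beta_b)

    r = np.empty(n)
    for i in range(n):
        r[i] = y[i] - mu

    df_g = max(m - 2, 1)
    df_n = max(n - 2, 1)
    save_idx = 0
    max_drift = 0.0
    bad_cycle = -1

    for t in range(n_cycles):
        if not prior_only:
            # overall mean, flat prior
            rhs = 0.0
            for i in range(n):
                rhs += w[i] * (r[i] + mu)
            mu_new = rhs / sw + np.random.standard_normal() * np.sqrt(s2e / sw)
            d_mu = mu - mu_new
            for i in range(n):
                r[i] += d_mu
            mu = mu_new

        # SNP effects: joint (delta_j, g_j), effect integrated out for delta
        v0 = s2g0
        v1 = ratio * s2g0
        log_prior_odds_large = np.log((1.0 - pi0) / pi0)
        m1_count = 0
        for j in range(m):
            gj = g[j]
            if prior_only:
                take_large = np.random.random() < (1.0 - pi0)
                if take_large:
                    g[j] = np.random.standard_normal() * np.sqrt(v1)
                    delta[j] = 1
                    m1_count += 1
                else:
                    g[j] = np.random.standard_normal() * np.sqrt(v0)
                    delta[j] = 0
                continue
            rhs = 0.0
            for i in range(n):
                x = Xt[j, i]
                rhs += w[i] * x * (r[i] + x * gj)
            cj = c[j]
            V0 = 1.0 / (cj / s2e + 1.0 / v0)
            V1 = 1.0 / (cj / s2e + 1.0 / v1)
            mean0 = V0 * rhs / s2e
            mean1 = V1 * rhs / s2e
            l0 = 0.5 * (np.log(V0 / v0) + mean0 * mean0 / V0)
            l1 = 0.5 * (np.log(V1 / v1) + mean1 * mean1 / V1)
            logit1 = (l1 - l0) + log_prior_odds_large
            p1 = 1.0 / (1.0 + np.exp(-logit1))
            if np.random.random() < p1:
                gnew = mean1 + np.random.standard_normal() * np.sqrt(V1)
                delta[j] = 1
                m1_count += 1
            else:
                gnew = mean0 + np.random.standard_normal() * np.sqrt(V0)
                delta[j] = 0
            diff = gj - gnew
            if diff != 0.0:
                for i in range(n):
                    r[i] += Xt[j, i] * diff
            g[j] = gnew

        # mixture proportion
        pi0 = _beta(beta_a + (m - m1_count), beta_b + m1_count)
        if pi0 <= 0.0:
            pi0 = 1e-12
        if pi0 >= 1.0:
            pi0 = 1.0 - 1e-12

        # common effect variance, flat prior with finite support bound
        S = 0.0
        for j in range(m):
            if delta[j] == 1:
                S += g[j] * g[j] / ratio
            else:
                S += g[j] * g[j]
        if S <= 0.0:
            S = 1e-30
        s2g0_new = S / _chi2(df_g)
        tries = 0
        while s2g0_new > s2g0_max and tries < 100:
            s2g0_new = S / _chi2(df_g)
            tries += 1
        if s2g0_new > s2g0_max:
            s2g0_new = s2g0_max
        s2g0 = s2g0_new

        if has_poly and not prior_only:
            # polygenic values, single-site with sparse A-inverse rows
            for i in range(n):
                aii = 0.0
                soff = 0.0
                for k in range(indptr[i], indptr[i + 1]):
                    col = indices[k]
                    if col == i:
                        aii = data[k]
                    else:
                        soff += data[k] * u[col]
                ri = r[i] + u[i]
                prec = w[i] / s2e + aii / s2u
                mean = (w[i] * ri / s2e - soff / s2u) / prec
                unew = mean + np.random.standard_normal() / np.sqrt(prec)
                r[i] = ri - unew
                u[i] = unew
            # polygenic variance: S_u = u' A^{-1} u
            Su = 0.0
            for i in range(n):
                row = 0.0
                for k in range(indptr[i], indptr[i + 1]):
                    row += data[k] * u[indices[k]]
                Su += u[i] * row
            if Su <= 0.0:
                Su = 1e-30
            s2u = Su / _chi2(df_n)

        if not prior_only:
            Se = 0.0
            for i in range(n):
                Se += w[i] * r[i] * r[i]
            if Se <= 0.0:
                Se = 1e-30
            s2e = Se / _chi2(df_n)

        if not (np.isfinite(s2e) and np.isfinite(s2u) and np.isfinite(s2g0)):
            bad_cycle = t
            return STATUS_NONFINITE, bad_cycle, max_drift

        if (not prior_only) and check_every > 0 and (t + 1) % check_every == 0:
            # recompute residual from scratch
            drift = 0.0
            rec = np.empty(n)
            for i in range(n):
                rec[i] = y[i] - mu - u[i]
            for j in range(m):
                gj = g[j]
                if gj != 0.0:
                    for i in range(n):
                        rec[i] -= Xt[j, i] * gj
            for i in range(n):
                d = abs(rec[i] - r[i])
                if d > drift:
                    drift = d
            if drift > max_drift:
                max_drift = drift

        if t >= burn_in and (t - burn_in + 1) % thin == 0:
            if save_idx < g_out.shape[0]:
                for j in range(m):
                    g_out[save_idx, j] = g[j]
                    delta_out[save_idx, j] = delta[j]
                for i in range(n):
                    u_out[save_idx, i] = u[i]
                mu_out[save_idx] = mu
                s2g0_out[save_idx] = s2g0
                pi0_out[save_idx] = pi0
                s2u_out[save_idx] = s2u
                s2e_out[save_idx] = s2e
                save_idx += 1

    return STATUS_OK, bad_cycle, max_drift
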