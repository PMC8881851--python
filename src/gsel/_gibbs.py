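"""Numba Gibbs-sampling kernels for the Bayesian whole-genome regressions.

One compiled chain runner covers the five sampler families; the family code
selects the marker-effect prior:

====  ==============  ===================================================
code  family          marker prior
====  ==============  ===================================================
0     brr             alpha_j ~ N(0, s2a), common variance
1     bayesA          alpha_j ~ N(0, s2_j), per-marker scaled-inv-chi2
2     bayesB          spike-and-slab, slab with per-marker variance, P(in)=pi
3     bayesC          spike-and-slab, common slab variance, P(in)=pi
4     bayesian_lasso  alpha_j ~ N(0, s2e*tau2_j), tau2_j ~ Exp(lam2/2)
====  ==============  ===================================================

Scaled-inverse-chi-square draws use sigma2 = (nu*S2 + SS) / chi2_{nu + k}.
The model is y = mu + Z alpha + e with Z the centred dosage block.
"""

from __future__ import annotations

import numpy as np
from numba import njit

FAM_BRR = 0
FAM_BAYESA = 1
FAM_BAYESB = 2
FAM_BAYESC = 3
FAM_BL = 4


@njit(cache=False)
def gibbs_chain(
    Z,
    y,
    family,
    pi,
    nu,
    S2_a,
    nu_e,
    S2_e,
    n_iter,
    burn_in,
    thin,
    seed,
    fix_variances,
    sigma2_a_fix,
    sigma2_e_fix,
):
    np.random.seed(seed)
    n, m = Z.shape
    zjz = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        zjz[j] = s

    alpha = np.zeros(m)
    incl = np.ones(m)
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    e = y - mu

    sigma2e = sigma2_e_fix if fix_variances else S2_e
    sig2 = np.full(m, S2_a)  # per-marker slab variance (bayesA / bayesB)
    sig2a = S2_a  # common slab variance (brr / bayesC)
    if fix_variances:
        sigma2e = sigma2_e_fix
        sig2a = sigma2_a_fix
        for j in range(m):
            sig2[j] = sigma2_a_fix
    tau2 = np.ones(m)
    lam2 = 1.0
    log_pi_ratio = np.log(pi / (1.0 - pi)) if pi < 1.0 else 1e30

    n_saved = 0
    alpha_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    max_keep = (n_iter - burn_in + thin - 1) // thin
    sigma2e_chain = np.empty(max_keep)
    sig2a_chain = np.empty(max_keep)

    for it in range(n_iter):
        # intercept
        e += mu
        ebar = 0.0
        for i in range(n):
            ebar += e[i]
        ebar /= n
        mu = ebar + np.random.standard_normal() * np.sqrt(sigma2e / n)
        e -= mu

        # marker sweep
        for j in range(m):
            cj = zjz[j]
            if cj <= 0.0:
                alpha[j] = 0.0
                continue
            rj = alpha[j] * cj
            for i in range(n):
                rj += Z[i, j] * e[i]
            old = alpha[j]

            if family == FAM_BRR:
                vprior = sig2a
            elif family == FAM_BAYESA:
                vprior = sig2[j]
            elif family == FAM_BAYESB:
                vprior = sig2[j]
            elif family == FAM_BAYESC:
                vprior = sig2a
            else:  # bayesian lasso
                vprior = sigma2e * tau2[j]

            draw_in = True
            if family == FAM_BAYESB or family == FAM_BAYESC:
                if pi < 1.0:
                    v0 = cj * sigma2e
                    v1 = cj * cj * vprior + cj * sigma2e
                    log_bf = 0.5 * (
                        np.log(v0) - np.log(v1) + rj * rj * (1.0 / v0 - 1.0 / v1)
                    )
                    logit = log_pi_ratio + log_bf
                    if logit > 35.0:
                        p_in = 1.0
                    elif logit < -35.0:
                        p_in = 0.0
                    else:
                        p_in = 1.0 / (1.0 + np.exp(-logit))
                    draw_in = np.random.random_sample() < p_in
                incl[j] = 1.0 if draw_in else 0.0

            if draw_in:
                prec = cj / sigma2e + 1.0 / vprior
                mean = (rj / sigma2e) / prec
                alpha[j] = mean + np.random.standard_normal() / np.sqrt(prec)
            else:
                alpha[j] = 0.0
            # residual update
            diff = old - alpha[j]
            if diff != 0.0:
                for i in range(n):
                    e[i] += Z[i, j] * diff

        # variance updates
        if not fix_variances:
            if family == FAM_BRR:
                ss = 0.0
                for j in range(m):
                    ss += alpha[j] * alpha[j]
                sig2a = (nu * S2_a + ss) / np.random.chisquare(nu + m)
            elif family == FAM_BAYESA:
                for j in range(m):
                    sig2[j] = (nu * S2_a + alpha[j] * alpha[j]) / np.random.chisquare(
                        nu + 1.0
                    )
            elif family == FAM_BAYESB:
                for j in range(m):
                    if incl[j] > 0.5:
                        sig2[j] = (
                            nu * S2_a + alpha[j] * alpha[j]
                        ) / np.random.chisquare(nu + 1.0)
                    else:
                        sig2[j] = nu * S2_a / np.random.chisquare(nu)
            elif family == FAM_BAYESC:
                ss = 0.0
                kin = 0.0
                for j in range(m):
                    if incl[j] > 0.5:
                        ss += alpha[j] * alpha[j]
                        kin += 1.0
                sig2a = (nu * S2_a + ss) / np.random.chisquare(nu + kin)
            else:  # bayesian lasso: tau2 and lambda2
                sumtau = 0.0
                for j in range(m):
                    aj2 = alpha[j] * alpha[j]
                    if aj2 < 1e-12:
                        aj2 = 1e-12
                    mu_ig = np.sqrt(lam2 * sigma2e / aj2)
                    inv_tau = np.random.wald(mu_ig, lam2)
                    tau2[j] = 1.0 / inv_tau
                    sumtau += tau2[j]
                lam2 = np.random.gamma(1.0 + m, 1.0 / (1.0 + 0.5 * sumtau))

            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            if family == FAM_BL:
                # lasso scale mixture puts sigma2e in the effect prior too
                for j in range(m):
                    sse += alpha[j] * alpha[j] / tau2[j]
                sigma2e = (nu_e * S2_e + sse) / np.random.chisquare(nu_e + n + m)
            else:
                sigma2e = (nu_e * S2_e + sse) / np.random.chisquare(nu_e + n)

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(m):
                alpha_sum[j] += alpha[j]
                incl_sum[j] += incl[j]
            mu_sum += mu
            sigma2e_chain[n_saved] = sigma2e
            if family == FAM_BAYESA or family == FAM_BAYESB:
                sbar = 0.0
                for j in range(m):
                    sbar += sig2[j]
                sig2a_chain[n_saved] = sbar / m
            elif family == FAM_BL:
                tbar = 0.0
                for j in range(m):
                    tbar += tau2[j]
                sig2a_chain[n_saved] = sigma2e * tbar / m
            else:
                sig2a_chain[n_saved] = sig2a
            n_saved += 1

    alpha_mean = alpha_sum / n_saved
    incl_mean = incl_sum / n_saved
    mu_mean = mu_sum / n_saved
    return (
        alpha_mean,
        mu_mean,
        incl_mean,
        sigma2e_chain[:n_saved],
        sig2a_chain[:n_saved],
    )
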