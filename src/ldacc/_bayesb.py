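"""Numba kernel for the BayesB Gibbs/Metropolis-Hastings sampler.

State per locus k: inclusion indicator delta_k, effect beta_k and locus
variance sig2b_k.  Each iteration sweeps:

* intercept alpha — Gibbs under a flat prior;
* for every locus, a Metropolis-Hastings move proposing (delta*, sig2b*)
  from the prior (delta* ~ Bernoulli(pi), sig2b* ~ scaled-inv-chi2), accepted
  on the residual marginal likelihood with beta_k integrated out, followed
  by a Gibbs draw of beta_k when the locus is in the model;
* residual variance sigma2_e — Gibbs from its scaled-inv-chi2 conditional.

Residuals are weighted: Var(e_i) = sigma2_e / w_i.  With the prior
proposal, prior and proposal densities cancel and the acceptance ratio is
the marginal-likelihood ratio alone.  Setting ``fixed_var >= 0`` pins every
locus variance to that value (no variance proposals), which at pi = 1
reduces the sampler to a weighted Bayesian ridge whose posterior mean is
the closed-form RR-BLUP solution — the oracle used to validate the kernel.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _scaled_inv_chi2(nu, scale):
    return nu * scale / np.random.chisquare(nu)


@njit(cache=True)
def _marginal_loglik_ratio(rhs, v0, sig2b, sigma2_e):
    """log L(delta=1, sig2b) - log L(delta=0) with beta integrated out.

    rhs = x' W e_k (weighted, residual excluding locus k), v0 = x' W x,
    both with W = diag(w) (sigma2_e factored out)."""
    a = 1.0 + sig2b * v0 / sigma2_e
    return -0.5 * np.log(a) + 0.5 * sig2b * rhs * rhs / (sigma2_e * sigma2_e * a)


@njit(cache=True)
def bayesb_chain(
    X,            # (n, K) float64 dosage matrix
    y,            # (n,) phenotypes
    w,            # (n,) reliability weights in (0, 1]
    pi,
    nu_e, s2_e,   # residual prior df and scale
    nu_b, s2_b,   # locus-variance prior df and scale
    fixed_var,    # >= 0: pin locus variances to this value; < 0: sample
    n_iter, burn_in, thin, seed,
):
    np.random.seed(seed)
    n, K = X.shape
    Xw = np.empty_like(X)
    v0 = np.empty(K)
    for k in range(K):
        s = 0.0
        for i in range(n):
            Xw[i, k] = X[i, k] * w[i]
            s += X[i, k] * Xw[i, k]
        v0[k] = s

    sw = w.sum()
    alpha = 0.0
    for i in range(n):
        alpha += w[i] * y[i]
    alpha /= sw

    delta = np.zeros(K, dtype=np.int8)
    beta = np.zeros(K)
    sig2b = np.empty(K)
    for k in range(K):
        sig2b[k] = fixed_var if fixed_var >= 0.0 else _scaled_inv_chi2(nu_b, s2_b)
    sigma2_e = nu_e * s2_e / max(nu_e - 2.0, 0.5)

    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - alpha

    n_keep = 0
    beta_sum = np.zeros(K)
    incl_sum = np.zeros(K)
    alpha_sum = 0.0
    sig2e_sum = 0.0
    n_trace = (n_iter - burn_in + thin - 1) // thin
    trace_alpha = np.zeros(n_trace)
    trace_sig2e = np.zeros(n_trace)
    trace_nincl = np.zeros(n_trace)
    accept = 0.0
    t = 0

    for it in range(n_iter):
        # ---- intercept (flat prior)
        num = 0.0
        for i in range(n):
            num += w[i] * (e[i] + alpha)
        new_alpha = num / sw + np.random.normal() * np.sqrt(sigma2_e / sw)
        for i in range(n):
            e[i] += alpha - new_alpha
        alpha = new_alpha

        # ---- loci
        for k in range(K):
            # residual excluding locus k
            if delta[k] == 1 and beta[k] != 0.0:
                for i in range(n):
                    e[i] += X[i, k] * beta[k]
            rhs = 0.0
            for i in range(n):
                rhs += Xw[i, k] * e[i]

            # MH proposal from the prior
            d_new = 1 if np.random.random() < pi else 0
            if d_new == 1:
                s2_new = fixed_var if fixed_var >= 0.0 else _scaled_inv_chi2(nu_b, s2_b)
            else:
                s2_new = sig2b[k]
            ll_old = 0.0
            if delta[k] == 1:
                ll_old = _marginal_loglik_ratio(rhs, v0[k], sig2b[k], sigma2_e)
            ll_new = 0.0
            if d_new == 1:
                ll_new = _marginal_loglik_ratio(rhs, v0[k], s2_new, sigma2_e)
            if np.log(np.random.random() + 1e-300) < ll_new - ll_old:
                delta[k] = d_new
                if d_new == 1:
                    sig2b[k] = s2_new
                accept += 1.0

            if delta[k] == 1:
                prec = v0[k] / sigma2_e + 1.0 / sig2b[k]
                mean = rhs / sigma2_e / prec
                beta[k] = mean + np.random.normal() / np.sqrt(prec)
                for i in range(n):
                    e[i] -= X[i, k] * beta[k]
            else:
                beta[k] = 0.0

        # ---- residual variance
        sse = 0.0
        for i in range(n):
            sse += w[i] * e[i] * e[i]
        sigma2_e = (nu_e * s2_e + sse) / np.random.chisquare(nu_e + n)

        if it >= burn_in:
            n_keep += 1
            alpha_sum += alpha
            sig2e_sum += sigma2_e
            for k in range(K):
                if delta[k] == 1:
                    beta_sum[k] += beta[k]
                    incl_sum[k] += 1.0
            if (it - burn_in) % thin == 0:
                trace_alpha[t] = alpha
                trace_sig2e[t] = sigma2_e
                trace_nincl[t] = delta.sum()
                t += 1

    return (
        alpha_sum / n_keep,
        beta_sum / n_keep,
        incl_sum / n_keep,
        sig2e_sum / n_keep,
        trace_alpha[:t],
        trace_sig2e[:t],
        trace_nincl[:t],
        accept / (n_iter * K),
    )
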