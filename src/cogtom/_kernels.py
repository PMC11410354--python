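"""Numba kernels for the hot loops of filtering and sampling.

Everything here is deterministic given its inputs; all randomness is drawn
outside (from a numpy Generator) and passed in as arrays, so runs are
reproducible from a single seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@njit(cache=True)
def _norm_logpdf(z):
    return -0.5 * z * z - _LOG_SQRT_2PI


@njit(cache=True)
def _norm_cdf(z):
    return 0.5 * (1.0 + math.erf(z / _SQRT2))


@njit(cache=True)
def forward_filter_kernel(initial, trans, emis, y, floor):
    """HMM forward filtering with one-step-ahead predictive probabilities.

    Returns (probs, realized, loglik, n_floored): probs[t] is the exact
    predictive distribution over the 4 stimuli before observing y[t];
    realized[t] = max(probs[t, y[t]], floor).  The filtered posterior is
    renormalised each step; a zero-likelihood observation is recovered by
    flooring the emission column for that step only.
    """
    T = y.shape[0]
    K = emis.shape[0]
    M = emis.shape[1]
    probs = np.zeros((T, M))
    realized = np.zeros(T)
    filt = np.zeros(K)
    q = np.zeros(K)
    loglik = 0.0
    n_floored = 0
    for t in range(T):
        if t == 0:
            for k in range(K):
                q[k] = initial[k]
        else:
            for k in range(K):
                acc = 0.0
                for j in range(K):
                    acc += filt[j] * trans[j, k]
                q[k] = acc
        for c in range(M):
            acc = 0.0
            for k in range(K):
                acc += q[k] * emis[k, c]
            probs[t, c] = acc
        p = probs[t, y[t]]
        if p < floor:
            p = floor
            n_floored += 1
        realized[t] = p
        loglik += math.log(p)
        c_t = 0.0
        for k in range(K):
            filt[k] = q[k] * emis[k, y[t]]
            c_t += filt[k]
        if c_t <= 0.0:
            c_t = 0.0
            for k in range(K):
                e = emis[k, y[t]]
                if e < floor:
                    e = floor
                filt[k] = q[k] * e
                c_t += filt[k]
        for k in range(K):
            filt[k] /= c_t
    return probs, realized, loglik, n_floored


@njit(cache=True)
def rt_loglik_grad_hmm(initial, trans, emis, y, rt, mask, mu, sigma, theta0,
                       pfloor):
    """LATER RT log likelihood under HMM-filtered predictive probabilities,
    with its gradient w.r.t. the transition matrix, the emission matrix and
    the LATER parameters.

    The realized predictive probability p_t equals the per-step
    normalisation constant of the filter; gradients are obtained by
    reverse-mode accumulation through the filtering recursion.  Floored
    p_t contribute zero gradient through p.
    """
    T = y.shape[0]
    K = emis.shape[0]
    q_arr = np.zeros((T, K))
    filt_arr = np.zeros((T, K))
    c_arr = np.zeros(T)
    g_p = np.zeros(T)
    d_emis = np.zeros_like(emis)
    d_trans = np.zeros_like(trans)
    ll = 0.0
    dmu = 0.0
    dsigma = 0.0
    dtheta0 = 0.0
    zcdf = _norm_cdf(mu / sigma)
    if zcdf < 1e-300:
        zcdf = 1e-300
    log_trunc = math.log(zcdf)
    phi_over_Phi = math.exp(_norm_logpdf(mu / sigma)) / zcdf

    for t in range(T):
        if t == 0:
            for k in range(K):
                q_arr[t, k] = initial[k]
        else:
            for k in range(K):
                acc = 0.0
                for j in range(K):
                    acc += filt_arr[t - 1, j] * trans[j, k]
                q_arr[t, k] = acc
        c_t = 0.0
        for k in range(K):
            filt_arr[t, k] = q_arr[t, k] * emis[k, y[t]]
            c_t += filt_arr[t, k]
        floored = False
        p = c_t
        if p < pfloor:
            p = pfloor
            floored = True
        if c_t <= 0.0:
            # degenerate step: recover with floored emission column
            c_t = 0.0
            for k in range(K):
                e = emis[k, y[t]]
                if e < pfloor:
                    e = pfloor
                filt_arr[t, k] = q_arr[t, k] * e
                c_t += filt_arr[t, k]
        for k in range(K):
            filt_arr[t, k] /= c_t
        c_arr[t] = c_t
        if mask[t]:
            x = theta0 - math.log(p)
            r = x / rt[t]
            z = (r - mu) / sigma
            ll += (-math.log(sigma) - 0.5 * z * z - log_trunc
                   + math.log(x) - 2.0 * math.log(rt[t]))
            dmu += z / sigma - phi_over_Phi / sigma
            dsigma += -1.0 / sigma + z * z / sigma + phi_over_Phi * mu / (sigma * sigma)
            dldx = -z / (sigma * rt[t]) + 1.0 / x
            dtheta0 += dldx
            if not floored:
                g_p[t] = -dldx / p

    # reverse pass
    bar_filt = np.zeros(K)
    bar_q = np.zeros(K)
    for t in range(T - 1, -1, -1):
        dot = 0.0
        for k in range(K):
            dot += bar_filt[k] * filt_arr[t, k]
        c_t = c_arr[t]
        for k in range(K):
            bar_a = (bar_filt[k] - dot) / c_t + g_p[t]
            e = emis[k, y[t]]
            bar_q[k] = bar_a * e
            d_emis[k, y[t]] += bar_a * q_arr[t, k]
        if t > 0:
            for j in range(K):
                acc = 0.0
                fprev = filt_arr[t - 1, j]
                for k in range(K):
                    acc += trans[j, k] * bar_q[k]
                    d_trans[j, k] += fprev * bar_q[k]
                bar_filt[j] = acc
    return ll, d_trans, d_emis, dmu, dsigma, dtheta0


@njit(cache=True)
def rt_loglik_grad_markov(M_mat, init_marginal, y, rt, mask, mu, sigma, theta0,
                          pfloor):
    """As :func:`rt_loglik_grad_hmm` for the first-order Markov predictor:
    p_n = M[y_{n-1}, y_n]; the first trial uses the initial marginal."""
    T = y.shape[0]
    dM = np.zeros_like(M_mat)
    ll = 0.0
    dmu = 0.0
    dsigma = 0.0
    dtheta0 = 0.0
    zcdf = _norm_cdf(mu / sigma)
    if zcdf < 1e-300:
        zcdf = 1e-300
    log_trunc = math.log(zcdf)
    phi_over_Phi = math.exp(_norm_logpdf(mu / sigma)) / zcdf
    for t in range(T):
        if not mask[t]:
            continue
        if t == 0:
            p = init_marginal[y[t]]
            grad_entry = False
        else:
            p = M_mat[y[t - 1], y[t]]
            grad_entry = True
        floored = False
        if p < pfloor:
            p = pfloor
            floored = True
        x = theta0 - math.log(p)
        r = x / rt[t]
        z = (r - mu) / sigma
        ll += (-math.log(sigma) - 0.5 * z * z - log_trunc
               + math.log(x) - 2.0 * math.log(rt[t]))
        dmu += z / sigma - phi_over_Phi / sigma
        dsigma += -1.0 / sigma + z * z / sigma + phi_over_Phi * mu / (sigma * sigma)
        dldx = -z / (sigma * rt[t]) + 1.0 / x
        dtheta0 += dldx
        if grad_entry and not floored:
            dM[y[t - 1], y[t]] += -dldx / p
    return ll, dM, dmu, dsigma, dtheta0


@njit(cache=True)
def beam_ffbs(pi0, pi, emis, y, u, rand_backward):
    """Forward filter / backward sample over the slice-truncated state set.

    pi0 : (K,) initial state probabilities (represented states)
    pi : (K, K) represented-block transition probabilities
    u : (T,) slice variables; transitions with pi <= u are cut
    rand_backward : (T,) uniforms for the backward draws

    Returns (path, ok).  ok=False signals an empty candidate set at some
    step (caller redraws slice variables).
    """
    T = y.shape[0]
    K = pi.shape[0]
    f = np.zeros((T, K))
    s_out = np.zeros(T, dtype=np.int64)
    tot = 0.0
    for k in range(K):
        if pi0[k] > u[0]:
            f[0, k] = emis[k, y[0]]
            tot += f[0, k]
    if tot <= 0.0:
        return s_out, False
    for k in range(K):
        f[0, k] /= tot
    for t in range(1, T):
        tot = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                if pi[j, k] > u[t]:
                    acc += f[t - 1, j]
            val = emis[k, y[t]] * acc
            f[t, k] = val
            tot += val
        if tot <= 0.0:
            return s_out, False
        for k in range(K):
            f[t, k] /= tot
    # backward sampling
    r = rand_backward[T - 1]
    acc = 0.0
    s = K - 1
    for k in range(K):
        acc += f[T - 1, k]
        if r <= acc:
            s = k
            break
    s_out[T - 1] = s
    for t in range(T - 2, -1, -1):
        tot = 0.0
        for j in range(K):
            if pi[j, s_out[t + 1]] > u[t + 1]:
                tot += f[t, j]
        if tot <= 0.0:
            return s_out, False
        r = rand_backward[t] * tot
        acc = 0.0
        s = 0
        for j in range(K):
            if pi[j, s_out[t + 1]] > u[t + 1]:
                acc += f[t, j]
                if r <= acc:
                    s = j
                    break
        s_out[t] = s
    return s_out, True


@njit(cache=True)
def path_counts(s, y, K, n_obs):
    """Transition and emission counts along a sampled state path."""
    trans_counts = np.zeros((K, K), dtype=np.int64)
    emis_counts = np.zeros((K, n_obs), dtype=np.int64)
    T = s.shape[0]
    emis_counts[s[0], y[0]] += 1
    for t in range(1, T):
        trans_counts[s[t - 1], s[t]] += 1
        emis_counts[s[t], y[t]] += 1
    return trans_counts, emis_counts
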