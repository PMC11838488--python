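"""Numerical kernels for the batch two-state Gaussian HMM.

One forward-backward pass (scaled) returns, per trace, the log-likelihood
and the EM sufficient statistics; Viterbi returns the decoded path.  The
kernels are compiled with numba when available (the loops over frames
dominate the pipeline's runtime); a vectorized numpy implementation with
identical semantics is the fallback.
"""

from __future__ import annotations

import math

import numpy as np

_Z2_CLIP = 600.0  # caps the emission exponent so likelihoods never hit exact zero


def _fb_pass_numpy(X, mu, sigma, A, pi):
    n, T = X.shape
    z0 = (X - mu[:, 0:1]) / sigma[:, None]
    z1 = (X - mu[:, 1:2]) / sigma[:, None]
    b0 = np.exp(-np.clip(0.5 * z0 * z0, None, _Z2_CLIP)).T  # (T, n)
    b1 = np.exp(-np.clip(0.5 * z1 * z1, None, _Z2_CLIP)).T
    a00, a01 = A[:, 0, 0], A[:, 0, 1]
    a10, a11 = A[:, 1, 0], A[:, 1, 1]
    alphas = np.empty((T, n, 2))
    c = np.empty((T, n))
    f0 = pi[:, 0] * b0[0]
    f1 = pi[:, 1] * b1[0]
    s = f0 + f1
    bad = s <= 0
    if bad.any():
        f0 = np.where(bad, 0.5, f0)
        f1 = np.where(bad, 0.5, f1)
        s = np.where(bad, 1.0, s)
    c[0] = s
    alphas[0, :, 0], alphas[0, :, 1] = f0 / s, f1 / s
    for t in range(1, T):
        f0, f1 = alphas[t - 1, :, 0], alphas[t - 1, :, 1]
        g0 = (f0 * a00 + f1 * a10) * b0[t]
        g1 = (f0 * a01 + f1 * a11) * b1[t]
        s = g0 + g1
        bad = s <= 0
        if bad.any():
            g0 = np.where(bad, 0.5, g0)
            g1 = np.where(bad, 0.5, g1)
            s = np.where(bad, 1.0, s)
        c[t] = s
        alphas[t, :, 0], alphas[t, :, 1] = g0 / s, g1 / s
    ll = np.log(np.maximum(c, 1e-300)).sum(axis=0)

    xt = X.T
    e = np.zeros((n, 2))
    m = np.zeros((n, 2))
    v = np.zeros((n, 2))
    xi = np.zeros((n, 2, 2))
    g0v = alphas[T - 1, :, 0]
    g1v = alphas[T - 1, :, 1]
    e[:, 0] += g0v
    e[:, 1] += g1v
    m[:, 0] += g0v * xt[T - 1]
    m[:, 1] += g1v * xt[T - 1]
    v[:, 0] += g0v * (xt[T - 1] - mu[:, 0]) ** 2
    v[:, 1] += g1v * (xt[T - 1] - mu[:, 1]) ** 2
    bt0 = np.ones(n)
    bt1 = np.ones(n)
    gamma0 = np.stack([g0v, g1v], axis=1)
    for t in range(T - 2, -1, -1):
        w0 = b0[t + 1] * bt0 / c[t + 1]
        w1 = b1[t + 1] * bt1 / c[t + 1]
        f0 = alphas[t, :, 0]
        f1 = alphas[t, :, 1]
        xi[:, 0, 0] += f0 * a00 * w0
        xi[:, 0, 1] += f0 * a01 * w1
        xi[:, 1, 0] += f1 * a10 * w0
        xi[:, 1, 1] += f1 * a11 * w1
        bt0 = a00 * w0 + a01 * w1
        bt1 = a10 * w0 + a11 * w1
        g0v = f0 * bt0
        g1v = f1 * bt1
        e[:, 0] += g0v
        e[:, 1] += g1v
        m[:, 0] += g0v * xt[t]
        m[:, 1] += g1v * xt[t]
        v[:, 0] += g0v * (xt[t] - mu[:, 0]) ** 2
        v[:, 1] += g1v * (xt[t] - mu[:, 1]) ** 2
        if t == 0:
            gamma0 = np.stack([g0v, g1v], axis=1)
    return ll, e, m, v, xi, gamma0


def _viterbi_numpy(X, mu, sigma, A, pi):
    n, T = X.shape
    logA = np.log(np.maximum(A, 1e-300))
    ls = np.log(sigma)
    z0 = (X - mu[:, 0:1]) / sigma[:, None]
    z1 = (X - mu[:, 1:2]) / sigma[:, None]
    lb0 = (-0.5 * z0 * z0).T - ls
    lb1 = (-0.5 * z1 * z1).T - ls
    back = np.empty((T, n, 2), dtype=np.uint8)
    d0 = np.log(np.maximum(pi[:, 0], 1e-300)) + lb0[0]
    d1 = np.log(np.maximum(pi[:, 1], 1e-300)) + lb1[0]
    l00, l01 = logA[:, 0, 0], logA[:, 0, 1]
    l10, l11 = logA[:, 1, 0], logA[:, 1, 1]
    for t in range(1, T):
        cand00 = d0 + l00
        cand10 = d1 + l10
        take1 = cand10 > cand00
        back[t, :, 0] = take1
        nd0 = np.where(take1, cand10, cand00) + lb0[t]
        cand01 = d0 + l01
        cand11 = d1 + l11
        take1 = cand11 > cand01
        back[t, :, 1] = take1
        d1 = np.where(take1, cand11, cand01) + lb1[t]
        d0 = nd0
    path = np.empty((T, n), dtype=np.uint8)
    path[T - 1] = d1 > d0
    rng_n = np.arange(n)
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, rng_n, path[t]]
    return path.T.astype(bool)


try:  # pragma: no cover - exercised indirectly through idealize tests
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _fb_pass_nb(X, mu, sigma, A, pi):  # noqa: C901 - hot loop
        n, T = X.shape
        ll = np.empty(n)
        e = np.zeros((n, 2))
        m = np.zeros((n, 2))
        v = np.zeros((n, 2))
        xi = np.zeros((n, 2, 2))
        gamma0 = np.zeros((n, 2))
        alpha = np.empty((T, 2))
        b = np.empty((T, 2))
        c = np.empty(T)
        for i in range(n):
            mu0 = mu[i, 0]
            mu1 = mu[i, 1]
            sd = sigma[i]
            a00 = A[i, 0, 0]
            a01 = A[i, 0, 1]
            a10 = A[i, 1, 0]
            a11 = A[i, 1, 1]
            for t in range(T):
                z0 = (X[i, t] - mu0) / sd
                z1 = (X[i, t] - mu1) / sd
                e0 = 0.5 * z0 * z0
                e1 = 0.5 * z1 * z1
                if e0 > _Z2_CLIP:
                    e0 = _Z2_CLIP
                if e1 > _Z2_CLIP:
                    e1 = _Z2_CLIP
                b[t, 0] = math.exp(-e0)
                b[t, 1] = math.exp(-e1)
            f0 = pi[i, 0] * b[0, 0]
            f1 = pi[i, 1] * b[0, 1]
            s = f0 + f1
            if s <= 0.0:
                f0 = 0.5
                f1 = 0.5
                s = 1.0
            c[0] = s
            alpha[0, 0] = f0 / s
            alpha[0, 1] = f1 / s
            for t in range(1, T):
                f0 = alpha[t - 1, 0]
                f1 = alpha[t - 1, 1]
                g0 = (f0 * a00 + f1 * a10) * b[t, 0]
                g1 = (f0 * a01 + f1 * a11) * b[t, 1]
                s = g0 + g1
                if s <= 0.0:
                    g0 = 0.5
                    g1 = 0.5
                    s = 1.0
                c[t] = s
                alpha[t, 0] = g0 / s
                alpha[t, 1] = g1 / s
            acc = 0.0
            for t in range(T):
                ct = c[t]
                if ct < 1e-300:
                    ct = 1e-300
                acc += math.log(ct)
            ll[i] = acc
            bt0 = 1.0
            bt1 = 1.0
            gg0 = alpha[T - 1, 0]
            gg1 = alpha[T - 1, 1]
            ee0 = gg0
            ee1 = gg1
            mm0 = gg0 * X[i, T - 1]
            mm1 = gg1 * X[i, T - 1]
            vv0 = gg0 * (X[i, T - 1] - mu0) ** 2
            vv1 = gg1 * (X[i, T - 1] - mu1) ** 2
            sx00 = 0.0
            sx01 = 0.0
            sx10 = 0.0
            sx11 = 0.0
            for t in range(T - 2, -1, -1):
                w0 = b[t + 1, 0] * bt0 / c[t + 1]
                w1 = b[t + 1, 1] * bt1 / c[t + 1]
                f0 = alpha[t, 0]
                f1 = alpha[t, 1]
                sx00 += f0 * a00 * w0
                sx01 += f0 * a01 * w1
                sx10 += f1 * a10 * w0
                sx11 += f1 * a11 * w1
                bt0 = a00 * w0 + a01 * w1
                bt1 = a10 * w0 + a11 * w1
                gg0 = f0 * bt0
                gg1 = f1 * bt1
                ee0 += gg0
                ee1 += gg1
                mm0 += gg0 * X[i, t]
                mm1 += gg1 * X[i, t]
                vv0 += gg0 * (X[i, t] - mu0) ** 2
                vv1 += gg1 * (X[i, t] - mu1) ** 2
            e[i, 0] = ee0
            e[i, 1] = ee1
            m[i, 0] = mm0
            m[i, 1] = mm1
            v[i, 0] = vv0
            v[i, 1] = vv1
            xi[i, 0, 0] = sx00
            xi[i, 0, 1] = sx01
            xi[i, 1, 0] = sx10
            xi[i, 1, 1] = sx11
            gamma0[i, 0] = gg0
            gamma0[i, 1] = gg1
        return ll, e, m, v, xi, gamma0

    @njit(cache=True, fastmath=True)
    def _viterbi_nb(X, mu, sigma, A, pi):
        n, T = X.shape
        out = np.empty((n, T), dtype=np.uint8)
        back = np.empty((T, 2), dtype=np.uint8)
        for i in range(n):
            mu0 = mu[i, 0]
            mu1 = mu[i, 1]
            sd = sigma[i]
            ls = math.log(sd)
            l00 = math.log(max(A[i, 0, 0], 1e-300))
            l01 = math.log(max(A[i, 0, 1], 1e-300))
            l10 = math.log(max(A[i, 1, 0], 1e-300))
            l11 = math.log(max(A[i, 1, 1], 1e-300))
            z0 = (X[i, 0] - mu0) / sd
            z1 = (X[i, 0] - mu1) / sd
            d0 = math.log(max(pi[i, 0], 1e-300)) - 0.5 * z0 * z0 - ls
            d1 = math.log(max(pi[i, 1], 1e-300)) - 0.5 * z1 * z1 - ls
            for t in range(1, T):
                z0 = (X[i, t] - mu0) / sd
                z1 = (X[i, t] - mu1) / sd
                lb0 = -0.5 * z0 * z0 - ls
                lb1 = -0.5 * z1 * z1 - ls
                c00 = d0 + l00
                c10 = d1 + l10
                if c10 > c00:
                    back[t, 0] = 1
                    nd0 = c10 + lb0
                else:
                    back[t, 0] = 0
                    nd0 = c00 + lb0
                c01 = d0 + l01
                c11 = d1 + l11
                if c11 > c01:
                    back[t, 1] = 1
                    d1 = c11 + lb1
                else:
                    back[t, 1] = 0
                    d1 = c01 + lb1
                d0 = nd0
            state = 1 if d1 > d0 else 0
            out[i, T - 1] = state
            for t in range(T - 1, 0, -1):
                state = back[t, state]
                out[i, t - 1] = state
        return out

    def fb_pass(X, mu, sigma, A, pi):
        return _fb_pass_nb(X, mu, sigma, A, pi)

    def viterbi(X, mu, sigma, A, pi):
        return _viterbi_nb(X, mu, sigma, A, pi).astype(bool)

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    fb_pass = _fb_pass_numpy
    viterbi = _viterbi_numpy
    HAVE_NUMBA = False
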