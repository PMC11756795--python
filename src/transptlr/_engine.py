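"""Low-level jitted kernels: weighted-lasso coordinate descent and the EM loop.

All kernels operate on plain float64 arrays. Datasets enter as a row-stacked
design with an integer group label per row so that a single kernel serves both
the single-dataset fit and the joint multi-dataset fit (each group keeps its
own scale sigma2 and degrees of freedom nu). The t-family E-step uses the
conjugate gamma-normal results; the Gaussian family is the same loop with unit
latent weights and no nu update.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# status codes returned by _em_fit
STATUS_OK = 0
STATUS_DEGENERATE_SCALE = 1


@njit(cache=True)
def _digamma(x: float) -> float:
    # recurrence to x >= 6, then asymptotic series; |err| < 1e-12 for x > 0
    res = 0.0
    while x < 6.0:
        res -= 1.0 / x
        x += 1.0
    inv = 1.0 / x
    inv2 = inv * inv
    res += (
        math.log(x)
        - 0.5 * inv
        - inv2
        * (
            1.0 / 12.0
            - inv2
            * (
                1.0 / 120.0
                - inv2 * (1.0 / 252.0 - inv2 * (1.0 / 240.0 - inv2 / 132.0))
            )
        )
    )
    return res


@njit(cache=True)
def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=True)
def _cd_pass(X, r, w, beta, colnorm, lam, pf, coords):
    """One cyclic pass over `coords`; r is kept equal to z - X @ beta."""
    n = X.shape[0]
    maxd = 0.0
    for idx in range(coords.shape[0]):
        j = coords[idx]
        a = colnorm[j]
        if a <= 0.0:
            continue
        rho = a * beta[j]
        for i in range(n):
            rho += w[i] * X[i, j] * r[i]
        bj = _soft(rho, lam * pf[j]) / a
        d = bj - beta[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * d
            beta[j] = bj
            ad = abs(d)
            if ad > maxd:
                maxd = ad
    return maxd


@njit(cache=True)
def _cd_solve(X, r, w, beta, lam, pf, active, inner_tol, max_pass):
    """Minimize 0.5 * sum_i w_i (z_i - x_i'b)^2 + lam * sum_j pf_j |b_j|.

    beta and the residual r (= z - X beta on entry) are updated in place.
    Uses the glmnet-style scheme: full cyclic passes alternating with passes
    restricted to the current active set. Returns the number of passes.
    """
    n, p = X.shape
    colnorm = np.zeros(p)
    for j in range(p):
        if active[j]:
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            colnorm[j] = s
    all_coords = np.empty(p, dtype=np.int64)
    na = 0
    for j in range(p):
        if active[j]:
            all_coords[na] = j
            na += 1
    all_coords = all_coords[:na]

    npass = 0
    while npass < max_pass:
        maxd = _cd_pass(X, r, w, beta, colnorm, lam, pf, all_coords)
        npass += 1
        if maxd < inner_tol:
            break
        # restrict to the nonzero set until it stabilizes
        nz = np.empty(na, dtype=np.int64)
        k = 0
        for idx in range(na):
            j = all_coords[idx]
            if beta[j] != 0.0:
                nz[k] = j
                k += 1
        nzc = nz[:k]
        while npass < max_pass:
            maxd = _cd_pass(X, r, w, beta, colnorm, lam, pf, nzc)
            npass += 1
            if maxd < inner_tol:
                break
    return npass


@njit(cache=True)
def _t_logpdf_sum(r, sigma2, nu):
    n = r.shape[0]
    c = (
        math.lgamma((nu + 1.0) / 2.0)
        - math.lgamma(nu / 2.0)
        - 0.5 * math.log(nu * math.pi * sigma2)
    )
    s = 0.0
    for i in range(n):
        s += c - 0.5 * (nu + 1.0) * math.log1p(r[i] * r[i] / (nu * sigma2))
    return s


@njit(cache=True)
def _norm_logpdf_sum(r, sigma2):
    n = r.shape[0]
    c = -0.5 * math.log(2.0 * math.pi * sigma2)
    s = 0.0
    for i in range(n):
        s += c - 0.5 * r[i] * r[i] / sigma2
    return s


@njit(cache=True)
def _nu_score(nu: float, c: float) -> float:
    # d/dnu of E[L2] per observation (up to factor n/2):
    # log(nu/2) + 1 - psi(nu/2) + mean(E[log tau] - E[tau])
    return math.log(nu / 2.0) + 1.0 - _digamma(nu / 2.0) + c


@njit(cache=True)
def _solve_nu(c: float, lo: float, hi: float) -> float:
    """Root of the monotone-decreasing nu score on [lo, hi] by bisection.

    Without a sign change the boundary on the favourable side of the
    (monotone) score is the constrained maximizer of E[L2].
    """
    flo = _nu_score(lo, c)
    fhi = _nu_score(hi, c)
    if flo <= 0.0:
        return lo
    if fhi >= 0.0:
        return hi
    a, b = lo, hi
    for _ in range(200):
        m = 0.5 * (a + b)
        fm = _nu_score(m, c)
        if fm > 0.0:
            a = m
        else:
            b = m
        if b - a < 1e-10 * (1.0 + b):
            break
    return 0.5 * (a + b)


@njit(cache=True)
def _nu_mle(r, sigma2, lo, hi):
    """Conditional MLE of nu given residuals and sigma2 (golden section on
    the observed t log-likelihood; unimodal in nu)."""
    invphi = 0.6180339887498949
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _t_logpdf_sum(r, sigma2, c)
    fd = _t_logpdf_sum(r, sigma2, d)
    for _ in range(30):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _t_logpdf_sum(r, sigma2, c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _t_logpdf_sum(r, sigma2, d)
        if b - a < 1e-8 * (1.0 + b):
            break
    m = 0.5 * (a + b)
    # the boundaries can dominate the interior (near-Gaussian or ultra-heavy)
    fm = _t_logpdf_sum(r, sigma2, m)
    flo = _t_logpdf_sum(r, sigma2, lo)
    fhi = _t_logpdf_sum(r, sigma2, hi)
    if flo >= fm and flo >= fhi:
        return lo
    if fhi >= fm and fhi >= flo:
        return hi
    return m


@njit(cache=True)
def _penalized_obj(r, group, sigma2, nu, beta, lam, pf, family_t):
    """Observed-data objective: sum of log-likelihoods minus the
    scale-equivariant penalty lam * ||beta||_1 / sigma_0."""
    G = sigma2.shape[0]
    obj = 0.0
    for g in range(G):
        sel = group == g
        rg = r[sel]
        if family_t:
            obj += _t_logpdf_sum(rg, sigma2[g], nu[g])
        else:
            obj += _norm_logpdf_sum(rg, sigma2[g])
    pen = 0.0
    for j in range(beta.shape[0]):
        pen += pf[j] * abs(beta[j])
    return obj - lam * pen / sigma2[0]


@njit(cache=True)
def _em_fit(
    X,
    z,
    group,
    beta,
    sigma2,
    nu,
    lam,
    pf,
    active,
    family_t,
    estimate_nu,
    nu_lo,
    nu_hi,
    tol,
    max_iter,
    inner_tol,
    max_pass,
    obj_trace,
    track_obj,
    estimate_scale,
    cd_passes,
    polish,
):
    """EM-type loop for the l1-penalized t (or Gaussian) regression.

    The beta step solves the weighted lasso

        min_b  0.5 * sum_i tau_i (sigma0^2 / sigma_g(i)^2) r_i^2 + lam ||b||_1

    with lam calibrated on the weighted-RSS (data) scale — for the Gaussian
    family this is exactly the standard lasso criterion. Relative to the
    likelihood this equals the penalty lam * ||beta||_1 / sigma0^2 at the
    current target scale, which keeps the problem bounded when p >= n (the
    raw likelihood-scale penalty is degenerate there: an interpolating beta
    drives sigma -> 0 and the objective to +infinity). sigma_g and nu_g keep
    their ML updates; group scales are floored at 1e-3 of their null
    variance to keep cross-group weights finite.

    Rows must be ordered so that each group occupies a contiguous block
    (group labels ascending), which lets every per-group pass run on a slice.
    beta, sigma2, nu are warm-start inputs updated in place; obj_trace (length
    max_iter) receives the penalized observed-data objective after each
    iteration when track_obj is set. Returns (n_iter, converged, status).
    """
    n, p = X.shape
    G = sigma2.shape[0]
    # contiguous group offsets: group g occupies rows start[g]:start[g+1]
    start = np.zeros(G + 1, dtype=np.int64)
    for i in range(n):
        start[group[i] + 1] += 1
    for g in range(G):
        start[g + 1] += start[g]
    ng = np.empty(G)
    floor = np.empty(G)
    for g in range(G):
        ng[g] = start[g + 1] - start[g]
        a = 0.0
        for i in range(start[g], start[g + 1]):
            a += z[i] * z[i]
        floor[g] = max(1e-3 * a / ng[g], 1e-12)

    r = z - X @ beta
    w = np.empty(n)
    tau = np.empty(n)
    it = 0
    converged = False
    status = STATUS_OK
    while it < max_iter:
        # E-step at theta^(u-1)
        s0 = sigma2[0]
        if family_t:
            for g in range(G):
                nug = nu[g]
                s_ratio = s0 / sigma2[g]
                inv_s = 1.0 / sigma2[g]
                for i in range(start[g], start[g + 1]):
                    t_i = (nug + 1.0) / (nug + r[i] * r[i] * inv_s)
                    tau[i] = t_i
                    w[i] = t_i * s_ratio
        else:
            for g in range(G):
                s_ratio = s0 / sigma2[g]
                for i in range(start[g], start[g + 1]):
                    tau[i] = 1.0
                    w[i] = s_ratio

        # M-step: beta by coordinate descent on the weighted surrogate.
        # A handful of passes per reweighting suffices (generalized EM);
        # the final solution is polished to full accuracy below.
        d_theta = 0.0
        beta_prev = beta.copy()
        _cd_solve(X, r, w, beta, lam, pf, active, inner_tol, cd_passes)
        for j in range(p):
            d_theta += abs(beta[j] - beta_prev[j])

        # M-step: per-group scale (weighted MLE, floored)
        if estimate_scale:
            for g in range(G):
                a = 0.0
                for i in range(start[g], start[g + 1]):
                    a += tau[i] * r[i] * r[i]
                if a <= 0.0:
                    status = STATUS_DEGENERATE_SCALE
                    return it, False, status
                s = max(a / ng[g], floor[g])
                d_theta += abs(s - sigma2[g])
                sigma2[g] = s

        # CM-step for nu on the observed likelihood (ECME; far faster than
        # the Q-function root, which inches along when nu is weakly informed)
        if family_t and estimate_nu:
            for g in range(G):
                rg = r[start[g]:start[g + 1]]
                new_nu = _nu_mle(rg, sigma2[g], nu_lo, nu_hi)
                d_theta += abs(new_nu - nu[g])
                nu[g] = new_nu

        if track_obj:
            obj_trace[it] = _penalized_obj(
                r, group, sigma2, nu, beta, lam, pf, family_t)
        it += 1
        if d_theta < tol:
            converged = True
            break

    # polish beta to a weight-consistent solution at the final (sigma2, nu):
    # alternate E-step reweighting with full-accuracy CD until beta is a
    # fixed point of its own weights, so the KKT certificate holds at the
    # weights recomputed from the returned beta.
    if polish:
        s0 = sigma2[0]
        for _ in range(20):
            if family_t:
                for g in range(G):
                    nug = nu[g]
                    s_ratio = s0 / sigma2[g]
                    inv_s = 1.0 / sigma2[g]
                    for i in range(start[g], start[g + 1]):
                        t_i = (nug + 1.0) / (nug + r[i] * r[i] * inv_s)
                        w[i] = t_i * s_ratio
            else:
                for g in range(G):
                    s_ratio = s0 / sigma2[g]
                    for i in range(start[g], start[g + 1]):
                        w[i] = s_ratio
            beta_pre = beta.copy()
            _cd_solve(X, r, w, beta, lam, pf, active, 0.01 * inner_tol, max_pass)
            d = 0.0
            for j in range(p):
                dj = abs(beta[j] - beta_pre[j])
                if dj > d:
                    d = dj
            if d < 0.1 * inner_tol:
                break
            if not family_t:
                break  # gaussian weights do not depend on beta
    return it, converged, status


@njit(cache=True)
def _kkt_max_violation(X, r, w, beta, lam, pf, active):
    """Max violation of the lasso subgradient conditions at beta.

    gradient_j = -sum_i w_i x_ij r_i; optimality requires |grad_j| <= lam*pf_j
    when beta_j = 0 and grad_j = -sign(beta_j) * lam * pf_j otherwise.
    """
    n, p = X.shape
    v = 0.0
    for j in range(p):
        if not active[j]:
            continue
        g = 0.0
        for i in range(n):
            g -= w[i] * X[i, j] * r[i]
        lj = lam * pf[j]
        if beta[j] == 0.0:
            excess = abs(g) - lj
            if excess > v:
                v = excess
        else:
            excess = abs(g + (lj if beta[j] > 0.0 else -lj))
            if excess > v:
                v = excess
    return v
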