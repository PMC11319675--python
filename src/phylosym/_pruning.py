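"""Numerical kernels for the phylogenetic logistic model.

The binary trait is modelled as a two-state Markov process running along
the tree: a single switching rate ``alpha`` (per unit branch length) and a
branch-specific stationary frequency, equal to the mean of the logistic
equilibria ``sigmoid(x_i' beta)`` of the tips subtended by the branch.
Transition probability over a branch of length t with equilibrium pi:
``P(a -> b) = (1 - e) * pi(b) + e * delta_ab`` with ``e = exp(-alpha t)``.
The exact likelihood follows by Felsenstein pruning; as alpha grows the
tips decouple and the model reduces to independent logistic regression.

Kernels are JIT-compiled with numba when available; the pure-Python
fallback computes identical values.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


LOG_ALPHA_MIN = -4.0
LOG_ALPHA_MAX = 4.0


@njit(cache=False)
def _node_equilibria(post, child_list, child_ptr, pi_tip):
    n = post.shape[0]
    s = np.zeros(n)
    cnt = np.zeros(n)
    for k in range(n):
        u = post[k]
        lo, hi = child_ptr[u], child_ptr[u + 1]
        if lo == hi:
            s[u] = pi_tip[u]
            cnt[u] = 1.0
        else:
            acc = 0.0
            c_acc = 0.0
            for ci in range(lo, hi):
                c = child_list[ci]
                acc += s[c]
                c_acc += cnt[c]
            s[u] = acc
            cnt[u] = c_acc
    return s / cnt


@njit(cache=False)
def _markov_loglik(post, child_list, child_ptr, decay, pi_node, y, root):
    n = post.shape[0]
    L0 = np.empty(n)
    L1 = np.empty(n)
    scale = 0.0
    for k in range(n):
        u = post[k]
        lo, hi = child_ptr[u], child_ptr[u + 1]
        if lo == hi:
            if y[u] == 1:
                L0[u] = 0.0
                L1[u] = 1.0
            else:
                L0[u] = 1.0
                L1[u] = 0.0
        elif u == root:
            # lineages diverging at the root share no path, hence carry no
            # covariance: each root-child subtree starts from an
            # independent stationary draw at its own equilibrium
            tot = 1.0
            for ci in range(lo, hi):
                c = child_list[ci]
                pi1 = pi_node[c]
                v = (1.0 - pi1) * L0[c] + pi1 * L1[c]
                if v <= 0.0:
                    return -1.0e300
                tot *= v
                if tot < 1.0e-280:
                    scale += np.log(tot)
                    tot = 1.0
            return np.log(tot) + scale
        else:
            a0 = 1.0
            a1 = 1.0
            for ci in range(lo, hi):
                c = child_list[ci]
                e = decay[c]
                pi1 = pi_node[c]
                base = (1.0 - pi1) * L0[c] + pi1 * L1[c]
                a0 *= (1.0 - e) * base + e * L0[c]
                a1 *= (1.0 - e) * base + e * L1[c]
            s = a0 if a0 > a1 else a1
            if s <= 0.0:
                return -1.0e300
            L0[u] = a0 / s
            L1[u] = a1 / s
            scale += np.log(s)
    return -1.0e300  # unreachable for a rooted tree with >= 2 tips


@njit(cache=False)
def _chol_small(A):
    """Cholesky of a small SPD matrix; returns (L, ok flag)."""
    p = A.shape[0]
    L = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return L, False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L, True


@njit(cache=False)
def _chol_solve(L, b):
    p = L.shape[0]
    x = b.copy()
    for i in range(p):
        for k in range(i):
            x[i] -= L[i, k] * x[k]
        x[i] /= L[i, i]
    for i in range(p - 1, -1, -1):
        for k in range(i + 1, p):
            x[i] -= L[k, i] * x[k]
        x[i] /= L[i, i]
    return x


@njit(cache=False)
def _neg_pen_loglik(params, X, post, child_list, child_ptr, blen, y, root):
    """Negative penalized log-likelihood: -( loglik + 0.5*logdet(X'WX) )."""
    n_tips, p = X.shape
    la = params[p]
    if la < LOG_ALPHA_MIN:
        la = LOG_ALPHA_MIN
    if la > LOG_ALPHA_MAX:
        la = LOG_ALPHA_MAX
    alpha = np.exp(la)
    n = post.shape[0]
    pi_tip = np.empty(n)
    for i in range(n_tips):
        eta = 0.0
        for a in range(p):
            eta += X[i, a] * params[a]
        if eta > 35.0:
            eta = 35.0
        if eta < -35.0:
            eta = -35.0
        pi_tip[i] = 1.0 / (1.0 + np.exp(-eta))
    pi_node = _node_equilibria(post, child_list, child_ptr, pi_tip)
    decay = np.exp(-alpha * blen)
    ll = _markov_loglik(post, child_list, child_ptr, decay, pi_node, y, root)
    # Firth bias-reduction penalty on the tip-level information
    M = np.zeros((p, p))
    for i in range(n_tips):
        w = pi_tip[i] * (1.0 - pi_tip[i])
        for a in range(p):
            for b in range(p):
                M[a, b] += w * X[i, a] * X[i, b]
    L, ok = _chol_small(M)
    if not ok:
        return 1.0e300
    ld = 0.0
    for a in range(p):
        ld += np.log(L[a, a])
    return -(ll + ld)


@njit(cache=False)
def _fd_gradient(params, free, X, post, child_list, child_ptr, blen, y, root):
    k = params.shape[0]
    g = np.zeros(k)
    for i in range(k):
        if not free[i]:
            continue
        h = 1.0e-5 * (1.0 + abs(params[i]))
        xp = params.copy()
        xm = params.copy()
        xp[i] += h
        xm[i] -= h
        fp = _neg_pen_loglik(xp, X, post, child_list, child_ptr, blen, y, root)
        fm = _neg_pen_loglik(xm, X, post, child_list, child_ptr, blen, y, root)
        g[i] = (fp - fm) / (2.0 * h)
    return g


@njit(cache=False)
def _newton_fit(params0, free, X, post, child_list, child_ptr, blen, y, root,
                max_iter, tol):
    """Damped Newton with finite-difference derivatives on the free
    parameters; the log-alpha coordinate is clamped to its box."""
    k = params0.shape[0]
    x = params0.copy()
    p = X.shape[1]
    f0 = _neg_pen_loglik(x, X, post, child_list, child_ptr, blen, y, root)
    converged = False
    nfree = 0
    for i in range(k):
        if free[i]:
            nfree += 1
    idx = np.empty(nfree, dtype=np.int64)
    j = 0
    for i in range(k):
        if free[i]:
            idx[j] = i
            j += 1
    H = np.zeros((nfree, nfree))
    blind = 0
    for it in range(max_iter):
        g = _fd_gradient(x, free, X, post, child_list, child_ptr, blen, y, root)
        if it % 4 == 0:
            # FD Hessian on free coords from gradient differences; the
            # objective is near-quadratic, so the factor is reused for a
            # few Newton steps before refreshing
            H = np.zeros((nfree, nfree))
            for a in range(nfree):
                i = idx[a]
                h = 1.0e-4 * (1.0 + abs(x[i]))
                xp = x.copy()
                xm = x.copy()
                xp[i] += h
                xm[i] -= h
                gp = _fd_gradient(xp, free, X, post, child_list, child_ptr, blen, y, root)
                gm = _fd_gradient(xm, free, X, post, child_list, child_ptr, blen, y, root)
                for b in range(nfree):
                    H[a, b] += (gp[idx[b]] - gm[idx[b]]) / (2.0 * h)
            for a in range(nfree):
                for b in range(a + 1, nfree):
                    m = 0.5 * (H[a, b] + H[b, a])
                    H[a, b] = m
                    H[b, a] = m
        ridge = 0.0
        tr = 0.0
        for a in range(nfree):
            tr += abs(H[a, a])
        tr = tr / nfree + 1.0
        gf = np.empty(nfree)
        for a in range(nfree):
            gf[a] = g[idx[a]]
        step = np.zeros(nfree)
        for attempt in range(8):
            Hr = H.copy()
            for a in range(nfree):
                Hr[a, a] += ridge
            L, ok = _chol_small(Hr)
            if ok:
                step = _chol_solve(L, gf)
                break
            ridge = tr * (10.0 ** (attempt - 4))
        gnorm = 0.0
        for a in range(nfree):
            gnorm += gf[a] * gf[a]
        if np.sqrt(gnorm) < tol:
            converged = True
            break
        # backtracking line search
        lam = 1.0
        improved = False
        for _ in range(30):
            xn = x.copy()
            for a in range(nfree):
                xn[idx[a]] = x[idx[a]] - lam * step[a]
            if xn[p] < LOG_ALPHA_MIN:
                xn[p] = LOG_ALPHA_MIN
            if xn[p] > LOG_ALPHA_MAX:
                xn[p] = LOG_ALPHA_MAX
            fn = _neg_pen_loglik(xn, X, post, child_list, child_ptr, blen, y, root)
            if fn < f0:
                x = xn
                f0 = fn
                improved = True
                break
            lam *= 0.5
        if not improved:
            # near the optimum the objective differences fall below the
            # floating-point noise floor; Newton converges quadratically
            # there, so take a few full steps on the gradient alone
            if np.sqrt(gnorm) < 1.0e-3 and blind < 6:
                blind += 1
                xn = x.copy()
                for a in range(nfree):
                    xn[idx[a]] = x[idx[a]] - step[a]
                if xn[p] < LOG_ALPHA_MIN:
                    xn[p] = LOG_ALPHA_MIN
                if xn[p] > LOG_ALPHA_MAX:
                    xn[p] = LOG_ALPHA_MAX
                x = xn
                f0 = _neg_pen_loglik(x, X, post, child_list, child_ptr, blen, y, root)
                continue
            converged = True  # no descent direction left at FD resolution
            break
    return x, f0, converged


@njit(cache=False)
def _simulate_markov(pre, parent, decay, pi_node, root, urand, n_tips):
    n = pre.shape[0]
    state = np.zeros(n, dtype=np.int8)
    for k in range(n):
        u = pre[k]
        if u == root:
            continue  # root-child lineages are initialized independently
        if parent[u] == root:
            state[u] = 1 if urand[u] < pi_node[u] else 0
        else:
            e = decay[u]
            p1 = (1.0 - e) * pi_node[u]
            if state[parent[u]] == 1:
                p1 += e
            state[u] = 1 if urand[u] < p1 else 0
    return state[:n_tips]


@njit(cache=False)
def _bootstrap_markov(params_hat, free, X, post, pre, parent, child_list,
                      child_ptr, blen, y_dummy, root, urand, max_iter, tol):
    """Parametric bootstrap: simulate under the fitted model and refit.

    ``urand`` has shape (B, n_nodes). Returns (B, p) array of bootstrap
    coefficient estimates (free coordinates refit, others held)."""
    n_tips, p = X.shape
    B = urand.shape[0]
    out = np.empty((B, p))
    la = params_hat[p]
    alpha = np.exp(la)
    pi_tip = np.empty(post.shape[0])
    for i in range(n_tips):
        eta = 0.0
        for a in range(p):
            eta += X[i, a] * params_hat[a]
        pi_tip[i] = 1.0 / (1.0 + np.exp(-eta))
    pi_node = _node_equilibria(post, child_list, child_ptr, pi_tip)
    decay = np.exp(-alpha * blen)
    for b in range(B):
        ystar = _simulate_markov(pre, parent, decay, pi_node, root, urand[b], n_tips)
        ystar64 = ystar.astype(np.int64)
        xb, _, _ = _newton_fit(params_hat.copy(), free, X, post, child_list,
                               child_ptr, blen, ystar64, root, max_iter, tol)
        for a in range(p):
            out[b, a] = xb[a]
    return out
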