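"""Phylogenetic regressions for lifestyle-linked traits.

Two models, matching the two kinds of response in the pipeline:

* **Binary traits** (presence of a molecular function, presence of a BGC
  group): phylogenetic logistic regression in the Ives-Garland spirit.
  ``logit P(y_i = 1) = x_i' beta`` with dependence among tips controlled by
  a switching rate ``alpha`` acting on the shared-ancestry structure; the
  exact two-state Markov likelihood on the tree is maximized jointly over
  ``(beta, log alpha)`` with Firth's bias-reduction penalty
  ``+ 1/2 log det I(beta)``, which keeps estimates finite under complete
  separation. Inference combines Wald tests with a parametric bootstrap
  (default B = 100) of trait evolution under the fitted model.

* **Counts** (total and per-class BGC counts): phylogenetic linear
  regression under a Pagel's-lambda covariance, ``y ~ N(X beta,
  sigma^2 * V_lambda)`` where ``V_lambda`` multiplies off-diagonal
  phylogenetic covariances by ``lambda`` in [0, 1]. ``lambda`` is profiled
  on a 0.01 grid and refined by bounded optimization; bootstrap as above.

Significance scans flag traits at p < 0.05 (no multiple-testing
correction; a Benjamini-Hochberg column is emitted for transparency only).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from ._pruning import (
    LOG_ALPHA_MAX,
    LOG_ALPHA_MIN,
    _bootstrap_markov,
    _neg_pen_loglik,
    _newton_fit,
)
from .tree import PhyloTree

__all__ = [
    "vcv_from_tree",
    "lambda_transform",
    "PhyloLMResult",
    "PhyloGLMResult",
    "phylo_linear_fit",
    "phylo_logistic_fit",
    "enrichment_scan",
    "count_enrichment_scan",
    "trait_seed",
    "make_design",
]


def vcv_from_tree(tree: PhyloTree) -> np.ndarray:
    """Phylogenetic covariance: V[i,j] = root-to-MRCA path length."""
    return tree.vcv()


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda: multiply off-diagonal entries by ``lam``; the
    diagonal is unchanged."""
    if not 0 <= lam <= 1:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out


def trait_seed(global_seed: int, trait_id: str) -> int:
    """Stable per-trait RNG seed (reproducible under parallel scans)."""
    return zlib.crc32(f"{global_seed}:{trait_id}".encode()) & 0x7FFFFFFF


@dataclass
class PhyloLMResult:
    trait_id: str
    coef_names: List[str]
    beta: np.ndarray
    se: np.ndarray
    lambda_: float
    sigma2: float
    p_wald: np.ndarray
    p_boot: np.ndarray
    bootstrap_replicates: np.ndarray  # (B, p)
    loglik: float
    converged: bool = True


@dataclass
class PhyloGLMResult:
    trait_id: str
    coef_names: List[str]
    beta: np.ndarray
    se: np.ndarray
    alpha: float  # switching rate per original branch-length unit
    p_wald: np.ndarray
    p_boot: np.ndarray
    bootstrap_replicates: np.ndarray  # (B, p)
    loglik: float
    converged: bool = True
    separation: bool = False


# ---------------------------------------------------------------------
# linear model (Pagel's lambda GLS)
# ---------------------------------------------------------------------


class _LambdaGLS:
    """Per-tree cache of Cholesky factors of V_lambda over the profile grid."""

    def __init__(self, V: np.ndarray, grid_step: float = 0.01):
        self.V = V
        self.n = V.shape[0]
        self.grid = np.round(np.arange(0.0, 1.0 + 1e-9, grid_step), 10)
        self.chols = [linalg.cholesky(lambda_transform(V, l) +
                                      1e-12 * np.eye(self.n), lower=True)
                      for l in self.grid]
        self.logdets = [2.0 * np.sum(np.log(np.diag(L))) for L in self.chols]

    def whiten(self, L: np.ndarray, M: np.ndarray) -> np.ndarray:
        return linalg.solve_triangular(L, M, lower=True)


def _gls_profile(Xw: np.ndarray, yw: np.ndarray, logdet: float):
    """ML profile log-likelihood given a whitened design/response."""
    n, p = Xw.shape
    beta, res, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    rss = float(r @ r)
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return beta, sigma2, ll


def phylo_linear_fit(
    y: np.ndarray,
    X: np.ndarray,
    tree: Optional[PhyloTree] = None,
    B: int = 100,
    seed: int = 0,
    trait_id: str = "trait",
    coef_names: Optional[List[str]] = None,
    V: Optional[np.ndarray] = None,
    _cache: Optional[_LambdaGLS] = None,
) -> PhyloLMResult:
    """ML fit of y ~ N(X beta, sigma^2 V_lambda) with lambda in [0, 1]."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than predictors")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular design matrix")
    if _cache is None:
        if V is None:
            if tree is None:
                raise ValueError("provide a tree, V, or a cache")
            V = vcv_from_tree(tree)
        _cache = _LambdaGLS(V)
    cache = _cache

    def eval_lambda_fresh(lam: float):
        Vl = lambda_transform(cache.V, lam) + 1e-12 * np.eye(n)
        L = linalg.cholesky(Vl, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        Xw = cache.whiten(L, X)
        yw = cache.whiten(L, y)
        return (*_gls_profile(Xw, yw, logdet), L)

    # profile over the grid
    lls = np.empty(len(cache.grid))
    for k, L in enumerate(cache.chols):
        Xw = cache.whiten(L, X)
        yw = cache.whiten(L, y)
        _, _, lls[k] = _gls_profile(Xw, yw, cache.logdets[k])
    k_best = int(np.argmax(lls))
    lo = cache.grid[max(0, k_best - 1)]
    hi = cache.grid[min(len(cache.grid) - 1, k_best + 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda l: -eval_lambda_fresh(l)[2], bounds=(lo, hi),
            method="bounded", options={"xatol": 1e-6},
        )
        lam_hat = float(res.x)
    else:
        lam_hat = float(cache.grid[k_best])
    beta, sigma2_ml, ll, Lhat = eval_lambda_fresh(lam_hat)

    # Wald (t) tests with the unbiased variance estimate
    Xw = cache.whiten(Lhat, X)
    yw = cache.whiten(Lhat, y)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    sigma2_u = rss / (n - p)
    se = np.sqrt(sigma2_u * np.diag(XtX_inv))
    tstat = beta / se
    p_wald = 2.0 * stats.t.sf(np.abs(tstat), df=n - p)

    # parametric bootstrap (vectorized over replicates, lambda on the grid)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, B))
    Ystar = (X @ beta)[:, None] + np.sqrt(sigma2_ml) * (Lhat @ Z)
    boot_ll = np.empty((len(cache.grid), B))
    boot_beta = np.empty((len(cache.grid), p, B))
    for k, L in enumerate(cache.chols):
        Xw_k = cache.whiten(L, X)
        Yw_k = cache.whiten(L, Ystar)
        Bk, _, _, _ = np.linalg.lstsq(Xw_k, Yw_k, rcond=None)
        R = Yw_k - Xw_k @ Bk
        rss_k = np.sum(R * R, axis=0)
        rss_k = np.maximum(rss_k, 1e-300)
        boot_ll[k] = -0.5 * (n * np.log(2 * np.pi * rss_k / n) + cache.logdets[k] + n)
        boot_beta[k] = Bk
    kb = np.argmax(boot_ll, axis=0)
    reps = boot_beta[kb, :, np.arange(B)]  # (B, p)
    p_boot = (1.0 + np.sum(np.abs(reps - beta) >= np.abs(beta), axis=0)) / (B + 1.0)

    names = coef_names or [f"b{j}" for j in range(p)]
    return PhyloLMResult(
        trait_id=trait_id, coef_names=names, beta=beta, se=se, lambda_=lam_hat,
        sigma2=sigma2_ml, p_wald=np.asarray(p_wald), p_boot=p_boot,
        bootstrap_replicates=reps, loglik=float(ll),
    )


# ---------------------------------------------------------------------
# logistic model (two-state Markov likelihood + Firth penalty)
# ---------------------------------------------------------------------


class _TreeArrays:
    """Flat-array tree representation for the pruning kernels, with branch
    lengths rescaled to unit tree height (the rate alpha is reported back
    on the original scale)."""

    def __init__(self, tree: PhyloTree):
        self.height = tree.height()
        if self.height <= 0:
            raise ValueError("tree height must be positive")
        self.n_tips = tree.n_tips
        self.n_nodes = tree.n_nodes
        self.root = tree.root
        self.parent = tree.parent.astype(np.int64)
        self.post = tree.postorder.astype(np.int64)
        self.pre = tree.preorder.astype(np.int64)
        self.blen = (tree.branch_length / self.height).astype(np.float64)
        child_list = []
        child_ptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
        for i in range(self.n_nodes):
            child_list.extend(tree.children[i])
            child_ptr[i + 1] = len(child_list)
        self.child_list = np.asarray(child_list, dtype=np.int64)
        self.child_ptr = child_ptr


def _firth_logistic_start(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Cheap Firth-penalized IRLS starting values (independence model)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(50):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        XtWX = X.T @ (X * W[:, None])
        try:
            Minv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            break
        H = (X * W[:, None]) @ Minv @ X.T
        h = np.diag(H)
        U = X.T @ (y - mu + h * (0.5 - mu))
        step = Minv @ U
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def phylo_logistic_fit(
    y: np.ndarray,
    X: np.ndarray,
    tree: PhyloTree,
    B: int = 100,
    seed: int = 0,
    trait_id: str = "trait",
    coef_names: Optional[List[str]] = None,
    max_iter: int = 200,
    _arrays: Optional[_TreeArrays] = None,
) -> PhyloGLMResult:
    """Penalized-ML fit of the phylogenetic logistic model.

    ``y`` must contain both classes; rows of ``y``/``X`` are aligned with
    ``tree.tip_labels``. Bootstrap p-values compare |beta_hat| against the
    spread of B parametric-bootstrap re-estimates (alpha held at its
    estimate during the refits).
    """
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n != tree.n_tips:
        raise ValueError("response length must equal the number of tips")
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1}:
        raise ValueError("response must be binary 0/1")
    if len(uniq) < 2:
        raise ValueError("response has no variation (all equal)")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular design matrix")
    ta = _arrays if _arrays is not None else _TreeArrays(tree)
    y64 = y.astype(np.int64)

    beta0 = _firth_logistic_start(y.astype(float), X)
    x0 = np.concatenate([beta0, [0.5 * (LOG_ALPHA_MIN + LOG_ALPHA_MAX)]])
    args = (X, ta.post, ta.child_list, ta.child_ptr, ta.blen, y64, ta.root)

    res = optimize.minimize(
        lambda par: _neg_pen_loglik(par, *args),
        x0,
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [(LOG_ALPHA_MIN, LOG_ALPHA_MAX)],
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    # polish with the damped-Newton kernel (also used by the bootstrap)
    free = np.ones(p + 1, dtype=np.bool_)
    xhat, fhat, newton_conv = _newton_fit(
        res.x.copy(), free, X, ta.post, ta.child_list, ta.child_ptr, ta.blen,
        y64, ta.root, 50, 1e-8,
    )
    if fhat > res.fun:
        xhat, fhat = res.x, res.fun
    converged = bool(res.success or newton_conv)
    beta = xhat[:p].copy()
    log_alpha = float(np.clip(xhat[p], LOG_ALPHA_MIN, LOG_ALPHA_MAX))
    alpha_unit = float(np.exp(log_alpha))

    # complete-separation diagnostic: the fitted direction classifies the
    # response perfectly (the unpenalized MLE would diverge; Firth's
    # penalty keeps the reported estimates finite)
    eta = X @ beta
    separation = bool(np.all((eta > 0) == (y == 1)))

    # Wald covariance from the FD Hessian of the penalized objective (beta
    # block, alpha profiled out at its estimate)
    se = np.full(p, np.nan)
    Hb = np.zeros((p, p))
    hsteps = 1e-4 * (1.0 + np.abs(beta))
    for a in range(p):
        for b in range(a, p):
            xpp = xhat.copy(); xpm = xhat.copy(); xmp = xhat.copy(); xmm = xhat.copy()
            xpp[a] += hsteps[a]; xpp[b] += hsteps[b]
            xpm[a] += hsteps[a]; xpm[b] -= hsteps[b]
            xmp[a] -= hsteps[a]; xmp[b] += hsteps[b]
            xmm[a] -= hsteps[a]; xmm[b] -= hsteps[b]
            val = (
                _neg_pen_loglik(xpp, *args) - _neg_pen_loglik(xpm, *args)
                - _neg_pen_loglik(xmp, *args) + _neg_pen_loglik(xmm, *args)
            ) / (4 * hsteps[a] * hsteps[b])
            Hb[a, b] = Hb[b, a] = val
    try:
        cov = np.linalg.inv(Hb)
        d = np.diag(cov)
        se = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        pass
    z = beta / se
    p_wald = 2.0 * stats.norm.sf(np.abs(z))

    # parametric bootstrap under the fitted model
    rng = np.random.default_rng(seed)
    urand = rng.random((B, ta.n_nodes))
    free_boot = np.ones(p + 1, dtype=np.bool_)
    free_boot[p] = False  # alpha held fixed during refits
    reps = _bootstrap_markov(
        xhat.copy(), free_boot, X, ta.post, ta.pre, ta.parent, ta.child_list,
        ta.child_ptr, ta.blen, y64, ta.root, urand, 50, 1e-6,
    )
    p_boot = (1.0 + np.sum(np.abs(reps - beta) >= np.abs(beta), axis=0)) / (B + 1.0)

    names = coef_names or [f"b{j}" for j in range(p)]
    return PhyloGLMResult(
        trait_id=trait_id, coef_names=names, beta=beta, se=se,
        alpha=alpha_unit / ta.height, p_wald=np.asarray(p_wald), p_boot=p_boot,
        bootstrap_replicates=reps, loglik=-float(fhat), converged=converged,
        separation=separation,
    )


# ---------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------


def make_design(
    predictor: pd.Series, genome_ids: Sequence[str]
) -> Tuple[np.ndarray, List[str]]:
    """Design matrix for a lifestyle/host-source predictor.

    A binary predictor (two levels) becomes an intercept plus one indicator
    for the level sorted last (so 'host-associated' vs 'free-living' yields
    the host-associated effect). A multi-level factor is dummy-coded with
    'free-living' (if present, else the first sorted level) as baseline.
    """
    s = predictor.reindex(genome_ids)
    if s.isna().any():
        missing = list(s[s.isna()].index[:5])
        raise ValueError(f"predictor missing for genomes: {missing}")
    levels = sorted(s.unique())
    if len(levels) < 2:
        raise ValueError("predictor is constant")
    baseline = "free-living" if "free-living" in levels else levels[0]
    others = [l for l in levels if l != baseline]
    cols = [np.ones(len(s))]
    names = ["intercept"]
    for lvl in others:
        cols.append((s == lvl).to_numpy(dtype=float))
        names.append(str(lvl))
    return np.column_stack(cols), names


_SCAN_COLUMNS = ["trait_id", "predictor", "estimate", "se", "p_wald",
                 "p_boot", "significant", "direction", "converged", "note"]


def _scan_frame(rows: List[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=_SCAN_COLUMNS)
    if len(df) and "p_boot" in df:
        # BH column for transparency; the significance flag stays uncorrected
        p = df["p_boot"].to_numpy(dtype=float)
        m = int(np.sum(~np.isnan(p)))
        if m:
            order = np.argsort(p)  # NaNs sort last
            ranked = p[order] * m / (np.arange(len(p)) + 1.0)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            q = np.empty_like(p)
            q[order] = np.minimum(ranked, 1.0)
            df["q_bh"] = q
    return df


def enrichment_scan(
    tm: pd.DataFrame,
    predictor: pd.Series,
    tree: PhyloTree,
    alpha_level: float = 0.05,
    B: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Phylogenetic logistic regression of every binary trait column on the
    predictor. Returns one row per trait with the focal (non-intercept)
    coefficient, Wald and bootstrap p-values, the p < alpha_level flag on
    the bootstrap p, and the enrichment direction in the non-baseline
    level. Traits failing preconditions are flagged, not dropped."""
    genome_ids = [g for g in tree.tip_labels if g in tm.index]
    if len(genome_ids) != tree.n_tips:
        missing = set(tree.tip_labels) - set(tm.index)
        raise ValueError(f"trait matrix missing tree tips: {sorted(missing)[:5]}")
    X, names = make_design(predictor, genome_ids)
    arrays = _TreeArrays(tree)
    rows = []
    for trait in tm.columns:
        yv = tm.loc[genome_ids, trait].to_numpy()
        base = {
            "trait_id": trait, "predictor": names[1] if len(names) == 2 else "factor",
        }
        try:
            fit = phylo_logistic_fit(
                yv, X, tree, B=B, seed=trait_seed(seed, str(trait)),
                trait_id=str(trait), coef_names=names, _arrays=arrays,
            )
        except ValueError as exc:
            rows.append({**base, "estimate": np.nan, "se": np.nan,
                         "alpha": np.nan, "p_wald": np.nan, "p_boot": np.nan,
                         "significant": False, "direction": "none",
                         "converged": False, "note": str(exc)})
            continue
        for j in range(1, len(names)):
            est = float(fit.beta[j])
            pb = float(fit.p_boot[j])
            rows.append({
                "trait_id": trait,
                "predictor": names[j],
                "estimate": est,
                "se": float(fit.se[j]),
                "alpha": fit.alpha,
                "p_wald": float(fit.p_wald[j]),
                "p_boot": pb,
                "significant": bool(pb < alpha_level),
                "direction": "enriched" if est > 0 else "depleted",
                "converged": fit.converged,
                "note": "separation" if fit.separation else "",
            })
    return _scan_frame(rows)


def count_enrichment_scan(
    counts: pd.DataFrame,
    predictor: pd.Series,
    tree: PhyloTree,
    alpha_level: float = 0.05,
    B: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Phylogenetic linear regression (lambda covariance) of each count
    column (total and per class) on the predictor; estimates are on the
    raw-count scale. All-zero / constant columns are flagged and excluded
    from the fitted rows."""
    genome_ids = [g for g in tree.tip_labels if g in counts.index]
    if len(genome_ids) != tree.n_tips:
        missing = set(tree.tip_labels) - set(counts.index)
        raise ValueError(f"count table missing tree tips: {sorted(missing)[:5]}")
    X, names = make_design(predictor, genome_ids)
    cache = _LambdaGLS(vcv_from_tree(tree))
    rows = []
    for col in counts.columns:
        yv = counts.loc[genome_ids, col].to_numpy(dtype=float)
        base = {"trait_id": col, "predictor": names[1] if len(names) == 2 else "factor"}
        if np.all(yv == yv[0]):
            rows.append({**base, "estimate": np.nan, "se": np.nan,
                         "lambda": np.nan, "p_wald": np.nan, "p_boot": np.nan,
                         "significant": False, "direction": "none",
                         "converged": False, "note": "constant response"})
            continue
        fit = phylo_linear_fit(
            yv, X, tree, B=B, seed=trait_seed(seed, str(col)), trait_id=str(col),
            coef_names=names, _cache=cache,
        )
        for j in range(1, len(names)):
            est = float(fit.beta[j])
            pb = float(fit.p_boot[j])
            rows.append({
                "trait_id": col,
                "predictor": names[j],
                "estimate": est,
                "se": float(fit.se[j]),
                "lambda": fit.lambda_,
                "p_wald": float(fit.p_wald[j]),
                "p_boot": pb,
                "significant": bool(pb < alpha_level),
                "direction": "enriched" if est > 0 else "depleted",
                "converged": fit.converged,
                "note": "",
            })
    return _scan_frame(rows)
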