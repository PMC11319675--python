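"""Fritz-Purvis D statistic: phylogenetic signal for binary traits.

The observed quantity is the sum of sister-clade differences: nodal values
are estimated tips-to-root (each internal node takes the arithmetic mean of
its children's values) and every internal node contributes the summed
absolute difference between each child's value and the node's value.
Polytomies simply sum over all children. This sum is then scaled between
two simulated expectations — random tip shuffles (expectation of D: 1) and
a Brownian threshold model (expectation of D: 0):

    D = (d_obs - mean d_Brownian) / (mean d_random - mean d_Brownian)

Clumped traits give D < 0; overdispersed traits give D > 1. Both null sets
preserve the observed prevalence exactly (the Brownian liabilities are cut
at the empirical quantile), so d values are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = [
    "DStatResult",
    "sum_sister_differences",
    "simulate_brownian_threshold",
    "d_statistic",
    "d_statistic_scan",
]


@dataclass
class DStatResult:
    trait_id: str
    d_obs: float
    d_random_mean: float
    d_brownian_mean: float
    D: float
    p_random: float
    p_brownian: float
    n_null: int
    seed: int


def _sister_differences_multi(tree: PhyloTree, Y: np.ndarray) -> np.ndarray:
    """Sum of sister-clade differences for each column of ``Y`` (n_tips, K)."""
    n_nodes = tree.n_nodes
    K = Y.shape[1]
    vals = np.zeros((n_nodes, K))
    vals[: tree.n_tips] = Y
    d = np.zeros(K)
    for u in tree.postorder:
        kids = tree.children[u]
        if not kids:
            continue
        child_vals = vals[kids]  # (n_kids, K)
        node_val = child_vals.mean(axis=0)
        vals[u] = node_val
        d += np.abs(child_vals - node_val[None, :]).sum(axis=0)
    return d


def sum_sister_differences(tree: PhyloTree, y: Dict[str, float] | np.ndarray) -> float:
    """Observed sum of sister-clade differences for one binary trait.

    ``y`` is either an array aligned with ``tree.tip_labels`` or a mapping
    from tip label to 0/1 value (every tip must be present).
    """
    if isinstance(y, dict):
        missing = [t for t in tree.tip_labels if t not in y]
        if missing:
            raise ValueError(f"tips without trait value: {missing[:5]}")
        arr = np.asarray([y[t] for t in tree.tip_labels], dtype=float)
    else:
        arr = np.asarray(y, dtype=float)
        if arr.shape[0] != tree.n_tips:
            raise ValueError("trait vector length must equal the number of tips")
    return float(_sister_differences_multi(tree, arr[:, None])[0])


def _threshold_by_prevalence(liab: np.ndarray, k_ones: int) -> np.ndarray:
    """Binarize liability columns so that exactly ``k_ones`` tips are 1
    (the tips with the largest liabilities; ties broken by index order)."""
    n, K = liab.shape
    out = np.zeros((n, K), dtype=np.int8)
    if k_ones > 0:
        idx = np.argpartition(-liab, k_ones - 1, axis=0)[:k_ones]
        np.put_along_axis(out, idx, 1, axis=0)
    return out


def simulate_brownian_threshold(
    tree: PhyloTree,
    prevalence: float,
    seed: int = 0,
    size: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Brownian-threshold binary traits with exact prevalence.

    A Brownian liability (root 0, per-branch variance equal to branch
    length) is simulated along the tree; tip liabilities are thresholded at
    the empirical quantile so that exactly ``round(prevalence * n)`` tips
    are 1. Returns an (n_tips, size) int array.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be strictly between 0 and 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = tree.n_tips
    k_ones = int(round(prevalence * n))
    if k_ones == 0 or k_ones == n:
        raise ValueError("prevalence rounds to a degenerate trait")
    Z = rng.standard_normal((tree.n_nodes, size))
    liab = np.zeros((tree.n_nodes, size))
    sd = np.sqrt(tree.branch_length)
    for u in tree.preorder:
        p = tree.parent[u]
        if p >= 0:
            liab[u] = liab[p] + sd[u] * Z[u]
    return _threshold_by_prevalence(liab[:n], k_ones)


def d_statistic(
    tree: PhyloTree,
    y: Dict[str, float] | np.ndarray,
    n_null: int = 1000,
    seed: int = 0,
    trait_id: str = "trait",
) -> DStatResult:
    """Fritz-Purvis D with permutation and Brownian-threshold null sets.

    ``p_random`` is the fraction of permuted-tip d values <= d_obs (small
    when the trait is more clumped than random); ``p_brownian`` is the
    fraction of Brownian-threshold d values >= d_obs.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    if isinstance(y, dict):
        arr = np.asarray([y[t] for t in tree.tip_labels], dtype=np.int8)
    else:
        arr = np.asarray(y, dtype=np.int8)
    uniq = set(np.unique(arr).tolist())
    if not uniq == {0, 1}:
        raise ValueError("trait must contain both states 0 and 1")
    n = tree.n_tips
    k_ones = int(arr.sum())
    d_obs = sum_sister_differences(tree, arr.astype(float))

    rng = np.random.default_rng(seed)
    # permutation null: shuffle tip labels, preserving prevalence
    perm = np.empty((n, n_null), dtype=np.int8)
    for j in range(n_null):
        perm[:, j] = rng.permutation(arr)
    d_rand = _sister_differences_multi(tree, perm.astype(float))
    # Brownian-threshold null at the same prevalence
    brow = simulate_brownian_threshold(tree, k_ones / n, rng=rng, size=n_null)
    d_brow = _sister_differences_multi(tree, brow.astype(float))

    mean_r = float(d_rand.mean())
    mean_b = float(d_brow.mean())
    denom = mean_r - mean_b
    D = float((d_obs - mean_b) / denom) if denom != 0 else float("nan")
    return DStatResult(
        trait_id=trait_id,
        d_obs=float(d_obs),
        d_random_mean=mean_r,
        d_brownian_mean=mean_b,
        D=D,
        p_random=float(np.mean(d_rand <= d_obs)),
        p_brownian=float(np.mean(d_brow >= d_obs)),
        n_null=n_null,
        seed=seed,
    )


def d_statistic_scan(
    tm: pd.DataFrame,
    tree: PhyloTree,
    n_null: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """D statistic for every binary trait column of ``tm`` (rows indexed by
    genome id and covering all tree tips)."""
    columns = ["trait_id", "d_obs", "D", "p_random", "p_brownian",
               "n_null", "seed", "note"]
    rows = []
    for trait in tm.columns:
        yv = tm.loc[list(tree.tip_labels), trait].to_numpy()
        base = {"trait_id": str(trait), "n_null": n_null, "seed": seed}
        try:
            res = d_statistic(tree, yv, n_null=n_null, seed=seed, trait_id=str(trait))
        except ValueError as exc:
            rows.append({**base, "d_obs": np.nan, "D": np.nan,
                         "p_random": np.nan, "p_brownian": np.nan,
                         "note": str(exc)})
            continue
        rows.append({
            "trait_id": str(trait), "d_obs": res.d_obs, "D": res.D,
            "p_random": res.p_random, "p_brownian": res.p_brownian,
            "n_null": n_null, "seed": seed, "note": "",
        })
    return pd.DataFrame(rows, columns=columns)
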