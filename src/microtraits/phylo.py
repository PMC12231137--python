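"""Trees, phylofactorization and phylogenetic signal.

Covers neighbor-joining tree construction from a distance matrix,
ILR-balance phylofactorization of a community table against a covariate,
and the two standard phylogenetic-signal statistics (Blomberg's K and
Pagel's lambda) plus phylogenetic generalized least squares.

Signal statistics need a root to define shared-path covariances; the
unrooted working trees are midpoint-rooted internally for that purpose
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from skbio import DistanceMatrix, TreeNode

from .tables_io import logger

# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classic Saitou-Nei neighbor joining.

    Iteratively agglomerates the pair minimising the Q criterion.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch, so pairwise path lengths are preserved where
    possible.  The returned tree is unrooted (trifurcating root).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=str(t)) for t in dm.ids]

    while len(nodes) > 3:
        r = len(nodes)
        sums = d.sum(axis=1)
        q = (r - 2) * d - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.extend([nodes[i], nodes[j]])
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d_new = np.empty((r - 1, r - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        d = d_new

    # terminal three-point configuration
    l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode()
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = max(ln, 0.0)
        root.append(node)
    return root


# ---------------------------------------------------------------------------
# shared-path covariance


def phylo_covariance(tree: TreeNode, taxa: list[str] | None = None) -> pd.DataFrame:
    """Shared-path-length covariance matrix of tips.

    The tree is midpoint-rooted (a root convention is required on an
    unrooted tree) and C[i, j] is the depth of the most recent common
    ancestor of tips i and j.
    """
    work = tree.copy()
    if len(work.children) != 2:
        work = work.root_at_midpoint()
    tips = [t.name for t in work.tips()]
    depth: dict[str, float] = {}
    node_depth = {id(work): 0.0}
    for node in work.preorder(include_self=False):
        nd = node_depth[id(node.parent)] + (node.length or 0.0)
        node_depth[id(node)] = nd
        if node.is_tip():
            depth[node.name] = nd
    dmat = work.tip_tip_distances(list(tips))
    dvec = np.array([depth[t] for t in tips])
    c = 0.5 * (dvec[:, None] + dvec[None, :] - dmat.data)
    np.fill_diagonal(c, dvec)
    out = pd.DataFrame(c, index=tips, columns=tips)
    if taxa is not None:
        out = out.loc[list(taxa), list(taxa)]
    return out


# ---------------------------------------------------------------------------
# ILR balances and phylofactorization


def ilr_balance(
    counts: pd.DataFrame,
    group_r,
    group_s,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Isometric log-ratio balance between two disjoint taxon groups.

    Per sample: ``sqrt(r*s/(r+s)) * ln(gm_R / gm_S)`` with geometric means
    taken over relative abundances after adding ``pseudocount`` to the
    counts and re-closing each sample.
    """
    group_r, group_s = list(group_r), list(group_s)
    if set(group_r) & set(group_s):
        raise ValueError("ILR groups overlap")
    if not group_r or not group_s:
        raise ValueError("ILR groups must be non-empty")
    mat = counts.to_numpy(dtype=float) + pseudocount
    rel = mat / mat.sum(axis=0, keepdims=True)
    logrel = pd.DataFrame(np.log(rel), index=counts.index, columns=counts.columns)
    r, s = len(group_r), len(group_s)
    y = np.sqrt(r * s / (r + s)) * (
        logrel.loc[group_r].mean(axis=0) - logrel.loc[group_s].mean(axis=0)
    )
    return y.rename("ilr_balance")


@dataclass
class Factor:
    """One phylofactorization step."""

    index: int
    edge: str                      # stable identifier of the winning edge
    group_r: frozenset             # tips on the edge's far side within the bin
    group_s: frozenset             # remainder of the bin
    objective: float
    p_value: float
    significant: bool


@dataclass
class PhyloFactorResult:
    factors: list[Factor] = field(default_factory=list)
    bins: list[frozenset] = field(default_factory=list)
    mode: str = "taxon"
    alpha: float = 0.01

    @property
    def n_significant(self) -> int:
        return sum(f.significant for f in self.factors)


def _edge_table(tree: TreeNode):
    """Stable edge enumeration: (edge_id, child_node, below tip set)."""
    edges = []
    for k, node in enumerate(tree.preorder(include_self=False)):
        below = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        label = node.name if node.is_tip() else f"edge{k:04d}"
        edges.append((f"{label}", node, below))
    return edges


def phylofactor(
    counts: pd.DataFrame,
    tree: TreeNode,
    covariate: pd.Series,
    mode: str = "taxon",
    n_factors: int = 15,
    alpha: float = 0.01,
    pseudocount: float = 1.0,
) -> PhyloFactorResult:
    """Greedy edge-wise phylofactorization.

    At each step every tree edge interior to a current bin is scored and
    the best edge splits its bin in two.  In ``"taxon"`` mode the
    objective is the absolute two-sample t statistic comparing a
    per-taxon covariate (e.g. SNB) between the edge's two groups; in
    ``"sample"`` mode it is the regression F statistic of the groups' ILR
    balance on a per-sample covariate.
    """
    if mode not in ("taxon", "sample"):
        raise ValueError("mode must be 'taxon' or 'sample'")
    tips = {t.name for t in tree.tips()}
    if mode == "taxon":
        missing = [t for t in tips if t not in covariate.index or pd.isna(covariate[t])]
        if missing:
            raise ValueError(f"covariate missing for taxa: {missing[:5]} ...")
    else:
        missing = [
            s for s in counts.columns if s not in covariate.index or pd.isna(covariate[s])
        ]
        if missing:
            raise ValueError(f"covariate missing for samples: {missing[:5]} ...")

    edges = _edge_table(tree)
    n_internal_splits = len(edges)
    if n_factors > n_internal_splits:
        logger.warning(
            "phylofactor: requested %d factors but only %d edges; truncating",
            n_factors,
            n_internal_splits,
        )
        n_factors = n_internal_splits

    cut: set[str] = set()
    result = PhyloFactorResult(mode=mode, alpha=alpha)

    # bin bookkeeping: a tip -> bin map, updated after each split
    bin_of: dict[str, int] = {t: 0 for t in tips}
    bins: dict[int, frozenset] = {0: frozenset(tips)}
    next_bin = 1

    for step in range(n_factors):
        best = None
        for edge_id, node, below in edges:
            if edge_id in cut:
                continue
            # the edge lives in the unique bin it splits into two non-empty
            # parts; for every other bin its below-set is all or nothing
            tally: dict[int, int] = {}
            for t in below:
                b = bin_of[t]
                tally[b] = tally.get(b, 0) + 1
            b = next(
                (bb for bb, cnt in tally.items() if 0 < cnt < len(bins[bb])), None
            )
            if b is None:
                continue
            bin_tips = bins[b]
            g1 = below & bin_tips
            g2 = bin_tips - g1
            score, p = _edge_objective(counts, covariate, g1, g2, mode, pseudocount)
            if score is None:
                continue
            if best is None or score > best[0]:
                best = (score, p, edge_id, g1, g2, b)
        if best is None:
            logger.warning("phylofactor: no splittable bins left after %d factors", step)
            break
        score, p, edge_id, g1, g2, b = best
        cut.add(edge_id)
        bins[b] = g1
        bins[next_bin] = g2
        for t in g2:
            bin_of[t] = next_bin
        next_bin += 1
        result.factors.append(
            Factor(
                index=step + 1,
                edge=edge_id,
                group_r=frozenset(g1),
                group_s=frozenset(g2),
                objective=float(score),
                p_value=float(p),
                significant=bool(p < alpha),
            )
        )
    result.bins = list(bins.values())
    logger.info(
        "phylofactor: %d factors, %d significant at %g",
        len(result.factors),
        result.n_significant,
        alpha,
    )
    return result


def _edge_objective(counts, covariate, g1, g2, mode, pseudocount):
    if mode == "taxon":
        x = covariate.loc[list(g1)].to_numpy(dtype=float)
        y = covariate.loc[list(g2)].to_numpy(dtype=float)
        if len(x) + len(y) < 3:
            return None, None
        t, p = stats.ttest_ind(x, y, equal_var=True)
        if np.isnan(t):
            return None, None
        return abs(float(t)), float(p)
    balance = ilr_balance(counts, g1, g2, pseudocount)
    z = covariate.loc[balance.index].to_numpy(dtype=float)
    if np.std(z) == 0 or len(z) < 3:
        return None, None
    fit = stats.linregress(z, balance.to_numpy())
    t2 = fit.slope**2 / fit.stderr**2 if fit.stderr > 0 else np.inf
    return float(t2), float(fit.pvalue)


def factor_balances(
    counts: pd.DataFrame, result: PhyloFactorResult, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-sample ILR balances of every recorded factor (columns)."""
    cols = {}
    for f in result.factors:
        cols[f"factor{f.index}"] = ilr_balance(
            counts, f.group_r, f.group_s, pseudocount
        )
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# phylogenetic signal


def _align(tree: TreeNode, tip_values: pd.Series):
    c = phylo_covariance(tree)
    taxa = [t for t in c.index if t in tip_values.index]
    if len(taxa) < 3:
        raise ValueError("need at least 3 tips with values")
    y = tip_values.loc[taxa].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("tip values contain missing entries")
    return c.loc[taxa, taxa].to_numpy(), y, taxa


def _k_ratio(y: np.ndarray, cinv: np.ndarray) -> float:
    n = len(y)
    ones = np.ones(n)
    denom = ones @ cinv @ ones
    ahat = (ones @ cinv @ y) / denom
    resid = y - ahat
    mse0 = resid @ resid / (n - 1)
    mse = resid @ cinv @ resid / (n - 1)
    return mse0 / mse


def blomberg_k(
    tree: TreeNode,
    tip_values: pd.Series,
    n_perm: int = 999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Blomberg's K with a permutation p-value.

    K is the observed MSE0/MSE ratio scaled by its Brownian-motion
    expectation on the same tree; K = 1 under Brownian evolution, K < 1
    when signal is weaker.  The p-value is the proportion of tip-label
    permutations whose ratio reaches the observed one.
    """
    c, y, _ = _align(tree, tip_values)
    if np.ptp(y) == 0:
        raise ValueError("tip values are constant; K undefined")
    n = len(y)
    cinv = np.linalg.inv(c)
    ones = np.ones(n)
    expected = (np.trace(c) - n / (ones @ cinv @ ones)) / (n - 1)
    obs_ratio = _k_ratio(y, cinv)
    k = obs_ratio / expected
    if n_perm <= 0:
        return float(k), float("nan")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _k_ratio(rng.permutation(y), cinv) >= obs_ratio:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return float(k), float(p)


def _lambda_loglik(lam: float, c: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    cl = lam * c
    np.fill_diagonal(cl, np.diag(c))
    try:
        cf = cho_factor(cl)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ones = np.ones(n)
    cinv_y = cho_solve(cf, y)
    cinv_1 = cho_solve(cf, ones)
    mu = (ones @ cinv_y) / (ones @ cinv_1)
    resid = y - mu
    sigma2 = resid @ cho_solve(cf, resid) / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagel_lambda(tree: TreeNode, tip_values: pd.Series) -> tuple[float, float]:
    """Maximum-likelihood Pagel's lambda on [0, 1].

    Off-diagonal covariances are scaled by lambda; mean and variance are
    profiled analytically and lambda maximised by bounded scalar
    optimisation (tolerance 1e-6).
    """
    c, y, _ = _align(tree, tip_values)
    if np.ptp(y) == 0:
        raise ValueError("tip values are constant; lambda undefined")
    res = optimize.minimize_scalar(
        lambda lam: -_lambda_loglik(lam, c, y),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [(res.x, -res.fun), (0.0, _lambda_loglik(0.0, c, y)),
                  (1.0, _lambda_loglik(1.0, c, y))]
    lam, ll = max(candidates, key=lambda t: t[1])
    return float(lam), float(ll)


def pgls(
    tree: TreeNode,
    y: pd.Series,
    x: pd.DataFrame,
    lam: float | None = None,
) -> pd.DataFrame:
    """Phylogenetic GLS regression of y on predictors x (plus intercept).

    The phylogenetic covariance uses Pagel's lambda — supplied, or
    estimated by profiling the regression likelihood over [0, 1].
    Returns a coefficient table with Wald t-tests on n - p degrees of
    freedom.
    """
    c_full = phylo_covariance(tree)
    taxa = [t for t in c_full.index if t in y.index and t in x.index]
    c = c_full.loc[taxa, taxa].to_numpy()
    yv = y.loc[taxa].to_numpy(dtype=float)
    xmat = np.column_stack([np.ones(len(taxa)), x.loc[taxa].to_numpy(dtype=float)])
    names = ["intercept", *list(x.columns)]
    if np.linalg.matrix_rank(xmat) < xmat.shape[1]:
        raise ValueError("design matrix is rank deficient")

    def fit(lmb):
        cl = lmb * c
        np.fill_diagonal(cl, np.diag(c))
        cf = cho_factor(cl)
        xtci_x = xmat.T @ cho_solve(cf, xmat)
        xtci_y = xmat.T @ cho_solve(cf, yv)
        beta = np.linalg.solve(xtci_x, xtci_y)
        resid = yv - xmat @ beta
        rss = resid @ cho_solve(cf, resid)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        n = len(yv)
        sigma2_ml = rss / n
        ll = (
            -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
            if sigma2_ml > 0
            else np.inf if rss == 0 else -np.inf
        )
        return beta, rss, xtci_x, ll

    if lam is None:
        res = optimize.minimize_scalar(
            lambda lmb: -fit(lmb)[3],
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        cand = [(res.x, fit(res.x)[3]), (0.0, fit(0.0)[3]), (1.0, fit(1.0)[3])]
        lam = max(cand, key=lambda t: t[1])[0]
    beta, rss, xtci_x, _ = fit(lam)
    n, p = xmat.shape
    sigma2 = rss / max(n - p, 1)
    cov = sigma2 * np.linalg.inv(xtci_x)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=max(n - p, 1))
    out = pd.DataFrame(
        {"coef": beta, "se": se, "t": tvals, "p": pvals}, index=names
    )
    out.attrs["lambda"] = float(lam)
    out.attrs["n"] = n
    return out
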