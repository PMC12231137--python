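"""Community filtering, rarefaction, diversity and ordination.

The preparation order is fixed: remove organelle and non-prokaryote
taxa, drop shallow samples (< 8000 reads by default), then rarefy every
remaining sample to a common depth (7555 reads by default) before any
dissimilarity, diversity or trait-weighting step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS, smacof

from .tables_io import RANKS, logger

#: default minimum per-sample read count
MIN_READS = 8000
#: default rarefaction depth
RAREFACTION_DEPTH = 7555

_ORGANELLES = ("chloroplast", "mitochondria")
_KEEP_DOMAINS = {"Bacteria", "Archaea"}


@dataclass
class OrdinationResult:
    """2-D non-metric MDS configuration with Kruskal stress-1."""

    coordinates: pd.DataFrame  # sample_id x (NMDS1, NMDS2, ...)
    stress: float


def filter_taxa(counts: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Drop organelle reads and taxa outside Bacteria/Archaea.

    A taxon is removed when any rank of its lineage is Chloroplast or
    Mitochondria (case-insensitive), or when its domain is not Bacteria or
    Archaea.  Taxa absent from the taxonomy count as unclassified at the
    domain rank and are removed.
    """
    keep = []
    n_organelle = n_domain = n_untaxed = 0
    for tid in counts.index:
        if tid not in taxonomy.index:
            n_untaxed += 1
            continue
        lineage = taxonomy.loc[tid, list(RANKS)]
        if any(str(v).lower() in _ORGANELLES for v in lineage):
            n_organelle += 1
            continue
        if lineage["domain"] not in _KEEP_DOMAINS:
            n_domain += 1
            continue
        keep.append(tid)
    if not keep:
        raise ValueError("taxon filtering removed every taxon")
    removed = counts.shape[0] - len(keep)
    if removed:
        logger.info(
            "filter_taxa: removed %d/%d taxa (%d organelle, %d non-prokaryote, "
            "%d without taxonomy)",
            removed,
            counts.shape[0],
            n_organelle,
            n_domain,
            n_untaxed,
        )
    return counts.loc[keep]


def filter_samples(counts: pd.DataFrame, min_reads: int = MIN_READS) -> pd.DataFrame:
    """Drop samples whose total read count is below ``min_reads``."""
    sums = counts.sum(axis=0)
    keep = sums[sums >= min_reads].index
    if len(keep) == 0:
        raise ValueError(f"all samples fall below {min_reads} reads")
    dropped = counts.shape[1] - len(keep)
    if dropped:
        logger.info(
            "filter_samples: removed %d/%d samples below %d reads",
            dropped,
            counts.shape[1],
            min_reads,
        )
    return counts[keep]


def rarefy(
    counts: pd.DataFrame, depth: int = RAREFACTION_DEPTH, seed: int | None = 0
) -> pd.DataFrame:
    """Subsample each sample to ``depth`` reads without replacement.

    A single multivariate-hypergeometric draw per sample; every output
    column sums exactly to ``depth``.  Samples already at exactly
    ``depth`` reads are returned unchanged.
    """
    sums = counts.sum(axis=0)
    short = sums[sums < depth]
    if len(short):
        raise ValueError(
            f"samples below rarefaction depth {depth}: {short.index.tolist()}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty(counts.shape, dtype=np.int64)
    mat = counts.to_numpy()
    for j in range(counts.shape[1]):
        col = mat[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    logger.info("rarefy: %d samples drawn to depth %d", counts.shape[1], depth)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def bray_curtis(counts: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples (columns)."""
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sums = counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-sum samples: {zero.index.tolist()}")
    data = squareform(pdist(counts.to_numpy().T, metric="braycurtis"))
    return DistanceMatrix(data, ids=[str(c) for c in counts.columns])


def _stress1(config_d: np.ndarray, diss: np.ndarray) -> float:
    """Kruskal stress-1 against a monotone regression of distances on
    dissimilarities (ties averaged — Kruskal's primary approach)."""
    order = np.argsort(diss, kind="mergesort")
    iso = IsotonicRegression(increasing=True)
    fitted = np.empty_like(config_d)
    fitted[order] = iso.fit_transform(diss[order], config_d[order])
    denom = np.sum(config_d**2)
    return float(np.sqrt(np.sum((config_d - fitted) ** 2) / denom))


def nmds(
    dm: DistanceMatrix, n_dim: int = 2, seed: int = 0, restarts: int = 20
) -> OrdinationResult:
    """Non-metric multidimensional scaling, best of several starts.

    Runs ``restarts`` random SMACOF starts plus one start initialised from
    the metric (classical-style) MDS solution, and returns the
    configuration with the lowest Kruskal stress-1.  Coordinates are
    centred at the origin.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("NMDS needs at least 3 samples")
    if n_dim >= n:
        raise ValueError(f"n_dim ({n_dim}) must be below sample count ({n})")
    diss = dm.data
    tri = np.triu_indices(n, k=1)
    flat = diss[tri]

    candidates = []
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mds = MDS(
            n_components=n_dim,
            metric=False,
            dissimilarity="precomputed",
            n_init=restarts,
            random_state=seed,
            normalized_stress=True,
            eps=1e-9,
            max_iter=500,
        )
        candidates.append(mds.fit_transform(diss))
        # metric-MDS-initialised start
        metric_init = MDS(
            n_components=n_dim,
            metric=True,
            dissimilarity="precomputed",
            n_init=4,
            random_state=seed,
            eps=1e-9,
            max_iter=500,
        ).fit_transform(diss)
        coords, _ = smacof(
            diss,
            metric=False,
            n_components=n_dim,
            init=metric_init,
            n_init=1,
            random_state=seed,
            normalized_stress=True,
            eps=1e-9,
            max_iter=500,
        )
        candidates.append(coords)

    best, best_stress = None, np.inf
    for cand in candidates:
        d = squareform(
            np.sqrt(((cand[:, None, :] - cand[None, :, :]) ** 2).sum(-1)),
            checks=False,
        )
        s = _stress1(d, flat)
        if s < best_stress:
            best, best_stress = cand, s
    best = best - best.mean(axis=0)
    cols = [f"NMDS{i + 1}" for i in range(n_dim)]
    return OrdinationResult(
        coordinates=pd.DataFrame(best, index=list(dm.ids), columns=cols),
        stress=best_stress,
    )


def simpson_diversity(counts: pd.DataFrame) -> pd.Series:
    """Gini-Simpson diversity 1 - sum(p_i^2) per sample."""
    sums = counts.sum(axis=0)
    if (sums <= 0).any():
        bad = sums[sums <= 0].index.tolist()
        raise ValueError(f"non-positive sample sums: {bad}")
    p = counts.to_numpy(dtype=float) / sums.to_numpy()
    return pd.Series(1.0 - (p**2).sum(axis=0), index=counts.columns, name="simpson")


def aggregate_rank(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum counts to a taxonomic rank; unclassified labels form one group."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    labels = taxonomy.reindex(counts.index)[rank].fillna("unclassified")
    return counts.groupby(labels.to_numpy()).sum()


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def phylum_env_correlations(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    meta: pd.DataFrame,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman screen of phylum relative abundances vs environment.

    Counts are aggregated to phylum relative abundances; for each
    (phylum, variable) pair the Spearman rho and p-value are computed and
    p-values are Benjamini-Hochberg adjusted across the whole screen.
    Stars refer to the adjusted p at 0.001/0.01/0.05.  A constant variable
    or phylum yields missing rho.
    """
    from statsmodels.stats.multitest import multipletests

    if variables is None:
        variables = [
            c
            for c in ("pH", "om_loi", "phosphorus", "potassium", "magnesium",
                      "sand", "silt", "clay")
            if c in meta.columns
        ]
    phyla = aggregate_rank(counts, taxonomy, "phylum")
    rel = phyla / phyla.sum(axis=0)
    shared = [s for s in counts.columns if s in meta.index]
    rows = []
    for phylum in rel.index:
        x = rel.loc[phylum, shared].to_numpy(dtype=float)
        for var in variables:
            y = meta.loc[shared, var].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(x[ok], y[ok])
            rows.append({"phylum": phylum, "variable": var, "rho": rho, "p": p})
    table = pd.DataFrame(rows)
    mask = table["p"].notna()
    table["p_adj"] = np.nan
    if mask.any():
        table.loc[mask, "p_adj"] = multipletests(
            table.loc[mask, "p"], method="fdr_bh"
        )[1]
    table["stars"] = [_stars(p) for p in table["p_adj"]]
    return table


def archaea_bacteria_ratio(
    counts: pd.DataFrame, taxonomy: pd.DataFrame
) -> pd.Series:
    """Per-sample archaeal:bacterial read ratio (missing when no bacteria)."""
    domain = taxonomy.reindex(counts.index)["domain"]
    arch = counts.loc[domain == "Archaea"].sum(axis=0)
    bact = counts.loc[domain == "Bacteria"].sum(axis=0)
    ratio = arch / bact.replace(0, np.nan)
    return ratio.rename("archaea_bacteria_ratio")
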