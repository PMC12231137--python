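"""Social niche breadth (SNB) from co-occurrence across samples.

A taxon's SNB is the mean Bray-Curtis dissimilarity between all pairs of
samples in which it occurs: a taxon found only in compositionally similar
communities scores low (specialist) and one spanning dissimilar
communities scores high (generalist).  Scores are undefined for taxa
occupying fewer than two samples — rarity is not evidence of extreme
specialism.  Per-sample community niche breadth is the abundance-weighted
mean of the member taxa's scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import community_prep
from .tables_io import logger

#: minimum occupancy for a defined score (one pair of samples)
MIN_OCCUPANCY = 2


def sample_profiles(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    rank: str = "asv",
) -> pd.DataFrame:
    """Per-sample relative-abundance profiles at a chosen aggregation level.

    ``rank="asv"`` keeps ASV resolution; any taxonomic rank aggregates
    counts first (taxonomy required).  Profiles are closed to sum 1.
    """
    if rank != "asv":
        if taxonomy is None:
            raise ValueError("taxonomy required for rank aggregation")
        counts = community_prep.aggregate_rank(counts, taxonomy, rank)
    sums = counts.sum(axis=0)
    if (sums == 0).any():
        bad = sums[sums == 0].index.tolist()
        raise ValueError(f"zero-sum samples: {bad}")
    return (counts / sums).T  # samples x features


def snb_scores(
    counts: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
    dissimilarity: str = "braycurtis",
) -> pd.DataFrame:
    """Per-taxon SNB score and occupancy.

    ``profiles`` defaults to ASV-level relative abundances of ``counts``;
    pass profiles aggregated at another rank to change the community
    representation the dissimilarities are computed on.
    """
    from scipy.spatial.distance import pdist, squareform

    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if profiles is None:
        profiles = sample_profiles(counts)
    profiles = profiles.loc[list(counts.columns)]
    d = squareform(pdist(profiles.to_numpy(), metric=dissimilarity))
    present = (counts.to_numpy() > 0).astype(float)  # taxa x samples
    occupancy = present.sum(axis=1)
    pair_sums = np.einsum("is,st,it->i", present, d, present) / 2.0
    n_pairs = occupancy * (occupancy - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = pair_sums / n_pairs
    scores[occupancy < MIN_OCCUPANCY] = np.nan
    out = pd.DataFrame(
        {"snb": scores, "occupancy": occupancy.astype(int)}, index=counts.index
    )
    out.index.name = "taxon_id"
    logger.info(
        "snb_scores: %d/%d taxa scored (occupancy >= %d)",
        int(out["snb"].notna().sum()),
        len(out),
        MIN_OCCUPANCY,
    )
    return out


def weighted_mean_snb(counts: pd.DataFrame, snb: pd.DataFrame) -> pd.Series:
    """Per-sample abundance-weighted mean SNB (``ave.snb``)."""
    scores = snb.reindex(counts.index)["snb"].to_numpy(dtype=float)
    defined = ~np.isnan(scores)
    w = counts.to_numpy(dtype=float)[defined, :]
    denom = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = (w * scores[defined, None]).sum(axis=0) / denom
    means[denom == 0] = np.nan
    return pd.Series(means, index=counts.columns, name="ave.snb")
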