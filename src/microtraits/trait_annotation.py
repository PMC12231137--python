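"""Per-ASV genomic trait assignment and community-weighted trait means.

Traits (genome size, rRNA operon copies, GC content) are looked up in a
rank-indexed reference.  Each ASV walks its lineage from the lowest
classified rank upward until the reference holds a value for the trait —
so a genus may supply GC content while the family supplies genome size.
The rank that supplied each value is recorded as provenance.  Per-sample
trait profiles are abundance-weighted means over the annotated taxa of
the rarefied table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables_io import RANKS, TRAIT_COLUMNS, UNCLASSIFIED, logger

#: traits that participate in rank-fallback assignment
ASSIGNED_TRAITS = ("genome_size", "rrna_copies", "gc")

#: provenance label for a trait no rank could supply
UNASSIGNED = "unassigned"

#: default minimum fraction of a sample's reads that must carry a trait
#: for downstream models to accept the sample
COVERAGE_FLOOR = 0.5


def build_reference_index(
    reference: pd.DataFrame, statistic: str = "mean"
) -> dict[str, pd.DataFrame]:
    """Aggregate reference rows into per-rank lookup tables.

    Multiple rows for the same (name, rank) are combined by ``statistic``
    (arithmetic mean by default, median via ``statistic="median"``).  When
    the reference carries lineage columns named after higher ranks, each
    row also contributes to its ancestors' aggregates, so a family lookup
    reflects all genomes below it.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    contributions: list[pd.DataFrame] = []
    base = reference.assign(_name=reference["taxon_name"], _rank=reference["rank"])
    contributions.append(base[["_name", "_rank", *TRAIT_COLUMNS]])
    lineage_cols = [c for c in RANKS if c in reference.columns]
    for col in lineage_cols:
        sub = reference[reference[col].notna() & (reference["rank"] != col)]
        if len(sub):
            contributions.append(
                sub.assign(_name=sub[col], _rank=col)[
                    ["_name", "_rank", *TRAIT_COLUMNS]
                ]
            )
    stacked = pd.concat(contributions, ignore_index=True)
    index: dict[str, pd.DataFrame] = {}
    for rank, grp in stacked.groupby("_rank"):
        agg = getattr(grp.groupby("_name")[list(TRAIT_COLUMNS)], statistic)()
        index[rank] = agg
    return index


def assign_traits(
    taxonomy: pd.DataFrame, index: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Walk ranks upward per ASV and per trait independently.

    Returns one row per taxon with the trait values and a
    ``provenance_<trait>`` column holding the rank that supplied each
    value (``"unassigned"`` when no rank did).
    """
    low_to_high = list(RANKS)[::-1]  # species .. domain
    rows = []
    for tid, lineage in taxonomy.iterrows():
        row: dict[str, object] = {"taxon_id": tid}
        classified = [
            r for r in low_to_high if lineage.get(r, UNCLASSIFIED) != UNCLASSIFIED
        ]
        for trait in ASSIGNED_TRAITS:
            value, prov = np.nan, UNASSIGNED
            for rank in classified:
                table = index.get(rank)
                if table is None:
                    continue
                name = lineage[rank]
                if name in table.index:
                    v = table.loc[name, trait]
                    if pd.notna(v):
                        value, prov = float(v), rank
                        break
            row[trait] = value
            row[f"provenance_{trait}"] = prov
        rows.append(row)
    out = pd.DataFrame(rows).set_index("taxon_id")
    n_missing = int(out[list(ASSIGNED_TRAITS)].isna().any(axis=1).sum())
    logger.info(
        "assign_traits: %d/%d taxa fully annotated",
        len(out) - n_missing,
        len(out),
    )
    return out


def consensus_rrna(
    assigned: pd.DataFrame, predicted: pd.Series | None = None
) -> pd.DataFrame:
    """Merge database and predicted rRNA copy numbers.

    Both present -> arithmetic mean (kept fractional), provenance
    ``"consensus"``; one present -> that source; neither -> missing.
    Non-positive predictions are rejected with a warning and the database
    value kept.
    """
    out = assigned.copy()
    if predicted is None:
        return out
    bad = predicted[predicted <= 0].index
    if len(bad):
        logger.warning(
            "consensus_rrna: rejected %d non-positive predicted values", len(bad)
        )
    pred = predicted.drop(bad).dropna()
    for tid in out.index:
        db = out.at[tid, "rrna_copies"]
        if tid not in pred.index:
            continue
        pv = float(pred.loc[tid])
        if pd.isna(db):
            out.at[tid, "rrna_copies"] = pv
            out.at[tid, "provenance_rrna_copies"] = "predicted"
        else:
            out.at[tid, "rrna_copies"] = 0.5 * (float(db) + pv)
            out.at[tid, "provenance_rrna_copies"] = "consensus"
    return out


def weighted_sample_traits(
    counts: pd.DataFrame,
    assigned: pd.DataFrame,
    snb: pd.DataFrame | None = None,
    simpson: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Abundance-weighted per-sample trait means from a rarefied table.

    For each sample and trait the mean is taken over taxa with the trait
    defined and a positive count, with weights renormalised over that
    annotated subset.  Returns ``(profile, coverage)``: the profile has
    columns ``ave.gs``, ``ave.rrna``, ``ave.gc`` (plus ``ave.snb`` when
    SNB scores are supplied and ``simpson`` when given); coverage holds
    the fraction of each sample's reads carrying each trait.
    """
    colmap = {"genome_size": "ave.gs", "rrna_copies": "ave.rrna", "gc": "ave.gc"}
    trait_values = {t: assigned.reindex(counts.index)[t] for t in ASSIGNED_TRAITS}
    if snb is not None:
        trait_values["snb"] = snb.reindex(counts.index)["snb"]
        colmap["snb"] = "ave.snb"
    mat = counts.to_numpy(dtype=float)
    totals = mat.sum(axis=0)
    profile = pd.DataFrame(index=counts.columns)
    coverage = pd.DataFrame(index=counts.columns)
    for trait, col in colmap.items():
        v = trait_values[trait].to_numpy(dtype=float)
        defined = ~np.isnan(v)
        w = mat[defined, :]
        denom = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = (w * v[defined, None]).sum(axis=0) / denom
        means[denom == 0] = np.nan
        profile[col] = means
        coverage[col] = np.where(totals > 0, denom / totals, np.nan)
        n_missing = int(np.isnan(means).sum())
        if n_missing:
            logger.warning(
                "weighted_sample_traits: %d samples lack any %s-annotated reads",
                n_missing,
                trait,
            )
    if simpson is not None:
        profile["simpson"] = simpson.reindex(counts.columns)
    for col in profile.columns:
        if col in coverage.columns:
            logger.info(
                "weighted_sample_traits: %s read coverage median %.3f",
                col,
                float(np.nanmedian(coverage[col])),
            )
    profile.index.name = "sample_id"
    coverage.index.name = "sample_id"
    return profile, coverage
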