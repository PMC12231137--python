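"""Readers and writers for the tabular and tree formats the pipeline touches.

Canonical table dialect is TSV with a literal ``taxon_id`` first header
cell; commas are used only for the sample-metadata file.  Taxonomy uses the
seven SILVA-style ranks (domain .. species) with the sentinel
``"unclassified"`` for missing names.  Trees travel as Newick and are
unrooted on read, since every downstream tree method here (ILR
phylofactorization, phylogenetic-signal statistics) is defined on unrooted
phylogenies.
"""

from __future__ import annotations

import io
import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger("microtraits")

#: positional taxonomic ranks, highest to lowest
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: name used for any missing taxonomic label
UNCLASSIFIED = "unclassified"

#: strings (case-insensitive) that normalize to the unclassified sentinel
_MISSING_TOKENS = {"", "na", "n/a", "nan", "none", "unclassified", "unassigned"}

ROTATIONS = ("arable", "mixed", "grass")


class TableFormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class NewickError(ValueError):
    """A tree file could not be parsed as Newick."""


def configure_logging(level: str = "INFO") -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# count tables


def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate an ASV-by-sample count table.

    Requires unique taxon and sample identifiers, at least one taxon and
    one sample, and non-negative integer counts.  Returns the table with an
    integer dtype.
    """
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate taxon ids: {dups}")
    if counts.columns.duplicated().any():
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate sample ids: {dups}")
    if counts.shape[0] < 1 or counts.shape[1] < 1:
        raise TableFormatError("count table needs at least 1 taxon and 1 sample")
    values = counts.to_numpy()
    bad = pd.isna(values) | ~np.isfinite(values.astype(float))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric count at taxon {counts.index[r]!r}, "
            f"sample {counts.columns[c]!r}"
        )
    fvals = values.astype(float)
    if (fvals < 0).any():
        r, c = np.argwhere(fvals < 0)[0]
        raise ValueError(
            f"negative count {fvals[r, c]:g} at taxon {counts.index[r]!r}, "
            f"sample {counts.columns[c]!r}"
        )
    if not np.allclose(fvals, np.round(fvals)):
        r, c = np.argwhere(~np.isclose(fvals, np.round(fvals)))[0]
        raise ValueError(
            f"non-integer count {fvals[r, c]!r} at taxon {counts.index[r]!r}, "
            f"sample {counts.columns[c]!r}"
        )
    out = counts.astype(np.int64)
    out.index.name = "taxon_id"
    return out


def _check_header_unique(path, sep: str) -> None:
    # pandas mangles duplicate header cells, so check the raw line
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        raise TableFormatError(f"duplicate sample ids: {dups}")


def read_count_table(path) -> pd.DataFrame:
    """Read a TSV count table (rows = taxa, columns = samples)."""
    _check_header_unique(path, "\t")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "taxon_id":
        raise TableFormatError(
            f"first header cell must be 'taxon_id', got {df.columns[0]!r}"
        )
    df = df.set_index("taxon_id")
    return validate_count_table(df)


def write_count_table(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# taxonomy


def _normalize_label(raw) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return UNCLASSIFIED
    s = str(raw).strip()
    # SILVA-style empty prefixes like "g__" normalize to unclassified
    if len(s) >= 3 and s[1:3] == "__":
        s = s[3:]
    if s.lower() in _MISSING_TOKENS:
        return UNCLASSIFIED
    return s


def validate_taxonomy(taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Normalize sentinels and enforce the unclassified-suffix rule.

    Once a rank is unclassified, every lower rank is coerced to
    unclassified too (with a logged warning when a repair happens).
    """
    missing = [r for r in RANKS if r not in taxonomy.columns]
    if missing:
        raise TableFormatError(f"taxonomy missing rank columns: {missing}")
    if taxonomy.index.duplicated().any():
        raise TableFormatError("duplicate taxon ids in taxonomy")
    tax = taxonomy[list(RANKS)].map(_normalize_label)
    repaired = 0
    arr = tax.to_numpy(dtype=object)
    for i in range(arr.shape[0]):
        seen_unclassified = False
        for j in range(arr.shape[1]):
            if seen_unclassified and arr[i, j] != UNCLASSIFIED:
                arr[i, j] = UNCLASSIFIED
                repaired += 1
            if arr[i, j] == UNCLASSIFIED:
                seen_unclassified = True
    if repaired:
        logger.warning(
            "taxonomy repair: truncated %d labels below an unclassified rank",
            repaired,
        )
    out = pd.DataFrame(arr, index=tax.index, columns=list(RANKS))
    out.index.name = "taxon_id"
    return out


def read_taxonomy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "taxon_id":
        raise TableFormatError(
            f"first header cell must be 'taxon_id', got {df.columns[0]!r}"
        )
    df = df.set_index("taxon_id")
    return validate_taxonomy(df)


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    out = taxonomy.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample metadata

_NUMERIC_META = (
    "pH",
    "om_loi",
    "phosphorus",
    "potassium",
    "magnesium",
    "sand",
    "silt",
    "clay",
)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    if meta.index.duplicated().any():
        raise TableFormatError("duplicate sample ids in metadata")
    if "pH" not in meta.columns:
        raise TableFormatError("metadata must contain a pH column")
    meta = meta.copy()
    for col in _NUMERIC_META:
        if col in meta.columns:
            meta[col] = pd.to_numeric(meta[col], errors="coerce")
    ph = meta["pH"].dropna()
    if ((ph <= 0) | (ph >= 14)).any():
        bad = ph[(ph <= 0) | (ph >= 14)].index.tolist()
        raise ValueError(f"pH outside (0, 14) for samples {bad}")
    if {"sand", "silt", "clay"} <= set(meta.columns):
        total = meta[["sand", "silt", "clay"]].sum(axis=1, skipna=False)
        off = total.dropna()[(total.dropna() < 99) | (total.dropna() > 101)]
        if len(off):
            raise ValueError(
                f"sand+silt+clay outside [99, 101] for samples {off.index.tolist()}"
            )
    if "rotation" in meta.columns:
        bad = set(meta["rotation"].dropna()) - set(ROTATIONS)
        if bad:
            raise ValueError(f"unknown rotation values: {sorted(bad)}")
    meta.index.name = "sample_id"
    return meta


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "sample_id":
        raise TableFormatError(
            f"first header cell must be 'sample_id', got {df.columns[0]!r}"
        )
    return validate_metadata(df.set_index("sample_id"))


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# trait reference

TRAIT_COLUMNS = ("genome_size", "rrna_copies", "gc", "coding_density")


def validate_trait_reference(ref: pd.DataFrame) -> pd.DataFrame:
    for col in ("taxon_name", "rank"):
        if col not in ref.columns:
            raise TableFormatError(f"trait reference missing column {col!r}")
    ref = ref.copy()
    bad_ranks = set(ref["rank"]) - set(RANKS)
    if bad_ranks:
        raise TableFormatError(f"unknown ranks in trait reference: {sorted(bad_ranks)}")
    for col in TRAIT_COLUMNS:
        if col in ref.columns:
            ref[col] = pd.to_numeric(ref[col], errors="coerce")
        else:
            ref[col] = np.nan
    gs = ref["genome_size"].dropna()
    if (gs <= 0).any():
        raise ValueError("genome_size must be positive where present")
    gc = ref["gc"].dropna()
    if ((gc <= 0) | (gc >= 100)).any():
        raise ValueError("gc must lie in (0, 100) where present")
    return ref


def read_trait_reference(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"taxon_name": str, "rank": str})
    return validate_trait_reference(df)


def write_trait_reference(ref: pd.DataFrame, path) -> None:
    ref.to_csv(path, sep="\t", index=False)


def read_predicted_rrna(path) -> pd.Series:
    """Read optional per-ASV predicted rRNA copy numbers (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "taxon_id":
        raise TableFormatError(
            f"first header cell must be 'taxon_id', got {df.columns[0]!r}"
        )
    df = df.set_index("taxon_id")
    col = df.columns[0]
    return pd.to_numeric(df[col], errors="coerce").rename("rrna_predicted")


# ---------------------------------------------------------------------------
# trees and distance matrices


def _as_unrooted(tree: TreeNode) -> TreeNode:
    """Collapse a rooted (degree-2 root) tree into its unrooted form."""
    if len(tree.children) == 2:
        tree.unroot()
    return tree


def read_newick(path) -> TreeNode:
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises format-specific errors
        raise NewickError(f"could not parse Newick file {path}: {exc}") from exc
    return _as_unrooted(tree)


def parse_newick(text: str) -> TreeNode:
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:
        raise NewickError(f"could not parse Newick string: {exc}") from exc
    return _as_unrooted(tree)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a labeled square distance matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise TableFormatError("distance matrix row and column labels differ")
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
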