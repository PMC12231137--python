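"""Synthetic pH-structured soil communities with known ground truth.

The generator emulates the statistical structure of a survey of managed
agricultural topsoils: ~245 samples spanning pH 5.6-8.7 with organic
matter weakly and positively coupled to pH, and a few hundred taxa whose
abundances follow Gaussian pH niches of heterogeneous width.  Genomic
traits are planted along the pH-optimum axis — genome size decreases and
GC content increases with pH optimum, and rRNA copy number is an affine
function of genome size — so downstream community-weighted trait means,
social niche breadth and phylogenetic-signal stages all have recoverable
targets.  pH optima evolve as Brownian motion on a Yule tree, which plants
phylogenetic signal for the phylofactorization and Blomberg's K / Pagel's
lambda stages; setting ``phylo_signal=False`` shuffles optima across tips
to produce a signal-free null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import tables_io
from .tables_io import RANKS, UNCLASSIFIED, logger


class ConfigError(ValueError):
    """A generator configuration is internally inconsistent."""


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic community generator.

    The defaults are the generator's study conditions: sample count, pH
    range, OM coupling and trait slopes mirror the survey the package is
    modelled on; they are not tuning parameters.
    """

    n_taxa: int = 300
    n_samples: int = 245
    mean_depth: int = 20_000
    depth_sd_log: float = 0.25          # lognormal spread of sampling depth
    n_low_depth_samples: int = 2        # forced below the 8000-read filter
    low_depth_range: tuple[int, int] = (2_000, 7_999)
    ph_range: tuple[float, float] = (5.6, 8.7)
    om_intercept: float = 2.52          # % LOI at pH 0 (extrapolated)
    om_slope: float = 0.725             # % LOI per pH unit -> r^2 ~ 0.08
    om_noise_sd: float = 2.2            # % LOI residual spread
    generalist_fraction: float = 0.3
    sigma_generalist: float = 1.5       # pH units, lognormal median
    sigma_specialist: float = 0.4
    sigma_log_sd: float = 0.2
    width_ph_coupling: float = 0.25     # wider niches at low pH optimum
    abundance_noise_sd: float = 0.7     # lognormal noise on expected composition
    gs_intercept: float = 4.7e6         # bp at pH optimum 5.5
    b_gs: float = 350_000.0             # bp lost per pH-optimum unit
    gs_noise_sd: float = 1.2e5          # bp
    gc_intercept: float = 55.0          # % at mid pH optimum
    b_gc: float = 3.0                   # % per pH-optimum unit
    gc_noise_sd: float = 1.0
    b_rrna: float = 1.7e-6              # copies per bp of genome size
    rrna_intercept: float = -3.5
    rrna_noise_sd: float = 0.6
    asvs_per_genus: int = 4
    genera_per_family: int = 5
    families_per_phylum: int = 3
    archaeal_phyla: int = 1             # leading phyla labelled Archaea
    p_unclassified_genus: float = 0.15
    reference_coverage: float = 0.7     # fraction of genera with genus rows
    n_contaminants: int = 0             # chloroplast/mitochondria spike-ins
    phylo_signal: bool = True
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_taxa < 2 or self.n_samples < 2:
            raise ConfigError("need at least 2 taxa and 2 samples")
        for name in (
            "generalist_fraction",
            "p_unclassified_genus",
            "reference_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_depth < self.n_taxa:
            raise ConfigError(
                f"mean depth {self.mean_depth} below taxon count {self.n_taxa}"
            )
        if self.n_low_depth_samples > self.n_samples:
            raise ConfigError("more forced low-depth samples than samples")
        return self


@dataclass
class SyntheticTruth:
    """Planted per-taxon and per-sample ground truth."""

    taxa: pd.DataFrame     # pH_optimum, niche_width, niche_class, traits, lineage
    samples: pd.DataFrame  # pH, om_loi, depth
    config: GeneratorConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# tree simulation (also used directly by phylogenetic-signal calibration)


def yule_tree(n_tips: int, rng: np.random.Generator, birth_rate: float = 1.0) -> TreeNode:
    """Simulate a pure-birth (Yule) tree with exponential branch lengths.

    Tips are labelled ``t0001`` onwards; the returned tree is rooted at the
    initial split (two children) — callers that need an unrooted tree
    should unroot it themselves.
    """
    if n_tips < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    root = TreeNode()
    first, second = TreeNode(length=0.0), TreeNode(length=0.0)
    root.extend([first, second])
    active = [first, second]
    while len(active) < n_tips:
        dt = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.length += dt
        idx = rng.integers(len(active))
        parent = active.pop(idx)
        kids = [TreeNode(length=0.0), TreeNode(length=0.0)]
        parent.extend(kids)
        active.extend(kids)
    dt = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length += dt
    width = len(str(n_tips))
    for i, tip in enumerate(root.tips()):
        tip.name = f"t{i + 1:0{width}d}"
    return root


def brownian_tips(
    tree: TreeNode, rng: np.random.Generator, sigma2: float = 1.0, x0: float = 0.0
) -> pd.Series:
    """Evolve a trait by Brownian motion along a rooted tree; tip values."""
    values: dict[int, float] = {id(tree): x0}
    for node in tree.preorder(include_self=False):
        bl = node.length or 0.0
        values[id(node)] = values[id(node.parent)] + rng.normal(
            0.0, np.sqrt(sigma2 * bl)
        )
    return pd.Series({tip.name: values[id(tip)] for tip in tree.tips()})


# ---------------------------------------------------------------------------
# generator


def _lineage_frame(cfg: GeneratorConfig, tip_names: list[str]) -> pd.DataFrame:
    """Nest tips into genera, families and phyla along the tip order."""
    n = len(tip_names)
    genus_idx = np.arange(n) // cfg.asvs_per_genus
    family_idx = genus_idx // cfg.genera_per_family
    phylum_idx = family_idx // cfg.families_per_phylum
    rows = []
    for i, tid in enumerate(tip_names):
        phylum = f"Phylum{phylum_idx[i] + 1:02d}"
        domain = "Archaea" if phylum_idx[i] < cfg.archaeal_phyla else "Bacteria"
        rows.append(
            {
                "taxon_id": tid,
                "domain": domain,
                "phylum": phylum,
                "class": f"Class{family_idx[i] + 1:03d}",
                "order": f"Order{family_idx[i] + 1:03d}",
                "family": f"Family{family_idx[i] + 1:03d}",
                "genus": f"Genus{genus_idx[i] + 1:04d}",
                "species": f"Species{i + 1:04d}",
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def generate_dataset(config: GeneratorConfig | None = None):
    """Generate one synthetic dataset.

    Returns ``(counts, taxonomy, metadata, trait_reference, tree, truth)``
    where the first four are the pipeline's standard tables, ``tree`` is
    the unrooted phylogeny over taxa and ``truth`` holds the planted
    per-taxon and per-sample parameters.
    """
    cfg = (config or GeneratorConfig()).validate()
    rng = np.random.default_rng(cfg.seed)

    # --- phylogeny and pH optima -----------------------------------------
    rooted = yule_tree(cfg.n_taxa, rng)
    bm = brownian_tips(rooted, rng)
    tip_names = list(bm.index)
    lo, hi = cfg.ph_range
    span = bm.max() - bm.min()
    margin = 0.1
    optima = (lo - margin) + (bm - bm.min()) / span * ((hi + margin) - (lo - margin))
    if not cfg.phylo_signal:
        optima = pd.Series(
            rng.permutation(optima.to_numpy()), index=optima.index
        )

    # --- niche widths ------------------------------------------------------
    n = cfg.n_taxa
    is_generalist = rng.random(n) < cfg.generalist_fraction
    base = np.where(is_generalist, cfg.sigma_generalist, cfg.sigma_specialist)
    sigma = base * np.exp(rng.normal(0.0, cfg.sigma_log_sd, n))
    mid = 0.5 * (lo + hi)
    sigma = sigma * np.exp(-cfg.width_ph_coupling * (optima.to_numpy() - mid))

    # --- true genomic traits ----------------------------------------------
    opt = optima.to_numpy()
    genome_size = (
        cfg.gs_intercept
        - cfg.b_gs * (opt - 5.5)
        + rng.normal(0.0, cfg.gs_noise_sd, n)
    )
    genome_size = np.clip(genome_size, 1.0e6, None)
    gc = np.clip(
        cfg.gc_intercept + cfg.b_gc * (opt - mid) + rng.normal(0.0, cfg.gc_noise_sd, n),
        20.001,
        79.999,
    )
    rrna = np.clip(
        cfg.rrna_intercept
        + cfg.b_rrna * genome_size
        + rng.normal(0.0, cfg.rrna_noise_sd, n),
        1.0,
        15.0,
    )

    # --- samples -----------------------------------------------------------
    m = cfg.n_samples
    ph = rng.uniform(lo, hi, m)
    om = np.clip(
        cfg.om_intercept + cfg.om_slope * ph + rng.normal(0.0, cfg.om_noise_sd, m),
        0.5,
        None,
    )
    depths = np.maximum(
        rng.lognormal(np.log(cfg.mean_depth), cfg.depth_sd_log, m).astype(int),
        cfg.n_taxa,
    )
    low_lo, low_hi = cfg.low_depth_range
    for i in range(cfg.n_low_depth_samples):
        depths[i] = rng.integers(low_lo, low_hi + 1)
    sample_ids = [f"s{i + 1:03d}" for i in range(m)]

    # --- counts ------------------------------------------------------------
    # expected composition: Gaussian niche response x lognormal noise
    z = (ph[None, :] - opt[:, None]) / sigma[:, None]
    expected = np.exp(-0.5 * z**2)
    expected *= np.exp(rng.normal(0.0, cfg.abundance_noise_sd, expected.shape))
    expected += 1e-12  # keep every column a valid multinomial
    probs = expected / expected.sum(axis=0, keepdims=True)
    counts = np.empty((n, m), dtype=np.int64)
    for j in range(m):
        counts[:, j] = rng.multinomial(depths[j], probs[:, j])
    count_table = pd.DataFrame(counts, index=tip_names, columns=sample_ids)
    count_table.index.name = "taxon_id"

    # --- taxonomy ----------------------------------------------------------
    lineage = _lineage_frame(cfg, tip_names)
    unclassified_mask = rng.random(n) < cfg.p_unclassified_genus
    taxonomy = lineage.copy()
    taxonomy.loc[unclassified_mask, ["genus", "species"]] = UNCLASSIFIED

    # --- contaminants (optional spike-ins) ---------------------------------
    if cfg.n_contaminants:
        ids, rows, extra = [], [], []
        kinds = ["Chloroplast", "Mitochondria", "Eukaryota"]
        for k in range(cfg.n_contaminants):
            cid = f"contam{k + 1:02d}"
            kind = kinds[k % 3]
            ids.append(cid)
            if kind == "Eukaryota":
                rows.append(
                    dict(domain="Eukaryota", phylum=UNCLASSIFIED, **{
                        r: UNCLASSIFIED for r in RANKS[2:]
                    })
                )
            else:
                rank = "order" if kind == "Chloroplast" else "family"
                row = {r: UNCLASSIFIED for r in RANKS}
                row.update(domain="Bacteria", phylum="Cyanobacteria")
                row[rank] = kind
                rows.append(row)
            extra.append(rng.poisson(20, m))
        contam_tax = pd.DataFrame(rows, index=pd.Index(ids, name="taxon_id"))
        taxonomy = pd.concat([taxonomy, tables_io.validate_taxonomy(contam_tax)])
        contam_counts = pd.DataFrame(
            np.array(extra), index=ids, columns=sample_ids
        )
        count_table = pd.concat([count_table, contam_counts])
        count_table.index.name = "taxon_id"

    # --- metadata ----------------------------------------------------------
    texture = rng.dirichlet([4.0, 3.0, 2.0], m) * 100.0
    metadata = pd.DataFrame(
        {
            "pH": np.round(ph, 3),
            "om_loi": np.round(om, 3),
            "phosphorus": np.round(rng.lognormal(np.log(30), 0.4, m), 1),
            "potassium": np.round(rng.lognormal(np.log(180), 0.4, m), 1),
            "magnesium": np.round(rng.lognormal(np.log(90), 0.4, m), 1),
            "sand": np.round(texture[:, 0], 2),
            "silt": np.round(texture[:, 1], 2),
            "clay": np.round(texture[:, 2], 2),
            "rotation": rng.choice(
                ["arable", "mixed", "grass"], m, p=[0.85, 0.06, 0.09]
            ),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    metadata["clay"] = np.round(100.0 - metadata["sand"] - metadata["silt"], 2)

    # --- trait reference ----------------------------------------------------
    truth_taxa = pd.DataFrame(
        {
            "pH_optimum": opt,
            "niche_width": sigma,
            "niche_class": np.where(is_generalist, "generalist", "specialist"),
            "genome_size": genome_size,
            "rrna_copies": rrna,
            "gc": gc,
            "genus": lineage["genus"],
            "family": lineage["family"],
        },
        index=pd.Index(tip_names, name="taxon_id"),
    )
    reference = _build_reference(cfg, rng, truth_taxa)

    truth_samples = pd.DataFrame(
        {"pH": ph, "om_loi": om, "depth": depths},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SyntheticTruth(taxa=truth_taxa, samples=truth_samples, config=cfg)

    tree = rooted
    tree.unroot()
    logger.info(
        "generated synthetic dataset: %d taxa x %d samples, %d genera covered",
        count_table.shape[0],
        m,
        reference["rank"].eq("genus").sum(),
    )
    return count_table, taxonomy, metadata, reference, tree, truth


def _build_reference(
    cfg: GeneratorConfig, rng: np.random.Generator, truth_taxa: pd.DataFrame
) -> pd.DataFrame:
    """Genus rows for a covered fraction of genera; family rows for all.

    Genus values are the means of member taxa's true traits; family rows
    aggregate the genus means, so rank fallback lands on a value that is
    unbiased for the clade.
    """
    genus_means = truth_taxa.groupby("genus")[
        ["genome_size", "rrna_copies", "gc"]
    ].mean()
    genus_family = truth_taxa.groupby("genus")["family"].first()
    genera = genus_means.index.to_numpy()
    covered = rng.random(len(genera)) < cfg.reference_coverage
    rows = []
    for g, cov in zip(genera, covered):
        if cov:
            rows.append(
                {
                    "taxon_name": g,
                    "rank": "genus",
                    "genome_size": genus_means.loc[g, "genome_size"],
                    "rrna_copies": genus_means.loc[g, "rrna_copies"],
                    "gc": genus_means.loc[g, "gc"],
                    "coding_density": np.round(rng.uniform(85, 92), 2),
                }
            )
    fam_means = genus_means.assign(family=genus_family).groupby("family").mean(
        numeric_only=True
    )
    for f, row in fam_means.iterrows():
        rows.append(
            {
                "taxon_name": f,
                "rank": "family",
                "genome_size": row["genome_size"],
                "rrna_copies": row["rrna_copies"],
                "gc": row["gc"],
                "coding_density": np.round(rng.uniform(85, 92), 2),
            }
        )
    ref = pd.DataFrame(rows)
    ref["covered_genus"] = ref["rank"].eq("genus")
    ref = ref.drop(columns="covered_genus")
    return tables_io.validate_trait_reference(ref)


def expected_provenance(
    truth: SyntheticTruth, taxonomy: pd.DataFrame, reference: pd.DataFrame
) -> pd.Series:
    """Rank each ASV's traits should come from, by construction.

    Covered classified genus -> ``genus``; otherwise the family aggregate.
    Contaminant spike-ins (absent from truth) are excluded.
    """
    covered = set(reference.loc[reference["rank"] == "genus", "taxon_name"])
    out = {}
    for tid in truth.taxa.index:
        genus = taxonomy.loc[tid, "genus"]
        out[tid] = "genus" if genus in covered else "family"
    return pd.Series(out, name="expected_rank")


def truth_report(truth: SyntheticTruth, out_dir) -> dict[str, str]:
    """Export planted truth as TSV for recovery tests; returns paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    taxa_path = out / "truth_taxa.tsv"
    samples_path = out / "truth_samples.tsv"
    truth.taxa.to_csv(taxa_path, sep="\t")
    truth.samples.to_csv(samples_path, sep="\t")
    return {"taxa": str(taxa_path), "samples": str(samples_path)}


def config_from_dict(d: dict) -> GeneratorConfig:
    """Build a GeneratorConfig from a plain mapping (e.g. YAML section)."""
    known = {f.name for f in fields(GeneratorConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown generator keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("ph_range", "low_depth_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)
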