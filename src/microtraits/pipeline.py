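"""End-to-end orchestration: simulate/load -> filter -> rarefy -> annotate
-> SNB -> phylofactor & signal -> models, with a reproducibility manifest.

Every stage writes its outputs under the run directory and records a
SHA-256 digest in the manifest, so a rerun with the same configuration
and seed can be checked for bitwise identity.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    community_prep,
    phylo,
    snb as snb_mod,
    synthetic_data,
    tables_io,
    trait_annotation,
    trait_models,
)
from .tables_io import logger

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"enabled": True},
    "inputs": {},
    "filter": {"min_reads": community_prep.MIN_READS},
    "rarefy": {"depth": community_prep.RAREFACTION_DEPTH},
    "nmds": {"restarts": 20, "n_dim": 2},
    "snb": {"rank": "asv", "dissimilarity": "braycurtis"},
    "phylofactor": {"n_factors": 15, "alpha": 0.01, "mode": "taxon",
                    "pseudocount": 1.0},
    "models": {"basis_df": 10, "coverage_floor": 0.5},
}


def merge_config(overrides: dict | None) -> dict:
    """Deep-merge user overrides onto the default configuration."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _load_inputs(cfg: dict):
    paths = cfg.get("inputs", {})
    required = ("counts", "taxonomy", "metadata", "trait_reference")
    missing = [k for k in required if not paths.get(k)]
    if missing:
        raise PipelineError(
            f"stage load: simulate disabled and inputs missing: {missing}"
        )
    counts = tables_io.read_count_table(paths["counts"])
    taxonomy = tables_io.read_taxonomy(paths["taxonomy"])
    metadata = tables_io.read_metadata(paths["metadata"])
    reference = tables_io.read_trait_reference(paths["trait_reference"])
    predicted = (
        tables_io.read_predicted_rrna(paths["predicted_rrna"])
        if paths.get("predicted_rrna")
        else None
    )
    tree = tables_io.read_newick(paths["tree"]) if paths.get("tree") else None
    if tree is None and paths.get("distance_matrix"):
        dm = tables_io.read_distance_matrix(paths["distance_matrix"])
        tree = phylo.neighbor_joining(dm)
    return counts, taxonomy, metadata, reference, predicted, tree, None


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    cfg = merge_config(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "microtraits_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg,
        "seed": seed,
        "package_version": _package_version(),
        "stages": {},
        "outputs": {},
    }

    def record(name: str, path: Path):
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                manifest["stages"][name] = round(dt, 3)
                if exc is not None:
                    raise PipelineError(f"stage {name} failed: {exc}") from exc
                logger.info("stage %s: done in %.2fs", name, dt)

        return _Timer()

    # --- simulate or load -------------------------------------------------
    with stage("inputs"):
        if cfg["simulate"].get("enabled", False):
            gen_cfg = {
                k: v for k, v in cfg["simulate"].items() if k != "enabled"
            }
            gen_cfg.setdefault("seed", seed)
            gcfg = synthetic_data.config_from_dict(gen_cfg)
            counts, taxonomy, metadata, reference, tree, truth = (
                synthetic_data.generate_dataset(gcfg)
            )
            predicted = None
            tables_io.write_count_table(counts, out / "counts.tsv")
            tables_io.write_taxonomy(taxonomy, out / "taxonomy.tsv")
            tables_io.write_metadata(metadata, out / "metadata.csv")
            tables_io.write_trait_reference(reference, out / "trait_reference.tsv")
            tables_io.write_newick(tree, out / "tree.nwk")
            synthetic_data.truth_report(truth, out)
            for name in ("counts.tsv", "taxonomy.tsv", "metadata.csv",
                         "trait_reference.tsv", "tree.nwk",
                         "truth_taxa.tsv", "truth_samples.tsv"):
                record(name.split(".")[0], out / name)
        else:
            counts, taxonomy, metadata, reference, predicted, tree, truth = (
                _load_inputs(cfg)
            )

    # --- community preparation -------------------------------------------
    with stage("filter"):
        counts = community_prep.filter_taxa(counts, taxonomy)
        counts = community_prep.filter_samples(
            counts, int(cfg["filter"]["min_reads"])
        )
    with stage("rarefy"):
        rarefied = community_prep.rarefy(
            counts, int(cfg["rarefy"]["depth"]), seed=seed + 1
        )
        tables_io.write_count_table(rarefied, out / "rarefied.tsv")
        record("rarefied", out / "rarefied.tsv")

    with stage("community"):
        simpson = community_prep.simpson_diversity(rarefied)
        dm = community_prep.bray_curtis(rarefied)
        ord_res = community_prep.nmds(
            dm,
            n_dim=int(cfg["nmds"]["n_dim"]),
            seed=seed + 2,
            restarts=int(cfg["nmds"]["restarts"]),
        )
        cors = community_prep.phylum_env_correlations(rarefied, taxonomy, metadata)
        ratio = community_prep.archaea_bacteria_ratio(rarefied, taxonomy)
        tables_io.write_distance_matrix(dm, out / "bray_curtis.tsv")
        ord_res.coordinates.to_csv(out / "nmds_coords.tsv", sep="\t")
        (out / "nmds_stats.json").write_text(
            json.dumps({"stress": ord_res.stress, "n": len(dm.ids)}, indent=2)
        )
        cors.to_csv(out / "phylum_env_correlations.tsv", sep="\t", index=False)
        ratio.to_frame().to_csv(out / "archaea_bacteria_ratio.tsv", sep="\t")
        for name in ("bray_curtis", "nmds_coords", "nmds_stats",
                     "phylum_env_correlations", "archaea_bacteria_ratio"):
            suffix = ".json" if name == "nmds_stats" else ".tsv"
            record(name, out / f"{name}{suffix}")

    # --- trait annotation ---------------------------------------------------
    with stage("annotate"):
        index = trait_annotation.build_reference_index(reference)
        assigned = trait_annotation.assign_traits(
            taxonomy.loc[taxonomy.index.isin(rarefied.index)], index
        )
        assigned = trait_annotation.consensus_rrna(assigned, predicted)
        assigned.to_csv(out / "trait_assignments.tsv", sep="\t")
        record("trait_assignments", out / "trait_assignments.tsv")

    # --- social niche breadth ----------------------------------------------
    with stage("snb"):
        rank = cfg["snb"].get("rank", "asv")
        profiles_for_snb = snb_mod.sample_profiles(
            rarefied, taxonomy if rank != "asv" else None, rank=rank
        )
        snb_res = snb_mod.snb_scores(
            rarefied,
            profiles_for_snb,
            dissimilarity=cfg["snb"].get("dissimilarity", "braycurtis"),
        )
        snb_res.to_csv(out / "snb_scores.tsv", sep="\t")
        record("snb_scores", out / "snb_scores.tsv")

    with stage("profiles"):
        profile, coverage = trait_annotation.weighted_sample_traits(
            rarefied, assigned, snb=snb_res, simpson=simpson
        )
        profile.to_csv(out / "sample_trait_profile.tsv", sep="\t")
        coverage.to_csv(out / "trait_read_coverage.tsv", sep="\t")
        record("sample_trait_profile", out / "sample_trait_profile.tsv")
        record("trait_read_coverage", out / "trait_read_coverage.tsv")

    # --- phylogenetic stages -------------------------------------------------
    with stage("phylo"):
        if tree is None:
            raise PipelineError(
                "stage phylo: no tree or distance matrix was provided"
            )
        scored = snb_res["snb"].dropna()
        shared = [t.name for t in tree.tips() if t.name in scored.index]
        work = tree.shear(shared)
        work.prune()
        if len(work.children) == 2:
            work.unroot()
        pf = phylo.phylofactor(
            rarefied.loc[shared],
            work,
            scored,
            mode=cfg["phylofactor"].get("mode", "taxon"),
            n_factors=int(cfg["phylofactor"]["n_factors"]),
            alpha=float(cfg["phylofactor"]["alpha"]),
            pseudocount=float(cfg["phylofactor"]["pseudocount"]),
        )
        factor_rows = [
            {
                "factor": f.index,
                "edge": f.edge,
                "n_group_r": len(f.group_r),
                "n_group_s": len(f.group_s),
                "objective": f.objective,
                "p_value": f.p_value,
                "significant": f.significant,
                "group_r": ";".join(sorted(f.group_r)),
                "group_s": ";".join(sorted(f.group_s)),
            }
            for f in pf.factors
        ]
        pd.DataFrame(factor_rows).to_csv(
            out / "phylofactors.tsv", sep="\t", index=False
        )
        balances = phylo.factor_balances(rarefied.loc[shared], pf)
        balances.to_csv(out / "factor_balances.tsv", sep="\t")
        k_stat, k_p = phylo.blomberg_k(work, scored, seed=seed + 3)
        lam, lam_ll = phylo.pagel_lambda(work, scored)
        signal = {
            "blomberg_k": k_stat,
            "blomberg_k_p": k_p,
            "pagel_lambda": lam,
            "pagel_lambda_loglik": lam_ll,
            "n_tips": len(shared),
        }
        (out / "phylo_signal.json").write_text(json.dumps(signal, indent=2))
        record("phylofactors", out / "phylofactors.tsv")
        record("factor_balances", out / "factor_balances.tsv")
        record("phylo_signal", out / "phylo_signal.json")

    # --- models ---------------------------------------------------------------
    with stage("models"):
        battery = trait_models.model_battery(
            profile,
            metadata,
            coverage=coverage,
            coverage_floor=float(cfg["models"]["coverage_floor"]),
            basis_df=int(cfg["models"]["basis_df"]),
        )
        battery["report"].to_csv(out / "model_report.tsv", sep="\t", index=False)
        gam_json = {
            resp: {
                "r_squared_adj": g.r_squared_adj,
                "deviance_explained": g.deviance_explained,
                "gcv": g.gcv,
                "scale": g.scale,
                "intercept": g.intercept,
                "intercept_se": g.intercept_se,
                "n": g.n,
                "terms": g.terms.reset_index().to_dict(orient="records"),
            }
            for resp, g in battery["gams"].items()
        }
        (out / "gam_summaries.json").write_text(json.dumps(gam_json, indent=2))
        record("model_report", out / "model_report.tsv")
        record("gam_summaries", out / "gam_summaries.json")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("microtraits")
    except Exception:
        return "unknown"
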