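import numpy as np
import pandas as pd
import pytest

from microtraits import community_prep, snb as snb_mod, trait_annotation
from microtraits.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the generator's study conditions."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def prepared(default_dataset):
    """Filtered, rarefied and fully annotated state of the default dataset."""
    counts, taxonomy, metadata, reference, tree, truth = default_dataset
    filtered = community_prep.filter_taxa(counts, taxonomy)
    filtered = community_prep.filter_samples(filtered)
    rarefied = community_prep.rarefy(filtered, seed=2)
    index = trait_annotation.build_reference_index(reference)
    assigned = trait_annotation.assign_traits(
        taxonomy.loc[taxonomy.index.isin(rarefied.index)], index
    )
    scores = snb_mod.snb_scores(rarefied)
    simpson = community_prep.simpson_diversity(rarefied)
    profile, coverage = trait_annotation.weighted_sample_traits(
        rarefied, assigned, snb=scores, simpson=simpson
    )
    return {
        "counts": counts,
        "taxonomy": taxonomy,
        "metadata": metadata,
        "reference": reference,
        "tree": tree,
        "truth": truth,
        "rarefied": rarefied,
        "assigned": assigned,
        "snb": scores,
        "profile": profile,
        "coverage": coverage,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_count_table(rng, n_taxa, n_samples, low=0, high=50):
    counts = pd.DataFrame(
        rng.integers(low, high, (n_taxa, n_samples)),
        index=[f"t{i:03d}" for i in range(n_taxa)],
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )
    # guarantee positive sample sums
    zero = counts.sum(axis=0) == 0
    counts.loc[counts.index[0], zero[zero].index] = 1
    counts.index.name = "taxon_id"
    return counts
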