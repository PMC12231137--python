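import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from microtraits import community_prep as cp
from microtraits.tables_io import RANKS

from conftest import random_count_table


def _taxonomy(rows: dict[str, list[str]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(RANKS)
    ).rename_axis("taxon_id")


class TestFilterTaxa:
    def test_organelle_and_domain_rules(self):
        taxonomy = _taxonomy(
            {
                "chl": ["Bacteria", "Cyanobacteria", "c", "Chloroplast", "f", "g", "s"],
                "mit": ["Bacteria", "Proteobacteria", "c", "o", "Mitochondria", "g", "s"],
                "euk": ["Eukaryota", "p", "c", "o", "f", "g", "s"],
                "bac1": ["Bacteria", "p", "c", "o", "f", "g", "s"],
                "bac2": ["Bacteria", "p2", "c", "o", "f", "g", "s"],
            }
        )
        counts = pd.DataFrame(
            {"s1": [5, 5, 5, 5, 5]}, index=list(taxonomy.index)
        )
        kept = cp.filter_taxa(counts, taxonomy)
        assert set(kept.index) == {"bac1", "bac2"}

    def test_all_bacteria_identity(self):
        taxonomy = _taxonomy(
            {f"t{i}": ["Bacteria", "p", "c", "o", "f", "g", "s"] for i in range(4)}
        )
        counts = pd.DataFrame({"s1": [1, 2, 3, 4]}, index=list(taxonomy.index))
        pd.testing.assert_frame_equal(cp.filter_taxa(counts, taxonomy), counts)

    def test_read_conservation(self):
        taxonomy = _taxonomy(
            {
                "euk": ["Eukaryota", "p", "c", "o", "f", "g", "s"],
                "bac": ["Bacteria", "p", "c", "o", "f", "g", "s"],
            }
        )
        counts = pd.DataFrame({"s1": [7, 13]}, index=["euk", "bac"])
        kept = cp.filter_taxa(counts, taxonomy)
        assert counts.to_numpy().sum() - kept.to_numpy().sum() == 7

    def test_empty_result_is_error(self):
        taxonomy = _taxonomy({"euk": ["Eukaryota", "p", "c", "o", "f", "g", "s"]})
        counts = pd.DataFrame({"s1": [3]}, index=["euk"])
        with pytest.raises(ValueError):
            cp.filter_taxa(counts, taxonomy)


class TestFilterSamples:
    def test_threshold_boundary(self):
        counts = pd.DataFrame(
            [[7999, 8000, 12000]], index=["t1"], columns=["a", "b", "c"]
        )
        kept = cp.filter_samples(counts, min_reads=8000)
        assert list(kept.columns) == ["b", "c"]

    def test_zero_threshold_identity(self, rng):
        counts = random_count_table(rng, 5, 4)
        pd.testing.assert_frame_equal(cp.filter_samples(counts, 0), counts)

    def test_all_dropped_is_error(self):
        counts = pd.DataFrame([[10]], index=["t1"], columns=["a"])
        with pytest.raises(ValueError):
            cp.filter_samples(counts, min_reads=100)


class TestRarefy:
    def test_column_sums_exact(self, rng):
        counts = random_count_table(rng, 20, 6, low=10, high=200)
        rare = cp.rarefy(counts, depth=300, seed=1)
        assert (rare.sum(axis=0) == 300).all()

    def test_exhaustive_draw_unchanged(self):
        counts = pd.DataFrame({"s1": [3, 7]}, index=["a", "b"])
        rare = cp.rarefy(counts, depth=10, seed=0)
        pd.testing.assert_frame_equal(rare, counts)

    def test_shallow_sample_named_in_error(self):
        counts = pd.DataFrame({"deep": [100], "shallow": [5]}, index=["a"])
        with pytest.raises(ValueError, match="shallow"):
            cp.rarefy(counts, depth=50)

    def test_never_adds_taxa(self, rng):
        counts = random_count_table(rng, 30, 5, low=0, high=40)
        counts += 5  # ensure depth attainable
        rare = cp.rarefy(counts, depth=100, seed=3)
        assert ((rare > 0) <= (counts > 0)).all().all()


class TestBrayCurtis:
    def test_known_value(self):
        counts = pd.DataFrame({"x": [5, 5, 0], "y": [0, 5, 5]}, index=list("abc"))
        dm = cp.bray_curtis(counts)
        assert dm["x", "y"] == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        counts = pd.DataFrame(
            {"x": [3, 1, 0, 0], "y": [3, 1, 0, 0], "z": [0, 0, 2, 2]},
            index=list("abcd"),
        )
        dm = cp.bray_curtis(counts)
        assert dm["x", "y"] == pytest.approx(0.0)
        assert dm["x", "z"] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        counts = random_count_table(rng, 6, 4, low=0, high=30)
        dm = cp.bray_curtis(counts)
        for i, a in enumerate(counts.columns):
            for b in counts.columns[i + 1:]:
                x, y = counts[a].to_numpy(), counts[b].to_numpy()
                expected = 1 - 2 * np.minimum(x, y).sum() / (x.sum() + y.sum())
                assert dm[a, b] == pytest.approx(expected, abs=1e-12)

    def test_zero_sum_sample_is_error(self):
        counts = pd.DataFrame({"x": [1, 1], "y": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="y"):
            cp.bray_curtis(counts)


class TestNMDS:
    def test_collinear_points_embed_perfectly(self):
        from skbio import DistanceMatrix

        pts = np.arange(8, dtype=float)[:, None]
        d = squareform(pdist(pts))
        res = cp.nmds(DistanceMatrix(d, ids=[str(i) for i in range(8)]),
                      seed=0, restarts=4)
        assert res.stress < 0.01

    def test_deterministic_under_seed(self, rng):
        from skbio import DistanceMatrix

        pts = rng.normal(size=(9, 3))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(9)])
        a = cp.nmds(dm, seed=5, restarts=4)
        b = cp.nmds(dm, seed=5, restarts=4)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_coordinates_centered(self, rng):
        from skbio import DistanceMatrix

        pts = rng.normal(size=(7, 2))
        d = squareform(pdist(pts))
        res = cp.nmds(DistanceMatrix(d, ids=[str(i) for i in range(7)]),
                      seed=1, restarts=2)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_too_many_dimensions_rejected(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float),
                            ids=list("abc"))
        with pytest.raises(ValueError):
            cp.nmds(dm, n_dim=3)


class TestSimpson:
    def test_uniform_four_taxa(self):
        counts = pd.DataFrame({"s": [5, 5, 5, 5]}, index=list("abcd"))
        assert cp.simpson_diversity(counts)["s"] == pytest.approx(0.75)

    def test_single_taxon_zero(self):
        counts = pd.DataFrame({"s": [9, 0]}, index=["a", "b"])
        assert cp.simpson_diversity(counts)["s"] == pytest.approx(0.0)

    def test_evenness_monotonicity(self):
        skewed = pd.DataFrame({"s": [70, 10, 10, 10]}, index=list("abcd"))
        evened = pd.DataFrame({"s": [40, 20, 20, 20]}, index=list("abcd"))
        assert (
            cp.simpson_diversity(evened)["s"] > cp.simpson_diversity(skewed)["s"]
        )


class TestPhylumCorrelations:
    def _fixture(self, rng, n_phyla=20, n_samples=30):
        taxonomy = _taxonomy(
            {
                f"t{i}": ["Bacteria", f"P{i % n_phyla}", "c", "o", "f", "g", "s"]
                for i in range(n_phyla * 2)
            }
        )
        counts = pd.DataFrame(
            rng.integers(1, 50, (n_phyla * 2, n_samples)),
            index=list(taxonomy.index),
            columns=[f"s{j}" for j in range(n_samples)],
        )
        meta = pd.DataFrame(
            {"pH": rng.uniform(5, 9, n_samples)},
            index=pd.Index(counts.columns, name="sample_id"),
        )
        return counts, taxonomy, meta

    def test_monotone_phylum_gets_rho_one(self, rng):
        counts, taxonomy, meta = self._fixture(rng, n_phyla=4, n_samples=12)
        counts.loc[:, :] = 10  # constant background: relative abundance of
        order = meta["pH"].rank().astype(int)  # P0 is monotone in its counts
        counts.loc["t0"] = (order * 1000).to_numpy()
        table = cp.phylum_env_correlations(counts, taxonomy, meta, ["pH"])
        row = table[(table.phylum == "P0") & (table.variable == "pH")]
        assert row["rho"].iloc[0] == pytest.approx(1.0)

    def test_null_metadata_rarely_significant(self, rng):
        counts, taxonomy, meta = self._fixture(rng)
        meta["pH"] = rng.permutation(meta["pH"].to_numpy())
        table = cp.phylum_env_correlations(counts, taxonomy, meta, ["pH"])
        frac = (table["p_adj"] < 0.05).mean()
        assert frac <= 0.1

    def test_aggregation_conserves_reads(self, rng):
        counts, taxonomy, _ = self._fixture(rng, n_phyla=5, n_samples=6)
        phyla = cp.aggregate_rank(counts, taxonomy, "phylum")
        np.testing.assert_array_equal(
            phyla.sum(axis=0).to_numpy(), counts.sum(axis=0).to_numpy()
        )


class TestArchaeaRatio:
    def _taxonomy(self):
        return _taxonomy(
            {
                "arc": ["Archaea", "Crenarchaeota", "c", "o", "f", "g", "s"],
                "bac": ["Bacteria", "p", "c", "o", "f", "g", "s"],
            }
        )

    def test_known_ratio(self):
        counts = pd.DataFrame({"s": [100, 900]}, index=["arc", "bac"])
        ratio = cp.archaea_bacteria_ratio(counts, self._taxonomy())
        assert ratio["s"] == pytest.approx(0.1111, abs=5e-5)

    def test_no_archaea_is_zero(self):
        counts = pd.DataFrame({"s": [0, 500]}, index=["arc", "bac"])
        assert cp.archaea_bacteria_ratio(counts, self._taxonomy())["s"] == 0

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s": [30, 400]}, index=["arc", "bac"])
        a = cp.archaea_bacteria_ratio(counts, self._taxonomy())["s"]
        b = cp.archaea_bacteria_ratio(counts * 2, self._taxonomy())["s"]
        assert a == pytest.approx(b)
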