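"""Bias-vector similarity, UPGMA clustering and PCA."""

import numpy as np
import pytest

from sdbiasscan.errors import DegenerateInputError
from sdbiasscan.gstats import expected_frequencies, g_profile
from sdbiasscan.hybridization import classify_genes, split_by_label
from sdbiasscan.sequence_io import extract_gene_records
from sdbiasscan.similarity import (
    BiasVector,
    SimilarityMatrix,
    cluster,
    pca,
    similarity_matrix,
)


def vec(sid, values, window=(-2, -1)):
    return BiasVector(species_id=sid, values=np.asarray(values, float), window=window)


def manual_pearson(x, y):
    """Textbook formula with one grand mean per vector."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestSimilarity:
    def test_self_similarity_and_anticorrelation(self):
        x = vec("x", [1, 2, 3, 4, 2, 0, 1, 3], window=(-2, -1))
        y = vec("y", -np.asarray(x.values) + 2 * np.mean(x.values), window=(-2, -1))
        sim = similarity_matrix([x, y])
        assert sim.D.loc["x", "x"] == pytest.approx(0.0)
        assert sim.D.loc["y", "y"] == pytest.approx(0.0)
        assert sim.D.loc["x", "y"] == pytest.approx(2.0)

    def test_matches_textbook_pearson(self, rng):
        vs = [vec(f"s{i}", rng.normal(size=8)) for i in range(3)]
        sim = similarity_matrix(vs)
        for i in range(3):
            for j in range(3):
                r = manual_pearson(vs[i].values, vs[j].values)
                assert sim.r.iloc[i, j] == pytest.approx(r)
                assert sim.D.iloc[i, j] == pytest.approx(1 - r)
        # symmetry and range
        np.testing.assert_allclose(sim.D.to_numpy(), sim.D.to_numpy().T)
        assert np.all(sim.D.to_numpy() >= -1e-12)
        assert np.all(sim.D.to_numpy() <= 2 + 1e-12)

    def test_zero_variance_vector_names_species(self):
        with pytest.raises(DegenerateInputError, match="flatliner"):
            similarity_matrix(
                [vec("ok", [1, 2, 3, 4, 1, 2, 3, 4]), vec("flatliner", [1.0] * 8)]
            )

    def test_vector_length_must_match_window(self):
        with pytest.raises(ValueError):
            BiasVector("x", np.zeros(7), window=(-2, -1))


class TestCluster:
    def test_two_species_single_merge(self):
        vs = [vec("a", [1, 0, 2, 1, 0, 1, 2, 3]), vec("b", [0, 1, 1, 2, 3, 0, 1, 2])]
        sim = similarity_matrix(vs)
        dendro = cluster(sim)
        assert dendro.linkage.shape == (1, 4)
        assert dendro.merge_heights[0] == pytest.approx(sim.D.loc["a", "b"])

    def test_three_point_hand_executed_group_average(self):
        D = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]])
        import pandas as pd

        ids = ["A", "B", "C"]
        sim = SimilarityMatrix(
            species=ids,
            r=pd.DataFrame(1 - D, index=ids, columns=ids),
            D=pd.DataFrame(D, index=ids, columns=ids),
        )
        dendro = cluster(sim)
        # merges (A,B) at 0.1, then ((AB),C) at mean(0.5, 0.5) = 0.5
        assert dendro.merge_heights[0] == pytest.approx(0.1)
        assert dendro.merge_heights[1] == pytest.approx(0.5)
        assert sorted(dendro.linkage[0, :2]) == [0, 1]
        cut = dendro.cut(2)
        assert cut["A"] == cut["B"] != cut["C"]

    def test_merge_heights_monotone(self, rng):
        vs = [vec(f"s{i}", rng.normal(size=8)) for i in range(7)]
        dendro = cluster(similarity_matrix(vs))
        heights = dendro.merge_heights
        assert np.all(np.diff(heights) >= -1e-12)

    def test_newick_contains_all_species(self):
        vs = [vec(f"s{i}", np.arange(8) * (i + 1.0) + i) for i in range(4)]
        nwk = cluster(similarity_matrix(vs)).to_newick()
        for i in range(4):
            assert f"s{i}" in nwk


class TestPCA:
    def test_identical_species_flagged_degenerate(self):
        vs = [vec(f"s{i}", [1, 2, 3, 4, 5, 6, 7, 8]) for i in range(4)]
        res = pca(vs, 2)
        assert res.degenerate
        assert np.all(res.variance_ratio == 0)

    def test_single_axis_toy_recovered(self, rng):
        base = rng.normal(size=8)
        axis = rng.normal(size=8)
        axis /= np.linalg.norm(axis)
        vs = [vec(f"s{i}", base + t * axis) for i, t in enumerate([-3, -1, 0, 1, 3])]
        res = pca(vs, 2)
        assert res.variance_ratio[0] == pytest.approx(1.0)
        load = res.loadings.iloc[0].to_numpy()
        assert abs(np.dot(load, axis)) == pytest.approx(1.0, abs=1e-8)

    def test_reconstruction_from_all_components(self, rng):
        vs = [vec(f"s{i}", rng.normal(size=8)) for i in range(6)]
        X = np.vstack([v.values for v in vs])
        res = pca(vs, k=5)
        scores = res.scores.to_numpy()
        loadings = res.loadings.to_numpy()
        recon = scores @ loadings + X.mean(axis=0)
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_species_permutation_consistency(self, rng):
        vs = [vec(f"s{i}", rng.normal(size=8)) for i in range(5)]
        res1 = pca(vs, 2)
        res2 = pca(vs[::-1], 2)
        for sid in res1.scores.index:
            np.testing.assert_allclose(
                res1.scores.loc[sid], res2.scores.loc[sid], atol=1e-8
            )

    def test_too_many_components_rejected(self):
        vs = [vec(f"s{i}", np.arange(8) * (i + 1.0)) for i in range(3)]
        with pytest.raises(DegenerateInputError):
            pca(vs, 5)


class TestPlantedCohort:
    """Species groups with distinct planted upstream motifs must separate."""

    @staticmethod
    def cohort_vectors(planted_cohort):
        vectors, labels = [], {}
        for (sp, _truth), profile in planted_cohort:
            recs = extract_gene_records(sp).records
            cls = classify_genes(recs, sp.anti_sd_tail)
            _, nonsd = split_by_label(recs, cls)
            gp = g_profile(nonsd, expected_frequencies(nonsd), (-40, -1))
            vectors.append(BiasVector.from_profile(sp.species_id, gp))
            labels[sp.species_id] = profile
        return vectors, labels

    def test_two_groups_form_separate_clusters(self, planted_cohort):
        vectors, labels = self.cohort_vectors(planted_cohort)
        dendro = cluster(similarity_matrix(vectors))
        cut = dendro.cut(2)
        groups = {}
        for sid, cl in cut.items():
            groups.setdefault(cl, set()).add(labels[sid])
        assert len(groups) == 2
        assert all(len(v) == 1 for v in groups.values())

    def test_separating_pc_loads_on_planted_positions(self, planted_cohort):
        vectors, labels = self.cohort_vectors(planted_cohort)
        res = pca(vectors, 3)
        scores = res.scores
        arch = [s for s, l in labels.items() if l == "archaeal"]
        bact = [s for s, l in labels.items() if l == "bacterial"]
        # find the PC separating the groups most strongly
        sep = max(
            scores.columns,
            key=lambda c: abs(scores.loc[arch, c].mean() - scores.loc[bact, c].mean()),
        )
        loadings = res.loadings.loc[sep].abs().sort_values(ascending=False)
        top = set(loadings.index[:20])
        planted = {
            f"{pos}:{n}"
            for pos in list(range(-37, -22)) + list(range(-20, -9))
            for n in "AUGC"
        }
        overlap = len(top & planted) / len(top)
        assert overlap >= 0.8
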