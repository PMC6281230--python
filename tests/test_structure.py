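"""Classical MDS, neighbor joining and the admixture EM."""

import io

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from canipop.grm import DistanceMatrix, ibs_distance_matrix
from canipop.structure import admixture_cv, admixture_fit, classical_mds, nj_tree
from canipop.simulate import sim_admixture, sim_breed_panel
from conftest import toy_dataset


def _dm(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"t{i}" for i in range(len(values))]
    return DistanceMatrix(labels, values)


def _tip_distances(newick, labels):
    tree = TreeNode.read(io.StringIO(newick))
    tt = tree.tip_tip_distances()
    import pandas as pd

    return pd.DataFrame(tt.data, index=tt.ids, columns=tt.ids).loc[labels, labels].to_numpy()


class TestClassicalMDS:
    def test_collinear_points_recovered(self):
        D = _dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        coords = classical_mds(D, 1).coords.ravel()
        assert sorted(np.round(coords, 8)) == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_distances_give_zero_coordinates(self):
        out = classical_mds(_dm(np.zeros((4, 4))), 3)
        assert out.coords.size == 0 or np.allclose(out.coords, 0)

    def test_euclidean_distances_reconstructed_exactly(self, rng):
        pts = rng.normal(size=(15, 3))
        D = _dm(squareform(pdist(pts)))
        coords = classical_mds(D, 3).coords
        assert np.abs(squareform(pdist(coords)) - D.values).max() < 1e-8

    def test_matches_skbio_pcoa(self, rng):
        pts = rng.normal(size=(10, 4))
        D = _dm(squareform(pdist(pts)))
        ours = classical_mds(D, 2).coords
        from skbio.stats.ordination import pcoa
        from skbio import DistanceMatrix as SkDM

        ref = pcoa(SkDM(D.values, ids=D.labels)).samples.iloc[:, :2].to_numpy()
        for k in range(2):  # column signs are arbitrary
            assert min(
                np.abs(ours[:, k] - ref[:, k]).max(),
                np.abs(ours[:, k] + ref[:, k]).max(),
            ) < 1e-8

    def test_coordinates_are_centered(self, rng):
        pts = rng.normal(size=(9, 2))
        coords = classical_mds(_dm(squareform(pdist(pts))), 2).coords
        assert np.abs(coords.mean(axis=0)).max() < 1e-10

    def test_breeds_separate_on_synthetic_panel(self):
        ds, _ = sim_breed_panel(n_breeds=3, n_per_breed=10, m=1000, seed=2)
        D = ibs_distance_matrix(ds)
        coords = classical_mds(D, 2).coords
        breed = np.repeat([0, 1, 2], 10)
        within, between = [], []
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                d = np.linalg.norm(coords[i] - coords[j])
                (within if breed[i] == breed[j] else between).append(d)
        assert np.mean(within) < np.mean(between)


class TestNeighborJoining:
    def test_three_taxa_solves_three_point_equations(self):
        D = _dm([[0, 3, 4], [3, 0, 5], [4, 5, 0]], list("abc"))
        rec = _tip_distances(nj_tree(D), list("abc"))
        assert np.abs(rec - D.values).max() < 1e-9

    def test_additive_five_taxon_matrix_recovered(self):
        true = TreeNode.read(io.StringIO("((A:2,B:3):1,(C:1,D:4):2,E:5);"))
        tt = true.tip_tip_distances()
        labels = list(tt.ids)
        D = _dm(tt.data, labels)
        rec = _tip_distances(nj_tree(D), labels)
        assert np.abs(rec - D.values).max() < 1e-9

    def test_duplicate_rows_join_in_zero_length_cherry(self):
        D = _dm([[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0.5], [1, 1, 0.5, 0]], list("abcd"))
        rec = _tip_distances(nj_tree(D), list("ab"))
        assert rec[0, 1] == pytest.approx(0.0)

    def test_duplicate_labels_rejected(self):
        D = _dm(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="duplicate"):
            nj_tree(D, labels=["x", "x", "y"])


class TestAdmixtureEM:
    def test_k1_closed_form(self):
        ds = toy_dataset([[0, 2, 1], [1, 2, -1]])
        fit = admixture_fit(ds, 1)
        assert np.all(fit.Q == 1.0)
        assert fit.P[0] == pytest.approx([0.25, 1.0, 0.5])

    def test_loglik_monotone_and_constraints_hold(self):
        ds, _ = sim_admixture(2, 40, 200, seed=5)
        fit = admixture_fit(ds, 2, seed=1, max_iter=300)
        assert np.all(np.diff(fit.loglik_path) >= -1e-6)
        assert fit.Q.min() >= 0
        np.testing.assert_allclose(fit.Q.sum(axis=1), 1.0, atol=1e-9)
        assert 0 < fit.P.min() and fit.P.max() < 1

    def test_fixed_opposite_populations_fully_resolved(self):
        # two source populations fixed for opposite alleles at every locus
        n_half, m = 6, 40
        dosage = np.vstack([np.zeros((n_half, m)), np.full((n_half, m), 2)]).astype(np.int8)
        fit = admixture_fit(toy_dataset(dosage), 2, seed=0)
        q1 = fit.Q[:n_half, 0]
        col = 0 if q1.mean() > 0.5 else 1
        assert np.all(fit.Q[:n_half, col] > 1 - 1e-3)
        assert np.all(fit.Q[n_half:, col] < 1e-3)

    def test_missing_genotypes_are_skipped_not_imputed(self):
        ds = toy_dataset([[0, -1], [2, 1], [0, 1], [2, -1]])
        fit = admixture_fit(ds, 1)
        # frequencies use observed calls only
        assert fit.P[0, 1] == pytest.approx(0.5)

    def test_k_larger_than_samples_rejected(self):
        with pytest.raises(ValueError, match="exceeds sample count"):
            admixture_fit(toy_dataset([[0], [1]]), 3)


class TestAdmixtureCV:
    def test_homogeneous_population_prefers_k1(self, rng):
        dosage = rng.binomial(2, rng.uniform(0.2, 0.8, 300), size=(40, 300)).astype(np.int8)
        cv = admixture_cv(toy_dataset(dosage), [1, 2], folds=3, seed=0)
        assert cv.selected_K == 1

    def test_folds_partition_all_observed_entries(self):
        ds = toy_dataset([[0, 1, 2], [2, -1, 0]])
        # leave-one-out on the 5 observed entries exercises the partition
        cv = admixture_cv(ds, [1], folds=5, seed=0)
        assert len(cv.table) == 1 and np.isfinite(cv.table["cv_error"]).all()

    def test_fewer_than_two_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            admixture_cv(toy_dataset([[0, 1]]), [1], folds=1)
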