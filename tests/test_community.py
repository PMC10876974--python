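"""Richness downsampling, Bray–Curtis, PCoA, k-means scan, hull membership."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from longmeta.community import (
    bray_curtis_matrix,
    cluster_membership,
    downsampled_richness,
    pcoa,
    scan_kmeans,
)
from longmeta.taxonomy import ReadAssignment
from longmeta.validation import ValidationResult


def vres(taxid, validated=True):
    return ValidationResult(
        taxid=taxid, name="", rank="species", n_assigned=10, n_sampled=10,
        n_validated=10 if validated else 0,
        rate=1.0 if validated else 0.0, validated=validated,
    )


def reads(taxid, n, prefix):
    return [ReadAssignment(f"{prefix}{i}", True, taxid, 500) for i in range(n)]


class TestBrayCurtis:
    def frame(self, rows):
        return pd.DataFrame(rows)

    def test_identical_vectors(self):
        df = self.frame([{"a": 0.5, "b": 0.5}, {"a": 0.5, "b": 0.5}])
        dm = bray_curtis_matrix(df)
        assert dm.data[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports(self):
        df = self.frame([{"a": 1.0, "b": 0.0}, {"a": 0.0, "b": 1.0}])
        assert bray_curtis_matrix(df).data[0, 1] == pytest.approx(1.0)

    def test_hand_computed(self):
        # (0.5, 0.5) vs (1, 0): sum|x-y| = 1, sum(x+y) = 2 -> 0.5.
        df = self.frame([{"a": 0.5, "b": 0.5}, {"a": 1.0, "b": 0.0}])
        assert bray_curtis_matrix(df).data[0, 1] == pytest.approx(0.5)

    def test_metric_axioms_on_random_compositions(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.dirichlet(np.ones(8), size=12))
        d = bray_curtis_matrix(df).data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()

    def test_all_zero_vector_rejected(self):
        df = self.frame([{"a": 1.0, "b": 0.0}, {"a": 0.0, "b": 0.0}])
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis_matrix(df)


class TestPcoa:
    def test_euclidean_distances_reconstructed(self):
        # Planar points: PCoA must reproduce pairwise distances exactly.
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        ord_ = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(6)]))
        rec = squareform(pdist(ord_.coordinates))
        assert np.allclose(rec, d, atol=1e-8)
        assert ord_.n_negative_eigenvalues == 0

    def test_two_samples_single_axis(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        ord_ = pcoa(DistanceMatrix(d, ids=["a", "b"]))
        sep = abs(ord_.coordinates[0, 0] - ord_.coordinates[1, 0])
        assert sep == pytest.approx(0.4)

    def test_zero_distances_zero_coordinates(self):
        d = np.zeros((3, 3))
        ord_ = pcoa(DistanceMatrix(d, ids=list("abc")))
        assert np.allclose(ord_.coordinates, 0)

    def test_eigenvalues_decreasing(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        ord_ = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(8)]))
        assert (np.diff(ord_.eigenvalues) <= 1e-12).all()

    def test_matches_skbio_reference(self):
        # Independent route: scikit-bio's PCoA on the same matrix.
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(3)
        comp = rng.dirichlet(np.ones(5), size=7)
        dm = DistanceMatrix(
            squareform(pdist(comp, metric="braycurtis")),
            ids=[str(i) for i in range(7)],
        )
        ours = pcoa(dm)
        ref = skbio_pcoa(dm)
        k = ours.coordinates.shape[1]
        ref_coords = ref.samples.to_numpy()[:, :k]
        assert np.allclose(
            ours.eigenvalues, ref.eigvals.to_numpy()[:k], atol=1e-8
        )
        # Coordinates match up to per-axis sign.
        for j in range(k):
            col, ref_col = ours.coordinates[:, j], ref_coords[:, j]
            assert np.allclose(col, ref_col, atol=1e-6) or np.allclose(
                col, -ref_col, atol=1e-6
            )


def blob_ordination(k, n_per, seed, spread=0.05):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-5, 5, size=(k, 3))
    pts = np.concatenate(
        [c + spread * rng.normal(size=(n_per, 3)) for c in centers]
    )
    d = squareform(pdist(pts))
    ids = [f"s{i}" for i in range(len(pts))]
    return pcoa(DistanceMatrix(d, ids=ids))


class TestKmeansScan:
    def test_three_blobs_recovered(self):
        ord_ = blob_ordination(3, 8, seed=4)
        res = scan_kmeans(ord_, seed=0, restarts=20)
        assert res.k == 3

    def test_two_blobs_high_silhouette(self):
        ord_ = blob_ordination(2, 8, seed=5)
        res = scan_kmeans(ord_, seed=0, restarts=20)
        assert res.k == 2
        assert res.silhouette_by_k[2] > 0.9

    def test_deterministic_given_seed(self):
        ord_ = blob_ordination(3, 6, seed=6)
        a = scan_kmeans(ord_, seed=1, restarts=10)
        b = scan_kmeans(ord_, seed=1, restarts=10)
        assert a.labels == b.labels

    def test_infeasible_k_skipped(self):
        ord_ = blob_ordination(2, 2, seed=7)  # only 4 samples
        res = scan_kmeans(ord_, k_range=(2, 6), seed=0, restarts=5)
        assert set(res.skipped_k) >= {4, 5, 6}


class TestClusterMembership:
    def ordination(self):
        # 3-point cluster around origin + 3-point cluster far away.
        pts = np.array(
            [[0, 0], [1, 0], [0, 1], [10, 10], [11, 10], [10, 11],
             [0.3, 0.3], [50, 50]],
            dtype=float,
        )
        d = squareform(pdist(pts))
        ids = ["a1", "a2", "a3", "b1", "b2", "b3", "q_in", "q_out"]
        return pcoa(DistanceMatrix(d, ids=ids))

    def test_membership_calls(self):
        ord_ = self.ordination()
        labels = {"a1": 0, "a2": 0, "a3": 0, "b1": 1, "b2": 1, "b3": 1}
        got = cluster_membership(ord_, labels, ["q_in", "q_out", "a1"])
        assert got.loc["q_in", "inside"]
        assert got.loc["q_in", "cluster"] == 0
        assert not got.loc["q_out", "inside"]
        assert got.loc["a1", "inside"]  # coincident with a baseline member

    def test_centroid_of_triangle_inside(self):
        ord_ = self.ordination()
        labels = {"a1": 0, "a2": 0, "a3": 0}
        coords = ord_.coordinates_frame().iloc[:, :2]
        centroid = coords.loc[["a1", "a2", "a3"]].mean()
        # q_in sits near the centroid of cluster 0 by construction.
        assert np.linalg.norm(
            coords.loc["q_in"] - centroid
        ) < np.linalg.norm(coords.loc["a2"] - centroid)
        got = cluster_membership(ord_, labels, ["q_in"])
        assert got.loc["q_in", "inside"]


class TestDownsampledRichness:
    def samples(self, ncbi_tree):
        s1 = reads(562, 40, "a") + reads(1311, 20, "b") + reads(9606, 30, "h")
        s2 = reads(562, 25, "c") + reads(621, 5, "d")
        return {"s1": s1, "s2": s2}

    def validation(self):
        v = [vres(562), vres(621), vres(1311)]
        return {"s1": v, "s2": v}

    def test_host_reads_excluded_before_depth(self, ncbi_tree):
        out = downsampled_richness(
            self.samples(ncbi_tree), ncbi_tree, self.validation(), seed=0
        )
        # s1 retains 60 after dropping human (Chordata); s2 has 30.
        assert (out["depth"] == 30).all()

    def test_richness_bounded_by_full_counts(self, ncbi_tree):
        out = downsampled_richness(
            self.samples(ncbi_tree), ncbi_tree, self.validation(), seed=0
        )
        assert out.loc["s1", "n_species"] <= 2
        assert out.loc["s2", "n_species"] <= 2

    def test_equal_depth_counts_exact(self, ncbi_tree):
        samples = {
            "s1": reads(562, 10, "a") + reads(1311, 10, "b"),
            "s2": reads(621, 20, "c"),
        }
        out = downsampled_richness(
            samples, ncbi_tree, self.validation(), seed=0
        )
        assert out.loc["s1", "n_species"] == 2
        assert out.loc["s2", "n_species"] == 1

    def test_unvalidated_taxa_not_counted(self, ncbi_tree):
        samples = {
            "s1": reads(562, 10, "a"),
            "s2": reads(621, 10, "b"),
        }
        validation = {
            "s1": [vres(562)],
            "s2": [vres(621, validated=False)],
        }
        out = downsampled_richness(samples, ncbi_tree, validation, seed=0)
        assert out.loc["s2", "n_species"] == 0

    def test_empty_sample_named_in_error(self, ncbi_tree):
        samples = {"s1": reads(562, 10, "a"), "s2": reads(9606, 5, "h")}
        with pytest.raises(ValueError, match="s2"):
            downsampled_richness(
                samples, ncbi_tree, self.validation(), seed=0
            )
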