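"""Relatedness, IBS distance, MDS, neighbor joining, clustering, admixture."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cnvpopgen as c
from cnvpopgen.calling import GenotypeMatrix
from cnvpopgen.errors import InputError
from cnvpopgen.popstruct import (
    DistanceMatrix,
    align_q_to_truth,
    dendrogram_to_newick,
    hier_cluster,
    ibd_probs,
    ibs_distance,
    mds,
    nj_tree,
    pihat,
    pihat_matrix,
    relatedness_filter,
)
from cnvpopgen.synthetic import simulate_deletion_markers


def codes_from_dosage(X):
    codes = np.where(np.asarray(X) == 1, "12", "22").astype(object)
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(codes.shape[0])],
        markers=[f"m{j}" for j in range(codes.shape[1])],
        codes=codes,
    )


# ---------------------------------------------------------------------------
# relatedness


class TestPihat:
    def test_duplicate_pair_near_one(self):
        rng = np.random.default_rng(8)
        q = rng.uniform(0.1, 0.6, 200)
        x = (rng.random(200) < (1 - (1 - q) ** 2)).astype(int)
        assert pihat(x, x, q) >= 0.95

    def test_unrelated_pairs_near_zero(self):
        cfg = dataclasses.replace(
            c.SimConfig(), n_groups=1, breeds_per_group=1, n_per_breed=100,
            n_hybrids=0, n_differentiated_loci=0)
        g, _, _ = simulate_deletion_markers(cfg, 200, seed=5)
        P = pihat_matrix(g).to_numpy()
        pairs = [(2 * k, 2 * k + 1) for k in range(50)]
        assert abs(np.mean([P[i, j] for i, j in pairs])) <= 0.1

    def test_always_within_unit_interval(self):
        rng = np.random.default_rng(3)
        q = rng.uniform(0.05, 0.95, 80)
        for _ in range(20):
            x1 = (rng.random(80) < 0.5).astype(int)
            x2 = (rng.random(80) < 0.5).astype(int)
            assert 0.0 <= pihat(x1, x2, q) <= 1.0

    def test_monomorphic_markers_rejected(self):
        with pytest.raises(InputError, match="monomorphic"):
            pihat(np.ones(10, int), np.ones(10, int), np.ones(10))

    def test_ibd_decomposition_consistent(self):
        for theta in (0.0, 0.2, 0.5, 0.7, 1.0):
            p0, p1, p2 = ibd_probs(theta)
            assert p0 + p1 + p2 == pytest.approx(1.0)
            assert min(p0, p1, p2) >= 0.0
            assert p1 / 2 + p2 == pytest.approx(theta)


class TestRelatednessFilter:
    def test_one_duplicate_pair_removes_exactly_one(self):
        cfg = dataclasses.replace(
            c.SimConfig(), n_groups=1, breeds_per_group=1, n_per_breed=30,
            n_hybrids=0, n_differentiated_loci=0)
        g, _, _ = simulate_deletion_markers(cfg, 150, seed=2)
        codes = np.vstack([g.codes, g.codes[0]])
        gd = GenotypeMatrix(samples=g.samples + ["dup"], markers=g.markers, codes=codes)
        retained = relatedness_filter(gd, max_pihat=0.4)
        assert len(retained) == 30
        assert (g.samples[0] in retained) != ("dup" in retained)

    def test_identity_when_no_relatives(self):
        cfg = dataclasses.replace(
            c.SimConfig(), n_groups=1, breeds_per_group=1, n_per_breed=25,
            n_hybrids=0, n_differentiated_loci=0, base_freq_range=(0.1, 0.5))
        g, _, _ = simulate_deletion_markers(cfg, 300, seed=6)
        assert relatedness_filter(g, max_pihat=0.4) == g.samples

    def test_fixture_300_to_205(self):
        # 205 unrelated individuals plus 95 injected duplicates
        cfg = dataclasses.replace(
            c.SimConfig(), n_groups=1, breeds_per_group=1, n_per_breed=205,
            n_hybrids=0, n_differentiated_loci=0, base_freq_range=(0.1, 0.5))
        g, _, _ = simulate_deletion_markers(cfg, 400, seed=10)
        codes = np.vstack([g.codes, g.codes[:95]])
        gd = GenotypeMatrix(
            samples=g.samples + [f"rel{i}" for i in range(95)],
            markers=g.markers, codes=codes)
        retained = relatedness_filter(gd, max_pihat=0.4)
        assert len(retained) == 205


# ---------------------------------------------------------------------------
# distance and embedding


class TestIbsDistance:
    def test_identical_vectors_give_zero(self):
        g = codes_from_dosage([[1, 0, 1, 0], [1, 0, 1, 0]])
        D = ibs_distance(g)
        assert D.D[0, 1] == 0.0

    def test_hand_counted_formula(self):
        # g1 = 12,22,22,12 ; g2 = 22,22,12,12 -> IBS2=2, IBS1=2, D = 0.25
        g = codes_from_dosage([[1, 0, 0, 1], [0, 0, 1, 1]])
        D = ibs_distance(g)
        assert D.D[0, 1] == pytest.approx(0.25)

    def test_maximum_distance_is_half(self):
        g = codes_from_dosage([[1, 1, 1], [0, 0, 0]])
        D = ibs_distance(g)
        assert D.D[0, 1] == pytest.approx(0.5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(2, 8), st.integers(1, 20), st.integers(0, 10_000))
    def test_bounds_symmetry_zero_diagonal(self, n, L, seed):
        rng = np.random.default_rng(seed)
        g = codes_from_dosage(rng.integers(0, 2, size=(n, L)))
        D = ibs_distance(g)
        assert np.allclose(D.D, D.D.T)
        assert np.allclose(np.diag(D.D), 0.0)
        assert D.D.max() <= 0.5 + 1e-12

    def test_zero_markers_rejected(self):
        g = GenotypeMatrix(samples=["a", "b"], markers=[],
                           codes=np.empty((2, 0), dtype=object))
        with pytest.raises(InputError):
            ibs_distance(g)


class TestMDS:
    def test_equilateral_triangle_exact(self):
        D = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        coords = mds(D, dims=2).to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0, abs=1e-9)

    def test_points_on_a_line_recovered(self):
        pts = np.array([0.0, 1.0, 3.0]) / 10
        D = DistanceMatrix(list("abc"), np.abs(pts[:, None] - pts[None, :]))
        x = mds(D, dims=1)["C1"].to_numpy()
        gaps = np.abs(np.diff(x))
        assert gaps == pytest.approx([0.1, 0.2], abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_euclidean_rank_le_dims_reproduced(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(7, 3)) * 0.1
        D = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        coords = mds(DistanceMatrix([f"s{i}" for i in range(7)], D), dims=3).to_numpy()
        D2 = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        assert np.allclose(D, D2, atol=1e-9)

    def test_separates_most_diverged_group(self, standard_pipeline):
        _, sheet, _, segset, regions = standard_pipeline
        g = c.recode_deletions(regions, samples=segset.samples)
        coords = mds(ibs_distance(g), dims=4)
        c1 = coords["C1"].to_numpy()
        g1 = (sheet["group"] == "G1").to_numpy()
        pure_other = sheet["group"].isin(["G2", "G3"]).to_numpy()
        lo, hi = c1[g1].min(), c1[g1].max()
        other = c1[pure_other]
        # zero overlap between the diverged group and the remaining purebreds
        assert (other.min() > hi) or (other.max() < lo)


class TestNJ:
    def test_recovers_hand_built_additive_tree(self):
        # tree ((A:1,B:2):5,(C:3,D:4)) scaled into [0,1]
        D = np.array([[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]],
                     dtype=float) / 20
        tree = nj_tree(DistanceMatrix(list("ABCD"), D))
        M = tree.path_lengths().loc[list("ABCD"), list("ABCD")].to_numpy()
        assert np.allclose(M, D, atol=1e-9)
        assert sorted(tree.leaf_names()) == list("ABCD")

    def test_three_taxa_exact(self):
        D = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        tree = nj_tree(DistanceMatrix(list("abc"), D))
        M = tree.path_lengths().loc[list("abc"), list("abc")].to_numpy()
        assert np.allclose(M, D, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_additive_trees_reproduced(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        D = random_additive_matrix(n, rng)
        ids = [f"t{i}" for i in range(n)]
        tree = nj_tree(DistanceMatrix(ids, D))
        M = tree.path_lengths().loc[ids, ids].to_numpy()
        assert np.allclose(M, D, atol=1e-9)

    def test_agrees_with_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(17)
        n = 7
        D = random_additive_matrix(n, rng)
        ids = [f"t{i}" for i in range(n)]
        ours = nj_tree(DistanceMatrix(ids, D)).path_lengths().loc[ids, ids].to_numpy()
        sk_tree = sk_nj(skbio.DistanceMatrix(D, ids))
        theirs = sk_tree.tip_tip_distances(ids).data
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_non_symmetric_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = 0.2
        with pytest.raises(InputError):
            nj_tree(DistanceMatrix(list("abc"), D))


def random_additive_matrix(n, rng):
    """Path-distance matrix of a random binary tree with random lengths."""
    nodes = [{i} for i in range(n)]
    dist = np.zeros((n, n))
    extra = np.zeros(n)  # distance from each leaf to its current cluster root
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        li, lj = rng.uniform(0.01, 0.1, 2)
        for a in nodes[i]:
            for b in nodes[j]:
                dist[a, b] = dist[b, a] = extra[a] + li + lj + extra[b]
        for a in nodes[i]:
            extra[a] += li
        for b in nodes[j]:
            extra[b] += lj
        nodes[i] |= nodes[j]
        del nodes[j]
    return dist


# ---------------------------------------------------------------------------
# hierarchical clustering


class TestHierCluster:
    def test_hand_traced_average_linkage(self):
        # distances: d(A,B)=1, d(C,A)=d(C,B)=2 -> first merge at 1, final at 2
        pts = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(4 - 0.25)]],
                           index=list("ABC"))
        Z = hier_cluster(pts)
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(2.0)

    def test_top_split_separates_far_groups(self, standard_pipeline):
        _, sheet, _, _, regions = standard_pipeline
        means = c.region_mean_matrix(regions)
        Z = hier_cluster(means)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(Z, t=2, criterion="maxclust")
        # the top split should be group-coherent for the diverged group G1
        g1 = (sheet["group"] == "G1").to_numpy()
        assert len(set(labels[g1])) == 1

    def test_heights_non_decreasing(self, standard_pipeline):
        _, _, _, _, regions = standard_pipeline
        Z = hier_cluster(c.region_mean_matrix(regions))
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_newick_serialization_has_all_leaves(self):
        pts = pd.DataFrame(np.eye(4), index=list("wxyz"))
        Z = hier_cluster(pts)
        nwk = dendrogram_to_newick(Z, list("wxyz"))
        for leaf in "wxyz":
            assert leaf in nwk
        assert nwk.endswith(";")


# ---------------------------------------------------------------------------
# admixture


class TestAdmixture:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        g = codes_from_dosage(rng.integers(0, 2, size=(20, 30)))
        fit = c.admixture_fit(g, K=1, seed=0, n_restarts=1)
        assert np.allclose(fit.Q.to_numpy(), 1.0)
        assert np.allclose(fit.F.to_numpy()[0], g.dosage.mean(axis=0), atol=1e-6)

    def test_two_fixed_populations_fully_assigned(self):
        X = np.zeros((20, 50), dtype=int)
        X[:10] = 1  # population 1 fixed for the deletion, population 2 without
        fit = c.admixture_fit(codes_from_dosage(X), K=2, seed=1)
        Q = fit.Q.to_numpy()
        assert np.all(Q.max(axis=1) >= 0.99)
        # the two populations map to different clusters
        assert Q[:10].argmax(axis=1).mean() != Q[10:].argmax(axis=1).mean()

    def test_loglik_trace_non_decreasing(self, admixture_cohort):
        g, _, _ = admixture_cohort
        for K in (2, 3):
            fit = c.admixture_fit(g, K=K, seed=4, n_restarts=2)
            assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_three_group_ancestry_recovered(self, admixture_cohort):
        g, sheet, ancestry = admixture_cohort
        fit = c.admixture_fit(g, K=3, seed=3)
        aligned = align_q_to_truth(fit.Q, ancestry)
        mae = np.abs(aligned.to_numpy() - ancestry.to_numpy()).mean()
        assert mae <= 0.08

    def test_k_exceeding_samples_rejected(self):
        g = codes_from_dosage([[1, 0], [0, 1]])
        with pytest.raises(InputError):
            c.admixture_fit(g, K=3)
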