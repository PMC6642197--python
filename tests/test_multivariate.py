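"""Clustering, bootstrap support, PCA, projection, correspondence calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from digitexpr import (
    ExpressionMatrix,
    ValidationError,
    average_linkage,
    bootstrap_pca,
    bootstrap_support,
    call_correspondence,
    correlation_dissimilarity,
    fit_pca,
    project_supplementary,
)


def random_expression(n_genes=30, n_samples=6, seed=0, state="sqrt_tpm"):
    rng = np.random.default_rng(seed)
    vals = pd.DataFrame(
        rng.lognormal(3, 1, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(vals, transform_state=state)


def em_from(rows, samples, state="sqrt_tpm"):
    return ExpressionMatrix(
        pd.DataFrame(
            np.asarray(rows, float),
            index=[f"g{i}" for i in range(len(rows))],
            columns=samples,
        ),
        transform_state=state,
    )


class TestCorrelationDissimilarity:
    def test_duplicate_sample_zero(self):
        em = em_from([[1, 1, 5], [2, 2, 1], [3, 3, 9]], ["a", "b", "c"])
        d = correlation_dissimilarity(em)
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_is_two(self):
        em = em_from([[1, 3], [2, 2], [3, 1]], ["a", "b"])
        assert correlation_dissimilarity(em).loc["a", "b"] == pytest.approx(2.0)

    def test_hand_pearson(self):
        em = em_from([[1, 1], [2, 2], [3, 4]], ["a", "b"])
        expected = 1 - np.corrcoef([1, 2, 3], [1, 2, 4])[0, 1]
        assert correlation_dissimilarity(em).loc["a", "b"] == pytest.approx(expected)

    def test_zero_variance_sample_named(self):
        em = em_from([[1, 5], [1, 6], [1, 7]], ["flat", "ok"])
        with pytest.raises(ValidationError, match="flat"):
            correlation_dissimilarity(em)


class TestAverageLinkage:
    def test_hand_linkage_example(self):
        d = pd.DataFrame(
            [[0, 1, 4], [1, 0, 5], [4, 5, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = average_linkage(d)
        heights = sorted(n.height for n in tree.internal_nodes())
        assert heights == pytest.approx([1.0, 4.5])
        assert frozenset("AB") in tree.clusters()

    def test_duplicates_join_first_and_node_count(self):
        rng = np.random.default_rng(0)
        em = random_expression(20, 5, seed=1)
        em.values["s5"] = em.values["s0"]
        d = correlation_dissimilarity(em)
        tree = average_linkage(d)
        assert frozenset(["s0", "s5"]) in tree.clusters()
        assert len(tree.internal_nodes()) == 6 - 1
        del rng

    def test_heights_permutation_invariant(self):
        em = random_expression(25, 7, seed=2)
        d = correlation_dissimilarity(em)
        h1 = sorted(n.height for n in average_linkage(d).internal_nodes())
        perm = list(np.random.default_rng(0).permutation(d.index))
        h2 = sorted(n.height for n in average_linkage(d.loc[perm, perm]).internal_nodes())
        assert h1 == pytest.approx(h2)

    def test_matches_scipy_upgma_heights(self):
        em = random_expression(30, 6, seed=3)
        d = correlation_dissimilarity(em)
        ours = sorted(n.height for n in average_linkage(d).internal_nodes())
        from scipy.spatial.distance import squareform

        Z = hierarchy.average(squareform(d.to_numpy(), checks=False))
        assert ours == pytest.approx(sorted(Z[:, 2]))


class TestBootstrapSupport:
    def planted_em(self, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(2, 1, size=(60, 1))
        vals = np.tile(base, (1, 8)) + rng.normal(0, 0.05 * base, size=(60, 8))
        vals[:20, 4:] *= 6.0  # second cluster strongly shifted
        return em_from(np.abs(vals), [f"s{j}" for j in range(8)])

    def test_separated_clusters_get_high_support(self):
        tree = bootstrap_support(self.planted_em(), n_boot=200, seed=1)
        bp = tree.support_of([f"s{j}" for j in range(4)])
        if bp is None:
            bp = tree.support_of([f"s{j}" for j in range(4, 8)])
        assert bp is not None and bp >= 99.0

    def test_same_seed_reproducible(self):
        em = random_expression(40, 6, seed=4)
        t1 = bootstrap_support(em, n_boot=120, seed=9)
        t2 = bootstrap_support(em, n_boot=120, seed=9)
        assert [n.bp for n in t1.internal_nodes()] == [n.bp for n in t2.internal_nodes()]

    def test_structureless_data_low_support(self):
        meds = []
        for seed in range(10):
            em = random_expression(80, 8, seed=100 + seed)
            tree = bootstrap_support(em, n_boot=150, seed=seed)
            bps = [
                n.bp for n in tree.internal_nodes()
                if len(n.leaves()) < 8  # skip root (always 100)
            ]
            meds.append(np.median(bps))
        assert np.median(meds) < 70

    def test_au_values_in_range(self):
        tree = bootstrap_support(self.planted_em(), n_boot=120, seed=2, compute_au=True)
        for n in tree.internal_nodes():
            assert 0 <= n.bp <= 100
            assert n.au is None or 0 <= n.au <= 100


class TestPCA:
    def test_training_scores_reproduced_by_projection(self):
        em = random_expression(50, 8, seed=5)
        model = fit_pca(em)
        proj = project_supplementary(model, em)
        np.testing.assert_allclose(
            proj.to_numpy(), model.scores.to_numpy(), atol=1e-8
        )

    def test_gene_mean_projects_to_origin(self):
        em = random_expression(30, 5, seed=6)
        model = fit_pca(em)
        mean_sample = ExpressionMatrix(
            model.gene_means.to_frame("mean_sample"), em.transform_state
        )
        proj = project_supplementary(model, mean_sample)
        np.testing.assert_allclose(proj.to_numpy(), 0.0, atol=1e-8)

    def test_diagonal_line_loading(self):
        # samples along y = x in 2-gene space: PC1 loading (1,1)/sqrt(2)
        vals = pd.DataFrame(
            {"s0": [1.0, 1.0], "s1": [2.0, 2.0], "s2": [3.0, 3.0], "s3": [4.0, 4.0]},
            index=["gx", "gy"],
        )
        em = ExpressionMatrix(vals, "sqrt_tpm")
        model = fit_pca(em)
        np.testing.assert_allclose(
            model.loadings["PC1"].abs(), 1 / np.sqrt(2), atol=1e-10
        )
        assert (model.loadings["PC1"] > 0).all()  # deterministic sign

    def test_orthonormal_loadings_and_reconstruction(self):
        em = random_expression(40, 7, seed=7)
        model = fit_pca(em)
        L = model.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        centered = em.values.to_numpy().T - model.gene_means.to_numpy()
        recon = model.scores.to_numpy() @ L.T
        np.testing.assert_allclose(recon, centered, atol=1e-8)
        assert model.explained.sum() <= 1 + 1e-12

    def test_hand_projection(self):
        em = random_expression(2, 3, seed=8)
        model = fit_pca(em)
        model.gene_means = pd.Series([1.0, 1.0], index=em.values.index)
        model.loadings = pd.DataFrame(
            {"PC1": [1.0, 0.0]}, index=em.values.index
        )
        held = ExpressionMatrix(
            pd.DataFrame({"h": [3.0, 1.0]}, index=em.values.index), "sqrt_tpm"
        )
        proj = project_supplementary(model, held)
        assert proj.loc["h", "PC1"] == pytest.approx(2.0)

    def test_gene_universe_mismatch_rejected(self):
        em = random_expression(10, 4, seed=9)
        model = fit_pca(em)
        held = random_expression(5, 2, seed=10)
        with pytest.raises(ValidationError, match="lacks genes"):
            project_supplementary(model, held)

    def test_duplicate_heldout_lands_on_training_score(self):
        em = random_expression(25, 5, seed=11)
        model = fit_pca(em)
        dup = ExpressionMatrix(em.values[["s2"]].rename(columns={"s2": "dup"}), "sqrt_tpm")
        proj = project_supplementary(model, dup)
        np.testing.assert_allclose(
            proj.loc["dup"].to_numpy(), model.scores.loc["s2"].to_numpy(), atol=1e-8
        )


class TestBootstrapPCA:
    def separated_em(self, n_per_group, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(2, 0.5, size=(30, 1))
        cols = {}
        for j in range(n_per_group):
            cols[f"a{j}"] = (base[:, 0] + rng.normal(0, 0.1, 30))
            shifted = base[:, 0].copy()
            shifted[:10] *= 5
            cols[f"b{j}"] = shifted + rng.normal(0, 0.1, 30)
        return ExpressionMatrix(
            pd.DataFrame(np.abs(pd.DataFrame(cols).to_numpy()),
                         index=[f"g{i}" for i in range(30)],
                         columns=list(cols)),
            "sqrt_tpm",
        )

    def test_same_seed_identical_summaries(self):
        em = self.separated_em(3, seed=1)
        s1, _ = bootstrap_pca(em, n_boot=100, seed=3)
        s2, _ = bootstrap_pca(em, n_boot=100, seed=3)
        pd.testing.assert_frame_equal(s1, s2)

    def test_groups_non_overlapping_clouds(self):
        em = self.separated_em(4, seed=2)
        summary, ref = bootstrap_pca(em, n_boot=150, seed=4)
        a = summary.loc[[s for s in summary.index if s.startswith("a")]]
        b = summary.loc[[s for s in summary.index if s.startswith("b")]]
        # clouds (mean +- 2 sd) of the two groups do not overlap on PC1
        lo_a = (a["mean_PC1"] - 2 * a["sd_PC1"]).min()
        hi_a = (a["mean_PC1"] + 2 * a["sd_PC1"]).max()
        lo_b = (b["mean_PC1"] - 2 * b["sd_PC1"]).min()
        hi_b = (b["mean_PC1"] + 2 * b["sd_PC1"]).max()
        assert hi_a < lo_b or hi_b < lo_a

    def test_variability_shrinks_with_samples(self):
        sds_small, sds_big = [], []
        for seed in range(5):
            em_s = self.separated_em(3, seed=seed)
            em_b = self.separated_em(10, seed=seed)
            s, _ = bootstrap_pca(em_s, n_boot=100, seed=seed)
            b, _ = bootstrap_pca(em_b, n_boot=100, seed=seed)
            sds_small.append(s["sd_PC1"].median())
            sds_big.append(b["sd_PC1"].median())
        assert np.mean(sds_big) < np.mean(sds_small)


class TestCorrespondence:
    def labelled_model(self):
        rng = np.random.default_rng(0)
        centers = {1: (-10, 0), 2: (0, 0), 3: (10, 0)}
        cols, labels = {}, {}
        for d, (cx, cy) in centers.items():
            for r in range(3):
                s = f"d{d}_r{r}"
                cols[s] = [cx + rng.normal(0, 0.1), cy + rng.normal(0, 0.1), 0.0]
                labels[s] = d
        vals = pd.DataFrame(cols, index=["g0", "g1", "g2"])
        em = ExpressionMatrix(vals + 20, "sqrt_tpm")
        model = fit_pca(em, digit_labels=pd.Series(labels))
        return model

    def test_centroid_assignment_distance_zero(self):
        model = self.labelled_model()
        cents = model.scores.loc[model.digit_labels.index].groupby(
            model.digit_labels
        ).mean()
        probe = cents.loc[[2]].set_axis(["probe"])
        call = call_correspondence(model, probe)
        assert call.table.loc["probe", "digit"] == 2
        assert call.table.loc["probe", "distance"] == pytest.approx(0.0, abs=1e-9)

    def test_tie_goes_to_lower_digit(self):
        model = self.labelled_model()
        cents = call_correspondence(model, model.scores).centroids
        mid = (cents.loc[1] + cents.loc[2]) / 2
        probe = pd.DataFrame([mid], index=["probe"])
        call = call_correspondence(model, probe)
        assert call.table.loc["probe", "digit"] == 1
        assert call.table.loc["probe", "margin"] == pytest.approx(0.0, abs=1e-9)
        assert bool(call.table.loc["probe", "tie"])

    def test_unlabelled_model_rejected(self):
        em = random_expression(10, 4, seed=12)
        model = fit_pca(em)
        with pytest.raises(ValidationError):
            call_correspondence(model, model.scores)
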