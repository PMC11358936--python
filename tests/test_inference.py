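"""PERMANOVA, beta-dispersion, t-tests and PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from traitcomm import (
    ValidationError,
    beta_dispersion,
    pca_scores,
    per_trait_t_tests,
    permanova,
)


def euclidean_f_oracle(X, groups):
    """Independent pseudo-F oracle from explicit centroid geometry."""
    X = np.asarray(X, float)
    g = np.asarray(groups)
    grand = X.mean(axis=0)
    ssw = sum(
        ((X[g == lab] - X[g == lab].mean(axis=0)) ** 2).sum() for lab in np.unique(g)
    )
    sst = ((X - grand) ** 2).sum()
    ssb = sst - ssw
    a, n = len(np.unique(g)), len(g)
    return (ssb / (a - 1)) / (ssw / (n - a)), sst, ssw, ssb


class TestPermanova:
    def test_pseudo_f_matches_centroid_geometry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            X = rng.normal(size=(9, 3))
            g = np.array(["a"] * 4 + ["b"] * 5)
            D = squareform(pdist(X))
            res = permanova(D, g, n_perm=19, seed=0)
            F, sst, ssw, ssb = euclidean_f_oracle(X, g)
            assert res.pseudo_F == pytest.approx(F, rel=1e-9)
            assert res.ss_total == pytest.approx(sst, rel=1e-9)
            assert res.ss_within == pytest.approx(ssw, rel=1e-9)
            assert res.ss_total == pytest.approx(res.ss_within + res.ss_between, rel=1e-9)

    def test_matches_skbio_statistic(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 4))
        g = ["a"] * 6 + ["b"] * 6
        D = squareform(pdist(X))
        res = permanova(D, g, n_perm=9, seed=0)
        sk = sk_permanova(DistanceMatrix(D), grouping=g, permutations=9)
        assert res.pseudo_F == pytest.approx(float(sk["test statistic"]), rel=1e-9)

    def test_perfect_separation_hits_p_floor(self):
        # two coincident clusters far apart: SS_within = 0, F = inf, p at floor
        X = np.array([[0.0]] * 8 + [[5.0]] * 8)
        D = squareform(pdist(X))
        res = permanova(D, ["a"] * 8 + ["b"] * 8, n_perm=99, seed=1)
        assert res.ss_within == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 100)

    def test_degenerate_groups_rejected(self):
        D = squareform(pdist(np.arange(4.0)[:, None]))
        with pytest.raises(ValidationError, match="replication"):
            permanova(D, ["a", "a", "a", "b"], n_perm=9)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        D = squareform(pdist(rng.normal(size=(10, 2))))
        g = ["a"] * 5 + ["b"] * 5
        r1 = permanova(D, g, n_perm=99, seed=3)
        r2 = permanova(D, g, n_perm=99, seed=3)
        assert r1.p_value == r2.p_value


class TestBetaDispersion:
    def test_identical_points_have_zero_distances(self):
        X = np.array([[0, 0], [0, 0], [0, 0], [1, 2], [3, 1], [2, 2]], dtype=float)
        D = squareform(pdist(X))
        res = beta_dispersion(D, ["a"] * 3 + ["b"] * 3, n_perm=19, seed=0)
        np.testing.assert_allclose(res.distances.iloc[:3], 0.0, atol=1e-10)

    def test_scaled_group_detected(self):
        # one group blown up 3x around its centroid: dispersion differs
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=(15, 3))
            b = rng.normal(size=(15, 3)) * 3
            D = squareform(pdist(np.vstack([a, b])))
            res = beta_dispersion(D, ["a"] * 15 + ["b"] * 15, n_perm=199, seed=seed)
            hits += res.p_permutation <= 0.05
        assert hits >= 18

    def test_mirror_groups_not_detected(self):
        # mirror-image clouds have equal dispersion by construction
        sig = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            a = rng.normal(size=(12, 3))
            b = -a + 10.0
            D = squareform(pdist(np.vstack([a, b])))
            res = beta_dispersion(D, ["a"] * 12 + ["b"] * 12, n_perm=199, seed=seed)
            sig += res.p_permutation <= 0.05
        assert sig <= 3

    def test_matches_r_vegan_betadisper(self, tmp_path):
        """Cross-check centroid distances against vegan::betadisper."""
        import subprocess

        rng = np.random.default_rng(17)
        X = rng.normal(size=(10, 3))
        D = squareform(pdist(X))
        g = ["a"] * 5 + ["b"] * 5
        res = beta_dispersion(D, g, n_perm=19, seed=0)
        np.savetxt(tmp_path / "d.csv", D, delimiter=",")
        script = tmp_path / "bd.R"
        script.write_text(
            'suppressMessages(library(vegan))\n'
            f'd <- as.dist(as.matrix(read.csv("{tmp_path}/d.csv", header=FALSE)))\n'
            'g <- factor(rep(c("a","b"), each=5))\n'
            'b <- betadisper(d, g, type="centroid")\n'
            'cat(b$distances, sep="\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        vegan_d = np.array([float(x) for x in out.stdout.split()])
        np.testing.assert_allclose(res.distances.to_numpy(), vegan_d, rtol=1e-6)


class TestTraitTTests:
    def test_closed_form_on_hand_samples(self):
        a = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        b = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        tab = per_trait_t_tests(a, b)
        # textbook pooled-variance Student's t
        sp2 = (2 * 1.0 + 2 * 4.0) / 4
        t_expected = (2.0 - 4.0) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=4)
        row = tab.loc["x"]
        assert row["t"] == pytest.approx(t_expected, rel=1e-12)
        assert row["df"] == 4
        assert row["p_value"] == pytest.approx(p_expected, rel=1e-12)
        assert np.sign(row["t"]) == np.sign(row["mean_dominant"] - row["mean_subordinate"])

    def test_identical_matrices_give_null_results(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        tab = per_trait_t_tests(m, m.copy())
        np.testing.assert_allclose(tab["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(tab["p_value"], 1.0)
        assert not tab["significant"].any()

    def test_shifted_trait_flagged_others_near_alpha(self):
        rng = np.random.default_rng(1)
        hits = np.zeros(6)
        n_rep = 60
        for _ in range(n_rep):
            a = pd.DataFrame(rng.normal(size=(20, 6)))
            b = pd.DataFrame(rng.normal(size=(20, 6)))
            b[0] += 10.0
            tab = per_trait_t_tests(a, b)
            hits += tab["significant"].to_numpy()
        assert hits[0] == n_rep
        null_rate = hits[1:].mean() / n_rep
        assert 0.0 <= null_rate < 0.15

    def test_constant_columns_flagged_not_nan_propagated(self):
        a = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        b = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        tab = per_trait_t_tests(a, b)
        assert bool(tab.loc["x", "undefined"])
        eq = per_trait_t_tests(a, a.copy())
        assert eq.loc["x", "t"] == 0.0 and eq.loc["x", "p_value"] == 1.0

    def test_insufficient_replication_rejected(self):
        a = pd.DataFrame({"x": [1.0]})
        b = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="replication"):
            per_trait_t_tests(a, b)


class TestPCA:
    def test_collinear_data_one_component(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([t, 2 * t, -t])
        res = pca_scores(X, standardize=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_rotation_invariant_spectrum(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3)) @ np.diag([3.0, 1.0, 0.3])
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        r1 = pca_scores(X, standardize=False)
        r2 = pca_scores(X @ Q, standardize=False)
        np.testing.assert_allclose(r1.explained_variance, r2.explained_variance, rtol=1e-9)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 6))
        res = pca_scores(X, standardize=False)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, X - X.mean(axis=0), atol=1e-10)
        var = res.explained_variance
        assert np.all(np.diff(var) <= 1e-12)

    def test_all_constant_rejected(self):
        with pytest.raises(ValidationError):
            pca_scores(np.ones((5, 3)))
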