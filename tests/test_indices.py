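"""Community-weighted means and Rao quadratic diversity."""

import numpy as np
import pandas as pd
import pytest

from traitcomm import (
    ValidationError,
    build_group_matrices,
    circular_weighted_mean,
    community_weighted_mean,
    expand_traits,
    rao_quadratic_diversity,
    relative_abundances,
)


def brute_force_rao(p, D):
    """Independent oracle: explicit double sum over all ordered pairs."""
    total = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            total += D[i][j] * p[i] * p[j]
    return total


class TestCWM:
    @pytest.mark.parametrize(
        "p,x,expected",
        [((1.0,), (10.0,), 10.0), ((0.5, 0.5), (0.0, 10.0), 5.0), ((0.25, 0.75), (4.0, 8.0), 7.0)],
    )
    def test_weighted_mean_arithmetic(self, p, x, expected):
        assert community_weighted_mean(p, x) == pytest.approx(expected)

    def test_missing_values_renormalise_weights(self):
        assert community_weighted_mean([0.5, 0.25, 0.25], [np.nan, 2.0, 6.0]) == pytest.approx(4.0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            community_weighted_mean([1.0], [np.nan])


class TestCircularCWM:
    def test_wraparound_mean(self):
        mean, r = circular_weighted_mean([0.5, 0.5], [350.0, 10.0])
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert r > 0.9

    def test_single_species(self):
        mean, _ = circular_weighted_mean([1.0], [123.0])
        assert mean == pytest.approx(123.0)

    def test_antipodal_is_undefined(self):
        mean, r = circular_weighted_mean([0.5, 0.5], [0.0, 180.0])
        assert np.isnan(mean)
        assert r < 1e-9


class TestRao:
    def test_single_species_is_zero(self):
        assert rao_quadratic_diversity([1.0], [[0.0]]) == 0.0

    def test_two_species_maximum(self):
        D = [[0.0, 1.0], [1.0, 0.0]]
        assert rao_quadratic_diversity([0.5, 0.5], D) == pytest.approx(0.5)

    def test_three_equal_species_all_dissimilar(self):
        D = 1.0 - np.eye(3)
        assert rao_quadratic_diversity([1 / 3] * 3, D) == pytest.approx(2 / 3)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(2, 11)
            p = rng.dirichlet(np.ones(n))
            D = rng.uniform(0, 1, (n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            assert rao_quadratic_diversity(p, D) == pytest.approx(
                brute_force_rao(p, D), rel=1e-12
            )

    def test_invariant_to_zero_abundance_species(self):
        rng = np.random.default_rng(3)
        n = 5
        p = rng.dirichlet(np.ones(n))
        D = rng.uniform(0, 1, (n, n)); D = (D + D.T) / 2; np.fill_diagonal(D, 0)
        base = rao_quadratic_diversity(p, D)
        p2 = np.append(p, 0.0)
        D2 = np.pad(D, ((0, 1), (0, 1)), constant_values=0.7)
        D2[-1, -1] = 0.0
        assert rao_quadratic_diversity(p2, D2) == pytest.approx(base, rel=1e-12)

    def test_adding_identical_species_never_increases_fd(self):
        """Monotone dilution: a species at d=0 to all residents dilutes pairs."""
        rng = np.random.default_rng(11)
        n = 4
        p = rng.dirichlet(np.ones(n))
        D = rng.uniform(0.2, 1, (n, n)); D = (D + D.T) / 2; np.fill_diagonal(D, 0)
        base = rao_quadratic_diversity(p, D)
        for share in (0.1, 0.5, 0.9):
            p2 = np.append(p * (1 - share), share)
            D2 = np.pad(D, ((0, 1), (0, 1)))  # new species at d=0 to everyone
            assert rao_quadratic_diversity(p2, D2) <= base + 1e-12

    def test_missing_pairs_renormalised(self):
        D = np.array([[0.0, np.nan, 1.0], [np.nan, 0.0, 1.0], [1.0, 1.0, 0.0]])
        p = np.array([1 / 3] * 3)
        # retained pair weight: all but the (0,1)/(1,0) pair = 1 - 2/9 = 7/9
        expected = (4 / 9) / (7 / 9)
        assert rao_quadratic_diversity(p, D) == pytest.approx(expected, rel=1e-12)


class TestGroupMatrices:
    def test_shapes_and_indicator_conservation(self, default_community, default_percent, default_assignment):
        _, traits, _ = default_community
        tm = expand_traits(traits)
        dom, sub = build_group_matrices(default_percent, tm, default_assignment, trait_table=traits)
        assert dom.cwm.shape == (35, 35)
        assert sub.cwm.shape == (35, 35)
        assert dom.fd.shape == (35, 16)
        # indicator CWM == summed relative abundance of species in that class
        species = default_assignment.species("subordinate")
        props = relative_abundances(default_percent, species)
        ind = tm.values.loc[species, "LF_he"]
        expected = (props * ind).sum(axis=1, min_count=1)
        valid = expected.dropna().index
        np.testing.assert_allclose(
            sub.cwm.loc[valid, "LF_he"], expected[valid], atol=1e-12
        )
        # indicator CWMs live in [0,1]
        ind_cols = [c for c in tm.column_ids if tm.column_source[c] != c]
        vals = sub.cwm[ind_cols].to_numpy()
        vals = vals[np.isfinite(vals)]
        assert vals.min() >= -1e-12 and vals.max() <= 1 + 1e-12

    def test_fd_nonnegative_and_bounded(self, default_community, default_percent, default_assignment):
        _, traits, _ = default_community
        tm = expand_traits(traits)
        dom, sub = build_group_matrices(default_percent, tm, default_assignment, trait_table=traits)
        for fd in (dom.fd, sub.fd):
            vals = fd.to_numpy()
            vals = vals[np.isfinite(vals)]
            assert vals.min() >= 0
            assert vals.max() <= 0.5 + 1e-12

    def test_single_member_plot_has_zero_fd(self, two_trait_table):
        from traitcomm import GroupAssignment, PercentCoverMatrix

        df = pd.DataFrame({"a": [37.5, 5.0], "b": [0.0, 5.0], "c": [0.0, 5.0]},
                          index=["p1", "p2"])
        m = PercentCoverMatrix(values=df, presence=df > 0)
        g = GroupAssignment(
            labels=pd.Series({"a": "dominant", "b": "subordinate", "c": "subordinate"}),
            max_cover=df.max(),
            inclusion_pct=1.0,
            dominance_pct=25.0,
        )
        tm = expand_traits(two_trait_table)
        dom, _ = build_group_matrices(m, tm, g, trait_table=two_trait_table)
        assert (dom.fd.loc["p1"] == 0).all()

    def test_species_order_is_irrelevant(self, default_community, default_percent, default_assignment):
        _, traits, _ = default_community
        tm = expand_traits(traits)
        _, sub1 = build_group_matrices(default_percent, tm, default_assignment, trait_table=None)
        shuffled = traits.values.sample(frac=1, random_state=0)
        from traitcomm import TraitTable
        tm2 = expand_traits(TraitTable(values=shuffled, schema=traits.schema))
        _, sub2 = build_group_matrices(default_percent, tm2, default_assignment, trait_table=None)
        pd.testing.assert_frame_equal(sub1.cwm, sub2.cwm)
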