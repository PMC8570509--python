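import itertools
import math

import numpy as np
import pandas as pd
import pytest

from geohab.community_stats import (
    communality_check, factor_analysis, indval, significant_indicators,
    tucker_congruence, varimax,
)
from geohab.synthetic_landscape import (
    CommunitySpec, FactorSpec, make_community, make_env_table,
)


# ---------------------------------------------------------------------------
# brute-force IndVal oracle: direct loops, no shared code with the package
# ---------------------------------------------------------------------------

def oracle_stat(presence, labels, combo):
    """IndVal.g for one species and one group combination, by loops."""
    groups = sorted(set(labels))
    means = {}
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        means[g] = sum(presence[i] for i in idx) / len(idx)
    denom = sum(means.values())
    a = sum(means[g] for g in combo) / denom if denom > 0 else 0.0
    sites = [i for i, l in enumerate(labels) if l in combo]
    b = sum(presence[i] for i in sites) / len(sites)
    return math.sqrt(a * b)


def oracle_best(presence, labels):
    groups = sorted(set(labels))
    return max(oracle_stat(presence, labels, (g,)) for g in groups)


def oracle_exact_p(presence, labels):
    """Exact permutation p over all distinct label arrangements."""
    obs = oracle_best(presence, labels)
    perms = set(itertools.permutations(labels))
    hits = sum(oracle_best(presence, p) >= obs - 1e-12 for p in perms)
    return hits / len(perms)


def toy_community():
    """6 sites, 2 groups; one perfect indicator, one spread species."""
    return pd.DataFrame({
        "group": [1, 1, 1, 2, 2, 2],
        "perfect": [1, 1, 1, 0, 0, 0],
        "everywhere": [1, 1, 1, 1, 1, 1],
        "patchy": [1, 0, 1, 1, 0, 0],
    }, index=[f"s{i}" for i in range(6)])


class TestIndval:
    def test_perfect_indicator_scores_one(self):
        tab = pd.DataFrame({
            "group": [1] * 5 + [2] * 5,
            "sp": [1] * 5 + [0] * 5,
        })
        res = indval(tab, n_perm=99, seed=0)
        row = res.table.iloc[0]
        assert row.A == 1.0 and row.B == 1.0 and row.stat == 1.0
        assert row.group == 1

    def test_ubiquitous_species_uninformative(self):
        tab = toy_community()[["group", "everywhere"]]
        res = indval(tab, n_perm=199, seed=1)
        row = res.table.iloc[0]
        assert row.stat == pytest.approx(math.sqrt(0.5))
        assert row.p_value == 1.0

    def test_permutation_p_lower_bound(self):
        spec = CommunitySpec(n_groups=3, sites_per_group=10,
                             n_indicators_per_group=1, n_noise_species=0,
                             seed=4)
        res = indval(make_community(spec), n_perm=999, seed=5)
        np.testing.assert_allclose(res.table.p_value, 1 / 1000)

    def test_exact_mode_matches_enumeration_oracle(self):
        tab = toy_community()
        res = indval(tab, n_perm="exact")
        labels = tab.group.tolist()
        for _, row in res.table.iterrows():
            presence = tab[row.species].tolist()
            assert row.p_value == pytest.approx(
                oracle_exact_p(presence, labels), abs=1e-12)

    def test_monte_carlo_within_3se_of_exact(self):
        tab = toy_community()
        labels = tab.group.tolist()
        n_perm = 2000
        res = indval(tab, n_perm=n_perm, seed=7)
        for _, row in res.table.iterrows():
            exact = oracle_exact_p(tab[row.species].tolist(), labels)
            se = math.sqrt(exact * (1 - exact) / n_perm)
            assert abs(row.p_value - exact) <= 3 * se + 2 / n_perm

    def test_stat_matches_oracle_on_random_tables(self, rng):
        for _ in range(20):
            labels = rng.integers(1, 4, 12)
            while len(set(labels)) < 3:
                labels = rng.integers(1, 4, 12)
            pres = rng.integers(0, 2, 12)
            tab = pd.DataFrame({"group": labels, "sp": pres})
            res = indval(tab, n_perm=1, seed=0)
            assert res.table.iloc[0].stat == pytest.approx(
                oracle_best(pres.tolist(), labels.tolist()), abs=1e-12)

    def test_group_combination_mode_scores_subsets(self):
        # species filling groups 1 and 2 entirely, absent from 3: the pair
        # {1,2} is the perfect combination
        tab = pd.DataFrame({
            "group": [1, 1, 2, 2, 3, 3],
            "sp": [1, 1, 1, 1, 0, 0],
        })
        res = indval(tab, n_perm=99, mode="group_combinations", seed=2)
        row = res.table.iloc[0]
        assert tuple(row.group) == (1, 2)
        assert row.stat == 1.0

    def test_null_p_values_super_uniform(self):
        # label-free noise species: P(p <= alpha) should not exceed alpha
        # by more than sampling error
        rng = np.random.default_rng(99)
        n_sites, n_species = 30, 500
        tab = pd.DataFrame(
            rng.integers(0, 2, (n_sites, n_species)),
            columns=[f"sp{i}" for i in range(n_species)])
        tab.insert(0, "group", np.repeat([1, 2, 3], 10))
        res = indval(tab, n_perm=199, seed=100)
        for alpha in (0.05, 0.1):
            rate = (res.table.p_value <= alpha).mean()
            se = math.sqrt(alpha * (1 - alpha) / n_species)
            assert rate <= alpha + 3 * se

    def test_zero_site_group_rejected(self):
        tab = pd.DataFrame({"group": [1, 1, 1], "sp": [1, 0, 1]})
        with pytest.raises(ValueError, match="2 site groups"):
            indval(tab, n_perm=9)


class TestSignificantIndicators:
    def make_result(self):
        spec = CommunitySpec(n_groups=3, sites_per_group=8,
                             n_indicators_per_group=2,
                             n_noise_species=10, seed=8)
        return indval(make_community(spec), n_perm=999, seed=9)

    def test_alpha_zero_empty(self):
        assert len(significant_indicators(self.make_result(), 0.0)) == 0

    def test_perfect_indicators_retained_at_005(self):
        sig = significant_indicators(self.make_result(), 0.05)
        planted = {f"ind_g{g}_{i}" for g in (1, 2, 3) for i in (1, 2)}
        assert planted <= set(sig.species)
        counts = sig.attrs["n_significant_by_group"]
        assert all(counts[str(g)] >= 2 for g in (1, 2, 3))

    def test_raising_alpha_never_removes_rows(self):
        res = self.make_result()
        small = set(significant_indicators(res, 0.01).species)
        large = set(significant_indicators(res, 0.2).species)
        assert small <= large


class TestVarimax:
    def test_rotation_matrix_orthonormal(self, rng):
        L = rng.normal(size=(10, 3))
        _, R = varimax(L)
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-9)

    def test_fixed_point_up_to_permutation_and_sign(self):
        # a perfectly simple structure is already varimax-optimal
        L = np.kron(np.eye(3), np.full((4, 1), 0.8))
        rotated, _ = varimax(L)
        assert tucker_congruence(L, rotated) == pytest.approx(1.0, abs=1e-6)

    def test_communalities_invariant_under_rotation(self, rng):
        L = rng.normal(size=(8, 3)) * 0.5
        rotated, _ = varimax(L)
        np.testing.assert_allclose((rotated**2).sum(axis=1),
                                   (L**2).sum(axis=1), atol=1e-9)


def strong_three_factor_spec(seed=12345):
    """18 variables, 3 orthogonal factors, loadings 0.9, unique sd
    sqrt(1 - 0.81): 6 variables per factor keeps the principal-component
    h2 inflation (~(1 - h2)/m) inside the test tolerances."""
    L = np.kron(np.eye(3), np.full((6, 1), 0.9))
    return FactorSpec(n_obs=2000, loading_matrix=L, seed=seed)


class TestFactorAnalysis:
    def test_three_factor_recovery(self):
        spec = strong_three_factor_spec()
        env = make_env_table(spec)
        res = factor_analysis(env)
        assert res.n_factors == 3
        cong = tucker_congruence(spec.loading_matrix,
                                 res.loadings.to_numpy())
        assert cong >= 0.95
        assert np.allclose(res.communalities, 0.81, atol=0.05)

    def test_pure_noise_explains_only_its_share(self):
        L = np.zeros((11, 1))
        env = make_env_table(FactorSpec(n_obs=4000, loading_matrix=L,
                                        unique_sd=np.ones(11), seed=3))
        res = factor_analysis(env)
        # identity correlation: each retained component explains ~1/11
        assert res.cumulative_var.iloc[-1] == pytest.approx(
            res.n_factors / 11, abs=0.05)

    def test_reverse_scoring_flips_loadings(self):
        spec = strong_three_factor_spec()
        env = make_env_table(spec)
        plain = factor_analysis(env)
        flipped = factor_analysis(env, reverse_scored=[env.columns[0]])
        # the sign convention re-aligns columns, so the magnitude pattern
        # is unchanged
        np.testing.assert_allclose(
            np.abs(plain.loadings.to_numpy()),
            np.abs(flipped.loadings.to_numpy()), atol=1e-9)

    def test_variance_table_monotone_and_bounded(self):
        env = make_env_table(strong_three_factor_spec())
        res = factor_analysis(env)
        cum = res.cumulative_var.to_numpy()
        assert (np.diff(cum) > 0).all()
        assert cum[-1] <= 1.0 + 1e-12
        np.testing.assert_allclose(res.ss_loadings.sum() / 18, cum[-1])

    def test_h2_u2_sum_to_one(self):
        env = make_env_table(strong_three_factor_spec())
        res = factor_analysis(env)
        np.testing.assert_allclose(res.communalities + res.uniquenesses,
                                   1.0, atol=1e-6)

    def test_zero_variance_variable_named(self):
        env = make_env_table(strong_three_factor_spec())
        env["dead"] = 1.0
        with pytest.raises(ValueError, match="dead"):
            factor_analysis(env)

    def test_too_few_observations_rejected(self):
        env = make_env_table(strong_three_factor_spec()).head(10)
        with pytest.raises(ValueError, match="more observations"):
            factor_analysis(env)


class TestCommunalityCheck:
    def test_threshold_inclusive(self):
        env = make_env_table(strong_three_factor_spec())
        res = factor_analysis(env)
        res.communalities.iloc[0] = 0.3
        res.communalities.iloc[1] = 0.29
        out = communality_check(res, 0.3)
        assert bool(out.iloc[0]) is True
        assert bool(out.iloc[1]) is False

    def test_all_pass_on_strong_synthetic(self):
        env = make_env_table(strong_three_factor_spec())
        assert communality_check(factor_analysis(env), 0.3).all()
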