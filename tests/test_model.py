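import numpy as np
import pytest
from scipy.integrate import quad

from conftest import make_observation
from oracles import brute_pair_posterior
from sclineage.model import (
    DistanceMatrix,
    ModelParameters,
    aggregate_distances,
    enumerate_mutation_types,
    likelihood_matrix,
    mutation_count_weight,
    mutation_type_prior,
    pair_posterior,
    prepare_site,
    site_bulk_distance,
    site_distance,
    site_distance_matrix,
)
from sclineage.readlike import cell_genotype_likelihood
from sclineage.sites import SiteObservation, SiteRead


class TestMutationTypes:
    def test_singleton_homozygous(self):
        types = enumerate_mutation_types(("A", "A"))
        assert types == [("A", "C"), ("A", "G"), ("A", "T")]

    def test_paired_heterozygous(self):
        types = enumerate_mutation_types(("AA", "AT"), candidate_index=0)
        assert len(types) == 6
        assert tuple(sorted(("AA", "GT"))) in types

    def test_each_type_one_substitution_away(self):
        bulk = ("CA", "GA")
        for z in enumerate_mutation_types(bulk, candidate_index=1):
            diffs = sum(
                a != b for ha, hb in zip(sorted(bulk), z) for a, b in zip(ha, hb)
            )
            assert diffs == 1


class TestMutationTypePrior:
    @pytest.mark.parametrize("K", [3, 6])
    def test_uniform_for_all_ones(self, K):
        prior = mutation_type_prior(None, K)
        assert np.allclose(prior, 1.0 / K)
        assert prior.sum() == pytest.approx(1.0)

    def test_general_alpha_matches_beta_functions(self):
        from scipy.special import beta as beta_fn

        alpha = np.array([2.0, 1.0, 1.0])
        prior = mutation_type_prior(alpha, 3)
        direct = np.array([beta_fn(alpha.sum(), 1.0) / beta_fn(a, 1.0) for a in alpha])
        assert np.allclose(prior, direct)
        assert prior.sum() == pytest.approx(1.0)


class TestMutationCountWeight:
    def test_two_cells_uniform_prior(self):
        assert mutation_count_weight(0, 2) == pytest.approx(1 / 3)
        assert mutation_count_weight(1, 2) == pytest.approx(1 / 6)
        assert mutation_count_weight(2, 2) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("C", [1, 2, 5, 10])
    def test_total_mass_one_uniform(self, C):
        from math import comb

        total = sum(comb(C, m) * mutation_count_weight(m, C) for m in range(C + 1))
        assert total == pytest.approx(1.0)

    def test_matches_numeric_beta_binomial_integral(self):
        a, b, C, m = 2.5, 0.7, 6, 2
        integrand = lambda p: (
            p**m * (1 - p) ** (C - m)
            * p ** (a - 1) * (1 - p) ** (b - 1)
        )
        num, _ = quad(integrand, 0, 1)
        from scipy.special import beta as beta_fn

        assert mutation_count_weight(m, C, a, b) == pytest.approx(num / beta_fn(a, b))


class TestVectorizedLikelihoods:
    @pytest.mark.parametrize("kind", ["singleton", "paired"])
    def test_matches_reference_implementation(self, kind, rng):
        obs = make_observation(rng, 5, kind=kind, min_reads=0, max_reads=3)
        params = ModelParameters(p_ado=0.15, p_ae=0.01)
        ps = prepare_site(obs)
        lik, logscale = likelihood_matrix(ps, params.p_ado, params.p_ae)
        for c in range(5):
            bases = [r.bases for r in obs.cell_reads[c]]
            eps = [r.error_probs for r in obs.cell_reads[c]]
            for g, X in enumerate(ps.genotypes):
                ref = cell_genotype_likelihood(
                    bases, eps, X, kind, params.p_ado, params.p_ae
                )
                assert lik[g, c] * np.exp(logscale[c]) == pytest.approx(ref, rel=1e-10)


class TestPairPosterior:
    @pytest.mark.parametrize("kind", ["singleton", "paired"])
    @pytest.mark.parametrize("C", [2, 5])
    def test_matches_exhaustive_status_enumeration(self, kind, C, rng):
        obs = make_observation(rng, C, kind=kind)
        params = ModelParameters(p_ado=0.1, p_ae=5e-3)
        got = pair_posterior(obs, 0, 1, params)
        want = brute_pair_posterior(obs, 0, 1, params)
        assert np.allclose(got, want, rtol=1e-9, atol=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_inputs_give_symmetric_table(self, rng):
        obs = make_observation(rng, 4, kind="singleton")
        obs.cell_reads[1] = list(obs.cell_reads[0])
        pp = pair_posterior(obs, 0, 1, ModelParameters())
        assert pp[0, 1] == pytest.approx(pp[1, 0], rel=1e-9)

    def test_bulk_distance_is_marginal(self, rng):
        obs = make_observation(rng, 4, kind="singleton")
        params = ModelParameters(p_ado=0.1, p_ae=1e-3)
        pp = pair_posterior(obs, 2, 0, params)
        assert site_bulk_distance(obs, 2, params) == pytest.approx(
            pp[1, :].sum(), rel=1e-9
        )


class TestSiteDistance:
    def test_fixed_points(self):
        conc = np.zeros((2, 2))
        conc[0, 0] = 1.0
        assert site_distance(conc) == 0.0
        assert site_distance(np.full((2, 2), 0.25)) == pytest.approx(0.5)

    def test_bounded(self, rng):
        for _ in range(5):
            obs = make_observation(rng, 4)
            pp = pair_posterior(obs, 0, 1, ModelParameters())
            assert 0.0 <= site_distance(pp) <= 1.0


class TestSiteDistanceMatrix:
    def test_uncovered_cells_are_masked(self, rng):
        obs = make_observation(rng, 4, min_reads=1)
        obs.cell_reads[2] = []
        D, mask = site_distance_matrix(obs, ModelParameters())
        assert not mask[2, 0] and not mask[0, 2] and not mask[2, 4]
        assert mask[0, 1] and mask[0, 4]
        assert np.allclose(D, D.T)


class TestAggregation:
    def test_single_site_identity(self, rng):
        obs = make_observation(rng, 3)
        D, mask = site_distance_matrix(obs, ModelParameters())
        agg = aggregate_distances(D[None], mask[None], warn=False)
        assert np.allclose(agg.values, D)

    def test_mean_of_two_sites(self):
        n = 3
        d1 = np.full((n, n), 0.2)
        d2 = np.full((n, n), 0.4)
        np.fill_diagonal(d1, 0)
        np.fill_diagonal(d2, 0)
        mask = np.ones((n, n), dtype=bool)
        agg = aggregate_distances(np.stack([d1, d2]), np.stack([mask, mask]))
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(agg.values[off], 0.3)

    def test_partial_coverage_uses_covered_sites_only(self):
        n = 3
        d1 = np.full((n, n), 0.2)
        d2 = np.full((n, n), 0.4)
        np.fill_diagonal(d1, 0)
        np.fill_diagonal(d2, 0)
        m1 = np.ones((n, n), dtype=bool)
        m2 = np.ones((n, n), dtype=bool)
        m2[0, 1] = m2[1, 0] = False
        agg = aggregate_distances(np.stack([d1, d2]), np.stack([m1, m2]))
        assert agg.values[0, 1] == pytest.approx(0.2)
        assert agg.values[0, 2] == pytest.approx(0.3)

    def test_never_covered_pair_is_imputed_with_warning(self):
        n = 3
        d = np.full((n, n), 0.2)
        np.fill_diagonal(d, 0)
        m = np.ones((n, n), dtype=bool)
        m[0, 1] = m[1, 0] = False
        with pytest.warns(UserWarning):
            agg = aggregate_distances(d[None], m[None])
        assert 0.0 <= agg.values[0, 1] <= 1.0
        assert np.allclose(agg.values, agg.values.T)

    def test_matrix_invariants(self, rng):
        obs = [make_observation(rng, 4) for _ in range(3)]
        params = ModelParameters()
        mats = [site_distance_matrix(o, params) for o in obs]
        agg = aggregate_distances(
            np.stack([m[0] for m in mats]), np.stack([m[1] for m in mats]), warn=False
        )
        assert np.allclose(agg.values, agg.values.T)
        assert np.allclose(np.diag(agg.values), 0.0)
        assert agg.values.min() >= 0.0 and agg.values.max() <= 1.0

    def test_tsv_round_trip(self, rng, tmp_path):
        obs = make_observation(rng, 3)
        D, mask = site_distance_matrix(obs, ModelParameters())
        agg = aggregate_distances(D[None], mask[None], warn=False)
        agg.to_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert back.labels == agg.labels
        assert np.allclose(back.values, agg.values)


def test_shared_mutation_shrinks_site_distance():
    """At a site where two cells carry the same alternative allele and a third
    does not, the concordant pair is closer than the discordant pairs."""
    q = (1e-3,)
    mutated = [SiteRead("A", q), SiteRead("G", q), SiteRead("A", q), SiteRead("G", q)]
    normal = [SiteRead("A", q)] * 4
    obs = SiteObservation(
        "singleton", 11, None, ("A", "A"), [list(mutated), list(mutated), list(normal)]
    )
    params = ModelParameters(p_ado=0.0, p_ae=1e-5)
    d_mm = site_distance(pair_posterior(obs, 0, 1, params))
    d_mn = site_distance(pair_posterior(obs, 0, 2, params))
    assert d_mm < d_mn


def test_coverage_cap_limits_reads_used(rng):
    obs = make_observation(rng, 3, min_reads=4, max_reads=6)
    from sclineage.model import prepare_site

    capped = prepare_site(obs, max_coverage=2)
    full = prepare_site(obs)
    assert capped.L.max() == 2
    assert full.L.min() >= 4
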