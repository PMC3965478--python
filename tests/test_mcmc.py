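import itertools
import math

import numpy as np
import pytest

from pgmix import (
    apply_detection_floor,
    check_concordance,
    ContributorProfile,
    GenotypePair,
    infer,
    infer_multi_k,
    InferenceSettings,
    InputError,
    MixtureSpec,
    ModelParameters,
    PopulationFrequencyTable,
    simulate_profile,
    suggest_contributor_count,
)
from pgmix.likelihood import log_likelihood
from pgmix.mcmc import (
    _LocusEngine,
    gibbs_update_genotype,
    MCMCState,
    update_weights_mass,
)
from pgmix.population import genotype_prior


def toy_freqs():
    return PopulationFrequencyTable(
        "TOY", {"TPOX": {"8": 0.3, "9": 0.25, "10": 0.45}}
    )


def make_state(panel, observed, weights, mass, settings, seed=0):
    freqs = toy_freqs().with_rare_allele_floor()
    eng = _LocusEngine("TPOX", observed, panel, freqs, settings)
    rng = np.random.default_rng(seed)
    K = len(weights)
    idx = np.zeros(K, dtype=int)
    return (
        MCMCState(
            engines={"TPOX": eng},
            settings=settings,
            rng=rng,
            genotype_idx={"TPOX": idx},
            stacks={"TPOX": eng.patterns[idx].copy()},
            weights=np.asarray(weights, dtype=float),
            mass=mass,
            stutter_rate=settings.stutter_rate,
            degradation_rate=settings.degradation_rate,
            variance_floor=settings.variance_floor,
            variance_scale=settings.variance_scale,
        ),
        eng,
    )


class TestGibbsKernel:
    def test_flat_likelihood_recovers_prior(self, panel):
        """With an essentially uninformative likelihood the genotype
        conditional equals the population prior."""
        settings = InferenceSettings(
            n_contributors=1,
            iterations=10,
            burn_in=1,
            stutter_rate=0.0,
            variance_floor=1e14,  # variance so large the data are ignored
            variance_scale=1.0,
            candidate_support="panel",
        )
        observed = {"8": 500.0, "9": 500.0}
        state, eng = make_state(panel, observed, [1.0], 1000.0, settings, seed=3)
        n = 30_000
        counts = np.zeros(len(eng.pairs))
        for _ in range(n):
            gibbs_update_genotype(state, 0, "TPOX")
            counts[state.genotype_idx["TPOX"][0]] += 1
        prior = np.exp(eng.log_prior)
        prior /= prior.sum()
        for i in range(len(eng.pairs)):
            sigma = math.sqrt(prior[i] * (1 - prior[i]) / n)
            assert abs(counts[i] / n - prior[i]) < 4 * sigma + 1e-9

    def test_conditional_matches_brute_force(self, panel):
        """The enumerated conditional agrees with an independently computed
        likelihood x prior table at a three-allele toy locus."""
        settings = InferenceSettings(
            n_contributors=1,
            iterations=10,
            burn_in=1,
            stutter_rate=0.0,
            variance_floor=100.0,
            variance_scale=5.0,
            candidate_support="panel",
        )
        observed = {"8": 620.0, "9": 350.0}
        state, eng = make_state(panel, observed, [1.0], 1000.0, settings, seed=5)
        params = ModelParameters(
            weights=[1.0], mass=1000.0, stutter_rate=0.0,
            variance_floor=100.0, variance_scale=5.0,
        )
        freqs = toy_freqs().with_rare_allele_floor()
        # independent oracle: direct density evaluation per candidate pair
        expected = np.array(
            [
                math.exp(log_likelihood(observed, [p], params, panel))
                * genotype_prior(p, freqs, settings.theta)
                for p in eng.pairs
            ]
        )
        expected /= expected.sum()
        n = 40_000
        counts = np.zeros(len(eng.pairs))
        for _ in range(n):
            gibbs_update_genotype(state, 0, "TPOX")
            counts[state.genotype_idx["TPOX"][0]] += 1
        for i in range(len(eng.pairs)):
            sigma = math.sqrt(expected[i] * (1 - expected[i]) / n)
            assert abs(counts[i] / n - expected[i]) < 4 * sigma + 1e-9

    def test_sampled_pairs_stay_inside_candidate_support(self, panel):
        settings = InferenceSettings(
            n_contributors=1, iterations=10, burn_in=1, stutter_rate=0.0,
            variance_scale=5.0,
        )
        observed = {"8": 500.0, "9": 480.0}
        state, eng = make_state(panel, observed, [1.0], 1000.0, settings, seed=1)
        allowed = set(range(len(eng.pairs)))
        for _ in range(10_000):
            gibbs_update_genotype(state, 0, "TPOX")
            assert int(state.genotype_idx["TPOX"][0]) in allowed
        labels = {a for p in eng.pairs for a in p.alleles}
        assert labels == {"8", "9"}


class TestWeightMassKernel:
    def test_zero_step_proposals_always_accepted(self, panel):
        settings = InferenceSettings(
            n_contributors=2, iterations=10, burn_in=1, stutter_rate=0.0,
            weight_step=0.0, mass_step=0.0, variance_scale=5.0,
        )
        observed = {"8": 600.0, "9": 400.0}
        state, _ = make_state(panel, observed, [0.5, 0.5], 1000.0, settings)
        for _ in range(200):
            update_weights_mass(state)
        accepted, proposed = state.accept["weights"]
        assert accepted == proposed == 200
        accepted, proposed = state.accept["mass"]
        assert accepted == proposed == 200

    def test_mass_chain_targets_gridded_posterior(self, panel):
        """Empirical mass distribution from the Metropolis kernel matches a
        dense grid evaluation of the single-locus posterior."""
        settings = InferenceSettings(
            n_contributors=1, iterations=10, burn_in=1, stutter_rate=0.0,
            mass_step=0.15, variance_scale=5.0,
        )
        observed = {"8": 520.0, "9": 480.0}
        state, eng = make_state(panel, observed, [1.0], 900.0, settings, seed=8)
        # pin the genotype at (8,9)
        pair_idx = eng.pair_index[GenotypePair.make("TPOX", "8", "9")]
        state.genotype_idx["TPOX"][0] = pair_idx
        state.stacks["TPOX"][0] = eng.patterns[pair_idx]
        samples = []
        for i in range(60_000):
            update_weights_mass(state)
            if i > 2_000:
                samples.append(state.mass)
        # grid oracle: posterior with flat prior on log m
        grid = np.linspace(800, 1200, 2001)
        logp = []
        params_v = (settings.variance_floor, settings.variance_scale)
        data = eng.data
        pat = eng.patterns[pair_idx]
        for m in grid:
            mu = m * pat
            var = params_v[0] + params_v[1] * mu
            logp.append(
                -0.5 * np.sum(np.log(2 * np.pi * var) + (data - mu) ** 2 / var)
                - math.log(m)
            )
        logp = np.array(logp) - max(logp)
        w = np.exp(logp)
        w /= w.sum()
        grid_mean = float(np.sum(grid * w))
        grid_sd = float(np.sqrt(np.sum((grid - grid_mean) ** 2 * w)))
        assert np.mean(samples) == pytest.approx(grid_mean, abs=0.15 * grid_sd)

    def test_weight_recovery_on_noiseless_data(self, panel, freqs):
        """cv = 0 data with true weights (0.7, 0.3) yield a posterior mean
        within +-0.05."""
        contributors = [
            ContributorProfile("a", {"TPOX": GenotypePair.make("TPOX", "8", "9")}),
            ContributorProfile("b", {"TPOX": GenotypePair.make("TPOX", "11", "12")}),
        ]
        spec = MixtureSpec(
            contributors=contributors,
            weights=[0.7, 0.3],
            total_mass=2000.0,
            stutter_rate=0.0,
            degradation_rate=0.0,
            cv=0.0,
            panel=panel,
        )
        peaks = simulate_profile(spec, ["TPOX"], rng=0)
        settings = InferenceSettings(
            n_contributors=2, iterations=4000, burn_in=1000, seed=2,
            stutter_rate=0.0, variance_scale=5.0,
        )
        result = infer(peaks, settings, freqs, panel)
        assert result.weight_mean[0] == pytest.approx(0.7, abs=0.05)


class TestInfer:
    def test_single_source_recovery(self, freqs, panel):
        """A clean single-source profile resolves to the true pair with at
        least 99% posterior mass at every locus."""
        from pgmix import random_mixture

        spec = random_mixture(
            freqs, panel, n_contributors=1, rng=7, cv=0.05, total_mass=2000.0
        )
        peaks = apply_detection_floor(simulate_profile(spec, rng=8))
        settings = InferenceSettings(
            n_contributors=1, iterations=800, burn_in=200, seed=9,
            variance_scale=5.0,
        )
        result = infer(peaks, settings, freqs, panel)
        truth = spec.contributors[0].genotypes
        for locus, dists in result.posteriors.items():
            assert dists[0].prob(truth[locus]) >= 0.99

    def test_minor_contributor_resolved_in_two_to_one_mixture(
        self, pentae_mixture, freqs, panel
    ):
        """The 600/600/300/300 pattern concentrates the minor contributor's
        posterior on the 10,12 pair."""
        import dataclasses

        spec = dataclasses.replace(pentae_mixture, cv=0.02)
        peaks = simulate_profile(spec, rng=21)
        settings = InferenceSettings(
            n_contributors=2, iterations=3000, burn_in=1000, seed=4,
            stutter_rate=0.0, variance_scale=5.0,
        )
        result = infer(peaks, settings, freqs, panel)
        minor = result.posteriors["PentaE"][1]
        assert minor.mode() == GenotypePair.make("PentaE", "10", "12")
        assert minor.prob(minor.mode()) >= 0.93

    def test_seeded_determinism(self, freqs, panel):
        from pgmix import random_mixture

        spec = random_mixture(freqs, panel, 2, rng=3, cv=0.1)
        peaks = apply_detection_floor(simulate_profile(spec, rng=4))
        settings = InferenceSettings(
            n_contributors=2, iterations=300, burn_in=100, seed=5,
            variance_scale=5.0,
        )
        a = infer(peaks, settings, freqs, panel)
        b = infer(peaks, settings, freqs, panel)
        assert np.array_equal(a.weight_samples, b.weight_samples)
        for locus in a.posteriors:
            for k in range(2):
                assert a.posteriors[locus][k].mass == b.posteriors[locus][k].mass

    def test_assumed_contributor_pinned(self, freqs, panel):
        from pgmix import random_mixture

        spec = random_mixture(freqs, panel, 2, rng=31, cv=0.05)
        peaks = apply_detection_floor(simulate_profile(spec, rng=32))
        assumed = spec.contributors[0]
        settings = InferenceSettings(
            n_contributors=2,
            iterations=400,
            burn_in=100,
            seed=6,
            assumed_contributors=[assumed],
            variance_scale=5.0,
        )
        result = infer(peaks, settings, freqs, panel)
        for locus, dists in result.posteriors.items():
            assert dists[0].prob(assumed.genotypes[locus]) == pytest.approx(1.0)

    def test_empty_profile_rejected(self, freqs, panel):
        import pandas as pd

        from pgmix import PeakTable

        empty = PeakTable(
            pd.DataFrame(
                columns=[
                    "sample", "locus", "dye", "allele",
                    "size_bp", "height_rfu", "injection_s",
                ]
            )
        )
        settings = InferenceSettings(n_contributors=1, iterations=10, burn_in=1)
        with pytest.raises(InputError):
            infer(empty, settings, freqs, panel)


class TestExactness:
    def test_marginals_match_enumeration_two_contributors(self, panel):
        """With weights and mass fixed, MCMC genotype marginals on a toy
        locus agree with full brute-force enumeration (independent oracle)
        within Monte-Carlo error."""
        import pandas as pd

        from pgmix import enumerate_pairs, PeakTable

        freqs = toy_freqs()
        weights = [0.65, 0.35]
        mass = 2000.0
        observed = {"8": 650.0, "9": 650.0, "10": 700.0}
        rows = pd.DataFrame(
            {
                "sample": "s",
                "locus": "TPOX",
                "dye": "yellow",
                "allele": list(observed),
                "size_bp": [262.0, 266.0, 270.0],
                "height_rfu": list(observed.values()),
                "injection_s": 5,
            }
        )
        peaks = PeakTable(rows)
        settings = InferenceSettings(
            n_contributors=2,
            iterations=30_000,
            burn_in=2_000,
            seed=13,
            stutter_rate=0.0,
            fix_weights=weights,
            fix_mass=mass,
            variance_floor=100.0,
            variance_scale=5.0,
        )
        result = infer(peaks, settings, freqs, panel)

        # independent oracle: enumerate all pair combinations directly
        params = ModelParameters(
            weights=weights, mass=mass, stutter_rate=0.0,
            variance_floor=100.0, variance_scale=5.0,
        )
        pairs = enumerate_pairs(["8", "9", "10"], "TPOX")
        post = {}
        for ga, gb in itertools.product(pairs, pairs):
            ll = log_likelihood(observed, [ga, gb], params, panel)
            post[(ga, gb)] = (
                math.exp(ll)
                * genotype_prior(ga, toy_freqs(), settings.theta)
                * genotype_prior(gb, toy_freqs(), settings.theta)
            )
        total = sum(post.values())
        # weight-ranked marginals: slot 0 is the 0.65 contributor
        marg = [dict.fromkeys(pairs, 0.0), dict.fromkeys(pairs, 0.0)]
        for (ga, gb), p in post.items():
            marg[0][ga] += p / total
            marg[1][gb] += p / total
        n = settings.iterations - settings.burn_in
        for k in range(2):
            top = max(marg[k], key=marg[k].get)
            expected = marg[k][top]
            sigma = math.sqrt(expected * (1 - expected) / n)
            observed_mass = result.posteriors["TPOX"][k].prob(top)
            # allow autocorrelation: inflate the binomial sigma
            assert abs(observed_mass - expected) < max(6 * sigma, 0.015)


class TestConcordance:
    def _mixture(self, freqs, panel):
        from pgmix import random_mixture

        spec = random_mixture(freqs, panel, 2, rng=41, cv=0.05, weights=[0.75, 0.25])
        return apply_detection_floor(simulate_profile(spec, rng=42))

    def test_identical_runs_pass_with_zero_kl(self, freqs, panel):
        peaks = self._mixture(freqs, panel)
        settings = InferenceSettings(
            n_contributors=2, iterations=400, burn_in=100, seed=1,
            variance_scale=5.0,
        )
        r = infer(peaks, settings, freqs, panel)
        report = check_concordance(r, r, 0.05)
        assert report.passed
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in report.kl_by_locus.values())

    def test_independent_seeds_concordant_on_resolved_data(self, freqs, panel):
        peaks = self._mixture(freqs, panel)
        s1 = InferenceSettings(
            n_contributors=2, iterations=2000, burn_in=500, seed=1,
            variance_scale=5.0,
        )
        s2 = InferenceSettings(
            n_contributors=2, iterations=2000, burn_in=500, seed=99,
            variance_scale=5.0,
        )
        report = check_concordance(
            infer(peaks, s1, freqs, panel), infer(peaks, s2, freqs, panel), 0.05
        )
        assert report.passed, report.flagged

    def test_truncated_chain_flagged(self, freqs, panel):
        peaks = self._mixture(freqs, panel)
        short = InferenceSettings(
            n_contributors=2, iterations=10, burn_in=2, seed=1,
            variance_scale=5.0,
        )
        long = InferenceSettings(
            n_contributors=2, iterations=2000, burn_in=500, seed=99,
            variance_scale=5.0,
        )
        report = check_concordance(
            infer(peaks, short, freqs, panel), infer(peaks, long, freqs, panel), 0.05
        )
        assert not report.passed

    def test_mismatched_settings_rejected(self, freqs, panel):
        peaks = self._mixture(freqs, panel)
        s1 = InferenceSettings(
            n_contributors=2, iterations=100, burn_in=10, seed=1, variance_scale=5.0
        )
        s2 = InferenceSettings(
            n_contributors=2, iterations=100, burn_in=10, seed=2, theta=0.03,
            variance_scale=5.0,
        )
        with pytest.raises(InputError):
            check_concordance(
                infer(peaks, s1, freqs, panel), infer(peaks, s2, freqs, panel)
            )


class TestConvenience:
    def test_suggest_contributor_count(self, freqs, panel):
        from pgmix import random_mixture

        spec = random_mixture(freqs, panel, 2, rng=51, cv=0.0, stutter_rate=0.0)
        peaks = simulate_profile(spec, rng=0)
        assert suggest_contributor_count(peaks) == 2

    def test_multi_k_reports_both(self, freqs, panel):
        from pgmix import random_mixture

        spec = random_mixture(freqs, panel, 2, rng=52, cv=0.05)
        peaks = apply_detection_floor(simulate_profile(spec, rng=53))
        settings = InferenceSettings(
            n_contributors=2, iterations=200, burn_in=50, seed=3,
            variance_scale=5.0,
        )
        results = infer_multi_k(peaks, settings, freqs, panel)
        assert set(results) == {2, 3}
        assert results[3].n_contributors == 3
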