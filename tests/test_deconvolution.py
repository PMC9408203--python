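import math

import numpy as np
import pytest
from scipy import stats

import mixlr
from mixlr.deconvolution import (
    MCMCSettings,
    MCMCState,
    enumerate_genotype_sets,
    export_deconvolved_profiles,
    gelman_rubin,
    oracle_posterior,
    run_mcmc,
    state_loglikelihood,
)
from mixlr.epg_simulator import ContributionSpec, SimulatorParams, simulate_epg_profile
from mixlr.panel_io import AnalysisConfig
from mixlr.variance_model import VarianceModel


@pytest.fixture(scope="module")
def toy(panel8):
    """3-locus toy: panel, stutter-free variance model and donor pair."""
    panel = mixlr.mini_panel(3)
    names = panel.locus_names
    vm = VarianceModel(vf=40.0, stutter={l: 0.0 for l in names})
    params = SimulatorParams(stutter_rate=0.0)
    g_minor = {names[0]: ("12", "13"), names[1]: ("10", "11"), names[2]: ("11", "11")}
    g_major = {names[0]: ("13", "14"), names[1]: ("11", "12"), names[2]: ("12", "13")}
    return panel, vm, params, g_minor, g_major


def toy_profile(toy, minor_pg, major_pg, seed):
    panel, vm, params, g_minor, g_major = toy
    return simulate_epg_profile(
        [ContributionSpec("m", g_minor, minor_pg), ContributionSpec("M", g_major, major_pg)],
        params, 30.0, seed, panel,
    )


class TestEnumeration:
    def test_single_allele_single_contributor_forced(self):
        sets = enumerate_genotype_sets(["10"], 1, allow_q=False)
        assert sets == [(("10", "10"),)]

    def test_two_alleles_two_contributors_with_q(self):
        sets = enumerate_genotype_sets(["12", "13"], 2, allow_q=True)
        # 36 ordered pairs - 9 missing '12' - 9 missing '13' + 1 missing both
        assert len(sets) == 19

    def test_dropin_never_reduces_admissible_sets(self):
        for observed in (["12"], ["12", "13"], ["12", "13", "14"]):
            without = enumerate_genotype_sets(observed, 2, dropin_enabled=False)
            with_di = enumerate_genotype_sets(observed, 2, dropin_enabled=True)
            assert set(without) <= set(with_di)

    def test_nonpositive_contributors_rejected(self):
        with pytest.raises(ValueError):
            enumerate_genotype_sets(["12"], 0)

    def test_stutter_explanation_expands_sets(self):
        plain = enumerate_genotype_sets(["12", "13"], 1, allow_q=True)
        stutter = enumerate_genotype_sets(["12", "13"], 1, allow_q=True, stutter=True)
        assert set(plain) < set(stutter)
        assert (("13", "13"),) in stutter  # 12 as backward stutter of 13


class TestLikelihood:
    def test_gamma_term_matches_scipy(self, toy):
        panel, vm50, params, g_minor, g_major = toy
        names = panel.locus_names
        vm = VarianceModel(vf=50.0, stutter={l: 0.0 for l in names})
        from mixlr.panel_io import EPGProfile, PeakRecord

        nu = 1000.0
        profile = EPGProfile(
            "s", 30.0,
            {names[0]: [PeakRecord("s", names[0], "12", 100.0, nu)]},
        )
        state = MCMCState(
            genotypes={names[0]: (("12", "12"),)},
            phi=np.array([1.0]),
            amplitude={names[0]: nu / 2.0},
        )
        ll = state_loglikelihood(state, profile, vm, AnalysisConfig())
        expected = stats.gamma.logpdf(nu, a=nu / 50.0, scale=50.0)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_truth_beats_single_allele_swaps(self, toy):
        panel, vm, params, g_minor, g_major = toy
        names = panel.locus_names
        profile = simulate_epg_profile(
            [ContributionSpec("M", g_major, 500.0)], params, 30.0, 41, panel
        )
        amp = {l: sum(profile.heights(l).values()) / 2.0 for l in names}
        truth = {l: (tuple(sorted(g_major[l])),) for l in names}
        config = AnalysisConfig()
        ll_truth = state_loglikelihood(
            MCMCState(truth, np.array([1.0]), amp), profile, vm, config
        )
        # swap one allele at one locus for every observed alternative
        for l in names:
            observed = profile.alleles(l)
            for alt in observed + ["Q"]:
                g = tuple(sorted((g_major[l][0], alt)))
                if g == tuple(sorted(g_major[l])):
                    continue
                mutated = dict(truth)
                mutated[l] = (g,)
                ll_alt = state_loglikelihood(
                    MCMCState(mutated, np.array([1.0]), amp), profile, vm, config
                )
                assert ll_alt < ll_truth

    def test_unexplained_peak_is_impossible_without_dropin(self, toy):
        panel, vm, params, g_minor, g_major = toy
        names = panel.locus_names
        profile = toy_profile(toy, 300.0, 150.0, 42)
        amp = {l: sum(profile.heights(l).values()) / 2.0 for l in names}
        state = MCMCState(
            genotypes={l: (("Q", "Q"), ("Q", "Q")) for l in names},
            phi=np.array([0.5, 0.5]),
            amplitude=amp,
        )
        ll = state_loglikelihood(state, profile, vm, AnalysisConfig())
        assert ll == -math.inf


class TestRunMCMC:
    def test_single_source_recovers_truth(self, toy):
        panel, vm, params, g_minor, g_major = toy
        profile = simulate_epg_profile(
            [ContributionSpec("M", g_major, 500.0)], params, 30.0, 43, panel
        )
        wg = run_mcmc(
            profile, 1, [], vm,
            MCMCSettings(chains=4, iterations_per_chain=1500, preprocessing_steps=500, seed=1),
            AnalysisConfig(),
        )
        for l in panel.locus_names:
            marg = wg.marginal(l, 0)
            truth = tuple(sorted(g_major[l]))
            assert marg.get(truth, 0.0) >= 0.999

    def test_weights_are_normalized_distributions(self, wg_1_10):
        for l, by_key in wg_1_10.locus_weights.items():
            assert all(w >= 0 for w in by_key.values())
            assert sum(by_key.values()) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_under_seed(self, toy):
        panel, vm, params, g_minor, g_major = toy
        profile = toy_profile(toy, 300.0, 150.0, 44)
        settings = MCMCSettings(
            chains=2, iterations_per_chain=500, preprocessing_steps=200, seed=77
        )
        a = run_mcmc(profile, 2, [], vm, settings, AnalysisConfig())
        b = run_mcmc(profile, 2, [], vm, settings, AnalysisConfig())
        assert a.locus_weights == b.locus_weights
        assert np.array_equal(a.phi_traces, b.phi_traces)

    def test_mixture_ratio_recovered_for_1_10(self, wg_1_10):
        est = wg_1_10.ratio_estimate()
        assert est[0] == pytest.approx(10 / 11, abs=0.05)
        assert est[1] == pytest.approx(1 / 11, abs=0.05)

    def test_conditioning_on_known_contributor(self, toy):
        panel, vm, params, g_minor, g_major = toy
        profile = toy_profile(toy, 300.0, 150.0, 45)
        settings = MCMCSettings(
            chains=4, iterations_per_chain=2000, preprocessing_steps=500, seed=5
        )
        wg = run_mcmc(profile, 2, [g_major], vm, settings, AnalysisConfig())
        # known occupies position 0 with its full genotype everywhere
        for l in panel.locus_names:
            truth = tuple(sorted(g_major[l]))
            assert wg.marginal(l, 0) == {truth: pytest.approx(1.0)}


class TestOracle:
    def test_single_admissible_set_gets_weight_one(self, toy):
        panel, vm, params, g_minor, g_major = toy
        profile = simulate_epg_profile(
            [ContributionSpec("M", g_major, 500.0)], params, 30.0, 46, panel
        )
        og = oracle_posterior(profile, 1, [g_major], vm, AnalysisConfig())
        for l, by_key in og.locus_weights.items():
            assert len(by_key) == 1
            assert next(iter(by_key.values())) == pytest.approx(1.0, abs=1e-12)

    def test_oracle_weights_sum_to_one(self, toy):
        panel, vm, params, g_minor, g_major = toy
        profile = toy_profile(toy, 300.0, 150.0, 47)
        og = oracle_posterior(profile, 2, [], vm, AnalysisConfig())
        for by_key in og.locus_weights.values():
            assert sum(by_key.values()) == pytest.approx(1.0, abs=1e-12)

    def test_refuses_large_instances(self, mix_1_10, vm_true, config):
        with pytest.raises(ValueError, match="contributors"):
            oracle_posterior(mix_1_10, 4, [], vm_true, config)


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        rng = np.random.default_rng(0)
        one = rng.normal(size=(1, 200, 2))
        traces = np.concatenate([one, one, one], axis=0)
        assert gelman_rubin(traces) == pytest.approx(np.ones(2))

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, size=(1, 1000, 1))
        b = rng.normal(5.0, 1.0, size=(1, 1000, 1))
        rhat = gelman_rubin(np.concatenate([a, b], axis=0))
        assert rhat[0] > 1.2

    def test_invariant_to_chain_order(self):
        rng = np.random.default_rng(2)
        traces = rng.normal(size=(4, 300, 2))
        assert gelman_rubin(traces) == pytest.approx(
            gelman_rubin(traces[::-1]), rel=1e-12
        )

    def test_zero_variance_reports_one(self):
        traces = np.ones((3, 50, 1))
        assert gelman_rubin(traces)[0] == 1.0


class TestExport:
    def test_single_source_fully_recovered(self, toy):
        panel, vm, params, g_minor, g_major = toy
        profile = simulate_epg_profile(
            [ContributionSpec("M", g_major, 500.0)], params, 30.0, 48, panel
        )
        wg = run_mcmc(
            profile, 1, [], vm,
            MCMCSettings(chains=4, iterations_per_chain=1500, preprocessing_steps=500, seed=9),
            AnalysisConfig(),
        )
        [exported] = export_deconvolved_profiles(wg, min_weight=0.9)
        assert exported == {l: tuple(sorted(g_major[l])) for l in panel.locus_names}

    def test_major_contributor_recovered_from_1_10(self, wg_1_10, donors22, panel22):
        exported = export_deconvolved_profiles(wg_1_10, min_weight=0.9)
        major = exported[0]  # largest contributor is numbered first
        hits = sum(
            major[l] == donors22["major"][l] for l in panel22.locus_names
        )
        assert hits >= 20

    def test_min_weight_one_requires_unanimity(self, wg_1_10):
        exported = export_deconvolved_profiles(wg_1_10, min_weight=1.0)
        for rank, profile in enumerate(exported):
            pos = wg_1_10.n_knowns + rank
            for l, g in profile.items():
                if g is None:
                    continue
                marg: dict = {}
                for key, w in wg_1_10.canonical_weights[l].items():
                    marg[key[pos]] = marg.get(key[pos], 0.0) + w
                assert marg[g] == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(ValueError):
            export_deconvolved_profiles(wg_1_10, min_weight=0.0)
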