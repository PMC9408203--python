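import numpy as np
import pytest

import mixlr
from mixlr.deconvolution import WeightedGenotypes
from mixlr.lr_engine import (
    LRCalculator,
    Proposition,
    genotype_set_prior,
    matches_poi,
    overall_lr,
    overall_lr_orderform,
    simple_lr,
    verbal_scale_bin,
)
from mixlr.panel_io import AlleleFrequencyTable, EPGProfile, PeakRecord
from mixlr.popgen import PopGenModel


LOCUS = "L1"
MODEL = PopGenModel("HWE", 0.0, "All")


@pytest.fixture()
def locus_freqs():
    return AlleleFrequencyTable(
        {"All": {LOCUS: {"10": 0.5, "11": 0.1, "12": 0.3, "13": 0.05, "14": 0.05}}}
    )


def one_locus_profile(alleles):
    return EPGProfile(
        "s", 30.0,
        {LOCUS: [PeakRecord("s", LOCUS, a, 100.0, 500.0) for a in alleles]},
    )


def make_wg(weights, n, n_knowns=0):
    return WeightedGenotypes(
        n_contributors=n, n_knowns=n_knowns,
        locus_weights={LOCUS: weights}, canonical_weights={LOCUS: weights},
        phi_traces=np.full((1, 1, n), 1.0 / n), n_samples=10_000,
    )


class TestVerbalScale:
    @pytest.mark.parametrize(
        "lr,label",
        [
            (1e6, "very strong support"),
            (11.1, "limited support"),
            (1.0, "limited support"),
            (0.5, "exclusionary direction"),
            (5e3, "moderate support"),
            (1e5, "strong support"),
        ],
    )
    def test_default_bins(self, lr, label):
        assert verbal_scale_bin(lr) == label

    def test_nonpositive_lr_rejected(self):
        with pytest.raises(ValueError):
            verbal_scale_bin(0.0)


class TestQMatching:
    def test_exact_match(self):
        assert matches_poi(("10", "11"), ("10", "11"), {"10", "11"})

    def test_q_stands_for_unobserved_allele_only(self):
        assert matches_poi(("10", "Q"), ("10", "15"), {"10"})
        assert not matches_poi(("10", "Q"), ("10", "11"), {"10", "11"})

    def test_double_q_full_dropout(self):
        assert matches_poi(("Q", "Q"), ("15", "16"), set())
        assert not matches_poi(("Q", "Q"), ("10", "16"), {"10"})

    def test_real_allele_mismatch(self):
        assert not matches_poi(("10", "12"), ("10", "11"), {"10", "11", "12"})


class TestSetPrior:
    def test_known_mismatch_is_zero(self, locus_freqs):
        fmap = {"10": 0.5, "11": 0.1, "Q": 0.4}
        s = (("10", "11"),)
        assert genotype_set_prior(
            s, ["known0"], None, [("10", "10")], fmap, MODEL, {"10", "11"}
        ) == 0.0

    def test_all_known_matching_is_one(self):
        fmap = {"10": 0.5, "11": 0.1, "Q": 0.4}
        s = (("10", "11"), ("10", "10"))
        assert genotype_set_prior(
            s, ["known0", "known1"], None, [("10", "11"), ("10", "10")],
            fmap, MODEL, {"10", "11"},
        ) == 1.0

    def test_two_unknowns_multiply(self):
        fmap = {"10": 0.5, "11": 0.1, "12": 0.3, "Q": 0.1}
        s = (("10", "11"), ("12", "12"))
        expected = (2 * 0.5 * 0.1) * (0.3 * 0.3)
        assert genotype_set_prior(
            s, ["unknown", "unknown"], None, [], fmap, MODEL, {"10", "11", "12"}
        ) == pytest.approx(expected, rel=1e-12)


class TestLRFormulas:
    def test_single_contributor_is_inverse_rmp(self, locus_freqs):
        poi = ("10", "11")  # HWE: 2 * 0.5 * 0.1 = 0.1
        wg = make_wg({(poi,): 1.0}, n=1)
        prop = Proposition({LOCUS: poi}, (), 1, MODEL)
        res = overall_lr(wg, prop, one_locus_profile(["10", "11"]), locus_freqs)
        assert res.profile_overall_lr == pytest.approx(10.0, rel=1e-9)
        assert res.profile_simple_lr == pytest.approx(res.profile_overall_lr)

    def test_two_unknown_position_prior(self, locus_freqs):
        # sets {(POI, B): 0.6, (B, POI): 0.4} with Pr(POI)=0.1:
        # simple and overall both reduce to 0.5 / Pr(POI) = 5
        poi, b = ("10", "11"), ("12", "12")
        wg = make_wg({(poi, b): 0.6, (b, poi): 0.4}, n=2)
        prop = Proposition({LOCUS: poi}, (), 2, MODEL)
        profile = one_locus_profile(["10", "11", "12"])
        res = simple_lr(wg, prop, profile, locus_freqs)
        assert res.profile_simple_lr == pytest.approx(5.0, rel=1e-9)
        assert res.profile_overall_lr == pytest.approx(5.0, rel=1e-9)

    def test_poi_absent_from_weights_gives_lr_below_one(self, locus_freqs):
        b, c = ("12", "12"), ("10", "10")
        wg = make_wg({(b, c): 1.0}, n=2)
        prop = Proposition({LOCUS: ("10", "11")}, (), 2, MODEL)
        res = overall_lr(wg, prop, one_locus_profile(["10", "11", "12"]), locus_freqs)
        assert 0.0 < res.profile_overall_lr < 1.0

    def test_order_form_equivalence(self, wg_1_10, mix_1_10, freqs22, donors22):
        model = PopGenModel("NRC4.1", 0.01, "All")
        prop = Proposition(donors22["major"], (), 2, model)
        res = overall_lr(wg_1_10, prop, mix_1_10, freqs22)
        alt = overall_lr_orderform(wg_1_10, prop, mix_1_10, freqs22)
        assert alt == pytest.approx(res.profile_overall_lr, rel=1e-12)

    def test_order_form_equivalence_three_unknowns(self, locus_freqs):
        poi, b, c = ("10", "11"), ("12", "12"), ("10", "13")
        weights = {
            (poi, b, c): 0.3, (b, poi, c): 0.25, (c, b, poi): 0.2,
            (poi, c, b): 0.15, (b, c, poi): 0.1,
        }
        wg = make_wg(weights, n=3)
        prop = Proposition({LOCUS: poi}, (), 3, MODEL)
        profile = one_locus_profile(["10", "11", "12", "13"])
        res = overall_lr(wg, prop, profile, locus_freqs)
        alt = overall_lr_orderform(wg, prop, profile, locus_freqs)
        assert alt == pytest.approx(res.profile_overall_lr, rel=1e-12)

    def test_locus_order_invariance(self, locus_freqs):
        poi = ("10", "11")
        freqs = AlleleFrequencyTable(
            {"All": {
                "L1": {"10": 0.5, "11": 0.1, "12": 0.3, "13": 0.1},
                "L2": {"10": 0.5, "11": 0.1, "12": 0.3, "13": 0.1},
            }}
        )
        def build(order):
            lw = {
                l: {(poi, ("12", "12")): 0.7, (("12", "12"), poi): 0.3}
                for l in order
            }
            return WeightedGenotypes(2, 0, lw, lw, np.full((1, 1, 2), 0.5), 10_000)
        profile = EPGProfile(
            "s", 30.0,
            {l: [PeakRecord("s", l, a, 100.0, 400.0) for a in ("10", "11", "12")]
             for l in ("L1", "L2")},
        )
        prop = Proposition({"L1": poi, "L2": poi}, (), 2, MODEL)
        r1 = overall_lr(build(["L1", "L2"]), prop, profile, freqs)
        r2 = overall_lr(build(["L2", "L1"]), prop, profile, freqs)
        assert r1.profile_overall_lr == pytest.approx(r2.profile_overall_lr, rel=1e-12)


class TestMixtureLRs:
    def test_true_contributors_supported_noncontributor_excluded(
        self, wg_1_10, mix_1_10, freqs22, donors22
    ):
        model = PopGenModel("NRC4.1", 0.01, "All")
        calc = LRCalculator(wg_1_10, mix_1_10, freqs22, model)
        major = calc.compute(donors22["major"])
        minor = calc.compute(donors22["minor"])
        non = calc.compute(donors22["non1"])
        assert major.log10_overall > 6
        assert minor.log10_overall > 6
        assert non.log10_overall < 0
        assert non.verbal_bin == "exclusionary direction"

    def test_simple_at_least_overall_on_synthetic_suite(
        self, wg_1_10, mix_1_10, freqs22, donors22
    ):
        # the position-marginalized LR cannot exceed the presence-only LR
        # in more than a small fraction of random POIs
        model = PopGenModel("NRC4.1", 0.01, "All")
        calc = LRCalculator(wg_1_10, mix_1_10, freqs22, model)
        from mixlr.popgen import sample_insilico_database

        db = sample_insilico_database(freqs22, ["AfAm", "Cau"], 8, seed=3)
        pois = list(db.values()) + [donors22["major"], donors22["minor"]]
        wins = sum(
            calc.compute(g).log10_simple >= calc.compute(g).log10_overall - 1e-9
            for g in pois
        )
        assert wins >= 0.95 * len(pois)

    def test_single_unknown_makes_simple_equal_overall(
        self, mix_1_10, freqs22, donors22, vm_true, config
    ):
        settings = mixlr.MCMCSettings(
            chains=4, iterations_per_chain=1000, preprocessing_steps=500, seed=21
        )
        wg = mixlr.run_mcmc(
            mix_1_10, 2, [donors22["major"]], vm_true, settings, config
        )
        model = PopGenModel("NRC4.1", 0.01, "All")
        calc = LRCalculator(
            wg, mix_1_10, freqs22, model, (donors22["major"],)
        )
        res = calc.compute(donors22["minor"])
        assert res.log10_simple == pytest.approx(res.log10_overall, abs=1e-9)
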