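"""Validation-study harness: sensitivity/specificity grids, number-of-
contributor stress tests, precision studies, and peak-height analytics.

The harness replays, on synthetic electropherograms, the internal
validation design a casework laboratory runs on a probabilistic
genotyping system: H1-true tests (the queried person is a true
contributor; LR < 1 is a false exclusion / Type I error), H2-true tests
(a true non-contributor; LR >= 1 is a false inclusion / Type II error),
in silico non-contributor databases, deliberately wrong contributor
numbers (N plus or minus one), and replicate analyses compared across
MCMC iteration settings with Levene's test (median-centered,
Brown-Forsythe variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import AlleleFrequencyTable, AnalysisConfig, EPGProfile, STRPanel
from .popgen import PopGenModel, sample_insilico_database
from .epg_simulator import (
    ContributionSpec,
    MixtureCondition,
    MixtureDesign,
    SimulatorParams,
    simulate_epg_profile,
)
from .deconvolution import MCMCSettings, run_mcmc
from .lr_engine import LRCalculator
from .variance_model import VarianceModel

GenotypeProfile = dict[str, tuple[str, str]]


# ---------------------------------------------------------------------------
# Printed test-plan enumeration

# Per mixture size: analyses run and LR tests by proposition class for the
# full validation study (correct number of contributors only).
STUDY_TEST_COUNTS: dict[int, dict[str, int]] = {
    2: {"analyses": 195, "h1_unconditioned": 300, "h1_conditioned": 50,
        "h2_unconditioned": 40, "h2_conditioned": 0},
    3: {"analyses": 276, "h1_unconditioned": 538, "h1_conditioned": 200,
        "h2_unconditioned": 90, "h2_conditioned": 0},
    4: {"analyses": 135, "h1_unconditioned": 420, "h1_conditioned": 40,
        "h2_unconditioned": 60, "h2_conditioned": 20},
    5: {"analyses": 181, "h1_unconditioned": 730, "h1_conditioned": 80,
        "h2_unconditioned": 95, "h2_conditioned": 0},
}


def enumerate_study_plan(
    counts: dict[int, dict[str, int]] | None = None
) -> pd.DataFrame:
    """One row per LR test of the full study plan (no MCMC is run).

    The plan's per-class totals are inputs; the enumerator materializes
    them into individually tagged test rows so downstream summaries can
    be checked against printed totals.
    """
    counts = STUDY_TEST_COUNTS if counts is None else counts
    rows = []
    for n, by_class in counts.items():
        for cls in ("h1_unconditioned", "h1_conditioned",
                    "h2_unconditioned", "h2_conditioned"):
            for i in range(by_class[cls]):
                rows.append(
                    {"n_contributors": n,
                     "tag": "H1-true" if cls.startswith("h1") else "H2-true",
                     "conditioned": cls.endswith("_conditioned"),
                     "test_index": i}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Grid running


@dataclass
class GridTest:
    """One LR test: a POI scored against one mixture condition."""

    condition: MixtureCondition
    poi: str
    poi_genotype: GenotypeProfile
    tag: str  # 'H1-true' or 'H2-true'
    known_donors: tuple[str, ...] = ()


@dataclass
class TestPlan:
    tests: list[GridTest]
    genotypes: dict[str, GenotypeProfile]
    replicates: int = 5

    def __post_init__(self) -> None:
        for t in self.tests:
            truths = set(t.condition.donors)
            if t.tag == "H1-true" and t.poi not in truths:
                raise ValueError(f"H1-true test references non-contributor {t.poi}")
            if t.tag == "H2-true" and t.poi in truths:
                raise ValueError(f"H2-true test references true contributor {t.poi}")


def settings_for_n(n: int, scale: float = 1.0, seed: int = 0,
                   preprocessing: int = 10_000) -> MCMCSettings:
    """Eight-chain defaults with per-chain iterations that grow with the
    number of contributors; ``scale`` shrinks them for reduced studies."""
    base = {1: 5000, 2: 5000, 3: 10000}.get(n, 20000)
    return MCMCSettings(
        chains=8,
        iterations_per_chain=max(200, int(base * scale)),
        preprocessing_steps=preprocessing,
        seed=seed,
    )


def run_validation_grid(
    plan: TestPlan,
    params: SimulatorParams,
    panel: STRPanel,
    freqs: AlleleFrequencyTable,
    vm: VarianceModel,
    config: AnalysisConfig,
    iteration_scale: float = 1.0,
    preprocessing: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run every test of a plan; one row per (test x replicate analysis).

    Deconvolutions are shared between tests on the same condition and
    conditioning set.  Engine failures become rows with ``error`` set and
    the run continues.
    """
    rows: list[dict] = []
    if not plan.tests:
        return pd.DataFrame(
            columns=["condition_id", "poi", "tag", "replicate",
                     "log10_overall", "log10_simple", "verbal", "error"]
        )
    model = PopGenModel(config.popgen_model, config.theta, config.population)
    # group tests sharing a deconvolution
    groups: dict[tuple[str, tuple[str, ...]], list[GridTest]] = {}
    for t in plan.tests:
        groups.setdefault((t.condition.condition_id, t.known_donors), []).append(t)
    rng = np.random.default_rng(seed)
    for (cond_id, known_donors), tests in groups.items():
        cond = tests[0].condition
        contributions = [
            ContributionSpec(d, plan.genotypes[d], t)
            for d, t in zip(cond.donors, cond.templates_pg)
        ]
        profile_seed = int(rng.integers(2**31))
        profile = simulate_epg_profile(
            contributions, params, cond.at, profile_seed, panel,
            sample_id=cond.condition_id,
        )
        knowns = tuple(plan.genotypes[d] for d in known_donors)
        for rep in range(plan.replicates):
            run_seed = int(rng.integers(2**31))
            try:
                settings = settings_for_n(
                    cond.n_contributors, iteration_scale, run_seed, preprocessing
                )
                wg = run_mcmc(
                    profile, cond.n_contributors, list(knowns), vm, settings, config
                )
                calc = LRCalculator(wg, profile, freqs, model, knowns)
            except Exception as exc:  # recorded, run continues
                for t in tests:
                    rows.append(
                        {"condition_id": cond_id, "poi": t.poi, "tag": t.tag,
                         "replicate": rep, "log10_overall": np.nan,
                         "log10_simple": np.nan, "verbal": None,
                         "error": f"{type(exc).__name__}: {exc}"}
                    )
                continue
            for t in tests:
                res = calc.compute(t.poi_genotype)
                rows.append(
                    {"condition_id": cond_id, "poi": t.poi, "tag": t.tag,
                     "replicate": rep, "log10_overall": res.log10_overall,
                     "log10_simple": res.log10_simple,
                     "verbal": res.verbal_bin, "error": None}
                )
    return pd.DataFrame(rows)


def summarize_grid(results: pd.DataFrame) -> dict:
    """Error-rate summary with a binomial CI on the very-strong fraction."""
    if results.empty:
        return {"n_tests": 0, "n_failed": 0, "h1_n": 0, "h2_n": 0,
                "h1_fraction_ge_1e6": float("nan"), "h1_fraction_gt_1": float("nan"),
                "false_exclusions": 0, "false_inclusions": 0,
                "h1_ge_1e6_ci": (float("nan"), float("nan"))}
    ok = results[results["error"].isna()]
    h1 = ok[ok["tag"] == "H1-true"]
    h2 = ok[ok["tag"] == "H2-true"]
    n_vs = int((h1["log10_overall"] >= 6).sum())
    ci = (float("nan"), float("nan"))
    if len(h1):
        bt = stats.binomtest(n_vs, len(h1))
        interval = bt.proportion_ci(confidence_level=0.95)
        ci = (float(interval.low), float(interval.high))
    return {
        "n_tests": int(len(results)),
        "n_failed": int(results["error"].notna().sum()),
        "h1_n": int(len(h1)),
        "h2_n": int(len(h2)),
        "h1_fraction_ge_1e6": float((h1["log10_overall"] >= 6).mean()) if len(h1) else float("nan"),
        "h1_fraction_gt_1": float((h1["log10_overall"] > 0).mean()) if len(h1) else float("nan"),
        "false_exclusions": int((h1["log10_overall"] < 0).sum()),
        "false_inclusions": int((h2["log10_overall"] >= 0).sum()),
        "h1_ge_1e6_ci": ci,
    }


def reduced_grid_plan(
    design: MixtureDesign,
    replicates: int = 1,
    dilutions: tuple[int, ...] = (1, 4),
    per_type_ratios: int = 2,
) -> TestPlan:
    """A reduced H1-true plan spanning every contributor number and the
    requested dilution levels (every true contributor of each selected
    condition is tested once)."""
    tests: list[GridTest] = []
    seen_ratios: dict[str, list[str]] = {}
    for cond in design.conditions:
        if cond.dilution not in dilutions:
            continue
        chosen = seen_ratios.setdefault(cond.mixture_type, [])
        if cond.ratio_label not in chosen:
            if len(chosen) >= per_type_ratios:
                continue
            chosen.append(cond.ratio_label)
        for donor in cond.donors:
            tests.append(
                GridTest(cond, donor, design.genotypes[donor], "H1-true")
            )
    return TestPlan(tests, design.genotypes, replicates=replicates)


# ---------------------------------------------------------------------------
# In silico specificity


def run_insilico_specificity(
    profile: EPGProfile,
    n_contributors: int,
    freqs: AlleleFrequencyTable,
    vm: VarianceModel,
    config: AnalysisConfig,
    settings: MCMCSettings,
    populations: list[str],
    n_per_pop: int = 100,
    replicates: int = 5,
    knowns: tuple[GenotypeProfile, ...] = (),
    loci: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Score a random in silico genotype database against one mixture.

    Each replicate analysis re-runs the deconvolution and generates a
    fresh database (four populations plus a combined draw), then computes
    one overall LR per database genotype — 500 genotypes per analysis at
    the defaults, 2500 non-contributor results over five replicates.
    """
    model = PopGenModel(config.popgen_model, config.theta, config.population)
    rows = []
    ss = np.random.SeedSequence(settings.seed)
    children = ss.spawn(replicates)
    for rep in range(replicates):
        rep_seed = int(children[rep].generate_state(1)[0] % (2**31))
        rep_settings = MCMCSettings(
            chains=settings.chains,
            iterations_per_chain=settings.iterations_per_chain,
            burn_in_fraction=settings.burn_in_fraction,
            thin_n=settings.thin_n,
            preprocessing_steps=settings.preprocessing_steps,
            seed=rep_seed,
        )
        wg = run_mcmc(profile, n_contributors, list(knowns), vm, rep_settings, config)
        calc = LRCalculator(wg, profile, freqs, model, knowns)
        db = sample_insilico_database(
            freqs, populations, n_per_pop, seed=rep_seed, loci=loci
        )
        for name, genotype in db.items():
            res = calc.compute(genotype)
            rows.append(
                {"replicate": rep, "genotype": name,
                 "population": name.rsplit("_", 1)[0],
                 "log10_overall": res.log10_overall,
                 "lr_ge_1": res.log10_overall >= 0}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Number-of-contributors stress tests


def run_noc_tests(
    condition: MixtureCondition,
    profile: EPGProfile,
    genotypes: dict[str, GenotypeProfile],
    non_contributor: GenotypeProfile,
    freqs: AlleleFrequencyTable,
    vm: VarianceModel,
    config: AnalysisConfig,
    iteration_scale: float = 1.0,
    preprocessing: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """LRs at N-1, N and N+1 contributors, plus conditioned variants.

    Unconditioned: every true contributor is scored at each contributor
    number.  Conditioned N-1: the smallest contributor is fixed as a
    known.  Conditioned N+1: a true non-contributor is scored in place of
    the largest contributor.  Constraint failures (e.g. more required
    alleles than N-1 contributors can carry) are recorded, not raised.
    """
    model = PopGenModel(config.popgen_model, config.theta, config.population)
    true_n = condition.n_contributors
    if true_n < 2:
        raise ValueError("NOC stress tests need at least 2 true contributors")
    donors = list(condition.donors)
    templates = list(condition.templates_pg)
    minor = donors[int(np.argmin(templates))]
    rows = []
    rng = np.random.default_rng(seed)

    def analyze(n: int, knowns: tuple[str, ...], pois: list[tuple[str, GenotypeProfile]],
                variant: str) -> None:
        run_seed = int(rng.integers(2**31))
        try:
            settings = settings_for_n(n, iteration_scale, run_seed, preprocessing)
            wg = run_mcmc(
                profile, n, [genotypes[d] for d in knowns], vm, settings, config
            )
            calc = LRCalculator(
                wg, profile, freqs, model, tuple(genotypes[d] for d in knowns)
            )
        except ValueError as exc:
            for poi, _ in pois:
                rows.append(
                    {"variant": variant, "n_assumed": n, "poi": poi,
                     "log10_overall": np.nan, "log10_simple": np.nan,
                     "error": f"constraint failure: {exc}"}
                )
            return
        for poi, g in pois:
            res = calc.compute(g)
            rows.append(
                {"variant": variant, "n_assumed": n, "poi": poi,
                 "log10_overall": res.log10_overall,
                 "log10_simple": res.log10_simple, "error": None}
            )

    truths = [(d, genotypes[d]) for d in donors]
    for n, variant in ((true_n - 1, "N-1"), (true_n, "N"), (true_n + 1, "N+1")):
        analyze(n, (), truths, variant)
    analyze(true_n - 1, (minor,), [(d, genotypes[d]) for d in donors if d != minor],
            "N-1 conditioned (minor known)")
    analyze(true_n + 1, (), truths + [("non_contributor", non_contributor)],
            "N+1 with non-contributor")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Precision


def levene_statistic(groups: list[np.ndarray]) -> tuple[float, float]:
    """Median-centered (Brown-Forsythe) Levene test across groups."""
    stat, p = stats.levene(*groups, center="median")
    return float(stat), float(p)


def run_precision_study(
    profile: EPGProfile,
    n_contributors: int,
    pois: list[tuple[str, GenotypeProfile]],
    freqs: AlleleFrequencyTable,
    vm: VarianceModel,
    config: AnalysisConfig,
    iterations_list: list[int],
    replicates: int = 5,
    chains: int = 8,
    preprocessing: int = 2000,
    seed: int = 0,
    deviation_flag_logs: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate analyses per iteration setting; Levene's test across settings.

    Returns (per-replicate results, per-POI stats with the Levene p-value
    and a flag for any replicate deviating more than two log units from
    its setting's mean).
    """
    if replicates < 2:
        raise ValueError("precision study needs >= 2 replicates")
    if len(iterations_list) < 2:
        raise ValueError("need >= 2 iteration settings to compare")
    model = PopGenModel(config.popgen_model, config.theta, config.population)
    rng = np.random.default_rng(seed)
    rows = []
    for iters in iterations_list:
        for rep in range(replicates):
            settings = MCMCSettings(
                chains=chains, iterations_per_chain=iters,
                preprocessing_steps=preprocessing, seed=int(rng.integers(2**31)),
            )
            wg = run_mcmc(profile, n_contributors, [], vm, settings, config)
            calc = LRCalculator(wg, profile, freqs, model)
            for poi, g in pois:
                res = calc.compute(g)
                rows.append(
                    {"iterations": iters, "replicate": rep, "poi": poi,
                     "log10_overall": res.log10_overall}
                )
    results = pd.DataFrame(rows)
    stat_rows = []
    for poi, sub in results.groupby("poi"):
        groups = [
            sub[sub["iterations"] == i]["log10_overall"].to_numpy()
            for i in iterations_list
        ]
        stat, p = levene_statistic(groups)
        sds = {f"sd_log10_{i}": float(np.std(g, ddof=1)) for i, g in zip(iterations_list, groups)}
        means = {f"mean_log10_{i}": float(np.mean(g)) for i, g in zip(iterations_list, groups)}
        outlier = any(
            np.any(np.abs(g - g.mean()) > deviation_flag_logs) for g in groups
        )
        stat_rows.append(
            {"poi": poi, "levene_stat": stat, "levene_p": p,
             "outlier_flagged": bool(outlier), **means, **sds}
        )
    return results, pd.DataFrame(stat_rows)


# ---------------------------------------------------------------------------
# Obligate peak height vs LR


def analyze_peakheight_vs_lr(
    results: pd.DataFrame,
    conditions: dict[str, MixtureCondition],
    profiles: dict[str, EPGProfile],
    genotypes: dict[str, GenotypeProfile],
    max_template_pg: float = 100.0,
) -> pd.DataFrame:
    """Obligate (unshared) allele peak heights vs log10 LR for low-template
    contributors, with a Spearman correlation attached as metadata.

    ``results`` must carry H1-true rows with condition_id/poi/log10_overall.
    Contributors whose alleles are all shared are excluded.
    """
    rows = []
    h1 = results[(results["tag"] == "H1-true") & results["error"].isna()]
    for (cond_id, poi), sub in h1.groupby(["condition_id", "poi"]):
        cond = conditions[cond_id]
        if poi not in cond.donors:
            continue
        template = cond.templates_pg[cond.donors.index(poi)]
        if template > max_template_pg or template <= 0:
            continue
        profile = profiles[cond_id]
        own = genotypes[poi]
        others = {
            a
            for d in cond.donors if d != poi
            for l in own
            for a in genotypes[d].get(l, ())
        }
        obligate_heights = []
        all_heights = []
        dropped = 0
        for l, pair in own.items():
            heights = profile.heights(l)
            for a in set(pair):
                h = heights.get(a)
                if h is not None:
                    all_heights.append(h)
                else:
                    dropped += 1
                if a not in others:
                    if h is not None:
                        obligate_heights.append(h)
        if not obligate_heights and not any(
            a not in others for l, p in own.items() for a in set(p)
        ):
            continue  # fully shared contributor: excluded
        rows.append(
            {"condition_id": cond_id, "poi": poi, "template_pg": template,
             "obligate_aph": float(np.mean(obligate_heights)) if obligate_heights else 0.0,
             "all_aph": float(np.mean(all_heights)) if all_heights else 0.0,
             "n_dropped": dropped,
             "mean_log10_lr": float(sub["log10_overall"].mean())}
        )
    df = pd.DataFrame(rows)
    if len(df) >= 3:
        rho, p = stats.spearmanr(df["obligate_aph"], df["mean_log10_lr"])
        df.attrs["spearman_rho"] = float(rho)
        df.attrs["spearman_p"] = float(p)
    return df
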