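"""Synthetic electropherogram generator and mixture-design enumerator.

The generative peak model is deliberately simple but carries every feature
the deconvolution engine models:

* expected allele height ``mu = gamma * e_l * sum_k template_k * n_ka``
  (gamma in RFU/pg, ``e_l`` a per-locus amplification efficiency,
  ``n_ka`` the 0/1/2 copy number of allele ``a`` in contributor ``k``);
* backward (N-1) stutter *reallocates* a fraction ``xi_l`` of each
  allele's expected height to the one-repeat-shorter position, so total
  expected locus signal is conserved;
* observed heights are Gamma with mean ``nu`` and variance ``VF * nu``
  (``VF`` is the same dispersion the MCMC likelihood uses), giving a
  closed-form dropout probability — the Gamma CDF at the analytical
  threshold — that decreases monotonically with template;
* drop-in peaks are Poisson with population-frequency allele labels and
  AT-shifted exponential heights (default rate 0: the validated protocol
  observed no drop-in);
* peaks below the analytical threshold are censored.

The default mixture design enumerates the full validation grid: two- to
five-person mixtures over 24 ratio conditions, each serially diluted 1:2,
1:4 and 1:8 and amplified in triplicate — 96 conditions, 288 profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._alleles import allele_key, stutter_target
from .panel_io import (
    ALL_POP,
    AlleleFrequencyTable,
    EPGProfile,
    PeakRecord,
    STRPanel,
)
from .popgen import sample_genotype_profile

GenotypeProfile = dict[str, tuple[str, str]]


@dataclass(frozen=True)
class ContributionSpec:
    """One donor's genotype and (possibly diluted) template in picograms."""

    donor: str
    genotype: GenotypeProfile
    template_pg: float

    def __post_init__(self) -> None:
        if self.template_pg < 0:
            raise ValueError("template must be >= 0 pg")


@dataclass(frozen=True)
class SimulatorParams:
    """Knobs of the generative peak model.

    ``gamma`` = 3 RFU/pg and ``vf`` = 40 put a ~6 pg contributor's
    heterozygous alleles (mu ~ 18 RFU) mostly below a 30 RFU threshold,
    reproducing the heavy-dropout regime of the most dilute mixtures,
    while a 500 pg contributor (mu ~ 1500 RFU) essentially never drops.
    """

    gamma: float = 3.0
    vf: float = 40.0
    stutter_rate: float = 0.07
    locus_efficiency: dict[str, float] = field(default_factory=dict)
    dropin_rate: float = 0.0
    dropin_height_scale: float = 40.0
    degradation: float = 0.0  # exponential size decay per bp; 0 = off

    def __post_init__(self) -> None:
        if not self.gamma > 0 or not self.vf > 0:
            raise ValueError("gamma and vf must be > 0")
        if not 0 <= self.stutter_rate < 0.2:
            raise ValueError("stutter_rate must be in [0, 0.2)")

    def efficiency(self, locus: str) -> float:
        return self.locus_efficiency.get(locus, 1.0)


@dataclass(frozen=True)
class MixtureCondition:
    condition_id: str
    mixture_type: str
    ratio_label: str
    donors: tuple[str, ...]
    undiluted_templates_pg: tuple[float, ...]
    dilution: int  # 1 (undiluted), 2, 4, or 8
    at: float
    replicates: int = 3

    @property
    def templates_pg(self) -> tuple[float, ...]:
        return tuple(t / self.dilution for t in self.undiluted_templates_pg)

    @property
    def n_contributors(self) -> int:
        return len(self.donors)


@dataclass
class MixtureDesign:
    conditions: list[MixtureCondition]
    genotypes: dict[str, GenotypeProfile]  # donor id -> genotype

    def __len__(self) -> int:
        return len(self.conditions)

    @property
    def n_profiles(self) -> int:
        return sum(c.replicates for c in self.conditions)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition_id": c.condition_id,
                    "mixture_type": c.mixture_type,
                    "ratio": c.ratio_label,
                    "contributors": "|".join(c.donors),
                    "templates_pg": "|".join(f"{t:g}" for t in c.templates_pg),
                    "dilution": c.dilution,
                    "AT": c.at,
                    "replicates": c.replicates,
                }
                for c in self.conditions
            ]
        )


# Ratio grid of the full validation design: per mixture type, the ratio
# labels and the approximate undiluted per-contributor templates (pg),
# largest contributor held at ~500 pg.
DEFAULT_DESIGN_SPEC: dict[str, list[tuple[str, tuple[float, ...]]]] = {
    "2p_low_share": [
        ("1:1", (500, 500)), ("1:2", (250, 500)), ("1:3", (160, 500)),
        ("1:5", (100, 500)), ("1:10", (50, 500)),
    ],
    "2p_high_share": [
        ("1:1", (500, 500)), ("1:2", (250, 500)), ("1:3", (160, 500)),
        ("1:5", (100, 500)), ("1:10", (50, 500)),
    ],
    "3p_low_share": [
        ("1:1:1", (500, 500, 500)), ("1:1:2", (250, 250, 500)),
        ("1:2:10", (50, 100, 500)), ("1:3:5", (100, 300, 500)),
    ],
    "3p_high_share": [
        ("1:1:1", (500, 500, 500)), ("1:1:2", (250, 250, 500)),
        ("1:2:10", (50, 100, 500)), ("1:3:5", (100, 300, 500)),
    ],
    "4p_random": [
        ("1:1:1:1", (500, 500, 500, 500)), ("1:1:3:10", (50, 50, 150, 500)),
        ("1:2:2:5", (100, 200, 200, 500)),
    ],
    "5p_random": [
        ("1:1:1:1:1", (500, 500, 500, 500, 500)),
        ("1:1:5:5:10", (50, 50, 250, 250, 500)),
        ("1:2:2:5:10", (50, 100, 100, 250, 500)),
    ],
}

DEFAULT_DILUTIONS = (1, 2, 4, 8)


def _condition_at(mixture_type: str, dilution: int) -> float:
    """Analytical threshold by condition: two-person mixtures at 50 RFU,
    three-person at 50 except the 1:8 dilutions (30), four/five at 30."""
    n = int(mixture_type[0])
    if n == 2:
        return 50.0
    if n == 3:
        return 30.0 if dilution == 8 else 50.0
    return 30.0


def build_mixture_design(
    panel: STRPanel,
    freqs: AlleleFrequencyTable,
    seed: int = 0,
    spec: dict[str, list[tuple[str, tuple[float, ...]]]] | None = None,
    dilutions: tuple[int, ...] = DEFAULT_DILUTIONS,
    replicates: int = 3,
    population: str = ALL_POP,
) -> MixtureDesign:
    """Enumerate the (ratio x dilution) validation grid with fresh donors.

    Donor genotypes are drawn once per mixture type from the population
    frequency table; every ratio/dilution condition of a type shares its
    donors, as the wet-lab design shared physical extracts.
    """
    spec = DEFAULT_DESIGN_SPEC if spec is None else spec
    rng = np.random.default_rng(seed)
    genotypes: dict[str, GenotypeProfile] = {}
    conditions: list[MixtureCondition] = []
    for mixture_type, ratio_rows in spec.items():
        n = max(len(t) for _, t in ratio_rows)
        donors = tuple(f"{mixture_type}_d{k + 1}" for k in range(n))
        for d in donors:
            genotypes[d] = sample_genotype_profile(
                freqs, panel.locus_names, population, rng
            )
        for (ratio_label, templates), dilution in itertools.product(ratio_rows, dilutions):
            if len(templates) != len(ratio_label.split(":")):
                raise ValueError(
                    f"{mixture_type} {ratio_label}: ratio/template length mismatch"
                )
            conditions.append(
                MixtureCondition(
                    condition_id=f"{mixture_type}_{ratio_label.replace(':', '-')}_x{dilution}",
                    mixture_type=mixture_type,
                    ratio_label=ratio_label,
                    donors=donors[: len(templates)],
                    undiluted_templates_pg=templates,
                    dilution=dilution,
                    at=_condition_at(mixture_type, dilution),
                    replicates=replicates,
                )
            )
    return MixtureDesign(conditions, genotypes)


# ---------------------------------------------------------------------------
# Peak simulation


def expected_heights(
    contributions: list[ContributionSpec],
    locus_name: str,
    panel: STRPanel,
    params: SimulatorParams,
) -> dict[str, float]:
    """Post-stutter expected peak heights (RFU) by allele position."""
    locus = panel.locus(locus_name)
    eff = params.efficiency(locus_name)
    mu: dict[str, float] = {}
    for spec in contributions:
        genotype = spec.genotype.get(locus_name)
        if genotype is None:
            continue
        for allele in genotype:
            mu[allele] = mu.get(allele, 0.0) + params.gamma * eff * spec.template_pg
    if params.degradation > 0:
        for allele in list(mu):
            mu[allele] *= float(
                np.exp(-params.degradation * locus.fragment_size(allele))
            )
    if params.stutter_rate == 0:
        return mu
    nu: dict[str, float] = {}
    for allele, m in mu.items():
        nu[allele] = nu.get(allele, 0.0) + (1.0 - params.stutter_rate) * m
        target = stutter_target(allele)
        nu[target] = nu.get(target, 0.0) + params.stutter_rate * m
    return nu


def dropout_probability(mu: float, vf: float, at: float) -> float:
    """P(observed height < AT) for an expected height ``mu``."""
    if mu <= 0:
        return 1.0
    return float(stats.gamma.cdf(at, a=mu / vf, scale=vf))


def simulate_epg_profile(
    contributions: list[ContributionSpec],
    params: SimulatorParams,
    at: float,
    seed: int,
    panel: STRPanel,
    freqs: AlleleFrequencyTable | None = None,
    population: str = ALL_POP,
    sample_id: str = "sim",
) -> EPGProfile:
    """Draw one thresholded synthetic profile.  Reproducible under seed."""
    if not contributions:
        raise ValueError("at least one contribution required")
    rng = np.random.default_rng(seed)
    peaks: dict[str, list[PeakRecord]] = {}
    for locus in panel.loci:
        nu = expected_heights(contributions, locus.name, panel, params)
        records: dict[str, float] = {}
        for allele in sorted(nu, key=allele_key):
            m = nu[allele]
            if m <= 0:
                continue
            h = float(rng.gamma(shape=m / params.vf, scale=params.vf))
            if h >= at:
                records[allele] = h
        if params.dropin_rate > 0:
            if freqs is None:
                raise ValueError("drop-in simulation requires a frequency table")
            col = freqs.freqs[population][locus.name]
            labels = list(col)
            p = np.array([col[a] for a in labels])
            p = p / p.sum()
            for _ in range(rng.poisson(params.dropin_rate / len(panel.loci))):
                allele = labels[int(rng.choice(len(labels), p=p))]
                h = at + float(rng.exponential(params.dropin_height_scale))
                records[allele] = max(records.get(allele, 0.0), h)
        peaks[locus.name] = [
            PeakRecord(sample_id, locus.name, a, locus.fragment_size(a), h)
            for a, h in records.items()
        ]
    return EPGProfile(sample_id, at, peaks)


def simulate_design(
    design: MixtureDesign,
    params: SimulatorParams,
    panel: STRPanel,
    seed: int = 0,
    freqs: AlleleFrequencyTable | None = None,
) -> list[tuple[MixtureCondition, int, EPGProfile]]:
    """Materialize every replicate of every condition in a design.

    Replicates differ only by RNG stream, emulating replicate
    amplifications of the same physical mixture.
    """
    ss = np.random.SeedSequence(seed)
    out = []
    streams = ss.spawn(sum(c.replicates for c in design.conditions))
    i = 0
    for cond in design.conditions:
        contributions = [
            ContributionSpec(d, design.genotypes[d], t)
            for d, t in zip(cond.donors, cond.templates_pg)
        ]
        for rep in range(cond.replicates):
            child_seed = int(streams[i].generate_state(1)[0] % (2**31))
            out.append(
                (
                    cond,
                    rep,
                    simulate_epg_profile(
                        contributions, params, cond.at, child_seed, panel,
                        freqs=freqs, sample_id=f"{cond.condition_id}_r{rep + 1}",
                    ),
                )
            )
            i += 1
    return out


def generate_protocol_dataset(
    params: SimulatorParams,
    panel: STRPanel,
    freqs: AlleleFrequencyTable,
    donors: int = 10,
    levels: tuple[float, ...] = (500.0, 250.0, 125.0),
    replicates: int = 5,
    at: float = 30.0,
    seed: int = 0,
    population: str = ALL_POP,
) -> tuple[list[EPGProfile], dict[str, GenotypeProfile]]:
    """Single-source calibration profiles for variance/stutter fitting.

    Defaults emulate the standard protocol dataset: ten donors at 500,
    250 and 125 pg, five replicate amplifications each — 150 profiles.
    """
    rng = np.random.default_rng(seed)
    genotypes: dict[str, GenotypeProfile] = {
        f"donor_{k + 1:02d}": sample_genotype_profile(
            freqs, panel.locus_names, population, rng
        )
        for k in range(donors)
    }
    profiles = []
    for donor, genotype in genotypes.items():
        for level in levels:
            for rep in range(replicates):
                child_seed = int(rng.integers(2**31))
                profile = simulate_epg_profile(
                    [ContributionSpec(donor, genotype, level)],
                    params, at, child_seed, panel,
                    sample_id=f"{donor}_{level:g}pg_r{rep + 1}",
                )
                profiles.append(profile)
    return profiles, genotypes


def write_design(
    simulated: list[tuple[MixtureCondition, int, EPGProfile]],
    out_dir: str | Path,
) -> None:
    """Write per-profile peak tables plus the design manifest CSV."""
    from .panel_io import write_peak_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cond, rep, profile in simulated:
        name = f"{profile.sample_id}.tsv"
        write_peak_table(profile, out_dir / name)
        rows.append(
            {"condition_id": cond.condition_id, "replicate": rep + 1,
             "file": name, "AT": cond.at, "dilution": cond.dilution,
             "ratio": cond.ratio_label, "contributors": "|".join(cond.donors),
             "templates_pg": "|".join(f"{t:g}" for t in cond.templates_pg)}
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
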