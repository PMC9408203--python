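"""Genotype probability models and random-match probabilities.

Three co-ancestry treatments are supported, matching the options a
probabilistic-genotyping run exposes:

* ``HWE`` — Hardy-Weinberg proportions, ``p_i^2`` and ``2 p_i p_j``.
* ``NRC4.1`` — NRC II recommendation 4.1: homozygotes get the conservative
  adjustment ``p^2 + p (1 - p) theta``; heterozygotes stay ``2 p_i p_j``.
  Note this is deliberately *not* a normalized distribution for theta > 0
  (its total mass is ``1 + theta * sum_i p_i (1 - p_i)``).
* ``NRC4.2`` — the conditional (Balding-Nichols) match probabilities,
  normalized by ``(1 + theta)(1 + 2 theta)`` so genotype probabilities sum
  to one over the allele domain.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from ._alleles import Q_ALLELE, allele_key
from .panel_io import ALL_POP, AlleleFrequencyTable


@dataclass(frozen=True)
class Genotype:
    """Unordered allele pair at one locus; either allele may be Q."""

    locus: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.alleles
        if (a, b) != tuple(sorted((a, b), key=allele_key)):
            object.__setattr__(self, "alleles", tuple(sorted((a, b), key=allele_key)))

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    @property
    def has_q(self) -> bool:
        return Q_ALLELE in self.alleles


@dataclass(frozen=True)
class PopGenModel:
    kind: str = "NRC4.1"
    theta: float = 0.01
    population: str = ALL_POP

    def __post_init__(self) -> None:
        if self.kind not in ("HWE", "NRC4.1", "NRC4.2"):
            raise ValueError(f"unknown popgen model kind: {self.kind}")
        if not 0.0 <= self.theta <= 0.05:
            raise ValueError("theta must be in [0, 0.05]")


def pair_probability(p_i: float, p_j: float, homozygous: bool, model: PopGenModel) -> float:
    """Genotype probability from the two allele frequencies alone."""
    th = 0.0 if model.kind == "HWE" else model.theta
    if model.kind in ("HWE", "NRC4.1"):
        if homozygous:
            return p_i * p_i + p_i * (1.0 - p_i) * th
        return 2.0 * p_i * p_j
    # NRC4.2: Balding-Nichols conditional form, normalized
    denom = (1.0 + th) * (1.0 + 2.0 * th)
    if homozygous:
        return (2.0 * th + (1.0 - th) * p_i) * (3.0 * th + (1.0 - th) * p_i) / denom
    return 2.0 * (th + (1.0 - th) * p_i) * (th + (1.0 - th) * p_j) / denom


def genotype_probability(
    g: Genotype, freqs: AlleleFrequencyTable, model: PopGenModel
) -> float:
    """Population probability of genotype ``g`` (no Q alleles here;
    the virtual Q allele is priced in the LR engine's set prior)."""
    if g.has_q:
        raise ValueError("Q alleles are handled by the genotype-set prior")
    p_i = freqs.freq(model.population, g.locus, g.alleles[0])
    p_j = freqs.freq(model.population, g.locus, g.alleles[1])
    return pair_probability(p_i, p_j, g.is_homozygous, model)


def rmp_profile(
    profile: list[Genotype], freqs: AlleleFrequencyTable, model: PopGenModel
) -> tuple[float, dict[str, float]]:
    """Random-match probability of a full profile.

    Returns the whole-profile product and the per-locus vector, the latter
    for concordance reports against hand calculations.
    """
    seen = [g.locus for g in profile]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate loci in profile")
    per_locus = {g.locus: genotype_probability(g, freqs, model) for g in profile}
    return float(np.exp(sum(math.log(p) for p in per_locus.values()))), per_locus


def enumerate_genotypes(alleles: tuple[str, ...], locus: str) -> list[Genotype]:
    """All unordered genotypes over an allele domain."""
    return [
        Genotype(locus, (a, b))
        for a, b in itertools.combinations_with_replacement(
            sorted(alleles, key=allele_key), 2
        )
    ]


def sample_genotype_profile(
    freqs: AlleleFrequencyTable,
    loci: tuple[str, ...],
    population: str,
    rng: np.random.Generator,
) -> dict[str, tuple[str, str]]:
    """One HWE draw per locus from the named population column."""
    out = {}
    for locus in loci:
        labels = list(freqs.freqs[population][locus])
        p = np.array([freqs.freqs[population][locus][a] for a in labels])
        p = p / p.sum()
        pair = rng.choice(len(labels), size=2, p=p)
        out[locus] = tuple(sorted((labels[pair[0]], labels[pair[1]]), key=allele_key))
    return out


def sample_insilico_database(
    freqs: AlleleFrequencyTable,
    populations: list[str],
    n_per_pop: int,
    seed: int,
    loci: tuple[str, ...] | None = None,
) -> dict[str, dict[str, tuple[str, str]]]:
    """Random non-contributor genotype database.

    For each named population ``n_per_pop`` profiles are drawn under HWE,
    plus ``n_per_pop`` "combined" profiles whose population column is
    re-drawn uniformly at each locus — so with four populations and 100
    per group the database holds 500 profiles per analysis run.
    """
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    for pop in populations:
        if pop not in freqs.populations:
            raise KeyError(f"unknown population: {pop}")
    rng = np.random.default_rng(seed)
    if loci is None:
        loci = tuple(freqs.freqs[populations[0]])
    db: dict[str, dict[str, tuple[str, str]]] = {}
    for pop in populations:
        for i in range(n_per_pop):
            db[f"{pop}_{i:03d}"] = sample_genotype_profile(freqs, loci, pop, rng)
    for i in range(n_per_pop):  # combined draw: population re-drawn per locus
        profile = {}
        for locus in loci:
            pop = populations[int(rng.integers(len(populations)))]
            profile.update(sample_genotype_profile(freqs, (locus,), pop, rng))
        db[f"combined_{i:03d}"] = profile
    return db
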