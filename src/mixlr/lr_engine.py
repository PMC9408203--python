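"""Likelihood ratios from weighted genotype sets.

Two statistics are computed from a deconvolution's per-locus weights
``w_jl`` under a proposition pair:

* the **simple** (sub-source) LR, which asks only whether the person of
  interest (POI) is *among* the contributors — per locus the numerator
  averages, over unknown positions, the weighted probability that the POI
  occupies that position while the remaining unknowns are random members
  of the population; the profile LR is the product over loci;
* the **overall** (sub-sub-source) LR, which marginalizes over the
  *position* the POI occupies: the numerator sums, over unknown positions
  ``i``, the whole-profile product with the POI fixed at position ``i``,
  and the denominator multiplies the unconditioned product by the number
  of unknown positions.  For a single unknown the two coincide.

Q (dropout) alleles: at each locus the virtual allele Q aggregates every
allele not observed there, with frequency ``1 - sum(observed allele
frequencies)`` (clamped to the minimum frequency if non-positive).  A set
genotype containing Q matches the POI when its real alleles are the POI's
and each Q stands for a POI allele that is *not* observed at the locus;
conditioned knowns match on full genotypes only.  LRs are accumulated in
log space and never truncated to zero: a locus numerator with no sampled
mass is floored at one pseudo-sample times the POI's own genotype
probability, so exclusionary LRs stay finite and strictly positive.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

from ._alleles import Q_ALLELE, allele_key
from .panel_io import AlleleFrequencyTable, EPGProfile
from .deconvolution import Pair, SetKey, WeightedGenotypes
from .popgen import PopGenModel, pair_probability

GenotypeProfile = dict[str, tuple[str, str]]

DEFAULT_VERBAL_BINS: tuple[tuple[float, str], ...] = (
    (1.0, "exclusionary direction"),
    (1e2, "limited support"),
    (1e4, "moderate support"),
    (1e6, "strong support"),
    (math.inf, "very strong support"),
)


@dataclass(frozen=True)
class Proposition:
    """H1: POI + knowns + (N-1-K) unknowns vs H2: knowns + (N-K) unknowns."""

    poi: GenotypeProfile
    knowns: tuple[GenotypeProfile, ...]
    n_contributors: int
    model: PopGenModel

    def __post_init__(self) -> None:
        if len(self.knowns) + 1 > self.n_contributors:
            raise ValueError("propositions need at least one unknown position for the POI")
        for kg in self.knowns:
            if kg == self.poi:
                raise ValueError("POI cannot also be a conditioned known")


@dataclass
class LRResult:
    profile_simple_lr: float
    profile_overall_lr: float
    log10_simple: float
    log10_overall: float
    per_locus_simple: dict[str, float]
    per_locus_overall: dict[str, float]
    verbal_bin: str
    n_contributors: int
    n_knowns: int
    any_locus_below_one: bool
    flags: list[str] = field(default_factory=list)


def verbal_scale_bin(
    lr: float, bins: tuple[tuple[float, str], ...] = DEFAULT_VERBAL_BINS
) -> str:
    """Map an LR onto the qualitative verbal scale."""
    if not lr > 0:
        raise ValueError("LR must be > 0 (the engine never reports an absolute exclusion)")
    for upper, label in bins:
        if lr < upper:
            return label
    return bins[-1][1]


# ---------------------------------------------------------------------------
# Genotype-set priors


def _q_frequency(
    freq_col: dict[str, float], observed: list[str], min_freq: float
) -> float:
    q = 1.0 - sum(freq_col.get(a, min_freq) for a in observed)
    if q <= 0.0:
        warnings.warn("observed allele frequencies sum to >= 1; clamping Q frequency")
        return min_freq
    return q


def _locus_freqs(
    freqs: AlleleFrequencyTable, model: PopGenModel, locus: str, observed: list[str]
) -> dict[str, float]:
    # observed alleles missing from the table are priced at the minimum
    # frequency without renormalizing: the LR denominator must use the
    # same genotype probabilities as a hand RMP on the published column
    col = freqs.freqs[model.population][locus]
    out = {a: col.get(a, freqs.min_freq) for a in observed}
    out[Q_ALLELE] = _q_frequency(col, observed, freqs.min_freq)
    return out


def _pair_prob(g: Pair, fmap: dict[str, float], model: PopGenModel) -> float:
    p_i = fmap[g[0]]
    p_j = fmap[g[1]]
    return pair_probability(p_i, p_j, g[0] == g[1], model)


def matches_poi(g: Pair, poi_g: Pair, observed: set[str]) -> bool:
    """Does set genotype ``g`` (possibly with Q) denote the POI genotype?

    Real alleles must match exactly; each Q must stand for a POI allele
    that is not observed at the locus (Q aggregates unobserved alleles).
    """
    remaining = list(poi_g)
    n_q = 0
    for a in g:
        if a == Q_ALLELE:
            n_q += 1
        elif a in remaining:
            remaining.remove(a)
        else:
            return False
    if len(remaining) != n_q:
        return False
    return all(a not in observed for a in remaining)


def genotype_set_prior(
    s: SetKey,
    roles: list[str],
    poi_g: Pair | None,
    known_gs: list[Pair],
    fmap: dict[str, float],
    model: PopGenModel,
    observed: set[str],
) -> float:
    """Pr(S | hypothesis) for one locus.

    ``roles`` assigns each position 'poi', 'known<i>' or 'unknown'.  POI
    positions contribute the (Q-aware) match indicator, known positions an
    exact-genotype indicator, unknown positions the population genotype
    probability with Q as the aggregate unobserved allele.
    """
    if len(roles) != len(s):
        raise ValueError("role assignment must cover every position")
    prob = 1.0
    k_i = 0
    for g, role in zip(s, roles):
        if role == "poi":
            if poi_g is None or not matches_poi(g, poi_g, observed):
                return 0.0
        elif role.startswith("known"):
            if g != known_gs[k_i]:
                return 0.0
            k_i += 1
        else:
            prob *= _pair_prob(g, fmap, model)
    return prob


# ---------------------------------------------------------------------------
# The calculator


class LRCalculator:
    """Precomputes per-locus structures so many POIs can be scored fast
    against one deconvolution (e.g. an in silico non-contributor database)."""

    def __init__(
        self,
        wg: WeightedGenotypes,
        profile: EPGProfile,
        freqs: AlleleFrequencyTable,
        model: PopGenModel,
        knowns: tuple[GenotypeProfile, ...] = (),
        pseudo_samples: int = 10_000,
    ):
        self.wg = wg
        self.model = model
        self.knowns = knowns
        n = wg.n_contributors
        k = len(knowns)
        if k != wg.n_knowns:
            raise ValueError("proposition knowns must match the deconvolution conditioning")
        self.unknown_positions = list(range(k, n))
        self.u = len(self.unknown_positions)
        if self.u == 0:
            raise ValueError("no unknown position available for the POI")
        self.w_floor = 1.0 / (max(wg.n_samples, 0) + pseudo_samples)
        self.loci = list(wg.locus_weights)
        self.observed: dict[str, set[str]] = {
            l: set(profile.alleles(l)) for l in self.loci
        }
        self.fmap: dict[str, dict[str, float]] = {
            l: _locus_freqs(freqs, model, l, sorted(self.observed[l], key=allele_key))
            for l in self.loci
        }
        # den_l = sum_j w_j Pr(S_j | H2); pos_mass[l][i][g] = sum_j w_j *
        # (prod over other unknowns of Pr) restricted to sets with g at i
        self.den: dict[str, float] = {}
        self.pos_mass: dict[str, dict[int, dict[Pair, float]]] = {}
        for l in self.loci:
            fmap = self.fmap[l]
            known_gs = [tuple(sorted(kg[l], key=allele_key)) for kg in knowns]
            den = 0.0
            pos_mass: dict[int, dict[Pair, float]] = {i: {} for i in self.unknown_positions}
            for s, w in wg.locus_weights[l].items():
                if any(s[j] != known_gs[j] for j in range(k)):
                    continue  # conditioning mismatch carries no mass
                probs = [_pair_prob(s[i], fmap, model) for i in self.unknown_positions]
                total = math.prod(probs)
                den += w * total
                for idx, i in enumerate(self.unknown_positions):
                    others = total / probs[idx] if probs[idx] > 0 else math.prod(
                        p for jdx, p in enumerate(probs) if jdx != idx
                    )
                    d = pos_mass[i]
                    d[s[i]] = d.get(s[i], 0.0) + w * others
            self.den[l] = den
            self.pos_mass[l] = pos_mass

    def _poi_locus_numerators(self, poi: GenotypeProfile) -> dict[str, dict[int, float]]:
        """num[l][i] = sum_j w_jl Pr(S_jl | POI at position i)."""
        out: dict[str, dict[int, float]] = {}
        for l in self.loci:
            poi_g = tuple(sorted(poi[l], key=allele_key))
            obs = self.observed[l]
            out[l] = {}
            for i in self.unknown_positions:
                acc = 0.0
                for g, mass in self.pos_mass[l][i].items():
                    if matches_poi(g, poi_g, obs):
                        acc += mass
                out[l][i] = acc
        return out

    def _floor(self, l: str, poi_g: Pair) -> float:
        """Smallest reportable numerator mass: one pseudo-sample times the
        POI's own genotype probability (unobserved alleles priced at the
        locus minimum frequency)."""
        fmap = self.fmap[l]
        min_f = min(fmap.values())
        p = pair_probability(
            fmap.get(poi_g[0], min_f),
            fmap.get(poi_g[1], min_f),
            poi_g[0] == poi_g[1],
            self.model,
        )
        return self.w_floor * max(p, 1e-12)

    def compute(self, poi: GenotypeProfile) -> LRResult:
        num = self._poi_locus_numerators(poi)
        per_locus_simple: dict[str, float] = {}
        per_locus_overall: dict[str, float] = {}
        log10_simple = 0.0
        flags: list[str] = []
        # overall numerator: per position, product over loci (log space)
        log_num_by_pos = {i: 0.0 for i in self.unknown_positions}
        log_den_total = 0.0
        for l in self.loci:
            den = self.den[l]
            poi_g = tuple(sorted(poi[l], key=allele_key))
            if den <= 0:
                flags.append(f"{l}: zero H2 mass, locus LR reported as +inf")
                per_locus_simple[l] = math.inf
                per_locus_overall[l] = math.inf
                continue
            floor = self._floor(l, poi_g)
            s_num = max(sum(num[l].values()) / self.u, floor)
            per_locus_simple[l] = s_num / den
            log10_simple += math.log10(s_num / den)
            o_num = max(sum(num[l].values()), floor)
            per_locus_overall[l] = o_num / (self.u * den)
            log_den_total += math.log(den)
            for i in self.unknown_positions:
                log_num_by_pos[i] += math.log(max(num[l][i], floor))
        m = max(log_num_by_pos.values())
        log_overall_num = m + math.log(
            sum(math.exp(v - m) for v in log_num_by_pos.values())
        )
        log10_overall = (
            log_overall_num - math.log(self.u) - log_den_total
        ) / math.log(10)
        simple = 10.0 ** log10_simple if abs(log10_simple) < 300 else math.inf
        overall = 10.0 ** log10_overall if abs(log10_overall) < 300 else (
            math.inf if log10_overall > 0 else 0.0
        )
        return LRResult(
            profile_simple_lr=simple,
            profile_overall_lr=overall,
            log10_simple=log10_simple,
            log10_overall=log10_overall,
            per_locus_simple=per_locus_simple,
            per_locus_overall=per_locus_overall,
            verbal_bin=verbal_scale_bin(max(10.0 ** log10_overall, 5e-324)),
            n_contributors=self.wg.n_contributors,
            n_knowns=len(self.knowns),
            any_locus_below_one=any(v < 1 for v in per_locus_overall.values()),
            flags=flags,
        )


def simple_lr(
    wg: WeightedGenotypes,
    prop: Proposition,
    profile: EPGProfile,
    freqs: AlleleFrequencyTable,
) -> LRResult:
    """Simple (sub-source) LR; the result also carries the overall LR."""
    return LRCalculator(wg, profile, freqs, prop.model, prop.knowns).compute(prop.poi)


def overall_lr(
    wg: WeightedGenotypes,
    prop: Proposition,
    profile: EPGProfile,
    freqs: AlleleFrequencyTable,
) -> LRResult:
    """Overall (sub-sub-source) LR; the result also carries the simple LR."""
    return LRCalculator(wg, profile, freqs, prop.model, prop.knowns).compute(prop.poi)


def overall_lr_orderform(
    wg: WeightedGenotypes,
    prop: Proposition,
    profile: EPGProfile,
    freqs: AlleleFrequencyTable,
) -> float:
    """Overall LR by literal summation over contributor orderings.

    Enumerates every bijection of the unknown labels (POI, U2, ..., U_u)
    onto the unknown positions in both numerator and denominator — the
    factorial form the position-sum formula simplifies, for unrelated
    unknowns.  Independent of :class:`LRCalculator`; used as a cross-check.
    """
    calc = LRCalculator(wg, profile, freqs, prop.model, prop.knowns)
    u = calc.u
    num = calc._poi_locus_numerators(prop.poi)
    log_orders = []
    for perm in itertools.permutations(range(u)):
        poi_pos = calc.unknown_positions[perm.index(0)]
        log_v = 0.0
        for l in calc.loci:
            val = num[l][poi_pos]
            floor = calc._floor(l, tuple(sorted(prop.poi[l], key=allele_key)))
            log_v += math.log(max(val, floor))
        log_orders.append(log_v)
    m = max(log_orders)
    log_num = m + math.log(sum(math.exp(v - m) for v in log_orders))
    log_den = math.log(math.factorial(u)) + sum(
        math.log(calc.den[l]) for l in calc.loci
    )
    return math.exp(log_num - log_den)
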