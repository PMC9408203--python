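"""MCMC mixture deconvolution into weighted genotype sets.

The sampler explores, per locus, an ordered assignment of one genotype per
contributor (alleles drawn from the observed alleles plus the virtual
dropout allele Q), a shared mixture-proportion simplex ``phi``, and a
per-locus amplitude ``A_l`` (RFU per unit template share).  The peak-height
likelihood at a locus is fully continuous:

* expected height per allele position ``nu_a = A_l * sum_k phi_k n_ka``,
  with backward stutter reallocating a fraction ``xi_l`` to the
  one-repeat-shorter position (Q generates no stutter);
* an observed peak of height ``h`` contributes a Gamma log-density with
  mean ``nu`` and variance ``VF * nu``;
* an expected-but-unobserved position contributes the log Gamma CDF at the
  analytical threshold (dropout);
* an observed peak with no expected signal contributes a drop-in term
  ``log(lambda * p_allele * f(h))`` — or ``-inf`` when drop-in is disabled,
  which is what makes inadmissible genotype sets unreachable.

The genotype-set prior during MCMC is uniform over admissible sets;
population probabilities enter only in the LR stage, where the weights are
multiplied by ``Pr(S|H)`` — keeping them here would double-count.

``oracle_posterior`` computes the same posterior exactly (on a discrete
``(phi, A)`` grid) by exhaustive enumeration, for small instances; it is
the independent check the MCMC sampler is validated against.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc, gammaln

from ._alleles import Q_ALLELE, allele_key, stutter_target
from .panel_io import AlleleFrequencyTable, AnalysisConfig, EPGProfile
from .variance_model import VarianceModel

GenotypeProfile = dict[str, tuple[str, str]]
Pair = tuple[str, str]
SetKey = tuple[Pair, ...]

_LOG_FLOOR = 1e-300
_A_MIN, _A_MAX = 1e-2, 1e8


@dataclass
class MCMCSettings:
    """Sampler controls.

    The proposal mixture allocates ``p_genotype`` to genotype moves (with
    part of that mass spent on joint two-contributor moves at one locus
    when two or more unknowns exist), ``p_phi`` to mixture-proportion
    moves (logistic-normal random walk), a small share to always-accepted
    relabeling swaps of exchangeable unknowns, and the remainder to
    per-locus amplitude moves (lognormal random walk)."""

    chains: int = 8
    iterations_per_chain: int = 5000
    burn_in_fraction: float = 0.20
    thin_n: int = 1
    preprocessing_steps: int = 10000
    phi_step: float = 0.35
    amp_step: float = 0.15
    p_genotype: float = 0.70
    p_phi: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations_per_chain < 1:
            raise ValueError("chains and iterations_per_chain must be >= 1")
        if not 0 < self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in (0, 1)")
        if self.thin_n < 1:
            raise ValueError("thin_n must be >= 1")


@dataclass
class MCMCState:
    """One point of the chain: genotypes per contributor per locus, the
    mixture-proportion simplex, and per-locus amplitudes."""

    genotypes: dict[str, tuple[Pair, ...]]
    phi: np.ndarray
    amplitude: dict[str, float]

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.phi)) - 1.0) > 1e-9 or np.any(self.phi <= 0):
            raise ValueError("phi must be a strictly positive simplex")


@dataclass
class WeightedGenotypes:
    """Posterior weights per locus plus mixture-ratio traces.

    ``locus_weights`` keys genotype sets by contributor *position* (knowns
    first); exchangeable unknown positions make it symmetric under their
    permutation.  ``canonical_weights`` keys the same mass with unknown
    positions reordered largest-contributor-first (by the mixture
    proportions at sampling time), which is what deconvolved-profile
    export reads.
    """

    n_contributors: int
    n_knowns: int
    locus_weights: dict[str, dict[SetKey, float]]
    canonical_weights: dict[str, dict[SetKey, float]]
    phi_traces: np.ndarray  # (chains, samples, N)
    n_samples: int

    @property
    def mean_phi(self) -> np.ndarray:
        return self.phi_traces.reshape(-1, self.n_contributors).mean(axis=0)

    def ratio_estimate(self) -> np.ndarray:
        """Posterior mean of the size-ordered mixture proportions
        (largest first) — the ratio-trace summary, invariant to the
        labeling of exchangeable unknown positions."""
        flat = self.phi_traces.reshape(-1, self.n_contributors)
        return np.sort(flat, axis=1)[:, ::-1].mean(axis=0)

    def marginal(self, locus: str, position: int) -> dict[Pair, float]:
        out: dict[Pair, float] = {}
        for key, w in self.locus_weights[locus].items():
            g = key[position]
            out[g] = out.get(g, 0.0) + w
        return out


# ---------------------------------------------------------------------------
# Genotype-set enumeration


def _pairs_over(alleles: list[str], allow_q: bool) -> list[Pair]:
    domain = sorted(alleles, key=allele_key) + ([Q_ALLELE] if allow_q else [])
    return list(itertools.combinations_with_replacement(domain, 2))


def enumerate_genotype_sets(
    observed_alleles: list[str],
    n_contributors: int,
    allow_q: bool = True,
    dropin_enabled: bool = False,
    stutter: bool = False,
    knowns: list[Pair] | None = None,
) -> list[SetKey]:
    """All ordered genotype-set assignments that explain the observed peaks.

    An observed allele is explained if some contributor carries it, if
    ``stutter`` is on and a carried allele sits one repeat above it, or if
    drop-in is enabled.  Known contributors occupy the leading positions
    with fixed genotypes.
    """
    if n_contributors <= 0:
        raise ValueError("number of contributors must be >= 1")
    knowns = knowns or []
    if len(knowns) > n_contributors:
        raise ValueError("more knowns than contributors")
    n_unknown = n_contributors - len(knowns)
    unknown_pairs = _pairs_over(list(observed_alleles), allow_q)
    out: list[SetKey] = []
    observed = list(observed_alleles)
    for combo in itertools.product(unknown_pairs, repeat=n_unknown):
        full: SetKey = tuple(knowns) + combo
        carried = {a for g in full for a in g if a != Q_ALLELE}
        ok = True
        if not dropin_enabled:
            for a in observed:
                if a in carried:
                    continue
                if stutter and any(stutter_target(b) == a for b in carried):
                    continue
                ok = False
                break
        if ok:
            out.append(full)
    return out


# ---------------------------------------------------------------------------
# Per-locus likelihood engine


class _LocusEngine:
    """Precomputed structures for fast per-locus likelihood evaluation."""

    def __init__(
        self,
        locus: str,
        heights: dict[str, float],
        known_genotypes: list[Pair],
        vf: float,
        xi: float,
        at: float,
        dropin_lambda: float,
        freq_col: dict[str, float] | None,
        min_freq: float,
    ):
        self.locus = locus
        self.vf = vf
        self.xi = xi
        self.at = at
        self.lam = dropin_lambda
        observed = sorted(heights, key=allele_key)
        known_alleles = [a for g in known_genotypes for a in g if a != Q_ALLELE]
        real = sorted(set(observed) | set(known_alleles), key=allele_key)
        positions = list(real)
        if xi > 0:
            for a in real:
                t = stutter_target(a)
                if t not in positions:
                    positions.append(t)
        positions = sorted(positions, key=allele_key) + [Q_ALLELE]
        self.positions = positions
        self.index = {a: i for i, a in enumerate(positions)}
        P = len(positions)
        self.obs_h = np.zeros(P)
        self.obs_mask = np.zeros(P, dtype=bool)
        for a, h in heights.items():
            self.obs_h[self.index[a]] = h
            self.obs_mask[self.index[a]] = True
        with np.errstate(divide="ignore"):
            self.log_h = np.where(self.obs_mask, np.log(np.maximum(self.obs_h, 1e-12)), 0.0)
        self.log_vf = math.log(vf)
        # stutter reallocation matrix: nu_out = M @ nu_in
        M = np.zeros((P, P))
        for a in positions:
            i = self.index[a]
            if a == Q_ALLELE or xi == 0:
                M[i, i] = 1.0
                continue
            M[i, i] = 1.0 - xi
            t = stutter_target(a)
            if t in self.index:
                M[self.index[t], i] += xi
            else:
                M[i, i] = 1.0  # target outside the modeled universe: keep signal
        self.M = M
        # drop-in log term per observed position
        self.const = -self.lam if self.lam > 0 else 0.0
        self.dropin_logterm = np.full(P, -np.inf)
        if self.lam > 0:
            scale = max(at, 1.0)
            for a, h in heights.items():
                p_a = min_freq
                if freq_col is not None:
                    p_a = freq_col.get(a, min_freq)
                self.dropin_logterm[self.index[a]] = (
                    math.log(self.lam * p_a) - math.log(scale) - max(h - at, 0.0) / scale
                )
        # genotype domain for unknown contributors: observed alleles + Q;
        # known genotypes may add pairs outside it (never proposed)
        self.genotypes: list[Pair] = _pairs_over(observed, allow_q=True)
        self.n_unknown_domain = len(self.genotypes)
        for g in known_genotypes:
            if g not in self.genotypes:
                self.genotypes.append(g)
        self.geno_index = {g: i for i, g in enumerate(self.genotypes)}
        counts = np.zeros((len(self.genotypes), P))
        for g, i in self.geno_index.items():
            for a in g:
                counts[i, self.index[a]] += 1.0
        self.counts = counts
        self.observed = observed

    def count_vector(self, genotype: Pair) -> np.ndarray:
        return self.counts[self.geno_index[genotype]]

    def loglik_nu(self, nu_base: np.ndarray) -> float:
        """Log-likelihood from pre-stutter expected heights."""
        nu = self.M @ nu_base
        ll = self.const
        pos = nu > 0
        m = self.obs_mask & pos
        if m.any():
            k = nu[m] / self.vf
            ll += float(
                np.sum((k - 1.0) * self.log_h[m] - self.obs_h[m] / self.vf
                       - k * self.log_vf - gammaln(k))
            )
        m2 = self.obs_mask & ~pos
        if m2.any():
            if self.lam <= 0:
                return -np.inf
            ll += float(np.sum(self.dropin_logterm[m2]))
        m3 = ~self.obs_mask & pos
        if m3.any():
            cdf = gammainc(nu[m3] / self.vf, self.at / self.vf)
            ll += float(np.sum(np.log(np.maximum(cdf, _LOG_FLOOR))))
        return ll

    def loglik(self, geno_idx: np.ndarray, phi: np.ndarray, amplitude: float) -> float:
        w = phi @ self.counts[geno_idx]
        return self.loglik_nu(amplitude * w)


def _build_engines(
    profile: EPGProfile,
    n_contributors: int,
    known_genotypes: list[GenotypeProfile],
    vm: VarianceModel,
    config: AnalysisConfig,
    freqs: AlleleFrequencyTable | None,
) -> dict[str, _LocusEngine]:
    if config.degradation_mode != "none":
        raise NotImplementedError("only the 'none' degradation mode is implemented")
    lam_total = config.drop_in_coefficient * config.dropin_base_rate
    loci = profile.loci
    engines = {}
    for locus in loci:
        knowns = []
        for kg in known_genotypes:
            pair = kg.get(locus)
            if pair is None:
                raise ValueError(f"known genotype missing locus {locus}")
            knowns.append(tuple(sorted(pair, key=allele_key)))
        freq_col = None
        if freqs is not None:
            freq_col = freqs.freqs.get(config.population, {}).get(locus)
        engines[locus] = _LocusEngine(
            locus,
            profile.heights(locus),
            knowns,
            vf=vm.vf,
            xi=vm.stutter_rate(locus),
            at=profile.at,
            dropin_lambda=lam_total / max(len(loci), 1),
            freq_col=freq_col,
            min_freq=freqs.min_freq if freqs is not None else 1e-3,
        )
    return engines


def state_loglikelihood(
    state: MCMCState,
    profile: EPGProfile,
    vm: VarianceModel,
    config: AnalysisConfig,
    freqs: AlleleFrequencyTable | None = None,
    known_genotypes: list[GenotypeProfile] | None = None,
) -> float:
    """Total log-likelihood of a full state against a profile."""
    n = len(state.phi)
    engines = _build_engines(profile, n, known_genotypes or [], vm, config, freqs)
    total = 0.0
    for locus, engine in engines.items():
        sets = state.genotypes[locus]
        for g in sets:
            if g not in engine.geno_index:
                engine.genotypes.append(g)
                engine.geno_index[g] = len(engine.genotypes) - 1
                row = np.zeros((1, len(engine.positions)))
                for a in g:
                    row[0, engine.index[a]] += 1.0
                engine.counts = np.vstack([engine.counts, row])
        idx = np.array([engine.geno_index[g] for g in sets])
        ll = engine.loglik(idx, state.phi, state.amplitude[locus])
        if not np.isfinite(ll):
            return -np.inf
        total += ll
    return total


# ---------------------------------------------------------------------------
# Feasibility and initialization


def _carriage_cover(
    engine: _LocusEngine,
    pre_carried: set[str],
    stutter_height_ratio: float | None,
) -> list[str]:
    """A carried-allele set under which every observed peak is explained.

    An observed allele needs no carriage when the allele one repeat above
    it is carried (its peak can then be backward stutter).  Alleles are
    processed in descending repeat order so parents settle first.  With
    ``stutter_height_ratio`` set, a peak taller than that fraction of its
    parent's peak is carried anyway (a height-guided, rather than
    minimal, cover).
    """
    observed = sorted(engine.observed, key=allele_key, reverse=True)
    carried = set(pre_carried)
    out: list[str] = []
    for a in observed:
        if a in carried:
            continue
        if engine.xi > 0:
            parent = next(
                (b for b in carried if stutter_target(b) == a), None
            )
            if parent is not None:
                if stutter_height_ratio is None:
                    continue
                h_a = engine.obs_h[engine.index[a]]
                h_p = engine.obs_h[engine.index[parent]] if parent in engine.index else 0.0
                if h_p > 0 and h_a < stutter_height_ratio * h_p:
                    continue
        carried.add(a)
        out.append(a)
    return out


def _feasibility_check(engine: _LocusEngine, n_contributors: int, dropin: bool) -> list[str]:
    """Minimal carried-allele set; raises if it cannot fit in N genotypes."""
    if dropin:
        return []
    required = _carriage_cover(engine, set(), stutter_height_ratio=None)
    if len(required) > 2 * n_contributors:
        raise ValueError(
            f"no admissible genotype set at locus {engine.locus}: "
            f"{len(required)} alleles require carriage but only "
            f"{2 * n_contributors} allele slots exist"
        )
    return required


def _initial_assignment(
    engine: _LocusEngine, n_unknown: int, known_pairs: list[Pair], dropin: bool
) -> list[int]:
    """Admissible, height-guided starting genotypes for unknown positions."""
    carried = {a for g in known_pairs for a in g if a != Q_ALLELE}
    todo = _carriage_cover(engine, carried, stutter_height_ratio=0.25)
    if len(todo) > 2 * n_unknown:
        todo = _carriage_cover(engine, carried, stutter_height_ratio=None)
    todo.sort(key=lambda a: -engine.obs_h[engine.index[a]])
    if len(todo) > 2 * n_unknown:
        raise ValueError(
            f"no admissible genotype set at locus {engine.locus}: known "
            f"contributors leave {len(todo)} required alleles for "
            f"{2 * n_unknown} unknown allele slots"
        )
    slots: list[list[str]] = [[] for _ in range(n_unknown)]
    for i, a in enumerate(todo):
        slots[i % n_unknown].append(a)
    idx = []
    for s in slots:
        if len(s) == 2:
            pair = (s[0], s[1])
        elif len(s) == 1:
            pair = (s[0], s[0])
        else:
            tall = max(
                engine.observed,
                key=lambda a: engine.obs_h[engine.index[a]],
                default=None,
            )
            pair = (tall, tall) if tall is not None else (Q_ALLELE, Q_ALLELE)
        idx.append(engine.geno_index[tuple(sorted(pair, key=allele_key))])
    return idx


# ---------------------------------------------------------------------------
# The sampler


def _phi_to_z(phi: np.ndarray) -> np.ndarray:
    return np.log(phi[:-1]) - math.log(phi[-1])


def _z_to_phi(z: np.ndarray) -> np.ndarray:
    e = np.exp(np.concatenate([z, [0.0]]) - max(float(np.max(z)), 0.0))
    return e / e.sum()


def _preprocess_seed(
    engines: dict[str, _LocusEngine],
    loci: list[str],
    N: int,
    n_known: int,
    n_unknown: int,
    known_idx: dict[str, list[int]],
    dropin: bool,
    settings: MCMCSettings,
    profile: EPGProfile,
    rng: np.random.Generator,
) -> tuple[dict, np.ndarray, dict, dict, int]:
    """Structured likelihood-ascent seed, computed once per analysis.

    Tries candidate mixture proportions, each with a height-matched
    genotype assignment polished by greedy coordinate sweeps; the winner
    is refined by alternating sweeps, amplitude rescaling and a
    nonnegative least-squares refit of phi.
    """
    amp = {l: max(float(engines[l].obs_h.sum()) / 2.0, profile.at) for l in loci}
    cur_idx = {
        l: list(known_idx[l])
        + _initial_assignment(
            engines[l], n_unknown,
            [engines[l].genotypes[i] for i in known_idx[l]], dropin,
        )
        for l in loci
    }
    phi = np.full(N, 1.0 / N)
    ll_locus = {
        l: engines[l].loglik(np.asarray(cur_idx[l]), phi, amp[l]) for l in loci
    }
    steps_used = 0
    budget = settings.preprocessing_steps

    def height_matched(phi_c: np.ndarray) -> dict:
        # per locus, assign each required allele to the unknown whose
        # expected height (phi_k * A_l) best matches the peak, then
        # resolve hom/het/Q per slot
        out = {}
        for l in loci:
            e = engines[l]
            known_pairs = [e.genotypes[i] for i in known_idx[l]]
            pre = {a for g in known_pairs for a in g if a != Q_ALLELE}
            req = _carriage_cover(e, pre, stutter_height_ratio=0.25)
            if len(req) > 2 * n_unknown:
                req = _carriage_cover(e, pre, stutter_height_ratio=None)
            req.sort(key=lambda a: -e.obs_h[e.index[a]])
            expected = np.maximum(phi_c[n_known:] * amp[l], 1e-6)
            slots: list[list[str]] = [[] for _ in range(n_unknown)]
            for a in req:
                h = e.obs_h[e.index[a]]
                costs = [
                    abs(math.log(max(h, 1e-6)) - math.log(expected[k]))
                    if len(slots[k]) < 2 else math.inf
                    for k in range(n_unknown)
                ]
                slots[int(np.argmin(costs))].append(a)
            idx_l = list(known_idx[l])
            for k, s in enumerate(slots):
                if len(s) == 2:
                    pair = tuple(sorted(s, key=allele_key))
                elif len(s) == 1:
                    h = e.obs_h[e.index[s[0]]]
                    hom = abs(
                        math.log(max(h, 1e-6)) - math.log(2 * expected[k])
                    ) < abs(math.log(max(h, 1e-6)) - math.log(expected[k]))
                    pair = (s[0], s[0]) if hom else tuple(
                        sorted((s[0], Q_ALLELE), key=allele_key)
                    )
                else:
                    pair = (Q_ALLELE, Q_ALLELE)
                idx_l.append(e.geno_index[pair])
            out[l] = idx_l
        return out

    def greedy_sweep(phi_c: np.ndarray, idx: dict, amps: dict, passes: int = 2) -> dict:
        nonlocal steps_used
        lls = {}
        for l in loci:
            e = engines[l]
            cur = list(idx[l])
            ll_best = e.loglik(np.asarray(cur), phi_c, amps[l])
            for _ in range(passes):
                for k in range(n_known, N):
                    trial = list(cur)
                    for g in range(e.n_unknown_domain):
                        if g == cur[k]:
                            continue
                        trial[k] = g
                        ll_new = e.loglik(np.asarray(trial), phi_c, amps[l])
                        steps_used += 1
                        if ll_new > ll_best:
                            ll_best, cur = ll_new, list(trial)
                    trial = list(cur)
            idx[l] = cur
            lls[l] = ll_best
        return lls

    if n_unknown > 0 and N > 1 and budget > 0:
        candidates = [phi]
        for draw in rng.dirichlet(np.ones(N), size=7):
            candidates.append(np.maximum(draw, 1e-3) / np.maximum(draw, 1e-3).sum())
        if n_unknown == N:  # ordered spread candidates
            for major in (0.75, 0.91):
                rest = (1.0 - major) / (N - 1)
                base = np.full(N, rest)
                base[0] = major
                candidates.append(base.copy())
                candidates.append(base[::-1].copy())
        best = None
        for cand in candidates:
            cand = np.asarray(cand, dtype=float)
            idx_c = height_matched(cand)
            lls = greedy_sweep(cand, idx_c, amp, passes=1)
            total = sum(lls.values())
            if best is None or total > best[0]:
                best = (total, cand, idx_c, lls)
        _, phi, cur_idx, ll_locus = best
        phi = np.asarray(phi, dtype=float)

    def total_ll() -> float:
        return float(sum(ll_locus.values()))

    for _ in range(3):
        if steps_used >= budget:
            break
        if n_unknown > 0:
            ll_locus = greedy_sweep(phi, cur_idx, amp, passes=1)
        # amplitude: match total expected to total observed signal
        for l in loci:
            e = engines[l]
            nu = e.M @ (phi @ e.counts[np.asarray(cur_idx[l])]) * amp[l]
            expected_obs = float(nu[e.obs_mask].sum())
            observed = float(e.obs_h.sum())
            if expected_obs > 0 and observed > 0:
                a_new = float(np.clip(amp[l] * observed / expected_obs, _A_MIN, _A_MAX))
                ll_new = e.loglik(np.asarray(cur_idx[l]), phi, a_new)
                steps_used += 1
                if ll_new >= ll_locus[l]:
                    amp[l], ll_locus[l] = a_new, ll_new
        # phi: nonnegative LS on observed peak heights given genotypes
        if N > 1:
            rows, y = [], []
            for l in loci:
                e = engines[l]
                design = amp[l] * (e.M @ e.counts[np.asarray(cur_idx[l])].T)
                rows.append(design[e.obs_mask])
                y.append(e.obs_h[e.obs_mask])
            X = np.vstack(rows)
            h = np.concatenate(y)
            if len(h) >= N:
                sol, _ = _nnls(X, h)
                if sol.sum() > 0:
                    phi_new = np.maximum(sol / sol.sum(), 1e-3)
                    phi_new = phi_new / phi_new.sum()
                    ll_new = {
                        l: engines[l].loglik(np.asarray(cur_idx[l]), phi_new, amp[l])
                        for l in loci
                    }
                    steps_used += len(loci)
                    if sum(ll_new.values()) >= total_ll():
                        phi, ll_locus = phi_new, ll_new
    return cur_idx, phi, amp, ll_locus, steps_used


def run_mcmc(
    profile: EPGProfile,
    n_contributors: int,
    knowns: list[GenotypeProfile],
    vm: VarianceModel,
    settings: MCMCSettings,
    config: AnalysisConfig,
    freqs: AlleleFrequencyTable | None = None,
) -> WeightedGenotypes:
    """Metropolis-Hastings deconvolution into weighted genotype sets.

    Known contributors occupy the leading positions and are never
    proposed.  Each chain is seeded by greedy likelihood-ascent
    preprocessing, then run for ``iterations_per_chain`` sweeps; the first
    ``burn_in_fraction`` is discarded and post-burn-in samples are pooled
    across chains (thinned by ``thin_n``) into per-locus weights.
    Deterministic under ``settings.seed``.
    """
    N = n_contributors
    if N < 1 or len(knowns) > N:
        raise ValueError("need n_contributors >= 1 and len(knowns) <= n_contributors")
    n_known = len(knowns)
    n_unknown = N - n_known
    dropin = config.drop_in_coefficient * config.dropin_base_rate > 0
    engines = _build_engines(profile, N, knowns, vm, config, freqs)
    loci = list(engines)
    for engine in engines.values():
        _feasibility_check(engine, N, dropin)

    iters = settings.iterations_per_chain
    burn = int(round(settings.burn_in_fraction * iters))
    n_rec = len(range(burn, iters, settings.thin_n))
    phi_traces = np.zeros((settings.chains, n_rec, N))
    raw_counts_all: dict[str, dict[SetKey, float]] = {l: {} for l in loci}
    canon_counts_all: dict[str, dict[SetKey, float]] = {l: {} for l in loci}

    ss = np.random.SeedSequence(settings.seed)
    chain_seeds = ss.spawn(settings.chains)
    known_idx = {
        l: [engines[l].geno_index[tuple(sorted(kg[l], key=allele_key))] for kg in knowns]
        for l in loci
    }

    # Rao-Blackwellized recording: where the admissible-set space is small,
    # the conditional set posterior given (phi, A_l) is computed exactly at
    # regular intervals instead of counting visited point masses — the
    # genotype dimension is integrated out, sharply reducing Monte Carlo
    # error on the weights
    rb_every = 20
    rb_structs: dict[str, tuple[list[SetKey], np.ndarray]] = {}
    for l in loci:
        e = engines[l]
        if n_unknown >= 1 and e.n_unknown_domain**n_unknown <= 30_000:
            known_pairs = [e.genotypes[i] for i in known_idx[l]]
            sets = enumerate_genotype_sets(
                e.observed, N, allow_q=True, dropin_enabled=dropin,
                stutter=e.xi > 0, knowns=known_pairs,
            )
            if 0 < len(sets) <= 3000:
                arr = np.zeros((len(sets), N, len(e.positions)))
                for j, s in enumerate(sets):
                    for k, g in enumerate(s):
                        for a in g:
                            arr[j, k, e.index[a]] += 1.0
                rb_structs[l] = (sets, arr)
    rb_acc: dict[str, np.ndarray] = {
        l: np.zeros(len(sets)) for l, (sets, _) in rb_structs.items()
    }
    rb_n = 0

    # --- preprocessing (shared across chains): structured likelihood
    # ascent.  The mixture proportion is strongly coupled to the genotype
    # assignment, so a set of candidate proportions is tried first, each
    # with its own greedy genotype sweep; the best joint seed is refined by
    # further sweeps, amplitude rescaling and a nonnegative least-squares
    # refit of phi.  Chains then diversify with randomized greedy polish.
    seed_rng = np.random.default_rng(ss.spawn(1)[0])
    seed_state = _preprocess_seed(
        engines, loci, N, n_known, n_unknown, known_idx, dropin,
        settings, profile, seed_rng,
    )
    polish_budget = max(
        0, (settings.preprocessing_steps - seed_state[4]) // settings.chains
    )

    for c in range(settings.chains):
        rng = np.random.default_rng(chain_seeds[c])
        cur_idx = {l: list(seed_state[0][l]) for l in loci}
        phi = seed_state[1].copy()
        amp = dict(seed_state[2])
        ll_locus = dict(seed_state[3])

        def total_ll() -> float:
            return float(sum(ll_locus.values()))

        for _ in range(polish_budget):
            u = rng.random()
            if u < 0.8 and n_unknown > 0:
                l = loci[int(rng.integers(len(loci)))]
                k = n_known + int(rng.integers(n_unknown))
                g_new = int(rng.integers(engines[l].n_unknown_domain))
                if g_new == cur_idx[l][k]:
                    continue
                trial = list(cur_idx[l])
                trial[k] = g_new
                ll_new = engines[l].loglik(np.asarray(trial), phi, amp[l])
                if ll_new >= ll_locus[l]:
                    cur_idx[l] = trial
                    ll_locus[l] = ll_new
            elif u < 0.9 and N > 1:
                z = _phi_to_z(phi) + rng.normal(0, settings.phi_step, N - 1)
                phi_new = _z_to_phi(z)
                ll_new = {
                    l: engines[l].loglik(np.asarray(cur_idx[l]), phi_new, amp[l])
                    for l in loci
                }
                if sum(ll_new.values()) >= total_ll():
                    phi, ll_locus = phi_new, ll_new
            else:
                l = loci[int(rng.integers(len(loci)))]
                a_new = amp[l] * math.exp(rng.normal(0, settings.amp_step))
                if not _A_MIN <= a_new <= _A_MAX:
                    continue
                ll_new = engines[l].loglik(np.asarray(cur_idx[l]), phi, a_new)
                if ll_new >= ll_locus[l]:
                    amp[l], ll_locus[l] = a_new, ll_new

        # --- Metropolis-Hastings
        counts: dict[str, dict[SetKey, float]] = {l: {} for l in loci}
        canon_counts: dict[str, dict[SetKey, float]] = {l: {} for l in loci}
        last_change = {l: 0 for l in loci}
        rec_i = 0
        p_gen = settings.p_genotype if n_unknown > 0 else 0.0
        p_phi = settings.p_phi if N > 1 else 0.0
        p_swap = 0.02 if n_unknown >= 2 else 0.0
        # joint two-contributor moves at one locus hop between genotype
        # configurations that single-contributor moves cannot reach
        p_pair = 0.15 if n_unknown >= 2 else 0.0
        if p_pair:
            p_gen = max(p_gen - p_pair, 0.3)

        def unknown_order() -> tuple[int, ...]:
            # unknown positions sorted by current phi, largest first
            return tuple(
                sorted(range(n_known, N), key=lambda k: -phi[k])
            )

        cur_order = unknown_order()

        def flush(l: str, upto: int) -> None:
            lo = max(last_change[l], burn)
            if upto <= lo:
                return
            if settings.thin_n == 1:
                n_hits = upto - lo
            else:
                n_hits = sum(
                    1 for i in range(lo, upto) if (i - burn) % settings.thin_n == 0
                )
            if n_hits:
                genos = engines[l].genotypes
                key = tuple(genos[i] for i in cur_idx[l])
                counts[l][key] = counts[l].get(key, 0.0) + n_hits
                canon = key[:n_known] + tuple(key[k] for k in cur_order)
                canon_counts[l][canon] = canon_counts[l].get(canon, 0.0) + n_hits

        def flush_all(upto: int) -> None:
            for l in loci:
                flush(l, upto)
                last_change[l] = upto

        for it in range(iters):
            u = rng.random()
            if u < p_gen:
                l = loci[int(rng.integers(len(loci)))]
                k = n_known + int(rng.integers(n_unknown))
                g_new = int(rng.integers(engines[l].n_unknown_domain))
                if g_new != cur_idx[l][k]:
                    trial = list(cur_idx[l])
                    trial[k] = g_new
                    ll_new = engines[l].loglik(np.asarray(trial), phi, amp[l])
                    if math.log(rng.random() + 1e-300) < ll_new - ll_locus[l]:
                        flush(l, it)
                        last_change[l] = it
                        cur_idx[l] = trial
                        ll_locus[l] = ll_new
            elif u < p_gen + p_pair:
                l = loci[int(rng.integers(len(loci)))]
                k1, k2 = (
                    n_known + int(x)
                    for x in rng.choice(n_unknown, size=2, replace=False)
                )
                trial = list(cur_idx[l])
                trial[k1] = int(rng.integers(engines[l].n_unknown_domain))
                trial[k2] = int(rng.integers(engines[l].n_unknown_domain))
                if trial != cur_idx[l]:
                    ll_new = engines[l].loglik(np.asarray(trial), phi, amp[l])
                    if math.log(rng.random() + 1e-300) < ll_new - ll_locus[l]:
                        flush(l, it)
                        last_change[l] = it
                        cur_idx[l] = trial
                        ll_locus[l] = ll_new
            elif u < p_gen + p_pair + p_phi:
                z = _phi_to_z(phi) + rng.normal(0, settings.phi_step, N - 1)
                phi_new = _z_to_phi(z)
                if np.all(phi_new > 1e-12):
                    ll_new = {
                        l: engines[l].loglik(np.asarray(cur_idx[l]), phi_new, amp[l])
                        for l in loci
                    }
                    # uniform simplex prior; Jacobian of the ALR transform
                    log_ratio = (
                        sum(ll_new.values()) - total_ll()
                        + float(np.sum(np.log(phi_new)) - np.sum(np.log(phi)))
                    )
                    if math.log(rng.random() + 1e-300) < log_ratio:
                        phi = phi_new
                        ll_locus = ll_new
                        new_order = unknown_order()
                        if new_order != cur_order:
                            flush_all(it)
                            cur_order = new_order
            elif u < p_gen + p_pair + p_phi + p_swap:
                # relabeling swap of two unknown positions: likelihood-
                # invariant, always accepted; mixes exchangeable labels
                i_pos, j_pos = (
                    n_known + int(x)
                    for x in rng.choice(n_unknown, size=2, replace=False)
                )
                flush_all(it)
                phi = phi.copy()
                phi[i_pos], phi[j_pos] = phi[j_pos], phi[i_pos]
                for l in loci:
                    cur_idx[l][i_pos], cur_idx[l][j_pos] = (
                        cur_idx[l][j_pos],
                        cur_idx[l][i_pos],
                    )
                cur_order = unknown_order()
            else:
                l = loci[int(rng.integers(len(loci)))]
                a_new = amp[l] * math.exp(rng.normal(0, settings.amp_step))
                if _A_MIN <= a_new <= _A_MAX:
                    ll_new = engines[l].loglik(np.asarray(cur_idx[l]), phi, a_new)
                    if math.log(rng.random() + 1e-300) < ll_new - ll_locus[l]:
                        amp[l], ll_locus[l] = a_new, ll_new
            if it >= burn and (it - burn) % settings.thin_n == 0:
                phi_traces[c, rec_i] = phi
                rec_i += 1
            if rb_structs and it >= burn and (it - burn) % rb_every == 0:
                for l, (_, arr) in rb_structs.items():
                    rb_acc[l] += _rb_conditional(engines[l], arr, phi, amp[l])
                rb_n += 1
        flush_all(iters)
        for l in loci:
            for k, v in counts[l].items():
                raw_counts_all[l][k] = raw_counts_all[l].get(k, 0.0) + v
            for k, v in canon_counts[l].items():
                canon_counts_all[l][k] = canon_counts_all[l].get(k, 0.0) + v

    pooled = _normalize_weights(raw_counts_all)
    for l, (sets, _) in rb_structs.items():
        if rb_n > 0 and rb_acc[l].sum() > 0:
            w = rb_acc[l] / rb_acc[l].sum()
            pooled[l] = {
                s: float(wj) for s, wj in zip(sets, w) if wj > 1e-12
            }
    if 2 <= n_unknown <= 3:
        pooled = _symmetrize_unknowns(pooled, n_known, N)
    canonical = _normalize_weights(canon_counts_all)
    return WeightedGenotypes(
        n_contributors=N,
        n_knowns=n_known,
        locus_weights=pooled,
        canonical_weights=canonical,
        phi_traces=phi_traces,
        n_samples=n_rec * settings.chains,
    )


def _nnls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    from scipy.optimize import nnls as scipy_nnls

    return scipy_nnls(X, y)


def _rb_conditional(
    e: _LocusEngine, arr: np.ndarray, phi: np.ndarray, amplitude: float
) -> np.ndarray:
    """Exact conditional posterior over admissible sets given (phi, A_l)."""
    w = np.tensordot(phi, arr, axes=(0, 1))  # (n_sets, P)
    nu = (w @ e.M.T) * amplitude
    pos = nu > 0
    k = np.where(pos, nu / e.vf, 1.0)
    obs = e.obs_mask[None, :]
    ll = np.where(
        obs & pos,
        (k - 1.0) * e.log_h[None, :] - e.obs_h[None, :] / e.vf
        - k * e.log_vf - gammaln(k),
        0.0,
    ).sum(axis=1)
    bad = (obs & ~pos).any(axis=1)
    if bad.any():
        if e.lam > 0:
            ll += np.where(obs & ~pos, e.dropin_logterm[None, :], 0.0).sum(axis=1)
        else:
            ll[bad] = -np.inf
    m3 = ~obs & pos
    cdf = np.log(np.maximum(gammainc(k, e.at / e.vf), _LOG_FLOOR))
    ll += np.where(m3, cdf, 0.0).sum(axis=1)
    mx = ll.max()
    if not np.isfinite(mx):
        return np.zeros(len(ll))
    out = np.exp(ll - mx)
    return out / out.sum()


def _normalize_weights(
    counts: dict[str, dict[SetKey, float]]
) -> dict[str, dict[SetKey, float]]:
    out = {}
    for l, by_key in counts.items():
        tot = sum(by_key.values())
        if tot <= 0:
            raise RuntimeError(f"no post-burn-in samples recorded at locus {l}")
        out[l] = {k: v / tot for k, v in by_key.items()}
    return out


def _symmetrize_unknowns(
    weights: dict[str, dict[SetKey, float]], n_known: int, n: int
) -> dict[str, dict[SetKey, float]]:
    """Average weights over permutations of the exchangeable unknown
    positions (an exact symmetry of the likelihood), removing residual
    labeling noise before comparison or LR use."""
    perms = list(itertools.permutations(range(n_known, n)))
    out: dict[str, dict[SetKey, float]] = {}
    for l, by_key in weights.items():
        sym: dict[SetKey, float] = {}
        for key, w in by_key.items():
            share = w / len(perms)
            for perm in perms:
                new = key[:n_known] + tuple(key[k] for k in perm)
                sym[new] = sym.get(new, 0.0) + share
        out[l] = sym
    return out


# ---------------------------------------------------------------------------
# Exhaustive oracle


@dataclass
class OracleGrid:
    """Discretization of the nuisance parameters for exact summation."""

    phi_step: float = 0.02
    a_points: int = 33
    a_span: float = 4.0  # amplitude grid covers [A_hat/span, A_hat*span]
    max_sets: int = 200_000


def _simplex_grid(n: int, step: float) -> np.ndarray:
    if n == 1:
        return np.array([[1.0]])
    ticks = np.arange(step / 2, 1.0, step)
    pts = []
    for combo in itertools.product(ticks, repeat=n - 1):
        s = sum(combo)
        if s < 1.0 - step / 4:
            pts.append(list(combo) + [1.0 - s])
    return np.array(pts)


def oracle_posterior(
    profile: EPGProfile,
    n_contributors: int,
    knowns: list[GenotypeProfile],
    vm: VarianceModel,
    config: AnalysisConfig,
    grid: OracleGrid | None = None,
    freqs: AlleleFrequencyTable | None = None,
) -> WeightedGenotypes:
    """Exact posterior weights by exhaustive enumeration on a (phi, A) grid.

    Uniform prior over admissible genotype sets, uniform over the phi grid,
    log-uniform over the per-locus amplitude grid — the same priors the
    MCMC sampler targets.  Refuses instances that are too large.
    """
    grid = grid or OracleGrid()
    if n_contributors > 3:
        raise ValueError("oracle limited to <= 3 contributors")
    N = n_contributors
    dropin = config.drop_in_coefficient * config.dropin_base_rate > 0
    engines = _build_engines(profile, N, knowns, vm, config, freqs)
    loci = list(engines)
    sets_per_locus: dict[str, list[SetKey]] = {}
    total_sets = 0
    for l, engine in engines.items():
        known_pairs = [
            tuple(sorted(kg[l], key=allele_key)) for kg in knowns
        ]
        sets = enumerate_genotype_sets(
            engine.observed, N, allow_q=True, dropin_enabled=dropin,
            stutter=engine.xi > 0, knowns=known_pairs,
        )
        if not sets:
            raise ValueError(f"no admissible genotype set at locus {l}")
        sets_per_locus[l] = sets
        total_sets += len(sets)
    phi_grid = _simplex_grid(N, grid.phi_step)
    if total_sets * len(phi_grid) * grid.a_points > grid.max_sets * 100:
        raise ValueError(
            f"oracle instance too large: {total_sets} sets x {len(phi_grid)} "
            f"phi points x {grid.a_points} amplitude points"
        )

    # logL[l][j, p] = log sum over the A grid of the likelihood of set j at phi p
    log_l: dict[str, np.ndarray] = {}
    for l, engine in engines.items():
        total_h = float(engine.obs_h.sum())
        a_hat = max(total_h / 2.0, profile.at)
        a_grid = np.exp(
            np.linspace(math.log(a_hat / grid.a_span), math.log(a_hat * grid.a_span), grid.a_points)
        )
        sets = sets_per_locus[l]
        arr = np.full((len(sets), len(phi_grid)), -np.inf)
        for j, s in enumerate(sets):
            for g in s:
                if g not in engine.geno_index:
                    engine.genotypes.append(g)
                    engine.geno_index[g] = len(engine.genotypes) - 1
                    row = np.zeros((1, len(engine.positions)))
                    for a in g:
                        row[0, engine.index[a]] += 1.0
                    engine.counts = np.vstack([engine.counts, row])
            idx = np.asarray([engine.geno_index[g] for g in s])
            for p, phi in enumerate(phi_grid):
                vals = np.array(
                    [engine.loglik(idx, phi, a) for a in a_grid]
                )
                mx = vals.max()
                if np.isfinite(mx):
                    arr[j, p] = mx + math.log(np.sum(np.exp(vals - mx)))
        log_l[l] = arr

    # per-locus totals at each phi, then leave-one-out products
    log_t = {l: _logsumexp_rows(log_l[l]) for l in loci}  # (n_phi,)
    log_all = np.sum([log_t[l] for l in loci], axis=0)
    weights: dict[str, dict[SetKey, float]] = {}
    log_z = _logsumexp(log_all)
    for l in loci:
        rest = log_all - log_t[l]
        logw = _logsumexp_cols(log_l[l] + rest[None, :])
        w = np.exp(logw - _logsumexp(logw))
        weights[l] = {s: float(wj) for s, wj in zip(sets_per_locus[l], w)}
    post_phi = np.exp(log_all - log_z)
    mean_phi = (post_phi[:, None] * phi_grid).sum(axis=0)
    return WeightedGenotypes(
        n_contributors=N,
        n_knowns=len(knowns),
        locus_weights=weights,
        canonical_weights=weights,
        phi_traces=mean_phi[None, None, :].copy(),
        n_samples=0,
    )


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.sum(np.exp(x - m))))


def _logsumexp_rows(x: np.ndarray) -> np.ndarray:
    m = np.max(x, axis=0)
    out = np.full(x.shape[1], -np.inf)
    ok = np.isfinite(m)
    out[ok] = m[ok] + np.log(np.sum(np.exp(x[:, ok] - m[ok]), axis=0))
    return out


def _logsumexp_cols(x: np.ndarray) -> np.ndarray:
    m = np.max(x, axis=1)
    out = np.full(x.shape[0], -np.inf)
    ok = np.isfinite(m)
    out[ok] = m[ok] + np.log(np.sum(np.exp(x[ok] - m[ok, None]), axis=1))
    return out


def total_variation(
    w1: dict[SetKey, float], w2: dict[SetKey, float]
) -> float:
    keys = set(w1) | set(w2)
    return 0.5 * sum(abs(w1.get(k, 0.0) - w2.get(k, 0.0)) for k in keys)


# ---------------------------------------------------------------------------
# Diagnostics and export


def gelman_rubin(phi_traces: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per mixture-proportion coordinate.

    ``phi_traces`` has shape (chains, samples, dims).  Degenerate
    zero-variance coordinates report R-hat = 1.
    """
    m, n, d = phi_traces.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains with >= 10 samples each")
    rhat = np.ones(d)
    for j in range(d):
        x = phi_traces[:, :, j]
        w = x.var(axis=1, ddof=1).mean()
        b = n * x.mean(axis=1).var(ddof=1)
        if w <= 1e-300:
            rhat[j] = 1.0
            continue
        v_hat = (n - 1) / n * w + b / n
        rhat[j] = max(math.sqrt(v_hat / w), 1.0)  # sampling noise can push below 1
    return rhat


def export_deconvolved_profiles(
    wg: WeightedGenotypes, min_weight: float
) -> list[dict[str, Pair | None]]:
    """Modal genotype per unknown contributor per locus.

    A locus is reported only when the modal genotype's marginal weight
    reaches ``min_weight``; otherwise it is left inconclusive (None).
    Contributors are numbered largest-first (the canonical ordering of
    the unknown positions by mixture proportion at sampling time).
    """
    if not 0 < min_weight <= 1:
        raise ValueError("min_weight must be in (0, 1]")
    N, K = wg.n_contributors, wg.n_knowns
    out: list[dict[str, Pair | None]] = []
    for rank in range(N - K):
        pos = K + rank
        profile: dict[str, Pair | None] = {}
        for locus, by_key in wg.canonical_weights.items():
            marg: dict[Pair, float] = {}
            for key, w in by_key.items():
                marg[key[pos]] = marg.get(key[pos], 0.0) + w
            if not marg:
                profile[locus] = None
                continue
            best, w_best = max(marg.items(), key=lambda kv: kv[1])
            profile[locus] = best if w_best >= min_weight else None
        out.append(profile)
    return out
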