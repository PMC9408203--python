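"""Peak-height variance factor and stutter-rate estimation.

The variance factor VF is the Gamma dispersion of peak heights — the
variance-to-mean ratio of an allele position's height across replicate
amplifications — and is the same parameter the MCMC likelihood uses, so a
protocol dataset of replicated single-source profiles calibrates the
engine directly.  Backward stutter rates are estimated per locus from the
stutter-to-total signal ratio at positions one repeat below an allele that
carries no true allele.  Stutter observations censored by the analytical
threshold are excluded rather than modeled as censored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import sqrt as math_sqrt
from pathlib import Path

import numpy as np
import pandas as pd

from ._alleles import stutter_target
from .panel_io import EPGProfile, apply_analytical_threshold

GenotypeProfile = dict[str, tuple[str, str]]


@dataclass
class VarianceModel:
    """Fitted dispersion, per-locus stutter, and heterozygote balance."""

    vf: float
    stutter: dict[str, float]
    stutter_se: dict[str, float] = field(default_factory=dict)
    stutter_n: dict[str, int] = field(default_factory=dict)
    het_balance: pd.DataFrame | None = None
    n_positions: int = 0

    def __post_init__(self) -> None:
        if self.vf < 0:
            raise ValueError("VF must be >= 0")
        for locus, xi in self.stutter.items():
            if not 0 <= xi < 1:
                raise ValueError(f"{locus}: stutter rate must be in [0, 1)")

    def stutter_rate(self, locus: str) -> float:
        return self.stutter.get(locus, 0.0)

    @property
    def mean_stutter(self) -> float:
        return float(np.mean(list(self.stutter.values()))) if self.stutter else 0.0

    def to_json(self, path: str | Path) -> None:
        data = {
            "vf": self.vf,
            "stutter": self.stutter,
            "stutter_se": self.stutter_se,
            "stutter_n": self.stutter_n,
            "n_positions": self.n_positions,
        }
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "VarianceModel":
        data = json.loads(Path(path).read_text())
        return cls(
            vf=data["vf"],
            stutter=data["stutter"],
            stutter_se=data.get("stutter_se", {}),
            stutter_n={k: int(v) for k, v in data.get("stutter_n", {}).items()},
            n_positions=int(data.get("n_positions", 0)),
        )


def _replicate_group(sample_id: str) -> str:
    """Replicates share a sample id up to a trailing ``_r<k>`` tag."""
    stem, sep, tail = sample_id.rpartition("_r")
    return stem if sep and tail.isdigit() else sample_id


def _donor_of(sample_id: str, genotypes: dict[str, GenotypeProfile]) -> str:
    for donor in genotypes:
        if sample_id == donor or sample_id.startswith(donor + "_"):
            return donor
    raise ValueError(f"no known genotype matches sample '{sample_id}'")


def fit_variance_model(
    protocol: list[EPGProfile],
    known_genotypes: dict[str, GenotypeProfile],
    at: float,
) -> VarianceModel:
    """Fit VF, per-locus stutter and heterozygote balance.

    ``protocol`` must hold single-source replicate groups (>= 2 replicates
    each, matched to ``known_genotypes`` by sample-id prefix).  VF is the
    method-of-moments mean of Var(h)/Mean(h) over allele positions seen in
    every replicate of a group; stutter is the per-locus mean of
    ``s / (s + p)`` over isolated stutter/parent peak pairs, which targets
    the reallocated signal fraction directly.
    """
    if not protocol:
        raise ValueError("empty protocol dataset")
    profiles = [apply_analytical_threshold(p, at) for p in protocol]
    groups: dict[str, list[EPGProfile]] = {}
    for p in profiles:
        groups.setdefault(_replicate_group(p.sample_id), []).append(p)
    for name, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"replicate group '{name}' has fewer than 2 replicates")

    ratios: list[float] = []
    stutter_obs: dict[str, list] = {}  # locus -> [sum stutter, sum total, n pairs]
    hb_rows: list[dict] = []
    for name, members in groups.items():
        donor = _donor_of(name, known_genotypes)
        genotype = known_genotypes[donor]
        loci = members[0].loci
        for locus in loci:
            true_alleles = set(genotype.get(locus, ()))
            # VF: allele positions present in every replicate
            heights_by_rep = [m.heights(locus) for m in members]
            common = set.intersection(*(set(h) for h in heights_by_rep)) if heights_by_rep else set()
            for allele in common:
                h = np.array([rep[allele] for rep in heights_by_rep])
                mean = h.mean()
                if mean > 0:
                    ratios.append(h.var(ddof=1) / mean)
            # stutter: pooled signal ratio per isolated parent/stutter pair;
            # a censored stutter peak contributes zero to the numerator but
            # its parent still counts, limiting the upward censoring bias
            for rep in heights_by_rep:
                for parent in true_alleles:
                    target = stutter_target(parent)
                    if target in true_alleles:
                        continue  # stutter position confounded by a true allele
                    if parent in rep:
                        s = rep.get(target, 0.0)
                        num, den, n_obs = stutter_obs.setdefault(locus, [0.0, 0.0, 0])
                        stutter_obs[locus] = [
                            num + s, den + s + rep[parent], n_obs + 1
                        ]
            # heterozygote balance: log peak ratio vs expected height
            if len(true_alleles) == 2:
                a, b = sorted(true_alleles)
                for rep in heights_by_rep:
                    if a in rep and b in rep:
                        hb_rows.append(
                            {"group": name, "locus": locus,
                             "expected_height": 0.5 * (rep[a] + rep[b]),
                             "log_ratio": float(np.log(rep[a] / rep[b]))}
                        )

    if not ratios:
        raise ValueError("no allele positions usable for VF estimation")
    stutter = {
        l: (num / den if den > 0 else 0.0) for l, (num, den, _) in stutter_obs.items()
    }
    stutter_se = {
        # binomial-style scale of the pooled ratio; diagnostic only
        l: (math_sqrt(x * (1 - x) / n) if n > 0 else 0.0)
        for (l, x), n in zip(stutter.items(), (v[2] for v in stutter_obs.values()))
    }
    return VarianceModel(
        vf=float(np.mean(ratios)),
        stutter=stutter,
        stutter_se=stutter_se,
        stutter_n={l: int(v[2]) for l, v in stutter_obs.items()},
        het_balance=pd.DataFrame(hb_rows) if hb_rows else None,
        n_positions=len(ratios),
    )


def compare_variance_by_threshold(
    protocol: list[EPGProfile],
    known_genotypes: dict[str, GenotypeProfile],
    at_list: list[float],
) -> pd.DataFrame:
    """Fit VF at each analytical threshold and report the relative spread."""
    if len(at_list) < 2:
        raise ValueError("need at least 2 thresholds to compare")
    rows = []
    for at in at_list:
        vm = fit_variance_model(protocol, known_genotypes, at)
        rows.append({"AT": at, "vf": vm.vf, "n_positions": vm.n_positions})
    df = pd.DataFrame(rows)
    base = df["vf"].iloc[0]
    df["relative_difference"] = (df["vf"] - base).abs() / base
    return df
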