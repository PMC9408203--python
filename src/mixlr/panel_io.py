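"""STR panel, allele-frequency, peak-table and configuration data model.

The engine starts from *called* peak tables — tab-delimited exports of the
kind genotyping software produces after size/allele calling — not raw
capillary signal.  This module defines the panel description, the
electropherogram (EPG) container, the per-population allele-frequency
table with minimum-frequency rebasing, and the analysis configuration,
together with plain-text readers and writers for each.

Peak-table dialect: one row per peak, header
``SampleName  Marker  Allele  Size  Height`` (tab-delimited).
Frequency tables: CSV with ``locus,allele`` and one column per population.
Genotype files: CSV with ``sample,locus,allele1,allele2``.
Configs: YAML or JSON with the :class:`AnalysisConfig` field names verbatim.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._alleles import Q_ALLELE, allele_key, normalize_label, parse_allele


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class PanelMismatchError(ValueError):
    """Input refers to a locus or allele the panel does not define."""


# ---------------------------------------------------------------------------
# Panel


@dataclass(frozen=True)
class Locus:
    """One autosomal STR locus.

    ``size_intercept``/``size_slope`` give a linear fragment-size model
    ``size = intercept + slope * repeat_number`` used only to fill the Size
    column of simulated peak tables; the slope is the repeat-motif length.
    """

    name: str
    dye: str
    alleles: tuple[str, ...]
    size_intercept: float
    size_slope: float

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"locus {self.name}: empty allele domain")
        for a in self.alleles:
            parse_allele(a)  # validates the label

    def fragment_size(self, allele: str) -> float:
        rep, frac = parse_allele(allele)
        return self.size_intercept + self.size_slope * (rep + frac / 10.0)


@dataclass(frozen=True)
class STRPanel:
    """Ordered collection of autosomal loci with unique names."""

    loci: tuple[Locus, ...]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        for banned in ("AMEL", "Amelogenin", "DYS391"):
            if banned in names:
                raise ValueError(f"non-autosomal locus not admitted: {banned}")

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    def locus(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise PanelMismatchError(f"unknown locus: {name}")

    def subset(self, names: list[str]) -> "STRPanel":
        return STRPanel(tuple(self.locus(n) for n in names))


def _rng(lo: int, hi: int, extra: tuple[str, ...] = ()) -> tuple[str, ...]:
    labels = [str(i) for i in range(lo, hi + 1)] + list(extra)
    return tuple(sorted(labels, key=allele_key))


# A 22-locus autosomal panel matching the loci of a modern 5-dye
# megaplex STR kit.  Allele domains are representative ladder ranges
# (incl. the TH01 9.3 microvariant); size models are approximate and
# serve only to populate the Size column of simulated exports.
_DEFAULT_LOCI = (
    ("D3S1358", "B", _rng(12, 19), 98.0, 4.0),
    ("D1S1656", "B", _rng(10, 19, ("17.3",)), 165.0, 4.0),
    ("D2S441", "B", _rng(9, 16, ("11.3",)), 230.0, 4.0),
    ("D10S1248", "B", _rng(9, 17), 290.0, 4.0),
    ("D13S317", "B", _rng(7, 15), 360.0, 4.0),
    ("Penta_E", "B", _rng(5, 24), 376.0, 5.0),
    ("D16S539", "G", _rng(5, 15), 85.0, 4.0),
    ("D18S51", "G", _rng(9, 26), 135.0, 4.0),
    ("D2S1338", "G", _rng(15, 28), 225.0, 4.0),
    ("CSF1PO", "G", _rng(6, 15), 305.0, 4.0),
    ("Penta_D", "G", _rng(2, 17), 330.0, 5.0),
    ("TH01", "Y", _rng(4, 11, ("9.3",)), 125.0, 4.0),
    ("vWA", "Y", _rng(11, 21), 190.0, 4.0),
    ("D21S11", "Y", _rng(24, 35, ("31.2", "32.2")), 150.0, 4.0),
    ("D7S820", "Y", _rng(6, 14), 310.0, 4.0),
    ("D5S818", "Y", _rng(7, 16), 370.0, 4.0),
    ("TPOX", "Y", _rng(6, 13), 410.0, 4.0),
    ("D8S1179", "R", _rng(8, 18), 85.0, 4.0),
    ("D12S391", "R", _rng(14, 26), 140.0, 4.0),
    ("D19S433", "R", _rng(9, 17, ("13.2", "14.2")), 215.0, 4.0),
    ("FGA", "R", _rng(16, 30), 290.0, 4.0),
    ("D22S1045", "R", _rng(8, 19), 390.0, 3.0),
)


def default_panel() -> STRPanel:
    """The built-in 22-locus autosomal panel."""
    return STRPanel(tuple(Locus(*row) for row in _DEFAULT_LOCI))


def mini_panel(n_loci: int = 8) -> STRPanel:
    """A reduced panel (first ``n_loci`` loci) for small studies and tests."""
    return STRPanel(default_panel().loci[:n_loci])


# ---------------------------------------------------------------------------
# Allele frequencies

POPULATIONS = ("AfAm", "Cau", "His", "Asian")
ALL_POP = "All"


@dataclass
class AlleleFrequencyTable:
    """Per-population allele frequencies, with minimum-frequency rebasing.

    ``freqs[population][locus][allele]`` is the allele frequency.  Alleles
    seen in casework but absent from the table are inserted at the
    conventional floor ``5 / (2 N)`` (``N`` = population sample size,
    configurable) and the locus column renormalized, so every queried
    frequency is positive and each column sums to one.
    """

    freqs: dict[str, dict[str, dict[str, float]]]
    n_pop: int = 500

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(self.freqs)

    @property
    def min_freq(self) -> float:
        return 5.0 / (2.0 * self.n_pop)

    def freq(self, population: str, locus: str, allele: str) -> float:
        try:
            return self.freqs[population][locus][allele]
        except KeyError:
            raise KeyError(f"no frequency for {population}/{locus}/{allele}")

    def alleles(self, population: str, locus: str) -> tuple[str, ...]:
        return tuple(self.freqs[population][locus])

    def ensure_alleles(self, locus: str, alleles: list[str]) -> "AlleleFrequencyTable":
        """Insert unseen alleles at the minimum frequency and renormalize.

        Returns a new table; columns already covering ``alleles`` are
        unchanged (a column whose sum is already 1 stays exactly as read).
        """
        out = {p: {l: dict(col) for l, col in by_locus.items()}
               for p, by_locus in self.freqs.items()}
        for pop in out:
            col = out[pop][locus]
            missing = [a for a in alleles if a not in col and a != Q_ALLELE]
            if missing:
                for a in missing:
                    col[a] = self.min_freq
                total = sum(col.values())
                for a in col:
                    col[a] /= total
        return AlleleFrequencyTable(out, self.n_pop)

    def rebased(self) -> "AlleleFrequencyTable":
        """Renormalize every locus column to sum exactly to one."""
        out = {}
        for pop, by_locus in self.freqs.items():
            out[pop] = {}
            for locus, col in by_locus.items():
                total = sum(col.values())
                out[pop][locus] = {a: f / total for a, f in col.items()}
        return AlleleFrequencyTable(out, self.n_pop)


def synthetic_frequency_table(
    panel: STRPanel,
    populations: tuple[str, ...] = POPULATIONS,
    seed: int = 0,
    concentration: float = 12.0,
    n_pop: int = 500,
) -> AlleleFrequencyTable:
    """Generate a realistic multi-population frequency table.

    Per locus a common base frequency spectrum is drawn (triangular in
    allele rank, so mid-ladder alleles are common, as in real STR data) and
    each population perturbs it with a Dirichlet draw; the combined "All"
    column is the across-population mean, mirroring published
    multi-population tables that print a combined dataset column.
    """
    rng = np.random.default_rng(seed)
    freqs: dict[str, dict[str, dict[str, float]]] = {p: {} for p in (*populations, ALL_POP)}
    for locus in panel.loci:
        labels = locus.alleles
        k = len(labels)
        ranks = np.arange(k)
        base = np.minimum(ranks + 1, k - ranks).astype(float)  # triangular
        base /= base.sum()
        per_pop = {}
        for pop in populations:
            col = rng.dirichlet(concentration * k * base)
            col = np.maximum(col, 1e-4)
            col /= col.sum()
            per_pop[pop] = col
        for pop in populations:
            freqs[pop][locus.name] = dict(zip(labels, map(float, per_pop[pop])))
        combined = np.mean([per_pop[p] for p in populations], axis=0)
        combined /= combined.sum()
        freqs[ALL_POP][locus.name] = dict(zip(labels, map(float, combined)))
    return AlleleFrequencyTable(freqs, n_pop=n_pop)


def read_allele_frequencies(
    path: str | Path, panel: STRPanel, n_pop: int = 500
) -> AlleleFrequencyTable:
    """Read a ``locus,allele,<pop>,...`` CSV into a frequency table.

    Values outside [0, 1] are a validation error; a locus column whose sum
    deviates from 1 by more than 0.01 raises a warning before rebasing.
    """
    df = pd.read_csv(path, dtype={"locus": str, "allele": str})
    if "locus" not in df.columns or "allele" not in df.columns:
        raise FormatError("frequency CSV must have 'locus' and 'allele' columns")
    pops = [c for c in df.columns if c not in ("locus", "allele")]
    freqs: dict[str, dict[str, dict[str, float]]] = {p: {} for p in pops}
    for locus_name, group in df.groupby("locus", sort=False):
        panel.locus(str(locus_name))  # raises on unknown locus
        for pop in pops:
            vals = group[pop].astype(float).to_numpy()
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError(f"{pop}/{locus_name}: frequency outside [0, 1]")
            if abs(vals.sum() - 1.0) > 0.01:
                warnings.warn(
                    f"{pop}/{locus_name}: column sums to {vals.sum():.4f}, rebasing"
                )
            freqs[pop][str(locus_name)] = dict(zip(group["allele"], map(float, vals)))
    missing = set(panel.locus_names) - set(df["locus"])
    if missing:
        raise FormatError(f"frequency table missing panel loci: {sorted(missing)}")
    return AlleleFrequencyTable(freqs, n_pop=n_pop).rebased()


def write_allele_frequencies(table: AlleleFrequencyTable, path: str | Path) -> None:
    pops = list(table.populations)
    rows = []
    first = pops[0]
    for locus, col in table.freqs[first].items():
        for allele in sorted(col, key=allele_key):
            rows.append(
                {"locus": locus, "allele": allele,
                 **{p: table.freqs[p][locus].get(allele, 0.0) for p in pops}}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Peak tables / EPG profiles

PEAK_COLUMNS = ("SampleName", "Marker", "Allele", "Size", "Height")


@dataclass(frozen=True)
class PeakRecord:
    sample: str
    locus: str
    allele: str
    size: float
    height: float
    off_ladder: bool = False

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError(f"{self.locus}/{self.allele}: height must be > 0")


@dataclass
class EPGProfile:
    """Thresholded peak table for one sample: the MCMC 'signal'."""

    sample_id: str
    at: float
    peaks: dict[str, list[PeakRecord]]

    def __post_init__(self) -> None:
        for locus, records in self.peaks.items():
            seen = set()
            for r in records:
                if r.allele in seen:
                    raise ValueError(f"{locus}: duplicate peak for allele {r.allele}")
                seen.add(r.allele)

    def heights(self, locus: str) -> dict[str, float]:
        return {r.allele: r.height for r in self.peaks.get(locus, [])}

    def alleles(self, locus: str) -> list[str]:
        return sorted((r.allele for r in self.peaks.get(locus, [])), key=allele_key)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.peaks)

    def n_peaks(self) -> int:
        return sum(len(v) for v in self.peaks.values())


def apply_analytical_threshold(profile: EPGProfile, at: float) -> EPGProfile:
    """Censor peaks below ``at`` RFU.  Idempotent; records the AT applied."""
    if not at > 0:
        raise ValueError("analytical threshold must be > 0")
    peaks = {
        locus: [r for r in records if r.height >= at]
        for locus, records in profile.peaks.items()
    }
    return EPGProfile(profile.sample_id, at, peaks)


def read_peak_table(path: str | Path, panel: STRPanel, at: float) -> EPGProfile:
    """Read one sample's tab-delimited peak export and apply the AT.

    Every panel locus appears in the result; loci with no surviving peaks
    get an empty list.  Unknown markers and malformed rows are errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty peak table")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise FormatError(f"{path}: peak table has no rows")
    samples = df["SampleName"].unique()
    if len(samples) != 1:
        raise FormatError(f"{path}: expected one sample per file, found {list(samples)}")
    peaks: dict[str, list[PeakRecord]] = {name: [] for name in panel.locus_names}
    for idx, row in df.iterrows():
        marker = row["Marker"]
        if marker not in peaks:
            raise PanelMismatchError(f"{path}: unknown marker '{marker}'")
        try:
            height = float(row["Height"])
            size = float(row["Size"])
        except (TypeError, ValueError):
            raise FormatError(f"{path}: non-numeric Size/Height at line {idx + 2}")
        allele = normalize_label(str(row["Allele"]))
        off_ladder = allele not in panel.locus(marker).alleles
        peaks[marker].append(
            PeakRecord(str(samples[0]), marker, allele, size, height, off_ladder)
        )
    return apply_analytical_threshold(EPGProfile(str(samples[0]), at, peaks), at)


def write_peak_table(profile: EPGProfile, path: str | Path) -> None:
    rows = [
        {"SampleName": r.sample, "Marker": r.locus, "Allele": r.allele,
         "Size": f"{r.size:.2f}", "Height": f"{r.height:.6g}"}
        for records in profile.peaks.values()
        for r in records
    ]
    pd.DataFrame(rows, columns=list(PEAK_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype files


def read_genotypes(path: str | Path) -> dict[str, dict[str, tuple[str, str]]]:
    """``sample,locus,allele1,allele2`` CSV -> {sample: {locus: (a1, a2)}}."""
    df = pd.read_csv(path, dtype=str)
    need = ("sample", "locus", "allele1", "allele2")
    if any(c not in df.columns for c in need):
        raise FormatError(f"genotype CSV must have columns {need}")
    out: dict[str, dict[str, tuple[str, str]]] = {}
    for _, row in df.iterrows():
        pair = tuple(
            sorted(
                (normalize_label(row["allele1"]), normalize_label(row["allele2"])),
                key=allele_key,
            )
        )
        out.setdefault(row["sample"], {})[row["locus"]] = pair  # type: ignore[assignment]
    return out


def write_genotypes(profiles: dict[str, dict[str, tuple[str, str]]], path: str | Path) -> None:
    rows = [
        {"sample": s, "locus": l, "allele1": g[0], "allele2": g[1]}
        for s, by_locus in profiles.items()
        for l, g in by_locus.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Analysis configuration

DEGRADATION_MODES = ("none", "linear", "exponential")
POPGEN_MODELS = ("HWE", "NRC4.1", "NRC4.2")


@dataclass
class AnalysisConfig:
    """Run-level settings for deconvolution and LR computation.

    Defaults mirror the validated protocol: eight chains, 20% burn-in,
    thin 1, 10,000 preprocessing steps, drop-in coefficient 1 (on a zero
    base rate), no degradation adjustment, NRC II recommendation 4.1 with
    theta = 0.01 on the combined population column.
    """

    chains: int = 8
    iterations_per_chain: int = 5000
    burn_in_fraction: float = 0.20
    thin_n: int = 1
    preprocessing_steps: int = 10000
    drop_in_coefficient: float = 1.0
    dropin_base_rate: float = 0.0
    degradation_mode: str = "none"
    at: float = 30.0
    popgen_model: str = "NRC4.1"
    theta: float = 0.01
    population: str = ALL_POP
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in (0, 1)")
        if self.thin_n < 1:
            raise ValueError("thin_n must be >= 1")
        if self.degradation_mode not in DEGRADATION_MODES:
            raise ValueError(f"degradation_mode must be one of {DEGRADATION_MODES}")
        if self.popgen_model not in POPGEN_MODELS:
            raise ValueError(f"popgen_model must be one of {POPGEN_MODELS}")
        if self.drop_in_coefficient < 0:
            raise ValueError("drop_in_coefficient must be >= 0")


def default_iterations(n_contributors: int) -> int:
    """Per-chain iteration default by number of contributors."""
    return {1: 5000, 2: 5000, 3: 10000}.get(n_contributors, 20000)


def read_config(path: str | Path) -> AnalysisConfig:
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return AnalysisConfig(**data)


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(data, indent=2))
    else:
        Path(path).write_text(yaml.safe_dump(data))
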