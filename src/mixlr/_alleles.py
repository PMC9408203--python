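"""Allele-label arithmetic.

STR alleles are named by repeat count, with microvariants written as
``repeat.partial`` (e.g. TH01 "9.3").  Labels are kept as strings so that
microvariants stay exact; ordering and one-repeat arithmetic go through a
parsed ``(repeat, partial)`` integer pair.
"""

from __future__ import annotations

Q_ALLELE = "Q"  # virtual dropout allele


def normalize_label(label: str) -> str:
    """Canonical allele label: trims whitespace and a spurious '.0' that
    spreadsheet round-trips add to integer repeat numbers."""
    label = label.strip()
    if label.endswith(".0") and label[:-2].isdigit():
        return label[:-2]
    return label


def parse_allele(label: str) -> tuple[int, int]:
    """Parse an allele label into an exact (repeat, partial-repeat) pair."""
    if label == Q_ALLELE:
        raise ValueError("the Q allele has no repeat value")
    if "." in label:
        whole, frac = label.split(".", 1)
        return int(whole), int(frac)
    return int(label), 0


def allele_key(label: str) -> tuple[int, int]:
    """Sort key; Q sorts after every real allele."""
    if label == Q_ALLELE:
        return (10**6, 0)
    return parse_allele(label)


def stutter_target(label: str) -> str:
    """Label of the backward (N-1) stutter position of ``label``."""
    rep, frac = parse_allele(label)
    return f"{rep - 1}.{frac}" if frac else str(rep - 1)
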