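"""Motif representation and repetivity, after the FANTASTIC toolbox.

Consecutive note pairs are coded as "M-type" symbols combining a signed
pitch-interval class (same / step / third / ... / octave+, quality-blind:
major and minor thirds coincide) with a duration-ratio class (shorter /
equal / longer).  A motif of l notes is a window of l-1 consecutive
symbols.  For each motif length 2..6 the normalized entropy of the motif
frequency distribution measures how little the phrase repeats itself;
motif repetivity is the negated mean of those entropies, so it lives in
[-1, 0] with 0 for a maximally repetitive phrase.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction

from .model import Phrase
from .predictors import UndefinedFeatureError

MOTIF_LENGTHS = range(2, 7)

# duration-ratio band treated as "equal"; ratios are successor/predecessor
EQUAL_BAND = (Fraction(4, 5), Fraction(5, 4))

_INTERVAL_CLASSES = (
    (0, "same"),
    (2, "step"),
    (4, "third"),
    (5, "fourth"),
    (6, "tritone"),
    (7, "fifth"),
    (9, "sixth"),
    (11, "seventh"),
)


def interval_class(semitones: int) -> str:
    """Signed quality-blind interval category of a semitone distance."""
    size = abs(semitones)
    name = "octave+"
    for bound, label in _INTERVAL_CLASSES:
        if size <= bound:
            name = label
            break
    if name == "same":
        return name
    return ("+" if semitones > 0 else "-") + name


def duration_ratio_class(ratio: Fraction | float) -> str:
    if ratio < EQUAL_BAND[0]:
        return "shorter"
    if ratio > EQUAL_BAND[1]:
        return "longer"
    return "equal"


@dataclass(frozen=True)
class MotifSymbol:
    interval_class: str
    duration_ratio_class: str


def mtype_sequence(phrase: Phrase) -> list[MotifSymbol]:
    """The phrase's n-1 M-type symbols (consecutive-note codings)."""
    if len(phrase) < 2:
        raise UndefinedFeatureError(
            f"phrase {phrase.index} has fewer than two notes; no motifs"
        )
    out = []
    for a, b in zip(phrase.notes, phrase.notes[1:]):
        out.append(
            MotifSymbol(
                interval_class=interval_class(b.pitch - a.pitch),
                duration_ratio_class=duration_ratio_class(
                    Fraction(b.duration) / Fraction(a.duration)
                ),
            )
        )
    return out


@dataclass(frozen=True)
class MotifTable:
    """Motif counts for one length: total motifs and per-motif frequencies."""

    length: int
    counts: tuple[tuple[tuple[MotifSymbol, ...], int], ...]

    @property
    def total(self) -> int:
        return sum(c for _, c in self.counts)

    @property
    def relative_frequencies(self) -> dict[tuple[MotifSymbol, ...], float]:
        t = self.total
        return {motif: c / t for motif, c in self.counts}


def motif_table(phrase: Phrase, length: int) -> MotifTable:
    if not (2 <= length <= 6):
        raise ValueError("motif length must be in 2..6")
    symbols = mtype_sequence(phrase)
    width = length - 1
    windows = [
        tuple(symbols[i:i + width]) for i in range(len(symbols) - width + 1)
    ]
    return MotifTable(length=length, counts=tuple(sorted(
        Counter(windows).items(), key=lambda kv: (-kv[1], repr(kv[0])))))


def motif_entropy(phrase: Phrase, length: int) -> float | None:
    """Normalized entropy of the motif distribution at one length, in [0, 1].

    1.0 means every motif of this length is distinct (no repetition
    measurable); 0.0 means a single motif covers the phrase.  Returns None
    (skipped) when the phrase yields at most one motif of this length.
    """
    table = motif_table(phrase, length)
    n_total = table.total
    if n_total <= 1:
        return None
    h = -math.fsum(f * math.log2(f) for f in table.relative_frequencies.values())
    return h / math.log2(n_total)


def motif_repetivity(phrase: Phrase) -> float:
    """Negated mean normalized motif entropy over lengths 2..6, in [-1, 0].

    Lengths yielding at most one motif are disregarded; the mean runs over
    the contributing lengths only.
    """
    entropies = []
    if len(phrase) >= 2:
        for l in MOTIF_LENGTHS:
            if l - 1 > len(phrase) - 1:
                break
            h = motif_entropy(phrase, l)
            if h is not None:
                entropies.append(h)
    if not entropies:
        raise UndefinedFeatureError(
            f"phrase {phrase.index}: no motif length yields more than one motif"
        )
    return -math.fsum(entropies) / len(entropies)
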