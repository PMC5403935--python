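"""Phrase-occurrence detection across tune-family variants.

A query phrase "occurs" in a target melody when enough of three similarity
measures clear their thresholds: a windowed city-block measure (pitch-exact,
position-free), Smith–Waterman local alignment on pitch sequences
(insertion/deletion tolerant) and SIAM point-set structure induction
(transposition- and time-shift-invariant).  The measures deliberately differ
in their invariances; the combination rule and thresholds are configurable
and can be calibrated on annotated examples.  A phrase's stability is then
its frequency of occurrence across the other variants of its tune family.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import Melody, Phrase, TuneFamily, melody_point_set, phrase_point_set


@dataclass(frozen=True)
class SimilarityScores:
    """The three per-comparison similarity scores.

    cityblock: minus the mean absolute pitch difference of the best
        length-n window (0 is a perfect match; -inf when the melody is
        shorter than the query).
    alignment: best Smith-Waterman local score divided by query length,
        in [-1, 1] with 1 for a verbatim copy.
    siam: largest translated-overlap count divided by query length, in (0, 1].
    """

    cityblock: float
    alignment: float
    siam: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.cityblock, self.alignment, self.siam)


@dataclass(frozen=True)
class ThresholdSet:
    cityblock: float = -1.0
    alignment: float = 0.6
    siam: float = 0.75
    combination: str = "majority"

    _COMBINATIONS = ("majority", "all", "any")

    def __post_init__(self) -> None:
        if self.combination not in self._COMBINATIONS:
            raise ValueError(f"combination must be one of {self._COMBINATIONS}")
        for name in ("cityblock", "alignment", "siam"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")


@dataclass(frozen=True)
class OccurrenceRecord:
    tune_family_id: str
    source_melody_id: str
    phrase_index: int
    target_melody_id: str
    scores: SimilarityScores
    occurs: bool


def cityblock_similarity(query: Phrase, melody: Melody) -> float:
    """Negated mean absolute pitch difference over the best aligned window.

    Compares the query against every contiguous window of equal length in
    the melody; no gaps, no transposition invariance (variants within a
    family are transcribed in a common register).  Returns ``-inf`` when the
    melody has fewer notes than the query.
    """
    q = np.array([n.pitch for n in query.notes], dtype=float)
    s = np.array([n.pitch for n in melody.notes], dtype=float)
    n = q.size
    if s.size < n:
        return float("-inf")
    windows = np.lib.stride_tricks.sliding_window_view(s, n)
    dists = np.abs(windows - q).mean(axis=1)
    return float(-dists.min())


def local_alignment_similarity(
    query: Phrase,
    melody: Melody,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -0.5,
) -> float:
    """Smith-Waterman local alignment score on pitch sequences, per query note.

    Linear gap penalty; cells are floored at zero as usual.  The score is
    normalized by the query length so that a verbatim copy scores exactly 1.
    """
    q = [n.pitch for n in query.notes]
    s = [n.pitch for n in melody.notes]
    n, m = len(q), len(s)
    prev = np.zeros(m + 1)
    best = 0.0
    sarr = np.array(s)
    for i in range(1, n + 1):
        cur = np.zeros(m + 1)
        sub = np.where(sarr == q[i - 1], match, mismatch)
        for j in range(1, m + 1):
            cur[j] = max(0.0, prev[j - 1] + sub[j - 1], prev[j] + gap, cur[j - 1] + gap)
        best = max(best, cur.max())
        prev = cur
    return best / n


def siam_similarity(query: Phrase, melody: Melody) -> float:
    """SIAM structure-induction similarity on (onset, pitch) point sets.

    For every translation vector carrying a query point onto a melody
    point, counts how many query points land on melody points; the maximum
    count over all vectors, divided by the query length, is the score.
    Invariant under transposition and time shift by construction.
    """
    P = phrase_point_set(query)
    M = melody_point_set(melody)
    shifts: Counter[tuple] = Counter()
    for (pt, pp) in P:
        for (mt, mp) in M:
            shifts[(mt - pt, mp - pp)] += 1
    return max(shifts.values()) / len(P)


def score_pair(query: Phrase, melody: Melody) -> SimilarityScores:
    return SimilarityScores(
        cityblock=cityblock_similarity(query, melody),
        alignment=local_alignment_similarity(query, melody),
        siam=siam_similarity(query, melody),
    )


def detect_occurrence(scores: SimilarityScores, thresholds: ThresholdSet) -> bool:
    """Combine per-measure votes (score >= threshold) under the configured rule."""
    votes = (
        scores.cityblock >= thresholds.cityblock,
        scores.alignment >= thresholds.alignment,
        scores.siam >= thresholds.siam,
    )
    if thresholds.combination == "all":
        return all(votes)
    if thresholds.combination == "any":
        return any(votes)
    return sum(votes) >= 2


class CalibrationError(ValueError):
    pass


def calibrate_thresholds(
    annotated: Sequence[tuple[SimilarityScores, bool]],
    combination: str = "majority",
    max_candidates: int = 24,
) -> ThresholdSet:
    """Grid-search per-measure thresholds maximizing F1 against annotations.

    Candidate thresholds per measure are the (quantile-thinned) unique
    observed scores; ties in F1 are broken toward the higher threshold
    triple so the detector stays conservative.
    """
    labels = np.array([bool(lab) for _, lab in annotated])
    if labels.all() or (~labels).all():
        raise CalibrationError("annotations must contain both positive and negative labels")

    mats = {
        name: np.array([getattr(sc, name) for sc, _ in annotated])
        for name in ("cityblock", "alignment", "siam")
    }

    def candidates(x: np.ndarray) -> np.ndarray:
        vals = np.unique(x[np.isfinite(x)])
        if vals.size > max_candidates:
            idx = np.linspace(0, vals.size - 1, max_candidates).round().astype(int)
            vals = vals[np.unique(idx)]
        return vals

    cand = {k: candidates(v) for k, v in mats.items()}
    # vote tensors: candidate x annotation
    votes = {k: (mats[k][None, :] >= cand[k][:, None]) for k in cand}

    best = (-1.0, None)
    vc, va, vs = votes["cityblock"], votes["alignment"], votes["siam"]
    for ic in range(vc.shape[0]):
        for ia in range(va.shape[0]):
            pair = vc[ic].astype(np.int8) + va[ia]
            # combine with every siam candidate at once
            if combination == "majority":
                pred = (pair[None, :] + vs) >= 2
            elif combination == "all":
                pred = (pair[None, :] + vs) == 3
            else:
                pred = (pair[None, :] + vs) >= 1
            tp = (pred & labels).sum(axis=1)
            fp = (pred & ~labels).sum(axis=1)
            fn = ((~pred) & labels).sum(axis=1)
            denom = 2 * tp + fp + fn
            f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
            for is_ in range(len(f1)):
                key = (f1[is_], cand["cityblock"][ic], cand["alignment"][ia], cand["siam"][is_])
                if best[1] is None or key > (best[0], *best[1]):
                    best = (key[0], key[1:])
    f1, (tc, ta, ts) = best
    return ThresholdSet(cityblock=float(tc), alignment=float(ta), siam=float(ts),
                        combination=combination)


def detect_family_occurrences(
    family: TuneFamily, thresholds: ThresholdSet, include_source: bool = False
) -> list[OccurrenceRecord]:
    """Score every phrase of every melody against the family's other variants."""
    records = []
    for source in family.melodies:
        for phrase in source.phrases:
            for target in family.melodies:
                if target.id == source.id and not include_source:
                    continue
                scores = score_pair(phrase, target)
                records.append(
                    OccurrenceRecord(
                        tune_family_id=family.id,
                        source_melody_id=source.id,
                        phrase_index=phrase.index,
                        target_melody_id=target.id,
                        scores=scores,
                        occurs=detect_occurrence(scores, thresholds),
                    )
                )
    return records


def stability(
    phrase: Phrase,
    source_melody: Melody,
    family: TuneFamily,
    thresholds: ThresholdSet,
    include_source: bool = False,
) -> tuple[int, int, float]:
    """Frequency of occurrence of ``phrase`` across the family's variants.

    Returns ``(k, m, k/m)`` where m counts the family's melodies other than
    the source (all melodies with ``include_source``) and k those in which
    the phrase is detected.
    """
    if source_melody.id not in {m.id for m in family.melodies}:
        raise ValueError(f"melody {source_melody.id} not in family {family.id}")
    targets = [
        m for m in family.melodies if include_source or m.id != source_melody.id
    ]
    if not targets:
        raise ValueError(
            f"family {family.id} has no comparison variants for stability "
            "(size-1 family without include_source)"
        )
    k = sum(
        detect_occurrence(score_pair(phrase, t), thresholds) for t in targets
    )
    return k, len(targets), k / len(targets)
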