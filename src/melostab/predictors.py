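"""Structural memorability predictors for melody phrases.

Five of the seven predictors live here: phrase length (list-length effect),
phrase repetition (rehearsal), phrase position (primacy), and the two
factors of Schellenberg's reduction of Narmour's implication-realization
expectancy model — pitch proximity and pitch reversal.  The remaining two
(surprisal, motif repetivity) are computed by :mod:`melostab.expectancy`
and :mod:`melostab.motifs`.

Interval-based predictors use whole-melody context: the first notes of a
phrase take their intervals from the end of the preceding phrase, so only
the very first notes of a melody are undefined.  Undefined notes are
discarded from phrase averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import Melody, Phrase, phrase_point_set


class UndefinedFeatureError(ValueError):
    """No note in the phrase has a defined value for this predictor."""


# Schellenberg's revised two-factor quantification: implicative intervals
# strictly larger than a perfect fifth (6 semitones) expect a direction
# reversal; a realized note returning to within 2 semitones of the
# pre-implicative pitch earns an extra 1.5.
LARGE_INTERVAL = 6
RETURN_TOLERANCE = 2
DIRECTION_WEIGHT = 1.0
RETURN_WEIGHT = 1.5
OCTAVE = 12


def phrase_length(phrase: Phrase) -> int:
    """Number of notes in the phrase."""
    return len(phrase)


def phrase_repetition(phrase: Phrase, melody: Melody) -> int:
    """How many phrases of the melody restate this one exactly.

    Equality compares (onset-from-phrase-start, pitch) pairs only, so two
    restatements may differ in the duration of their final notes.  The
    query matches itself, so the count is always >= 1.
    """
    target = phrase_point_set(phrase)
    return sum(1 for p in melody.phrases if phrase_point_set(p) == target)


def phrase_position(phrase: Phrase) -> int:
    """The phrase's 1-based sequential index in its melody."""
    return phrase.index


def note_pitch_proximity(melody: Melody, note_index: int) -> float | None:
    """|pitch interval| into the note, or None when undefined.

    Undefined for the melody's first note (no predecessor) and for
    intervals of an octave or more, for which the proximity principle
    makes no prediction.
    """
    notes = melody.notes
    if not 0 <= note_index < len(notes):
        raise IndexError(note_index)
    if note_index == 0:
        return None
    interval = notes[note_index].pitch - notes[note_index - 1].pitch
    if abs(interval) >= OCTAVE:
        return None
    return float(abs(interval))


def note_pitch_reversal(melody: Melody, note_index: int) -> float | None:
    """Pitch-reversal expectancy of the note, in [-1, 2.5], or None.

    Needs two preceding notes (an implicative interval I and a realized
    interval R).  Direction: after a large leap (|I| > 6 semitones) a
    change of direction scores +1, a continuation -1; small implicative
    intervals score 0.  Return: a direction change that lands within 2
    semitones of the pre-implicative pitch adds +1.5.  Lateral motion
    (R = 0) counts as a direction change.
    """
    notes = melody.notes
    if not 0 <= note_index < len(notes):
        raise IndexError(note_index)
    if note_index < 2:
        return None
    implicative = notes[note_index - 1].pitch - notes[note_index - 2].pitch
    realized = notes[note_index].pitch - notes[note_index - 1].pitch
    return pitch_reversal_value(implicative, realized)


def pitch_reversal_value(implicative: int, realized: int) -> float:
    """The two-factor reversal score for an (implicative, realized) interval pair."""
    reverses = realized == 0 or (realized > 0) != (implicative > 0)
    if abs(implicative) <= LARGE_INTERVAL:
        direction = 0.0
    else:
        direction = DIRECTION_WEIGHT if reverses else -DIRECTION_WEIGHT
    returns = reverses and abs(implicative + realized) <= RETURN_TOLERANCE
    return direction + (RETURN_WEIGHT if returns else 0.0)


def _phrase_note_values(phrase: Phrase, melody: Melody, note_fn) -> list[float]:
    values = []
    for k in range(len(phrase)):
        v = note_fn(melody, phrase.start_note_index + k)
        if v is not None:
            values.append(v)
    return values


def avg_proximity(phrase: Phrase, melody: Melody) -> float:
    """Negated mean |interval| over the phrase's notes with defined proximity.

    0 is the maximum (all repeated pitches); more negative means larger
    leaps.  The phrase's first note uses the interval from the preceding
    phrase when one exists.
    """
    vals = _phrase_note_values(phrase, melody, note_pitch_proximity)
    if not vals:
        raise UndefinedFeatureError(
            f"no defined pitch-proximity values in phrase {phrase.index}"
        )
    return -math.fsum(vals) / len(vals)


def avg_reversal(phrase: Phrase, melody: Melody) -> float:
    """Mean pitch-reversal score over the phrase's notes with defined values."""
    vals = _phrase_note_values(phrase, melody, note_pitch_reversal)
    if not vals:
        raise UndefinedFeatureError(
            f"no defined pitch-reversal values in phrase {phrase.index}"
        )
    return math.fsum(vals) / len(vals)


FEATURE_NAMES = ("length", "repetition", "position", "proximity", "reversal",
                 "surprisal", "motif_repetivity")


@dataclass(frozen=True)
class PhraseFeatures:
    """The seven predictor values for one phrase (raw scale).

    ``surprisal`` and ``motif_repetivity`` may be NaN when undefined for
    degenerate phrases; such phrases are dropped from the outcome table
    with a logged count.
    """

    melody_id: str
    phrase_index: int
    length: float
    repetition: float
    position: float
    proximity: float
    reversal: float
    surprisal: float
    motif_repetivity: float

    def as_dict(self) -> dict:
        return {
            "melody_id": self.melody_id,
            "phrase_index": self.phrase_index,
            **{name: getattr(self, name) for name in FEATURE_NAMES},
        }
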