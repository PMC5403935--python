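from __future__ import annotations

from fractions import Fraction

import pytest

from melostab.model import Corpus, Melody, Note, Phrase, TuneFamily


def build_melody(
    phrase_pitches: list[list[int]],
    durations: list[list[Fraction]] | None = None,
    melody_id: str = "m1",
    family_id: str = "f1",
) -> Melody:
    """Assemble a melody from per-phrase pitch lists (quarter notes by default)."""
    onset = Fraction(0)
    phrases = []
    pos = 0
    for i, pitches in enumerate(phrase_pitches, start=1):
        durs = durations[i - 1] if durations else [Fraction(1)] * len(pitches)
        notes = []
        for p, d in zip(pitches, durs):
            notes.append(Note(onset=onset, duration=Fraction(d), pitch=p))
            onset += Fraction(d)
        phrases.append(Phrase(index=i, notes=tuple(notes), start_note_index=pos))
        pos += len(notes)
    return Melody(id=melody_id, phrases=tuple(phrases), tune_family_id=family_id)


def build_family(melodies, family_id="f1", role="test") -> TuneFamily:
    return TuneFamily(id=family_id, melodies=tuple(melodies), role=role)


@pytest.fixture
def simple_melody() -> Melody:
    return build_melody([[60, 62, 64], [64, 62, 60]])


@pytest.fixture
def worked_example_melody() -> Melody:
    """Ten phrases; phrases 1 and 2 restate exactly as phrases 3 and 4.

    Mirrors the structure of the running folk-song example: the opening
    pair repeats, the remaining six phrases are unique.
    """
    p1 = [60, 62, 64, 65, 67, 65, 64]
    p2 = [64, 67, 71, 74, 71, 67, 64]
    rest = [
        [67, 65, 64, 62, 60, 62, 64, 65],
        [72, 71, 69, 67, 65, 64, 62],
        [60, 64, 67, 72, 67, 64, 60, 64],
        [62, 62, 64, 65, 65, 67, 69],
        [74, 72, 71, 69, 67, 65, 64, 62, 60],
        [55, 57, 59, 60, 62, 64],
    ]
    return build_melody([p1, p2, p1, p2] + rest)
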