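"""Symbolic-music data model for monophonic folk-song melodies.

Melodies are hierarchies of tune family -> melody -> phrase -> note.  Time is
kept rational (quarter-note units) so that phrase equality, which compares
onsets exactly, is immune to floating-point drift.  Pitch is a bare MIDI
number: the downstream predictors consult only pitch and onset, never
spelling or key.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterator, Sequence


class CorpusValidationError(ValueError):
    """A melody or family violates a structural invariant."""


class CorpusParseError(ValueError):
    """The on-disk representation could not be parsed."""


@dataclass(frozen=True)
class Note:
    """A single note: onset and duration in quarter-note units, MIDI pitch."""

    onset: Fraction
    duration: Fraction
    pitch: int

    def __post_init__(self) -> None:
        if not (0 <= self.pitch <= 127):
            raise CorpusValidationError(f"pitch {self.pitch} outside MIDI range 0..127")
        if self.duration <= 0:
            raise CorpusValidationError(f"duration {self.duration} must be positive")
        if self.onset < 0:
            raise CorpusValidationError(f"onset {self.onset} must be non-negative")


@dataclass(frozen=True)
class Phrase:
    """A human-annotated melodic unit.

    ``index`` is the 1-based sequential position of the phrase within its
    melody; ``start_note_index`` the 0-based offset of its first note in the
    melody's flat note list, so a phrase can reach back across its boundary
    for interval context.
    """

    index: int
    notes: tuple[Note, ...]
    start_note_index: int = 0

    def __post_init__(self) -> None:
        if self.index < 1:
            raise CorpusValidationError("phrase index must be >= 1")
        if not self.notes:
            raise CorpusValidationError("phrase must contain at least one note")
        object.__setattr__(self, "notes", tuple(self.notes))
        onsets = [n.onset for n in self.notes]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise CorpusValidationError(
                f"phrase {self.index}: note onsets must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.notes)


@dataclass(frozen=True)
class Melody:
    id: str
    phrases: tuple[Phrase, ...]
    tune_family_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "phrases", tuple(self.phrases))
        if not self.phrases:
            raise CorpusValidationError(f"melody {self.id}: no phrases")
        indices = [p.index for p in self.phrases]
        if indices != list(range(1, len(indices) + 1)):
            raise CorpusValidationError(
                f"melody {self.id}: phrase indices must be contiguous starting at 1, got {indices}"
            )
        flat = self.notes
        onsets = [n.onset for n in flat]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise CorpusValidationError(
                f"melody {self.id}: onsets must be strictly increasing across phrases"
            )
        # start_note_index must agree with the flat concatenation
        pos = 0
        for p in self.phrases:
            if p.start_note_index != pos:
                raise CorpusValidationError(
                    f"melody {self.id}: phrase {p.index} start_note_index "
                    f"{p.start_note_index} != {pos}"
                )
            pos += len(p)

    @property
    def notes(self) -> tuple[Note, ...]:
        return tuple(n for p in self.phrases for n in p.notes)

    def __len__(self) -> int:
        return sum(len(p) for p in self.phrases)


@dataclass(frozen=True)
class TuneFamily:
    """A group of melody variants descended from the same tune.

    ``role`` marks how the family is used: ``training`` families carry
    occurrence annotations for threshold calibration, ``test`` families feed
    the stability analysis, ``background`` families train the expectancy
    model.
    """

    id: str
    melodies: tuple[Melody, ...]
    role: str = "test"

    _ROLES = ("training", "test", "background")

    def __post_init__(self) -> None:
        object.__setattr__(self, "melodies", tuple(self.melodies))
        if not self.melodies:
            raise CorpusValidationError(f"family {self.id}: no melodies")
        if self.role not in self._ROLES:
            raise CorpusValidationError(
                f"family {self.id}: role {self.role!r} not in {self._ROLES}"
            )
        for m in self.melodies:
            if m.tune_family_id != self.id:
                raise CorpusValidationError(
                    f"melody {m.id} has tune_family_id {m.tune_family_id!r}, "
                    f"expected {self.id!r}"
                )


@dataclass(frozen=True)
class Corpus:
    families: tuple[TuneFamily, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "families", tuple(self.families))
        fids = [f.id for f in self.families]
        if len(set(fids)) != len(fids):
            raise CorpusValidationError("family ids must be unique")
        mids = [m.id for f in self.families for m in f.melodies]
        if len(set(mids)) != len(mids):
            raise CorpusValidationError("melody ids must be unique corpus-wide")

    def melodies(self, role: str | None = None) -> Iterator[Melody]:
        for f in self.families:
            if role is None or f.role == role:
                yield from f.melodies

    def family(self, family_id: str) -> TuneFamily:
        for f in self.families:
            if f.id == family_id:
                return f
        raise KeyError(family_id)


# ---------------------------------------------------------------------------
# Derived sequences


def pitch_intervals(melody: Melody) -> list[tuple[int, int]]:
    """Signed semitone intervals over the whole melody, across phrase bounds.

    Returns ``(note_index, interval)`` for every note with a predecessor,
    where the interval is positive when the preceding note is lower.  The
    melody's first note has no entry.
    """
    notes = melody.notes
    return [(j, notes[j].pitch - notes[j - 1].pitch) for j in range(1, len(notes))]


def phrase_point_set(phrase: Phrase) -> frozenset[tuple[Fraction, int]]:
    """The phrase as (onset, pitch) points, onsets re-based to the phrase start.

    Two phrases restating the same material at different positions in a
    melody map to identical point sets, which is the equality the phrase
    repetition predictor relies on.
    """
    base = phrase.notes[0].onset
    return frozenset((n.onset - base, n.pitch) for n in phrase.notes)


def melody_point_set(melody: Melody) -> frozenset[tuple[Fraction, int]]:
    """All (onset, pitch) points of a melody, onsets re-based to the first note."""
    notes = melody.notes
    base = notes[0].onset
    return frozenset((n.onset - base, n.pitch) for n in notes)


# ---------------------------------------------------------------------------
# JSON corpus format
#
# {"families": [{"id": ..., "role": ..., "melodies": [{"id": ...,
#   "phrases": [{"index": 1, "notes": [{"onset": [num, den],
#   "duration": [num, den], "pitch": 60}, ...]}, ...]}]}]}


def _frac_from_json(value: object, where: str) -> Fraction:
    if not (isinstance(value, (list, tuple)) and len(value) == 2):
        raise CorpusParseError(f"{where}: rational values must be [numerator, denominator]")
    num, den = value
    try:
        return Fraction(int(num), int(den))
    except (ValueError, ZeroDivisionError) as exc:
        raise CorpusParseError(f"{where}: bad rational {value!r}") from exc


def read_json_corpus(path: str | Path) -> Corpus:
    """Load and validate a corpus from the documented JSON schema."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CorpusParseError(f"{path}: malformed JSON: {exc}") from exc
    return corpus_from_dict(doc)


def corpus_from_dict(doc: dict) -> Corpus:
    if "families" not in doc:
        raise CorpusParseError("top-level object must contain 'families'")
    families = []
    for fdoc in doc["families"]:
        fid = str(fdoc.get("id", ""))
        melodies = []
        for mdoc in fdoc.get("melodies", []):
            mid = str(mdoc.get("id", "?"))
            phrases = []
            note_pos = 0
            for pdoc in mdoc.get("phrases", []):
                notes = []
                for i, ndoc in enumerate(pdoc.get("notes", [])):
                    where = f"melody {mid}, phrase {pdoc.get('index')}, note {i}"
                    notes.append(
                        Note(
                            onset=_frac_from_json(ndoc["onset"], where),
                            duration=_frac_from_json(ndoc["duration"], where),
                            pitch=int(ndoc["pitch"]),
                        )
                    )
                phrases.append(
                    Phrase(index=int(pdoc["index"]), notes=tuple(notes),
                           start_note_index=note_pos)
                )
                note_pos += len(notes)
            melodies.append(Melody(id=mid, phrases=tuple(phrases), tune_family_id=fid))
        families.append(
            TuneFamily(id=fid, melodies=tuple(melodies), role=fdoc.get("role", "test"))
        )
    return Corpus(families=tuple(families))


def corpus_to_dict(corpus: Corpus) -> dict:
    def frac(x: Fraction) -> list[int]:
        return [x.numerator, x.denominator]

    return {
        "families": [
            {
                "id": f.id,
                "role": f.role,
                "melodies": [
                    {
                        "id": m.id,
                        "phrases": [
                            {
                                "index": p.index,
                                "notes": [
                                    {
                                        "onset": frac(n.onset),
                                        "duration": frac(n.duration),
                                        "pitch": n.pitch,
                                    }
                                    for n in p.notes
                                ],
                            }
                            for p in m.phrases
                        ],
                    }
                    for m in f.melodies
                ],
            }
            for f in corpus.families
        ]
    }


def write_json_corpus(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(corpus_to_dict(corpus), fh, indent=1)


def write_note_table(corpus: Corpus, path: str | Path) -> None:
    """Flat CSV of every note: melody_id, phrase_index, note_index, onset, duration, pitch."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["melody_id", "phrase_index", "note_index", "onset", "duration", "pitch"])
        for m in corpus.melodies():
            for p in m.phrases:
                for k, n in enumerate(p.notes):
                    w.writerow(
                        [m.id, p.index, p.start_note_index + k,
                         str(n.onset), str(n.duration), n.pitch]
                    )
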