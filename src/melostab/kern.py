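"""Minimal Humdrum **kern reader for monophonic, phrase-marked melodies.

Supports the subset of **kern needed for pitch/onset analysis of folk-song
transcriptions: one kern spine, recip durations (with dots), note names with
``#``/``-`` accidentals, ties (merged into single notes), rests (dropped —
the analysis is defined on notes only) and ``{`` ... ``}`` phrase marks.
Anything polyphonic (multiple kern spines or spine splits) is rejected.
"""

from __future__ import annotations

import re
from fractions import Fraction
from pathlib import Path

from .model import Melody, Note, Phrase

_STEP_TO_PC = {"c": 0, "d": 2, "e": 4, "f": 5, "g": 7, "a": 9, "b": 11}

_TOKEN_RE = re.compile(
    r"(?P<dur>\d+)(?P<dots>\.*)"  # recip duration + augmentation dots
    r"(?P<step>[a-gA-G]+|r)"      # note letters or rest
    r"(?P<acc>[#\-n]*)"           # accidentals
)


class KernError(ValueError):
    pass


def _token_pitch(step: str, acc: str) -> int:
    letters = set(step)
    if len(letters) != 1:
        raise KernError(f"mixed note letters in token step {step!r}")
    ch = step[0]
    k = len(step)
    if ch.islower():
        midi = 60 + _STEP_TO_PC[ch] + 12 * (k - 1)
    else:
        midi = 48 + _STEP_TO_PC[ch.lower()] - 12 * (k - 1)
    midi += acc.count("#") - acc.count("-")
    return midi


def _token_duration(dur: str, dots: str) -> Fraction:
    base = int(dur)
    if base == 0:  # breve
        quarters = Fraction(8)
    else:
        quarters = Fraction(4, base)
    add = quarters
    for _ in dots:
        add /= 2
        quarters += add
    return quarters


def read_kern_melody(
    path: str | Path,
    melody_id: str | None = None,
    tune_family_id: str = "",
    phrase_open: str = "{",
    phrase_close: str = "}",
) -> Melody:
    """Parse a monophonic phrase-marked **kern file into a :class:`Melody`.

    Phrase boundaries are taken from the encoded phrase marks
    (``phrase_open``/``phrase_close`` tokens, configurable per dialect); the
    reader trusts them and performs no segmentation of its own.
    """
    path = Path(path)
    if melody_id is None:
        melody_id = path.stem

    lines = path.read_text().splitlines()

    spine_count = None
    onset = Fraction(0)
    # accumulated notes: list of phrases, each a list of Note
    phrases: list[list[Note]] = []
    current: list[Note] | None = None
    tie_open = False

    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("*"):
            if line.startswith("**"):
                kinds = line.split("\t")
                kern_spines = [k for k in kinds if k == "**kern"]
                if len(kinds) != 1 or len(kern_spines) != 1:
                    raise KernError(
                        f"{path}: only a single **kern spine is supported, got {kinds}"
                    )
                spine_count = 1
            elif "*^" in line.split("\t"):
                raise KernError(f"{path}: spine splits (*^) are not supported")
            continue
        if line.startswith("="):
            continue
        if spine_count is None:
            raise KernError(f"{path}: data before **kern interpretation")
        if "\t" in line:
            raise KernError(f"{path}: multiple columns in data line {line!r}; polyphony unsupported")

        token = line
        if token == ".":
            continue
        opens = token.count(phrase_open)
        closes = token.count(phrase_close)
        starts_tie = "[" in token
        ends_tie = "]" in token  # "_" marks a tie middle: the tie stays open
        core = token
        for ch in (phrase_open, phrase_close, "[", "]", "_", "(", ")", ";"):
            core = core.replace(ch, "")
        # strip beaming / ornament cruft
        core = re.sub(r"[LJKkMmTtWwS$O:%@`'\"^~uvxXyY><]", "", core)
        m = _TOKEN_RE.fullmatch(core)
        if m is None:
            raise KernError(f"{path}: cannot parse token {token!r}")
        dur = _token_duration(m.group("dur"), m.group("dots"))
        if m.group("step") == "r":
            onset += dur  # rests advance time but produce no note
            continue
        pitch = _token_pitch(m.group("step"), m.group("acc"))

        if opens:
            if current is not None:
                phrases.append(current)
            current = []
        if current is None:
            raise KernError(
                f"{path}: note outside any phrase mark; supply phrase segmentation "
                f"({phrase_open}...{phrase_close} tokens)"
            )

        if tie_open:
            prev = current[-1] if current else (phrases[-1][-1] if phrases else None)
            if prev is None or prev.pitch != pitch:
                raise KernError(f"{path}: tie continuation with mismatched pitch at {token!r}")
            merged = Note(onset=prev.onset, duration=prev.duration + dur, pitch=pitch)
            if current:
                current[-1] = merged
            else:
                phrases[-1][-1] = merged
            if ends_tie:
                tie_open = False
        else:
            current.append(Note(onset=onset, duration=dur, pitch=pitch))
            if starts_tie:
                tie_open = True
        onset += dur

        if closes:
            phrases.append(current)
            current = None

    if current:
        phrases.append(current)
    if not phrases:
        raise KernError(
            f"{path}: no phrase marks found; supply phrase segmentation "
            f"({phrase_open}...{phrase_close} tokens)"
        )

    out: list[Phrase] = []
    pos = 0
    for i, notes in enumerate(phrases, start=1):
        out.append(Phrase(index=i, notes=tuple(notes), start_note_index=pos))
        pos += len(notes)
    return Melody(id=melody_id, phrases=tuple(out), tune_family_id=tune_family_id)
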