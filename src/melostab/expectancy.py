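"""Variable-order PPM expectancy model over pitch-interval sequences.

A Prediction-by-Partial-Matching model is trained on the interval n-grams
of a background corpus and then frozen (long-term model: query melodies are
never added to the counts).  Prediction blends all context orders by
interpolated smoothing with escape method C — at each order the escape mass
is proportional to the number of distinct continuations seen after that
context — terminating in a uniform order -1 floor over the training
alphabet plus one slot for unseen symbols.  A note's information content is
the natural log (configurable base) of its inverse probability; a phrase's
surprisal is the mean information content of its notes with defined
intervals, using whole-melody context across phrase boundaries.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .model import Corpus, Melody, Phrase, pitch_intervals
from .predictors import UndefinedFeatureError

DEFAULT_MAX_NGRAM = 9  # mean phrase length in notes; context of up to 8 intervals


class TrainingError(ValueError):
    pass


@dataclass
class PPMModel:
    """Frozen n-gram statistics over interval symbols.

    ``counts`` maps a context tuple (0 to max_ngram-1 intervals) to a
    Counter of next-symbol frequencies; the count of a context is by
    construction the sum of its continuations.
    """

    max_ngram: int = DEFAULT_MAX_NGRAM
    counts: dict[tuple[int, ...], Counter] = field(default_factory=dict)
    alphabet: frozenset[int] = frozenset()
    smoothing: str = "C"

    @property
    def max_context(self) -> int:
        return self.max_ngram - 1

    def probability(self, context: Sequence[int], symbol: int) -> float:
        """PPM-C interpolated probability of ``symbol`` after ``context``.

        Blends orders from min(len(context), max_ngram-1) down to 0, then a
        uniform order -1 distribution over |alphabet| + 1 symbols, so unseen
        symbols keep positive mass and the distribution over the alphabet
        plus a single novel-symbol slot sums to one.
        """
        ctx = tuple(context)[-self.max_context:] if self.max_context > 0 else ()
        return self._p(ctx, symbol)

    def _p(self, ctx: tuple[int, ...], symbol: int) -> float:
        if len(ctx) == 0:
            lower = 1.0 / (len(self.alphabet) + 1)
            cnt = self.counts.get((), None)
        else:
            lower = self._p(ctx[1:], symbol)
            cnt = self.counts.get(ctx, None)
        if not cnt:
            return lower
        total = sum(cnt.values())
        distinct = len(cnt)
        alpha = cnt.get(symbol, 0) / (total + distinct)
        gamma = distinct / (total + distinct)
        return alpha + gamma * lower

    def information_content(self, context: Sequence[int], symbol: int,
                            base: float = math.e) -> float:
        return -math.log(self.probability(context, symbol)) / math.log(base)

    # -- portable serialization (plain JSON count tables) -------------------

    def to_dict(self) -> dict:
        return {
            "max_ngram": self.max_ngram,
            "smoothing": self.smoothing,
            "alphabet": sorted(self.alphabet),
            "counts": [
                [list(ctx), sorted(cnt.items())] for ctx, cnt in sorted(self.counts.items())
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PPMModel":
        counts = {
            tuple(ctx): Counter({int(s): int(c) for s, c in items})
            for ctx, items in doc["counts"]
        }
        return cls(
            max_ngram=int(doc["max_ngram"]),
            counts=counts,
            alphabet=frozenset(int(s) for s in doc["alphabet"]),
            smoothing=doc.get("smoothing", "C"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PPMModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_ppm(
    background: Corpus | Iterable[Melody],
    max_ngram: int = DEFAULT_MAX_NGRAM,
    role: str | None = "background",
) -> PPMModel:
    """Count interval n-grams (orders 1..max_ngram) per melody of the corpus.

    Sequences never continue across melody boundaries.  When ``background``
    is a corpus, only melodies of the given role are used (all melodies if
    ``role`` is None or the corpus has none with that role).
    """
    if isinstance(background, Corpus):
        melodies = list(background.melodies(role))
        if not melodies and role is not None:
            melodies = list(background.melodies(None))
    else:
        melodies = list(background)
    sequences = [
        [iv for _, iv in pitch_intervals(m)] for m in melodies
    ]
    sequences = [s for s in sequences if s]
    if not sequences:
        raise TrainingError("background corpus has no melodies with >= 2 notes")

    counts: dict[tuple[int, ...], Counter] = defaultdict(Counter)
    alphabet: set[int] = set()
    for seq in sequences:
        alphabet.update(seq)
        for j, sym in enumerate(seq):
            for order in range(0, min(j, max_ngram - 1) + 1):
                counts[tuple(seq[j - order:j])][sym] += 1
    return PPMModel(max_ngram=max_ngram, counts=dict(counts),
                    alphabet=frozenset(alphabet))


def note_information(
    melody: Melody, model: PPMModel, base: float = math.e
) -> list[tuple[int, float, float, int]]:
    """Per-note (index, probability, information content, context length) rows.

    The first note has no interval and therefore no entry; every other
    note's symbol is its interval, with the preceding intervals (up to the
    model's maximum context) as conditioning context.
    """
    seq = [iv for _, iv in pitch_intervals(melody)]
    rows = []
    for j, sym in enumerate(seq):
        ctx = seq[max(0, j - model.max_context):j]
        p = model.probability(ctx, sym)
        rows.append((j + 1, p, -math.log(p) / math.log(base), len(ctx)))
    return rows


def surprisal(
    phrase: Phrase, melody: Melody, model: PPMModel, base: float = math.e
) -> float:
    """Mean information content over the phrase's notes with defined intervals.

    Equals the negative log of the geometric mean of the note probabilities.
    The melody's first note is excluded; a phrase's opening note conditions
    on the preceding phrase when one exists.
    """
    info = {idx: ic for idx, _, ic, _ in note_information(melody, model, base)}
    vals = [
        info[phrase.start_note_index + k]
        for k in range(len(phrase))
        if phrase.start_note_index + k in info
    ]
    if not vals:
        raise UndefinedFeatureError(
            f"no notes with defined intervals in phrase {phrase.index}"
        )
    return math.fsum(vals) / len(vals)
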