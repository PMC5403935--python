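"""Synthetic tune families and outcome tables.

Two tiers of simulation, matched to the two halves of the pipeline:

* **Melody level** — tune families built by mutating a prototype melody
  note-by-note (substitution, insertion, deletion), emulating variation
  under oral transmission.  Phrase lengths follow the corpus distribution
  N(9.11, 2.23²) clipped to [3, 26] notes; phrases restate earlier phrases
  with a configurable probability; pitches follow a mostly-stepwise random
  walk.  The mutation log provides lineage ground truth, so occurrence
  annotations are independent of any similarity measure.

* **Feature level** — outcome tables drawn directly from the logistic
  mixed model with configurable slopes and tune-family intercept SD
  (defaults: the published folk-song corpus estimates), for parameter
  recovery without melodic realism.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import Corpus, Melody, Note, Phrase, TuneFamily
from .predictors import FEATURE_NAMES

# Published phrase-length distribution (notes per phrase) and clip range.
PHRASE_LEN_MEAN = 9.11
PHRASE_LEN_SD = 2.23
PHRASE_LEN_RANGE = (3, 26)

# Reference slope estimates (standardized scale) and tune-family intercept SD
# from the folk-song corpus analysis; used as generator defaults so that
# recovery experiments double as a plausibility check of the reported model.
REFERENCE_INTERCEPT = -0.22
REFERENCE_BETA = {
    "length": -0.30,
    "repetition": 0.09,
    "position": -0.10,
    "proximity": 0.10,
    "reversal": 0.05,
    "surprisal": -0.24,
    "motif_repetivity": 0.08,
}
REFERENCE_SIGMA_TF = 0.84

# Corpus-level feature marginals (mean, SD) on the raw scale.
REFERENCE_FEATURE_MARGINALS = {
    "length": (9.11, 2.23),
    "repetition": (1.17, 0.39),
    "position": (3.44, 2.06),
    "proximity": (-2.01, 0.69),
    "reversal": (0.30, 0.24),
    "surprisal": (2.68, 0.53),
    "motif_repetivity": (-0.92, 0.09),
}

_DURATION_GRID = (Fraction(1, 2), Fraction(1), Fraction(3, 2), Fraction(2))
_DURATION_P = (0.35, 0.45, 0.1, 0.1)
_PITCH_FLOOR, _PITCH_CEIL = 48, 90


@dataclass(frozen=True)
class FamilyGenConfig:
    n_families: int = 30
    variants_per_family: int = 6          # families of at least five variants
    phrases_per_melody: int = 6
    phrase_length_mean: float = PHRASE_LEN_MEAN
    phrase_length_sd: float = PHRASE_LEN_SD
    phrase_length_range: tuple[int, int] = PHRASE_LEN_RANGE
    repeat_probability: float = 0.15      # chance a phrase restates an earlier one
    p_sub: float = 0.05
    p_ins: float = 0.02
    p_del: float = 0.02
    substitution_range: int = 2           # semitone half-width of pitch substitutions
    leap_probability: float = 0.12        # random-walk leap frequency in the prototype

    def __post_init__(self) -> None:
        for name in ("repeat_probability", "p_sub", "p_ins", "p_del"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.variants_per_family < 2:
            raise ValueError("variants_per_family must be >= 2")
        if self.phrases_per_melody < 1:
            raise ValueError("phrases_per_melody must be >= 1")


@dataclass(frozen=True)
class OutcomeGenConfig:
    n_phrases: int = 2000
    n_families: int = 150
    variants_per_family: int = 6
    intercept: float = REFERENCE_INTERCEPT
    beta: dict = field(default_factory=lambda: dict(REFERENCE_BETA))
    sigma_tf: float = REFERENCE_SIGMA_TF
    feature_marginals: dict = field(
        default_factory=lambda: dict(REFERENCE_FEATURE_MARGINALS)
    )

    def __post_init__(self) -> None:
        if self.sigma_tf < 0:
            raise ValueError("sigma_tf must be >= 0")


# ---------------------------------------------------------------------------
# Melody-level generation


def _sample_phrase_lengths(config: FamilyGenConfig, rng: np.random.Generator,
                           k: int) -> list[int]:
    lo, hi = config.phrase_length_range
    raw = rng.normal(config.phrase_length_mean, config.phrase_length_sd, size=k)
    return [int(np.clip(round(x), lo, hi)) for x in raw]


def _random_walk_pitches(config: FamilyGenConfig, rng: np.random.Generator,
                         n: int, start: int) -> list[int]:
    """Mostly stepwise contour with occasional leaps, reflected into range."""
    pitches = [start]
    for _ in range(n - 1):
        if rng.random() < config.leap_probability:
            step = int(rng.integers(3, 8))
        else:
            step = int(rng.choice([0, 1, 2], p=[0.15, 0.5, 0.35]))
        if rng.random() < 0.5:
            step = -step
        p = pitches[-1] + step
        if p > _PITCH_CEIL or p < _PITCH_FLOOR:
            p = pitches[-1] - step
        pitches.append(int(np.clip(p, _PITCH_FLOOR, _PITCH_CEIL)))
    return pitches


def _build_melody(melody_id: str, family_id: str,
                  phrase_contents: list[list[tuple[int, Fraction]]]) -> Melody:
    """Assemble a melody from per-phrase (pitch, duration) lists."""
    onset = Fraction(0)
    phrases = []
    pos = 0
    for i, content in enumerate(phrase_contents, start=1):
        notes = []
        for pitch, dur in content:
            notes.append(Note(onset=onset, duration=dur, pitch=pitch))
            onset += dur
        phrases.append(Phrase(index=i, notes=tuple(notes), start_note_index=pos))
        pos += len(notes)
    return Melody(id=melody_id, phrases=tuple(phrases), tune_family_id=family_id)


def _prototype_contents(config: FamilyGenConfig,
                        rng: np.random.Generator) -> list[list[tuple[int, Fraction]]]:
    lengths = _sample_phrase_lengths(config, rng, config.phrases_per_melody)
    contents: list[list[tuple[int, Fraction]]] = []
    start = int(rng.integers(60, 75))
    for i, n in enumerate(lengths):
        if contents and rng.random() < config.repeat_probability:
            contents.append(list(contents[int(rng.integers(0, len(contents)))]))
            continue
        pitches = _random_walk_pitches(config, rng, n, start)
        durs = rng.choice(len(_DURATION_GRID), size=n, p=_DURATION_P)
        contents.append([(p, _DURATION_GRID[d]) for p, d in zip(pitches, durs)])
        start = pitches[-1]
    return contents


def _mutate_phrase(content: list[tuple[int, Fraction]], config: FamilyGenConfig,
                   rng: np.random.Generator) -> tuple[list[tuple[int, Fraction]], int]:
    """Apply per-note substitutions/insertions/deletions; returns (notes, n_mutations)."""
    out: list[tuple[int, Fraction]] = []
    mutations = 0
    for pitch, dur in content:
        if rng.random() < config.p_del:
            mutations += 1
            continue
        if rng.random() < config.p_sub:
            shift = 0
            while shift == 0:
                shift = int(rng.integers(-config.substitution_range,
                                         config.substitution_range + 1))
            pitch = int(np.clip(pitch + shift, _PITCH_FLOOR, _PITCH_CEIL))
            mutations += 1
        out.append((pitch, dur))
        if rng.random() < config.p_ins:
            ins_pitch = int(np.clip(pitch + int(rng.integers(-2, 3)),
                                    _PITCH_FLOOR, _PITCH_CEIL))
            ins_dur = _DURATION_GRID[int(rng.choice(len(_DURATION_GRID), p=_DURATION_P))]
            out.append((ins_pitch, ins_dur))
            mutations += 1
    if not out:  # a phrase never vanishes entirely
        out = [content[0]]
    return out, mutations


def generate_family(
    config: FamilyGenConfig, seed: int, family_id: str = "TF1"
) -> tuple[TuneFamily, dict[tuple[str, int], int]]:
    """One tune family of mutated variants plus its mutation log.

    The log maps ``(melody_id, phrase_index)`` to the number of note-level
    mutations that phrase received relative to the prototype — the lineage
    ground truth used by :func:`generate_annotations`.
    """
    rng = np.random.default_rng(seed)
    proto = _prototype_contents(config, rng)
    melodies = []
    log: dict[tuple[str, int], int] = {}
    for v in range(config.variants_per_family):
        mid = f"{family_id}_v{v + 1}"
        contents = []
        for pi, content in enumerate(proto, start=1):
            mutated, k = _mutate_phrase(content, config, rng)
            contents.append(mutated)
            log[(mid, pi)] = k
        melodies.append(_build_melody(mid, family_id, contents))
    return TuneFamily(id=family_id, melodies=tuple(melodies), role="test"), log


def generate_corpus(
    config: FamilyGenConfig, seed: int, role: str = "test", prefix: str = "TF"
) -> tuple[Corpus, dict[tuple[str, int], int]]:
    """A corpus of ``config.n_families`` generated families with a merged log."""
    rng = np.random.default_rng(seed)
    families = []
    log: dict[tuple[str, int], int] = {}
    for i in range(config.n_families):
        fam, flog = generate_family(
            config, seed=int(rng.integers(0, 2**31 - 1)), family_id=f"{prefix}{i + 1}"
        )
        if role != "test":
            fam = TuneFamily(id=fam.id, melodies=fam.melodies, role=role)
        families.append(fam)
        log.update(flog)
    return Corpus(families=tuple(families)), log


def random_phrases(n: int, seed: int,
                   config: FamilyGenConfig | None = None) -> list[Phrase]:
    """A flat sample of n phrases drawn from freshly generated melodies."""
    config = config or FamilyGenConfig()
    rng = np.random.default_rng(seed)
    phrases: list[Phrase] = []
    while len(phrases) < n:
        contents = _prototype_contents(config, rng)
        melody = _build_melody("tmp", "tmp", contents)
        phrases.extend(melody.phrases)
    return phrases[:n]


def generate_annotations(
    family: TuneFamily,
    log: dict[tuple[str, int], int],
    max_mutations: int = 2,
) -> list[tuple[Phrase, Melody, Melody, bool]]:
    """Lineage-based occurrence annotations for threshold calibration.

    For each (query phrase, target variant) pair the label is true iff the
    query phrase and the target's corresponding phrase together received at
    most ``max_mutations`` mutations — ground truth from the generation
    log, independent of any similarity score.  Returns
    ``(query_phrase, source_melody, target_melody, label)`` tuples.
    """
    if not log:
        raise ValueError("missing mutation log; annotations need generation lineage")
    out = []
    for source in family.melodies:
        for phrase in source.phrases:
            for target in family.melodies:
                if target.id == source.id:
                    continue
                key_q = (source.id, phrase.index)
                key_t = (target.id, phrase.index)
                if key_q not in log or key_t not in log:
                    raise ValueError(f"mutation log lacks entries for {key_q} / {key_t}")
                label = log[key_q] + log[key_t] <= max_mutations
                out.append((phrase, source, target, label))
    return out


# ---------------------------------------------------------------------------
# Feature-level generation (outcome tables straight from the logistic GLMM)


def generate_outcomes(config: OutcomeGenConfig, seed: int) -> pd.DataFrame:
    """Sample an outcome table from the random-intercept logistic model.

    Phrases get independent standardized features; each phrase contributes
    one row per comparison variant (``variants_per_family - 1``), sharing
    its features and its family's intercept; outcomes are independent
    Bernoulli draws on the logistic scale.  The result feeds
    :func:`melostab.stability_model.fit_glmm` directly.
    """
    rng = np.random.default_rng(seed)
    n_ph, n_fam = config.n_phrases, config.n_families
    reps = max(config.variants_per_family - 1, 1)

    family_of_phrase = rng.integers(0, n_fam, size=n_ph)
    intercepts = rng.normal(0.0, config.sigma_tf, size=n_fam)
    z = rng.standard_normal(size=(n_ph, len(FEATURE_NAMES)))
    beta = np.array([config.beta[f] for f in FEATURE_NAMES])
    eta_phrase = config.intercept + z @ beta + intercepts[family_of_phrase]

    rows = np.repeat(np.arange(n_ph), reps)
    y = rng.random(size=rows.size) < expit(eta_phrase[rows])

    data = {
        "tune_family_id": [f"TF{family_of_phrase[i] + 1}" for i in rows],
        "melody_id": [f"M{i + 1}" for i in rows],
        "phrase_index": np.ones(rows.size, dtype=int),
        "target_melody_id": [f"M{i + 1}_t{k % reps + 1}" for k, i in enumerate(rows)],
        "occurs": y.astype(int),
    }
    for j, name in enumerate(FEATURE_NAMES):
        mean, sd = config.feature_marginals[name]
        data[name] = mean + sd * z[rows, j]
        data[name + "_z"] = z[rows, j]
    return pd.DataFrame(data)
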