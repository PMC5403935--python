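"""End-to-end glue: corpus -> occurrence records -> feature table -> model."""

from __future__ import annotations

import math

import pandas as pd

from . import motifs as motifs_mod
from . import predictors as pred
from .expectancy import PPMModel, surprisal
from .model import Corpus
from .occurrence import OccurrenceRecord, ThresholdSet, detect_family_occurrences
from .predictors import PhraseFeatures, UndefinedFeatureError


def compute_features(
    corpus: Corpus, ppm: PPMModel, role: str | None = "test"
) -> pd.DataFrame:
    """The seven raw predictors for every phrase of the corpus' melodies.

    Predictors that are undefined for a phrase (e.g. surprisal in a
    single-note melody) come back as NaN; the outcome-table builder drops
    and counts such phrases.
    """
    rows = []
    for melody in corpus.melodies(role):
        for phrase in melody.phrases:
            def guarded(fn, *args):
                try:
                    return float(fn(*args))
                except UndefinedFeatureError:
                    return math.nan

            rows.append(
                PhraseFeatures(
                    melody_id=melody.id,
                    phrase_index=phrase.index,
                    length=float(pred.phrase_length(phrase)),
                    repetition=float(pred.phrase_repetition(phrase, melody)),
                    position=float(pred.phrase_position(phrase)),
                    proximity=guarded(pred.avg_proximity, phrase, melody),
                    reversal=guarded(pred.avg_reversal, phrase, melody),
                    surprisal=guarded(surprisal, phrase, melody, ppm),
                    motif_repetivity=guarded(motifs_mod.motif_repetivity, phrase),
                ).as_dict()
            )
    return pd.DataFrame(rows)


def detect_occurrences(
    corpus: Corpus, thresholds: ThresholdSet, role: str | None = "test",
    include_source: bool = False,
) -> list[OccurrenceRecord]:
    """Occurrence records for every phrase of every melody in the corpus."""
    records: list[OccurrenceRecord] = []
    for family in corpus.families:
        if role is not None and family.role != role:
            continue
        records.extend(detect_family_occurrences(family, thresholds, include_source))
    return records


def occurrences_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tune_family_id": r.tune_family_id,
            "source_melody_id": r.source_melody_id,
            "phrase_index": r.phrase_index,
            "target_melody_id": r.target_melody_id,
            "cityblock": r.scores.cityblock,
            "alignment": r.scores.alignment,
            "siam": r.scores.siam,
            "occurs": int(r.occurs),
        }
        for r in records
    )
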