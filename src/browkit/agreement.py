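"""Rater-agreement statistics for the emotion-identification validation task.

Raters watch videos and pick one of four labels (neutral, surprised, angry,
other); the intended label is never "other".  Reported statistics: raw and
stratified accuracy, Cohen's kappa of each rater against the intended
labels, Light's kappa (mean pairwise Cohen's kappa) across raters, and the
chance-corrected accuracy (p - 1/k) / (1 - 1/k) commonly used in emotion
recognition, reported for both 3 and 4 answer categories.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RATING_LABELS = ("neutral", "surprised", "angry", "other")
INTENDED_LABELS = ("neutral", "surprised", "angry")

RATING_COLUMNS = ("video_id", "intended", "rater_id", "chosen", "sentence_type")


def validate_rating_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a rating table's schema and invariants; returns it unchanged."""
    missing = [c for c in RATING_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"rating table missing columns {missing}")
    bad = set(table["intended"]) - set(INTENDED_LABELS)
    if bad:
        raise ValueError(f"intended labels outside {INTENDED_LABELS}: {sorted(bad)}")
    bad = set(table["chosen"]) - set(RATING_LABELS)
    if bad:
        raise ValueError(f"chosen labels outside {RATING_LABELS}: {sorted(bad)}")
    if table.duplicated(["video_id", "rater_id"]).any():
        raise ValueError("duplicate (video_id, rater_id) pairs")
    return table


def accuracy(table: pd.DataFrame, stratifier: str | None = None):
    """Fraction of ratings whose chosen label equals the intended one.

    With ``stratifier`` (a column name), returns a Series of per-stratum
    accuracies; an empty stratum is absent (missing), never reported as 0.
    All responses, including "other", count in the denominator.
    """
    if len(table) == 0:
        raise ValueError("rating table is empty")
    correct = table["chosen"] == table["intended"]
    if stratifier is None:
        return float(correct.mean())
    return correct.groupby(table[stratifier]).mean()


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Unweighted Cohen's kappa: (p_o - p_e) / (1 - p_e).

    Chance agreement p_e is the inner product of the two raters' marginal
    label proportions.  Perfect agreement returns exactly 1, including the
    degenerate case of two identical constant raters (p_e = 1), which is
    logged.
    """
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("label sequences must have equal nonzero length")
    p_o = float((a == b).mean())
    pa = a.value_counts(normalize=True)
    pb = b.value_counts(normalize=True)
    p_e = float(sum(pa.get(lbl, 0.0) * pb.get(lbl, 0.0) for lbl in set(pa.index) | set(pb.index)))
    if p_e >= 1.0:
        if p_o == 1.0:
            logger.info("both raters constant and identical; kappa defined as 1")
            return 1.0
        return 0.0  # unreachable for finite tables: p_e = 1 forces p_o = 1
    return (p_o - p_e) / (1.0 - p_e)


def kappa_per_rater(table: pd.DataFrame) -> dict[str, float]:
    """Cohen's kappa of each rater's judgments against the intended labels."""
    out = {}
    for rater, sub in table.groupby("rater_id"):
        out[str(rater)] = cohen_kappa(sub["intended"], sub["chosen"])
    return out


def light_kappa(table: pd.DataFrame) -> float:
    """Light's kappa: mean Cohen's kappa over all unordered rater pairs.

    Raters are aligned on video_id; for each pair, videos missing for either
    rater are dropped pairwise.
    """
    pivot = table.pivot(index="video_id", columns="rater_id", values="chosen")
    raters = list(pivot.columns)
    if len(raters) < 2:
        raise ValueError("Light's kappa requires >= 2 raters")
    kappas = []
    for ra, rb in itertools.combinations(raters, 2):
        pair = pivot[[ra, rb]].dropna()
        kappas.append(cohen_kappa(pair[ra], pair[rb]))
    return float(np.mean(kappas))


def chance_corrected_accuracy(p_correct: float, n_choices: int) -> float:
    """(p_correct - 1/k) / (1 - 1/k): accuracy rescaled so chance maps to 0.

    Affine-increasing in ``p_correct``; negative for below-chance input;
    equals 1 at perfect accuracy for any k >= 2.
    """
    if n_choices < 2:
        raise ValueError("n_choices must be >= 2")
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError("p_correct must lie in [0, 1]")
    chance = 1.0 / n_choices
    return (p_correct - chance) / (1.0 - chance)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero, as report tables print.

    Python's built-in ``round`` rounds ties to even (0.415 -> 0.41); printed
    proportions conventionally round half up (0.415 -> 0.42).
    """
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(exp, rounding=ROUND_HALF_UP))


@dataclass
class AgreementReport:
    """All validation statistics for one rating table."""

    overall_accuracy: float
    accuracy_by_emotion: dict[str, float]
    accuracy_by_sentence_type: dict[str, float]
    kappa_per_rater: dict[str, float]
    light_kappa: float
    chance_corrected: dict[int, float]
    n_ratings: int

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "accuracy_by_emotion": self.accuracy_by_emotion,
            "accuracy_by_sentence_type": self.accuracy_by_sentence_type,
            "kappa_per_rater": self.kappa_per_rater,
            "light_kappa": self.light_kappa,
            "chance_corrected": {str(k): v for k, v in self.chance_corrected.items()},
            "n_ratings": self.n_ratings,
        }


def agreement_report(table: pd.DataFrame) -> AgreementReport:
    """Compute the full validation report from a rating table."""
    validate_rating_table(table)
    acc = accuracy(table)
    return AgreementReport(
        overall_accuracy=acc,
        accuracy_by_emotion=accuracy(table, "intended").to_dict(),
        accuracy_by_sentence_type=accuracy(table, "sentence_type").to_dict(),
        kappa_per_rater=kappa_per_rater(table),
        light_kappa=light_kappa(table) if table["rater_id"].nunique() >= 2 else float("nan"),
        chance_corrected={k: chance_corrected_accuracy(acc, k) for k in (3, 4)},
        n_ratings=len(table),
    )
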