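"""Action-unit data model, prototype-based emotion classification, and
expression scoring.

The Facial Action Coding System (FACS) describes any facial configuration as
a combination of Action Units (AUs), each scored for intensity on a 0-5
scale (0 absent, 1 trace ... 5 maximum).  Basic emotions correspond to
prototypical AU combinations (e.g. happiness = AU6 + AU12 + AU25); a posed
expression is "accurate" when the coded AU pattern matches the prototype of
the emotion the poser intended.

This module provides:

* :class:`AUVector` -- one rater's intensity coding of one face image;
* :class:`PrototypeTable` -- emotion -> prototype AU set, with the matching
  thresholds of the rule-based classifier;
* :func:`score_match` / :func:`classify_expression` -- a deterministic
  coverage-minus-penalty classifier over the prototype table;
* :func:`retain_accurate` -- the retention filter keeping only trials whose
  coded label equals the intended emotion;
* :func:`intensity_indices` -- the three per-expression intensity summaries
  (mean over all prototype AUs, mean over active prototype AUs, max);
* :func:`group_accuracy` -- percentage-accuracy table by group x emotion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The six basic emotions in the fixed tie-break order, plus neutral.
EMOTIONS = ("happiness", "sadness", "fear", "anger", "surprise", "disgust")
NEUTRAL = "neutral"
ALL_LABELS = EMOTIONS + (NEUTRAL,)

#: Full FACS AU id range coded by the human rater.
HUMAN_AU_IDS = tuple(range(1, 46))

#: The 17 AUs for which the automated coder emits continuous intensities.
MACHINE_AU_IDS = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 25, 26, 45)

#: AU45 is a blink, not an expression; it is ignored by the neutral test.
BLINK_AU = 45


class UnknownEmotionError(ValueError):
    """Raised when an emotion label is outside the closed 7-label set."""


@dataclass(frozen=True)
class AUVector:
    """One rater's AU intensity coding of a single face image.

    Parameters
    ----------
    values
        Mapping AU id -> intensity.  AUs absent from the mapping are zero.
        Human intensities are integers 0-5; machine intensities are reals
        in [0, 5].
    rater
        ``"human"`` or ``"machine"``.
    au_id_set
        The ordered AU ids this rater codes.  Keys of ``values`` must be a
        subset.
    """

    values: Mapping[int, float]
    rater: str = "human"
    au_id_set: Sequence[int] = HUMAN_AU_IDS

    def __post_init__(self) -> None:
        if self.rater not in ("human", "machine"):
            raise ValueError(f"unknown rater {self.rater!r}")
        idset = frozenset(self.au_id_set)
        for au, x in self.values.items():
            if au not in idset:
                raise ValueError(f"AU{au} not in the declared AU id set")
            if not 0 <= x <= 5:
                raise ValueError(f"AU{au} intensity {x} outside [0, 5]")
            if self.rater == "human" and x != int(x):
                raise ValueError(f"human intensity for AU{au} must be integer, got {x}")

    def intensity(self, au: int) -> float:
        """Intensity of ``au`` (0 when not coded)."""
        return self.values.get(au, 0)

    def active(self, threshold: float = 1.0) -> frozenset[int]:
        """AU ids with intensity >= ``threshold``."""
        return frozenset(a for a, x in self.values.items() if x >= threshold)


#: EMFACS-style prototype AU combinations for the six basic emotions.
#: Happiness is AU6+AU12+AU25; the remaining entries follow the same
#: Ekman/Friesen prototype conventions.  Neutral is the empty set.
DEFAULT_PROTOTYPES: dict[str, frozenset[int]] = {
    "happiness": frozenset({6, 12, 25}),
    "sadness": frozenset({1, 4, 15}),
    "fear": frozenset({1, 2, 4, 5, 20, 26}),
    "anger": frozenset({4, 5, 7, 23}),
    "surprise": frozenset({1, 2, 5, 26}),
    "disgust": frozenset({9, 15, 16}),
    NEUTRAL: frozenset(),
}


@dataclass(frozen=True)
class PrototypeTable:
    """Emotion -> prototype AU set, plus the classifier's thresholds.

    ``tau_active`` is the intensity at which an AU counts as present
    (default 1, the FACS trace level); ``beta`` penalises active AUs
    outside the prototype; ``s_min`` is the minimum match score below
    which an expression is labelled neutral.
    """

    prototypes: Mapping[str, frozenset[int]] = field(
        default_factory=lambda: dict(DEFAULT_PROTOTYPES)
    )
    tau_active: float = 1.0
    beta: float = 0.5
    s_min: float = 0.5

    def __post_init__(self) -> None:
        if not DEFAULT_PROTOTYPES["happiness"] <= self.prototypes.get("happiness", frozenset()):
            raise ValueError("happiness prototype must contain AUs 6, 12 and 25")
        if self.prototypes.get(NEUTRAL, frozenset()):
            raise ValueError("neutral must map to the empty AU set")

    def prototype(self, emotion: str) -> frozenset[int]:
        if emotion not in self.prototypes:
            raise UnknownEmotionError(f"no prototype for emotion {emotion!r}")
        return frozenset(self.prototypes[emotion])


@dataclass
class ExpressionTrial:
    """Participant x intended-emotion record with both raters' codings."""

    participant_id: str
    intended: str
    human: AUVector
    machine: AUVector | None = None
    coded: str | None = None
    accurate: bool | None = None

    def __post_init__(self) -> None:
        if self.intended not in ALL_LABELS:
            raise UnknownEmotionError(f"unknown intended emotion {self.intended!r}")
        if self.coded is not None:
            if self.coded not in ALL_LABELS:
                raise UnknownEmotionError(f"unknown coded emotion {self.coded!r}")
            self.accurate = self.coded == self.intended


@dataclass(frozen=True)
class IntensitySummary:
    """The three per-expression intensity indices over the prototype AUs."""

    mean_all: float
    mean_active: float
    max_au: float


def score_match(v: AUVector, emotion: str, table: PrototypeTable | None = None) -> float:
    """Score how well the active AUs of ``v`` match an emotion's prototype.

    The score is prototype coverage minus an off-template penalty::

        s = |A ∩ P| / |P|  -  beta * |A \\ P| / max(|A|, 1)

    with ``P`` the prototype AU set and ``A`` the AUs active at
    ``tau_active``.  ``s`` lies in ``[-beta, 1]`` and equals 1 exactly when
    all and only prototype AUs are active.
    """
    table = table or PrototypeTable()
    if emotion == NEUTRAL:
        raise UnknownEmotionError("neutral has no prototype to score against")
    proto = table.prototype(emotion)
    if not proto:
        raise UnknownEmotionError(f"empty prototype for {emotion!r}")
    active = v.active(table.tau_active)
    coverage = len(active & proto) / len(proto)
    penalty = table.beta * len(active - proto) / max(len(active), 1)
    return coverage - penalty


def classify_expression(v: AUVector, table: PrototypeTable | None = None) -> str:
    """Label the expression in ``v`` by best prototype match.

    Returns ``"neutral"`` when no AU other than the blink (AU45) is active,
    or when the best prototype score falls below ``s_min``.  Ties are broken
    by the higher mean intensity over the tied prototypes' AUs, then by the
    fixed emotion order.
    """
    table = table or PrototypeTable()
    active = v.active(table.tau_active) - {BLINK_AU}
    if not active:
        return NEUTRAL
    scores = {e: score_match(v, e, table) for e in EMOTIONS}
    best = max(scores.values())
    if best < table.s_min:
        return NEUTRAL
    tied = [e for e in EMOTIONS if scores[e] == best]
    if len(tied) == 1:
        return tied[0]

    def mean_proto_intensity(e: str) -> float:
        proto = table.prototype(e)
        return sum(v.intensity(a) for a in proto) / len(proto)

    best_intensity = max(mean_proto_intensity(e) for e in tied)
    for e in tied:  # EMOTIONS order is the final tie-break
        if mean_proto_intensity(e) == best_intensity:
            return e
    raise AssertionError("unreachable")


def retain_accurate(trials: Iterable[ExpressionTrial]) -> list[ExpressionTrial]:
    """Keep only trials whose coded label matches the intended emotion.

    Order is preserved; the number of removed trials is logged.
    """
    trials = list(trials)
    kept = [t for t in trials if t.accurate]
    removed = len(trials) - len(kept)
    if removed:
        logger.info("retention filter removed %d of %d trials", removed, len(trials))
    return kept


def intensity_indices(
    v: AUVector, emotion: str, table: PrototypeTable | None = None
) -> IntensitySummary:
    """Compute the three intensity indices of ``v`` for ``emotion``.

    ``mean_all`` averages over every prototype AU (zeros included),
    ``mean_active`` over prototype AUs with non-zero intensity (0 when none
    is active), and ``max_au`` is the single largest prototype-AU intensity.
    For neutral, which has no prototype, the indices run over the full AU
    id set of the vector.
    """
    table = table or PrototypeTable()
    if emotion == NEUTRAL:
        aus: frozenset[int] = frozenset(v.au_id_set)
    else:
        aus = table.prototype(emotion)
        if not aus:
            raise UnknownEmotionError(f"empty prototype for {emotion!r}")
    vals = [v.intensity(a) for a in aus]
    active = [x for x in vals if x > 0]
    return IntensitySummary(
        mean_all=sum(vals) / len(vals),
        mean_active=sum(active) / len(active) if active else 0.0,
        max_au=max(vals) if vals else 0.0,
    )


def group_accuracy(
    trials: Iterable[ExpressionTrial], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Percentage of accurate expressions per BP group x emotion.

    Each cell is ``100 * n_accurate / n_participants`` in that group for
    that emotion; cells with no participants are NaN.  Columns follow the
    fixed emotion order with neutral last, rows the order in which groups
    first appear in ``groups``.
    """
    rows = []
    for t in trials:
        rows.append(
            {
                "participant": t.participant_id,
                "group": groups[t.participant_id],
                "emotion": t.intended,
                "accurate": bool(t.accurate),
            }
        )
    df = pd.DataFrame(rows, columns=["participant", "group", "emotion", "accurate"])
    if df.duplicated(["participant", "emotion"]).any():
        raise ValueError("a participant contributes more than one trial per emotion")
    group_order = list(dict.fromkeys(groups.values()))
    group_n = df.groupby("group")["participant"].nunique()
    n_acc = (
        df.groupby(["group", "emotion"], sort=False)["accurate"]
        .sum()
        .unstack("emotion")
        .reindex(index=group_order, columns=list(ALL_LABELS))
    )
    table = n_acc.div(group_n, axis=0).mul(100.0)
    table.columns.name = None
    return table
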