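"""Synthetic study generator.

The study's raw materials (face photographs and their AU codings) are not
deposited, so end-to-end testing and parameter-recovery experiments run on
synthetic studies whose generative structure encodes the phenomena the
analysis is designed to detect:

* three JNC-7 blood-pressure groups with per-group sampling windows and a
  realistic measurement protocol (4 readings/day x 2 days, first reading of
  each day elevated, so the discard rule matters);
* a logistic accuracy model in continuous SBP -- the probability that a
  participant produces the intended prototype decays with BP at an
  emotion-specific rate, so categorical (group) and continuous (partial
  correlation) analyses share one ground truth;
* intensity dampening -- on correctly produced expressions, prototype AU
  intensities drop by a fixed step per BP group;
* sparse off-template activation (a few incidental AUs at low intensity);
* a machine rater that is a noisy, attenuated, dropout-prone transform of
  the human coding (gain < 1, additive noise, misses low-intensity AUs
  with probability ``p0 * exp(-h)``), mimicking an automated AU detector's
  behaviour on weak expressions.

Every draw flows from one ``numpy`` generator seeded from the config, so a
given (config, seed) reproduces a study exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import bp as bp_mod
from .bp import CATEGORIES, classify_jnc7
from .facs import (
    EMOTIONS,
    NEUTRAL,
    HUMAN_AU_IDS,
    MACHINE_AU_IDS,
    AUVector,
    ExpressionTrial,
    PrototypeTable,
    classify_expression,
)

_TABLE = PrototypeTable()

#: Confusable-emotion table used on the incorrect path: a failed attempt at
#: the key emotion resembles the value emotion's prototype.
CONFUSABLE = {
    "happiness": "surprise",
    "sadness": "fear",
    "fear": "sadness",
    "anger": "disgust",
    "disgust": "anger",
    "surprise": "fear",
}

#: Default per-group BP sampling windows (sbp_lo, sbp_hi, dbp_lo, dbp_hi),
#: centred near the observed group means and kept clear of band boundaries.
DEFAULT_BP_WINDOWS: dict[str, tuple[float, float, float, float]] = {
    "normotensive": (95.0, 111.0, 64.0, 77.0),
    "prehypertensive": (120.0, 131.0, 80.0, 84.0),
    "hypertensive_stage1": (140.0, 147.0, 90.0, 92.0),
}

#: Logistic accuracy model: intended-prototype production probability is
#: invlogit(b0 - b1 * (SBP - 100)/10).  Intercepts/slopes are calibrated
#: once so that group-level accuracies at the groups' mean SBPs fall in the
#: ranges the study design anticipates (happiness near ceiling and flat,
#: sadness/fear/surprise steeply BP-dependent, anger/disgust mildly so).
DEFAULT_ACCURACY_MODEL: dict[str, tuple[float, float]] = {
    "happiness": (6.0, 0.0),
    "sadness": (2.25, 0.85),
    "fear": (0.20, 0.85),
    "anger": (0.95, 0.40),
    "surprise": (2.00, 0.80),
    "disgust": (0.65, 0.20),
}

#: Base mean prototype-AU intensity per emotion (normotensive group).
DEFAULT_INTENSITY_MEANS: dict[str, float] = {
    "happiness": 2.2,
    "sadness": 1.7,
    "fear": 1.7,
    "anger": 1.8,
    "surprise": 2.2,
    "disgust": 2.0,
}

#: Per-group demographic models: (age mean, age sd), P(male), matching the
#: recruited sample's structure so covariate adjustment is exercised.
DEFAULT_AGE_MODEL = {
    "normotensive": (24.42, 6.73),
    "prehypertensive": (30.10, 9.88),
    "hypertensive_stage1": (40.25, 13.47),
}
DEFAULT_MALE_PROB = {
    "normotensive": 11 / 33,
    "prehypertensive": 16 / 21,
    "hypertensive_stage1": 13 / 20,
}


@dataclass
class SyntheticStudyConfig:
    """Full generative parameterisation of one synthetic study."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "normotensive": 33,
            "prehypertensive": 21,
            "hypertensive_stage1": 20,
        }
    )
    seed: int = 0
    bp_windows: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BP_WINDOWS)
    )
    reading_noise_sd: float = 2.0
    first_reading_boost: float = 8.0
    accuracy_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ACCURACY_MODEL)
    )
    intensity_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_MEANS)
    )
    dampening: float = 0.25  # intensity units per BP-group step
    intensity_sd: float = 0.8
    p_noise: float = 0.05  # per-AU off-template activation probability
    machine_gain: float = 0.7
    machine_noise_sd: float = 0.4
    machine_dropout_p0: float = 0.5  # per-AU miss probability p0 * exp(-h)
    image_failure_prob: float = 0.02  # whole-image automated-coder failure
    education_mean: float = 16.2
    education_sd: float = 2.3

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g} must have at least one participant")
        for prob in (self.p_noise, self.machine_dropout_p0, self.image_failure_prob):
            if not 0 <= prob <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for e, mu in self.intensity_means.items():
            if not 0 <= mu <= 5:
                raise ValueError(f"intensity mean for {e} outside [0, 5]")
        for g, (slo, shi, dlo, dhi) in self.bp_windows.items():
            if classify_jnc7(slo, dlo) != g or classify_jnc7(shi, dhi) != g:
                raise ValueError(f"BP window for {g} leaves its JNC-7 band")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticStudy:
    """One generated study: three table payloads plus the ground truth."""

    participants: pd.DataFrame
    human: pd.DataFrame
    machine: pd.DataFrame
    truth: dict
    trials: list = field(default_factory=list)


def _invlogit(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_participants(
    cfg: SyntheticStudyConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw participants with 8 BP readings, demographics, and group labels.

    The first reading of each day is boosted (the discard rule removes it);
    targets are redrawn until the six-reading mean classifies back into the
    intended group, so the generated labels are exact ground truth.
    """
    rng = rng if rng is not None else cfg.rng()
    rows = []
    pid = 0
    for group in CATEGORIES:
        n = cfg.group_sizes.get(group, 0)
        slo, shi, dlo, dhi = cfg.bp_windows[group]
        age_mu, age_sd = DEFAULT_AGE_MODEL[group]
        for _ in range(n):
            pid += 1
            while True:
                sbp_t = rng.uniform(slo, shi)
                dbp_t = rng.uniform(dlo, dhi)
                readings = {}
                kept_s, kept_d = [], []
                for day in (1, 2):
                    for idx in range(1, 5):
                        boost = cfg.first_reading_boost if idx == 1 else 0.0
                        s = sbp_t + boost + rng.normal(0, cfg.reading_noise_sd)
                        d = dbp_t + boost / 2 + rng.normal(0, cfg.reading_noise_sd)
                        d = min(d, s - 5.0)
                        readings[f"d{day}_sbp{idx}"] = round(s, 1)
                        readings[f"d{day}_dbp{idx}"] = round(d, 1)
                        if idx != 1:
                            kept_s.append(readings[f"d{day}_sbp{idx}"])
                            kept_d.append(readings[f"d{day}_dbp{idx}"])
                mean_s = sum(kept_s) / 6.0
                mean_d = sum(kept_d) / 6.0
                if classify_jnc7(mean_s, mean_d) == group:
                    break
            age = float(np.clip(rng.normal(age_mu, age_sd), 18, 65))
            rows.append(
                {
                    "participant_id": f"P{pid:03d}",
                    "age": round(age, 1),
                    "gender": "male" if rng.random() < DEFAULT_MALE_PROB[group] else "female",
                    "education_years": round(float(np.clip(rng.normal(cfg.education_mean, cfg.education_sd), 8, 22)), 1),
                    **readings,
                    "true_group": group,
                    "true_sbp": mean_s,
                    "true_dbp": mean_d,
                }
            )
    return pd.DataFrame(rows)


def generate_expression(
    sbp: float,
    group: str,
    emotion: str,
    cfg: SyntheticStudyConfig,
    rng: np.random.Generator,
) -> tuple[dict[int, int], bool]:
    """Generate one human AU coding and its latent correctness.

    On the correct path all prototype AUs activate at dampened intensities
    (clamped to 1-5); on the incorrect path either a sub-threshold partial
    prototype or the confusable emotion's prototype is produced.  Neutral
    is a near-zero vector with only incidental noise AUs.
    """
    g = CATEGORIES.index(group)
    values: dict[int, int] = {}
    if emotion == NEUTRAL:
        for au in HUMAN_AU_IDS:
            if au != 45 and rng.random() < cfg.p_noise:
                values[au] = 1
        return values, True

    proto = sorted(_TABLE.prototype(emotion))
    b0, b1 = cfg.accuracy_model[emotion]
    p_correct = _invlogit(b0 - b1 * (sbp - 100.0) / 10.0)
    correct = bool(rng.random() < p_correct)
    mu = cfg.intensity_means[emotion] - cfg.dampening * g

    def draw_intensity() -> int:
        return int(np.clip(round(rng.normal(mu, cfg.intensity_sd)), 1, 5))

    if correct:
        target_aus = proto
    else:
        if rng.random() < 0.5:
            # partial prototype, strictly below the classifier's s_min
            max_size = max(1, int(np.ceil(len(proto) / 2)) - 1)
            size = int(rng.integers(1, max_size + 1))
            target_aus = sorted(rng.choice(proto, size=size, replace=False).tolist())
        else:
            target_aus = sorted(_TABLE.prototype(CONFUSABLE[emotion]))
    for au in target_aus:
        values[au] = draw_intensity()
    # sparse off-template activation; kept off the intended prototype so the
    # latent correctness label always matches the rule-based classifier
    proto_set = set(proto)
    for au in HUMAN_AU_IDS:
        if au == 45 or au in values or au in proto_set:
            continue
        if rng.random() < cfg.p_noise:
            values[au] = int(rng.integers(1, 3))
    if correct and classify_expression(AUVector(values), _TABLE) != emotion:
        # incidental AUs can in rare cases outvote the prototype; strip them
        values = {au: values[au] for au in proto}
    return values, correct


def simulate_machine_rating(
    human: Mapping[int, float],
    cfg: SyntheticStudyConfig,
    rng: np.random.Generator,
) -> dict[int, float]:
    """Automated-coder transform of a human coding over the machine AU set.

    Per AU with human intensity h: dropped to 0 with probability
    ``p0 * exp(-h)``; otherwise ``clamp(gain * h + N(0, sd), 0, 5)``.
    """
    out: dict[int, float] = {}
    for au in MACHINE_AU_IDS:
        h = float(human.get(au, 0))
        if rng.random() < cfg.machine_dropout_p0 * np.exp(-h):
            continue
        x = cfg.machine_gain * h + rng.normal(0, cfg.machine_noise_sd)
        x = float(np.clip(x, 0.0, 5.0))
        if x > 0:
            out[au] = round(x, 3)
    return out


def generate_study(cfg: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate a complete study: participants, human and machine codings.

    Each participant poses the six basic emotions plus neutral (7 images).
    The machine payload follows the automated coder's CSV dialect
    (``AU01_r`` ... columns, ``success``/``confidence`` flags); failed
    images get ``success = 0`` and empty intensities.
    """
    rng = cfg.rng()
    participants = generate_participants(cfg, rng)
    human_rows, machine_rows, trials = [], [], []
    for _, p in participants.iterrows():
        for emotion in (*EMOTIONS, NEUTRAL):
            values, correct = generate_expression(
                p["true_sbp"], p["true_group"], emotion, cfg, rng
            )
            hv = AUVector(values)
            coded = classify_expression(hv, _TABLE)
            human_rows.append(
                {
                    "participant_id": p["participant_id"],
                    "emotion_intended": emotion,
                    "emotion_coded": coded,
                    **{f"AU{au:02d}": int(values.get(au, 0)) for au in HUMAN_AU_IDS},
                }
            )
            failed = rng.random() < cfg.image_failure_prob
            if failed:
                machine_rows.append(
                    {
                        "participant_id": p["participant_id"],
                        "emotion_intended": emotion,
                        "confidence": round(float(rng.uniform(0.0, 0.5)), 3),
                        "success": 0,
                        **{f"AU{au:02d}_r": 0.0 for au in MACHINE_AU_IDS},
                    }
                )
                mv = None
            else:
                mvals = simulate_machine_rating(values, cfg, rng)
                machine_rows.append(
                    {
                        "participant_id": p["participant_id"],
                        "emotion_intended": emotion,
                        "confidence": round(float(rng.uniform(0.85, 0.99)), 3),
                        "success": 1,
                        **{f"AU{au:02d}_r": mvals.get(au, 0.0) for au in MACHINE_AU_IDS},
                    }
                )
                mv = AUVector(mvals, rater="machine", au_id_set=MACHINE_AU_IDS)
            trials.append(
                ExpressionTrial(
                    participant_id=p["participant_id"],
                    intended=emotion,
                    human=hv,
                    machine=mv,
                    coded=coded,
                )
            )
    truth = {
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in asdict(cfg).items()
        },
        "group_of": dict(zip(participants["participant_id"], participants["true_group"])),
    }
    return SyntheticStudy(
        participants=participants,
        human=pd.DataFrame(human_rows),
        machine=pd.DataFrame(machine_rows),
        truth=truth,
        trials=trials,
    )
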