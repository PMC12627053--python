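"""Inter-rater agreement panel between human and automated AU codings.

For each face image the human coder assigns integer AU intensities (0-5)
and the automated coder continuous ones; after binning the machine values,
the two raters' codings over a fixed comparison AU set form the paired
ratings on which five complementary indices are computed:

* percent agreement — raw proportion of matching AU scores;
* Cohen's κ — chance correction from each rater's observed marginals;
* Gwet's AC1 — chance correction from mean marginals over the full
  6-category scale, robust to prevalence imbalance;
* Krippendorff's α (ordinal) — coincidence-matrix coefficient with the
  ordinal squared-rank distance metric;
* ICC(3,1) — two-way mixed-model intraclass correlation (consistency by
  default; an absolute-agreement variant is available).

Indices that are undefined on a given image (e.g. κ when both raters are
constant) propagate as ``None`` rather than zero, and group aggregation
reports how many panels were excluded — sparse, low-intensity codings make
such degeneracies informative rather than ignorable (the κ paradox).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .facs import ALL_LABELS, MACHINE_AU_IDS, ExpressionTrial

#: Number of categories on the AU intensity scale (0-5).
N_CATEGORIES = 6


@dataclass(frozen=True)
class PairedRatings:
    """Per-AU (human, binned-machine) rating pairs for one image."""

    pairs: tuple[tuple[int, int], ...]
    n_categories: int = N_CATEGORIES

    def __post_init__(self) -> None:
        for h, m in self.pairs:
            if not (0 <= h < self.n_categories and 0 <= m < self.n_categories):
                raise ValueError(f"rating pair ({h}, {m}) outside 0..{self.n_categories - 1}")

    def __len__(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.asarray(self.pairs, dtype=float).reshape(-1, 2)
        return a[:, 0], a[:, 1]


@dataclass(frozen=True)
class AgreementPanel:
    """The five agreement indices for one paired coding (None = undefined)."""

    percent_agreement: float
    kappa: float | None
    ac1: float | None
    alpha_ordinal: float | None
    icc31: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "percent_agreement": self.percent_agreement,
            "kappa": self.kappa,
            "ac1": self.ac1,
            "alpha_ordinal": self.alpha_ordinal,
            "icc31": self.icc31,
        }


def bin_machine_intensity(x: float) -> int:
    """Bin a continuous 0-5 machine intensity to the integer scale.

    Rounds half away from zero, then clamps to [0, 5].  Negative input is
    an error (upstream ingestion clamps negatives with a warning).
    """
    if x < 0:
        raise ValueError(f"negative machine intensity {x}")
    return min(5, int(math.floor(x + 0.5)))


def percent_agreement(p: PairedRatings) -> float:
    """Percentage of AU pairs on which the two raters match exactly."""
    if not len(p):
        raise ValueError("no rating pairs")
    return 100.0 * sum(h == m for h, m in p.pairs) / len(p)


def _marginals(p: PairedRatings) -> tuple[np.ndarray, np.ndarray]:
    h, m = p.arrays()
    q = p.n_categories
    r1 = np.bincount(h.astype(int), minlength=q) / len(p)
    r2 = np.bincount(m.astype(int), minlength=q) / len(p)
    return r1, r2


def cohens_kappa(p: PairedRatings) -> float | None:
    """Cohen's κ with expected agreement from observed marginals.

    Returns None when both raters are constant on the same category
    (expected agreement 1, κ undefined).
    """
    po = percent_agreement(p) / 100.0
    r1, r2 = _marginals(p)
    pe = float(r1 @ r2)
    if pe >= 1.0:
        return None
    return (po - pe) / (1.0 - pe)


def gwets_ac1(p: PairedRatings) -> float | None:
    """Gwet's AC1 over the full category scale.

    Chance agreement uses mean marginals pi_q = (r1_q + r2_q)/2 and
    pe = sum_q pi_q (1 - pi_q) / (Q - 1), with Q the number of scale
    categories (6 by default) whether or not all were observed.
    """
    po = percent_agreement(p) / 100.0
    r1, r2 = _marginals(p)
    pi = (r1 + r2) / 2.0
    pe = float(np.sum(pi * (1.0 - pi))) / (p.n_categories - 1)
    if pe >= 1.0:
        return None
    return (po - pe) / (1.0 - pe)


def _coincidence(p: PairedRatings) -> np.ndarray:
    """Coincidence matrix over units with two ratings each."""
    q = p.n_categories
    o = np.zeros((q, q))
    for h, m in p.pairs:
        o[h, m] += 1.0
        o[m, h] += 1.0
    return o


def _ordinal_delta2(n_g: np.ndarray) -> np.ndarray:
    """Ordinal squared-distance metric from coincidence value frequencies.

    delta2(c, k) = (sum_{g=c..k} n_g - (n_c + n_k)/2)^2 for c <= k, using
    the marginal frequencies n_g of the coincidence matrix.
    """
    q = len(n_g)
    d2 = np.zeros((q, q))
    for c in range(q):
        for k in range(c + 1, q):
            s = n_g[c : k + 1].sum() - (n_g[c] + n_g[k]) / 2.0
            d2[c, k] = d2[k, c] = s * s
    return d2


def kripp_alpha_ordinal(p: PairedRatings) -> float | None:
    """Krippendorff's α with the ordinal metric, two raters, no missing data.

    α = 1 - D_o/D_e with observed and expected disagreement computed from
    the coincidence matrix; None when D_e == 0 (fewer than two distinct
    values observed).
    """
    if len(p) < 2:
        raise ValueError("need at least two rating pairs")
    o = _coincidence(p)
    n_g = o.sum(axis=0)
    n_total = n_g.sum()
    d2 = _ordinal_delta2(n_g)
    d_o = float((o * d2).sum()) / n_total
    d_e = float((np.outer(n_g, n_g) * d2).sum()) / (n_total * (n_total - 1.0))
    if d_e == 0.0:
        return None
    return 1.0 - d_o / d_e


def icc_3_1(
    human: Sequence[float], machine: Sequence[float], variant: str = "consistency"
) -> float | None:
    """ICC(3,1) from a two-way (units x 2 raters) mean-square decomposition.

    ``consistency`` ignores a constant rater offset; ``absolute`` penalises
    it.  Returns None when the denominator degenerates (no between-unit
    variance).  Accepts unbinned machine values: ICC is not categorical.
    """
    if variant not in ("consistency", "absolute"):
        raise ValueError(f"unknown ICC variant {variant!r}")
    x = np.column_stack([np.asarray(human, float), np.asarray(machine, float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least three units")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if variant == "consistency":
        denom = ms_r + (k - 1) * ms_e
    else:
        denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom <= 0:
        return None
    return float((ms_r - ms_e) / denom)


def panel(
    trial: ExpressionTrial,
    au_set: Sequence[int] = MACHINE_AU_IDS,
    icc_variant: str = "consistency",
    icc_binned: bool = False,
) -> AgreementPanel:
    """All five agreement indices for one trial over ``au_set``.

    Machine intensities are binned for the categorical indices; ICC uses
    the raw continuous values unless ``icc_binned``.
    """
    if trial.machine is None:
        raise ValueError(f"trial {trial.participant_id}/{trial.intended} has no machine coding")
    human = [int(trial.human.intensity(a)) for a in au_set]
    machine_raw = [trial.machine.intensity(a) for a in au_set]
    machine_binned = [bin_machine_intensity(x) for x in machine_raw]
    p = PairedRatings(tuple(zip(human, machine_binned)))
    icc_machine = machine_binned if icc_binned else machine_raw
    try:
        icc = icc_3_1(human, icc_machine, icc_variant)
    except ValueError:
        icc = None
    return AgreementPanel(
        percent_agreement=percent_agreement(p),
        kappa=cohens_kappa(p),
        ac1=gwets_ac1(p),
        alpha_ordinal=kripp_alpha_ordinal(p),
        icc31=icc,
    )


def group_mean_panel(
    trials: Iterable[ExpressionTrial],
    groups: Mapping[str, str],
    au_set: Sequence[int] = MACHINE_AU_IDS,
    icc_variant: str = "consistency",
) -> pd.DataFrame:
    """Mean ± SD of each agreement index per (BP group, emotion) cell.

    ``trials`` must already be retention-filtered.  Trials without a
    machine coding are skipped and counted.  Undefined index values are
    excluded from that index's mean, with per-index exclusion counts in
    ``n_undef_<index>`` columns.  Cells with no trials appear with n = 0
    and NaN statistics (rendered as dashes downstream).
    """
    metrics = ("percent_agreement", "kappa", "ac1", "alpha_ordinal", "icc31")
    rows = []
    for t in trials:
        if t.machine is None:
            rows.append(
                {"group": groups[t.participant_id], "emotion": t.intended, "no_machine": True}
            )
            continue
        rec = panel(t, au_set, icc_variant).as_dict()
        rec.update(group=groups[t.participant_id], emotion=t.intended, no_machine=False)
        rows.append(rec)
    df = pd.DataFrame(rows, columns=["group", "emotion", "no_machine", *metrics])
    group_order = list(dict.fromkeys(groups.values()))
    out = []
    for g in group_order:
        for e in ALL_LABELS:
            cell = df[(df.group == g) & (df.emotion == e)]
            rated = cell[~cell.no_machine]
            rec: dict[str, object] = {
                "group": g,
                "emotion": e,
                "n": len(rated),
                "n_no_machine": int(cell.no_machine.sum()),
            }
            for mname in metrics:
                vals = rated[mname].dropna().astype(float)
                rec[f"{mname}_mean"] = vals.mean() if len(vals) else np.nan
                rec[f"{mname}_sd"] = vals.std(ddof=1) if len(vals) > 1 else (0.0 if len(vals) else np.nan)
                rec[f"n_undef_{mname}"] = int(len(rated) - len(vals))
            out.append(rec)
    return pd.DataFrame(out)


#: Benchmark bands per metric: ordered (upper bound, label); value <= bound.
_BENCHMARKS = {
    "icc": ((0.5, "poor"), (0.75, "moderate"), (0.90, "good"), (1.0, "excellent")),
    "kappa": ((0.60, "weak"), (0.80, "acceptable"), (1.0, "strong")),
    "ac1": ((0.60, "weak"), (0.80, "acceptable"), (1.0, "strong")),
    "alpha": ((0.667, "unacceptable"), (0.80, "acceptable"), (1.0, "good")),
}


def benchmark(value: float, metric: str) -> str:
    """Qualitative reliability label for an index value.

    ICC: <0.5 poor, 0.5-0.75 moderate, 0.75-0.90 good, >0.90 excellent.
    κ/AC1: >0.60 acceptable, >0.80 strong.  α: >0.667 acceptable, >0.80
    good (boundaries belong to the lower band: "above" is strict).
    """
    key = metric.lower()
    if key in ("icc31", "icc(3,1)"):
        key = "icc"
    if key == "alpha_ordinal":
        key = "alpha"
    if key not in _BENCHMARKS:
        raise ValueError(f"unknown metric {metric!r}")
    if value > 1:
        raise ValueError(f"agreement index {value} exceeds 1")
    if key == "icc":
        # "below 0.5 poor" is strict; "above 0.90 excellent" is strict.
        if value < 0.5:
            return "poor"
        if value <= 0.75:
            return "moderate"
        if value <= 0.90:
            return "good"
        return "excellent"
    for bound, label in _BENCHMARKS[key]:
        if value <= bound:
            return label
    return _BENCHMARKS[key][-1][1]
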