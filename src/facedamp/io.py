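"""File formats and the end-to-end analysis pipeline.

Readers parse the three study inputs -- a participants table with the raw
BP readings, the human coder's wide AU table, and the automated coder's
CSV dialect (``AU01_r``-style intensity columns with ``success`` and
``confidence`` flags) -- into the package's in-memory objects.  The
``run_pipeline`` driver chains every stage of the analysis:

1. BP averaging and JNC-7 classification;
2. expression accuracy by group with per-emotion ANCOVA (F, partial eta
   squared, Bonferroni subset letters);
3. retention filtering (only trials whose human-coded label matches the
   intended emotion survive into intensity/agreement analyses);
4. three intensity indices and the five-index human-machine agreement
   panel, aggregated per group x emotion;
5. partial correlations of SBP/DBP with per-emotion accuracy, controlling
   for age, gender and education;

and writes four tidy CSV output tables plus a JSON run log with every
exclusion count, so no record is ever dropped silently.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .agreement import group_mean_panel
from .bp import OUT_OF_RANGE, BPProfile, BPReading
from .facs import (
    ALL_LABELS,
    EMOTIONS,
    HUMAN_AU_IDS,
    MACHINE_AU_IDS,
    NEUTRAL,
    AUVector,
    ExpressionTrial,
    PrototypeTable,
    classify_expression,
    group_accuracy,
    intensity_indices,
    retain_accurate,
)
from .inference import (
    GroupSummary,
    ancova,
    anova_from_summaries,
    bonferroni_subsets,
    chi_square_independence,
    partial_correlation,
)

logger = logging.getLogger(__name__)

_AU_R = re.compile(r"^AU(\d{2})_r$")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and options steering one pipeline run."""

    participants_csv: str | Path = "participants.csv"
    human_csv: str | Path = "human_coding.csv"
    machine_csv: str | Path = "machine_coding.csv"
    out_dir: str | Path | None = None
    au_set: Sequence[int] = MACHINE_AU_IDS
    prototype_table: PrototypeTable = field(default_factory=PrototypeTable)
    icc_variant: str = "consistency"
    alpha: float = 0.05
    seed: int | None = None


def read_prototype_file(path: str | Path) -> PrototypeTable:
    """Parse a prototype override file of ``emotion: au, au, ...`` lines."""
    prototypes: dict[str, frozenset[int]] = {NEUTRAL: frozenset()}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'emotion: au, au, ...'")
        emotion, aus = line.split(":", 1)
        emotion = emotion.strip().lower()
        if emotion not in ALL_LABELS:
            raise ValueError(f"{path}:{lineno}: unknown emotion {emotion!r}")
        ids = frozenset(int(tok) for tok in re.split(r"[,\s]+", aus.strip()) if tok)
        prototypes[emotion] = ids
    return PrototypeTable(prototypes=prototypes)


def read_participants_csv(path: str | Path) -> pd.DataFrame:
    """Read the participants table and derive BP means and JNC-7 category.

    Expects ``participant_id, age, gender, education_years`` plus the raw
    reading columns ``d{1,2}_{sbp,dbp}{1..4}``.  Adds ``mean_sbp``,
    ``mean_dbp`` and ``bp_group`` columns.
    """
    df = pd.read_csv(path)
    needed = ["participant_id", "age", "gender", "education_years"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        readings = []
        for day in (1, 2):
            for idx in range(1, 5):
                readings.append(
                    BPReading(
                        day=day,
                        index_within_day=idx,
                        sbp=float(row[f"d{day}_sbp{idx}"]),
                        dbp=float(row[f"d{day}_dbp{idx}"]),
                    )
                )
        profile = BPProfile.from_readings(readings)
        out.append(
            {
                "participant_id": str(row["participant_id"]),
                "age": float(row["age"]),
                "gender": str(row["gender"]),
                "education_years": float(row["education_years"]),
                "mean_sbp": profile.mean_sbp,
                "mean_dbp": profile.mean_dbp,
                "bp_group": profile.category,
            }
        )
    return pd.DataFrame(out)


def read_human_csv(path: str | Path) -> dict[tuple[str, str], tuple[AUVector, str | None]]:
    """Read the human coder's wide AU table.

    Format: ``participant_id, emotion_intended, emotion_coded, AU01..AU45``
    with integer intensities 0-5.  Returns a map
    ``(participant, intended) -> (AUVector, coded label or None)``.
    Out-of-range or non-integer intensities raise with the cell address.
    """
    df = pd.read_csv(path)
    au_cols = [c for c in df.columns if re.fullmatch(r"AU\d{2}", c)]
    if not au_cols:
        raise ValueError(f"{path}: no AU intensity columns found")
    result: dict[tuple[str, str], tuple[AUVector, str | None]] = {}
    for i, row in df.iterrows():
        values: dict[int, int] = {}
        for c in au_cols:
            raw = row[c]
            x = float(raw)
            if x != int(x) or not 0 <= x <= 5:
                raise ValueError(
                    f"{path}: row {i + 2}, column {c}: invalid human intensity {raw!r}"
                )
            if x:
                values[int(c[2:])] = int(x)
        coded = row.get("emotion_coded")
        coded = None if pd.isna(coded) else str(coded)
        key = (str(row["participant_id"]), str(row["emotion_intended"]))
        result[key] = (AUVector(values), coded)
    return result


def read_openface_csv(path: str | Path) -> tuple[dict[tuple[str, str], AUVector], dict]:
    """Read automated-coder output into machine AU vectors.

    Accepts either a combined CSV carrying ``participant_id`` and
    ``emotion_intended`` manifest columns, or a directory of per-image
    ``<participant>_<emotion>.csv`` files.  Rows with ``success == 0`` are
    excluded and counted; a missing ``success`` column keeps all rows with
    a warning.  Negative intensities clamp to 0 and values above 5 clamp
    to 5, with warnings.  Returns (vectors, stats) where stats counts rows
    read, excluded and clamped.
    """
    path = Path(path)
    stats = {"n_rows": 0, "n_excluded_success": 0, "n_clamped": 0}
    vectors: dict[tuple[str, str], AUVector] = {}

    def ingest(df: pd.DataFrame, key_fn, source: str) -> None:
        au_cols = {c: int(_AU_R.match(c).group(1)) for c in df.columns if _AU_R.match(c)}
        if not au_cols:
            raise ValueError(f"{source}: header has no AU.._r intensity columns")
        has_success = "success" in df.columns
        if not has_success:
            logger.warning("%s: no success column; keeping all rows", source)
        for i, row in df.iterrows():
            stats["n_rows"] += 1
            if has_success and int(row["success"]) == 0:
                stats["n_excluded_success"] += 1
                continue
            values: dict[int, float] = {}
            for c, au in au_cols.items():
                try:
                    x = float(row[c])
                except (TypeError, ValueError) as exc:
                    raise ValueError(f"{source}: row {i + 2}, column {c}: {row[c]!r}") from exc
                if x < 0:
                    logger.warning("%s row %d: negative %s clamped to 0", source, i + 2, c)
                    stats["n_clamped"] += 1
                    x = 0.0
                elif x > 5:
                    logger.warning("%s row %d: %s=%s clamped to 5", source, i + 2, c, x)
                    stats["n_clamped"] += 1
                    x = 5.0
                if x:
                    values[au] = x
            au_id_set = tuple(sorted(au_cols.values()))
            vectors[key_fn(row)] = AUVector(values, rater="machine", au_id_set=au_id_set)

    if path.is_dir():
        for f in sorted(path.glob("*.csv")):
            m = re.fullmatch(r"(.+)_([a-z]+)", f.stem)
            if not m or m.group(2) not in ALL_LABELS:
                raise ValueError(f"{f}: filename does not match <participant>_<emotion>.csv")
            pid, emotion = m.group(1), m.group(2)
            ingest(pd.read_csv(f), lambda row: (pid, emotion), str(f))
    else:
        df = pd.read_csv(path)
        if "participant_id" not in df.columns or "emotion_intended" not in df.columns:
            raise ValueError(
                f"{path}: combined machine CSV needs participant_id and "
                "emotion_intended manifest columns"
            )
        ingest(
            df,
            lambda row: (str(row["participant_id"]), str(row["emotion_intended"])),
            str(path),
        )
    return vectors, stats


def build_trials(
    human: Mapping[tuple[str, str], tuple[AUVector, str | None]],
    machine: Mapping[tuple[str, str], AUVector],
    table: PrototypeTable | None = None,
) -> tuple[list[ExpressionTrial], int]:
    """Join human and machine codings into trials.

    The human label is the gold standard; when a row lacks one, the
    prototype classifier supplies it (logged, and counted in the second
    return value).
    """
    table = table or PrototypeTable()
    trials = []
    n_fallback = 0
    for (pid, intended), (hv, coded) in human.items():
        if coded is None:
            coded = classify_expression(hv, table)
            n_fallback += 1
            logger.info("classifier fallback label for %s/%s: %s", pid, intended, coded)
        trials.append(
            ExpressionTrial(
                participant_id=pid,
                intended=intended,
                human=hv,
                machine=machine.get((pid, intended)),
                coded=coded,
            )
        )
    return trials, n_fallback


def _covariate_matrix(participants: pd.DataFrame) -> np.ndarray:
    gender01 = (participants["gender"].str.lower() == "male").astype(float)
    return np.column_stack(
        [participants["age"].to_numpy(float), gender01.to_numpy(), participants["education_years"].to_numpy(float)]
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def demographics_table(participants: pd.DataFrame) -> pd.DataFrame:
    """Demographics table: per-group summaries with ANOVA / chi-square tests."""
    groups = [g for g in participants["bp_group"].unique()]
    rows = []
    for var in ("age", "education_years", "mean_sbp", "mean_dbp"):
        summaries, rec = [], {"variable": var}
        for g in groups:
            vals = participants.loc[participants.bp_group == g, var]
            summaries.append(GroupSummary(len(vals), float(vals.mean()), float(vals.std(ddof=1))))
            rec[f"{g}_n"] = len(vals)
            rec[f"{g}_mean"] = round(float(vals.mean()), 2)
            rec[f"{g}_sd"] = round(float(vals.std(ddof=1)), 2)
        if len(summaries) >= 2:
            F, df1, df2 = anova_from_summaries(summaries)
            rec.update(test="anova", statistic=round(F, 3), df1=df1, df2=df2,
                       p=float(sps.f.sf(F, df1, df2)))
        rows.append(rec)
    counts = pd.crosstab(participants["bp_group"], participants["gender"]).reindex(groups)
    chi2, df, p = chi_square_independence(counts.to_numpy())
    rec = {"variable": "gender"}
    for g in groups:
        rec[f"{g}_n"] = int(counts.loc[g].sum())
        rec[f"{g}_mean"] = "/".join(f"{c}:{counts.loc[g, c]}" for c in counts.columns)
    rec.update(test="chi_square", statistic=round(chi2, 3), df1=df, df2=np.nan, p=p)
    rows.append(rec)
    return pd.DataFrame(rows)


def accuracy_table(
    trials: Sequence[ExpressionTrial],
    participants: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Accuracy table: accuracy % by group x emotion + ANCOVA per emotion."""
    groups_map = dict(zip(participants["participant_id"], participants["bp_group"]))
    acc = group_accuracy(trials, groups_map)
    cov = _covariate_matrix(participants)
    pid_order = {p: i for i, p in enumerate(participants["participant_id"])}
    rows = []
    for emotion in ALL_LABELS:
        rec = {"emotion": emotion}
        emo_trials = [t for t in trials if t.intended == emotion]
        idx = [pid_order[t.participant_id] for t in emo_trials]
        y = np.array([100.0 if t.accurate else 0.0 for t in emo_trials])
        g = participants["bp_group"].to_numpy()[idx]
        letters = {}
        try:
            res = ancova(y, g, cov[idx])
            _, letters = bonferroni_subsets(y, g, cov[idx], alpha=alpha)
            rec.update(F=round(res.F, 3), df1=res.df1, df2=res.df2, p=res.p,
                       partial_eta2=round(res.partial_eta2, 3))
        except (ValueError, np.linalg.LinAlgError):
            rec.update(F=np.nan, df1=np.nan, df2=np.nan, p=np.nan, partial_eta2=np.nan)
        for grp in acc.index:
            rec[f"{grp}_pct"] = round(acc.loc[grp, emotion], 2)
            rec[f"{grp}_subset"] = letters.get(grp, "")
        rows.append(rec)
    return pd.DataFrame(rows)


def intensity_table(
    trials: Sequence[ExpressionTrial],
    participants: pd.DataFrame,
    table: PrototypeTable,
) -> pd.DataFrame:
    """Per-group intensity summaries (retained trials) with ANCOVA F.

    The mean over active AUs is the headline index; the mean over all
    prototype AUs and the maximum are carried alongside.
    """
    groups_map = dict(zip(participants["participant_id"], participants["bp_group"]))
    pmeta = participants.set_index("participant_id")
    cov_all = _covariate_matrix(participants)
    pid_order = {p: i for i, p in enumerate(participants["participant_id"])}
    rows = []
    for emotion in ALL_LABELS:
        emo = [t for t in trials if t.intended == emotion]
        per_rater: dict[str, dict] = {}
        for rater in ("human", "machine"):
            recs = []
            for t in emo:
                v = t.human if rater == "human" else t.machine
                if v is None:
                    continue
                s = intensity_indices(v, emotion, table)
                recs.append(
                    {
                        "participant_id": t.participant_id,
                        "group": groups_map[t.participant_id],
                        "mean_all": s.mean_all,
                        "mean_active": s.mean_active,
                        "max_au": s.max_au,
                    }
                )
            per_rater[rater] = pd.DataFrame(
                recs, columns=["participant_id", "group", "mean_all", "mean_active", "max_au"]
            )
        for grp in pd.unique(participants["bp_group"]):
            rec = {"emotion": emotion, "group": grp}
            for rater in ("human", "machine"):
                cell = per_rater[rater][per_rater[rater].group == grp]
                rec[f"{rater}_n"] = len(cell)
                for index in ("mean_all", "mean_active", "max_au"):
                    rec[f"{rater}_{index}_mean"] = (
                        round(cell[index].mean(), 3) if len(cell) else np.nan
                    )
                    rec[f"{rater}_{index}_sd"] = (
                        round(cell[index].std(ddof=1), 3) if len(cell) > 1 else
                        (0.0 if len(cell) == 1 else np.nan)
                    )
            rows.append(rec)
        # one ANCOVA per emotion and rater on the headline (active-AU) index
        for rater in ("human", "machine"):
            df = per_rater[rater]
            if df.group.nunique() < 2 or len(df) < df.group.nunique() + 4:
                continue
            idx = [pid_order[p] for p in df.participant_id]
            try:
                res = ancova(df.mean_active.to_numpy(), df.group.to_numpy(), cov_all[idx])
            except (ValueError, np.linalg.LinAlgError):
                continue
            for rec in rows[-len(pd.unique(participants["bp_group"])):]:
                rec[f"{rater}_F"] = round(res.F, 3)
                rec[f"{rater}_F_p"] = res.p
    return pd.DataFrame(rows)


def partial_correlation_table(
    trials: Sequence[ExpressionTrial], participants: pd.DataFrame
) -> pd.DataFrame:
    """Correlation table: partial r of SBP/DBP with per-emotion accuracy."""
    cov = _covariate_matrix(participants)
    pid_order = {p: i for i, p in enumerate(participants["participant_id"])}
    rows = []
    for bp_var in ("mean_sbp", "mean_dbp"):
        rec = {"bp_measure": {"mean_sbp": "SBP", "mean_dbp": "DBP"}[bp_var]}
        for emotion in ALL_LABELS:
            emo = [t for t in trials if t.intended == emotion]
            idx = [pid_order[t.participant_id] for t in emo]
            y = np.array([100.0 if t.accurate else 0.0 for t in emo])
            x = participants[bp_var].to_numpy(float)[idx]
            pc = partial_correlation(x, y, cov[idx])
            if pc is None:
                rec[emotion] = np.nan
                rec[f"{emotion}_p"] = np.nan
                rec[f"{emotion}_sig"] = ""
            else:
                rec[emotion] = round(pc.r, 3)
                rec[f"{emotion}_p"] = pc.p
                rec[f"{emotion}_sig"] = _stars(pc.p)
        rows.append(rec)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns tables and the audit log.

    Result bundle keys: ``table1_demographics``, ``table2_accuracy``,
    ``table3_agreement``, ``table3_intensity``,
    ``table4_partial_correlations`` (DataFrames) and ``log`` (dict).  When
    ``config.out_dir`` is set, each table is written as CSV and the log as
    JSON; partial outputs survive a failing stage.
    """
    out: dict = {}
    log: dict = {"seed": config.seed}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def save(name: str, df: pd.DataFrame) -> None:
        out[name] = df
        if out_dir is not None:
            df.to_csv(out_dir / f"{name}.csv", index=False)

    stage = "read_inputs"
    try:
        participants = read_participants_csv(config.participants_csv)
        oor = participants[participants.bp_group == OUT_OF_RANGE]
        log["n_participants_read"] = len(participants)
        log["n_out_of_range_bp"] = len(oor)
        participants = participants[participants.bp_group != OUT_OF_RANGE].reset_index(drop=True)
        human = read_human_csv(config.human_csv)
        machine, mstats = read_openface_csv(config.machine_csv)
        log.update({f"machine_{k}": v for k, v in mstats.items()})

        stage = "build_trials"
        trials, n_fallback = build_trials(human, machine, config.prototype_table)
        known = set(participants["participant_id"])
        trials = [t for t in trials if t.participant_id in known]
        log["n_label_fallback"] = n_fallback
        log["n_trials"] = len(trials)

        stage = "demographics"
        save("table1_demographics", demographics_table(participants))

        stage = "accuracy_ancova"
        save("table2_accuracy", accuracy_table(trials, participants, config.alpha))

        stage = "retention_filter"
        retained = retain_accurate(trials)
        log["n_retention_removed"] = len(trials) - len(retained)
        log["n_retained"] = len(retained)

        stage = "agreement_panel"
        groups_map = dict(zip(participants["participant_id"], participants["bp_group"]))
        agree = group_mean_panel(retained, groups_map, config.au_set, config.icc_variant)
        save("table3_agreement", agree)
        log["n_agreement_analyzed"] = int(agree["n"].sum())
        log["n_no_machine_retained"] = int(agree["n_no_machine"].sum())
        log["n_undefined_panels"] = {
            m: int(agree[f"n_undef_{m}"].sum())
            for m in ("kappa", "ac1", "alpha_ordinal", "icc31")
        }

        stage = "intensity_indices"
        save("table3_intensity", intensity_table(retained, participants, config.prototype_table))

        stage = "partial_correlations"
        save("table4_partial_correlations", partial_correlation_table(trials, participants))
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # audit: every trial is analyzed, machine-excluded, or retention-removed
    log["audit"] = {
        "n_input_trials": log["n_trials"],
        "n_retention_removed": log["n_retention_removed"],
        "n_no_machine_among_retained": log["n_no_machine_retained"],
        "n_agreement_analyzed": log["n_agreement_analyzed"],
        "balanced": log["n_trials"]
        == log["n_agreement_analyzed"]
        + log["n_no_machine_retained"]
        + log["n_retention_removed"],
    }
    out["log"] = log
    if out_dir is not None:
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out


def write_study(study, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic study's three CSV payloads plus the truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": out_dir / "participants.csv",
        "human": out_dir / "human_coding.csv",
        "machine": out_dir / "machine_coding.csv",
        "truth": out_dir / "ground_truth.json",
    }
    study.participants.drop(columns=["true_group", "true_sbp", "true_dbp"]).to_csv(
        paths["participants"], index=False
    )
    study.human.to_csv(paths["human"], index=False)
    study.machine.to_csv(paths["machine"], index=False)
    paths["truth"].write_text(json.dumps(study.truth, indent=2, default=str))
    return paths
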