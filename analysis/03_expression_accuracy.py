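#!/usr/bin/env python
"""Accuracy of posed expressions by BP group, with per-emotion ANCOVA.

An expression is accurate when the human coder's label matches the emotion
the participant was asked to pose.  Per emotion, a one-way ANCOVA
(covariates: age, gender, education) tests the BP-group effect on the
0/100 accuracy outcome; Bonferroni-corrected post hoc comparisons yield
homogeneous-subset letters.  Writes the accuracy table.
"""

import argparse

from facedamp.io import accuracy_table, build_trials, read_human_csv, read_openface_csv, read_participants_csv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--out", default="results/table2_accuracy.csv")
    args = ap.parse_args()

    parts = read_participants_csv(f"{args.study}/participants.csv")
    human = read_human_csv(f"{args.study}/human_coding.csv")
    machine, _ = read_openface_csv(f"{args.study}/machine_coding.csv")
    trials, _ = build_trials(human, machine)

    tab = accuracy_table(trials, parts)
    tab.to_csv(args.out, index=False)
    cols = [c for c in tab.columns if c.endswith("_pct") or c in ("emotion", "F", "partial_eta2")]
    print(tab[cols].to_string(index=False))
    damp = tab[(tab.p < 0.05)]["emotion"].tolist()
    print(f"\nemotions with a significant BP-group effect: {', '.join(damp) or 'none'}")


if __name__ == "__main__":
    main()
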