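#!/usr/bin/env python
"""Partial correlations of SBP/DBP with per-emotion expression accuracy.

Controls for age, gender and education; two-tailed p values with
conventional stars.  Writes the correlation table.
"""

import argparse

from facedamp.io import (
    build_trials,
    partial_correlation_table,
    read_human_csv,
    read_openface_csv,
    read_participants_csv,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--out", default="results/table4_partial_correlations.csv")
    args = ap.parse_args()

    parts = read_participants_csv(f"{args.study}/participants.csv")
    human = read_human_csv(f"{args.study}/human_coding.csv")
    machine, _ = read_openface_csv(f"{args.study}/machine_coding.csv")
    trials, _ = build_trials(human, machine)

    tab = partial_correlation_table(trials, parts)
    tab.to_csv(args.out, index=False)
    show = ["bp_measure"] + [c for c in tab.columns if "_" not in c or c == "bp_measure"]
    print(tab[[c for c in tab.columns if not c.endswith("_p")]].to_string(index=False))
    neg = [c for c in tab.columns if not c.endswith(("_p", "_sig")) and c != "bp_measure"
           and (tab[c] < 0).all() and (tab[f"{c}_p"] < 0.05).all()]
    print(f"\nemotions negatively related to both SBP and DBP: {', '.join(neg) or 'none'}")


if __name__ == "__main__":
    main()
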