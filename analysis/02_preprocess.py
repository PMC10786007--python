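"""Preprocess the simulated cohorts: gate participants, keep correct trials.

Applies the 60%-accuracy inclusion gate, drops error trials (wrong word,
disfluency, no response), and writes the filtered trial tables plus the
exclusion report with counts and percentages of all administered trials per
session, mirroring how error rates are conventionally reported.
"""

from pathlib import Path

from namerel.trial_data import filter_trials, gate_participants, read_trials, write_trials

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for name in ("exp1", "exp2"):
        trials = read_trials(RESULTS / f"{name}_trials.csv")
        retained, excluded = gate_participants(trials, threshold=0.60)
        kept = trials[trials["participant_id"].isin(retained)]
        correct, report = filter_trials(kept)
        write_trials(correct, RESULTS / f"{name}_correct.csv")
        report.to_csv(RESULTS / f"{name}_exclusions.csv", index=False)
        print(f"{name}: retained {len(retained)}/{trials['participant_id'].nunique()} "
              f"participants; {len(correct)} correct trials")
        for _, row in report[report["response_class"] != "correct"].iterrows():
            print(f"  session {row['session']} {row['response_class']}: "
                  f"n = {row['count']}, {row['percent_of_all_trials']:.2f}% of all trials")


if __name__ == "__main__":
    main()
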