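"""Fit the hierarchical reliability models and grade the correlations.

For each cohort this fits the bivariate hierarchical model of log-latencies
for several splits — even/odd within each session (split-half), first/second
halves within each session, and the between-session split (test-retest /
cross-condition) — summarizes the posterior of the by-participant
random-effect correlation, and grades each estimate with the ROPE bands.
Writes a summary table (estimate, 95% credible bounds, label) per cohort.

Sampler preset: pass "default" as the first CLI argument for the full
4x-longer chains; the reduced preset is used otherwise.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from namerel.reliability_model import ModelSpec, SplitSpec, fit_reliability
from namerel.rope import classify_reliability
from namerel.trial_data import read_trials

RESULTS = Path(__file__).resolve().parents[1] / "results"


def spec_for(preset: str, seed: int) -> ModelSpec:
    return ModelSpec(seed=seed) if preset == "default" else ModelSpec.reduced(seed=seed)


def main() -> None:
    preset = sys.argv[1] if len(sys.argv) > 1 else "reduced"
    rows = []
    for name, between_label in (("exp1", "test-retest"), ("exp2", "cross-condition")):
        correct = read_trials(RESULTS / f"{name}_correct.csv")
        jobs = []
        for session in (1, 2):
            sub = correct[correct["session"] == session]
            jobs.append((f"even_odd (session {session})", sub, SplitSpec("even_odd")))
            jobs.append(
                (f"first_second (session {session})", sub, SplitSpec("first_second"))
            )
        jobs.append((between_label, correct, SplitSpec("session")))
        for k, (label, sub, split) in enumerate(jobs):
            fit = fit_reliability(sub, split, spec_for(preset, seed=9000 + 10 * k))
            s = fit.summary
            grade = classify_reliability(s)
            rows.append(
                {
                    "cohort": name,
                    "model": label,
                    "estimate": round(s.mean, 3),
                    "ci_lower": round(s.ci_low, 3),
                    "ci_upper": round(s.ci_high, 3),
                    "label": grade["label"],
                    "qualifier": grade["qualifier"],
                    "rhat": round(s.diagnostics["rhat"], 3),
                }
            )
            print(
                f"{name} {label}: rho = {s.mean:.3f} "
                f"[{s.ci_low:.3f}, {s.ci_high:.3f}] -> {grade['label']} "
                f"({grade['qualifier']})"
            )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "reliability_summary.csv", index=False)
    (RESULTS / "reliability_summary.json").write_text(
        json.dumps(rows, indent=1)
    )


if __name__ == "__main__":
    main()
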