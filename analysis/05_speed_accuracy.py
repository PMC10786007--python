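"""Speed-accuracy trade-off analysis on the task-variation cohort.

Fits the binomial-link hierarchical accuracy model (separate intercepts and
by-participant effects for the non-speeded and speeded conditions), extracts
per-participant posterior-mean speed and accuracy effects, and estimates the
correlation between them in each condition with the shifted/scaled Beta(3,3)
prior. A positive correlation (slower = more accurate) would indicate a
trade-off; a negative one indicates that faster participants are also more
accurate.
"""

import json
from pathlib import Path

from namerel.bayes_correlation import CorrelationPrior, estimate_correlation
from namerel.reliability_model import (
    AccuracyPriors,
    ModelSpec,
    SplitSpec,
    extract_participant_effects,
    fit_accuracy,
    fit_reliability,
)
from namerel.trial_data import read_trials

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = read_trials(RESULTS / "exp2_trials.csv")
    correct = trials[trials["response_class"] == "correct"]

    speed_fit = fit_reliability(
        correct, SplitSpec("condition"), ModelSpec.reduced(seed=7100)
    )
    acc_fit = fit_accuracy(trials, SplitSpec("condition"), AccuracyPriors(seed=7200))

    out = {}
    for cond in speed_fit.halves:
        speed = extract_participant_effects(speed_fit, "speed", cond)
        accur = extract_participant_effects(acc_fit, "accuracy", cond)
        accur = accur.reindex(speed.index)
        summ = estimate_correlation(
            speed.to_numpy(), accur.to_numpy(), CorrelationPrior(3, 3), seed=7300
        )
        out[cond] = summ.to_dict()
        print(
            f"{cond}: speed-accuracy rho = {summ.mean:.3f} "
            f"[{summ.ci_low:.3f}, {summ.ci_high:.3f}]"
        )
    (RESULTS / "speed_accuracy.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
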