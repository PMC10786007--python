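import subprocess

import numpy as np
import pandas as pd
import pytest

from namerel.reliability_model import (
    AccuracyPriors,
    ModelSpec,
    SplitSpec,
    assign_split,
    extract_participant_effects,
    fit_accuracy,
    fit_reliability,
)
from namerel.synthetic_data import GenerativeParams, simulate_dataset
from namerel.trial_data import filter_trials


class TestAssignSplit:
    def test_even_odd_by_presentation_parity(self, tiny_correct):
        correct, _ = tiny_correct
        out = assign_split(correct, SplitSpec("even_odd"))
        odd = out[out["half"] == "odd"]
        assert (odd["trial_index"] % 2 == 1).all()
        even = out[out["half"] == "even"]
        assert (even["trial_index"] % 2 == 0).all()

    def test_exclusions_do_not_renumber(self):
        df = pd.DataFrame(
            {
                "trial_index": [1, 2, 4, 5],  # index 3 excluded upstream
                "session": [1] * 4,
                "condition": ["nonspeeded"] * 4,
            }
        )
        out = assign_split(df, SplitSpec("even_odd"))
        assert list(out["half"]) == ["odd", "even", "even", "odd"]

    def test_first_second_midpoint(self):
        df = pd.DataFrame(
            {
                "trial_index": np.arange(1, 151),
                "session": [1] * 150,
                "condition": ["nonspeeded"] * 150,
            }
        )
        out = assign_split(df, SplitSpec("first_second"))
        assert (out.loc[out["trial_index"] <= 75, "half"] == "first").all()
        assert (out.loc[out["trial_index"] > 75, "half"] == "second").all()

    def test_session_and_condition_schemes(self, tiny_correct):
        correct, _ = tiny_correct
        out = assign_split(correct, SplitSpec("session"))
        assert set(out["half"]) == {"session1", "session2"}

    def test_condition_mismatch_errors(self, tiny_correct):
        correct, _ = tiny_correct
        one_session = correct[correct["session"] == 1]
        with pytest.raises(ValueError):
            assign_split(one_session, SplitSpec("session"))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec("alternate")


class TestFitReliability:
    def test_near_noise_free_split_half_is_near_one(self):
        params = GenerativeParams(
            n_participants=15, n_items=30, seed=21, sigma=0.01,
            p_disfluency=(0, 0), p_noresponse=(0, 0),
        )
        trials, _ = simulate_dataset(params)
        correct, _ = filter_trials(trials)
        s1 = correct[correct["session"] == 1]
        fit = fit_reliability(s1, SplitSpec("even_odd"), ModelSpec.reduced(seed=1))
        assert fit.summary.mean > 0.95

    def test_posterior_matches_lme4_point_estimate(self, tmp_path):
        # independent cross-check: the frequentist mixed-model correlation
        # (lme4) should fall inside our 95% credible interval
        params = GenerativeParams(n_participants=30, n_items=40, seed=11,
                                  rho_subj=0.8)
        trials, _ = simulate_dataset(params)
        correct, _ = filter_trials(trials)
        fit = fit_reliability(correct, SplitSpec("session"), ModelSpec.reduced(seed=6))

        lab = assign_split(correct, SplitSpec("session"))
        lab = lab.assign(log_lat=np.log(lab["latency_ms"]))
        csv = tmp_path / "fixture.csv"
        lab[["participant_id", "half", "item_id", "log_lat"]].to_csv(csv, index=False)
        rscript = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- lmer(log_lat ~ 0 + half + (0 + half | participant_id)"
            " + (1 | item_id), data=d, REML=TRUE);"
            "cat(attr(VarCorr(m)$participant_id, 'correlation')[1,2])"
        )
        res = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, check=True)
        lmer_rho = float(res.stdout.strip())
        assert fit.summary.ci_low <= lmer_rho <= fit.summary.ci_high
        assert abs(fit.summary.mean - lmer_rho) < 0.2

    def test_summary_invariants_and_draw_support(self, tiny_correct):
        correct, _ = tiny_correct
        fit = fit_reliability(correct, SplitSpec("session"), ModelSpec.reduced(seed=2))
        s = fit.summary
        assert -1 <= s.ci_low <= s.mean <= s.ci_high <= 1
        assert np.all(np.abs(s.draws) <= 1)
        assert {"rhat", "ess", "converged"} <= set(s.diagnostics)

    def test_empty_half_errors(self, tiny_correct):
        correct, _ = tiny_correct
        lab = assign_split(correct, SplitSpec("session"))
        broken = lab[
            ~((lab["participant_id"] == "p001") & (lab["half"] == "session2"))
        ]
        with pytest.raises(ValueError, match="empty half"):
            fit_reliability(broken, SplitSpec("session"), ModelSpec.reduced(seed=3))

    def test_two_participant_degenerate_case_runs(self):
        # constant distinct latencies: participant SD concentrates away from
        # zero and the correlation posterior stays proper (prior dominated)
        rows = []
        for pid, lat in (("a", 700.0), ("b", 1100.0)):
            for s in (1, 2):
                for t in range(1, 11):
                    rows.append(
                        {
                            "participant_id": pid, "session": s,
                            "condition": "nonspeeded", "trial_index": t,
                            "item_id": f"i{s}_{t}", "latency_ms": lat,
                            "response_class": "correct",
                        }
                    )
        df = pd.DataFrame(rows)
        fit = fit_reliability(df, SplitSpec("session"), ModelSpec.reduced(seed=4))
        tau = np.exp(fit.draws["log_tau_1"])
        assert np.quantile(tau, 0.05) > 0.05
        assert -1 <= fit.summary.mean <= 1


@pytest.fixture(scope="module")
def clean_accuracy_fit():
    # error classes that are not wrong-word responses are disabled so the
    # logistic intercept is the estimand being recovered
    params = GenerativeParams(
        seed=33, acc_alpha=(3.0, 3.0), p_disfluency=(0, 0),
        p_noresponse=(0, 0), n_low_accuracy=1, low_accuracy_alpha=-0.5,
    )
    trials, truth = simulate_dataset(params)
    fit = fit_accuracy(trials, SplitSpec("session"), AccuracyPriors(seed=8))
    return params, truth, fit


class TestAccuracyModel:
    def test_intercept_recovery(self, clean_accuracy_fit):
        _, _, fit = clean_accuracy_fit
        for name in ("alpha_1", "alpha_2"):
            assert fit.summaries[name].mean == pytest.approx(3.0, abs=0.4)

    def test_planted_low_accuracy_participant_most_negative(self, clean_accuracy_fit):
        _, truth, fit = clean_accuracy_fit
        eff = extract_participant_effects(fit, "accuracy", "session1")
        assert eff.idxmin() == truth.planted_exclusions[0]

    def test_all_correct_participants_shrink_to_zero(self):
        rows = []
        for p in range(8):
            for s in (1, 2):
                for t in range(1, 31):
                    rows.append(
                        {
                            "participant_id": f"p{p}", "session": s,
                            "condition": "nonspeeded", "trial_index": t,
                            "item_id": f"i{t}", "response_class": "correct",
                        }
                    )
        df = pd.DataFrame(rows)
        fit = fit_accuracy(df, SplitSpec("session"), AccuracyPriors(seed=9))
        eff = extract_participant_effects(fit, "accuracy", "session1")
        assert np.abs(eff).max() < 0.2

    def test_extraction_is_deterministic(self, clean_accuracy_fit):
        _, _, fit = clean_accuracy_fit
        e1 = extract_participant_effects(fit, "accuracy", "session1")
        e2 = extract_participant_effects(fit, "accuracy", "session1")
        pd.testing.assert_series_equal(e1, e2)

    def test_unknown_condition_rejected(self, clean_accuracy_fit):
        _, _, fit = clean_accuracy_fit
        with pytest.raises(ValueError):
            extract_participant_effects(fit, "accuracy", "session9")


class TestExtractSpeedEffects:
    def test_recovery_against_ground_truth(self, study_dataset):
        _, trials, truth = study_dataset
        correct, _ = filter_trials(trials)
        fit = fit_reliability(correct, SplitSpec("session"), ModelSpec.reduced(seed=10))
        eff = extract_participant_effects(fit, "speed", "session1")
        assert list(eff.index) == truth.participant_ids
        r = np.corrcoef(eff.to_numpy(), truth.speed_effects[:, 0])[0, 1]
        assert r >= 0.9

    def test_wrong_fit_type_rejected(self, study_dataset):
        _, trials, truth = study_dataset
        correct, _ = filter_trials(trials)
        fit = fit_reliability(
            correct[correct["session"] == 1], SplitSpec("even_odd"),
            ModelSpec.reduced(seed=12),
        )
        with pytest.raises(TypeError):
            extract_participant_effects(fit, "accuracy", "even")
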