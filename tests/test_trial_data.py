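import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from namerel.trial_data import (
    TRIAL_COLUMNS,
    TrialValidationError,
    classify_response,
    exclusion_report,
    filter_trials,
    gate_participants,
    normalize_word,
    read_trials,
    validate_trials,
    write_trials,
)


def _make_trials(rows):
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _row(pid="p1", session=1, idx=1, cls="correct", onset=500.0, vocal=1300.0,
         target="dog", resp="dog", disfl=False, item="i1"):
    if cls == "no_response":
        vocal, resp = np.nan, ""
    return (pid, session, "nonspeeded", idx, item, target, onset, vocal, resp,
            disfl, cls)


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "target, response, disfluent, present, expected",
        [
            ("dog", "dog", False, True, "correct"),
            ("dog", None, False, False, "no_response"),
            ("dog", "d-dog dog", True, True, "disfluency"),
            ("dog", "cat", False, True, "wrong_word"),
            # precedence: missing onset dominates everything
            ("dog", "cat", True, False, "no_response"),
            # disfluency dominates wrong word
            ("dog", "cat", True, True, "disfluency"),
            # normalization: case, whitespace, leading article
            ("Dog", " the dog ", False, True, "correct"),
            ("dog", "DOG", False, True, "correct"),
        ],
    )
    def test_classification(self, target, response, disfluent, present, expected):
        assert classify_response(target, response, disfluent, present) == expected

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            classify_response("", "dog", False, True)

    def test_normalize_strips_articles_not_infixes(self):
        assert normalize_word("The  Apple") == "apple"
        assert normalize_word("theatre") == "theatre"


class TestValidation:
    def test_round_trip_identity(self, tmp_path, tiny_dataset):
        _, trials, _ = tiny_dataset
        path = tmp_path / "trials.csv"
        write_trials(trials, path)
        back = read_trials(path)
        pd.testing.assert_frame_equal(
            back[TRIAL_COLUMNS].reset_index(drop=True),
            trials[TRIAL_COLUMNS].reset_index(drop=True),
        )
        assert back["response_class"].value_counts().to_dict() == \
            trials["response_class"].value_counts().to_dict()

    def test_well_formed_rows_accepted(self):
        df = _make_trials([_row(idx=1), _row(idx=2), _row(idx=3, cls="no_response")])
        out = validate_trials(df)
        assert len(out) == 3
        assert out.loc[0, "latency_ms"] == 800.0

    def test_vocal_before_picture_rejected(self):
        df = _make_trials([_row(vocal=400.0)])
        with pytest.raises(TrialValidationError, match="non-positive latency"):
            validate_trials(df)

    def test_missing_column_rejected(self):
        df = _make_trials([_row()]).drop(columns=["item_id"])
        with pytest.raises(TrialValidationError, match="item_id"):
            validate_trials(df)

    def test_duplicate_trial_index_rejected(self):
        df = _make_trials([_row(idx=1), _row(idx=1, item="i2")])
        with pytest.raises(TrialValidationError, match="duplicate"):
            validate_trials(df)

    def test_no_response_must_lack_onset(self):
        df = _make_trials([_row(cls="correct")])
        df.loc[0, "vocal_onset_ms"] = np.nan
        with pytest.raises(TrialValidationError, match="no_response"):
            validate_trials(df)


class TestExclusionReport:
    def test_printed_percentage_convention(self):
        # 232 wrong-word trials among 50 x 150 session trials -> 3.09%
        rows = []
        k = 0
        for p in range(50):
            for t in range(150):
                cls = "wrong_word" if k < 232 else "correct"
                k += 1
                rows.append(_row(pid=f"p{p}", idx=t + 1, cls=cls,
                                 resp="cat" if cls == "wrong_word" else "dog"))
        trials = validate_trials(_make_trials(rows))
        report = exclusion_report(trials)
        ww = report[report["response_class"] == "wrong_word"].iloc[0]
        assert ww["count"] == 232
        assert ww["denominator"] == 7500
        assert ww["percent_of_all_trials"] == 3.09

    def test_counts_sum_to_denominator(self, tiny_dataset):
        _, trials, _ = tiny_dataset
        report = exclusion_report(trials)
        for _, grp in report.groupby("session"):
            assert grp["count"].sum() == grp["denominator"].iloc[0]

    def test_percent_times_denominator_matches_count(self, tiny_dataset):
        _, trials, _ = tiny_dataset
        report = exclusion_report(trials)
        recon = report["percent_of_all_trials"] * report["denominator"] / 100
        assert (np.abs(recon - report["count"]) <= report["denominator"] * 5e-5 + 1e-9).all()

    def test_filter_keeps_only_correct_and_is_idempotent(self, tiny_dataset):
        _, trials, _ = tiny_dataset
        correct, report = filter_trials(trials)
        assert (correct["response_class"] == "correct").all()
        again, report2 = filter_trials(correct)
        assert len(again) == len(correct)
        bad = report2[report2["response_class"] != "correct"]
        assert (bad["count"] == 0).all()

    def test_filter_empty_input_errors(self):
        with pytest.raises(ValueError):
            filter_trials(_make_trials([]))

    def test_generator_no_response_rate_recovered(self, study_dataset):
        params, trials, _ = study_dataset
        report = exclusion_report(trials)
        nr = report[report["response_class"] == "no_response"]
        rate = nr["count"].sum() / nr["denominator"].sum()
        p = params.p_noresponse[0]
        # binomial sampling band around the programmed rate, n = 15,000
        se = np.sqrt(p * (1 - p) / nr["denominator"].sum())
        assert abs(rate - p) < 4 * se


class TestGateParticipants:
    def _cohort(self, accuracies):
        rows = []
        for pid, acc in accuracies.items():
            n_correct = int(round(acc * 150))
            for t in range(150):
                cls = "correct" if t < n_correct else "wrong_word"
                rows.append(_row(pid=pid, idx=t + 1, cls=cls,
                                 resp="dog" if cls == "correct" else "cat"))
        return validate_trials(_make_trials(rows))

    def test_below_threshold_excluded_at_threshold_retained(self):
        trials = self._cohort({"low": 0.593, "edge": 0.60, "high": 0.95})
        retained, excluded = gate_participants(trials)
        assert excluded == ["low"]
        assert retained == ["edge", "high"]

    def test_planted_low_accuracy_participant_is_caught(self):
        from namerel.synthetic_data import GenerativeParams, simulate_dataset

        params = GenerativeParams(
            n_participants=12, n_items=60, seed=5, n_low_accuracy=1,
            low_accuracy_alpha=-0.5,
        )
        trials, truth = simulate_dataset(params)
        _, excluded = gate_participants(trials)
        assert excluded == truth.planted_exclusions

    def test_invalid_threshold(self, tiny_dataset):
        _, trials, _ = tiny_dataset
        with pytest.raises(ValueError):
            gate_participants(trials, threshold=1.5)


@given(
    counts=st.lists(
        st.tuples(st.sampled_from(["correct", "wrong_word", "disfluency"]),
                  st.integers(1, 40)),
        min_size=1, max_size=4,
    )
)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_report_percentages_use_full_denominator(counts):
    rows = []
    idx = 1
    for cls, n in counts:
        for _ in range(n):
            rows.append(_row(idx=idx, cls=cls,
                             resp="dog" if cls == "correct" else "cat",
                             disfl=cls == "disfluency"))
            idx += 1
    trials = validate_trials(_make_trials(rows))
    report = exclusion_report(trials)
    total = sum(n for _, n in counts)
    assert (report["denominator"] == total).all()
    assert report["count"].sum() == total
    assert abs(report["percent_of_all_trials"].sum() - 100.0) < 0.05
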