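"""Synthetic trial-level picture-naming data with known ground truth.

The generator emulates a two-session naming study: each of ``n_participants``
names ``n_items`` pictures per session, with lognormal latencies driven by
crossed participant and item random effects,

    log latency = mu[c] + b_subj[p, c] + b_item[i] + eps,   eps ~ N(0, sigma)

where the per-participant speed effects across the two sessions/conditions,
together with the per-participant accuracy effects (log-odds scale), are
drawn from a joint zero-mean Gaussian with a user-specified correlation
structure. Correctness is Bernoulli under a logistic model; disfluencies and
response omissions are planted independently at fixed per-condition rates,
giving the near-ceiling accuracy (~91-96%) typical of good-faith online
naming data. Ground truth (realized effects, planted exclusions) is returned
for parameter-recovery studies.

Defaults reflect the study design the analysis targets: 50 participants x
150 items x 2 sessions, grand mean 6.75 log-ms (~854 ms), between-participant
SD 0.15, between-item SD 0.10, residual SD 0.30, true between-session
correlation 0.77, accuracy grand mean 3.0 log-odds, and disjoint
(counterbalanced two-list) item sets across sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .trial_data import TRIAL_COLUMNS, validate_trials

__all__ = [
    "GenerativeParams",
    "GroundTruth",
    "simulate_dataset",
    "expected_naive_split_correlation",
]


@dataclass(frozen=True)
class GenerativeParams:
    """Design sizes, variance components, and error rates for simulation.

    All latency parameters are on the log-ms scale; accuracy parameters are
    on the log-odds scale. Two-element tuples are per session/condition, in
    the order of ``conditions``.
    """

    n_participants: int = 50
    n_items: int = 150
    conditions: tuple[str, str] = ("nonspeeded", "nonspeeded")
    mu: tuple[float, float] = (6.75, 6.75)
    sd_subj: tuple[float, float] = (0.15, 0.15)
    rho_subj: float = 0.77
    sd_item: float = 0.10
    sigma: float = 0.30
    acc_alpha: tuple[float, float] = (3.0, 3.0)
    acc_sd_subj: tuple[float, float] = (0.5, 0.5)
    rho_speed_acc: tuple[float, float] = (-0.25, -0.25)
    rho_acc_subj: float = 0.6
    p_disfluency: tuple[float, float] = (0.006, 0.006)
    p_noresponse: tuple[float, float] = (0.012, 0.012)
    shared_items: bool = False
    n_low_accuracy: int = 0
    low_accuracy_alpha: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_items < 1:
            raise ValueError("design sizes must be positive")
        for name in ("sd_subj", "acc_sd_subj"):
            if any(s < 0 for s in getattr(self, name)):
                raise ValueError(f"{name} must be nonnegative")
        if self.sd_item < 0 or self.sigma < 0:
            raise ValueError("sd_item and sigma must be nonnegative")
        for name in ("p_disfluency", "p_noresponse"):
            if any(not 0 <= p <= 1 for p in getattr(self, name)):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("rho_subj", "rho_acc_subj"):
            if not -1 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [-1, 1]")
        # validated for positive semi-definiteness in correlation_matrix()
        self.correlation_matrix()

    def correlation_matrix(self) -> np.ndarray:
        """Correlation of the joint participant effect vector (b1, b2, a1, a2).

        Within-condition speed-accuracy correlations and the two
        across-condition correlations are specified directly; the
        cross-condition speed-accuracy terms follow the product (mediation)
        completion corr(b_c, a_c') = rho_subj * rho_speed_acc[c'].
        """
        rb = self.rho_subj
        ra = self.rho_acc_subj
        s1, s2 = self.rho_speed_acc
        R = np.array(
            [
                [1.0, rb, s1, rb * s2],
                [rb, 1.0, rb * s1, s2],
                [s1, rb * s1, 1.0, ra],
                [rb * s2, s2, ra, 1.0],
            ]
        )
        eigmin = np.linalg.eigvalsh(R).min()
        if eigmin < -1e-10:
            raise ValueError(
                f"joint participant-effect correlation matrix is not PSD "
                f"(min eigenvalue {eigmin:.3g}); adjust rho_subj/rho_acc_subj/"
                f"rho_speed_acc"
            )
        return R


@dataclass
class GroundTruth:
    """Realized effects and planted exclusions behind a simulated dataset."""

    participant_ids: list
    speed_effects: np.ndarray  # (n_participants, 2), log-ms
    accuracy_effects: np.ndarray  # (n_participants, 2), log-odds
    item_ids: list  # per-session lists
    item_effects: list  # per-session arrays, log-ms
    planted_exclusions: list
    params: GenerativeParams

    @property
    def realized_speed_correlation(self) -> float:
        """Pearson correlation of the drawn per-participant speed effects."""
        return float(np.corrcoef(self.speed_effects[:, 0], self.speed_effects[:, 1])[0, 1])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "participant_ids": self.participant_ids,
            "speed_effects": self.speed_effects.tolist(),
            "accuracy_effects": self.accuracy_effects.tolist(),
            "item_ids": self.item_ids,
            "item_effects": [e.tolist() for e in self.item_effects],
            "planted_exclusions": self.planted_exclusions,
            "params": asdict(self.params),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _draw_participant_effects(params: GenerativeParams, rng: np.random.Generator):
    sds = np.array(
        [params.sd_subj[0], params.sd_subj[1], params.acc_sd_subj[0], params.acc_sd_subj[1]]
    )
    R = params.correlation_matrix()
    cov = R * np.outer(sds, sds)
    # allow degenerate (zero-variance) components
    z = rng.multivariate_normal(np.zeros(4), cov, size=params.n_participants,
                                method="svd")
    return z[:, :2], z[:, 2:]


def simulate_dataset(params: GenerativeParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a two-session naming dataset; deterministic under params.seed.

    Returns the validated trial table (Trial CSV schema plus ``latency_ms``)
    and the :class:`GroundTruth` bookkeeping.
    """
    rng = np.random.default_rng(params.seed)
    P, I = params.n_participants, params.n_items

    b_speed, a_acc = _draw_participant_effects(params, rng)

    planted = []
    if params.n_low_accuracy:
        low = rng.choice(P, size=params.n_low_accuracy, replace=False)
        for p in low:
            # override so accuracy sits near inv_logit(low_accuracy_alpha)
            a_acc[p, :] = params.low_accuracy_alpha - np.array(params.acc_alpha)
        planted = [f"p{p + 1:03d}" for p in sorted(low)]

    participant_ids = [f"p{p + 1:03d}" for p in range(P)]
    if params.shared_items:
        item_ids = [[f"item{i + 1:03d}" for i in range(I)]] * 2
        g = rng.normal(0.0, params.sd_item, size=I)
        item_effects = [g, g]
    else:
        item_ids = [
            [f"item{i + 1:03d}" for i in range(I)],
            [f"item{i + 1:03d}" for i in range(I, 2 * I)],
        ]
        item_effects = [rng.normal(0.0, params.sd_item, size=I) for _ in range(2)]

    rows = []
    picture_onset = 500.0  # ms after trial start (fixation cross)
    for s in range(2):
        cond = params.conditions[s]
        for p in range(P):
            order = rng.permutation(I)
            eps = rng.normal(0.0, params.sigma, size=I)
            u_class = rng.random(I)
            u_correct = rng.random(I)
            log_lat = params.mu[s] + b_speed[p, s] + item_effects[s][order] + eps
            p_acc = 1.0 / (1.0 + np.exp(-(params.acc_alpha[s] + a_acc[p, s])))
            for t in range(I):
                item = item_ids[s][order[t]]
                target = f"word_{item}"
                lat = float(np.exp(log_lat[t]))
                if u_class[t] < params.p_noresponse[s]:
                    cls, vocal, resp, disfl = "no_response", np.nan, np.nan, False
                elif u_class[t] < params.p_noresponse[s] + params.p_disfluency[s]:
                    cls, vocal, resp, disfl = "disfluency", picture_onset + lat, target, True
                elif u_correct[t] < p_acc:
                    cls, vocal, resp, disfl = "correct", picture_onset + lat, target, False
                else:
                    cls, vocal, resp, disfl = (
                        "wrong_word", picture_onset + lat, f"not_{target}", False,
                    )
                rows.append(
                    (
                        participant_ids[p], s + 1, cond, t + 1, item, target,
                        picture_onset, vocal, resp, disfl, cls,
                    )
                )
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    trials = validate_trials(trials)
    truth = GroundTruth(
        participant_ids=participant_ids,
        speed_effects=b_speed,
        accuracy_effects=a_acc,
        item_ids=item_ids,
        item_effects=item_effects,
        planted_exclusions=planted,
        params=params,
    )
    return trials, truth


def expected_naive_split_correlation(
    params: GenerativeParams,
    n_trials_per_half: int,
    across_conditions: bool = False,
) -> float:
    """Expected Pearson correlation of per-participant mean log-latencies.

    Averaging m trials per half leaves residual noise sigma^2/m on each
    participant mean, attenuating the correlation of the means below the
    correlation of the underlying participant effects:

    - within a condition (both halves drawn from the same session):
      sd_subj^2 / (sd_subj^2 + sigma^2/m); item effects shared by all
      participants shift every mean equally and cancel (exactly so when both
      halves use identical item sets, to a good approximation for random
      even/odd splits);
    - across conditions: rho*sd1*sd2 / sqrt((sd1^2+sigma^2/m)(sd2^2+sigma^2/m)).
    """
    m = n_trials_per_half
    if m < 2:
        raise ValueError("n_trials_per_half must be at least 2")
    noise = params.sigma**2 / m
    s1, s2 = params.sd_subj
    if across_conditions:
        denom = np.sqrt((s1**2 + noise) * (s2**2 + noise))
        if denom == 0:
            raise ValueError("both halves have zero variance")
        return float(params.rho_subj * s1 * s2 / denom)
    if s1 == 0 and noise == 0:
        raise ValueError("zero variance in participant means")
    return float(s1**2 / (s1**2 + noise))
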