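"""Shared posterior-summary container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PosteriorSummary"]


@dataclass
class PosteriorSummary:
    """Mean and 95% equal-tailed credible interval of a scalar posterior.

    ``draws`` holds posterior draws (may be empty for purely analytic
    summaries); ``diagnostics`` carries convergence statistics such as
    split-chain R-hat and effective sample size where applicable.
    """

    mean: float
    ci_low: float
    ci_high: float
    draws: np.ndarray = field(default_factory=lambda: np.empty(0))
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ValueError(
                f"summary ordering violated: {self.ci_low} <= {self.mean} <= {self.ci_high}"
            )

    @classmethod
    def from_draws(cls, draws: np.ndarray, diagnostics: dict | None = None):
        draws = np.asarray(draws, dtype=float).ravel()
        lo, hi = np.quantile(draws, [0.025, 0.975])
        mean = float(draws.mean())
        diagnostics = dict(diagnostics or {})
        if not lo <= mean <= hi:
            # heavy multimodality (e.g. part of an ensemble stuck in a minor
            # mode): widen the interval to keep the summary coherent, and flag
            lo, hi = min(lo, mean), max(hi, mean)
            diagnostics["summary_widened"] = True
            diagnostics["converged"] = False
        return cls(
            mean=mean,
            ci_low=float(lo),
            ci_high=float(hi),
            draws=draws,
            diagnostics=diagnostics,
        )

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "diagnostics": self.diagnostics,
        }
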