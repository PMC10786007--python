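"""End-to-end orchestration: gate -> filter -> split -> fit -> classify -> report.

A run is configured by a YAML file (see :class:`RunConfig`), is a pure
function of (inputs, config, seed) up to timestamps, and writes per-stage
artifacts plus a combined machine-readable JSON report and a human-readable
text summary.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import power as power_mod
from .bayes_correlation import CorrelationPrior, estimate_correlation
from .reliability_model import (
    AccuracyPriors,
    ModelSpec,
    SplitSpec,
    assign_split,
    extract_participant_effects,
    fit_accuracy,
    fit_reliability,
)
from .rope import RopeBands, classify_reliability
from .trial_data import filter_trials, gate_participants, read_trials

__all__ = ["RunConfig", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    """Configuration for a full reliability-analysis run.

    ``splits`` is a list of mappings with a ``scheme`` key plus an optional
    ``session`` or ``condition`` key restricting the trials the model sees
    (within-session split-half models are fit per session). ``power_queries``
    are mappings with rho_true / rel_a / rel_b (optional alpha, power).
    """

    trials_csv: str
    out_dir: str
    seed: int
    splits: list = field(default_factory=lambda: [{"scheme": "even_odd", "session": 1}])
    accuracy_scheme: str | None = None
    speed_accuracy: bool = False
    gate_threshold: float = 0.60
    sampler_preset: str = "default"
    rope_edges: list = field(default_factory=lambda: list(RopeBands().edges))
    rope_labels: list = field(default_factory=lambda: list(RopeBands().labels))
    power_queries: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        cfg = cls(**raw)
        if not Path(cfg.trials_csv).exists():
            raise FileNotFoundError(cfg.trials_csv)
        return cfg

    def model_spec(self, seed: int) -> ModelSpec:
        if self.sampler_preset == "reduced":
            return ModelSpec.reduced(seed=seed)
        if self.sampler_preset == "default":
            return ModelSpec(seed=seed)
        raise ValueError(f"unknown sampler preset {self.sampler_preset!r}")

    def rope_bands(self) -> RopeBands:
        return RopeBands(edges=tuple(self.rope_edges), labels=tuple(self.rope_labels))


def _split_tag(entry: dict) -> str:
    tag = entry["scheme"]
    if "session" in entry:
        tag += f"_session{entry['session']}"
    if "condition" in entry:
        tag += f"_{entry['condition']}"
    return tag


def _subset(trials: pd.DataFrame, entry: dict) -> pd.DataFrame:
    sub = trials
    if "session" in entry:
        sub = sub[sub["session"] == entry["session"]]
    if "condition" in entry:
        sub = sub[sub["condition"] == entry["condition"]]
    if len(sub) == 0:
        raise ValueError(f"split entry {entry} selects no trials")
    return sub


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written to disk).

    Stages: participant gating, correct-trial filtering with exclusion
    report, one hierarchical reliability fit + ROPE classification per
    requested split, optionally the accuracy model and speed-accuracy
    correlations, and any power queries. A stage failure aborts with the
    stage name; artifacts of completed stages are retained and flagged in
    the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bands = config.rope_bands()
    report: dict = {"seed": config.seed, "stages": [], "splits": []}
    manifest = {"completed": [], "failed": None}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:
                manifest["failed"] = {"stage": name, "error": str(exc)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["completed"].append(name)
            report["stages"].append({"stage": name, "seconds": round(time.time() - t0, 2)})
            return result

        return deco

    @stage("read_trials")
    def trials():
        return read_trials(config.trials_csv)

    @stage("gate_participants")
    def gated():
        retained, excluded = gate_participants(trials, threshold=config.gate_threshold)
        report["gating"] = {"retained": len(retained), "excluded": excluded}
        return trials[trials["participant_id"].isin(retained)]

    @stage("filter_trials")
    def filtered():
        correct, excl = filter_trials(gated)
        excl.to_csv(out / "exclusion_report.csv", index=False)
        report["exclusions"] = excl.to_dict(orient="records")
        return correct

    fits = {}
    for k, entry in enumerate(config.splits):
        spec = SplitSpec(entry["scheme"])
        tag = _split_tag(entry)

        @stage(f"fit_reliability[{tag}]")
        def fitted(entry=entry, spec=spec, k=k):
            sub = _subset(filtered, entry)
            return fit_reliability(sub, spec, config.model_spec(seed=config.seed + k))

        fits[tag] = fitted
        cls = classify_reliability(fitted.summary, bands)
        row = {
            "split": tag,
            "estimate": round(fitted.summary.mean, 6),
            "ci_lower": round(fitted.summary.ci_low, 6),
            "ci_upper": round(fitted.summary.ci_high, 6),
            "label": cls["label"],
            "qualifier": cls["qualifier"],
            "diagnostics": fitted.summary.diagnostics,
        }
        report["splits"].append(row)

    if config.accuracy_scheme:
        spec = SplitSpec(config.accuracy_scheme)

        @stage("fit_accuracy")
        def afit():
            pri = AccuracyPriors(seed=config.seed + 101)
            return fit_accuracy(gated, spec, pri)

        report["accuracy"] = {
            name: s.to_dict() for name, s in afit.summaries.items()
        }

        if config.speed_accuracy:
            # speed effects come from the model fit on the same scheme
            tag_candidates = [t for t in fits if t.startswith(config.accuracy_scheme)]
            if not tag_candidates:
                raise RuntimeError(
                    "speed_accuracy requires a reliability split with the same scheme"
                )
            rfit = fits[tag_candidates[0]]

            @stage("speed_accuracy_correlation")
            def sa():
                rows = {}
                for half in rfit.halves:
                    speed = extract_participant_effects(rfit, "speed", half)
                    accur = extract_participant_effects(afit, "accuracy", half)
                    accur = accur.reindex(speed.index)
                    summ = estimate_correlation(
                        speed.to_numpy(), accur.to_numpy(),
                        CorrelationPrior(3, 3), seed=config.seed + 202,
                    )
                    rows[half] = summ.to_dict()
                return rows

            report["speed_accuracy"] = sa

    if config.power_queries:

        @stage("power")
        def pw():
            rows = []
            for q in config.power_queries:
                rho_obs = power_mod.attenuate(q["rho_true"], q["rel_a"], q["rel_b"])
                n = power_mod.required_n(
                    rho_obs, alpha=q.get("alpha", 0.05), power=q.get("power", 0.80)
                )
                rows.append(
                    {
                        **q,
                        "rho_observed": round(rho_obs, 6),
                        "required_n": n,
                        "achieved_power": round(
                            power_mod.power_at_n(rho_obs, n, q.get("alpha", 0.05)), 4
                        ),
                    }
                )
            return rows

        report["power"] = pw

    text, machine = make_report(report)
    # wall-times go to the run log so report.json is byte-stable under a seed
    (out / "run_log.json").write_text(
        json.dumps({"stages": report["stages"]}, indent=1)
    )
    (out / "report.json").write_text(json.dumps(machine, indent=1, sort_keys=True))
    (out / "report.txt").write_text(text)
    manifest["failed"] = None
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return machine


def make_report(report: dict) -> tuple[str, dict]:
    """Render stage outputs as (human-readable text, machine-readable dict).

    The table has one row per fitted split: posterior mean, 95% credible
    bounds, and the graded reliability label. Every number in the text
    appears in the dict.
    """
    lines = ["Reliability analysis report", "=" * 60]
    if "gating" in report:
        g = report["gating"]
        lines.append(
            f"Participants retained: {g['retained']}; excluded: {len(g['excluded'])}"
        )
    if report.get("splits"):
        lines.append("")
        lines.append(f"{'split':<28}{'estimate':>9}{'ci_lower':>9}{'ci_upper':>9}  label")
        for row in sorted(report["splits"], key=lambda r: r["split"]):
            lines.append(
                f"{row['split']:<28}{row['estimate']:>9.3f}{row['ci_lower']:>9.3f}"
                f"{row['ci_upper']:>9.3f}  {row['label']} ({row['qualifier']})"
            )
    if "speed_accuracy" in report:
        lines.append("")
        for half, s in sorted(report["speed_accuracy"].items()):
            lines.append(
                f"speed-accuracy [{half}]: {s['mean']:.3f} "
                f"[{s['ci_low']:.3f}, {s['ci_high']:.3f}]"
            )
    if "power" in report:
        lines.append("")
        for row in report["power"]:
            lines.append(
                f"power: rho_true={row['rho_true']} rel={row['rel_a']}/{row['rel_b']}"
                f" -> rho_obs={row['rho_observed']:.3f}, n={row['required_n']}"
            )
    machine = {k: v for k, v in report.items() if k != "stages"}
    return "\n".join(lines) + "\n", machine
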