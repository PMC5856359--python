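"""Study configuration files: a single YAML document drives a whole study.

Example::

    scenario:
      K: 3
      T: 302
      sigma: 1.0
      delta1: 0.545       # or an explicit means_h1: [0, 0.178, 0.178, 0.545]
      delta0: 0.178
    rules:
      - name: FR
      - name: GI
        discount: 0.995
      - name: TSB
        batch: 20
    calibration:
      reps: 10000
      alpha: 0.05
    study:
      reps: 10000
      seed: 20170628
    output:
      dir: results

The H0 scenario sets every mean to 0; the H1 scenario is the least
favourable configuration (0, delta0, ..., delta0, delta1) unless explicit
means are given.  Unknown keys anywhere are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

from .exceptions import ConfigurationError
from .rules import _ALLOWED_TUNING, RULE_NAMES, RuleSpec
from .trial import TrialConfig

__all__ = ["StudyConfig", "load_config"]

_SCENARIO_KEYS = {"K", "T", "sigma", "delta0", "delta1", "means_h0", "means_h1", "discount", "batch"}
_CALIBRATION_KEYS = {"reps", "alpha"}
_STUDY_KEYS = {"reps", "seed"}
_OUTPUT_KEYS = {"dir"}
_TOP_KEYS = {"scenario", "rules", "calibration", "study", "output"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(f"unknown keys {sorted(unknown)} in {where}; allowed: {sorted(allowed)}")


@dataclass
class StudyConfig:
    K: int
    T: int
    sigma: float = 1.0
    delta1: float = 0.545
    delta0: float = 0.178
    means_h0: Optional[tuple] = None
    means_h1: Optional[tuple] = None
    discount: float = 0.995
    batch: int = 20
    rules: list = field(default_factory=list)
    calibration_reps: int = 10_000
    alpha: float = 0.05
    study_reps: int = 10_000
    seed: int = 0
    output_dir: str = "results"

    def trial_config(self, rule: RuleSpec, hypothesis: str, seed: Optional[int] = None) -> TrialConfig:
        """TrialConfig for one rule under 'H0' or 'H1' (LFC unless explicit)."""
        if hypothesis == "H0":
            means = self.means_h0 or tuple([0.0] * (self.K + 1))
        elif hypothesis == "H1":
            if self.means_h1:
                means = self.means_h1
            elif self.K == 1:
                means = (0.0, self.delta1)
            else:
                means = (0.0,) + (self.delta0,) * (self.K - 1) + (self.delta1,)
        else:
            raise ConfigurationError(f"hypothesis must be 'H0' or 'H1', got {hypothesis!r}")
        return TrialConfig(
            K=self.K,
            T=self.T,
            true_means=means,
            sigma=self.sigma,
            rule=rule,
            discount=rule.tuning.get("discount", self.discount),
            batch_size=self.batch if rule.is_batched else None,
            seed=seed,
        )


def _parse_rule(entry) -> RuleSpec:
    if isinstance(entry, str):
        return RuleSpec(entry)
    if not isinstance(entry, dict) or "name" not in entry:
        raise ConfigurationError(f"each rule needs at least a name: {entry!r}")
    name = entry["name"]
    if name not in RULE_NAMES:
        raise ConfigurationError(f"unknown rule {name!r}")
    tuning = {k: v for k, v in entry.items() if k != "name"}
    _check_keys(tuning, _ALLOWED_TUNING[name], f"rule {name}")
    return RuleSpec(name, tuning)


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    scenario = raw.get("scenario") or {}
    _check_keys(scenario, _SCENARIO_KEYS, "scenario")
    if "K" not in scenario or "T" not in scenario:
        raise ConfigurationError("scenario must define K and T")
    calibration = raw.get("calibration") or {}
    _check_keys(calibration, _CALIBRATION_KEYS, "calibration")
    study = raw.get("study") or {}
    _check_keys(study, _STUDY_KEYS, "study")
    output = raw.get("output") or {}
    _check_keys(output, _OUTPUT_KEYS, "output")

    rules = [_parse_rule(r) for r in raw.get("rules") or []]
    cfg = StudyConfig(
        K=int(scenario["K"]),
        T=int(scenario["T"]),
        sigma=float(scenario.get("sigma", 1.0)),
        delta1=float(scenario.get("delta1", 0.545)),
        delta0=float(scenario.get("delta0", 0.178)),
        means_h0=tuple(scenario["means_h0"]) if "means_h0" in scenario else None,
        means_h1=tuple(scenario["means_h1"]) if "means_h1" in scenario else None,
        discount=float(scenario.get("discount", 0.995)),
        batch=int(scenario.get("batch", 20)),
        rules=rules,
        calibration_reps=int(calibration.get("reps", 10_000)),
        alpha=float(calibration.get("alpha", 0.05)),
        study_reps=int(study.get("reps", 10_000)),
        seed=int(study.get("seed", 0)),
        output_dir=str(output.get("dir", "results")),
    )
    for rule in cfg.rules:
        cfg.trial_config(rule, "H0")  # validates scenario/rule consistency early
    return cfg
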