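"""Single-trial state: arm sufficient statistics, posteriors, outcomes.

Each arm k = 0, .., K (0 = control) has a normally distributed endpoint
``X_k ~ N(mu_k, sigma**2)`` with common known ``sigma``.  Under the improper
uniform prior on ``mu_k`` the posterior after ``n`` observations with sample
mean ``xbar`` is ``N(xbar, sigma**2 / n)``, so ``(xbar, n)`` is a sufficient
statistic and is all that :class:`ArmState` carries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Any, Optional, Sequence

import numpy as np

from .exceptions import InvalidParameterError, UndefinedStateError

__all__ = [
    "ArmState",
    "TrialConfig",
    "TrialResult",
    "posterior",
    "draw_outcome",
    "update_state",
]


@dataclass(frozen=True)
class ArmState:
    """Sufficient statistic (n, running sum) for one arm's posterior."""

    arm_id: int
    n: int = 0
    total: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise InvalidParameterError("observation count cannot be negative")

    @property
    def mean(self) -> float:
        """Sample mean ``total / n``; undefined before the first observation."""
        if self.n == 0:
            raise UndefinedStateError(f"arm {self.arm_id} has no observations yet")
        return self.total / self.n


def update_state(state: ArmState, outcome: float) -> ArmState:
    """Fold one observed outcome into the sufficient statistic."""
    return replace(state, n=state.n + 1, total=state.total + float(outcome))


def posterior(state: ArmState, sigma: float) -> tuple[float, float]:
    """Posterior mean and variance of the arm mean: ``(xbar, sigma**2 / n)``."""
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive")
    if state.n == 0:
        raise UndefinedStateError(
            "no posterior at n=0 under the improper uniform prior; the "
            "allocation layer's initialization rule must run first"
        )
    return state.mean, sigma**2 / state.n


@dataclass(frozen=True)
class TrialConfig:
    """Full specification of one trial scenario and its allocation rule.

    ``true_means`` is ``(mu_0, ..., mu_K)`` with ``mu_0`` the control mean.
    ``discount`` feeds the index-based rules; ``batch_size`` is only
    meaningful for the batched rules (TSB, TPB).
    """

    K: int
    T: int
    true_means: tuple
    sigma: float = 1.0
    rule: Any = None  # RuleSpec; typed loosely to avoid a circular import
    discount: float = 0.995
    batch_size: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.K < 1 or self.T < 1:
            raise InvalidParameterError("K and T must be positive")
        means = tuple(float(m) for m in self.true_means)
        if len(means) != self.K + 1:
            raise InvalidParameterError(
                f"true_means must have K+1 = {self.K + 1} entries, got {len(means)}"
            )
        object.__setattr__(self, "true_means", means)
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be positive")
        if not 0.0 <= self.discount < 1.0:
            raise InvalidParameterError("discount must lie in [0, 1)")
        if self.batch_size is not None:
            if self.batch_size < 1:
                raise InvalidParameterError("batch_size must be positive")
            name = getattr(self.rule, "name", None)
            if name is not None and name not in ("TSB", "TPB"):
                raise InvalidParameterError(
                    f"batch_size is only meaningful for batched rules, not {name}"
                )

    @property
    def n_arms(self) -> int:
        return self.K + 1

    def config_hash(self) -> str:
        """Short stable digest of the scenario, used in output headers."""
        key = repr(
            (
                self.K,
                self.T,
                self.true_means,
                self.sigma,
                getattr(self.rule, "name", None),
                tuple(sorted(getattr(self.rule, "tuning", {}).items())),
                self.discount,
                self.batch_size,
            )
        )
        return hashlib.md5(key.encode()).hexdigest()[:10]


def draw_outcome(arm: int, config: TrialConfig, rng: np.random.Generator) -> float:
    """One endpoint draw ``N(mu_arm, sigma**2)``, consuming one normal deviate."""
    if not 0 <= arm <= config.K:
        raise InvalidParameterError(f"arm id {arm} outside 0..{config.K}")
    return config.true_means[arm] + config.sigma * rng.standard_normal()


@dataclass
class TrialResult:
    """Per-patient record of one trial replicate plus end-of-trial summaries."""

    config: TrialConfig
    allocations: np.ndarray  # (T,) arm ids
    outcomes: np.ndarray  # (T,) observed endpoints
    per_arm: Sequence[ArmState] = field(default_factory=list)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.allocations = np.asarray(self.allocations, dtype=int)
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        if not self.per_arm:
            self.per_arm = self._final_states()

    def _final_states(self) -> list[ArmState]:
        states = []
        for k in range(self.config.n_arms):
            mask = self.allocations == k
            states.append(ArmState(arm_id=k, n=int(mask.sum()), total=float(self.outcomes[mask].sum())))
        return states

    @property
    def arm_counts(self) -> np.ndarray:
        return np.array([s.n for s in self.per_arm])

    def mean_history(self) -> np.ndarray:
        """(T, K+1) running sample means after each patient.

        Entry [t, k] is arm k's sample mean once the first t+1 patients have
        been treated; NaN before the arm's first observation, and carried
        forward while the arm is frozen (its posterior does not move when it
        is not sampled).
        """
        T, m = len(self.allocations), self.config.n_arms
        hist = np.full((T, m), np.nan)
        for k in range(m):
            idx = np.flatnonzero(self.allocations == k)
            if len(idx):
                hist[idx, k] = np.cumsum(self.outcomes[idx]) / np.arange(1, len(idx) + 1)
        # forward-fill frozen arms
        import pandas as pd

        return pd.DataFrame(hist).ffill().to_numpy()

    def to_csv(self, path) -> None:
        """Two-column patient log with a header naming config hash and seed."""
        with open(path, "w") as fh:
            fh.write(f"# config={self.config.config_hash()} seed={self.seed}\n")
            fh.write("allocation,outcome\n")
            for a, y in zip(self.allocations, self.outcomes):
                fh.write(f"{a},{y:.12g}\n")

    @classmethod
    def from_csv(cls, path, config: TrialConfig) -> "TrialResult":
        seed = None
        alloc, out = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    for tok in line.lstrip("#").split():
                        if tok.startswith("seed="):
                            raw = tok[5:]
                            seed = None if raw == "None" else int(raw)
                    continue
                if not line or line.startswith("allocation"):
                    continue
                a, y = line.split(",")
                alloc.append(int(a))
                out.append(float(y))
        return cls(config=config, allocations=np.array(alloc), outcomes=np.array(out), seed=seed)
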