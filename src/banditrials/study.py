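"""Replicated-trial driver: operating characteristics and bias diagnostics.

A *study* runs many independent replicates of one trial configuration and
aggregates, per replicate: the test decision at a supplied critical value,
the proportion of patients on the designated best arm (p*), and the mean
patient outcome (EO).  Under the global null the designated best arm is the
control; under an alternative it is the truly best experimental arm.

Power is reported two ways.  ``type1_or_power`` follows the marginal
best-arm convention: under an alternative it is the probability that the
truly best arm's own Z statistic clears the critical value.  The global
rejection rate (max-Z exceeding the critical value, the quantity that
defines the type I error under the null) is always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError
from .gittins import BUNDLED_DISCOUNTS, GittinsTable, load_table
from .rules import make_allocator
from .trial import ArmState, TrialConfig, TrialResult

__all__ = [
    "StudySummary",
    "BiasTrajectory",
    "run_trial",
    "run_study",
    "bias_trajectories",
    "critical_value_vs_T",
]


def _resolve_table(config: TrialConfig, table: Optional[GittinsTable]) -> Optional[GittinsTable]:
    rule = config.rule
    if rule is None or not getattr(rule, "needs_table", False) or table is not None:
        return table
    d = rule.tuning.get("discount", config.discount)
    if d == 0.0:
        return GittinsTable(0.0, np.array([1]), np.array([0.0]))
    if d in BUNDLED_DISCOUNTS:
        return load_table(d)
    raise ConfigurationError(
        f"rule {rule.name} needs a Gittins table for discount {d}; pass one "
        "explicitly or use compute_gittins_table()"
    )


def run_trial(
    config: TrialConfig,
    table: Optional[GittinsTable] = None,
    rng: Optional[np.random.Generator] = None,
) -> TrialResult:
    """Simulate one trial: sequential allocation, immediate outcomes.

    Draw order within each patient: allocation randomness first (forced
    initialization, perturbations, probability draws, tie-breaks), then the
    outcome deviate.  Equal seeds and configs give identical results.
    """
    seed = config.seed
    rng = np.random.default_rng(seed) if rng is None else rng
    table = _resolve_table(config, table)
    allocator = make_allocator(config, table)
    m, T = config.n_arms, config.T
    mu = np.asarray(config.true_means)
    sigma = config.sigma
    n = np.zeros(m, dtype=int)
    total = np.zeros(m)
    mean = np.zeros(m)
    allocations = np.empty(T, dtype=int)
    outcomes = np.empty(T)
    for t in range(T):
        k = allocator.choose(t, n, mean, rng)
        y = mu[k] + sigma * rng.standard_normal()
        n[k] += 1
        total[k] += y
        mean[k] = total[k] / n[k]
        allocations[t] = k
        outcomes[t] = y
    per_arm = [ArmState(arm_id=k, n=int(n[k]), total=float(total[k])) for k in range(m)]
    return TrialResult(config=config, allocations=allocations, outcomes=outcomes, per_arm=per_arm, seed=seed)


# ---------------------------------------------------------------------------
# replicate-level summaries
# ---------------------------------------------------------------------------


def _hypothesis_label(config: TrialConfig) -> str:
    return "H0" if len(set(config.true_means)) == 1 else "H1"


def _best_arm(config: TrialConfig) -> int:
    """Designated best arm: control under the null, else best experimental."""
    if _hypothesis_label(config) == "H0":
        return 0
    return 1 + int(np.argmax(config.true_means[1:]))


def _spawn_rngs(rng: Optional[np.random.Generator], reps: int) -> list:
    if rng is None:
        rng = np.random.default_rng()
    return rng.spawn(reps)


def _replicate_stats(config, table, rng):
    """(z vector, arm counts, mean outcome) of one replicate."""
    res = run_trial(config, table=table, rng=rng)
    states = res.per_arm
    if states[0].n == 0:
        z = np.full(config.K, np.nan)
    else:
        n0, m0 = states[0].n, states[0].mean
        z = np.array(
            [
                (s.mean - m0) / (config.sigma * np.sqrt(1.0 / s.n + 1.0 / n0)) if s.n else np.nan
                for s in states[1:]
            ]
        )
    return z, res.arm_counts, float(res.outcomes.mean())


def _null_statistics(config, reps, rng=None, table=None, n_jobs: int = 1) -> np.ndarray:
    """Per-replicate Z (K=1) or max-Z (K>=2) under any configuration."""
    table = _resolve_table(config, table)
    rngs = _spawn_rngs(rng, reps)

    def one(r):
        z, _, _ = _replicate_stats(config, table, r)
        return np.nan if np.all(np.isnan(z)) else np.nanmax(z)

    if n_jobs != 1:
        from joblib import Parallel, delayed

        vals = Parallel(n_jobs=n_jobs)(delayed(one)(r) for r in rngs)
        return np.array(vals)
    return np.array([one(r) for r in rngs])


@dataclass
class StudySummary:
    """Operating characteristics aggregated over replicates (one table row)."""

    rule: object
    hypothesis: str
    reps: int
    critical_value: float
    type1_or_power: float
    global_rejection_rate: float
    e_pstar: float
    e_pstar_sd: float
    expected_outcome: float
    expected_outcome_sd: float
    excluded_reps: int = 0
    per_replicate: Optional[dict] = None  # raw arrays, kept on request

    def as_row(self) -> dict:
        return {
            "rule": getattr(self.rule, "name", str(self.rule)),
            "hypothesis": self.hypothesis,
            "reps": self.reps,
            "critical_value": self.critical_value,
            "type1_or_power": self.type1_or_power,
            "global_rejection_rate": self.global_rejection_rate,
            "e_pstar": self.e_pstar,
            "e_pstar_sd": self.e_pstar_sd,
            "expected_outcome": self.expected_outcome,
            "expected_outcome_sd": self.expected_outcome_sd,
            "excluded_reps": self.excluded_reps,
        }


def run_study(
    config: TrialConfig,
    reps: int,
    critical_value: float,
    table: Optional[GittinsTable] = None,
    rng: Optional[np.random.Generator] = None,
    keep_replicates: bool = False,
    n_jobs: int = 1,
) -> StudySummary:
    """Estimate operating characteristics over ``reps`` trial replicates.

    Under the null ``type1_or_power`` is the global rejection rate
    P(max Z > c); under an alternative it is the best-arm rejection rate
    P(Z_best > c).  p* is the proportion of patients on the designated best
    arm; EO is the mean patient outcome.  Replicates with an undefined test
    statistic are excluded from the error/power rates (their count is
    reported) but still contribute to p* and EO.
    """
    table = _resolve_table(config, table)
    rngs = _spawn_rngs(rng, reps)
    best = _best_arm(config)
    hyp = _hypothesis_label(config)

    def one(r):
        z, counts, eo = _replicate_stats(config, table, r)
        zmax = np.nan if np.all(np.isnan(z)) else np.nanmax(z)
        zbest = z[best - 1] if best >= 1 else np.nan
        return zmax, zbest, counts[best] / config.T, eo

    if n_jobs != 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(one)(r) for r in rngs)
    else:
        rows = [one(r) for r in rngs]
    zmax = np.array([r[0] for r in rows])
    zbest = np.array([r[1] for r in rows])
    pstar = np.array([r[2] for r in rows])
    eo = np.array([r[3] for r in rows])

    defined = ~np.isnan(zmax)
    excluded = int((~defined).sum())
    global_rate = float(np.mean(zmax[defined] > critical_value)) if defined.any() else np.nan
    if hyp == "H0":
        headline = global_rate
    else:
        ok = ~np.isnan(zbest)
        headline = float(np.mean(zbest[ok] > critical_value)) if ok.any() else np.nan
        excluded = max(excluded, int((~ok).sum()))

    return StudySummary(
        rule=config.rule,
        hypothesis=hyp,
        reps=reps,
        critical_value=critical_value,
        type1_or_power=headline,
        global_rejection_rate=global_rate,
        e_pstar=float(pstar.mean()),
        e_pstar_sd=float(pstar.std(ddof=1)),
        expected_outcome=float(eo.mean()),
        expected_outcome_sd=float(eo.std(ddof=1)),
        excluded_reps=excluded,
        per_replicate=(
            {"z_max": zmax, "z_best": zbest, "pstar": pstar, "eo": eo} if keep_replicates else None
        ),
    )


# ---------------------------------------------------------------------------
# bias diagnostics
# ---------------------------------------------------------------------------


@dataclass
class BiasTrajectory:
    """Mean bias E[xbar_k(t) - mu_k] of one arm's running estimate."""

    arm: int
    t_grid: np.ndarray
    mean_bias: np.ndarray
    reps: int


def bias_trajectories(
    results: Sequence[TrialResult], config: Optional[TrialConfig] = None
) -> list[BiasTrajectory]:
    """Average running-mean bias across replicates, per arm and patient count.

    An arm's running mean is carried forward while the arm is frozen (its
    posterior does not move); replicates where the arm has no observation
    yet at patient t are excluded from the average at that t.
    """
    if not results:
        raise ConfigurationError("need at least one replicate")
    config = config or results[0].config
    T, m = config.T, config.n_arms
    mu = np.asarray(config.true_means)
    total = np.zeros((T, m))
    count = np.zeros((T, m))
    for res in results:
        hist = res.mean_history()
        valid = ~np.isnan(hist)
        total[valid] += (hist - mu)[valid]
        count += valid
    with np.errstate(invalid="ignore"):
        bias = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    t_grid = np.arange(1, T + 1)
    return [BiasTrajectory(arm=k, t_grid=t_grid, mean_bias=bias[:, k], reps=len(results)) for k in range(m)]


def critical_value_vs_T(
    config: TrialConfig,
    T_grid: Sequence[int],
    alpha: float = 0.05,
    reps: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    table: Optional[GittinsTable] = None,
    n_jobs: int = 1,
) -> list[tuple[int, float]]:
    """Calibrated critical value at each trial size in ``T_grid``."""
    from dataclasses import replace

    from .design import calibrate_critical_value

    out = []
    rngs = _spawn_rngs(rng, len(list(T_grid)))
    for T, r in zip(T_grid, rngs):
        cfg = replace(config, T=int(T))
        cal = calibrate_critical_value(
            cfg, reps=reps, alpha=alpha, rng=r, table=table, keep_samples=False, n_jobs=n_jobs
        )
        out.append((int(T), cal.empirical_quantile))
    return out
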