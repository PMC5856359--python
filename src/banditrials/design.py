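"""Frequentist design layer: test statistics, design constants, calibration.

Superiority of arm k over the control is tested one-sided with

    Z_k = (xbar_k - xbar_0) / (sigma * sqrt(1/n_k + 1/n_0)),

rejecting when Z_k exceeds a critical value.  Under equal fixed
randomisation (FR) the Z_k are jointly normal with unit variances and
pairwise correlation 1/2 (shared control), which yields the analytic
family-wise critical value.  Adaptive allocation distorts the null
distribution of Z, so critical values for adaptive rules are calibrated by
Monte-Carlo simulation of the trial under the global null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate, optimize
from scipy.stats import norm

from .exceptions import ConvergenceError, InvalidParameterError, UndefinedStateError
from .trial import TrialConfig, TrialResult

__all__ = [
    "TestOutcome",
    "CalibrationResult",
    "z_statistics",
    "evaluate_test",
    "fr_critical_value",
    "required_sample_size",
    "effect_from_superiority_prob",
    "calibrate_critical_value",
]


@dataclass(frozen=True)
class TestOutcome:
    """End-of-trial test decision for one replicate."""

    z: np.ndarray  # (K,) statistics, NaN for never-sampled arms
    z_max: float
    critical_value: float
    reject_global: bool
    rejected_arms: tuple


def z_statistics(result: TrialResult, sigma: Optional[float] = None) -> np.ndarray:
    """Z statistics of every experimental arm against the control.

    Arms with no observations yield NaN; a trial whose control arm was never
    sampled admits no test at all.
    """
    sigma = result.config.sigma if sigma is None else sigma
    states = result.per_arm
    if states[0].n == 0:
        raise UndefinedStateError("control arm has no observations; trial invalid for testing")
    n0, m0 = states[0].n, states[0].mean
    out = np.full(result.config.K, np.nan)
    for k in range(1, result.config.K + 1):
        s = states[k]
        if s.n:
            out[k - 1] = (s.mean - m0) / (sigma * math.sqrt(1.0 / s.n + 1.0 / n0))
    return out


def evaluate_test(result: TrialResult, critical_value: float, sigma=None) -> TestOutcome:
    """Apply the one-sided max-Z test at ``critical_value``."""
    z = z_statistics(result, sigma)
    if np.all(np.isnan(z)):
        raise UndefinedStateError("no experimental arm has observations")
    z_max = float(np.nanmax(z))
    rejected = tuple(k + 1 for k in range(len(z)) if not np.isnan(z[k]) and z[k] > critical_value)
    return TestOutcome(
        z=z,
        z_max=z_max,
        critical_value=critical_value,
        reject_global=z_max > critical_value,
        rejected_arms=rejected,
    )


def fr_critical_value(K: int, alpha: float = 0.05) -> float:
    """Critical value controlling the FWER at ``alpha`` for an FR trial.

    Solves ``P(max_k Z_k > c) = alpha`` where ``(Z_1, ..., Z_K)`` is
    multivariate normal with unit variances and pairwise correlation 1/2.
    Conditioning on the shared control term reduces the probability to the
    one-dimensional integral ``P(max Z <= c) = E[Phi(U + c sqrt(2))**K]``
    with ``U`` standard normal.  ``K = 1`` reduces to the normal quantile.
    """
    if K < 1:
        raise InvalidParameterError("K must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    if K == 1:
        return float(norm.ppf(1.0 - alpha))
    sqrt2 = math.sqrt(2.0)

    def p_no_rejection(c: float) -> float:
        val, err = integrate.quad(
            lambda u: norm.pdf(u) * norm.cdf(u + c * sqrt2) ** K, -9.0, 9.0, limit=200
        )
        if err > 1e-7:
            raise ConvergenceError(f"FWER integral did not converge (err={err:.1e})")
        return val

    return float(optimize.brentq(lambda c: p_no_rejection(c) - (1.0 - alpha), -5.0, 8.0, xtol=1e-10))


def required_sample_size(
    K: int, sigma2: float, c_alpha: float, beta: float, delta: float
) -> int:
    """Total FR trial size for marginal power ``1 - beta`` at effect ``delta``.

    ``T = (K+1) * 2 * sigma^2 * (C_alpha + z_beta)^2 / delta^2``, rounded up
    to the next integer.  Each of the K marginal tests against the shared
    control is powered individually (not family-wise), hence the classical
    two-sample expression per arm.
    """
    if delta <= 0:
        raise InvalidParameterError("delta must be positive")
    if sigma2 <= 0:
        raise InvalidParameterError("sigma2 must be positive")
    z_beta = norm.ppf(1.0 - beta)
    t_exact = (K + 1) * 2.0 * sigma2 * (c_alpha + z_beta) ** 2 / delta**2
    return int(math.ceil(t_exact - 1e-12))


def effect_from_superiority_prob(p: float, sigma: float = 1.0) -> float:
    """Mean difference making ``P(X_1 > X_0) = p`` for independent normals.

    ``X_1 - X_0 ~ N(delta, 2 sigma^2)`` gives ``delta = sqrt(2) sigma
    Phi^{-1}(p)``; e.g. p = 0.65 -> 0.545 and p = 0.55 -> 0.178 at sigma=1.
    """
    if not 0.5 <= p < 1.0:
        raise InvalidParameterError("superiority probability must lie in [0.5, 1)")
    return float(math.sqrt(2.0) * sigma * norm.ppf(p))


@dataclass
class CalibrationResult:
    """Monte-Carlo calibration of a test critical value under the null."""

    rule: object  # RuleSpec
    reps: int
    alpha: float
    empirical_quantile: float
    z_mean: float
    z_sd: float
    ecdf: dict = field(default_factory=dict)
    excluded_reps: int = 0
    samples: Optional[np.ndarray] = None

    def ecdf_at(self, x: float) -> float:
        """Fraction of stored null statistics at or below ``x``."""
        if self.samples is None:
            raise InvalidParameterError("samples were not retained")
        return float(np.mean(self.samples <= x))

    def to_csv(self, path) -> None:
        import pandas as pd

        row = {
            "rule": getattr(self.rule, "name", str(self.rule)),
            "reps": self.reps,
            "alpha": self.alpha,
            "quantile": self.empirical_quantile,
            "z_mean": self.z_mean,
            "z_sd": self.z_sd,
            "excluded_reps": self.excluded_reps,
        }
        for x, v in self.ecdf.items():
            row[f"ecdf_{x}"] = v
        pd.DataFrame([row]).to_csv(path, index=False)

    def samples_to_file(self, path) -> None:
        if self.samples is None:
            raise InvalidParameterError("samples were not retained")
        np.savetxt(path, self.samples, fmt="%.10g")


def calibrate_critical_value(
    config: TrialConfig,
    reps: int,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    table=None,
    ecdf_points=(),
    keep_samples: bool = True,
    n_jobs: int = 1,
) -> CalibrationResult:
    """Empirical ``(1 - alpha)`` null quantile of Z (K=1) or max-Z (K>=2).

    Runs ``reps`` independent replicates of the trial under the configured
    rule with all arm means equal (the global null), records the test
    statistic of each, and returns the order-statistic quantile (smallest
    sample value whose ECDF reaches ``1 - alpha``).  Replicates whose
    statistic is undefined (a never-sampled reported arm) are excluded and
    counted; more than 1% exclusions triggers a warning.
    """
    from . import study  # local import: study depends on rules/design

    if len(set(config.true_means)) != 1:
        raise InvalidParameterError(
            "calibration requires the global null: all true means equal"
        )
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    zs = study._null_statistics(config, reps, rng=rng, table=table, n_jobs=n_jobs)
    excluded = int(np.isnan(zs).sum())
    if excluded > 0.01 * reps:
        import warnings

        warnings.warn(
            f"{excluded}/{reps} replicates had an undefined test statistic",
            stacklevel=2,
        )
    z = zs[~np.isnan(zs)]
    quant = float(np.quantile(z, 1.0 - alpha, method="inverted_cdf"))
    return CalibrationResult(
        rule=config.rule,
        reps=reps,
        alpha=alpha,
        empirical_quantile=quant,
        z_mean=float(z.mean()),
        z_sd=float(z.std(ddof=1)),
        ecdf={float(x): float(np.mean(z <= x)) for x in ecdf_points},
        excluded_reps=excluded,
        samples=z if keep_samples else None,
    )
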