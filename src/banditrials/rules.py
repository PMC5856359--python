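"""The thirteen patient-allocation procedures behind one interface.

Rules
-----
FR    fixed randomisation, probability 1/(K+1) per arm
TS    Thompson sampling with stabilising exponent c = t/(2T)
TSB   TS with allocation probabilities frozen within blocks of b patients
UCB   upper confidence bound, score xbar + sigma*sqrt(2 ln t / n)
KLU   KL-UCB variant, score xbar + sigma*sqrt(2 (ln t + 3 ln ln t) / n)
CB    current belief: highest posterior mean
GI    Gittins index: highest nu(xbar, n; sigma^2, d)
RGI   GI plus an arm-wise exponential perturbation ((K+1)/n) * Y
RBI   posterior mean plus the same perturbation
TP    Trippa et al. procedure (control weight tracks the leading arm)
TPB   batched TP
CG    protected control: control w.p. 1/(K+1), otherwise the GI argmax
CUC   protected control with the UCB score

Scores are undefined while any arm has n = 0 (improper prior), so every
rule except FR starts with one forced observation per arm: UCB, KLU and CUC
fill arms in id order (patient t gets arm t-1, 1-based), all others pick
uniformly among the still-empty arms.  Ties in any score are broken
uniformly at random.

Time indexing: ``t`` is the number of patients already allocated, so the
patient being placed is number ``t + 1`` (1-based).  The UCB/KLU bonus uses
the 1-based patient number; the TS/TP exponents use ``t``, making the very
first allocation probabilities uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr

from .exceptions import ConfigurationError, InvalidParameterError, UndefinedStateError
from .gittins import GittinsTable
from .trial import ArmState, TrialConfig

__all__ = [
    "RULE_NAMES",
    "RuleSpec",
    "allocate",
    "ts_probabilities",
    "tp_probabilities",
    "protected_control_wrap",
    "BatchedAllocator",
    "make_allocator",
]

RULE_NAMES = frozenset(
    ["FR", "TS", "TSB", "UCB", "KLU", "CB", "GI", "RGI", "RBI", "CG", "CUC", "TP", "TPB"]
)

#: rules whose score needs a standardized Gittins table
TABLE_RULES = frozenset(["GI", "RGI", "CG"])
#: rules that fill empty arms in arm-id order rather than randomly
ORDERED_INIT_RULES = frozenset(["UCB", "KLU", "CUC"])
BATCHED_RULES = frozenset(["TSB", "TPB"])

_ALLOWED_TUNING = {
    "FR": set(),
    "TS": {"mc_draws"},
    "TSB": {"mc_draws", "batch"},
    "UCB": {"log_factor"},
    "KLU": {"log_factor"},
    "CB": set(),
    "GI": {"discount", "index_offset"},
    "RGI": {"discount", "index_offset"},
    "RBI": set(),
    "TP": {"gamma_scale", "gamma_power", "eta_scale"},
    "TPB": {"gamma_scale", "gamma_power", "eta_scale", "batch"},
    "CG": {"discount", "index_offset", "control_prob", "experimental_only"},
    "CUC": {"log_factor", "control_prob", "experimental_only"},
}

_TUNING_DEFAULTS = {
    "mc_draws": 1000,
    "log_factor": 2.0,
    # observation count added to n when reading the standardized index.  The
    # printed index tables that the reference trial studies interpolate count
    # the flat prior as one observation in the index state, so their GI score
    # is xbar + sigma * nu(0, n+1; 1, d); set 0 for the pure n-observation
    # convention.
    "index_offset": 1,
    "gamma_scale": 3.0,
    "gamma_power": 1.75,
    "eta_scale": 0.25,
    # protected-control designs randomise the control arm with probability
    # 1/(K+1); set control_prob="K" for the 1/K variant
    "control_prob": "K+1",
    # False: the index step of CG/CUC considers every arm, control included;
    # True restricts it to the experimental arms
    "experimental_only": False,
}


@dataclass(frozen=True)
class RuleSpec:
    """An allocation rule name plus its tuning record."""

    name: str
    tuning: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in RULE_NAMES:
            raise ConfigurationError(f"unknown rule {self.name!r}; valid: {sorted(RULE_NAMES)}")
        bad = set(self.tuning) - _ALLOWED_TUNING[self.name]
        if bad:
            raise ConfigurationError(
                f"tuning keys {sorted(bad)} not valid for rule {self.name}; "
                f"allowed: {sorted(_ALLOWED_TUNING[self.name])}"
            )

    def get(self, key):
        return self.tuning.get(key, _TUNING_DEFAULTS[key])

    @property
    def needs_table(self) -> bool:
        return self.name in TABLE_RULES

    @property
    def is_batched(self) -> bool:
        return self.name in BATCHED_RULES


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _states_to_arrays(states: Sequence[ArmState]) -> tuple[np.ndarray, np.ndarray]:
    n = np.array([s.n for s in states], dtype=int)
    mean = np.array([s.total / s.n if s.n else np.nan for s in states])
    return n, mean


def _argmax_random_ties(scores: np.ndarray, rng: np.random.Generator) -> int:
    m = scores.max()
    ties = np.flatnonzero(scores == m)
    if len(ties) == 1:
        return int(ties[0])
    return int(ties[rng.integers(len(ties))])


def _draw_categorical(p: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(np.cumsum(p), rng.random()))


# ---------------------------------------------------------------------------
# probability vectors
# ---------------------------------------------------------------------------


def ts_probabilities(states, t, config: TrialConfig, mc_draws: int = 1000, rng=None):
    """Thompson-sampling allocation probabilities ``p_k^c / sum_l p_l^c``.

    ``p_k = P(mu_k = max_l mu_l | data)`` is estimated from ``mc_draws``
    joint samples of the K+1 independent posteriors; the stabilising
    exponent is ``c = t / (2T)``, so the probabilities start uniform and
    sharpen as the trial progresses.
    """
    n, mean = _states_to_arrays(states)
    if np.any(n == 0):
        raise UndefinedStateError("initialization not finished: some arm has n=0")
    rng = np.random.default_rng() if rng is None else rng
    return _ts_prob_arrays(n, mean, t, config.T, config.sigma, mc_draws, rng)


def _ts_prob_arrays(n, mean, t, T, sigma, mc_draws, rng):
    c = t / (2.0 * T)
    draws = mean + (sigma / np.sqrt(n)) * rng.standard_normal((mc_draws, len(n)))
    counts = np.bincount(np.argmax(draws, axis=1), minlength=len(n))
    p = counts / mc_draws
    w = p**c  # 0**0 == 1: c = 0 gives uniform probabilities
    return w / w.sum()


def tp_probabilities(states, t, config: TrialConfig, tuning: Optional[dict] = None, rng=None):
    """Trippa et al. allocation probabilities.

    Experimental arms are weighted by ``P(mu_k > mu_0 | data)**gamma_t``
    (normalized among themselves); the control weight
    ``(1/K) * exp(max_k (n_k - n_0) * eta_t)`` grows when the control lags
    the leading arm, keeping the comparison powered.  With
    ``gamma_t = 3 (t/T)**1.75`` and ``eta_t = 0.25 (t/T)``.  The posterior
    superiority probability has the closed form
    ``Phi((xbar_k - xbar_0) / (sigma * sqrt(1/n_k + 1/n_0)))``.
    """
    n, mean = _states_to_arrays(states)
    if np.any(n == 0):
        raise UndefinedStateError("initialization not finished: some arm has n=0")
    tuning = tuning or {}
    gs = tuning.get("gamma_scale", _TUNING_DEFAULTS["gamma_scale"])
    gp = tuning.get("gamma_power", _TUNING_DEFAULTS["gamma_power"])
    es = tuning.get("eta_scale", _TUNING_DEFAULTS["eta_scale"])
    return _tp_prob_arrays(n, mean, t, config.T, config.sigma, gs, gp, es)


def _tp_prob_arrays(n, mean, t, T, sigma, gamma_scale, gamma_power, eta_scale):
    frac = t / T
    gamma = gamma_scale * frac**gamma_power
    eta = eta_scale * frac
    K = len(n) - 1
    p_sup = ndtr((mean[1:] - mean[0]) / (sigma * np.sqrt(1.0 / n[1:] + 1.0 / n[0])))
    w = p_sup**gamma
    w_exp = w / w.sum()
    ctrl = (1.0 / K) * math.exp(min((n[1:].max() - n[0]) * eta, 700.0))
    pi = np.concatenate([[ctrl], w_exp])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# per-trial allocators (array-based, used by the study engine)
# ---------------------------------------------------------------------------


class _Allocator:
    """Chooses the next arm given (t, arm counts, arm means)."""

    ordered_init = False

    def __init__(self, rule: RuleSpec, config: TrialConfig, table: Optional[GittinsTable]):
        self.rule = rule
        self.config = config
        self.table = table
        self.m = config.n_arms

    def choose(self, t: int, n: np.ndarray, mean: np.ndarray, rng) -> int:
        empty = np.flatnonzero(n == 0)
        if len(empty):
            if self.ordered_init:
                return int(empty[0])
            return int(empty[rng.integers(len(empty))]) if len(empty) > 1 else int(empty[0])
        return self._choose_full(t, n, mean, rng)

    def _choose_full(self, t, n, mean, rng) -> int:
        raise NotImplementedError


class _FRAllocator(_Allocator):
    def choose(self, t, n, mean, rng) -> int:
        return int(rng.integers(self.m))


class _ScoreAllocator(_Allocator):
    def __init__(self, rule, config, table):
        super().__init__(rule, config, table)
        self.ordered_init = rule.name in ORDERED_INIT_RULES
        self.sigma = config.sigma
        name = rule.name
        if name in ("GI", "RGI"):
            cap = max(config.T, 512)
            off = rule.get("index_offset")
            self._bonus = config.sigma * table.bonus(np.arange(1, cap + 1) + off)
        if name in ("UCB", "KLU"):
            self._f = rule.get("log_factor")
        self._score = getattr(self, f"_score_{name.lower()}")

    def _choose_full(self, t, n, mean, rng) -> int:
        return _argmax_random_ties(self._score(t, n, mean, rng), rng)

    # individual scores ----------------------------------------------------
    def _score_cb(self, t, n, mean, rng):
        return mean

    def _score_gi(self, t, n, mean, rng):
        return mean + self._bonus[n - 1]

    def _perturbation(self, n, rng):
        m = self.m
        return (m / n) * rng.exponential(scale=1.0 / m, size=m)

    def _score_rgi(self, t, n, mean, rng):
        return mean + self._bonus[n - 1] + self._perturbation(n, rng)

    def _score_rbi(self, t, n, mean, rng):
        return mean + self._perturbation(n, rng)

    def _score_ucb(self, t, n, mean, rng):
        logt = math.log(t + 1)  # 1-based patient number
        return mean + self.sigma * np.sqrt(self._f * logt / n)

    def _score_klu(self, t, n, mean, rng):
        t1 = t + 1
        inner = max(self._f * (math.log(t1) + 3.0 * math.log(math.log(t1))), 0.0) if t1 >= 2 else 0.0
        return mean + self.sigma * np.sqrt(inner / n)


class _ProbabilityAllocator(_Allocator):
    """TS and TP: draw the arm from a freshly computed probability vector."""

    def __init__(self, rule, config, table):
        super().__init__(rule, config, table)
        name = rule.name
        if name.startswith("TS"):
            self._mc = rule.get("mc_draws")
            self.probabilities = self._ts
        else:
            self._gs = rule.get("gamma_scale")
            self._gp = rule.get("gamma_power")
            self._es = rule.get("eta_scale")
            self.probabilities = self._tp

    def _ts(self, t, n, mean, rng):
        return _ts_prob_arrays(n, mean, t, self.config.T, self.config.sigma, self._mc, rng)

    def _tp(self, t, n, mean, rng):
        return _tp_prob_arrays(
            n, mean, t, self.config.T, self.config.sigma, self._gs, self._gp, self._es
        )

    def _choose_full(self, t, n, mean, rng) -> int:
        return _draw_categorical(self.probabilities(t, n, mean, rng), rng)


class _ProtectedAllocator(_Allocator):
    """CG / CUC: control with fixed probability, otherwise an index argmax."""

    def __init__(self, rule, config, table):
        super().__init__(rule, config, table)
        self.ordered_init = rule.name in ORDERED_INIT_RULES
        base_name = "GI" if rule.name == "CG" else "UCB"
        base_tuning = {
            k: v for k, v in rule.tuning.items() if k in _ALLOWED_TUNING[base_name]
        }
        self._base = _ScoreAllocator(RuleSpec(base_name, base_tuning), config, table)
        denom = config.K + 1 if rule.get("control_prob") == "K+1" else config.K
        self.control_prob = 1.0 / denom
        self._experimental_only = rule.get("experimental_only")

    def _choose_full(self, t, n, mean, rng) -> int:
        if rng.random() < self.control_prob:
            return 0
        scores = self._base._score(t, n, mean, rng)
        if self._experimental_only:
            return 1 + _argmax_random_ties(scores[1:], rng)
        return _argmax_random_ties(scores, rng)


class BatchedAllocator(_Allocator):
    """TSB / TPB: the probability vector is recomputed only at block starts.

    The vector is refreshed at t in {0, b, 2b, ...} from all outcomes
    observed before the refresh, and frozen in between; the final partial
    block keeps the last vector.  At t = 0 (no data) the vector is uniform,
    which is also the analytic limit of both rules as their exponents
    vanish.  This allocator is stateful across a trial, so it must be
    constructed once per replicate.
    """

    def __init__(self, rule, config, table, batch_size: Optional[int] = None):
        super().__init__(rule, config, table)
        b = batch_size or config.batch_size or rule.tuning.get("batch")
        if not b or b < 1:
            raise ConfigurationError(f"rule {rule.name} needs a positive batch size")
        self.batch_size = int(b)
        base_name = rule.name[:-1]  # TSB -> TS, TPB -> TP
        base_tuning = {k: v for k, v in rule.tuning.items() if k in _ALLOWED_TUNING[base_name]}
        self._base = _ProbabilityAllocator(RuleSpec(base_name, base_tuning), config, table)
        self._vector: Optional[np.ndarray] = None
        self._computed_at = -1
        self.recompute_times: list[int] = []  # audit trail for tests

    def _refresh(self, t, n, mean, rng):
        if t == 0 or np.any(n == 0):
            self._vector = np.full(self.m, 1.0 / self.m)
        else:
            self._vector = self._base.probabilities(t, n, mean, rng)
        self._computed_at = t
        self.recompute_times.append(t)

    def choose(self, t, n, mean, rng) -> int:
        if t % self.batch_size == 0 and self._computed_at != t:
            self._refresh(t, n, mean, rng)
        empty = np.flatnonzero(n == 0)
        if len(empty):  # forced initialization: scores/posteriors need n >= 1
            return int(empty[rng.integers(len(empty))]) if len(empty) > 1 else int(empty[0])
        return _draw_categorical(self._vector, rng)


def make_allocator(
    config: TrialConfig, table: Optional[GittinsTable] = None, rule: Optional[RuleSpec] = None
) -> _Allocator:
    """Build the per-trial allocator for ``rule`` (default ``config.rule``)."""
    rule = rule or config.rule
    if rule is None:
        raise ConfigurationError("no allocation rule configured")
    if rule.needs_table and table is None:
        raise ConfigurationError(f"rule {rule.name} requires a Gittins index table")
    name = rule.name
    if name == "FR":
        return _FRAllocator(rule, config, table)
    if name in ("TS", "TP"):
        return _ProbabilityAllocator(rule, config, table)
    if name in BATCHED_RULES:
        return BatchedAllocator(rule, config, table)
    if name in ("CG", "CUC"):
        return _ProtectedAllocator(rule, config, table)
    return _ScoreAllocator(rule, config, table)


# ---------------------------------------------------------------------------
# stateless public entry points
# ---------------------------------------------------------------------------


def allocate(
    rule: RuleSpec,
    t: int,
    states: Sequence[ArmState],
    config: TrialConfig,
    table: Optional[GittinsTable] = None,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Return the arm for the next patient under ``rule``.

    Batched rules carry a frozen probability vector across patients and are
    therefore driven through :class:`BatchedAllocator` (or the trial
    engine), not this stateless call.
    """
    if rule.is_batched:
        raise ConfigurationError(
            f"{rule.name} is stateful across patients; construct a "
            "BatchedAllocator (or use study.run_trial)"
        )
    rng = np.random.default_rng() if rng is None else rng
    alloc = make_allocator(config, table, rule)
    n, mean = _states_to_arrays(states)
    return alloc.choose(t, n, np.nan_to_num(mean, nan=0.0) if np.any(n == 0) else mean, rng)


def protected_control_wrap(
    base: RuleSpec,
    t: int,
    states: Sequence[ArmState],
    config: TrialConfig,
    table: Optional[GittinsTable] = None,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Protected-control allocation (CG for a GI base, CUC for a UCB base)."""
    wrapped = {"GI": "CG", "UCB": "CUC"}.get(base.name)
    if wrapped is None:
        raise ConfigurationError(f"no protected-control variant for base rule {base.name}")
    keep = _ALLOWED_TUNING[wrapped]
    spec = RuleSpec(wrapped, {k: v for k, v in base.tuning.items() if k in keep})
    return allocate(spec, t, states, config, table, rng)
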