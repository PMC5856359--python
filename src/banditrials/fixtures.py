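"""Deterministic arm-state snapshots for unit-testing allocation rules.

These build :class:`~banditrials.trial.ArmState` collections directly from
given counts and means (or from a seeded draw), so rule behaviour can be
probed without running whole trials.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError
from .trial import ArmState

__all__ = ["make_fixture_states", "imbalanced_null_snapshot"]


def make_fixture_states(
    spec: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
    *,
    n: Optional[Sequence[int]] = None,
    mean: Optional[Sequence[float]] = None,
) -> list[ArmState]:
    """Build arm states from explicit counts/means or a seeded random draw.

    ``spec`` (or the keyword pair ``n`` / ``mean``) gives per-arm
    observation counts and sample means; arms with ``n=0`` take mean 0 as a
    placeholder (their mean is undefined and never read by rules).  With
    ``spec={"random": K+1, "t": total}`` and an ``rng``, draws a random
    snapshot: counts from a multinomial over ``t`` patients, means from
    standard normal scaled by 1/sqrt(n).
    """
    if spec is not None:
        if "random" in spec:
            if rng is None:
                raise ConfigurationError("random fixture states need an rng")
            m, t = int(spec["random"]), int(spec.get("t", 4 * int(spec["random"])))
            counts = rng.multinomial(t, np.full(m, 1.0 / m))
            means = np.where(counts > 0, rng.standard_normal(m) / np.sqrt(np.maximum(counts, 1)), 0.0)
            n, mean = counts, means
        else:
            n, mean = spec["n"], spec["mean"]
    if n is None or mean is None:
        raise ConfigurationError("need n and mean (or a spec dict)")
    if len(n) != len(mean):
        raise ConfigurationError("n and mean must be equally long")
    return [
        ArmState(arm_id=k, n=int(nk), total=float(nk) * float(mk))
        for k, (nk, mk) in enumerate(zip(n, mean))
    ]


def imbalanced_null_snapshot(T: int = 116) -> list[ArmState]:
    """A two-arm snapshot of the kind adaptive null trials often end in.

    The control arm performed badly early, was dropped at n0 = 19 with a
    negatively biased mean, and the experimental arm absorbed the rest of
    the trial with its mean regressed to the truth.
    """
    n0 = 19
    return make_fixture_states(n=[n0, T - n0], mean=[-0.45, 0.02])
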