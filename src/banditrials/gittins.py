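"""Gittins indices for the normal reward process with known variance.

For an arm with unknown mean, known variance ``sigma**2`` and an improper
uniform prior, the posterior after ``n`` observations with sample mean
``xbar`` is ``N(xbar, sigma**2 / n)``.  The Gittins index of that arm under
geometric discounting ``d`` separates into a location/scale form::

    nu(xbar, n; sigma**2, d) = xbar + sigma * nu(0, n; 1, d)

so only the standardized index ``nu(0, n; 1, d)`` has to be computed, once
per discount factor.  This module computes those values by the calibration
(retirement-option) formulation: ``nu(0, n)`` is the standing reward
``lam`` at which a decision maker is indifferent between retiring forever
(value ``lam / (1 - d)``) and sampling the unknown arm once more and then
proceeding optimally.  The continuation value is obtained by backward
induction over a discretized posterior-mean grid, and ``lam`` is located by
bisection.

Precomputed tables for the discount factors used in the trial studies
(0.9, 0.95, 0.99, 0.995) are bundled as plain-text files and loaded with
:func:`load_table`, so simulations never pay the dynamic-programming cost.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .exceptions import ConvergenceError, InvalidParameterError, UndefinedStateError

__all__ = [
    "GittinsTable",
    "compute_gittins_table",
    "arm_index",
    "load_table",
    "BUNDLED_DISCOUNTS",
]

#: Discount factors with a precomputed table shipped inside the package.
BUNDLED_DISCOUNTS = (0.9, 0.95, 0.99, 0.995)


@dataclass(frozen=True)
class GittinsTable:
    """Standardized Gittins index values ``nu(0, n; 1, d)`` on a grid of n.

    Attributes
    ----------
    discount : float
        Geometric discount factor ``d`` in ``[0, 1)``.
    n_grid : numpy.ndarray
        Strictly increasing positive integers (observation counts).
    values : numpy.ndarray
        Standardized index values, same length as ``n_grid``.  Non-negative
        and non-increasing in ``n``: the value of learning shrinks as data
        accumulate and tends to zero as ``n`` grows.
    meta : dict
        Dynamic-programming settings used to produce the table (horizon,
        grid extent/resolution, quadrature order, bisection tolerance).
    """

    discount: float
    n_grid: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = np.asarray(self.n_grid, dtype=int)
        v = np.asarray(self.values, dtype=float)
        if n.ndim != 1 or v.shape != n.shape:
            raise InvalidParameterError("n_grid and values must be 1-D and equally long")
        if len(n) == 0 or n[0] < 1 or np.any(np.diff(n) <= 0):
            raise InvalidParameterError("n_grid must be strictly increasing positive integers")
        object.__setattr__(self, "n_grid", n)
        object.__setattr__(self, "values", v)

    # ------------------------------------------------------------------ lookup

    def bonus(self, n):
        """Standardized index ``nu(0, n; 1, d)``, the learning bonus at count n.

        Exact on the stored grid; log-linearly interpolated in ``n``
        otherwise (the index decays smoothly and roughly power-law-like in
        ``n``, so interpolation linear in ``log n`` respects monotonicity).
        Beyond the last grid point the final value is carried forward.
        """
        arr = np.asarray(n)
        if np.any(arr < 1):
            raise UndefinedStateError(
                "the index is undefined at n=0 (no posterior under the uniform "
                "prior); use the allocation layer's initialization rule"
            )
        out = np.interp(np.log(arr), np.log(self.n_grid), self.values)
        return float(out) if np.isscalar(n) or arr.ndim == 0 else out

    def arm_index(self, sample_mean, n, sigma=1.0):
        """Gittins index ``nu(xbar, n; sigma**2, d) = xbar + sigma * nu(0, n; 1, d)``."""
        if np.any(np.asarray(sigma) <= 0):
            raise InvalidParameterError("sigma must be positive")
        return sample_mean + sigma * self.bonus(n)

    # --------------------------------------------------------------------- IO

    def to_file(self, path) -> None:
        """Write the documented plain-text format (12 significant digits)."""
        with open(path, "w") as fh:
            fh.write(self.dumps())

    def dumps(self) -> str:
        buf = io.StringIO()
        buf.write("# gittins index table: normal reward process, known variance\n")
        buf.write(f"# discount={self.discount!r}\n")
        for key, val in sorted(self.meta.items()):
            buf.write(f"# {key}={val!r}\n")
        buf.write("# columns: n value\n")
        for n, v in zip(self.n_grid, self.values):
            buf.write(f"{n} {v:.12g}\n")
        return buf.getvalue()

    @classmethod
    def from_file(cls, path) -> "GittinsTable":
        with open(path) as fh:
            return cls.loads(fh.read())

    @classmethod
    def loads(cls, text: str) -> "GittinsTable":
        import ast

        discount = None
        meta: dict = {}
        ns, vs = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, raw = body.partition("=")
                    key = key.strip()
                    try:
                        val = ast.literal_eval(raw.strip())
                    except (ValueError, SyntaxError):
                        val = raw.strip()
                    if key == "discount":
                        discount = float(val)
                    else:
                        meta[key] = val
                continue
            n_str, v_str = line.split()
            ns.append(int(n_str))
            vs.append(float(v_str))
        if discount is None:
            raise InvalidParameterError("table file lacks a '# discount=' header")
        return cls(discount=discount, n_grid=np.array(ns), values=np.array(vs), meta=meta)


def arm_index(table: GittinsTable, sample_mean, n, sigma=1.0):
    """Module-level convenience wrapper around :meth:`GittinsTable.arm_index`."""
    return table.arm_index(sample_mean, n, sigma)


# ---------------------------------------------------------------------------
# Dynamic programming
# ---------------------------------------------------------------------------


def default_n_grid(n_max: int) -> np.ndarray:
    """Observation-count grid: dense where the index moves fast, sparse later."""
    bands = [(1, 30, 1), (32, 60, 2), (65, 100, 5), (110, 200, 10), (220, 1000, 20)]
    out = []
    for start, stop, step in bands:
        for n in range(start, stop + 1, step):
            if n <= n_max:
                out.append(n)
    if out[-1] != n_max:
        out.append(n_max)
    return np.array(out)


def _hat_gaussian_weights(s: float, h: float, kernel_cut: float = 8.0) -> np.ndarray:
    """Exact overlap of unit hat functions with a centred N(0, s^2) kernel.

    For a piecewise-linear function on a uniform grid with spacing ``h``,
    the Gaussian expectation is a discrete convolution of the node values
    with these weights: ``w_k = int hat((x - k h)/h) * phi_s(x) dx`` with
    the closed form below.  Weights beyond ``kernel_cut`` standard
    deviations are dropped; the remainder sums to 1 up to Gaussian tail
    mass.
    """
    from scipy.special import ndtr

    kmax = int(math.ceil(kernel_cut * s / h)) + 1
    k = np.arange(-kmax, kmax + 1)
    c = k * h
    edges_lo, edges_hi = c - h, c + h

    def m0(a, b):  # P(a < X < b)
        return ndtr(b / s) - ndtr(a / s)

    def m1(a, b):  # E[X; a < X < b]
        return s * (_phi(a / s) - _phi(b / s))

    w = ((h - c) / h) * m0(edges_lo, c) + m1(edges_lo, c) / h
    w += ((c + h) / h) * m0(c, edges_hi) - m1(c, edges_hi) / h
    return w


def _phi(z):
    return np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)


def _expected_value(cont, x, h, s, retire, weights):
    """E[max(retire, C(y))] under y ~ N(x_i, s^2), for every grid centre x_i.

    ``cont`` holds the node values of the (increasing, smooth) continuation
    value C on the uniform grid ``x``.  The value function has a single
    kink where C crosses the constant ``retire``; handling that kink by
    interpolation would cost an O(h) bias, so it is handled analytically:
    the nodes left of the kink cell are replaced by the kink cell's own
    line a + b*y (making the convolution operand globally smooth), the
    Gaussian convolution of that piecewise-linear operand is computed
    exactly via the hat-overlap ``weights``, and the region y < yhat (where
    the true value is ``retire`` rather than the line) is corrected in
    closed form:

        E[V] = Conv + (retire - a - b x_i) Phi(z) + b s phi(z),
        z = (yhat - x_i)/s,  yhat = (retire - a)/b.
    """
    from scipy.special import ndtr

    N = len(x)
    j = int(np.searchsorted(cont, retire))
    cell = min(max(j - 1, 0), N - 2)
    b = (cont[cell + 1] - cont[cell]) / h
    if b <= 0:  # degenerate: continuation flat; no crossing to resolve
        return np.maximum(retire, cont)
    a = cont[cell] - b * x[cell]
    yhat = (retire - a) / b

    kmax = (len(weights) - 1) // 2
    ext = cont.copy()
    if cell > 0:
        ext[:cell] = a + b * x[:cell]
    left = a + b * (x[0] - h * np.arange(kmax, 0, -1))
    slope_r = (cont[-1] - cont[-2]) / h
    right = cont[-1] + slope_r * h * np.arange(1, kmax + 1)
    conv = np.convolve(np.concatenate([left, ext, right]), weights, mode="valid")

    z = (yhat - x) / s
    return conv + (retire - a - b * x) * ndtr(z) + b * s * _phi(z)


def _sample_value_at_zero(lam, n, d, x, stage_weights, stage_sds):
    """Value of sampling once at state (xbar=0, n) then acting optimally.

    Backward induction over stages m = n+horizon-1 ... n on the fixed
    posterior-mean grid ``x``; the terminal stage ignores further learning,
    which is damped by d**horizon.  The stage-m posterior-mean increment has
    standard deviation 1/sqrt(m(m+1)); ``stage_weights``/``stage_sds`` hold
    the precomputed convolution kernels, newest stage last.
    """
    retire = lam / (1.0 - d)
    h = x[1] - x[0]
    # V at the terminal stage: no more learning, max of the two constant
    # streams, i.e. continuation value x/(1-d) against retirement.
    cont = x / (1.0 - d)
    for w, s in zip(stage_weights, stage_sds):
        EV = _expected_value(cont, x, h, s, retire, w)
        cont = x + d * EV
    centre = (len(x) - 1) // 2  # grid is symmetric, x[centre] == 0
    return float(cont[centre])  # = 0 + d E[V_{n+1}] at xbar = 0


def _index_one_n(n, d, half_width, grid_points, kernel_cut, horizon, tol, hi_start):
    x = np.linspace(-half_width / math.sqrt(n), half_width / math.sqrt(n), grid_points)
    h = x[1] - x[0]
    # kernels for stages M-1 down to n, reused across bisection steps
    stage_sds = [1.0 / math.sqrt(m * (m + 1.0)) for m in range(n + horizon - 1, n - 1, -1)]
    stage_weights = [_hat_gaussian_weights(s, h, kernel_cut) for s in stage_sds]

    def gap(lam):
        return _sample_value_at_zero(lam, n, d, x, stage_weights, stage_sds) - lam / (1.0 - d)

    lo = 0.0
    hi = max(hi_start, 2.0 * tol)
    while gap(hi) > 0.0:
        lo, hi = hi, 2.0 * hi
        if hi > 1e3:  # pragma: no cover - defensive
            raise ConvergenceError("failed to bracket the index value")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compute_gittins_table(
    discount: float,
    n_max: int,
    *,
    n_grid=None,
    grid_half_width: float = 6.0,
    grid_points: int = 201,
    kernel_cut: float = 8.0,
    horizon: int | None = None,
    horizon_tol: float = 1e-6,
    tol: float = 1e-4,
    check: bool = False,
    check_tol: float = 1e-3,
) -> GittinsTable:
    """Compute standardized Gittins indices ``nu(0, n; 1, d)`` by DP.

    Parameters
    ----------
    discount : float
        Discount factor ``d`` in ``[0, 1)``.
    n_max : int
        Largest observation count in the table.
    n_grid : sequence of int, optional
        Explicit observation counts; defaults to :func:`default_n_grid`.
    grid_half_width : float
        State-grid half-width in posterior-standard-deviation units.
    grid_points : int
        Resolution of the posterior-mean grid (forced odd so the grid
        contains the origin exactly).
    kernel_cut : float
        Truncation of the Gaussian convolution kernel, in standard
        deviations of the one-step posterior-mean increment.
    horizon : int, optional
        Backward-induction depth; defaults to the smallest ``H`` with
        ``discount**H < horizon_tol``.
    tol : float
        Bisection tolerance on the index value.
    check : bool
        If True, re-solve a few entries at double grid resolution and double
        horizon and raise :class:`ConvergenceError` when any entry moves by
        more than ``check_tol``.
    """
    if not 0.0 <= discount < 1.0:
        raise InvalidParameterError(
            f"discount must lie in [0, 1); got {discount} (d >= 1 gives an "
            "infinite undiscounted value)"
        )
    if n_max < 1:
        raise InvalidParameterError("n_max must be >= 1")
    grid_points += 1 - grid_points % 2  # odd: the grid must contain 0
    grid = np.asarray(n_grid, dtype=int) if n_grid is not None else default_n_grid(n_max)
    if np.any(grid < 1) or np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("n_grid must be strictly increasing positive integers")

    meta = {
        "grid_half_width": grid_half_width,
        "grid_points": grid_points,
        "kernel_cut": kernel_cut,
        "horizon_tol": horizon_tol,
        "tol": tol,
    }
    if discount == 0.0:
        # Future rewards are worthless: the index is the immediate expected
        # reward, which is 0 at xbar = 0.
        meta["horizon"] = 0
        return GittinsTable(discount, grid, np.zeros(len(grid)), meta)

    if horizon is None:
        horizon = int(math.ceil(math.log(horizon_tol) / math.log(discount)))
    meta["horizon"] = horizon

    def solve(grid_points_, horizon_, entries):
        vals = []
        hi = 4.0
        for n in entries:
            v = _index_one_n(
                int(n), discount, grid_half_width, grid_points_, kernel_cut, horizon_, tol, hi
            )
            vals.append(v)
            hi = v + 10.0 * tol  # indices are non-increasing in n
        return np.array(vals)

    values = solve(grid_points, horizon, grid)

    if check:
        probe = sorted({int(grid[0]), int(grid[len(grid) // 2]), int(grid[-1])})
        coarse = np.interp(np.log(probe), np.log(grid), values)
        fine = solve(2 * grid_points - 1, 2 * horizon, probe)
        worst = float(np.max(np.abs(fine - coarse)))
        if worst > check_tol:
            raise ConvergenceError(
                f"grid-refinement check failed: max entry change {worst:.2e} "
                f"exceeds {check_tol:.2e} at n in {probe}; increase grid_points "
                "or the horizon"
            )
        meta["check_max_change"] = worst

    return GittinsTable(discount, grid, values, meta)


def _table_resource_name(discount: float) -> str:
    return f"gittins_normal_d{discount:.3f}.txt"


def load_table(discount: float) -> GittinsTable:
    """Load a bundled precomputed table for one of :data:`BUNDLED_DISCOUNTS`."""
    name = _table_resource_name(discount)
    pkg = resources.files("banditrials") / "tables"
    path = pkg / name
    if not path.is_file():
        raise InvalidParameterError(
            f"no bundled Gittins table for discount {discount}; available: "
            f"{BUNDLED_DISCOUNTS}; use compute_gittins_table() for other discounts"
        )
    return GittinsTable.loads(path.read_text())
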