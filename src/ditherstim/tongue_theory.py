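"""Closed-form Arnold-tongue theory for the stochastic sine circle map.

Frequency locking of the map ``theta -> theta + 2*pi*f0/fs + I*sin(theta)``
at ratio p:q survives dithering as long as the phase is unlikely to escape,
in a single random jump, the "trap" between the stable and the unstable
fixed point of the (q-fold composed) map.  Denoting the trap size ``h`` and
the jump standard deviation ``sigma``, locking is considered lost when
``h = n_sigma * sigma``.  This module implements, for the two analytically
tractable families

* ``p:1`` (one stable/unstable pair of the map itself, jump
  ``sigma = 2*pi*(f0/fs)*zeta``), and
* ``(2p-1):2`` (fixed points of the twice-composed map, approximated to one
  harmonic ``theta -> theta + 4*pi*f0/fs - (I**2/2)*sin(2*theta)``, jump
  ``sigma = 2*sqrt(2)*pi*(f0/fs)*zeta``),

the fixed points and trap sizes, the tongue boundaries I(f0), the tongue
widths in Hz at given (I, zeta), and the widths relative to the perfectly
periodic case.  The relative widths

    p:1      : 1 - n_sigma**2 * pi**2 * p**2 * zeta**2 / 2
    (2p-1):2 : 1 - n_sigma**2 * pi**2 * (2p-1)**2 * zeta**2

shrink faster for every higher-order family member than for 1:1, which is
the theoretical basis of selective entrainment by dithering.

All width/ratio formulas are small-``zeta``, small-``I`` Taylor
approximations; outside their validity range they can go negative and are
clamped to zero (tongue destroyed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["TongueSpec", "TheoryConfig", "FixedPointPair", "NoLockingError",
           "fixed_points_p1", "fixed_points_2pm1_2", "fixed_points_numeric",
           "boundary_p1", "boundary_2pm1_2", "width_p1", "width_2pm1_2",
           "relative_width_p1", "relative_width_2pm1_2"]


class NoLockingError(ValueError):
    """Raised when no locked fixed point exists for the given parameters."""


@dataclass(frozen=True)
class TongueSpec:
    """A p:q locking ratio with coprime integers p, q.

    The analytic families are q = 1 (any p >= 1) and q = 2 with odd p.
    Other ratios can only be measured empirically from sweeps.
    """

    p: int
    q: int

    def __post_init__(self):
        if self.p < 1 or self.q < 1:
            raise ValueError("p and q must be positive integers")
        if math.gcd(self.p, self.q) != 1:
            raise ValueError("p and q must be coprime")

    @property
    def value(self) -> float:
        return self.p / self.q

    @property
    def analytic(self) -> bool:
        return self.q == 1 or (self.q == 2 and self.p % 2 == 1)


@dataclass(frozen=True)
class TheoryConfig:
    """Parameters of the escape-based tongue theory.

    n_sigma is the number of jump-distribution standard deviations the trap
    must span for locking to persist; n_sigma = 4 corresponds to at least
    99.99% of locking cycles not escaping the periodic orbit.
    """

    zeta: float
    fs: float
    n_sigma: float = 4.0

    def __post_init__(self):
        if self.n_sigma < 3:
            raise ValueError("n_sigma must be >= 3")
        if self.zeta < 0:
            raise ValueError("zeta must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")


@dataclass(frozen=True)
class FixedPointPair:
    """A stable/unstable fixed-point pair and the trap size between them.

    ``trap_size`` is the shortest circular distance h (radians) from the
    stable point to the nearest unstable point.
    """

    theta_stable: float
    theta_unstable: float
    trap_size: float

    def __post_init__(self):
        if not 0 < self.trap_size <= np.pi:
            raise ValueError("trap size must lie in (0, pi]")


def _wrap(theta):
    return np.mod(theta, 2.0 * np.pi)


def _circ_dist(a, b):
    d = abs(a - b) % (2.0 * np.pi)
    return min(d, 2.0 * np.pi - d)


def fixed_points_p1(f0: float, fs: float, I: float, p: int) -> FixedPointPair:
    """Fixed points and trap size of p:1 locking.

    Solves ``sin(theta) = 2*pi*(p - f0/fs)/I`` and classifies stability by
    ``|1 + I*cos(theta)| < 1``.  Raises :class:`NoLockingError` when
    ``|2*pi*(f0/fs - p)| > I`` (no fixed points).
    """
    if I <= 0:
        raise NoLockingError("I must be > 0 for locking")
    delta = f0 / fs - p
    s = -2.0 * np.pi * delta / I
    if abs(s) > 1:
        raise NoLockingError(
            f"no p:1 fixed points: |2*pi*(f0/fs - p)| = "
            f"{abs(2 * np.pi * delta):.4g} exceeds I = {I:.4g}")
    a = math.asin(s)
    theta_stable = _wrap(np.pi - a)   # cos < 0 branch
    theta_unstable = _wrap(a)
    # piecewise trap size: h = pi + 2*asin(2*pi*(f0/fs - p)/I) below center,
    # pi - 2*asin(...) above; both equal pi - 2*asin(|...|)
    h = np.pi - 2.0 * math.asin(abs(2.0 * np.pi * delta / I))
    if h <= 0:  # tangent case at the exact boundary
        raise NoLockingError("degenerate trap (parameters on the boundary)")
    return FixedPointPair(theta_stable, theta_unstable, h)


def fixed_points_2pm1_2(f0: float, fs: float, I: float,
                        p: int) -> FixedPointPair:
    """Fixed points and trap size of (2p-1):2 locking (one-harmonic map).

    Uses the approximate twice-composed map
    ``theta -> theta + 4*pi*f0/fs - (I**2/2)*sin(2*theta)``, whose four
    fixed points satisfy ``sin(2*theta) = 8*pi*delta/I**2`` with
    ``delta = f0/fs - (2p-1)/2``.  The two stable points are equidistant
    from their neighbouring unstable points, so a single representative
    pair is returned.
    """
    if I <= 0:
        raise NoLockingError("I must be > 0 for locking")
    delta = f0 / fs - (2 * p - 1) / 2.0
    s2 = 8.0 * np.pi * delta / (I * I)
    if abs(s2) > 1:
        raise NoLockingError(
            f"no (2p-1):2 fixed points: |4*pi*delta| = "
            f"{abs(4 * np.pi * delta):.4g} exceeds I**2/2 = {I * I / 2:.4g}")
    a = math.asin(s2)
    theta_stable = _wrap(a / 2.0)          # cos(2*theta) > 0 branch
    theta_unstable = _wrap((np.pi - a) / 2.0)
    h = np.pi / 2.0 - abs(a)               # = pi/2 -+ asin(8*pi*delta/I**2)
    if h <= 0:
        raise NoLockingError("degenerate trap (parameters on the boundary)")
    return FixedPointPair(theta_stable, theta_unstable, h)


def fixed_points_numeric(f0: float, fs: float, I: float, p: int, q: int = 1,
                         approximate: bool = False,
                         n_grid: int = 4096) -> FixedPointPair:
    """Brute-force fixed points by dense-grid bracketing and root refinement.

    For q = 1 the map itself is solved; for q = 2 either the exact
    twice-composed map (default) or the one-harmonic approximation
    (``approximate=True``, matching the analytic path of
    :func:`fixed_points_2pm1_2`).  Roots of the residual g(theta) =
    (composed map)(theta) - theta - 2*pi*p are classified by the sign of
    g'(theta): attracting (stable) where g' < 0.  For moderate amplitudes
    this coincides with the map-multiplier criterion |1 + I*cos(theta)| < 1
    and it remains well defined where strong stimulation makes the
    multiplier overshoot below -1.  Returns the stable point closest to
    its nearest unstable point, with that circular distance as the trap
    size.
    """
    ratio = 2.0 * np.pi * f0 / fs

    if q == 1:
        def g(th):
            return ratio + I * np.sin(th) - 2.0 * np.pi * p

        def gprime(th):
            return I * np.cos(th)
    elif q == 2:
        if approximate:
            def g(th):
                return 2.0 * ratio - (I * I / 2.0) * np.sin(2.0 * th) \
                    - 2.0 * np.pi * (2 * p - 1)

            def gprime(th):
                return -I * I * np.cos(2.0 * th)
        else:
            def F(th):
                return th + ratio + I * np.sin(th)

            def g(th):
                return F(F(th)) - th - 2.0 * np.pi * (2 * p - 1)

            def gprime(th):
                return (1.0 + I * np.cos(F(th))) * (1.0 + I * np.cos(th)) \
                    - 1.0
    else:
        raise ValueError("only q in {1, 2} is supported")

    grid = np.linspace(0.0, 2.0 * np.pi, n_grid + 1)
    vals = np.array([g(t) for t in grid])
    roots = []
    for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if va == 0.0:
            roots.append(a)
        elif va * vb < 0:
            roots.append(brentq(g, a, b, xtol=1e-14))
    if not roots:
        raise NoLockingError("no fixed points found on the grid")
    stable = [r for r in roots if gprime(r) < 0.0]
    unstable = [r for r in roots if gprime(r) >= 0.0]
    if not stable or not unstable:
        raise NoLockingError("could not classify a stable/unstable pair")
    best = None
    for s in stable:
        for u in unstable:
            d = _circ_dist(s, u)
            if best is None or d < best[2]:
                best = (s, u, d)
    return FixedPointPair(_wrap(best[0]), _wrap(best[1]), best[2])


def boundary_p1(f0, p: int, cfg: TheoryConfig):
    """Stimulation magnitude |I| on the p:1 tongue boundary at frequency f0.

    Obtained from the escape condition ``h = n_sigma * sigma`` with
    ``sigma = 2*pi*(f0/fs)*zeta``:

        I(f0) = | 2*pi*(f0/fs - p) / sin(pi*[(f0/fs)*n_sigma*zeta - 1/2]) |

    In the zeta -> 0 limit the denominator is -1 and the boundary reduces
    to ``I = 2*pi*|f0/fs - p|``.  Accepts scalar or array ``f0``.
    """
    x = np.asarray(f0, dtype=float) / cfg.fs
    denom = np.sin(np.pi * (x * cfg.n_sigma * cfg.zeta - 0.5))
    with np.errstate(divide="ignore"):
        out = np.abs(2.0 * np.pi * (x - p) / denom)
    return out if out.ndim else float(out)


def boundary_2pm1_2(f0, p: int, cfg: TheoryConfig):
    """Stimulation magnitude |I| on the (2p-1):2 tongue boundary at f0.

    Escape condition with jump ``sigma = 2*sqrt(2)*pi*(f0/fs)*zeta``:

        I(f0) = | 8*pi*(f0/fs - (2p-1)/2)
                  / sin(pi*[2*sqrt(2)*(f0/fs)*n_sigma*zeta - 1/2]) | ** 0.5
    """
    x = np.asarray(f0, dtype=float) / cfg.fs
    denom = np.sin(np.pi * (2.0 * np.sqrt(2.0) * x * cfg.n_sigma * cfg.zeta
                            - 0.5))
    with np.errstate(divide="ignore"):
        out = np.sqrt(np.abs(8.0 * np.pi * (x - (2 * p - 1) / 2.0) / denom))
    return out if out.ndim else float(out)


def width_p1(I: float, p: int, cfg: TheoryConfig) -> float:
    """Approximate p:1 tongue width in Hz at magnitude I and level zeta.

        width = (fs*I/pi) * (1 - n_sigma**2*zeta**2*(4*p**2*pi**2 + I**2)/8)

    clamped below at 0 (the Taylor expression goes negative once the tongue
    is destroyed).  At zeta = 0 the width is fs*I/pi for every p.
    """
    if I <= 0:
        raise ValueError("I must be > 0")
    bracket = 1.0 - cfg.n_sigma ** 2 * cfg.zeta ** 2 * \
        (4.0 * p * p * np.pi ** 2 + I * I) / 8.0
    return max(0.0, cfg.fs * I / np.pi * bracket)


def width_2pm1_2(I: float, p: int, cfg: TheoryConfig) -> float:
    """Approximate (2p-1):2 tongue width in Hz at magnitude I, level zeta.

        width = (fs*I**2/(4*pi))
                * (1 - n_sigma**2*zeta**2*(16*(2p-1)**2*pi**2 + I**4)/16)

    clamped below at 0.  At zeta = 0 the width is fs*I**2/(4*pi).
    """
    if I <= 0:
        raise ValueError("I must be > 0")
    m = 2 * p - 1
    bracket = 1.0 - cfg.n_sigma ** 2 * cfg.zeta ** 2 * \
        (16.0 * m * m * np.pi ** 2 + I ** 4) / 16.0
    return max(0.0, cfg.fs * I * I / (4.0 * np.pi) * bracket)


def relative_width_p1(p: int, zeta: float, n_sigma: float = 4.0) -> float:
    """Width of the p:1 tongue relative to the perfectly periodic case.

    ``1 - n_sigma**2 * pi**2 * p**2 * zeta**2 / 2``, clamped to [0, 1].
    Strictly smaller for p = 2, 3, ... than for p = 1 at any zeta > 0.
    """
    return float(np.clip(
        1.0 - n_sigma ** 2 * np.pi ** 2 * p * p * zeta ** 2 / 2.0, 0.0, 1.0))


def relative_width_2pm1_2(p: int, zeta: float, n_sigma: float = 4.0) -> float:
    """Width of the (2p-1):2 tongue relative to the periodic case.

    ``1 - n_sigma**2 * pi**2 * (2p-1)**2 * zeta**2``, clamped to [0, 1].
    Already for p = 1 (the 1:2 tongue) this shrinks twice as fast in
    zeta**2 as the 1:1 tongue.
    """
    m = 2 * p - 1
    return float(np.clip(
        1.0 - n_sigma ** 2 * np.pi ** 2 * m * m * zeta ** 2, 0.0, 1.0))
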