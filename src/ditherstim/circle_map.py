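"""Sine circle map with and without dithered stimulation.

The sine circle map is the simplest description of a neural oscillator of
natural frequency ``f0`` receiving one stimulation pulse per period of a
pulse train of frequency ``fs``.  Writing ``theta_n`` for the oscillator
phase immediately before pulse ``n``,

    theta_{n+1} = theta_n + 2*pi*f0/fs + I*sin(theta_n)

where ``I`` is the stimulation magnitude and ``sin`` plays the role of the
oscillator's phase response curve.  Dithered stimulation multiplies the
stimulation period by ``(1 + z_n)`` with ``z_n ~ N(0, zeta**2)``, giving the
stochastic map

    theta_{n+1} = theta_n + 2*pi*(f0/fs)*(1 + z_n) + I*sin(theta_n).

Phases are accumulated unwrapped (not reduced mod 2*pi) so that rotation
numbers can be read off the trajectory endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CircleMapConfig", "PhaseTrajectory", "iterate_deterministic",
           "iterate_dithered"]

_Z_CHUNK = 1024  # steps of noise drawn per block when iterating


@dataclass(frozen=True)
class CircleMapConfig:
    """Parameters of the (stochastic) sine circle map.

    Parameters
    ----------
    f0 : float
        Oscillator natural frequency in Hz (>= 0).
    fs : float
        Base stimulation frequency in Hz (> 0).
    I : float
        Stimulation magnitude, a dimensionless phase advance in radians
        (>= 0).
    zeta : float, default 0
        Dithering level: standard deviation of the relative perturbation of
        the stimulation period (>= 0).
    """

    f0: float
    fs: float
    I: float
    zeta: float = 0.0

    def __post_init__(self):
        for name in ("f0", "fs", "I", "zeta"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.f0 < 0:
            raise ValueError("f0 must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.I < 0:
            raise ValueError("I must be >= 0")
        if self.zeta < 0:
            raise ValueError("zeta must be >= 0")

    @property
    def ratio(self) -> float:
        """Unperturbed per-pulse phase advance 2*pi*f0/fs (radians)."""
        return 2.0 * np.pi * self.f0 / self.fs


@dataclass
class PhaseTrajectory:
    """Unwrapped phases sampled immediately before each stimulation pulse.

    ``phases`` has length ``n_pulses + 1`` (initial phase included) and is
    cumulative: it is never reduced mod 2*pi.
    """

    phases: np.ndarray
    n_pulses: int
    seed: object = None
    config: CircleMapConfig | None = field(default=None, repr=False)

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 1 or len(self.phases) != self.n_pulses + 1:
            raise ValueError("phases must be 1-D with length n_pulses + 1")

    def to_csv(self, path) -> None:
        """Write (pulse index, unwrapped phase in radians) as two columns."""
        idx = np.arange(self.n_pulses + 1)
        arr = np.column_stack([idx, self.phases])
        np.savetxt(path, arr, delimiter=",", header="pulse,phase_rad",
                   comments="", fmt=("%d", "%.17g"))


def _validate(config: CircleMapConfig, theta0: float, n: int) -> None:
    if not isinstance(config, CircleMapConfig):
        raise TypeError("config must be a CircleMapConfig")
    if not np.isfinite(theta0):
        raise ValueError("theta0 must be finite")
    if n < 1:
        raise ValueError("n must be >= 1")


def iterate_deterministic(config: CircleMapConfig, theta0: float,
                          n: int) -> PhaseTrajectory:
    """Iterate the deterministic sine circle map for ``n`` pulses.

    Requires ``config.zeta == 0``.  Returns the unwrapped trajectory
    ``[theta0, theta1, ..., theta_n]``.
    """
    _validate(config, theta0, n)
    if config.zeta != 0:
        raise ValueError("iterate_deterministic requires zeta = 0; "
                         "use iterate_dithered for zeta > 0")
    ratio = config.ratio
    stim = config.I
    phases = np.empty(n + 1)
    phases[0] = theta0
    th = float(theta0)
    for k in range(n):
        th = th + ratio + stim * np.sin(th)
        phases[k + 1] = th
    return PhaseTrajectory(phases, n, seed=None, config=config)


def iterate_dithered(config: CircleMapConfig, theta0: float, n: int,
                     seed=None) -> PhaseTrajectory:
    """Iterate the stochastic (dithered) sine circle map for ``n`` pulses.

    Each step draws an independent ``z_k ~ N(0, zeta**2)`` perturbing the
    per-pulse phase advance.  A seed is required whenever ``zeta > 0``;
    identical seeds give bitwise-identical trajectories.  With ``zeta = 0``
    the output equals :func:`iterate_deterministic` for any seed.
    """
    _validate(config, theta0, n)
    if config.zeta == 0:
        traj = iterate_deterministic(
            CircleMapConfig(config.f0, config.fs, config.I, 0.0), theta0, n)
        traj.seed = seed
        traj.config = config
        return traj
    if seed is None:
        raise ValueError("a seed is required when zeta > 0")
    rng = np.random.default_rng(seed)
    ratio = config.ratio
    phases = np.empty(n + 1)
    phases[0] = theta0
    th = float(theta0)
    # draw noise in blocks; the stream is identical to one standard_normal(n)
    pos = 0
    while pos < n:
        blk = min(_Z_CHUNK, n - pos)
        z = rng.standard_normal(blk)
        for j in range(blk):
            th = th + ratio * (1.0 + config.zeta * z[j]) + \
                config.I * np.sin(th)
            phases[pos + j + 1] = th
        pos += blk
    return PhaseTrajectory(phases, n, seed=seed, config=config)
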