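"""Stimulated populations of coupled, noisy phase oscillators.

Each of ``M`` oscillators follows the stochastic phase equation

    d(phi_k) = [omega_k + kappa*rho*sin(psi - phi_k)
                + I(t)*Z(phi_k)] dt + xi dW_k

where ``rho * exp(i*psi)`` is the population order parameter (recomputed
from the current phases at every step), ``I(t)`` the stimulation pulse
train, ``Z`` the phase response curve, ``xi`` the intrinsic noise standard
deviation and ``W_k`` independent Wiener processes.  This is the
order-parameter (attractive mean-field) form of homogeneous all-to-all
sine coupling, integrated with an Euler-Maruyama scheme.

Intrinsic frequencies are Lorentzian (Cauchy) distributed in Hz around a
population centre; negative draws are resampled so all oscillators rotate
forward.  The default parameters (M = 100, kappa = 350 rad/s, xi = 7.9
rad/sqrt(s), width 20 Hz, dt = 1e-4 s) produce a partially synchronised
population whose output signal X(t) = rho*cos(psi) resembles a noisy
neural oscillation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from ._engine import kuramoto_integrate
from .pulse_trains import BiphasicWaveform, PulseTrain

__all__ = ["KuramotoConfig", "OrderParameterSeries",
           "sample_intrinsic_frequencies", "simulate", "psi_at_pulses",
           "load_prc_table"]


@dataclass(frozen=True)
class KuramotoConfig:
    """Population parameters.

    Parameters
    ----------
    f0_center : float
        Centre of the intrinsic-frequency distribution in Hz.
    M : int
        Population size (default 100).
    kappa : float
        Coupling strength in rad/s (default 350).
    xi : float
        Intrinsic noise standard deviation in rad/sqrt(s) (default 7.9).
    lorentz_width : float
        Scale (half width at half maximum) of the Cauchy distribution of
        intrinsic frequencies, in Hz (default 20).
    prc : str | numpy.ndarray | callable
        Phase response curve: ``"sin"`` (default), a table sampled
        uniformly on [0, 2*pi) (linearly interpolated, periodic), or any
        2*pi-periodic callable.
    dt : float
        Euler-Maruyama step in seconds (default 1e-4).
    seed : optional
        Seed for intrinsic frequencies, initial phases and noise.
    """

    f0_center: float
    M: int = 100
    kappa: float = 350.0
    xi: float = 7.9
    lorentz_width: float = 20.0
    prc: object = "sin"
    dt: float = 1e-4
    seed: object = None

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.lorentz_width < 0:
            raise ValueError("lorentz_width must be >= 0")
        if self.xi < 0:
            raise ValueError("xi must be >= 0")

    def with_seed(self, seed) -> "KuramotoConfig":
        return replace(self, seed=seed)


@dataclass
class OrderParameterSeries:
    """Order-parameter modulus, unwrapped phase and output signal.

    ``rho`` lies in [0, 1] at every sample; ``psi`` is accumulated without
    2*pi jumps; ``x = rho*cos(psi)`` is the population output signal.
    """

    times: np.ndarray
    rho: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if not (len(self.times) == len(self.rho) == len(self.psi)):
            raise ValueError("times, rho, psi must have equal length")
        if (self.rho < -1e-12).any() or (self.rho > 1.0 + 1e-9).any():
            raise ValueError("rho must lie in [0, 1]")

    @property
    def x(self) -> np.ndarray:
        return self.rho * np.cos(self.psi)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_csv(self, path, sidecar_path=None, config=None) -> None:
        arr = np.column_stack([self.times, self.rho, self.psi, self.x])
        np.savetxt(path, arr, delimiter=",", header="t_s,rho,psi_rad,x",
                   comments="", fmt="%.17g")
        if sidecar_path is not None:
            meta = {}
            if config is not None:
                meta = {"M": config.M, "kappa": config.kappa, "xi": config.xi,
                        "f0_center": config.f0_center,
                        "lorentz_width": config.lorentz_width,
                        "dt": config.dt,
                        "seed": None if config.seed is None
                        else int(config.seed)}
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1)


def sample_intrinsic_frequencies(config: KuramotoConfig,
                                 seed=None) -> np.ndarray:
    """Draw intrinsic frequencies omega_k in rad/s.

    ``omega_k / (2*pi)`` follows a Cauchy law centred on ``f0_center`` with
    scale ``lorentz_width`` (Hz); negative draws are resampled.  With
    ``lorentz_width == 0`` every oscillator gets exactly the centre
    frequency.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if config.lorentz_width == 0:
        return np.full(config.M, 2.0 * np.pi * config.f0_center)
    f = config.f0_center + config.lorentz_width * \
        rng.standard_cauchy(config.M)
    while True:
        bad = f <= 0
        if not bad.any():
            break
        f[bad] = config.f0_center + config.lorentz_width * \
            rng.standard_cauchy(int(bad.sum()))
    return 2.0 * np.pi * f


def simulate(config: KuramotoConfig, train: PulseTrain | None,
             duration: float | None = None, decimation: int = 1,
             min_steps_per_lobe: int = 10):
    """Simulate the stimulated population; return (series, final_phases).

    ``train`` may be None for an unstimulated run (then ``duration`` is
    required).  The integration step must resolve the positive pulse lobe
    with at least ``min_steps_per_lobe`` steps (judged on the nominal base
    period).  Identical ``config.seed`` gives identical series.
    ``decimation`` subsamples the recorded series (the integration step is
    unchanged).
    """
    if train is None and duration is None:
        raise ValueError("duration is required for an unstimulated run")
    if duration is None:
        duration = train.duration
    dt = config.dt
    n_steps = int(np.ceil(duration / dt))
    if train is not None:
        if not isinstance(train.waveform, BiphasicWaveform):
            raise ValueError("population simulation requires a pulse train "
                             "carrying a BiphasicWaveform")
        nominal_lobe = train.waveform.positive_fraction * \
            float(np.mean(train.periods))
        if nominal_lobe / dt < min_steps_per_lobe:
            raise ValueError(
                f"dt = {dt:g} s is too coarse for the waveform: the "
                f"positive lobe ({nominal_lobe:g} s) must span at least "
                f"{min_steps_per_lobe} integration steps")
        stim_t = train.stimulus_on_grid(dt, n_steps)
    else:
        stim_t = np.zeros(n_steps)

    seed = config.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_omega, s_phase, s_noise = ss.spawn(3)
    omegas = sample_intrinsic_frequencies(config, seed=s_omega)
    phases = np.random.default_rng(s_phase).uniform(0.0, 2.0 * np.pi,
                                                    config.M)
    if config.xi > 0:
        dW = np.random.default_rng(s_noise).standard_normal(
            (config.M, n_steps))
    else:
        dW = np.zeros((config.M, n_steps))

    rho, psi = kuramoto_integrate(phases, omegas, config.kappa, config.xi,
                                  dt, stim_t, dW, config.prc)
    times = np.arange(n_steps) * dt
    d = max(1, int(decimation))
    series = OrderParameterSeries(times[::d], rho[::d], psi[::d])
    return series, phases


def psi_at_pulses(series: OrderParameterSeries,
                  train: PulseTrain) -> np.ndarray:
    """Order-parameter phase one integration step before each pulse.

    Requires an undecimated series.  Used to measure the population
    rotation number with the same estimator as for the circle map.
    """
    dt = series.dt
    idx = np.maximum(np.round(train.pulse_times / dt).astype(int) - 1, 0)
    idx = idx[idx < len(series.psi)]
    return series.psi[idx]


def load_prc_table(path, n_points: int = 512) -> np.ndarray:
    """Load a tabulated PRC from a two-column CSV (theta_rad, Z).

    The table is interpolated onto ``n_points`` uniform samples of
    [0, 2*pi) and can be passed as ``KuramotoConfig.prc``.
    """
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    theta, z = data[:, 0], data[:, 1]
    grid = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return np.interp(grid, theta, z, period=2.0 * np.pi)
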