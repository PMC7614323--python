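"""Stimulation pulse trains and device-implementable dithering schemes.

Dithered stimulation in continuous time draws each inter-pulse interval as
``(1 + z)/fs`` with ``z ~ N(0, zeta**2)``.  Neurostimulators that cannot
generate such noise can approximate it by toggling within a finite set of
stimulation frequencies whose periods are symmetrically distributed around
the base period: randomly (a new set member per period), deterministically
(cycling through the set in order), or slowly (holding each frequency for
``N_r`` consecutive periods).

For continuous-time population simulations each period carries a
charge-balanced biphasic square waveform: a positive lobe occupying a fixed
fraction of the period followed by a negative lobe whose amplitude is set
so that the waveform integrates to zero over the period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.stats import norm

__all__ = ["FrequencySet", "CyclingScheme", "CyclingMode", "PulseTrain",
           "BiphasicWaveform", "dithered_train", "periodic_train",
           "build_frequency_set", "cycling_train", "biphasic_waveform",
           "switching_interval", "equivalent_zeta"]


class CyclingMode(str, Enum):
    PERIODIC = "periodic"
    WHITE_NOISE = "white_noise"
    RANDOM_CYCLING = "random_cycling"
    DETERMINISTIC_CYCLING = "deterministic_cycling"
    SLOW_DETERMINISTIC_CYCLING = "slow_deterministic_cycling"


@dataclass(frozen=True)
class CyclingScheme:
    """How successive stimulation periods are chosen.

    ``N_r`` (slow deterministic cycling only) is the number of consecutive
    periods spent at each frequency before toggling to the next;
    ``zeta`` applies to white-noise dithering only.
    """

    mode: CyclingMode
    N_r: int = 1
    zeta: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "mode", CyclingMode(self.mode))
        if self.N_r < 1:
            raise ValueError("N_r must be >= 1")
        if self.zeta < 0:
            raise ValueError("zeta must be >= 0")


@dataclass(frozen=True)
class FrequencySet:
    """An ordered set of stimulation frequencies for cycling schemes.

    The corresponding periods ``1/f`` are symmetrically distributed around
    the base period ``1/base_fs``; frequencies are strictly increasing.
    """

    frequencies: tuple
    base_fs: float

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", tuple(f))
        if f.ndim != 1 or len(f) < 1:
            raise ValueError("frequencies must be a non-empty 1-D sequence")
        if (f <= 0).any():
            raise ValueError("frequencies must be strictly positive")
        if (np.diff(f) <= 0).any():
            raise ValueError("frequencies must be strictly increasing")
        periods = 1.0 / f
        mean_period = periods.mean()
        if not np.isclose(mean_period, 1.0 / self.base_fs, rtol=1e-9):
            raise ValueError("base_fs must be the reciprocal mean period")
        # symmetry of periods around the base period
        centred = np.sort(periods) - mean_period
        if not np.allclose(centred, -centred[::-1], atol=1e-12):
            raise ValueError("periods must be symmetric around 1/base_fs")

    @property
    def periods(self) -> np.ndarray:
        """Periods in seconds, ordered to match ``frequencies``."""
        return 1.0 / np.asarray(self.frequencies)

    @property
    def n(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class BiphasicWaveform:
    """Charge-balanced biphasic square pulse, described per period.

    The positive lobe (amplitude ``positive_amplitude``) occupies
    ``positive_fraction`` of the period; the negative lobe fills the rest
    with amplitude ``negative_amplitude`` chosen so the per-period time
    integral vanishes.
    """

    positive_amplitude: float
    positive_fraction: float
    negative_amplitude: float

    def integral(self, period: float) -> float:
        """Time integral of the waveform over one period (== 0)."""
        t_pos = self.positive_fraction * period
        return self.positive_amplitude * t_pos + \
            self.negative_amplitude * (period - t_pos)

    def sample(self, t, period: float):
        """Waveform value at time ``t`` (in [0, period)) within a period."""
        t = np.asarray(t, dtype=float)
        out = np.where(t < self.positive_fraction * period,
                       self.positive_amplitude, self.negative_amplitude)
        return out if out.ndim else float(out)


@dataclass
class PulseTrain:
    """Pulse onset times, per-pulse periods, waveform and provenance."""

    pulse_times: np.ndarray
    periods: np.ndarray
    waveform: BiphasicWaveform | str
    scheme: CyclingScheme
    seed: object = None
    frequency_set: FrequencySet | None = field(default=None, repr=False)

    def __post_init__(self):
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        self.periods = np.asarray(self.periods, dtype=float)
        if len(self.pulse_times) != len(self.periods):
            raise ValueError("pulse_times and periods must match in length")
        if (self.periods <= 0).any():
            raise ValueError("all periods must be > 0")
        if (np.diff(self.pulse_times) <= 0).any():
            raise ValueError("pulse_times must be strictly increasing")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_times)

    @property
    def duration(self) -> float:
        """Total train duration: last onset plus its period (s)."""
        return float(self.pulse_times[-1] + self.periods[-1])

    def with_waveform(self, waveform: BiphasicWaveform) -> "PulseTrain":
        return PulseTrain(self.pulse_times.copy(), self.periods.copy(),
                          waveform, self.scheme, self.seed,
                          self.frequency_set)

    def stimulus_on_grid(self, dt: float, n_steps: int | None = None
                         ) -> np.ndarray:
        """Render I(t) on a uniform time grid of step ``dt``.

        Each period holds the biphasic waveform (positive lobe first).
        Raises if the waveform is symbolic ("impulse").
        """
        if not isinstance(self.waveform, BiphasicWaveform):
            raise ValueError("continuous-time rendering requires a "
                             "BiphasicWaveform (got an impulse train)")
        if n_steps is None:
            n_steps = int(np.ceil(self.duration / dt))
        out = np.zeros(n_steps)
        w = self.waveform
        for t0, T in zip(self.pulse_times, self.periods):
            i0 = int(round(t0 / dt))
            i1 = min(int(round((t0 + w.positive_fraction * T) / dt)), n_steps)
            i2 = min(int(round((t0 + T) / dt)), n_steps)
            if i0 >= n_steps:
                break
            out[i0:i1] = w.positive_amplitude
            out[i1:i2] = w.negative_amplitude
        return out

    def to_csv(self, path, sidecar_path=None) -> None:
        """Write (pulse index, onset s, period s, frequency Hz) as CSV,
        plus a JSON sidecar recording scheme and seed."""
        idx = np.arange(self.n_pulses)
        arr = np.column_stack([idx, self.pulse_times, self.periods,
                               1.0 / self.periods])
        np.savetxt(path, arr, delimiter=",",
                   header="pulse,onset_s,period_s,frequency_hz",
                   comments="", fmt=("%d", "%.17g", "%.17g", "%.17g"))
        if sidecar_path is not None:
            meta = {
                "mode": self.scheme.mode.value,
                "N_r": self.scheme.N_r,
                "zeta": self.scheme.zeta,
                "seed": None if self.seed is None else int(self.seed),
                "n_pulses": int(self.n_pulses),
            }
            if self.frequency_set is not None:
                meta["frequencies_hz"] = list(self.frequency_set.frequencies)
                meta["base_fs_hz"] = self.frequency_set.base_fs
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1)


def _times_from_periods(periods: np.ndarray) -> np.ndarray:
    times = np.empty_like(periods)
    times[0] = 0.0
    np.cumsum(periods[:-1], out=times[1:])
    return times


def periodic_train(fs: float, n_pulses: int,
                   waveform: BiphasicWaveform | str = "impulse"
                   ) -> PulseTrain:
    """Perfectly periodic train at frequency ``fs``."""
    if fs <= 0:
        raise ValueError("fs must be > 0")
    periods = np.full(n_pulses, 1.0 / fs)
    return PulseTrain(_times_from_periods(periods), periods, waveform,
                      CyclingScheme(CyclingMode.PERIODIC))


def dithered_train(fs: float, zeta: float, n_pulses: int, seed=None,
                   waveform: BiphasicWaveform | str = "impulse"
                   ) -> PulseTrain:
    """White-noise dithered train: periods ``(1 + z_k)/fs``.

    Draws with ``1 + z_k <= 0`` (which would produce a non-causal train)
    are resampled; for zeta <= 0.2 this affects fewer than 1e-6 of draws.
    A zeta so large that more than half the draws would be rejected is
    outside the intended regime and raises.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if zeta < 0:
        raise ValueError("zeta must be >= 0")
    if zeta == 0:
        tr = periodic_train(fs, n_pulses, waveform)
        return PulseTrain(tr.pulse_times, tr.periods, waveform,
                          CyclingScheme(CyclingMode.WHITE_NOISE, zeta=0.0),
                          seed)
    if norm.cdf(-1.0 / zeta) > 0.1:
        # resampling would then visibly distort the period distribution
        raise ValueError(
            f"zeta = {zeta:g} would reject {norm.cdf(-1.0 / zeta):.0%} of "
            "period draws; parameter far outside the intended regime "
            "(zeta <~ 0.2)")
    if seed is None:
        raise ValueError("a seed is required when zeta > 0")
    rng = np.random.default_rng(seed)
    z = zeta * rng.standard_normal(n_pulses)
    while True:
        bad = z <= -1.0
        if not bad.any():
            break
        z[bad] = zeta * rng.standard_normal(int(bad.sum()))
    periods = (1.0 + z) / fs
    return PulseTrain(_times_from_periods(periods), periods, waveform,
                      CyclingScheme(CyclingMode.WHITE_NOISE, zeta=zeta),
                      seed)


def build_frequency_set(f_min: float, f_max: float, n: int) -> FrequencySet:
    """Frequency set whose periods are equally spaced on [1/f_max, 1/f_min].

    Equally spaced periods make the (discrete-uniform) period distribution
    symmetric around its mean; the base frequency is the reciprocal of the
    mean period.  Note the resulting frequency values are skewed: equal
    period spacing concentrates frequencies toward ``f_min``.
    """
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    if n < 2:
        raise ValueError("n must be >= 2")
    periods = np.linspace(1.0 / f_max, 1.0 / f_min, n)
    freqs = np.sort(1.0 / periods)
    base_fs = 1.0 / periods.mean()
    return FrequencySet(tuple(freqs), base_fs)


def equivalent_zeta(freq_set: FrequencySet) -> float:
    """Dithering level equivalent to cycling over the frequency set.

    Standard deviation of the continuous uniform distribution of periods
    over [min period, max period], divided by the mean period.
    """
    periods = freq_set.periods
    lo, hi = periods.min(), periods.max()
    return float((hi - lo) / np.sqrt(12.0) / ((hi + lo) / 2.0))


def cycling_train(freq_set: FrequencySet, scheme: CyclingScheme,
                  n_pulses: int, seed=None,
                  waveform: BiphasicWaveform | str = "impulse",
                  start_index: int = 0) -> PulseTrain:
    """Pulse train cycling over a finite frequency set.

    random_cycling draws each period independently and uniformly from the
    set; deterministic_cycling steps through the set in order (from
    ``start_index``, default the lowest frequency) wrapping around; slow
    deterministic cycling holds each frequency ``N_r`` consecutive periods.
    """
    mode = scheme.mode
    set_periods = freq_set.periods  # ordered by increasing frequency
    if mode == CyclingMode.RANDOM_CYCLING:
        if seed is None:
            raise ValueError("random cycling requires a seed")
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, freq_set.n, size=n_pulses)
    elif mode == CyclingMode.DETERMINISTIC_CYCLING:
        idx = (start_index + np.arange(n_pulses)) % freq_set.n
    elif mode == CyclingMode.SLOW_DETERMINISTIC_CYCLING:
        idx = (start_index + np.arange(n_pulses) // scheme.N_r) % freq_set.n
    else:
        raise ValueError(f"{mode.value} is not a cycling mode")
    periods = set_periods[idx]
    return PulseTrain(_times_from_periods(periods), periods, waveform,
                      scheme, seed, freq_set)


def biphasic_waveform(positive_fraction: float = 0.2,
                      positive_amplitude: float = 1.0) -> BiphasicWaveform:
    """Charge-balanced biphasic square waveform description.

    The negative amplitude is
    ``-positive_amplitude * positive_fraction / (1 - positive_fraction)``
    so the per-period time integral is exactly zero.
    """
    if not 0 < positive_fraction < 1:
        raise ValueError("positive_fraction must lie in (0, 1)")
    neg = -positive_amplitude * positive_fraction / (1.0 - positive_fraction)
    return BiphasicWaveform(positive_amplitude, positive_fraction, neg)


def switching_interval(freq_set: FrequencySet, N_r: int) -> tuple:
    """(shortest, longest) frequency hold time in ms under slow cycling.

    With ``N_r`` periods per frequency, the hold time at frequency f is
    ``N_r / f``; the extremes of the set give the bounds.
    """
    if N_r < 1:
        raise ValueError("N_r must be >= 1")
    f = np.asarray(freq_set.frequencies)
    return (1000.0 * N_r / f.max(), 1000.0 * N_r / f.min())
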