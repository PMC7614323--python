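"""Entrainment metrics: rotation numbers, plateau detection, tongue widths.

The primary metric is the rotation number

    R = (phi_N - phi_0) / (2*pi*N)

over ``N`` stimulation pulses, with ``phi_n`` the unwrapped oscillator
phase (circle map) or order-parameter phase (population model) sampled
just before pulse ``n``.  A rational R = p/q signals p:q frequency
locking.

Frequency locking at ratio p:q is detected along a natural-frequency grid
where both

    |R - p/q| < tol         and        |S(dR/df0)| < tol'

hold, ``S`` being a LOWESS-smoothed derivative of the repeat-averaged
rotation number.  The derivative is taken with respect to the normalized
frequency ``f0/fs`` by default, which makes ``tol'`` dimensionless: an
unlocked oscillator tracks its own frequency with slope d R/d(f0/fs) ~ 1,
far above ``tol'``, while on a locking plateau the slope is ~0.  (A
per-Hz variant is available via ``derivative_scale="per_hz"``.)

Also provided: the mean instantaneous frequency of an order-parameter
series and the phase-locking value (PLV) between two phase signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .circle_map import PhaseTrajectory
from .kuramoto import OrderParameterSeries
from .pulse_trains import PulseTrain

__all__ = ["DetectionConfig", "EntrainmentMap", "default_candidate_ratios",
           "rotation_number", "smoothed_derivative", "detect_locking",
           "tongue_width_from_map", "mean_instantaneous_frequency", "plv",
           "train_instantaneous_phase"]


def default_candidate_ratios(p_max: int = 4, q_max: int = 4,
                             p1_max: int = 8) -> tuple:
    """All coprime p:q with p <= p_max, q <= q_max, plus p:1 up to p1_max."""
    out = set()
    for p in range(1, p1_max + 1):
        out.add((p, 1))
    for p in range(1, p_max + 1):
        for q in range(1, q_max + 1):
            if math.gcd(p, q) == 1:
                out.add((p, q))
    return tuple(sorted(out, key=lambda pq: pq[0] / pq[1]))


@dataclass(frozen=True)
class DetectionConfig:
    """Plateau-detection tolerances and smoothing span.

    ``tol`` bounds |R - p/q|; ``tol_prime`` bounds the smoothed derivative
    of R (dimensionless when ``derivative_scale="normalized"``, per Hz
    when ``"per_hz"``).  The LOWESS span is expressed as a
    nearest-neighbour sample count (``lowess_span_hz`` is the equivalent
    width in Hz for a given grid, kept for bookkeeping).
    """

    tol: float
    tol_prime: float
    fs: float
    lowess_span_samples: int = 4
    lowess_span_hz: float | None = None
    candidate_ratios: tuple = field(default_factory=default_candidate_ratios)
    derivative_scale: str = "normalized"

    def __post_init__(self):
        if self.tol <= 0 or self.tol_prime <= 0:
            raise ValueError("tol and tol_prime must be > 0")
        if self.derivative_scale not in ("normalized", "per_hz"):
            raise ValueError("derivative_scale must be 'normalized' or "
                             "'per_hz'")
        for p, q in self.candidate_ratios:
            if math.gcd(int(p), int(q)) != 1:
                raise ValueError(f"candidate ratio {p}:{q} is not coprime")

    @classmethod
    def circle_map(cls, fs: float = 130.0, **kw) -> "DetectionConfig":
        """Tolerances used for sine-circle-map sweeps."""
        return cls(tol=6e-4, tol_prime=1e-2, fs=fs, **kw)

    @classmethod
    def kuramoto(cls, fs: float = 130.0, **kw) -> "DetectionConfig":
        """Tolerances used for coupled-population sweeps."""
        return cls(tol=3e-2, tol_prime=2e-2, fs=fs, **kw)

    def min_ratio_gap(self) -> float:
        vals = sorted(p / q for p, q in self.candidate_ratios)
        return min(b - a for a, b in zip(vals[:-1], vals[1:]))


def rotation_number(traj) -> float:
    """Rotation number (phi_N - phi_0) / (2*pi*N) of an unwrapped series.

    Accepts a :class:`PhaseTrajectory`, a plain array of unwrapped phases
    sampled once per pulse, or an :class:`OrderParameterSeries` is *not*
    accepted directly (sample it at pulse times first).  Raises if the
    input looks wrapped (confined to one turn with near -2*pi drops).
    """
    if isinstance(traj, PhaseTrajectory):
        phases = traj.phases
    else:
        phases = np.asarray(traj, dtype=float)
    if phases.ndim != 1 or len(phases) < 2:
        raise ValueError("need a 1-D series of at least two phases")
    inc = np.diff(phases)
    # wrapped-input heuristic: a series confined to a single turn whose
    # increments both advance and drop by a combined spread of more than
    # pi is the sawtooth signature of phases reduced mod 2*pi
    if (phases.max() - phases.min() <= 2.0 * np.pi + 1e-9) \
            and inc.min() < -0.05 and inc.max() - inc.min() > np.pi:
        raise ValueError("phases appear to be wrapped mod 2*pi; rotation "
                         "numbers require unwrapped phases")
    N = len(phases) - 1
    return float((phases[-1] - phases[0]) / (2.0 * np.pi * N))


def smoothed_derivative(f0_grid, R_values, span_samples: int = 4
                        ) -> np.ndarray:
    """LOWESS-smoothed derivative dR/df0 (per Hz) on a uniform grid.

    Central finite differences (one-sided at the edges) followed by
    tricube-weighted local-linear smoothing with a nearest-neighbour span
    of ``span_samples``.  Linear data pass through unchanged.
    """
    f0 = np.asarray(f0_grid, dtype=float)
    R = np.asarray(R_values, dtype=float)
    if f0.ndim != 1 or f0.shape != R.shape:
        raise ValueError("f0_grid and R_values must be matching 1-D arrays")
    if len(f0) < 4:
        raise ValueError("need at least 4 samples")
    steps = np.diff(f0)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("f0_grid must be uniform")
    if span_samples < 2:
        raise ValueError("smoothing span must cover at least 2 grid steps")
    d = np.gradient(R, f0)
    frac = min(1.0, span_samples / len(f0))
    return _lowess(d, f0, frac=frac, it=0, return_sorted=False)


def detect_locking(f0_grid, R_values, cfg: DetectionConfig) -> list:
    """Per-frequency locking label: a (p, q) tuple or None.

    A bin is labelled p:q when |R - p/q| < tol and the smoothed derivative
    condition holds.  The candidate set must keep neighbouring ratios at
    least 2*tol apart so labels are unique.
    """
    if not cfg.candidate_ratios:
        raise ValueError("candidate_ratios must be nonempty")
    if len(cfg.candidate_ratios) > 1 and cfg.min_ratio_gap() < 2 * cfg.tol:
        raise ValueError("tol too large: two candidate ratios are closer "
                         "than 2*tol, labels would be ambiguous")
    R = np.asarray(R_values, dtype=float)
    S = smoothed_derivative(f0_grid, R, cfg.lowess_span_samples)
    if cfg.derivative_scale == "normalized":
        S = S * cfg.fs
    flat = np.abs(S) < cfg.tol_prime
    labels = [None] * len(R)
    for p, q in cfg.candidate_ratios:
        close = np.abs(R - p / q) < cfg.tol
        for i in np.nonzero(close & flat)[0]:
            labels[i] = (int(p), int(q))
    return labels


@dataclass
class EntrainmentMap:
    """Rotation numbers and locking labels over a (f0, I) grid.

    ``R`` has shape (len(I_grid), len(f0_grid)) and holds the
    repeat-averaged rotation number; ``label_p``/``label_q`` hold the
    detected ratio per cell (0 where unlocked); ``f_inst`` (population
    sweeps only) the mean instantaneous frequency in Hz.
    """

    f0_grid: np.ndarray
    I_grid: np.ndarray
    R: np.ndarray
    label_p: np.ndarray
    label_q: np.ndarray
    n_repeats: int
    n_pulses: int
    f_inst: np.ndarray | None = None
    zeta: float | None = None
    scheme: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.f0_grid = np.asarray(self.f0_grid, dtype=float)
        self.I_grid = np.asarray(self.I_grid, dtype=float)
        shape = (len(self.I_grid), len(self.f0_grid))
        for name in ("R", "label_p", "label_q"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            setattr(self, name, arr)
        if not np.isfinite(self.R).all():
            raise ValueError("R must be finite everywhere")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def bin_width(self) -> float:
        if len(self.f0_grid) < 2:
            raise ValueError("bin width undefined for a single-bin grid")
        return float(self.f0_grid[1] - self.f0_grid[0])

    def row_index(self, I: float) -> int:
        j = int(np.argmin(np.abs(self.I_grid - I)))
        if not np.isclose(self.I_grid[j], I, rtol=1e-9, atol=1e-12):
            raise ValueError(f"I = {I} is not on the amplitude grid")
        return j

    def to_csv(self, path, sidecar_path=None) -> None:
        """Tidy CSV (f0, I, R, label_p, label_q[, f_inst]) + JSON sidecar."""
        import json
        import pandas as pd
        nI, nf = self.R.shape
        df = pd.DataFrame({
            "f0_hz": np.tile(self.f0_grid, nI),
            "I": np.repeat(self.I_grid, nf),
            "R": self.R.ravel(),
            "label_p": self.label_p.ravel(),
            "label_q": self.label_q.ravel(),
        })
        if self.f_inst is not None:
            df["f_inst_hz"] = self.f_inst.ravel()
        df.to_csv(path, index=False)
        if sidecar_path is not None:
            meta = dict(self.metadata)
            meta.update({"n_repeats": self.n_repeats,
                         "n_pulses": self.n_pulses,
                         "zeta": self.zeta, "scheme": self.scheme,
                         "f0_grid": self.f0_grid.tolist(),
                         "I_grid": self.I_grid.tolist()})
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path, sidecar_path) -> "EntrainmentMap":
        import json
        import pandas as pd
        df = pd.read_csv(path)
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        f0 = np.asarray(meta["f0_grid"])
        I = np.asarray(meta["I_grid"])
        shape = (len(I), len(f0))
        f_inst = (df["f_inst_hz"].to_numpy().reshape(shape)
                  if "f_inst_hz" in df else None)
        return cls(f0, I, df["R"].to_numpy().reshape(shape),
                   df["label_p"].to_numpy().reshape(shape),
                   df["label_q"].to_numpy().reshape(shape),
                   n_repeats=meta["n_repeats"], n_pulses=meta["n_pulses"],
                   f_inst=f_inst, zeta=meta.get("zeta"),
                   scheme=meta.get("scheme"),
                   metadata={k: v for k, v in meta.items()
                             if k not in ("f0_grid", "I_grid", "n_repeats",
                                          "n_pulses", "zeta", "scheme")})


def tongue_width_from_map(emap: EntrainmentMap, p: int, q: int,
                          I: float) -> float:
    """Measured p:q tongue width (Hz) at amplitude I.

    The sum of the widths of all frequency bins labelled p:q in the map
    row at amplitude ``I`` (which must lie on the amplitude grid).
    """
    j = emap.row_index(I)
    hits = (emap.label_p[j] == p) & (emap.label_q[j] == q)
    n = int(hits.sum())
    return 0.0 if n == 0 else n * emap.bin_width


def mean_instantaneous_frequency(series: OrderParameterSeries,
                                 window: tuple | None = None) -> float:
    """Time-averaged d(psi)/dt / (2*pi) in Hz over ``window`` = (t0, t1)."""
    t, psi = series.times, series.psi
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        if m.sum() < 2:
            raise ValueError("window contains fewer than two samples")
        t, psi = t[m], psi[m]
    return float(np.mean(np.diff(psi) / np.diff(t)) / (2.0 * np.pi))


def plv(phase_a, phase_b) -> float:
    """Phase-locking value: |< exp(i*(phase_a - phase_b)) >| in [0, 1]."""
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("phase series must have equal shape")
    return float(np.abs(np.mean(np.exp(1j * (a - b)))))


def train_instantaneous_phase(train: PulseTrain, times) -> np.ndarray:
    """Stimulation phase ramping linearly 0 -> 2*pi over each interval.

    At pulse onset ``t_k`` the phase is ``2*pi*k``; between pulses it
    interpolates linearly.  Used to compute PLV between a population and
    its (possibly dithered) pulse train.
    """
    t = np.asarray(times, dtype=float)
    k = np.searchsorted(train.pulse_times, t, side="right") - 1
    k = np.clip(k, 0, train.n_pulses - 1)
    frac = (t - train.pulse_times[k]) / train.periods[k]
    return 2.0 * np.pi * (k + frac)
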