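"""Parameter sweeps over natural frequency and stimulation amplitude.

A sweep simulates every (f0, I) grid cell ``n_repeats`` times (fresh
initial conditions and noise per repeat), averages the rotation number
across repeats, runs plateau detection along each amplitude row and
returns an :class:`~ditherstim.metrics.EntrainmentMap`.

Per-cell random streams are derived by seeding with the tuple
(base seed, amplitude index, frequency index, repeat index), so every
output is fully reproducible from the configuration alone and cells are
statistically independent.

A configurable number of burn-in pulses (default 500) is discarded before
the rotation number is measured, so that on deterministic locking
plateaux the transient to the fixed point does not leave bin-to-bin
jitter in R (the plateau-detection derivative test is sensitive to
jitter far below the rotation-number tolerance itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._engine import circle_det_steps, circle_dith_steps
from .kuramoto import KuramotoConfig, psi_at_pulses, simulate
from .metrics import (DetectionConfig, EntrainmentMap,
                      mean_instantaneous_frequency, rotation_number,
                      detect_locking)
from .pulse_trains import (CyclingMode, CyclingScheme, FrequencySet,
                           PulseTrain, biphasic_waveform, cycling_train,
                           dithered_train, periodic_train)
from .tongue_theory import (TheoryConfig, TongueSpec, relative_width_p1,
                            relative_width_2pm1_2, width_p1, width_2pm1_2)

__all__ = ["SweepConfig", "run_sweep", "theory_report"]

_Z_CHUNK = 512


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a rotation-number sweep.

    ``zeta`` selects white-noise dithering; alternatively a cycling
    ``scheme`` plus ``frequency_set`` can be supplied (population model).
    ``I_values`` are circle-map stimulation magnitudes (radians) or, for
    the population model, positive-lobe amplitudes of the biphasic
    waveform (rad/s once multiplied by the PRC).
    """

    model: str
    f0_start: float
    f0_stop: float
    f0_step: float
    I_values: tuple
    fs: float = 130.0
    zeta: float = 0.0
    scheme: CyclingScheme | None = None
    frequency_set: FrequencySet | None = None
    n_pulses: int = 10_000
    n_repeats: int = 10
    burn_in: int = 500
    base_seed: int = 0
    detection: DetectionConfig | None = None
    kuramoto: KuramotoConfig | None = None
    positive_fraction: float = 0.2

    def __post_init__(self):
        if self.model not in ("circle_map", "kuramoto"):
            raise ValueError("model must be 'circle_map' or 'kuramoto'")
        if self.f0_stop < self.f0_start or self.f0_step <= 0:
            raise ValueError("invalid f0 grid specification")
        if len(self.I_values) == 0:
            raise ValueError("I_values must be nonempty")
        if self.n_repeats < 1 or self.n_pulses < 1 or self.burn_in < 0:
            raise ValueError("invalid repeat/pulse counts")
        if self.scheme is not None and self.scheme.mode in (
                CyclingMode.RANDOM_CYCLING,
                CyclingMode.DETERMINISTIC_CYCLING,
                CyclingMode.SLOW_DETERMINISTIC_CYCLING) \
                and self.frequency_set is None:
            raise ValueError("cycling schemes require a frequency_set")

    @property
    def f0_grid(self) -> np.ndarray:
        n = int(round((self.f0_stop - self.f0_start) / self.f0_step)) + 1
        return self.f0_start + self.f0_step * np.arange(n)

    def detection_config(self) -> DetectionConfig:
        if self.detection is not None:
            return self.detection
        if self.model == "circle_map":
            return DetectionConfig.circle_map(fs=self.fs)
        return DetectionConfig.kuramoto(fs=self.fs)


def _cell_seedseq(cfg: SweepConfig, j: int, i: int, r: int):
    ss = np.random.SeedSequence((cfg.base_seed, j, i, r))
    return ss.spawn(2)


def _circle_row(cfg: SweepConfig, j: int, I: float) -> np.ndarray:
    """Repeat-averaged rotation numbers for one amplitude row."""
    f0 = cfg.f0_grid
    lanes = len(f0)
    ratio = 2.0 * np.pi * f0 / cfg.fs
    n_total = cfg.burn_in + cfg.n_pulses
    R_sum = np.zeros(lanes)
    for r in range(cfg.n_repeats):
        gens = []
        theta = np.empty(lanes)
        for i in range(lanes):
            s_init, s_noise = _cell_seedseq(cfg, j, i, r)
            theta[i] = np.random.default_rng(s_init).uniform(
                0.0, 2.0 * np.pi)
            gens.append(np.random.default_rng(s_noise))
        if cfg.zeta == 0:
            if cfg.burn_in:
                circle_det_steps(theta, ratio, I, cfg.burn_in)
            start = theta.copy()
            circle_det_steps(theta, ratio, I, cfg.n_pulses)
        else:
            start = theta.copy() if cfg.burn_in == 0 else None
            done = 0
            while done < n_total:
                blk = min(_Z_CHUNK, n_total - done)
                if done < cfg.burn_in < done + blk:
                    blk = cfg.burn_in - done  # split chunk at burn-in mark
                z = np.empty((blk, lanes))
                for i, g in enumerate(gens):
                    z[:, i] = g.standard_normal(blk)
                circle_dith_steps(theta, ratio, I, cfg.zeta, z)
                done += blk
                if done == cfg.burn_in:
                    start = theta.copy()
        R_sum += (theta - start) / (2.0 * np.pi * cfg.n_pulses)
    return R_sum / cfg.n_repeats


def _make_train(cfg: SweepConfig, amplitude: float, n_pulses: int,
                seed) -> PulseTrain:
    wf = biphasic_waveform(cfg.positive_fraction, amplitude)
    scheme = cfg.scheme
    if scheme is None or scheme.mode == CyclingMode.WHITE_NOISE:
        zeta = cfg.zeta if scheme is None else scheme.zeta
        if zeta == 0:
            return periodic_train(cfg.fs, n_pulses, wf)
        return dithered_train(cfg.fs, zeta, n_pulses, seed, wf)
    if scheme.mode == CyclingMode.PERIODIC:
        return periodic_train(cfg.fs, n_pulses, wf)
    return cycling_train(cfg.frequency_set, scheme, n_pulses, seed, wf)


def _kuramoto_cell(cfg: SweepConfig, j: int, i: int, amplitude: float,
                   f0: float):
    """Repeat-averaged (R, f_inst) for one population grid cell."""
    base = cfg.kuramoto or KuramotoConfig(f0_center=f0)
    R_sum = 0.0
    fi_sum = 0.0
    for r in range(cfg.n_repeats):
        s_train, s_sim = _cell_seedseq(cfg, j, i, r)
        train = _make_train(cfg, amplitude, cfg.burn_in + cfg.n_pulses,
                            s_train)
        kcfg = replace(base, f0_center=f0, seed=s_sim)
        series, _ = simulate(kcfg, train)
        phis = psi_at_pulses(series, train)[cfg.burn_in:]
        R_sum += rotation_number(phis)
        t0 = train.pulse_times[cfg.burn_in] if cfg.burn_in else 0.0
        fi_sum += mean_instantaneous_frequency(
            series, window=(t0, series.times[-1]))
    return R_sum / cfg.n_repeats, fi_sum / cfg.n_repeats


def run_sweep(cfg: SweepConfig) -> EntrainmentMap:
    """Run the configured sweep and return the entrainment map."""
    f0 = cfg.f0_grid
    I_values = np.asarray(cfg.I_values, dtype=float)
    det = cfg.detection_config()
    R = np.empty((len(I_values), len(f0)))
    f_inst = None
    if cfg.model == "circle_map":
        for j, I in enumerate(I_values):
            R[j] = _circle_row(cfg, j, float(I))
    else:
        f_inst = np.empty_like(R)
        for j, A in enumerate(I_values):
            for i, x in enumerate(f0):
                R[j, i], f_inst[j, i] = _kuramoto_cell(cfg, j, i, float(A),
                                                       float(x))
    label_p = np.zeros(R.shape, dtype=int)
    label_q = np.zeros(R.shape, dtype=int)
    if len(f0) >= 4:
        for j in range(len(I_values)):
            for i, lab in enumerate(detect_locking(f0, R[j], det)):
                if lab is not None:
                    label_p[j, i], label_q[j, i] = lab
    scheme_name = cfg.scheme.mode.value if cfg.scheme else (
        "white_noise" if cfg.zeta > 0 else "periodic")
    return EntrainmentMap(
        f0, I_values, R, label_p, label_q,
        n_repeats=cfg.n_repeats, n_pulses=cfg.n_pulses, f_inst=f_inst,
        zeta=cfg.zeta if cfg.scheme is None else cfg.scheme.zeta,
        scheme=scheme_name,
        metadata={"model": cfg.model, "fs": cfg.fs,
                  "base_seed": cfg.base_seed, "burn_in": cfg.burn_in,
                  "tol": det.tol, "tol_prime": det.tol_prime,
                  "derivative_scale": det.derivative_scale})


def theory_report(cfg: TheoryConfig, families, I_grid,
                  zeta_grid) -> pd.DataFrame:
    """Tabulate theoretical tongue widths over amplitude and dithering.

    ``families`` is a sequence of :class:`TongueSpec` (q = 1 or q = 2 with
    odd p).  Returns a tidy frame with absolute widths in Hz and widths
    relative to the perfectly periodic case.
    """
    rows = []
    for spec in families:
        if not spec.analytic:
            raise ValueError(f"{spec.p}:{spec.q} has no analytic width")
        for zeta in zeta_grid:
            c = TheoryConfig(zeta=zeta, fs=cfg.fs, n_sigma=cfg.n_sigma)
            for I in I_grid:
                if spec.q == 1:
                    w = width_p1(I, spec.p, c)
                    rel = relative_width_p1(spec.p, zeta, cfg.n_sigma)
                else:
                    p_eff = (spec.p + 1) // 2
                    w = width_2pm1_2(I, p_eff, c)
                    rel = relative_width_2pm1_2(p_eff, zeta, cfg.n_sigma)
                rows.append({"family": f"{spec.p}:{spec.q}", "p": spec.p,
                             "q": spec.q, "I": I, "zeta": zeta,
                             "width_hz": w, "relative_width": rel,
                             "n_sigma": cfg.n_sigma, "fs": cfg.fs})
    return pd.DataFrame(rows)
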