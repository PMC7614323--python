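"""Low-level iteration kernels.

Numba-compiled when numba is importable; the same code paths run as plain
NumPy otherwise (identical arithmetic per lane, slower).  Everything here is
private: the public API lives in :mod:`ditherstim.circle_map`,
:mod:`ditherstim.kuramoto` and :mod:`ditherstim.sweep`.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - import guard
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# phase-only circle map, vectorised over independent lanes ------------------

@njit(cache=True)
def circle_det_steps(theta, ratio, stim, n):
    """Advance ``theta`` (lanes,) by ``n`` deterministic circle-map steps.

    ratio = 2*pi*f0/fs per lane, stim = stimulation magnitude I.
    """
    for _ in range(n):
        theta += ratio + stim * np.sin(theta)


@njit(cache=True)
def circle_dith_steps(theta, ratio, stim, zeta, z_chunk):
    """Advance ``theta`` by one chunk of dithered steps.

    ``z_chunk`` has shape (steps, lanes) and holds standard-normal draws;
    the per-step increment is ratio*(1 + zeta*z) + I*sin(theta).
    """
    for b in range(z_chunk.shape[0]):
        theta += ratio * (1.0 + zeta * z_chunk[b]) + stim * np.sin(theta)


# Kuramoto population, order-parameter reduced form -------------------------

_PRC_SIN = 0
_PRC_TABLE = 1


@njit(cache=True)
def _kuramoto_steps_njit(phases, omegas, kappa, xi, dt, stim_t, dW,
                         prc_mode, prc_table, rho_out, psi_out):
    M = phases.shape[0]
    n_steps = stim_t.shape[0]
    sqdt = np.sqrt(dt)
    n_tab = prc_table.shape[0]
    psi_prev = 0.0
    psi_acc = 0.0
    two_pi = 2.0 * np.pi
    for t in range(n_steps):
        cs = 0.0
        sn = 0.0
        for k in range(M):
            cs += np.cos(phases[k])
            sn += np.sin(phases[k])
        rho = np.sqrt(cs * cs + sn * sn) / M
        psi = np.arctan2(sn, cs)
        if t == 0:
            psi_acc = psi
        else:
            d = psi - psi_prev
            while d > np.pi:
                d -= two_pi
            while d < -np.pi:
                d += two_pi
            psi_acc += d
        psi_prev = psi
        rho_out[t] = rho
        psi_out[t] = psi_acc
        amp = stim_t[t]
        for k in range(M):
            ph = phases[k]
            if prc_mode == _PRC_SIN:
                z = np.sin(ph)
            else:
                pos = (ph % two_pi) / two_pi * n_tab
                i0 = int(pos)
                frac = pos - i0
                i0 = i0 % n_tab
                i1 = (i0 + 1) % n_tab
                z = prc_table[i0] * (1.0 - frac) + prc_table[i1] * frac
            phases[k] = ph + (omegas[k] + kappa * rho * np.sin(psi - ph)
                              + amp * z) * dt + xi * sqdt * dW[k, t]


def _kuramoto_steps_numpy(phases, omegas, kappa, xi, dt, stim_t, dW,
                          prc, rho_out, psi_out):
    """Vectorised-over-oscillators fallback; ``prc`` is a callable."""
    n_steps = stim_t.shape[0]
    M = phases.shape[0]
    sqdt = np.sqrt(dt)
    psi_prev = 0.0
    psi_acc = 0.0
    for t in range(n_steps):
        cs = np.cos(phases).sum()
        sn = np.sin(phases).sum()
        rho = np.hypot(cs, sn) / M
        psi = np.arctan2(sn, cs)
        if t == 0:
            psi_acc = psi
        else:
            d = (psi - psi_prev + np.pi) % (2 * np.pi) - np.pi
            psi_acc += d
        psi_prev = psi
        rho_out[t] = rho
        psi_out[t] = psi_acc
        phases += (omegas + kappa * rho * np.sin(psi - phases)
                   + stim_t[t] * prc(phases)) * dt + xi * sqdt * dW[:, t]


def kuramoto_integrate(phases, omegas, kappa, xi, dt, stim_t, dW, prc):
    """Integrate the reduced-form population and return (rho, psi) series.

    ``prc`` may be the string ``"sin"``, a 1-D table sampled uniformly on
    [0, 2*pi) (linear interpolation, periodic), or an arbitrary callable
    (NumPy path only).  ``phases`` is updated in place.
    """
    n_steps = stim_t.shape[0]
    rho_out = np.empty(n_steps)
    psi_out = np.empty(n_steps)
    if HAVE_NUMBA and (isinstance(prc, str) or isinstance(prc, np.ndarray)):
        if isinstance(prc, str):
            mode, table = _PRC_SIN, np.zeros(1)
        else:
            mode, table = _PRC_TABLE, np.asarray(prc, dtype=float)
        _kuramoto_steps_njit(phases, omegas, kappa, xi, dt, stim_t, dW,
                             mode, table, rho_out, psi_out)
    else:
        if isinstance(prc, str):
            fn = np.sin
        elif isinstance(prc, np.ndarray):
            table = np.asarray(prc, dtype=float)
            grid = np.linspace(0.0, 2 * np.pi, table.size, endpoint=False)

            def fn(ph, _g=grid, _t=table):
                return np.interp(np.mod(ph, 2 * np.pi), _g, _t,
                                 period=2 * np.pi)
        else:
            fn = prc
        _kuramoto_steps_numpy(phases, omegas, kappa, xi, dt, stim_t, dW,
                              fn, rho_out, psi_out)
    return rho_out, psi_out
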