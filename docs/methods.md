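# Methods

## Models

**Sine circle map.** A neural oscillator of natural frequency `f0`
receiving one pulse per period of a train at base frequency `fs` is
reduced to the phase map

    theta_{n+1} = theta_n + 2*pi*f0/fs + I*sin(theta_n),

where `theta_n` is the unwrapped phase immediately before pulse `n` and
`I` the stimulation magnitude (radians of phase advance); `sin` is the
oscillator's phase response curve (PRC).  Dithered stimulation
multiplies each stimulation period by `(1 + z_n)`, `z_n ~ N(0, zeta^2)`,
so the stochastic map adds `2*pi*(f0/fs)*zeta*z_n` per step.  Draws are
not truncated here: a draw with `1 + z_n < 0` merely produces a negative
phase increment, which the map tolerates.  Phases are stored unwrapped
in double precision; wrapping is applied only where an operation needs
it.

**Coupled populations.** Brain signals are better described by
populations of coupled oscillators.  We integrate `M` phases under the
order-parameter (attractive mean-field) form of homogeneous sine
coupling,

    dphi_k = [omega_k + kappa*rho*sin(psi - phi_k) + I(t)*Z(phi_k)] dt
             + xi dW_k,

with `rho*exp(i*psi)` the order parameter recomputed from the current
phases at every step.  (The all-to-all form with `sin(phi_k - phi_l)`
inside the sum corresponds to repulsive coupling; the reduced form
implemented here is the attractive one, which is the synchronising
regime of interest.)  Defaults: `M = 100`, `kappa = 350 rad/s`,
`xi = 7.9 rad/sqrt(s)`, Euler–Maruyama step `dt = 1e-4 s`.  Intrinsic
frequencies `omega_k/(2*pi)` are Cauchy (Lorentzian) distributed around
the population centre with scale 20 Hz — we read the stated "width" as
the half width at half maximum, i.e. the Cauchy scale parameter.
Negative frequency draws are resampled; this leaves centres well above
the scale essentially untouched but biases low centres upward (at a
30 Hz centre the median shifts by roughly +6 Hz), which the tests
document explicitly.  The PRC is pluggable: sinusoidal by default, or a
tabulated curve (uniform samples of [0, 2*pi), linearly interpolated),
or any 2*pi-periodic callable; the coupling function can likewise be
replaced by supplying a custom PRC-style callable for specialised
studies.

**Stimulation waveform.** Continuous-time trains carry a
charge-balanced biphasic square pulse: a positive lobe occupying 20% of
the current period, followed by a negative lobe whose amplitude is
`-A*0.2/0.8` so the waveform integrates to zero over each period.  The
integrator refuses steps that give the nominal positive lobe fewer than
10 samples.

## Arnold-tongue theory for the dithered map

Frequency locking at `p:q` survives dithering while the phase is
unlikely to escape, in one random jump, the trap of size `h` between the
stable and unstable fixed points of the q-fold composed map.  With jump
standard deviation `sigma` (equal to `2*pi*(f0/fs)*zeta` for `p:1` and
`2*sqrt(2)*pi*(f0/fs)*zeta` for `(2p-1):2`), locking is taken to be lost
when `h = n_sigma*sigma`.  The default `n_sigma = 4` keeps at least
99.99% of jumps inside the trap; any value >= 3 may be configured.
Solving the escape condition and Taylor-expanding to second order in
`zeta` yields the implemented boundaries and widths, e.g.

    width(p:1)      = (fs*I/pi)    * (1 - n_sigma^2*zeta^2*(4*p^2*pi^2 + I^2)/8)
    width((2p-1):2) = (fs*I^2/4/pi)* (1 - n_sigma^2*zeta^2*(16*(2p-1)^2*pi^2 + I^4)/16)

Relative widths reduce to `1 - n_sigma^2*pi^2*p^2*zeta^2/2` and
`1 - n_sigma^2*pi^2*(2p-1)^2*zeta^2`: every higher-order family member
shrinks strictly faster than 1:1, which is the selectivity guarantee.
The formulas hold for small `zeta` and small `I`; outside that range
they can go negative and are clamped to zero (tongue destroyed), and
the `(2p-1):2` family additionally relies on a one-harmonic
approximation of the twice-composed map whose trap size converges
linearly in `I` to the exact composed map (about 5% error at
`I = 0.15`, 40% at `I = 1` — the tests quantify this).  Only the
`q ∈ {1, 2}` families admit closed forms; other ratios are measured
empirically from sweeps.

## Entrainment metrics and plateau detection

The rotation number is `R = (phi_N - phi_0)/(2*pi*N)` with `phi_n` the
unwrapped circle-map phase, or the order-parameter phase sampled one
integration step before pulse `n`.  Locking at `p:q` is declared on a
natural-frequency grid where both `|R - p/q| < tol` and
`|S(dR/df0)| < tol'` hold, with `S` a smoothed derivative: central
finite differences (one-sided at the edges) followed by tricube
local-linear (LOWESS) smoothing over a 4-sample nearest-neighbour span,
with no robustifying iterations.  Defaults: `tol = 6e-4`,
`tol' = 1e-2` for circle-map sweeps; `tol = 3e-2`, `tol' = 2e-2` for
population sweeps; candidate ratios are all coprime `p:q` with
`p, q <= 4` plus `p:1` up to `p = 8`, and the tolerance must keep
neighbouring candidates at least `2*tol` apart.

A design choice that matters: the derivative in the second condition is
taken with respect to the **normalized frequency** `f0/fs`, making
`tol'` dimensionless.  An unlocked oscillator tracks its own frequency
with slope `dR/d(f0/fs) ~ 1`, and the residual "ghost" flattening left
behind by a noise-destroyed tongue has slope of order 0.1 — both far
above `tol'` — while a genuine plateau sits orders of magnitude below
it.  Had the threshold been applied to the per-Hz derivative, the
unlocked diagonal slope `1/fs ≈ 7.7e-3` would fall below `tol'` and the
condition could reject nothing: thin false plateaus would appear
wherever `R` drifts through a rational value, including sub-Hz ghost
plateaus at dithering levels where locking is theoretically destroyed.
The per-Hz variant remains available
(`DetectionConfig(derivative_scale="per_hz")`) for comparison.

Sweeps average `R` over repeats (fresh random initial phase and noise
per repeat) before detection, and by default discard 500 burn-in pulses
before measuring `R`.  The burn-in removes the O(1/N) transient of the
approach to a locked fixed point, which is far below `tol` but — as
bin-to-bin jitter — is exactly what the derivative condition is
sensitive to; without it, a quarter of the interior bins of a
deterministic plateau fail the flatness test.  Tongue widths are
measured as (number of bins labelled `p:q` at an amplitude) x (bin
width).  The PLV between two phase series is the modulus of the
time-averaged phasor of their difference; for train-versus-population
locking the train's instantaneous phase ramps linearly by `2*pi` over
each (possibly dithered) inter-pulse interval.

## Pulse trains and device-implementable dithering

Continuous-time dithered trains resample any draw with `1 + z <= 0`
(probability below 1e-6 for `zeta <= 0.2`); a `zeta` whose expected
rejection rate exceeds 10% is refused as outside the intended regime.
Cycling sets are built with equally spaced periods spanning a frequency
range — reconstructing a device table from its printed extremes
(100–185.7 Hz) — so the discrete period distribution is symmetric
around the base period and the frequency values are skewed toward the
low end; the equivalent dithering level of such a set is the standard
deviation of the continuous uniform period distribution divided by the
mean period (0.17 for 100–185.7 Hz).  Deterministic cycling starts at
the lowest frequency by default (configurable); slow cycling holds each
frequency `N_r` consecutive periods.

## Reproducibility and performance

Every stochastic component consumes a NumPy `SeedSequence`-derived
stream.  Sweeps derive per-cell streams from (base seed, amplitude
index, frequency index, repeat index), each split into an
initial-condition stream and a noise stream, so a single cell of a
sweep is bitwise-reproducible by calling the trajectory functions
directly with those child seeds.  Inner loops (circle-map lanes,
population integration) are numba-compiled when numba is available;
a pure-NumPy path consumes the identical random streams otherwise.

Desk-scale problem sizes used by the test suite: circle-map sweeps use
0.05 Hz frequency bins over targeted windows around the 1:2, 1:1, 3:2
and 2:1 tongue centres with 10 repeats x 10^4 pulses per cell;
population sweeps use 0.5 Hz bins, 5 repeats x 400 pulses, `M = 100`.
These windows resolve every quantity tested (the narrowest measured
plateau spans ~19 bins) while keeping the whole suite within minutes on
one core.

## What the generators emulate — and what they do not

The synthetic inputs are the study conditions themselves: pulse trains
with the stated dithering statistics and populations with the stated
coupling, noise and frequency dispersion.  They do not emulate measured
brain signals: there is no synaptic plasticity, no multi-population or
thalamo-cortical network structure, no evoked transient activity, and
no amplitude dynamics in the circle map (phase-only by construction).
Passing tests therefore demonstrate the mechanism — selective
destruction of higher-order locking by period dithering — in the
models, not clinical efficacy.

## Known limitations

* With the default **sinusoidal PRC**, subharmonic (1:2) locking of a
  *population* under a charge-balanced biphasic train is essentially
  absent: for a first-harmonic PRC the 1:2 mechanism is second order in
  the stimulation amplitude, and the charge-balanced waveform cancels
  most of what remains, leaving single-oscillator 1:2 plateaus of only
  ~1 Hz whose centre drifts below half the base frequency as amplitude
  grows.  The 20 Hz Lorentzian dispersion then erases them at
  population level.  PRCs with substantial second-harmonic content
  (e.g. a tabulated Hodgkin–Huxley PRC supplied via the loader) lock
  1:2 at first order and are the realistic route to population-level
  subharmonics; the corresponding acceptance test documents this gap
  honestly rather than papering over it.
* The analytic theory covers `p:1` and `(2p-1):2` only, at small `I`
  and `zeta`; boundaries and widths elsewhere must be measured.
* Resampling negative intrinsic frequencies biases populations whose
  centre is comparable to the Lorentzian scale (relevant below
  ~50 Hz with the default 20 Hz width).
* The locking detector's tolerances are calibrated for the grid
  resolutions and run lengths above; much finer grids raise the
  derivative-noise floor (jitter amplified by differencing) and may
  need longer runs or wider spans.
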