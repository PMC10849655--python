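"""MA and LN song-encoding models.

The multiplicative-adaptation (MA) neuron is a 4-parameter dynamical system:
mode-specific adaptation variables ``a_s``, ``a_p`` track the binary sine and
pulse inputs with timescale ``tau_a``, gate the drive multiplicatively through
``(1 - a_m)``, and the gated drive is leaky-integrated with timescale
``tau_int``::

    tau_int dr/dt  = -r + x_s (1 - a_s) I_s(t) + x_p (1 - a_p) I_p(t)
    tau_a   da_m/dt = -a_m + I_m(t)            (m = s, p)

The linear-nonlinear (LN) neuron convolves ``I_s``, ``I_p`` with filters
``h_s``, ``h_p`` and applies a signed rectification.  ``ln_from_ma`` builds
the LN filters so that both models have identical step responses to a pure
sine or pulse block, which makes them indistinguishable on block stimuli but
not on naturally patterned song.

Integration is exact: on each raster bin the inputs are constant, both ODEs
are linear with constant coefficients, and the bin-to-bin update is a pair of
first-order recursions evaluated with ``scipy.signal.lfilter``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, lfilter, lfiltic

from .songs import Mode, SongRaster

__all__ = [
    "MAParams",
    "MAState",
    "LNModel",
    "PopulationParams",
    "RegimeSpec",
    "REGIMES",
    "ResponseTrace",
    "ma_simulate",
    "ma_step_response",
    "ma_block_response",
    "ln_from_ma",
    "ln_simulate",
    "simulate_population",
    "sample_population",
    "perturb_population",
    "resample_regimes",
    "read_population_csv",
    "write_population_csv",
]


@dataclass(frozen=True)
class MAParams:
    """The four MA parameters plus a response polarity.

    ``tau_a = inf`` disables adaptation exactly (the neuron becomes a linear
    leaky integrator).  ``polarity`` is a pure sign on the output, standing in
    for neurons whose calcium signal decreases with song.
    """

    tau_int: float
    tau_a: float
    x_s: float
    x_p: float
    polarity: int = 1

    def __post_init__(self):
        if not (self.tau_int > 0):
            raise ValueError("tau_int must be positive")
        if not (self.tau_a > 0):
            raise ValueError("tau_a must be positive (inf allowed)")
        if self.x_s < 0 or self.x_p < 0:
            raise ValueError("selectivities must be non-negative")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")

    @property
    def adapting(self) -> bool:
        return math.isfinite(self.tau_a)


@dataclass(frozen=True)
class MAState:
    r: float = 0.0
    a_s: float = 0.0
    a_p: float = 0.0


@dataclass(frozen=True)
class LNModel:
    """Sine/pulse filters on a uniform grid plus signed rectification."""

    h_s: np.ndarray
    h_p: np.ndarray
    dt: float
    polarity: int = 1
    source_params: MAParams | None = None

    def __post_init__(self):
        object.__setattr__(self, "h_s", np.asarray(self.h_s, dtype=float))
        object.__setattr__(self, "h_p", np.asarray(self.h_p, dtype=float))
        if self.dt <= 0:
            raise ValueError("filter grid dt must be positive")
        if not (np.isfinite(self.h_s).all() and np.isfinite(self.h_p).all()):
            raise ValueError("filters must be finite")


@dataclass(frozen=True)
class PopulationParams:
    """A bank of MA neurons (the artificial population of the NC protocol)."""

    neurons: tuple
    regime_labels: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "neurons", tuple(self.neurons))
        if len(self.neurons) == 0:
            raise ValueError("population must be non-empty")

    def __len__(self) -> int:
        return len(self.neurons)


@dataclass(frozen=True)
class RegimeSpec:
    name: str
    low: float
    high: float


#: Timescale regimes for tau_int / tau_a resampling (seconds).
REGIMES = {
    "fast": RegimeSpec("fast", 0.1, 2.0),
    "medium": RegimeSpec("medium", 2.0, 20.0),
    "slow": RegimeSpec("slow", 20.0, 120.0),
}


@dataclass(frozen=True)
class ResponseTrace:
    t: np.ndarray
    r: np.ndarray
    neuron_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        if self.t.shape != self.r.shape:
            raise ValueError("t and r must have equal length")
        if not np.isfinite(self.r).all():
            raise ValueError("non-finite response values")


# ---------------------------------------------------------------------------
# exact simulation


def _adaptation_series(I: np.ndarray, dt: float, tau_a: float, a0: float) -> np.ndarray:
    """Adaptation level at the *start* of each bin, exact per-bin update.

    a(t+dt) = I + (a - I) e^{-dt/tau_a}, i.e. the AR(1) recursion
    a_end = E a_start + (1-E) I with E = e^{-dt/tau_a}.
    """
    if not math.isfinite(tau_a):
        return np.full(I.shape, a0)
    E = math.exp(-dt / tau_a)
    zi = lfiltic([1.0 - E], [1.0, -E], [a0])
    a_end, _ = lfilter([1.0 - E], [1.0, -E], I.astype(float), zi=zi)
    a_start = np.empty_like(a_end)
    a_start[0] = a0
    a_start[1:] = a_end[:-1]
    return a_start


def _drive(params: MAParams, raster: SongRaster, init: MAState) -> np.ndarray:
    """Adapted drive at the start of each bin: sum_m x_m (1 - a_m) I_m."""
    a_s = _adaptation_series(raster.I_s, raster.dt, params.tau_a, init.a_s)
    a_p = _adaptation_series(raster.I_p, raster.dt, params.tau_a, init.a_p)
    return params.x_s * (1.0 - a_s) * raster.I_s + params.x_p * (1.0 - a_p) * raster.I_p


def _integrate(params: MAParams, raster: SongRaster, A: np.ndarray, r0: float) -> np.ndarray:
    """Leaky-integrate the adapted drive exactly; returns r at bin ends.

    Within a bin the drive is A e^{-t/tau_a} (the song inputs are constant and
    the active mode's gate relaxes exponentially), so the bin update is
    r_end = E_int r_start + c A with c the closed-form response coefficient.
    """
    dt, ti, ta = raster.dt, params.tau_int, params.tau_a
    E_int = math.exp(-dt / ti)
    if not math.isfinite(ta):
        c = 1.0 - E_int
    elif abs(ta - ti) < 1e-9 * ti:
        c = (dt / ti) * E_int  # confluent limit tau_a -> tau_int
    else:
        E_a = math.exp(-dt / ta)
        c = ta / (ta - ti) * (E_a - E_int)
    zi = lfiltic([c], [1.0, -E_int], [r0])
    r_end, _ = lfilter([c], [1.0, -E_int], A, zi=zi)
    return r_end


def ma_simulate(
    params: MAParams,
    raster: SongRaster,
    init: MAState = MAState(),
    neuron_id: str = "",
) -> ResponseTrace:
    """Simulate the MA neuron on a song raster with exact per-bin updates.

    The returned trace holds the state at the *end* of each raster bin
    (times ``raster.bin_ends``), multiplied by the neuron's polarity.
    """
    if len(raster) == 0:
        raise ValueError("zero-length raster")
    A = _drive(params, raster, init)
    r = _integrate(params, raster, A, init.r)
    return ResponseTrace(t=raster.bin_ends, r=params.polarity * r, neuron_id=neuron_id)


def ma_step_response(params: MAParams, mode: Mode | str, t) -> np.ndarray:
    """Closed-form response to a pure-mode step from zero initial state.

    For finite ``tau_a``::

        r(t) = x_m tau_a / (tau_a - tau_int) (e^{-t/tau_a} - e^{-t/tau_int})

    with the confluent limit ``x_m (t/tau_int) e^{-t/tau_int}`` at
    ``tau_a = tau_int`` and the LTI limit ``x_m (1 - e^{-t/tau_int})`` at
    ``tau_a = inf``.  Polarity is applied as a sign.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if isinstance(mode, str):
        mode = Mode[mode.upper()]
    x = params.x_s if mode == Mode.SINE else params.x_p
    ti, ta = params.tau_int, params.tau_a
    if not math.isfinite(ta):
        r = x * (1.0 - np.exp(-t / ti))
    elif abs(ta - ti) < 1e-9 * ti:
        r = x * (t / ti) * np.exp(-t / ti)
    else:
        r = x * ta / (ta - ti) * (np.exp(-t / ta) - np.exp(-t / ti))
    return params.polarity * r


def ma_block_response(params: MAParams, mode: Mode | str, t, block_duration: float) -> np.ndarray:
    """Closed-form response to a pure-mode block of length ``block_duration``.

    During the block this is the step response; afterwards the drive is zero
    and activity decays as ``e^{-(t-T)/tau_int}`` from its offset value.
    """
    t = np.asarray(t, dtype=float)
    on = ma_step_response(params, mode, np.minimum(t, block_duration))
    decay = np.where(t > block_duration, np.exp(-np.maximum(t - block_duration, 0.0) / params.tau_int), 1.0)
    return on * decay


# ---------------------------------------------------------------------------
# LN construction and simulation


def ln_from_ma(params: MAParams, grid_dt: float = 0.01, grid_len: float | None = None) -> LNModel:
    """Build the LN model whose block responses match the MA model's.

    The filter is the per-bin increment of the MA step response,
    ``h[k] = (S((k+1) dt) - S(k dt)) / dt``, so the discrete convolution of a
    step input reproduces the MA step response exactly on the grid.  Filters
    carry the polarity sign so the signed rectification passes them through.
    """
    if grid_dt <= 0:
        raise ValueError("grid_dt must be positive")
    if grid_len is None:
        finite = [x for x in (params.tau_int, params.tau_a) if math.isfinite(x)]
        grid_len = 10.0 * max(finite)
    if grid_len <= 0:
        raise ValueError("grid_len must be positive")
    n = int(np.ceil(grid_len / grid_dt))
    edges = np.arange(n + 1) * grid_dt
    pos = replace(params, polarity=1)
    filters = {}
    for mode in (Mode.SINE, Mode.PULSE):
        S = ma_step_response(pos, mode, edges)
        filters[mode] = params.polarity * np.diff(S) / grid_dt
    return LNModel(h_s=filters[Mode.SINE], h_p=filters[Mode.PULSE], dt=grid_dt,
                   polarity=params.polarity, source_params=params)


def ln_simulate(model: LNModel, raster: SongRaster, neuron_id: str = "") -> ResponseTrace:
    """Convolve the song with the LN filters and apply signed rectification.

    ``z[n] = dt * sum_k (h_s[k] I_s[n-k] + h_p[k] I_p[n-k])`` followed by
    ``g(z) = polarity * max(polarity * z, 0)``.  The raster dt must equal the
    filter grid dt (rasterize at the filter's grid instead of resampling).
    """
    if len(raster) == 0:
        raise ValueError("zero-length raster")
    if not np.isclose(raster.dt, model.dt, rtol=1e-9):
        raise ValueError(
            f"raster dt {raster.dt} does not match filter grid dt {model.dt}; "
            "rasterize the song on the filter grid"
        )
    n = len(raster)
    z = model.dt * (
        fftconvolve(raster.I_s.astype(float), model.h_s)[:n]
        + fftconvolve(raster.I_p.astype(float), model.h_p)[:n]
    )
    p = model.polarity
    r = p * np.maximum(p * z, 0.0)
    return ResponseTrace(t=raster.bin_ends, r=r, neuron_id=neuron_id)


def simulate_population(
    pop: PopulationParams,
    raster: SongRaster,
    model: str = "ma",
    ln_grid_len: float | None = None,
) -> np.ndarray:
    """Activity matrix (time bins x neurons) for a whole population.

    ``model`` selects the MA dynamics or the matched LN model built per
    neuron with ``ln_from_ma`` on the raster's grid.
    """
    if model not in ("ma", "ln"):
        raise ValueError("model must be 'ma' or 'ln'")
    cols = []
    for prm in pop.neurons:
        if model == "ma":
            cols.append(ma_simulate(prm, raster).r)
        else:
            ln = ln_from_ma(prm, grid_dt=raster.dt,
                            grid_len=ln_grid_len if ln_grid_len is not None else min(
                                10.0 * max(x for x in (prm.tau_int, prm.tau_a) if math.isfinite(x)),
                                raster.duration,
                            ))
            cols.append(ln_simulate(ln, raster).r)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# population construction


def _draw(rng, spec, n):
    """Draw n values from a fixed scalar or a (low, high) uniform range."""
    if np.isscalar(spec):
        return np.full(n, float(spec))
    low, high = spec
    return rng.uniform(low, high, size=n)


def sample_population(
    n: int,
    tau_int_range=(20.0, 120.0),
    tau_a_range=(0.1, 2.0),
    x_range=(0.0, 1.0),
    selectivity_mode: str = "uniform01",
    seed=None,
) -> PopulationParams:
    """Random MA population with timescales and selectivities drawn uniformly.

    Defaults give the fast-adapt/slow-integrate regime.  ``tau_a_range`` may
    be ``inf`` (no adaptation) and either range may be a scalar to fix the
    value across neurons.  ``selectivity_mode='pure'`` makes each neuron
    selective to a single randomly chosen mode.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    tau_int = _draw(rng, tau_int_range, n)
    tau_a = _draw(rng, tau_a_range, n)
    if selectivity_mode == "uniform01":
        x_s = _draw(rng, x_range, n)
        x_p = _draw(rng, x_range, n)
    elif selectivity_mode == "pure":
        x_s = _draw(rng, x_range, n)
        x_p = _draw(rng, x_range, n)
        is_sine = rng.random(n) < 0.5
        x_s = np.where(is_sine, x_s, 0.0)
        x_p = np.where(is_sine, 0.0, x_p)
    else:
        raise ValueError("selectivity_mode must be 'uniform01' or 'pure'")
    neurons = tuple(
        MAParams(tau_int=tau_int[i], tau_a=tau_a[i], x_s=x_s[i], x_p=x_p[i])
        for i in range(n)
    )
    return PopulationParams(neurons=neurons)


def perturb_population(pop: PopulationParams, perturbation: str) -> PopulationParams:
    """Ablate a component of every neuron.

    ``no_adaptation`` sets tau_a = inf, ``no_sine`` sets x_s = 0, ``no_pulse``
    sets x_p = 0.  All are idempotent.
    """
    if perturbation == "no_adaptation":
        f = lambda p: replace(p, tau_a=math.inf)
    elif perturbation == "no_sine":
        f = lambda p: replace(p, x_s=0.0)
    elif perturbation == "no_pulse":
        f = lambda p: replace(p, x_p=0.0)
    else:
        raise ValueError(f"unknown perturbation {perturbation!r}")
    return PopulationParams(neurons=tuple(f(p) for p in pop.neurons),
                            regime_labels=pop.regime_labels)


def resample_regimes(
    pop: PopulationParams,
    tau_int_regime: str,
    tau_a_regime: str,
    seed=None,
) -> PopulationParams:
    """Redraw every neuron's timescales uniformly inside named regimes.

    Regimes are ``fast``/``medium``/``slow`` (see ``REGIMES``); a tau_a
    regime of ``'none'`` removes adaptation instead.
    """
    rng = np.random.default_rng(seed)
    spec_i = REGIMES[tau_int_regime]
    new = []
    for p in pop.neurons:
        ti = rng.uniform(spec_i.low, spec_i.high)
        if tau_a_regime == "none":
            ta = math.inf
        else:
            spec_a = REGIMES[tau_a_regime]
            ta = rng.uniform(spec_a.low, spec_a.high)
        new.append(replace(p, tau_int=ti, tau_a=ta))
    return PopulationParams(neurons=tuple(new),
                            regime_labels=(tau_int_regime, tau_a_regime))


# ---------------------------------------------------------------------------
# CSV interface: neuron_id,tau_int_s,tau_a_s,x_s,x_p,polarity


def read_population_csv(path) -> PopulationParams:
    df = pd.read_csv(path)
    neurons = tuple(
        MAParams(tau_int=row.tau_int_s, tau_a=float(row.tau_a_s),
                 x_s=row.x_s, x_p=row.x_p, polarity=int(row.polarity))
        for row in df.itertuples()
    )
    return PopulationParams(neurons=neurons)


def write_population_csv(pop: PopulationParams, path) -> None:
    df = pd.DataFrame(
        [
            {"neuron_id": f"n{i:03d}", "tau_int_s": p.tau_int, "tau_a_s": p.tau_a,
             "x_s": p.x_s, "x_p": p.x_p, "polarity": p.polarity}
            for i, p in enumerate(pop.neurons)
        ]
    )
    df.to_csv(path, index=False)
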