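"""Fitting MA and LN encoders to trial-averaged block-stimulus responses.

The data are responses to 10-second blocks of pure sine or pure pulse song,
sampled at the imaging frame rate over the stimulus plus a 10-second
post-stimulus window.  Both encoders are fit by minimizing the summed squared
error against the sine and pulse traces jointly over the shared 4-parameter
space (tau_int, tau_a, x_s, x_p); the selectivities enter linearly and are
profiled out in closed form, leaving a 2-D problem over log-timescales that
is solved by multi-start L-BFGS-B.

The LN forward model is the matched-filter construction of
``encoding.ln_from_ma``: during the block it coincides with the MA response
by design, but its post-offset decay is the filter tail ``S(t) - S(t - T)``
(signed-rectified) rather than the MA's pure exponential relaxation — the
offset period is what separates the two fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .encoding import MAParams, ma_step_response
from .songs import Mode

__all__ = [
    "BlockStimulusSpec",
    "BlockResponseSet",
    "FitResult",
    "fit_ma",
    "fit_ln",
    "goodness_r2",
    "read_block_csv",
    "write_block_csv",
]

_TAU_BOUNDS = (1e-2, 1e4)  # seconds, both timescales
_TAU_STARTS = (0.3, 3.0, 30.0, 100.0)


@dataclass(frozen=True)
class BlockStimulusSpec:
    """Block-song protocol: a pure-mode block then silence, at a fixed frame rate."""

    stim_duration: float = 10.0
    post_duration: float = 10.0
    frame_rate: float = 8.0

    def __post_init__(self):
        if self.stim_duration <= 0 or self.post_duration <= 0 or self.frame_rate <= 0:
            raise ValueError("durations and frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(round((self.stim_duration + self.post_duration) * self.frame_rate))

    @property
    def frame_times(self) -> np.ndarray:
        """Frame midpoints of the imaging grid."""
        return (np.arange(self.n_frames) + 0.5) / self.frame_rate


@dataclass(frozen=True)
class BlockResponseSet:
    """Trial-averaged sine- and pulse-block traces for one recording."""

    recording_id: str
    sine: np.ndarray
    pulse: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sine", np.asarray(self.sine, dtype=float))
        object.__setattr__(self, "pulse", np.asarray(self.pulse, dtype=float))
        if self.sine.shape != self.pulse.shape or self.sine.ndim != 1:
            raise ValueError("sine and pulse traces must be 1-D and equal length")
        if np.isnan(self.sine).all() or np.isnan(self.pulse).all():
            raise ValueError("all-NaN traces")


@dataclass
class FitResult:
    """Best-fit parameters plus goodness of fit for one recording."""

    params: MAParams
    model_type: str  # "ma" | "ln"
    r2: float
    loss: float
    converged: bool
    recording_id: str = ""
    loss_history: list = field(default_factory=list)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"{self.model_type.upper()} block fit: {self.recording_id or '<unnamed>'}",
            f"  tau_int  {p.tau_int:10.4g} s",
            f"  tau_a    {p.tau_a:10.4g} s",
            f"  x_s      {p.x_s:10.4g}",
            f"  x_p      {p.x_p:10.4g}",
            f"  polarity {p.polarity:+d}",
            f"  R^2      {self.r2:10.4f}   SSE {self.loss:.4g}   converged {self.converged}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# forward models (unit selectivity, positive polarity)


def _unit_block_ma(tau_int: float, tau_a: float, t: np.ndarray, T: float) -> np.ndarray:
    base = MAParams(tau_int=tau_int, tau_a=tau_a, x_s=1.0, x_p=1.0)
    S = ma_step_response(base, Mode.SINE, np.minimum(t, T))
    decay = np.where(t > T, np.exp(-np.maximum(t - T, 0.0) / tau_int), 1.0)
    return S * decay


def _unit_block_ln(tau_int: float, tau_a: float, t: np.ndarray, T: float) -> np.ndarray:
    # continuous-time matched-filter response to a block: S(t) - S(t-T), rectified
    base = MAParams(tau_int=tau_int, tau_a=tau_a, x_s=1.0, x_p=1.0)
    S_t = ma_step_response(base, Mode.SINE, t)
    S_off = ma_step_response(base, Mode.SINE, np.maximum(t - T, 0.0))
    return np.maximum(S_t - np.where(t > T, S_off, 0.0), 0.0)


def _infer_polarity(data: BlockResponseSet) -> int:
    both = np.concatenate([data.sine, data.pulse])
    both = both[np.isfinite(both)]
    if both.size == 0 or np.abs(both).max() == 0:
        return 1
    return 1 if both[np.abs(both).argmax()] > 0 else -1


def _profile_x(trace: np.ndarray, unit: np.ndarray, polarity: int) -> float:
    """Closed-form optimal non-negative selectivity given the unit response."""
    denom = float(unit @ unit)
    if denom == 0.0:
        return 0.0
    return max(0.0, polarity * float(trace @ unit) / denom)


def _fit_block(data: BlockResponseSet, spec: BlockStimulusSpec, unit_fn,
               extra_starts=(), maxiter: int = 10_000, ftol: float = 1e-14):
    t = spec.frame_times
    T = spec.stim_duration
    polarity = _infer_polarity(data)
    sine = np.nan_to_num(data.sine)
    pulse = np.nan_to_num(data.pulse)
    history: list = []

    def loss_of(log_taus):
        ti, ta = np.exp(log_taus)
        u = unit_fn(ti, ta, t, T)
        x_s = _profile_x(sine, u, polarity)
        x_p = _profile_x(pulse, u, polarity)
        resid_s = sine - polarity * x_s * u
        resid_p = pulse - polarity * x_p * u
        return float(resid_s @ resid_s + resid_p @ resid_p), x_s, x_p

    def objective(log_taus):
        return loss_of(log_taus)[0]

    starts = [(a, b) for a in _TAU_STARTS for b in _TAU_STARTS]
    starts += [tuple(s) for s in extra_starts]
    bounds = [tuple(np.log(_TAU_BOUNDS))] * 2
    best = None
    for s in starts:
        res = minimize(objective, np.log(s), method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
        history.append(float(res.fun))
    # simplex polish from the best point: cheap insurance against the
    # flat log-timescale valleys of the concentrated loss
    polish = minimize(objective, best.x, method="Nelder-Mead", bounds=bounds,
                      options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": maxiter})
    if polish.fun < best.fun:
        best = polish
    loss, x_s, x_p = loss_of(best.x)
    ti, ta = np.exp(best.x)
    params = MAParams(tau_int=ti, tau_a=ta, x_s=x_s, x_p=x_p, polarity=polarity)
    u = unit_fn(ti, ta, t, T)
    model_both = np.concatenate([polarity * x_s * u, polarity * x_p * u])
    data_both = np.concatenate([sine, pulse])
    r2 = goodness_r2(model_both, data_both)
    return params, loss, r2, bool(getattr(best, "success", True)), history


def fit_ma(data: BlockResponseSet, spec: BlockStimulusSpec = BlockStimulusSpec(),
           opts: dict | None = None) -> FitResult:
    """Fit the 4 MA parameters to a recording's sine and pulse block traces.

    Polarity is set from the sign of the dominant response; the loss covers
    the stimulus and post-stimulus periods of both traces jointly.
    """
    opts = opts or {}
    params, loss, r2, ok, hist = _fit_block(data, spec, _unit_block_ma, **opts)
    return FitResult(params=params, model_type="ma", r2=r2, loss=loss,
                     converged=ok, recording_id=data.recording_id, loss_history=hist)


def fit_ln(data: BlockResponseSet, spec: BlockStimulusSpec = BlockStimulusSpec(),
           opts: dict | None = None, ma_init: MAParams | None = None) -> FitResult:
    """Fit the matched LN model (same 4-parameter filter family) to block traces.

    The filters are parameterized exactly as in ``ln_from_ma``; initial
    timescales include the MA fit when supplied, and the descent adjusts all
    4 parameters against the full traces including the offset response.
    """
    opts = dict(opts or {})
    extra = list(opts.pop("extra_starts", ()))
    if ma_init is None:
        ma_init = fit_ma(data, spec).params
    finite_ta = ma_init.tau_a if math.isfinite(ma_init.tau_a) else _TAU_BOUNDS[1]
    extra.append((ma_init.tau_int, finite_ta))  # starts are in tau units
    params, loss, r2, ok, hist = _fit_block(data, spec, _unit_block_ln,
                                            extra_starts=extra, **opts)
    return FitResult(params=params, model_type="ln", r2=r2, loss=loss,
                     converged=ok, recording_id=data.recording_id, loss_history=hist)


def goodness_r2(model_trace, data_trace) -> float:
    """R^2 = 1 - SSE/SStot with SStot about the data mean; 0 when SStot = 0."""
    m = np.asarray(getattr(model_trace, "r", model_trace), dtype=float)
    d = np.asarray(getattr(data_trace, "r", data_trace), dtype=float)
    if m.shape != d.shape:
        raise ValueError("trace length mismatch")
    sstot = float(np.sum((d - d.mean()) ** 2))
    if sstot == 0.0:
        return 0.0
    sse = float(np.sum((d - m) ** 2))
    return 1.0 - sse / sstot


# ---------------------------------------------------------------------------
# CSV interface: recording_id,mode,t_s,dff


def read_block_csv(path, spec: BlockStimulusSpec = BlockStimulusSpec()) -> list:
    df = pd.read_csv(path)
    out = []
    for rid, grp in df.groupby("recording_id", sort=True):
        traces = {}
        for mode, sub in grp.groupby("mode"):
            traces[mode] = sub.sort_values("t_s")["dff"].to_numpy()
        if {"sine", "pulse"} - set(traces):
            raise ValueError(f"recording {rid} missing a mode")
        out.append(BlockResponseSet(recording_id=str(rid),
                                    sine=traces["sine"], pulse=traces["pulse"]))
    return out


def write_block_csv(sets: list, path, spec: BlockStimulusSpec = BlockStimulusSpec()) -> None:
    rows = []
    t = spec.frame_times
    for bs in sets:
        for mode, trace in (("sine", bs.sine), ("pulse", bs.pulse)):
            for ti, v in zip(t, trace):
                rows.append({"recording_id": bs.recording_id, "mode": mode,
                             "t_s": ti, "dff": v})
    pd.DataFrame(rows).to_csv(path, index=False)
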