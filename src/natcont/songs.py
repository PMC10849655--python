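"""Courtship song sequences: representation, generation, rasterization, features.

A song is a sequence of sine and pulse segments separated by quiet.  The two
modes are mutually exclusive, so a session is fully described by an ordered,
non-overlapping interval list; everything uncovered is quiet.  Rasters expose
the same content as a pair of binary indicator sequences ``I_s``, ``I_p`` on a
uniform time grid, which is the input format of the encoding models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Mode",
    "SongAnnotation",
    "SongRaster",
    "SongGenParams",
    "SongFeatures",
    "rasterize",
    "generate_song",
    "generate_iid_raster",
    "scramble_iid",
    "bout_stats",
    "song_features",
    "read_song_csv",
    "write_song_csv",
]


class Mode(IntEnum):
    QUIET = 0
    SINE = 1
    PULSE = 2


_MODE_NAMES = {"sine": Mode.SINE, "pulse": Mode.PULSE}


@dataclass(frozen=True)
class SongAnnotation:
    """Interval list of sine/pulse segments over a session.

    Intervals are half-open ``[start, end)`` in seconds, sorted and
    non-overlapping; uncovered time is quiet.
    """

    session_id: str
    intervals: tuple  # of (start_s, end_s, Mode)
    duration: float

    def __post_init__(self):
        ivs = tuple(
            (float(s), float(e), Mode(m) if not isinstance(m, Mode) else m)
            for s, e, m in self.intervals
        )
        object.__setattr__(self, "intervals", ivs)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        prev_end = 0.0
        for s, e, m in ivs:
            if e <= s:
                raise ValueError(f"interval ({s}, {e}) has non-positive length")
            if s < prev_end - 1e-12:
                raise ValueError("intervals overlap or are unsorted")
            if s < -1e-12 or e > self.duration + 1e-9:
                raise ValueError("interval outside [0, duration]")
            if m == Mode.QUIET:
                raise ValueError("quiet is implicit; do not annotate it")
            prev_end = e

    @property
    def total_song_time(self) -> float:
        return sum(e - s for s, e, _ in self.intervals)

    def mode_time(self, mode: Mode) -> float:
        return sum(e - s for s, e, m in self.intervals if m == mode)


@dataclass(frozen=True)
class SongRaster:
    """Binary sine/pulse indicators on a uniform grid of width ``dt`` seconds.

    Bin ``b`` covers ``[t0 + b*dt, t0 + (b+1)*dt)``.  ``I_s`` and ``I_p`` are
    mutually exclusive 0/1 arrays of equal length.
    """

    dt: float
    I_s: np.ndarray
    I_p: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        I_s = np.asarray(self.I_s, dtype=np.int8)
        I_p = np.asarray(self.I_p, dtype=np.int8)
        object.__setattr__(self, "I_s", I_s)
        object.__setattr__(self, "I_p", I_p)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if I_s.shape != I_p.shape or I_s.ndim != 1:
            raise ValueError("I_s and I_p must be 1-D arrays of equal length")
        if not np.isin(I_s, (0, 1)).all() or not np.isin(I_p, (0, 1)).all():
            raise ValueError("raster values must be binary")
        if np.any(I_s * I_p):
            raise ValueError("sine and pulse are mutually exclusive")

    def __len__(self) -> int:
        return self.I_s.size

    @property
    def duration(self) -> float:
        return len(self) * self.dt

    @property
    def bin_ends(self) -> np.ndarray:
        """Times at the right edge of each bin (where simulated state lives)."""
        return self.t0 + self.dt * np.arange(1, len(self) + 1)

    def states(self) -> np.ndarray:
        """Ternary state per bin: 0 quiet, 1 sine, 2 pulse."""
        return (self.I_s + 2 * self.I_p).astype(np.int8)


@dataclass(frozen=True)
class SongGenParams:
    """Semi-Markov song generator parameters.

    ``mean_dwell`` gives the mean holding time (s) per state in order
    (quiet, sine, pulse); ``transition_probs`` is a 3x3 row-stochastic
    matrix with zero diagonal giving the jump chain.  Dwells are exponential
    or gamma (shape ``gamma_shape``) with the stated means.
    """

    mean_dwell: tuple = (10.0, 0.6, 0.6)
    transition_probs: tuple = (
        (0.0, 0.5, 0.5),
        (0.2, 0.0, 0.8),
        (0.2, 0.8, 0.0),
    )
    dwell_family: str = "exponential"
    gamma_shape: float = 2.0

    def __post_init__(self):
        P = np.asarray(self.transition_probs, dtype=float)
        if P.shape != (3, 3):
            raise ValueError("transition_probs must be 3x3")
        if np.any(np.abs(np.diag(P)) > 0):
            raise ValueError("transition_probs diagonal must be zero")
        if not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition_probs rows must sum to 1")
        if np.any(P < 0):
            raise ValueError("transition_probs must be non-negative")
        if len(self.mean_dwell) != 3 or any(d <= 0 for d in self.mean_dwell):
            raise ValueError("mean_dwell must be 3 positive values")
        if self.dwell_family not in ("exponential", "gamma"):
            raise ValueError("dwell_family must be exponential or gamma")
        if self.dwell_family == "gamma" and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")


@dataclass(frozen=True)
class SongFeatures:
    """Summary features of a song span used in behavioral correlations."""

    song_density: float
    transitions_per_min: float
    sine_pulse_ratio: float  # inf flagged if no pulse time
    mean_mode_duration: float
    bout_durations: tuple = ()

    @property
    def ratio_defined(self) -> bool:
        return np.isfinite(self.sine_pulse_ratio)


# ---------------------------------------------------------------------------
# operations


def rasterize(annotation: SongAnnotation, dt: float) -> SongRaster:
    """Binarize an annotation onto a uniform grid.

    Bin ``b`` covers ``[b*dt, (b+1)*dt)``; its mode is whichever interval
    contains the bin midpoint (quiet if none).  Total bins =
    ``ceil(duration/dt)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(np.ceil(annotation.duration / dt - 1e-12))
    mid = (np.arange(n) + 0.5) * dt
    I_s = np.zeros(n, dtype=np.int8)
    I_p = np.zeros(n, dtype=np.int8)
    for s, e, m in annotation.intervals:
        lo, hi = np.searchsorted(mid, [s, e], side="left")
        if m == Mode.SINE:
            I_s[lo:hi] = 1
        else:
            I_p[lo:hi] = 1
    return SongRaster(dt=dt, I_s=I_s, I_p=I_p)


def generate_song(
    params: SongGenParams,
    duration: float,
    seed,
    session_id: str = "synthetic",
) -> SongAnnotation:
    """Draw a ternary semi-Markov song of the given duration.

    The chain starts in quiet (sessions begin before singing), holds each
    state for a random dwell, then jumps per ``transition_probs``.  The last
    state is truncated at ``duration``.  Deterministic given ``seed`` (an int
    or a ``numpy.random.Generator``).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    means = np.asarray(params.mean_dwell, dtype=float)
    P = np.asarray(params.transition_probs, dtype=float)

    def draw_dwell(state: int) -> float:
        m = means[state]
        if params.dwell_family == "exponential":
            return rng.exponential(m)
        k = params.gamma_shape
        return rng.gamma(k, m / k)

    intervals = []
    t = 0.0
    state = int(Mode.QUIET)
    while t < duration:
        dwell = draw_dwell(state)
        end = min(t + dwell, duration)
        if state != Mode.QUIET and end > t:
            intervals.append((t, end, Mode(state)))
        t = end
        state = int(rng.choice(3, p=P[state]))
    return SongAnnotation(session_id=session_id, intervals=tuple(intervals), duration=duration)


def stationary_marginals(params: SongGenParams) -> np.ndarray:
    """Long-run time fractions of (quiet, sine, pulse) for the semi-Markov chain.

    The jump-chain stationary distribution is weighted by the mean dwell per
    state and normalized.  These are the marginals a scramble of a long
    generated song converges to.
    """
    P = np.asarray(params.transition_probs, dtype=float)
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi = np.abs(pi) / np.abs(pi).sum()
    frac = pi * np.asarray(params.mean_dwell, dtype=float)
    return frac / frac.sum()


_DEFAULT_IID_P = tuple(stationary_marginals(SongGenParams()))


def generate_iid_raster(
    duration: float,
    dt: float,
    seed,
    p_quiet: float = _DEFAULT_IID_P[0],
    p_sine: float = _DEFAULT_IID_P[1],
    p_pulse: float = _DEFAULT_IID_P[2],
) -> SongRaster:
    """Song with every bin drawn i.i.d. over {quiet, sine, pulse}.

    Used for the diffusion-scaling runs, where temporal correlations in the
    stimulus are deliberately absent.  The default marginals are the
    stationary time fractions of the default naturalistic song generator, so
    an i.i.d. song is the marginal-matched scramble of a typical generated
    song.
    """
    if not np.isclose(p_quiet + p_sine + p_pulse, 1.0):
        raise ValueError("probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration / dt - 1e-12))
    states = rng.choice(3, size=n, p=[p_quiet, p_sine, p_pulse])
    return SongRaster(dt=dt, I_s=(states == 1).astype(np.int8), I_p=(states == 2).astype(np.int8))


def scramble_iid(raster: SongRaster, seed) -> SongRaster:
    """Destroy temporal structure: redraw each bin i.i.d. from the input's
    empirical marginal over {quiet, sine, pulse}."""
    n = len(raster)
    if n == 0:
        raise ValueError("empty raster")
    rng = np.random.default_rng(seed)
    p = np.bincount(raster.states(), minlength=3) / n
    states = rng.choice(3, size=n, p=p)
    return SongRaster(
        dt=raster.dt,
        I_s=(states == 1).astype(np.int8),
        I_p=(states == 2).astype(np.int8),
        t0=raster.t0,
    )


def _bouts(annotation: SongAnnotation, gap_tolerance: float) -> list:
    """Merge song intervals separated by quiet <= gap_tolerance into bouts.

    Returns a list of (start, end) pairs.  With the default tolerance 0 a
    bout is a maximal run of contiguous singing.
    """
    bouts = []
    for s, e, _ in annotation.intervals:
        if bouts and s - bouts[-1][1] <= gap_tolerance + 1e-12:
            bouts[-1][1] = max(bouts[-1][1], e)
        else:
            bouts.append([s, e])
    return [(s, e) for s, e in bouts]


def bout_stats(
    annotation: SongAnnotation,
    window: float = 120.0,
    gap_tolerance: float = 0.0,
    times: Sequence[float] | None = None,
):
    """Trailing-window mean bout duration.

    A bout is a contiguous singing period (sine and/or pulse, quiet gaps up
    to ``gap_tolerance`` bridged).  At each time ``t`` the statistic is the
    mean duration of bouts *ending* within ``(t - window, t]`` (0 if none).

    Returns ``(times, values, bouts)`` where ``bouts`` is the
    ``(start, end)`` list.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    bouts = _bouts(annotation, gap_tolerance)
    if times is None:
        times = np.arange(0.0, annotation.duration + 1e-9, 1.0)
    times = np.asarray(times, dtype=float)
    ends = np.array([e for _, e in bouts])
    durs = np.array([e - s for s, e in bouts])
    values = np.zeros_like(times)
    for i, t in enumerate(times):
        sel = (ends > t - window) & (ends <= t)
        if sel.any():
            values[i] = durs[sel].mean()
    return times, values, bouts


def song_features(
    annotation: SongAnnotation,
    span: tuple | None = None,
    gap_tolerance: float = 0.0,
) -> SongFeatures:
    """Summary features of a song over ``span = (start, end)`` seconds.

    Density is singing time over span length; transitions count quiet->song
    onsets plus direct sine<->pulse switches, per minute; the sine/pulse time
    ratio is flagged infinite when there is no pulse time.
    """
    if span is None:
        span = (0.0, annotation.duration)
    a, b = float(span[0]), float(span[1])
    if not (b > a):
        raise ValueError("empty span")
    # clip intervals to span, keep only the intersecting ones
    clipped = []
    for s, e, m in annotation.intervals:
        lo, hi = max(s, a), min(e, b)
        if hi > lo:
            clipped.append((s, e, lo, hi, m))
    sing = sum(hi - lo for _, _, lo, hi, _ in clipped)
    sine_t = sum(hi - lo for _, _, lo, hi, m in clipped if m == Mode.SINE)
    pulse_t = sing - sine_t
    transitions = 0
    prev_end = None
    for s, e, lo, hi, m in clipped:
        if prev_end is None or s > prev_end + 1e-12:
            transitions += 1  # quiet -> song onset
        else:
            transitions += 1  # contiguous sine<->pulse switch
        prev_end = e
    mode_durs = [e - s for s, e, _, _, _ in clipped]
    ratio = sine_t / pulse_t if pulse_t > 0 else np.inf
    sub = SongAnnotation(
        session_id=annotation.session_id,
        intervals=tuple((lo - a, hi - a, m) for _, _, lo, hi, m in clipped),
        duration=b - a,
    ) if clipped else None
    bouts = _bouts(sub, gap_tolerance) if sub is not None else []
    return SongFeatures(
        song_density=sing / (b - a),
        transitions_per_min=transitions / ((b - a) / 60.0),
        sine_pulse_ratio=ratio,
        mean_mode_duration=float(np.mean(mode_durs)) if mode_durs else 0.0,
        bout_durations=tuple(e - s for s, e in bouts),
    )


# ---------------------------------------------------------------------------
# CSV interface: columns start_s,end_s,mode with mode in {sine,pulse}


def read_song_csv(path, session_id: str | None = None, duration: float | None = None) -> SongAnnotation:
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "mode"}
    if not required.issubset(df.columns):
        raise ValueError(f"song CSV must have columns {sorted(required)}")
    intervals = tuple(
        (row.start_s, row.end_s, _MODE_NAMES[str(row.mode).strip().lower()])
        for row in df.itertuples()
    )
    if duration is None:
        duration = max((e for _, e, _ in intervals), default=1.0)
    if session_id is None:
        session_id = str(path)
    return SongAnnotation(session_id=session_id, intervals=intervals, duration=duration)


def write_song_csv(annotation: SongAnnotation, path) -> None:
    df = pd.DataFrame(
        [(s, e, m.name.lower()) for s, e, m in annotation.intervals],
        columns=["start_s", "end_s", "mode"],
    )
    df.to_csv(path, index=False)
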