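"""Characterization of the MA code: information, geometry, and readouts.

Four analyses of artificial recordings: (1) plug-in histogram entropy of a
neuron's activity, which for these deterministic encoders equals the mutual
information between activity and song; (2) population PCA with a behavioral
sign convention; (3) the power-law scaling exponent of inter-trajectory
Euclidean distance versus elapsed time (the diffusion signature of the
population dynamics); (4) reservoir-style ridge readouts that reconstruct
target waveforms from a single song-evoked trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge

from .encoding import MAParams, PopulationParams, ma_simulate, simulate_population
from .songs import SongAnnotation, SongRaster, rasterize, song_features

__all__ = [
    "InfoResult",
    "ScalingResult",
    "ReservoirFit",
    "response_entropy",
    "population_pca",
    "trajectory_distance_scaling",
    "fit_power_law",
    "accumulation_correlations",
    "reservoir_readout",
    "reservoir_sweep",
]


@dataclass(frozen=True)
class InfoResult:
    """Plug-in entropy of a response histogram, in bits.

    For a deterministic encoder H[r|song] = 0, so the entropy is also the
    song information carried by the momentary activity.  ``normalized``
    divides by log2(n_bins), the entropy of a uniform occupancy.
    """

    entropy_bits: float
    normalized_entropy: float
    n_bins: int


@dataclass(frozen=True)
class ScalingResult:
    gamma_mean: float
    gamma_sd: float
    lag_s: np.ndarray
    mean_distance: np.ndarray  # over pairs, averaged over reps
    n_pairs: int
    n_reps: int


@dataclass(frozen=True)
class ReservoirFit:
    weights: np.ndarray
    intercept: float
    rmse: float
    alpha: float
    prediction: np.ndarray


# ---------------------------------------------------------------------------
# entropy


def response_entropy(values, n_bins: int = 16, support=None) -> InfoResult:
    """Histogram entropy of activity samples over equal-width bins.

    The support defaults to the neuron's own observed [min, max]; a fixed
    support (e.g. the dynamic-range bound) may be passed instead.  Constant
    samples give 0 bits.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("need at least one finite sample")
    lo, hi = (float(v.min()), float(v.max())) if support is None else map(float, support)
    if hi <= lo:
        return InfoResult(entropy_bits=0.0, normalized_entropy=0.0, n_bins=n_bins)
    counts, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / v.size
    H = float(-(p * np.log2(p)).sum())
    return InfoResult(entropy_bits=H, normalized_entropy=H / np.log2(n_bins), n_bins=n_bins)


# ---------------------------------------------------------------------------
# PCA with behavioral sign convention


def population_pca(recordings, targets=None, n_components=None, ridge_alpha: float = 1e-6):
    """PCA of pooled, mean-centered population activity.

    ``recordings`` is a list of (timepoints x neurons) matrices (or
    ``PopulationRecording``); rows are pooled over sessions.  When behavior
    targets are supplied, each component's sign is flipped so that its weight
    in a ridge regression of the target on the PC projections is negative —
    an increase along any PC then predicts slowing.

    Returns ``(components, explained_variance, projections)`` with components
    as rows.
    """
    mats = [r.activity if hasattr(r, "activity") else np.asarray(r, dtype=float)
            for r in recordings]
    X = np.vstack(mats)
    n_t, n_n = X.shape
    rank = min(n_t, n_n)
    k = rank if n_components is None else min(n_components, rank)
    if n_t < n_n and n_components is None:
        import warnings

        warnings.warn("fewer timepoints than neurons; truncating to full rank")
    pca = PCA(n_components=k).fit(X)
    components = pca.components_.copy()
    proj = pca.transform(X)
    if targets is not None:
        y = np.concatenate([np.asarray(t, dtype=float) for t in targets])
        if y.size != n_t:
            raise ValueError("targets misaligned with pooled activity rows")
        reg = Ridge(alpha=ridge_alpha).fit(proj, y)
        flip = np.where(reg.coef_ > 0, -1.0, 1.0)
        components *= flip[:, None]
        proj *= flip[None, :]
    return components, pca.explained_variance_.copy(), proj


# ---------------------------------------------------------------------------
# trajectory distance scaling


def fit_power_law(lag_s, mean_distance) -> float:
    """Slope of the least-squares line of log(distance) vs log(lag)."""
    lag_s = np.asarray(lag_s, dtype=float)
    d = np.asarray(mean_distance, dtype=float)
    keep = (d > 0) & (lag_s > 0)
    if keep.sum() < 2:
        raise ValueError("need at least two positive distances for the fit")
    slope, _ = np.polyfit(np.log(lag_s[keep]), np.log(d[keep]), 1)
    return float(slope)


def _as_rasters(songs, dt):
    out = []
    for s in songs:
        out.append(s if isinstance(s, SongRaster) else rasterize(s, dt))
    return out


def trajectory_distance_scaling(
    pop: PopulationParams,
    songs,
    model: str = "ma",
    n_pairs: int = 100,
    n_reps: int = 30,
    lag_grid=None,
    seed=None,
    dt: float = 0.1,
) -> ScalingResult:
    """Power-law exponent of inter-trajectory distance versus elapsed time.

    Each song drives the population from zero initial state; the Euclidean
    distance between two songs' trajectories is measured at matched elapsed
    times on a logarithmic lag grid (default 20 points from 0.1 s to 80% of
    the song duration, chosen to stay clear of the finite-``tau_int``
    saturation regime).  Per repetition, ``n_pairs`` distinct song pairs are
    drawn, distances are averaged over pairs, and the exponent is the slope
    of log(mean distance) vs log(lag); the mean and sd over repetitions are
    reported.
    """
    rasters = _as_rasters(songs, dt)
    if len(rasters) < 2:
        raise ValueError("need at least 2 songs")
    duration = min(r.duration for r in rasters)
    if lag_grid is None:
        lag_grid = np.geomspace(max(0.1, rasters[0].dt), 0.8 * duration, 20)
    lag_grid = np.asarray(lag_grid, dtype=float)
    if lag_grid.max() > duration + 1e-9:
        raise ValueError("lag grid extends past the shortest song")
    trajs = [simulate_population(pop, r, model=model) for r in rasters]
    idx = np.searchsorted(rasters[0].bin_ends, lag_grid + 1e-9) - 1
    if np.any(idx < 0):
        raise ValueError("lag grid finer than the raster resolution")
    # snap lags to distinct raster bins so no grid point is double-counted
    idx = np.unique(idx)
    lag_grid = rasters[0].bin_ends[idx]
    points = np.stack([tr[idx] for tr in trajs])  # songs x lags x neurons

    rng = np.random.default_rng(seed)
    n_songs = len(rasters)
    gammas = np.empty(n_reps)
    mean_d_acc = np.zeros(lag_grid.size)
    for rep in range(n_reps):
        i = rng.integers(n_songs, size=n_pairs)
        j = rng.integers(n_songs, size=n_pairs)
        clash = i == j
        while clash.any():
            j[clash] = rng.integers(n_songs, size=int(clash.sum()))
            clash = i == j
        d = np.linalg.norm(points[i] - points[j], axis=2)  # pairs x lags
        mean_d = d.mean(axis=0)
        gammas[rep] = fit_power_law(lag_grid, mean_d)
        mean_d_acc += mean_d
    return ScalingResult(
        gamma_mean=float(gammas.mean()),
        gamma_sd=float(gammas.std(ddof=1)) if n_reps > 1 else 0.0,
        lag_s=lag_grid,
        mean_distance=mean_d_acc / n_reps,
        n_pairs=n_pairs,
        n_reps=n_reps,
    )


# ---------------------------------------------------------------------------
# accumulation correlations


def accumulation_correlations(
    params: MAParams,
    songs,
    segment_len: float = 60.0,
    dt: float = 0.01,
):
    """Correlate a neuron's end-of-segment activation with song features.

    For each song segment (annotation of length ``segment_len``), the neuron
    is simulated from zero init and its final activity is correlated (Pearson)
    across segments with the segment's song density and transition rate.
    Returns ``(corr_density, corr_transitions)``; NaN when a feature or the
    responses have zero variance across segments.
    """
    if len(songs) < 10:
        raise ValueError("need at least 10 segments")
    finals, dens, trans = [], [], []
    for song in songs:
        if isinstance(song, SongRaster):
            raise TypeError("accumulation_correlations expects annotations")
        raster = rasterize(song, dt)
        finals.append(ma_simulate(params, raster).r[-1])
        f = song_features(song, span=(0.0, min(segment_len, song.duration)))
        dens.append(f.song_density)
        trans.append(f.transitions_per_min)
    finals = np.asarray(finals)
    out = []
    for feat in (np.asarray(dens), np.asarray(trans)):
        if np.std(feat) == 0 or np.std(finals) == 0:
            out.append(float("nan"))
        else:
            out.append(float(stats.pearsonr(finals, feat).statistic))
    return tuple(out)


# ---------------------------------------------------------------------------
# reservoir-style readouts


def reservoir_readout(activity, target, alpha: float = 1e-15) -> ReservoirFit:
    """In-sample ridge readout of a target waveform from one trajectory.

    The readout weights the neuron activity columns (plus an intercept) and
    is evaluated on the same song's trajectory — the question is whether the
    target is realizable from the trajectory at all, not generalization.
    """
    X = activity.activity if hasattr(activity, "activity") else np.asarray(activity, dtype=float)
    y = np.asarray(target, dtype=float)
    if y.size != X.shape[0]:
        raise ValueError("target must be sampled on the recording grid")
    model = Ridge(alpha=alpha, solver="svd").fit(X, y)
    pred = model.predict(X)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    return ReservoirFit(weights=model.coef_.copy(), intercept=float(model.intercept_),
                        rmse=rmse, alpha=alpha, prediction=pred)


def reservoir_sweep(
    pop: PopulationParams,
    songs,
    periods,
    models=("ma", "ln"),
    alpha: float = 1e-15,
    dt: float = 0.1,
    include_song_baseline: bool = False,
) -> pd.DataFrame:
    """RMSE of sine-wave target reconstruction across target periods.

    For each song and model, the population trajectory is computed once and
    unit-amplitude sine targets ``sin(2 pi t / period)`` are read out
    in-sample; rows are (song, model, period, rmse).  Optionally adds a
    ``song`` pseudo-model reading out directly from the binary inputs.
    """
    rasters = _as_rasters(songs, dt)
    rows = []
    for si, raster in enumerate(rasters):
        t = raster.bin_ends
        feats = {m: simulate_population(pop, raster, model=m) for m in models}
        if include_song_baseline:
            feats["song"] = np.column_stack([raster.I_s, raster.I_p]).astype(float)
        for period in periods:
            y = np.sin(2.0 * np.pi * t / period)
            for name, X in feats.items():
                fit = reservoir_readout(X, y, alpha=alpha)
                rows.append({"song": si, "model": name, "period_s": float(period),
                             "rmse": fit.rmse})
    return pd.DataFrame(rows)
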