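"""Natural Continuation scoring: artificial recordings + ridge readout of behavior.

Given a bank of encoding-model neurons and a set of courtship sessions (song
annotation + walking-speed trace each), this module generates artificial
population recordings by running the encoders over each session's song, then
scores the encoding model by how well a linear (ridge) readout of the
artificial activity predicts the forward-averaged walking speed on held-out
sessions, over repeated session-level train/test splits.

Splits are always at the session level, features are standardized on
training rows only, and the ridge penalty is chosen by internal
cross-validation on the training rows unless fixed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge, RidgeCV

from .encoding import (
    PopulationParams,
    sample_population,
    resample_regimes,
    perturb_population,
    simulate_population,
)
from .songs import Mode, SongAnnotation, bout_stats, rasterize, read_song_csv

__all__ = [
    "Session",
    "PopulationRecording",
    "ReadoutModel",
    "NCScore",
    "simulate_session",
    "forward_average_target",
    "fit_readout",
    "nc_score",
    "score_features",
    "shuffle_songs",
    "baseline_predictors",
    "nc_sweep",
    "lowpass_ve",
    "read_session_manifest",
]

DEFAULT_ALPHAS = np.logspace(-4, 4, 9)


@dataclass(frozen=True)
class Session:
    """One courtship session: the male's song and the female's locomotion."""

    session_id: str
    song: SongAnnotation
    behavior: pd.DataFrame  # columns t_s, walking_speed_mm_s [, forward..., lateral...]

    def __post_init__(self):
        if not {"t_s", "walking_speed_mm_s"}.issubset(self.behavior.columns):
            raise ValueError("behavior needs columns t_s and walking_speed_mm_s")
        t = self.behavior["t_s"].to_numpy()
        if t.size and (t.min() < -1e-9 or t.max() > self.song.duration + 1e-6):
            raise ValueError("behavior times outside [0, song duration]")

    @property
    def duration(self) -> float:
        return self.song.duration


@dataclass(frozen=True)
class PopulationRecording:
    """Artificial activity matrix (timepoints x neurons) aligned to a session."""

    session_id: str
    t: np.ndarray
    activity: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "activity", np.asarray(self.activity, dtype=float))
        if self.activity.shape[0] != self.t.size:
            raise ValueError("activity rows must align with t")
        if not np.isfinite(self.activity).all():
            raise ValueError("non-finite activity")


@dataclass
class ReadoutModel:
    """Linear readout on standardized features: y = ((x - mu)/sd) @ w + b."""

    weights: np.ndarray
    intercept: float
    alpha: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_sd
        return Z @ self.weights + self.intercept


@dataclass
class NCScore:
    """Held-out variance explained over repeated session-level splits."""

    ve_per_split: np.ndarray
    n_splits: int
    train_frac: float

    def __post_init__(self):
        self.ve_per_split = np.asarray(self.ve_per_split, dtype=float)

    @property
    def mean_ve(self) -> float:
        return float(self.ve_per_split.mean())

    @property
    def se_ve(self) -> float:
        n = self.ve_per_split.size
        return float(self.ve_per_split.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    def summary(self) -> str:
        return (f"VE = {self.mean_ve:.4f} +/- {self.se_ve:.4f} (SE) over "
                f"{self.n_splits} splits ({self.train_frac:.0%} train)")


# ---------------------------------------------------------------------------
# artificial recordings and targets


def default_target_times(session: Session, window: float = 1.0, stride: float = 1.0) -> np.ndarray:
    return np.arange(stride, session.duration - window + 1e-9, stride)


def simulate_session(
    pop: PopulationParams,
    session: Session,
    model: str = "ma",
    dt_song: float = 0.01,
    target_times=None,
) -> PopulationRecording:
    """Artificial population recording over one session.

    Each neuron is simulated from zero initial state on the session's song
    raster; activity at a target time ``t`` is the simulated state at the
    last raster bin ending at or before ``t`` (song strictly up to ``t``).
    """
    if model not in ("ma", "ln"):
        raise ValueError("model must be 'ma' or 'ln'")
    if target_times is None:
        target_times = default_target_times(session)
    target_times = np.asarray(target_times, dtype=float)
    if target_times.size and (target_times.min() < 0 or target_times.max() > session.duration + 1e-9):
        raise ValueError("target_times outside the session")
    raster = rasterize(session.song, dt_song)
    act = simulate_population(pop, raster, model=model)
    idx = np.searchsorted(raster.bin_ends, target_times + 1e-9) - 1
    rows = np.where(idx[:, None] >= 0, act[np.maximum(idx, 0)], 0.0)
    return PopulationRecording(session_id=session.session_id, t=target_times, activity=rows)


def forward_average_target(
    session: Session,
    window: float = 1.0,
    target_times=None,
    column: str = "walking_speed_mm_s",
):
    """Forward-averaged behavior: target(t) = mean of ``column`` over (t, t+window].

    Returns ``(times, values)``; times with no behavior sample in the window,
    or whose window extends past the session, are dropped.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if window > session.duration:
        raise ValueError("window exceeds session duration")
    if target_times is None:
        target_times = default_target_times(session, window=window)
    target_times = np.asarray(target_times, dtype=float)
    bt = session.behavior["t_s"].to_numpy()
    bv = session.behavior[column].to_numpy()
    order = np.argsort(bt)
    bt, bv = bt[order], bv[order]
    csum = np.concatenate([[0.0], np.cumsum(bv)])
    lo = np.searchsorted(bt, target_times, side="right")
    hi = np.searchsorted(bt, target_times + window, side="right")
    count = hi - lo
    keep = (count > 0) & (target_times + window <= session.duration + 1e-9)
    vals = np.full(target_times.shape, np.nan)
    nz = keep & (count > 0)
    vals[nz] = (csum[hi[nz]] - csum[lo[nz]]) / count[nz]
    return target_times[keep], vals[keep]


# ---------------------------------------------------------------------------
# readout fitting and scoring


def _standardize_fit(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def fit_readout(recordings, targets, alpha: float | None = None) -> ReadoutModel:
    """Ridge readout on pooled rows of one or more recordings.

    Features are standardized on the pooled (training) rows; the intercept is
    unpenalized.  ``alpha=None`` selects the penalty by leave-out CV over a
    log grid.  Deterministic.
    """
    Xs = [r.activity if isinstance(r, PopulationRecording) else np.asarray(r) for r in np.atleast_1d(recordings)] \
        if isinstance(recordings, (list, tuple)) else [recordings.activity if isinstance(recordings, PopulationRecording) else np.asarray(recordings)]
    X = np.vstack(Xs)
    y = np.concatenate([np.asarray(t, dtype=float) for t in targets]) if isinstance(targets, (list, tuple)) else np.asarray(targets, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("misaligned rows between recordings and targets")
    mu, sd = _standardize_fit(X)
    Z = (X - mu) / sd
    if alpha is None:
        model = RidgeCV(alphas=DEFAULT_ALPHAS).fit(Z, y)
        alpha_used = float(model.alpha_)
    else:
        model = Ridge(alpha=alpha).fit(Z, y)
        alpha_used = float(alpha)
    return ReadoutModel(weights=model.coef_.copy(), intercept=float(model.intercept_),
                        alpha=alpha_used, feature_mean=mu, feature_sd=sd)


def _session_splits(n_sessions: int, n_splits: int, train_frac: float, seed):
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * n_sessions))
    n_train = min(max(n_train, 1), n_sessions - 1)
    for _ in range(n_splits):
        perm = rng.permutation(n_sessions)
        yield perm[:n_train], perm[n_train:]


def score_features(
    features: list,
    targets: list,
    alpha: float | None = None,
    n_splits: int = 30,
    train_frac: float = 0.8,
    seed=0,
    pooled: bool = True,
) -> NCScore:
    """Split/fit/score protocol on arbitrary per-session feature matrices.

    VE per split is 1 - SSE/SStot pooled over all held-out timepoints
    (``pooled=False`` averages per-session VE instead).  This is the common
    engine behind encoding-model scores and every baseline, so paired
    comparisons share identical splits for a given seed.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 sessions for held-out scoring")
    ves = []
    for train_idx, test_idx in _session_splits(len(features), n_splits, train_frac, seed):
        ro = fit_readout([features[i] for i in train_idx],
                         [targets[i] for i in train_idx], alpha=alpha)
        if pooled:
            y = np.concatenate([np.asarray(targets[i]) for i in test_idx])
            yhat = np.concatenate([ro.predict(_as_matrix(features[i])) for i in test_idx])
            ves.append(_ve(y, yhat))
        else:
            per = [_ve(np.asarray(targets[i]), ro.predict(_as_matrix(features[i])))
                   for i in test_idx]
            ves.append(float(np.mean(per)))
    return NCScore(ve_per_split=np.array(ves), n_splits=n_splits, train_frac=train_frac)


def _as_matrix(f):
    return f.activity if isinstance(f, PopulationRecording) else np.asarray(f, dtype=float)


def _ve(y, yhat) -> float:
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        return 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sstot


def _recordings_and_targets(pop, sessions, model, dt_song, window, stride):
    feats, targs = [], []
    for s in sessions:
        tt = default_target_times(s, window=window, stride=stride)
        times, y = forward_average_target(s, window=window, target_times=tt)
        rec = simulate_session(pop, s, model=model, dt_song=dt_song, target_times=times)
        feats.append(rec)
        targs.append(y)
    return feats, targs


def nc_score(
    pop: PopulationParams,
    sessions: list,
    model: str = "ma",
    alpha: float | None = None,
    n_splits: int = 30,
    train_frac: float = 0.8,
    seed=0,
    dt_song: float = 0.01,
    window: float = 1.0,
    stride: float = 1.0,
    pooled: bool = True,
) -> NCScore:
    """Score an encoding model by held-out ridge prediction of walking speed."""
    feats, targs = _recordings_and_targets(pop, sessions, model, dt_song, window, stride)
    return score_features(feats, targs, alpha=alpha, n_splits=n_splits,
                          train_frac=train_frac, seed=seed, pooled=pooled)


def shuffle_songs(sessions: list, seed=0) -> list:
    """Break the song-behavior pairing by permuting songs across sessions.

    Prefers a derangement (no session keeps its own song).  Each reassigned
    song is truncated, or padded with quiet, to the receiving session's
    behavior duration.
    """
    n = len(sessions)
    if n < 2:
        raise ValueError("need at least 2 sessions to shuffle")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            break
    out = []
    for i, s in enumerate(sessions):
        src = sessions[perm[i]].song
        dur = s.duration
        clipped = tuple((a, min(b, dur), m) for a, b, m in src.intervals if a < dur)
        song = SongAnnotation(session_id=s.session_id + "+shuffled",
                              intervals=clipped, duration=dur)
        out.append(Session(session_id=s.session_id, song=song, behavior=s.behavior))
    return out


# ---------------------------------------------------------------------------
# baselines


def baseline_predictors(
    sessions: list,
    which=("timestamp", "bout_duration", "linear_filter"),
    alpha: float | None = None,
    n_splits: int = 30,
    train_frac: float = 0.8,
    seed=0,
    window: float = 1.0,
    stride: float = 1.0,
    bout_window: float = 120.0,
    filter_lag_s: float = 1.0,
    filter_n_lags: int = 60,
    pooled: bool = True,
) -> dict:
    """Score the reference predictors under the identical split protocol.

    ``timestamp``: elapsed session time alone.  ``bout_duration``: trailing
    2-minute mean song-bout duration.  ``linear_filter``: ridge-learned
    lagged filters applied directly to the binary sine and pulse inputs
    (``filter_n_lags`` taps of ``filter_lag_s`` seconds each).
    Returns ``{name: NCScore}``; the same seed yields the same splits as
    ``nc_score``, making the comparison paired.
    """
    targets, times_per = [], []
    for s in sessions:
        tt = default_target_times(s, window=window, stride=stride)
        times, y = forward_average_target(s, window=window, target_times=tt)
        targets.append(y)
        times_per.append(times)

    scores = {}
    for name in which:
        feats = [_baseline_features(s, name, t, bout_window, filter_lag_s, filter_n_lags)
                 for s, t in zip(sessions, times_per)]
        scores[name] = score_features(feats, targets, alpha=alpha, n_splits=n_splits,
                                      train_frac=train_frac, seed=seed, pooled=pooled)
    return scores


def _baseline_features(session, name, times, bout_window, lag_s, n_lags):
    if name == "timestamp":
        return times[:, None].copy()
    if name == "bout_duration":
        _, vals, _ = bout_stats(session.song, window=bout_window, times=times)
        return vals[:, None]
    if name == "linear_filter":
        dt = 0.1
        raster = rasterize(session.song, dt)
        cs_s = np.concatenate([[0.0], np.cumsum(raster.I_s, dtype=float)]) * dt
        cs_p = np.concatenate([[0.0], np.cumsum(raster.I_p, dtype=float)]) * dt
        n = len(raster)

        def frac(cs, a, b):
            ia = np.clip(np.round(a / dt).astype(int), 0, n)
            ib = np.clip(np.round(b / dt).astype(int), 0, n)
            return (cs[ib] - cs[ia]) / lag_s

        cols = []
        for k in range(n_lags):
            a = times - (k + 1) * lag_s
            b = times - k * lag_s
            cols.append(frac(cs_s, a, b))
            cols.append(frac(cs_p, a, b))
        return np.column_stack(cols)
    raise ValueError(f"unknown baseline {name!r}")


# ---------------------------------------------------------------------------
# sweeps


def nc_sweep(
    pop_factory,
    sessions: list,
    sweep: str,
    model: str = "ma",
    seed=0,
    alpha: float | None = None,
    n_splits: int = 30,
    train_frac: float = 0.8,
    dt_song: float = 0.01,
    window: float = 1.0,
    stride: float = 1.0,
    sizes=(1, 2, 5, 10, 15, 20),
    n_instantiations: int = 30,
    pcs_grid=None,
    base_pop: PopulationParams | None = None,
    fixed_tau_int: float = 120.0,
    fixed_tau_a: float = 0.5,
) -> pd.DataFrame:
    """Tables of mean held-out VE against a swept design variable.

    ``population_size``: VE vs number of neurons for random draws from
    ``pop_factory(n, seed)``, mean and sd over instantiations.
    ``n_pcs``: recordings of ``base_pop`` projected onto their top-k
    training-set PCs (after the usual standardization) before readout.
    ``regime_grid``: all fast/medium/slow tau_int x tau_a cells plus a
    no-adaptation row.  ``heterogeneity``: fixed-tau_int/heterogeneous-tau_a
    versus heterogeneous-tau_int/fixed-tau_a.
    """
    common = dict(alpha=alpha, n_splits=n_splits, train_frac=train_frac, seed=seed,
                  pooled=True)
    rng = np.random.default_rng(seed)

    if sweep == "population_size":
        rows = []
        for n in sizes:
            ves = []
            for _ in range(n_instantiations):
                pop = pop_factory(n, int(rng.integers(1 << 31)))
                sc = nc_score(pop, sessions, model=model, dt_song=dt_song,
                              window=window, stride=stride, **common)
                ves.append(sc.mean_ve)
            rows.append({"n_neurons": n, "mean_ve": float(np.mean(ves)),
                         "sd_ve": float(np.std(ves, ddof=1)) if len(ves) > 1 else 0.0})
        return pd.DataFrame(rows)

    if sweep == "n_pcs":
        pop = base_pop if base_pop is not None else pop_factory(20, seed)
        feats, targs = _recordings_and_targets(pop, sessions, model, dt_song, window, stride)
        mats = [_as_matrix(f) for f in feats]
        k_max = mats[0].shape[1]
        grid = pcs_grid if pcs_grid is not None else range(1, k_max + 1)
        rows = []
        for k in grid:
            ves = []
            for train_idx, test_idx in _session_splits(len(feats), n_splits, train_frac, seed):
                Xtr = np.vstack([mats[i] for i in train_idx])
                ytr = np.concatenate([targs[i] for i in train_idx])
                mu, sd = _standardize_fit(Xtr)
                pca = PCA(n_components=min(k, k_max)).fit((Xtr - mu) / sd)
                Ztr = pca.transform((Xtr - mu) / sd)
                if alpha is None:
                    ro = RidgeCV(alphas=DEFAULT_ALPHAS).fit(Ztr, ytr)
                else:
                    ro = Ridge(alpha=alpha).fit(Ztr, ytr)
                y = np.concatenate([targs[i] for i in test_idx])
                Zte = pca.transform((np.vstack([mats[i] for i in test_idx]) - mu) / sd)
                ves.append(_ve(y, ro.predict(Zte)))
            rows.append({"n_pcs": int(k), "mean_ve": float(np.mean(ves)),
                         "se_ve": float(np.std(ves, ddof=1) / np.sqrt(len(ves)))})
        return pd.DataFrame(rows)

    if sweep == "regime_grid":
        pop = base_pop if base_pop is not None else pop_factory(20, seed)
        rows = []
        for ri in ("fast", "medium", "slow"):
            for ra in ("fast", "medium", "slow", "none"):
                resampled = resample_regimes(pop, ri, ra, seed=int(rng.integers(1 << 31)))
                sc = nc_score(resampled, sessions, model=model, dt_song=dt_song,
                              window=window, stride=stride, **common)
                rows.append({"tau_int_regime": ri, "tau_a_regime": ra,
                             "mean_ve": sc.mean_ve, "se_ve": sc.se_ve})
        return pd.DataFrame(rows)

    if sweep == "heterogeneity":
        n = len(base_pop) if base_pop is not None else 20
        configs = {
            "het_tau_a_fixed_tau_int": dict(tau_int_range=fixed_tau_int,
                                            tau_a_range=(0.1, 2.0)),
            "het_tau_int_fixed_tau_a": dict(tau_int_range=(20.0, 120.0),
                                            tau_a_range=fixed_tau_a),
        }
        rows = []
        for name, kw in configs.items():
            pop = sample_population(n, seed=int(rng.integers(1 << 31)), **kw)
            sc = nc_score(pop, sessions, model=model, dt_song=dt_song,
                          window=window, stride=stride, **common)
            rows.append({"config": name, "mean_ve": sc.mean_ve, "se_ve": sc.se_ve})
        return pd.DataFrame(rows)

    raise ValueError(f"unknown sweep {sweep!r}")


def lowpass_ve(y, yhat, stride: float = 1.0, smooth_s: float = 30.0) -> float:
    """VE after symmetric moving-average smoothing of target and prediction.

    A rough check of how much of the slow component of behavior is captured;
    not calibrated against any published quantity.
    """
    w = max(1, int(round(smooth_s / stride)))
    kernel = np.ones(w) / w
    ys = np.convolve(np.asarray(y, dtype=float), kernel, mode="same")
    yhs = np.convolve(np.asarray(yhat, dtype=float), kernel, mode="same")
    return _ve(ys, yhs)


# ---------------------------------------------------------------------------
# session manifest


def read_session_manifest(path) -> list:
    """Load sessions from a YAML manifest mapping session_id -> file paths.

    Each entry has ``song`` (interval CSV) and ``behavior`` (t_s,
    walking_speed_mm_s CSV), resolved relative to the manifest's directory.
    """
    import os

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(path))
    sessions = []
    for sid, entry in spec.items():
        behavior = pd.read_csv(os.path.join(base, entry["behavior"]))
        duration = entry.get("duration", float(behavior["t_s"].max()) + 1e-6)
        song = read_song_csv(os.path.join(base, entry["song"]), session_id=str(sid),
                             duration=duration)
        sessions.append(Session(session_id=str(sid), song=song, behavior=behavior))
    return sessions
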