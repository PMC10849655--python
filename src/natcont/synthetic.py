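"""Synthetic studies with known ground truth.

Everything downstream of raw data collection can be exercised without any
recorded dataset: this module fabricates (a) courtship-style sessions whose
walking speed is, by construction, a noisy linear readout of a known MA
population's song response, and (b) trial-averaged block-stimulus recordings
generated from known MA parameters.  Ground truth is returned alongside the
data so recovery can be asserted end to end.

Seeding is hierarchical (``numpy.random.SeedSequence.spawn``): each session
and each neuron gets an independent stream, so enlarging a study leaves the
existing sessions bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import MAParams, PopulationParams, sample_population, simulate_population
from .fitting import BlockResponseSet, BlockStimulusSpec, _unit_block_ma
from .nc import Session
from .songs import SongGenParams, generate_song, rasterize

__all__ = [
    "SyntheticStudyConfig",
    "SyntheticBlockConfig",
    "make_synthetic_study",
    "make_block_recordings",
    "write_study",
]


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Generator settings for a synthetic courtship study.

    Walking speed is ``max(0, intercept + w . activity + noise)`` sampled at
    ``behavior_rate``; weights default to a slowing-dominated draw
    (N(-0.8, 0.4) mm/s per unit activity) and the intercept is raised just
    enough above ``base_speed`` that the noiseless speed never clips, keeping
    the song-to-behavior map exactly linear at zero noise.
    """

    n_sessions: int = 10
    session_duration: float = 300.0
    song_params: SongGenParams = field(default_factory=SongGenParams)
    # across-session song heterogeneity: courtship pairs differ widely in how
    # much song is produced, so each session rescales the quiet dwell and the
    # within-bout continuation probability (log-uniform / uniform draws).
    heterogeneous_sessions: bool = True
    quiet_dwell_range: tuple = (4.0, 30.0)
    bout_continuation_range: tuple = (0.7, 0.9)
    n_neurons: int = 20
    ground_truth_pop: PopulationParams | None = None
    readout_weights: np.ndarray | None = None
    intercept: float | None = None
    base_speed: float = 2.0
    noise_sd: float = 0.5
    behavior_rate: float = 10.0
    dt_song: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_sessions < 1 or self.session_duration <= 0:
            raise ValueError("need >= 1 session of positive duration")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.readout_weights is not None:
            w = np.asarray(self.readout_weights, dtype=float)
            npop = len(self.ground_truth_pop) if self.ground_truth_pop is not None else self.n_neurons
            if w.size != npop:
                raise ValueError("readout weight count must equal population size")


@dataclass(frozen=True)
class SyntheticBlockConfig:
    """Generator settings for synthetic block-stimulus recordings."""

    ground_truth: tuple = ()
    noise_sd: float = 0.05
    frame_rate: float = 8.0
    n_trials: int = 10
    stim_duration: float = 10.0
    post_duration: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_trials < 1:
            raise ValueError("need >= 1 trial")


def make_synthetic_study(cfg: SyntheticStudyConfig):
    """Generate sessions with a known song -> activity -> walking-speed map.

    Returns ``(sessions, ground_truth)`` where ``ground_truth`` holds the
    population, readout weights, intercept, and per-session noiseless
    activity for recovery tests.
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_pop, ss_weights, *ss_sessions = root.spawn(2 + cfg.n_sessions)

    pop = cfg.ground_truth_pop
    if pop is None:
        pop = sample_population(cfg.n_neurons, seed=np.random.default_rng(ss_pop))
    wrng = np.random.default_rng(ss_weights)
    w = cfg.readout_weights
    if w is None:
        w = wrng.normal(-0.8, 0.4, size=len(pop))
    w = np.asarray(w, dtype=float)

    sessions, acts, drives = [], [], []
    for i, ss in enumerate(ss_sessions):
        srng = np.random.default_rng(ss)
        song_params = cfg.song_params
        if cfg.heterogeneous_sessions:
            lo, hi = cfg.quiet_dwell_range
            quiet = float(np.exp(srng.uniform(np.log(lo), np.log(hi))))
            cont = float(srng.uniform(*cfg.bout_continuation_range))
            md = (quiet,) + tuple(song_params.mean_dwell[1:])
            P = ((0.0, 0.5, 0.5),
                 (1.0 - cont, 0.0, cont),
                 (1.0 - cont, cont, 0.0))
            song_params = SongGenParams(mean_dwell=md, transition_probs=P,
                                        dwell_family=song_params.dwell_family,
                                        gamma_shape=song_params.gamma_shape)
        song = generate_song(song_params, cfg.session_duration, srng,
                             session_id=f"synth{i:03d}")
        raster = rasterize(song, cfg.dt_song)
        act = simulate_population(pop, raster, model="ma")
        t_beh = np.arange(0.0, cfg.session_duration, 1.0 / cfg.behavior_rate)
        idx = np.searchsorted(raster.bin_ends, t_beh + 1e-9) - 1
        rows = np.where(idx[:, None] >= 0, act[np.maximum(idx, 0)], 0.0)
        drives.append(rows @ w)
        sessions.append((song, t_beh, srng))
        acts.append(rows)

    intercept = cfg.intercept
    if intercept is None:
        # lift the noiseless speed floor to base_speed so max(0, .) never
        # bites: each neuron's activity is bounded by max(x_s, x_p), so the
        # worst-case negative drive is known from the population alone (and
        # the intercept therefore never depends on how many sessions exist)
        bound = sum(min(wi, 0.0) * max(p.x_s, p.x_p)
                    for wi, p in zip(w, pop.neurons))
        intercept = cfg.base_speed - bound

    out = []
    for (song, t_beh, srng), drive in zip(sessions, drives):
        speed = intercept + drive + srng.normal(0.0, cfg.noise_sd, size=t_beh.size)
        speed = np.maximum(speed, 0.0)
        behavior = pd.DataFrame({"t_s": t_beh, "walking_speed_mm_s": speed})
        out.append(Session(session_id=song.session_id, song=song, behavior=behavior))

    ground_truth = {
        "pop": pop,
        "weights": w,
        "intercept": float(intercept),
        "noiseless_activity": acts,
    }
    return out, ground_truth


def make_block_recordings(cfg: SyntheticBlockConfig):
    """Trial-averaged sine/pulse block traces from known MA parameters.

    Each neuron's noiseless response is the closed-form block response at the
    imaging frame midpoints; i.i.d. Gaussian noise is added per trial and
    averaged over ``n_trials``.  Returns ``(block_sets, spec)``.
    """
    if not cfg.ground_truth:
        raise ValueError("ground_truth must list at least one MAParams")
    spec = BlockStimulusSpec(stim_duration=cfg.stim_duration,
                             post_duration=cfg.post_duration,
                             frame_rate=cfg.frame_rate)
    t = spec.frame_times
    root = np.random.SeedSequence(cfg.seed)
    out = []
    for i, (params, ss) in enumerate(zip(cfg.ground_truth, root.spawn(len(cfg.ground_truth)))):
        rng = np.random.default_rng(ss)
        u = _unit_block_ma(params.tau_int, params.tau_a, t, spec.stim_duration)
        traces = {}
        for mode, x in (("sine", params.x_s), ("pulse", params.x_p)):
            clean = params.polarity * x * u
            trials = clean[None, :] + rng.normal(0.0, cfg.noise_sd,
                                                 size=(cfg.n_trials, t.size))
            traces[mode] = trials.mean(axis=0)
        out.append(BlockResponseSet(recording_id=f"rec{i:03d}",
                                    sine=traces["sine"], pulse=traces["pulse"]))
    return out, spec


def write_study(sessions, out_dir, manifest_name: str = "sessions.yaml") -> str:
    """Write a study to disk as the song/behavior CSVs plus a YAML manifest."""
    import os

    import yaml

    from .songs import write_song_csv

    os.makedirs(out_dir, exist_ok=True)
    manifest = {}
    for s in sessions:
        song_path = f"{s.session_id}_song.csv"
        beh_path = f"{s.session_id}_behavior.csv"
        write_song_csv(s.song, os.path.join(out_dir, song_path))
        s.behavior.to_csv(os.path.join(out_dir, beh_path), index=False)
        manifest[s.session_id] = {"song": song_path, "behavior": beh_path,
                                  "duration": float(s.duration)}
    path = os.path.join(out_dir, manifest_name)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path
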