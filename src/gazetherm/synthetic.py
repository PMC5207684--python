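"""Synthetic multi-viewer gaze data with planted collective structure.

The generator is the forward model of the analysis: direction series are
drawn from the Boltzmann distribution of a fully-connected XY model with
community-structured couplings (groups of viewers coupled strongly within,
weakly between), then integrated into pixel gaze trajectories on a
1440 x 2560 screen with border reflection, degraded with bursty tracker
dropout, and paired with preference ratings whose group means make the
panel as homophilous as desired.  Defaults emulate a 25-subject panel
watching 30-s clips sampled at 250 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mc import MCOptions, run_metropolis
from .correlations import RatingsTable
from .panels import DirectionPanel, GazePanel

__all__ = ["PlantedModel", "SyntheticConfig", "planted_community_model",
           "simulate_directions", "directions_to_gaze", "inject_dropout",
           "simulate_ratings", "simulate_gaze_video"]


@dataclass
class PlantedModel:
    """Ground-truth XY model on the generating side.

    J_true is symmetric with exactly zero diagonal; group_labels give the
    planted community of each subject; temperature is the level of
    directional fluctuation (operating value 1).
    """

    n_subjects: int
    group_labels: np.ndarray
    J_true: np.ndarray
    h_true: np.ndarray
    temperature: float = 1.0

    def __post_init__(self) -> None:
        self.group_labels = np.asarray(self.group_labels, dtype=int)
        self.J_true = np.asarray(self.J_true, dtype=float)
        self.h_true = np.asarray(self.h_true, dtype=float)
        n = self.n_subjects
        if self.group_labels.shape != (n,):
            raise ValueError("group_labels must have one entry per subject")
        if self.J_true.shape != (n, n):
            raise ValueError("J_true must be (N, N)")
        if not np.allclose(self.J_true, self.J_true.T, atol=1e-12):
            raise ValueError("J_true must be symmetric")
        if not np.all(np.diag(self.J_true) == 0):
            raise ValueError("J_true diagonal must be exactly zero")
        if self.h_true.shape != (n, 2):
            raise ValueError("h_true must be (N, 2)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class SyntheticConfig:
    """Study conditions emulated by the generator.

    Defaults mirror the recorded panel: 25 subjects, 30-s segments at
    250 Hz, a 1440 (h) x 2560 (w) pixel screen, two viewer groups with much
    stronger within- than between-group coupling (sub-critical at the
    operating temperature), ~5% bursty dropout, and 0-10 ratings whose
    group means differ with +-1 rating point of rater noise.
    """

    n_subjects: int = 25
    segment_seconds: float = 30.0
    sample_rate_hz: float = 250.0
    screen_px: tuple[int, int] = (1440, 2560)  # (height, width)
    n_groups: int = 2
    within_coupling: float = 0.12
    between_coupling: float = 0.02
    field_scale: float = 0.0
    temperature: float = 1.0
    dropout_rate: float = 0.05
    dropout_mean_burst: float = 25.0  # samples (~100 ms at 250 Hz)
    rating_group_means: tuple[float, ...] = (8.0, 6.0)
    rating_noise_sd: float = 1.0
    p_max: float = 10.0
    speed_px_per_sample: float = 4.0
    speed_jitter_frac: float = 0.1
    thin_sweeps: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if any(not 0 <= m <= self.p_max for m in self.rating_group_means):
            raise ValueError("rating group means must lie in [0, p_max]")

    @property
    def n_samples(self) -> int:
        return int(round(self.segment_seconds * self.sample_rate_hz))


def planted_community_model(config: SyntheticConfig,
                            coupling_scale: float = 1.0) -> PlantedModel:
    """Community-structured coupling matrix from the config's group layout.

    Subjects are split into ``n_groups`` nearly equal groups; J_ij equals
    ``within_coupling`` inside a group and ``between_coupling`` across,
    both multiplied by ``coupling_scale`` (the knob a synthetic study
    varies across "videos").
    """
    n = config.n_subjects
    labels = np.arange(n) % config.n_groups
    labels = np.sort(labels)
    same = labels[:, None] == labels[None, :]
    J = np.where(same, config.within_coupling, config.between_coupling)
    J = J * coupling_scale
    np.fill_diagonal(J, 0.0)
    h = np.zeros((n, 2))
    if config.field_scale:
        h[:, 0] = config.field_scale
    return PlantedModel(n, labels, J, h, config.temperature)


def simulate_directions(model: PlantedModel, n_samples: int, seed: int,
                        thin_sweeps: int = 10,
                        mc: MCOptions | None = None) -> DirectionPanel:
    """Draw direction series from the model's Boltzmann distribution.

    Samples are equilibrated and thinned Metropolis draws, so successive
    panel samples are approximately independent.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mc = mc or MCOptions(thin_sweeps=thin_sweeps)
    draws, _, _ = run_metropolis(model.J_true, model.h_true,
                                 model.temperature, n_samples, seed, mc)
    sigma = np.transpose(draws, (1, 0, 2))
    valid = np.ones(sigma.shape[:2], dtype=bool)
    ids = [f"s{i:02d}" for i in range(model.n_subjects)]
    return DirectionPanel(sigma, valid, ids)


def _reflect(pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions into [lo, hi] by mirror reflection at the borders."""
    span = hi - lo
    p = np.mod(pos - lo, 2 * span)
    p = np.where(p > span, 2 * span - p, p)
    return p + lo


def directions_to_gaze(directions: DirectionPanel, config: SyntheticConfig,
                       seed: int = 0) -> GazePanel:
    """Integrate directions into pixel trajectories on the screen.

    Positions advance on two interleaved time lattices,
    ``r(t+1) = r(t-1) + 2 s(t) sigma(t)``, which is the exact inverse of
    the central-difference velocity stencil used in preprocessing: away
    from border reflections, extracting directions from the produced gaze
    recovers the input directions.  The speed profile s(t) is constant with
    small Gaussian jitter (always positive).
    """
    if directions.n_samples == 0 or directions.n_subjects == 0:
        raise ValueError("empty direction panel")
    if not np.all(np.isfinite(directions.sigma)):
        raise ValueError("directions must be finite")
    rng = np.random.default_rng(seed)
    n, t = directions.n_subjects, directions.n_samples
    height, width = config.screen_px
    base = config.speed_px_per_sample
    speed = base * (1.0 + config.speed_jitter_frac
                    * rng.standard_normal((n, t)))
    speed = np.clip(speed, 0.1 * base, 2.0 * base)
    steps = 2.0 * speed[..., None] * directions.sigma
    x = np.empty((n, t))
    y = np.empty((n, t))
    # two interleaved lattices, both seeded near screen centre
    cx, cy = width / 2.0, height / 2.0
    start = np.stack([cx + rng.uniform(-0.1, 0.1, (n, 2)) * width / 4,
                      cy + rng.uniform(-0.1, 0.1, (n, 2)) * height / 4],
                     axis=-1)  # (n, 2 lattices, 2 coords)
    for parity in (0, 1):
        idx = np.arange(parity, t, 2)
        x[:, idx[0]] = start[:, parity, 0]
        y[:, idx[0]] = start[:, parity, 1]
        if idx.size > 1:
            # r(t+2) = r(t) + 2 s(t+1) sigma(t+1): each lattice advances
            # by the step evaluated at the opposite-parity time between
            cum = np.cumsum(steps[:, idx[:-1] + 1], axis=1)
            x[:, idx[1:]] = start[:, parity, 0, None] + cum[..., 0]
            y[:, idx[1:]] = start[:, parity, 1, None] + cum[..., 1]
    x = _reflect(x, 0.0, float(width))
    y = _reflect(y, 0.0, float(height))
    dt = 1000.0 / config.sample_rate_hz
    times = np.arange(t) * dt
    missing = np.zeros((n, t), dtype=bool)
    return GazePanel(times, x, y, missing, list(directions.subject_ids))


def inject_dropout(panel: GazePanel, rate: float, seed: int,
                   mean_burst: float = 25.0) -> GazePanel:
    """Mark contiguous missing-data bursts totalling ~``rate`` per subject.

    Burst lengths are geometric with the given mean (tracker lapses come in
    episodes, not isolated samples); bursts are placed uniformly until each
    subject's missing fraction reaches the requested rate.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    out = panel.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    t = panel.n_samples
    for s in range(panel.n_subjects):
        mask = out.missing[s]
        target = rate * t
        guard = 0
        while mask.sum() < target and guard < 100 * t:
            length = rng.geometric(1.0 / mean_burst)
            start = rng.integers(0, t)
            mask[start:start + length] = True
            guard += 1
        out.missing[s] = mask
    if rate >= 1.0:
        out.missing[:] = True
    return out


def simulate_ratings(config: SyntheticConfig, seed: int,
                     video: str = "v00",
                     group_labels: np.ndarray | None = None) -> RatingsTable:
    """Group-mean ratings plus Gaussian rater noise, clipped to [0, p_max]."""
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    if group_labels is None:
        group_labels = np.sort(np.arange(n) % config.n_groups)
    means = np.asarray(config.rating_group_means, dtype=float)
    base = means[np.asarray(group_labels) % means.size]
    vals = base + config.rating_noise_sd * rng.standard_normal(n)
    vals = np.clip(vals, 0.0, config.p_max)
    df = pd.DataFrame({"subject": [f"s{i:02d}" for i in range(n)],
                       "video": video, "rating": vals})
    return RatingsTable(df, p_max=config.p_max)


def simulate_gaze_video(config: SyntheticConfig, seed: int,
                        coupling_scale: float = 1.0,
                        n_segments: int = 1) -> tuple[GazePanel, PlantedModel]:
    """Full forward model for one synthetic "video".

    Directions from the planted Boltzmann model -> pixel gaze with border
    reflection -> bursty dropout.  ``n_segments`` chains several 30-s
    increments into one recording.
    """
    model = planted_community_model(config, coupling_scale)
    n_samples = config.n_samples * n_segments
    dirs = simulate_directions(model, n_samples, seed,
                               thin_sweeps=config.thin_sweeps)
    panel = directions_to_gaze(dirs, config, seed=seed + 1)
    panel = inject_dropout(panel, config.dropout_rate, seed + 2,
                           mean_burst=config.dropout_mean_burst)
    return panel, model
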