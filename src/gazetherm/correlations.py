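"""Inter-subject correlation of gaze, and rating homophily.

Three statistics drive the whole analysis:

* position ISC — per-pair Pearson correlation of horizontal (vertical)
  gaze position over jointly non-missing samples, averaged over all pairs;
* direction correlations — the connected correlation of movement
  directions, C_ij = <sigma_i . sigma_j> - mu_i . mu_j, whose all-pair
  average C_sigma is the susceptibility of the viewer ensemble;
* homophily — pairwise agreement of 0..p_max preference ratings,
  O = 1/(N(N-1)) * sum_{i != j} (1 - |p_i - p_j| / p_max),
  equal to 1 when everyone agrees and approaching 1/2 for the worst
  bimodal split (half rate p_max, half rate 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panels import DirectionPanel, GazePanel

__all__ = [
    "CorrelationSet", "RatingsTable",
    "position_isc", "direction_correlations", "homophily", "pearson_with_p",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationSet:
    """Observed moments of one video segment.

    c_pairwise is the symmetric matrix of connected direction correlations
    C_ij (NaN for pairs with too few joint samples; diagonal NaN by
    convention), mu the per-subject mean direction vectors.  c_sigma is the
    susceptibility: the average of C_ij over all ordered pairs i != j.
    """

    c_pairwise: np.ndarray
    mu: np.ndarray
    subject_ids: list[str]
    c_x: float | None = None
    c_y: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.c_pairwise, dtype=float)
        off = ~np.eye(c.shape[0], dtype=bool)
        finite = np.isfinite(c) & off
        if not np.allclose(np.where(finite, c, 0.0),
                           np.where(finite.T, c.T, 0.0), atol=1e-12):
            raise ValueError("C_ij must be symmetric")
        self.c_pairwise = c

    @property
    def n_subjects(self) -> int:
        return self.c_pairwise.shape[0]

    @property
    def c_sigma(self) -> float:
        """Susceptibility: mean of the off-diagonal C_ij (NaN pairs skipped)."""
        off = ~np.eye(self.n_subjects, dtype=bool)
        vals = self.c_pairwise[off]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no valid pairwise correlations")
        return float(vals.mean())


@dataclass
class RatingsTable:
    """Per-subject per-video preference ratings on a 0..p_max scale."""

    ratings: pd.DataFrame  # columns: subject, video, rating
    p_max: float = 10.0
    population: pd.Series | None = None  # per-video population rating

    def __post_init__(self) -> None:
        required = {"subject", "video", "rating"}
        if not required.issubset(self.ratings.columns):
            raise ValueError(f"ratings frame needs columns {sorted(required)}")
        r = self.ratings["rating"].to_numpy(dtype=float)
        if self.p_max <= 0:
            raise ValueError("p_max must be positive")
        if np.any((r < 0) | (r > self.p_max)):
            raise ValueError("ratings outside [0, p_max]")

    def for_video(self, video) -> np.ndarray:
        sel = self.ratings.loc[self.ratings["video"] == video, "rating"]
        return sel.to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path, p_max: float = 10.0,
                 population_path: str | Path | None = None) -> "RatingsTable":
        df = pd.read_csv(path)
        pop = None
        if population_path is not None:
            pdf = pd.read_csv(population_path)
            pop = pdf.set_index("video")["population_rating"]
        return cls(df, p_max=p_max, population=pop)


def position_isc(panel: GazePanel) -> tuple[float, float]:
    """Average pairwise Pearson correlation of x and of y gaze position.

    Each pair is correlated over its jointly non-missing samples; pairs with
    an undefined correlation (constant trajectory, <2 joint samples) are
    skipped and logged.  The average runs over all ordered pairs, which for
    a symmetric statistic equals the unordered-pair average.
    """
    n = panel.n_subjects
    if n < 2:
        raise ValueError("position ISC needs >= 2 subjects")
    ok = ~panel.missing
    out = []
    for coord in (panel.x, panel.y):
        acc, cnt = 0.0, 0
        for i in range(n):
            for j in range(i + 1, n):
                joint = ok[i] & ok[j]
                if joint.sum() < 2:
                    logger.info("pair (%s,%s): <2 joint samples, skipped",
                                panel.subject_ids[i], panel.subject_ids[j])
                    continue
                a = coord[i, joint]
                b = coord[j, joint]
                if a.std() == 0 or b.std() == 0:
                    logger.info("pair (%s,%s): constant trajectory, skipped",
                                panel.subject_ids[i], panel.subject_ids[j])
                    continue
                acc += float(np.corrcoef(a, b)[0, 1])
                cnt += 1
        if cnt == 0:
            raise ValueError("no valid pairs for position ISC")
        out.append(acc / cnt)
    return out[0], out[1]


def direction_correlations(
    dirs: DirectionPanel,
    min_joint_samples: int = 100,
    c_x: float | None = None,
    c_y: float | None = None,
) -> CorrelationSet:
    """Connected pairwise direction correlations C_ij and susceptibility.

    C_ij = <sigma_i . sigma_j>_t - mu_i . mu_j, the cross moment taken over
    jointly valid samples and mu_i over each subject's own valid samples.
    Pairs with fewer than ``min_joint_samples`` joint samples are marked
    missing (NaN) and excluded from the susceptibility average.
    """
    n = dirs.n_subjects
    if n < 2:
        raise ValueError("need >= 2 subjects")
    mu = dirs.mu
    c = np.full((n, n), np.nan)
    v = dirs.valid
    sig = dirs.sigma
    for i in range(n):
        for j in range(i + 1, n):
            joint = v[i] & v[j]
            m = int(joint.sum())
            if m < min_joint_samples:
                logger.info("pair (%s,%s): %d joint samples < %d, dropped",
                            dirs.subject_ids[i], dirs.subject_ids[j],
                            m, min_joint_samples)
                continue
            cross = float((sig[i, joint] * sig[j, joint]).sum(axis=-1).mean())
            c[i, j] = c[j, i] = cross - float(mu[i] @ mu[j])
    if not np.isfinite(c[~np.eye(n, dtype=bool)]).any():
        raise ValueError("all pairs dropped: correlation matrix fully missing")
    return CorrelationSet(c, mu, list(dirs.subject_ids), c_x=c_x, c_y=c_y)


def homophily(ratings: np.ndarray, p_max: float = 10.0) -> float:
    """Pairwise rating-agreement statistic.

    O = 1/(N(N-1)) sum_i sum_{j!=i} [1 - |p_i - p_j|/p_max], the double sum
    running over ordered pairs.  Equals 1 for unanimous ratings; for N
    raters split evenly between 0 and p_max it equals (N-2)/(2(N-1)),
    approaching 1/2 for large N.
    """
    p = np.asarray(ratings, dtype=float)
    if p_max <= 0:
        raise ValueError("p_max must be positive")
    if p.size < 2:
        raise ValueError("homophily needs >= 2 raters")
    if np.any((p < 0) | (p > p_max)):
        raise ValueError("ratings outside [0, p_max]")
    n = p.size
    diff = np.abs(p[:, None] - p[None, :]) / p_max
    total = (1.0 - diff).sum() - n  # remove i == j terms (each contributes 1)
    return float(total / (n * (n - 1)))


def pearson_with_p(xs, ys) -> tuple[float, float, int]:
    """Pearson r with two-sided t-test p-value; non-finite pairs dropped."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ValueError("xs and ys must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)
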