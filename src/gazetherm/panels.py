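"""In-memory containers for multi-viewer gaze data.

A :class:`GazePanel` holds time-aligned horizontal/vertical gaze positions
(in screen pixels) for all retained viewers of one video segment, together
with a per-sample missing-data mask.  A :class:`DirectionPanel` holds the
corresponding unit direction-of-movement vectors sigma_i(t), with a validity
mask (directions are undefined during fixations and around missing samples).

Both containers are plain dataclasses over numpy arrays, shaped
``(n_subjects, n_samples[, 2])``, with subjects addressed by string ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GazePanel", "DirectionPanel", "read_gaze_csv", "write_gaze_csv"]


@dataclass
class GazePanel:
    """Gaze positions for N subjects on a uniform time grid.

    Attributes
    ----------
    times_ms : (n_samples,) float array, strictly increasing, uniform step.
    x, y : (n_subjects, n_samples) float arrays, screen pixels.
    missing : (n_subjects, n_samples) bool array, True where the tracker
        lost the eye (or preprocessing flagged the sample).
    subject_ids : list of str.
    """

    times_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    missing: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.x.shape != self.y.shape or self.x.shape != self.missing.shape:
            raise ValueError("x, y and missing must share shape")
        if self.x.ndim != 2:
            raise ValueError("expected (n_subjects, n_samples) arrays")
        if self.x.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids length does not match data")
        if self.x.shape[1] != self.times_ms.size:
            raise ValueError("times length does not match data")
        if self.times_ms.size >= 2:
            dt = np.diff(self.times_ms)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must lie on a uniform grid")

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]

    @property
    def n_samples(self) -> int:
        return self.x.shape[1]

    @property
    def sample_rate_hz(self) -> float:
        if self.times_ms.size < 2:
            raise ValueError("sample rate undefined for <2 samples")
        return 1000.0 / (self.times_ms[1] - self.times_ms[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def missing_fraction(self) -> np.ndarray:
        """Per-subject fraction of missing samples."""
        return self.missing.mean(axis=1)

    def copy(self) -> "GazePanel":
        return GazePanel(
            self.times_ms.copy(), self.x.copy(), self.y.copy(),
            self.missing.copy(), list(self.subject_ids),
        )

    def zero_filled(self) -> "GazePanel":
        """Compatibility variant with missing samples set to 0 px.

        Mirrors a pipeline convention of zeroing missing samples before
        analysis; the default elsewhere in this package is to exclude
        masked samples from time averages instead.
        """
        out = self.copy()
        out.x[out.missing] = 0.0
        out.y[out.missing] = 0.0
        return out

    def take_subjects(self, idx: np.ndarray | list[int]) -> "GazePanel":
        idx = np.asarray(idx, dtype=int)
        return GazePanel(
            self.times_ms.copy(), self.x[idx], self.y[idx],
            self.missing[idx], [self.subject_ids[i] for i in idx],
        )


@dataclass
class DirectionPanel:
    """Unit direction-of-movement vectors sigma_i(t) for N subjects.

    ``sigma`` has shape (n_subjects, n_samples, 2); entries are unit
    vectors where ``valid`` is True and zero elsewhere.  ``mu`` is the
    per-subject time-averaged direction vector over valid samples.
    """

    sigma: np.ndarray
    valid: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.sigma.ndim != 3 or self.sigma.shape[2] != 2:
            raise ValueError("sigma must be (n_subjects, n_samples, 2)")
        if self.valid.shape != self.sigma.shape[:2]:
            raise ValueError("valid mask shape mismatch")
        if len(self.subject_ids) != self.sigma.shape[0]:
            raise ValueError("subject_ids length does not match data")
        norms = np.linalg.norm(self.sigma[self.valid], axis=-1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("valid direction vectors must be unit length")

    @property
    def n_subjects(self) -> int:
        return self.sigma.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sigma.shape[1]

    @property
    def mu(self) -> np.ndarray:
        """Mean direction vector per subject, (n_subjects, 2).

        Averages sigma_i(t) over that subject's valid samples; |mu_i| <= 1.
        Subjects with no valid sample get mu = 0.
        """
        w = self.valid[..., None].astype(float)
        n = np.maximum(w.sum(axis=1), 1.0)
        return (self.sigma * w).sum(axis=1) / n

    def copy(self) -> "DirectionPanel":
        return DirectionPanel(self.sigma.copy(), self.valid.copy(),
                              list(self.subject_ids))

    def take_subjects(self, idx: np.ndarray | list[int]) -> "DirectionPanel":
        idx = np.asarray(idx, dtype=int)
        return DirectionPanel(self.sigma[idx], self.valid[idx],
                              [self.subject_ids[i] for i in idx])


def write_gaze_csv(panel: GazePanel, path: str | Path) -> None:
    """Write a panel in the long gaze-CSV dialect.

    Columns ``time_ms,subject,x_px,y_px``; one row per sample per subject;
    missing samples carry empty x/y fields.
    """
    n_subj, n_samp = panel.x.shape
    times = np.repeat(panel.times_ms, n_subj)
    subjects = np.tile(np.asarray(panel.subject_ids, dtype=object), n_samp)
    x = panel.x.T.reshape(-1).astype(object)
    y = panel.y.T.reshape(-1).astype(object)
    miss = panel.missing.T.reshape(-1)
    x[miss] = None
    y[miss] = None
    df = pd.DataFrame({"time_ms": times, "subject": subjects,
                       "x_px": x, "y_px": y})
    df.to_csv(path, index=False)


def read_gaze_csv(path: str | Path) -> GazePanel:
    """Read the long gaze-CSV dialect written by :func:`write_gaze_csv`."""
    df = pd.read_csv(path, dtype={"subject": str})
    required = {"time_ms", "subject", "x_px", "y_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"gaze CSV must have columns {sorted(required)}")
    times = np.sort(df["time_ms"].unique())
    subjects = sorted(df["subject"].unique())
    xs = df.pivot_table(index="subject", columns="time_ms", values="x_px",
                        dropna=False)
    ys = df.pivot_table(index="subject", columns="time_ms", values="y_px",
                        dropna=False)
    xs = xs.reindex(index=subjects, columns=times)
    ys = ys.reindex(index=subjects, columns=times)
    x = xs.to_numpy(dtype=float)
    y = ys.to_numpy(dtype=float)
    missing = ~(np.isfinite(x) & np.isfinite(y))
    x[missing] = 0.0
    y[missing] = 0.0
    return GazePanel(times, x, y, missing, list(subjects))
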