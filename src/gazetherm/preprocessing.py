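"""Cleaning and direction extraction for raw gaze recordings.

The chain mirrors standard eye-tracking practice for inter-subject
analyses: zero-phase triangular low-pass smoothing (80 ms window, which
also expands each missing sample's mask by 40 ms on either side), exclusion
of subjects missing more than 20% of a video, low-rank cross-subject
reconstruction of outliers and gaps, segmentation into 30-s increments,
and central-difference direction extraction

    v_i(t) = 0.5 * (r_i(t+1) - r_i(t-1)),   sigma_i(t) = v_i(t)/|v_i(t)|.

Samples with zero velocity (fixations) or a missing stencil get no
direction and are excluded from downstream time averages.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import binary_dilation

from .panels import DirectionPanel, GazePanel

__all__ = ["UnusableVideoError", "lowpass_triangular", "exclude_subjects",
           "interpolate_outliers", "segment", "to_directions",
           "flag_outliers"]

logger = logging.getLogger(__name__)

ZERO_VELOCITY_TOL = 1e-9  # px/sample below which a direction is undefined


class UnusableVideoError(ValueError):
    """The video cannot be analysed (all subjects excluded, or too short)."""


def _triangular_kernel(half_samples: int) -> np.ndarray:
    """Symmetric triangular kernel with ``half_samples`` taps per side,
    strictly positive, normalised to unit sum (so DC is preserved)."""
    ramp = np.arange(1, half_samples + 2, dtype=float)
    kern = np.concatenate([ramp, ramp[-2::-1]])
    return kern / kern.sum()


def lowpass_triangular(panel: GazePanel, window_ms: float = 80.0) -> GazePanel:
    """Zero-phase triangular smoothing of both gaze coordinates.

    The window spans ``window_ms`` in total, so each output sample mixes
    data up to window_ms/2 away; accordingly every missing sample also
    marks its neighbours within half a window as missing (80 ms -> +-40 ms,
    i.e. +-10 samples at 250 Hz).  Smoothing is mask-aware: missing samples
    carry zero weight, and the kernel is renormalised over the taps
    actually present.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    fs = panel.sample_rate_hz
    half = int(round(window_ms / 2.0 * fs / 1000.0))
    if 2 * half + 1 < 2 or half < 1:
        raise ValueError("window shorter than 2 samples at this rate")
    kern = _triangular_kernel(half)
    out = panel.copy()
    w = (~panel.missing).astype(float)
    for coord_in, coord_out in ((panel.x, out.x), (panel.y, out.y)):
        for s in range(panel.n_subjects):
            num = np.convolve(coord_in[s] * w[s], kern, mode="same")
            den = np.convolve(w[s], kern, mode="same")
            with np.errstate(invalid="ignore", divide="ignore"):
                coord_out[s] = np.where(den > 0, num / den, 0.0)
    # expand the mask by half a window on each side
    structure = np.ones(2 * half + 1, dtype=bool)
    for s in range(panel.n_subjects):
        out.missing[s] = binary_dilation(panel.missing[s],
                                         structure=structure)
    return out


def exclude_subjects(panel: GazePanel,
                     max_missing_fraction: float = 0.2) -> GazePanel:
    """Drop subjects with strictly more than the allowed missing fraction.

    Raises :class:`UnusableVideoError` if nobody survives.
    """
    frac = panel.missing_fraction()
    keep = np.flatnonzero(frac <= max_missing_fraction)
    dropped = np.flatnonzero(frac > max_missing_fraction)
    for i in dropped:
        logger.info("excluding subject %s: %.1f%% missing",
                    panel.subject_ids[i], 100 * frac[i])
    if keep.size == 0:
        raise UnusableVideoError("all subjects exceed the missing-data limit")
    return panel.take_subjects(keep)


def flag_outliers(panel: GazePanel, n_mads: float = 5.0) -> np.ndarray:
    """Per-subject robust outlier flags on either coordinate.

    A sample is an outlier if its x or y deviates from the subject's median
    by more than ``n_mads`` scaled median absolute deviations (artifact
    spikes, e.g. partial pupil occlusion).  Missing samples are ignored.
    """
    flags = np.zeros_like(panel.missing)
    for coord in (panel.x, panel.y):
        for s in range(panel.n_subjects):
            ok = ~panel.missing[s]
            if ok.sum() < 3:
                continue
            med = np.median(coord[s, ok])
            mad = np.median(np.abs(coord[s, ok] - med))
            scale = 1.4826 * mad
            if scale <= 0:
                continue
            flags[s] |= ok & (np.abs(coord[s] - med) > n_mads * scale)
    return flags


def interpolate_outliers(panel: GazePanel, rank: int = 3,
                         n_mads: float = 5.0, max_iter: int = 50,
                         tol: float = 1e-6) -> GazePanel:
    """Fill gaps and outliers with a low-rank cross-subject reconstruction.

    For each coordinate, the subjects-by-samples matrix is completed by
    iterated truncated SVD: bad entries (missing or outlying) start at the
    per-sample mean of the good subjects and are repeatedly replaced by the
    rank-``rank`` reconstruction until it stabilises.  Good entries are
    never altered.  The missing mask of originally-missing samples is
    retained so correlation estimates can still exclude them.
    """
    if panel.n_subjects < 2:
        raise ValueError("need >= 2 retained subjects")
    if rank >= panel.n_subjects:
        raise ValueError("rank must be < number of subjects")
    bad = panel.missing | flag_outliers(panel, n_mads)
    if np.any(bad.all(axis=1)):
        raise UnusableVideoError("a subject has no usable samples at all")
    out = panel.copy()
    if not bad.any():
        return out
    for coord in (out.x, out.y):
        m = coord.copy()
        good = ~bad
        col_mean = np.where(good.sum(axis=0) > 0,
                            (m * good).sum(axis=0) /
                            np.maximum(good.sum(axis=0), 1),
                            0.0)
        m[bad] = np.broadcast_to(col_mean, m.shape)[bad]
        prev = m[bad].copy()
        for _ in range(max_iter):
            u, s, vt = np.linalg.svd(m, full_matrices=False)
            recon = (u[:, :rank] * s[:rank]) @ vt[:rank]
            m[bad] = recon[bad]
            delta = np.abs(m[bad] - prev).max() if bad.any() else 0.0
            scale = max(np.abs(m).max(), 1.0)
            if delta <= tol * scale:
                break
            prev = m[bad].copy()
        coord[...] = m
    return out


def segment(panel: GazePanel, seconds: float = 30.0) -> list[GazePanel]:
    """Split into consecutive non-overlapping increments of ``seconds``.

    Boundaries are half-open in sample index; a trailing remainder shorter
    than one increment is dropped.  A panel shorter than one increment is
    rejected (such videos are skipped upstream).
    """
    if seconds <= 0:
        raise ValueError("segment length must be positive")
    per = int(round(seconds * panel.sample_rate_hz))
    n_seg = panel.n_samples // per
    if n_seg < 1:
        raise UnusableVideoError(
            f"panel shorter than one {seconds:.0f}-s segment")
    out = []
    for k in range(n_seg):
        sl = slice(k * per, (k + 1) * per)
        out.append(GazePanel(panel.times_ms[sl], panel.x[:, sl],
                             panel.y[:, sl], panel.missing[:, sl],
                             list(panel.subject_ids)))
    return out


def to_directions(panel: GazePanel,
                  zero_tol: float = ZERO_VELOCITY_TOL) -> DirectionPanel:
    """Central-difference movement directions sigma_i(t) = v_i(t)/|v_i(t)|.

    v_i(t) = 0.5 * (r_i(t+1) - r_i(t-1)).  A sample is invalid when any
    sample in its three-point stencil is missing, when it sits at the panel
    edge, or when the velocity magnitude is below ``zero_tol`` (fixation:
    the direction of zero motion is undefined).
    """
    if panel.n_samples < 3:
        raise ValueError("need >= 3 samples for central differences")
    r = np.stack([panel.x, panel.y], axis=-1)  # (N, T, 2)
    v = np.zeros_like(r)
    v[:, 1:-1] = 0.5 * (r[:, 2:] - r[:, :-2])
    speed = np.linalg.norm(v, axis=-1)
    ok = ~panel.missing
    stencil_ok = np.zeros_like(ok)
    stencil_ok[:, 1:-1] = ok[:, :-2] & ok[:, 1:-1] & ok[:, 2:]
    valid = stencil_ok & (speed > zero_tol)
    sigma = np.zeros_like(v)
    sigma[valid] = v[valid] / speed[valid, None]
    return DirectionPanel(sigma, valid, list(panel.subject_ids))
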