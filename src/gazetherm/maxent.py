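"""Maximum-entropy XY model of collective gaze direction.

The least-structured distribution over N unit direction vectors that
matches observed per-subject means mu_i and connected pairwise
correlations C_ij is the Boltzmann distribution of a fully-connected XY
model,

    P_T(s) ~ exp(-E(s)/T),    E = -sum_i h_i.s_i - sum_{i<j} J_ij s_i.s_j,

at operating temperature T = 1.  The couplings J_ij are the "interactions"
between viewers: similarity of movement uniquely shared by a pair, as
opposed to the raw correlation C_ij which also carries indirect paths.

Fitting is Monte-Carlo Boltzmann learning: sample the current model,
compare its moments with the data moments, and nudge J and h along the
moment mismatch until the model reproduces the data correlations with
Pearson fidelity >= the target (default 0.99).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._mc import MCOptions, pair_dot_matrix, run_metropolis
from .correlations import CorrelationSet
from .panels import DirectionPanel

__all__ = ["XYModel", "FitOptions", "FitReport", "ConvergenceError",
           "energy", "sample", "model_moments", "fit",
           "average_over_segments", "save_model", "load_model"]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Boltzmann learning diverged; carries the fidelity trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class XYModel:
    """Fully-connected XY model: couplings J (symmetric, zero diagonal),
    per-spin 2-vector fields h, and temperature T (> 0, operating value 1)."""

    J: np.ndarray
    h: np.ndarray
    temperature: float = 1.0
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        n = self.J.shape[0]
        if self.J.shape != (n, n):
            raise ValueError("J must be square")
        if not np.allclose(self.J, self.J.T, atol=1e-10):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0):
            raise ValueError("self-interactions J_ii must be zero")
        if self.h.shape != (n, 2):
            raise ValueError("h must be (N, 2)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.subject_ids is None:
            self.subject_ids = [f"s{i:02d}" for i in range(n)]

    @property
    def n_subjects(self) -> int:
        return self.J.shape[0]

    def scaled(self, alpha: float) -> "XYModel":
        """Model with all couplings and fields scaled by alpha."""
        return XYModel(alpha * self.J, alpha * self.h, self.temperature,
                       list(self.subject_ids))

    def mean_offdiag_coupling(self) -> float:
        off = ~np.eye(self.n_subjects, dtype=bool)
        return float(self.J[off].mean())


@dataclass
class FitOptions:
    """Boltzmann-learning schedule.

    Learning rate eta decays geometrically; the per-iteration Monte Carlo
    sample count grows from n_samples_start toward n_samples_max so late
    iterations see less moment noise.  Convergence is declared on an
    exponentially averaged model-moment estimate (ema_decay), then
    confirmed with a fresh validation sample of n_validation draws.
    """

    eta_j: float = 0.25
    eta_h: float = 0.25
    eta_decay: float = 0.997
    n_samples_start: int = 1000
    n_samples_max: int = 8000
    sample_growth: float = 1.01
    max_iterations: int = 600
    fidelity_target: float = 0.99
    ema_decay: float = 0.9
    n_validation: int = 30000
    thin_sweeps: int = 2
    burn_sweeps_warm: int = 30
    check_every: int = 10
    l2_penalty: float = 0.0


@dataclass
class FitReport:
    iterations: int
    fidelity: float
    mu_error: float
    converged: bool
    fidelity_trace: list[float] = field(default_factory=list)
    eta_trace: list[float] = field(default_factory=list)


def energy(model: XYModel, state: np.ndarray) -> float:
    """E = -sum_i h_i.s_i - sum_{i<j} J_ij s_i.s_j for one spin state."""
    s = np.asarray(state, dtype=float)
    if s.shape != (model.n_subjects, 2):
        raise ValueError("state must be (N, 2)")
    norms = np.linalg.norm(s, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("state vectors must be unit length")
    pair = 0.5 * float(np.einsum("ic,ij,jc->", s, model.J, s))
    return -float(np.einsum("ic,ic->", s, model.h)) - pair


def sample(model: XYModel, n_samples: int, seed: int,
           options: MCOptions | None = None) -> DirectionPanel:
    """Equilibrated, thinned Metropolis samples from the model's Boltzmann
    distribution, returned as an all-valid :class:`DirectionPanel`
    (subjects x samples x 2)."""
    draws, _, _ = run_metropolis(model.J, model.h, model.temperature,
                                 n_samples, seed, options)
    sigma = np.transpose(draws, (1, 0, 2))
    valid = np.ones(sigma.shape[:2], dtype=bool)
    return DirectionPanel(sigma, valid, list(model.subject_ids))


def model_moments(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mu, connected C_ij) from an (n_samples, N, 2) sample array."""
    mu = samples.mean(axis=0)
    c = pair_dot_matrix(samples) - mu @ mu.T
    np.fill_diagonal(c, 0.0)
    return mu, c


def _fidelity(c_model: np.ndarray, c_data: np.ndarray,
              mask: np.ndarray) -> float:
    a = c_model[mask]
    b = c_data[mask]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit(targets: CorrelationSet, seed: int,
        options: FitOptions | None = None) -> tuple[XYModel, FitReport]:
    """Infer (J, h) by Monte-Carlo Boltzmann learning at T = 1.

    Iterates  J_ij += eta * (C_ij^data - C_ij^model),
              h_i  += eta * (mu_i^data - mu_i^model),
    with model moments estimated from warm-started Metropolis sampling.
    Stops when the Pearson fidelity between model and data C_ij reaches
    ``fidelity_target``, or after ``max_iterations``.  Pairs whose target
    C_ij is missing (NaN) are excluded from updates and their J frozen at 0.

    Raises :class:`ConvergenceError` if the fidelity trace collapses
    persistently (learning diverged), with the trace attached.
    """
    opts = options or FitOptions()
    n = targets.n_subjects
    c_data = targets.c_pairwise.copy()
    mu_data = np.asarray(targets.mu, dtype=float)
    if not np.all(np.isfinite(mu_data)) or np.any(
            np.linalg.norm(mu_data, axis=1) > 1 + 1e-9):
        raise ValueError("target means must be finite with |mu_i| <= 1")
    off = ~np.eye(n, dtype=bool)
    upper = np.triu(off)
    pair_ok = np.isfinite(c_data) & off
    mask = upper & pair_ok
    if not mask.any():
        raise ValueError("no finite target correlations")
    c_data_f = np.where(pair_ok, c_data, 0.0)

    J = np.zeros((n, n))
    h = np.zeros((n, 2))
    theta = None
    eta = opts.eta_j
    eta_h = opts.eta_h
    c_ema = None
    mu_ema = None
    trace: list[float] = []
    etas: list[float] = []
    mc = MCOptions(burn_sweeps=opts.burn_sweeps_warm,
                   thin_sweeps=opts.thin_sweeps, adapt=True)
    n_mc = float(opts.n_samples_start)
    best = -np.inf
    converged = False
    iterations = 0
    for it in range(opts.max_iterations):
        iterations = it + 1
        draws, theta, _ = run_metropolis(
            J, h, 1.0, int(n_mc), seed + 7919 * it, mc, theta0=theta)
        mu_m, c_m = model_moments(draws)
        if c_ema is None:
            c_ema, mu_ema = c_m, mu_m
        else:
            d = opts.ema_decay
            c_ema = d * c_ema + (1 - d) * c_m
            mu_ema = d * mu_ema + (1 - d) * mu_m
        grad = np.where(pair_ok, c_data_f - c_m, 0.0)
        grad = 0.5 * (grad + grad.T)
        J = J + eta * grad - eta * opts.l2_penalty * J
        np.fill_diagonal(J, 0.0)
        J[~pair_ok] = 0.0
        np.fill_diagonal(J, 0.0)
        h = h + eta_h * (mu_data - mu_m)
        eta *= opts.eta_decay
        eta_h *= opts.eta_decay
        n_mc = min(n_mc * opts.sample_growth, opts.n_samples_max)
        r = _fidelity(c_ema, c_data_f, mask)
        trace.append(r)
        etas.append(eta)
        best = max(best, r)
        if len(trace) >= 60 and best > 0.2 and trace[-1] < best - 0.5 \
                and all(t < best - 0.4 for t in trace[-20:]):
            raise ConvergenceError(
                f"fidelity collapsed from {best:.3f} to {trace[-1]:.3f}",
                trace)
        if (it + 1) % opts.check_every == 0 and r >= opts.fidelity_target:
            # confirm with a fresh, larger validation sample; keep
            # learning if the EMA estimate was optimistic noise
            draws, theta, _ = run_metropolis(
                J, h, 1.0, opts.n_validation, seed + 104729 + it, mc,
                theta0=theta)
            mu_v, c_v = model_moments(draws)
            if _fidelity(c_v, c_data_f, mask) >= opts.fidelity_target:
                converged = True
                break
    else:
        draws, _, _ = run_metropolis(J, h, 1.0, opts.n_validation,
                                     seed + 104729, mc, theta0=theta)
        mu_v, c_v = model_moments(draws)
    fidelity = _fidelity(c_v, c_data_f, mask)
    mu_err = float(np.abs(mu_v - mu_data).mean())
    converged = converged and fidelity >= opts.fidelity_target
    model = XYModel(J, h, 1.0, list(targets.subject_ids))
    report = FitReport(iterations, fidelity, mu_err, converged, trace, etas)
    logger.info("fit: %d iterations, fidelity %.4f, mu error %.4f",
                iterations, fidelity, mu_err)
    return model, report


def average_over_segments(
    models: list[XYModel],
    scans: list | None = None,
) -> tuple[XYModel, dict[str, float]]:
    """Per-video aggregation: element-wise mean of J and h over the 30-s
    segments (restricted to subjects retained in every segment), and the
    mean of each scan's critical temperature.

    Returns the averaged model and a dict of averaged scalars
    (``t_c`` and ``t_c_eigen`` when scans are given).
    """
    if not models:
        raise ValueError("empty model list")
    common = set(models[0].subject_ids)
    for m in models[1:]:
        common &= set(m.subject_ids)
    if not common:
        raise ValueError("no common subjects across segments")
    ids = [s for s in models[0].subject_ids if s in common]
    js, hs = [], []
    for m in models:
        idx = [m.subject_ids.index(s) for s in ids]
        js.append(m.J[np.ix_(idx, idx)])
        hs.append(m.h[idx])
    j_avg = np.mean(js, axis=0)
    j_avg = 0.5 * (j_avg + j_avg.T)
    np.fill_diagonal(j_avg, 0.0)
    model = XYModel(j_avg, np.mean(hs, axis=0), models[0].temperature, ids)
    scalars: dict[str, float] = {}
    if scans:
        tcs = [s.t_c for s in scans if s.t_c is not None and np.isfinite(s.t_c)]
        scalars["t_c"] = float(np.mean(tcs)) if tcs else float("nan")
    return model, scalars


def save_model(model: XYModel, j_path, h_path=None) -> None:
    """Plain-text serialisation: tab-separated square J with a header of
    subject ids; optional fields table ``subject\th_x\th_y``."""
    import pandas as pd
    pd.DataFrame(model.J, index=model.subject_ids,
                 columns=model.subject_ids).to_csv(j_path, sep="\t")
    if h_path is not None:
        pd.DataFrame({"subject": model.subject_ids,
                      "h_x": model.h[:, 0], "h_y": model.h[:, 1]}
                     ).to_csv(h_path, sep="\t", index=False)


def load_model(j_path, h_path=None, temperature: float = 1.0) -> XYModel:
    import pandas as pd
    jdf = pd.read_csv(j_path, sep="\t", index_col=0)
    ids = [str(c) for c in jdf.columns]
    J = jdf.to_numpy(dtype=float)
    J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 0.0)
    if h_path is not None:
        hdf = pd.read_csv(h_path, sep="\t")
        h = hdf[["h_x", "h_y"]].to_numpy(dtype=float)
    else:
        h = np.zeros((J.shape[0], 2))
    return XYModel(J, h, temperature, ids)
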