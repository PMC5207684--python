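"""Metropolis Monte Carlo kernel for the fully-connected XY model.

Single-site Metropolis updates: a sweep proposes, for each spin in turn,
a rotation of its angle by a uniform perturbation; the proposal width is
adapted during burn-in toward ~50% acceptance.  Samples are taken every
``thin_sweeps`` sweeps after ``burn_sweeps`` of equilibration, so that
successive returned states are approximately independent.

The hot loop is numba-compiled; everything returned is plain numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["MCOptions", "run_metropolis", "pair_dot_matrix", "energies"]


@dataclass
class MCOptions:
    """Knobs of the Metropolis sampler.

    burn_sweeps: equilibration sweeps before the first sample; ``None``
        auto-selects 100 * n_subjects.
    thin_sweeps: sweeps between consecutive retained samples.
    step: initial half-width of the uniform angle proposal (radians);
        adapted during burn-in when ``adapt`` is True.
    """

    burn_sweeps: int | None = None
    thin_sweeps: int = 10
    step: float = 1.0
    adapt: bool = True

    def resolved_burn(self, n_spins: int) -> int:
        return 100 * n_spins if self.burn_sweeps is None else self.burn_sweeps


@njit(cache=False)
def _mc_kernel(J, hx, hy, T, n_samples, burn_sweeps, thin_sweeps,
               step0, adapt, seed, theta0):  # pragma: no cover - numba
    np.random.seed(seed)
    n = J.shape[0]
    theta = theta0.copy()
    cos_t = np.cos(theta)
    sin_t = np.sin(theta)
    out = np.empty((n_samples, n, 2))
    step = step0
    accepted = 0
    proposed = 0
    # burn-in with step adaptation toward 50% acceptance
    for sweep in range(burn_sweeps):
        for i in range(n):
            lx = hx[i]
            ly = hy[i]
            for j in range(n):
                lx += J[i, j] * cos_t[j]
                ly += J[i, j] * sin_t[j]
            new = theta[i] + step * (2.0 * np.random.random() - 1.0)
            cn = np.cos(new)
            sn = np.sin(new)
            dE = -(lx * (cn - cos_t[i]) + ly * (sn - sin_t[i]))
            proposed += 1
            if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                theta[i] = new
                cos_t[i] = cn
                sin_t[i] = sn
                accepted += 1
        if adapt and (sweep + 1) % 20 == 0 and proposed > 0:
            rate = accepted / proposed
            if rate > 0.55:
                step = min(step * 1.15, np.pi)
            elif rate < 0.45:
                step = max(step * 0.87, 0.02)
            accepted = 0
            proposed = 0
    # sampling phase, fixed step
    accepted = 0
    proposed = 0
    for s in range(n_samples):
        for _ in range(thin_sweeps):
            for i in range(n):
                lx = hx[i]
                ly = hy[i]
                for j in range(n):
                    lx += J[i, j] * cos_t[j]
                    ly += J[i, j] * sin_t[j]
                new = theta[i] + step * (2.0 * np.random.random() - 1.0)
                cn = np.cos(new)
                sn = np.sin(new)
                dE = -(lx * (cn - cos_t[i]) + ly * (sn - sin_t[i]))
                proposed += 1
                if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                    theta[i] = new
                    cos_t[i] = cn
                    sin_t[i] = sn
                    accepted += 1
        for i in range(n):
            out[s, i, 0] = cos_t[i]
            out[s, i, 1] = sin_t[i]
    rate = accepted / proposed if proposed > 0 else 0.0
    return out, theta, rate, step


def run_metropolis(
    J: np.ndarray,
    h: np.ndarray,
    temperature: float,
    n_samples: int,
    seed: int,
    options: MCOptions | None = None,
    theta0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Draw thinned equilibrium samples from P(s) ~ exp(-E(s)/T).

    Parameters
    ----------
    J : (N, N) symmetric coupling matrix, zero diagonal.
    h : (N, 2) external field vectors.
    temperature : positive scalar T.
    n_samples : number of retained (thinned) states.
    seed : RNG seed (also seeds the random initial angles if theta0 is None).
    theta0 : optional warm-start angles, e.g. the final state of a previous
        call at nearby parameters; cuts the needed burn-in drastically.

    Returns
    -------
    samples : (n_samples, N, 2) unit vectors.
    theta_final : (N,) final chain angles, for warm-starting.
    acceptance : acceptance rate during the sampling phase.
    """
    J = np.ascontiguousarray(J, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    n = J.shape[0]
    if J.shape != (n, n):
        raise ValueError("J must be square")
    if not np.allclose(J, J.T, atol=1e-12):
        raise ValueError("J must be symmetric")
    if not np.allclose(np.diag(J), 0.0):
        raise ValueError("J must have zero diagonal")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if h.shape != (n, 2):
        raise ValueError("h must be (N, 2)")
    opts = options or MCOptions()
    seed = int(seed) % (2**31 - 1)
    if theta0 is None:
        rng = np.random.default_rng(seed)
        theta0 = rng.uniform(0.0, 2.0 * np.pi, size=n)
        burn = opts.resolved_burn(n)
    else:
        theta0 = np.asarray(theta0, dtype=np.float64).copy()
        burn = opts.burn_sweeps if opts.burn_sweeps is not None else 20
    samples, theta, rate, _ = _mc_kernel(
        J, np.ascontiguousarray(h[:, 0]), np.ascontiguousarray(h[:, 1]),
        float(temperature), int(n_samples), int(burn), int(opts.thin_sweeps),
        float(opts.step), bool(opts.adapt), seed, theta0,
    )
    return samples, theta, rate


def pair_dot_matrix(samples: np.ndarray) -> np.ndarray:
    """Sample average of sigma_i . sigma_j, shape (N, N), unit diagonal."""
    return np.einsum("sic,sjc->ij", samples, samples) / samples.shape[0]


def energies(samples: np.ndarray, J: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Energy of each sampled state: E = -sum_i h_i.s_i - sum_{i<j} J_ij s_i.s_j."""
    pair = 0.5 * np.einsum("sic,ij,sjc->s", samples, J, samples)
    fld = np.einsum("sic,ic->s", samples, h)
    return -fld - pair
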