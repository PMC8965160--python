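"""Markov state model estimation and MSM-weighted thermodynamics.

The estimator follows the plain maximum-likelihood row normalization
T_ij = C_ij / sum_j C_ij on the largest strongly connected component of the
transition-count graph.  The stationary distribution pi (leading left
eigenvector of T) supplies state populations; free energies follow as
G_i = -k_B T ln pi_i.  Equilibrium expectations over the raw (adaptively
sampled, hence biased) frames are recovered by weighting each frame with
pi_state / n_frames_in_state, which is what the weighted landscapes and
conditional probabilities below use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._util import DEFAULT_TEMPERATURE, KB_KCAL_PER_MOL_K

__all__ = [
    "CountMatrix",
    "MarkovStateModel",
    "FreeEnergySurface",
    "stationary_distribution",
    "count_transitions",
    "estimate_msm",
    "implied_timescales",
    "free_energy_of_states",
    "frame_weights",
    "weighted_landscape",
    "conditional_probability",
]


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalized to 1.

    Raises if the eigenvalue closest to 1 is not 1 within tolerance (the
    matrix is not stochastic) or the eigenvector has a significant imaginary
    part.
    """
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    if abs(vals[idx] - 1.0) > 1e-8:
        raise ValueError("matrix has no eigenvalue 1; not row-stochastic?")
    v = vecs[:, idx]
    if np.max(np.abs(v.imag)) > 1e-10 * max(1.0, np.max(np.abs(v.real))):
        raise ValueError("stationary eigenvector is not real")
    v = v.real
    if v.sum() < 0:
        v = -v
    pi = np.clip(v, 0.0, None)
    s = pi.sum()
    if s <= 0:
        raise ValueError("degenerate stationary eigenvector")
    return pi / s


@dataclass
class CountMatrix:
    """Transition counts at a fixed lag."""

    C: np.ndarray
    lag: int
    counting_mode: str = "sliding"

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C)
        if np.any(self.C < 0) or not np.issubdtype(self.C.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.counting_mode not in ("sliding", "strided"):
            raise ValueError("counting_mode must be 'sliding' or 'strided'")

    @property
    def n_states(self) -> int:
        return self.C.shape[0]


def count_transitions(
    dtrajs: Sequence[np.ndarray],
    lag: int,
    mode: str = "sliding",
    n_states: int | None = None,
) -> CountMatrix:
    """Count (state at t, state at t+lag) pairs, never crossing trajectory
    boundaries.

    ``sliding`` counts every t; ``strided`` counts only t = 0, lag, 2*lag...
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    if not dtrajs or all(len(d) <= lag for d in dtrajs):
        raise ValueError(f"no trajectory longer than lag={lag}")
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs)) + 1
    C = np.zeros((n_states, n_states), dtype=np.int64)
    for d in dtrajs:
        if len(d) <= lag:
            continue
        if mode == "sliding":
            a, b = d[:-lag], d[lag:]
        elif mode == "strided":
            sub = d[::lag]
            a, b = sub[:-1], sub[1:]
        else:
            raise ValueError("mode must be 'sliding' or 'strided'")
        np.add.at(C, (a, b), 1)
    return CountMatrix(C=C, lag=lag, counting_mode=mode)


@dataclass
class MarkovStateModel:
    """Row-stochastic transition matrix over the active (ergodic) state set.

    ``active_set`` maps internal indices 0..m-1 back to the original
    discrete-state labels; states outside it carry zero weight everywhere.
    """

    T: np.ndarray
    pi: np.ndarray
    active_set: np.ndarray
    lag: int
    frame_dt: float = 1.0
    C: CountMatrix | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.active_set = np.asarray(self.active_set, dtype=int)
        if len(np.unique(self.active_set)) != len(self.active_set):
            raise ValueError("active_set indices must be unique")
        assert np.allclose(self.T.sum(axis=1), 1.0, atol=1e-12), "rows must sum to 1"
        assert np.all(self.pi >= 0) and abs(self.pi.sum() - 1.0) < 1e-10
        assert np.max(np.abs(self.pi @ self.T - self.pi)) < 1e-10, "pi not stationary"

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def lag_time_ns(self) -> float:
        return self.lag * self.frame_dt

    def to_active(self, original_states: Sequence[int]) -> np.ndarray:
        """Map original labels to internal indices (-1 if outside)."""
        n_full = int(self.active_set.max()) + 1
        lut = np.full(max(n_full, int(np.max(original_states)) + 1), -1, dtype=int)
        lut[self.active_set] = np.arange(len(self.active_set))
        return lut[np.asarray(original_states, dtype=int)]

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        vals = np.linalg.eigvals(self.T)
        order = np.argsort(-np.abs(vals))
        vals = vals[order]
        return vals if k is None else vals[:k]

    def timescales(self, n_timescales: int | None = None) -> np.ndarray:
        """Implied timescales in ns for eigenvalues below 1 (see
        :func:`implied_timescales` for conventions)."""
        vals = self.eigenvalues()[1:]
        if n_timescales is not None:
            vals = vals[:n_timescales]
        ts = np.full(len(vals), np.nan)
        for i, lam in enumerate(vals):
            ts[i] = _timescale_from_eigenvalue(lam, self.lag * self.frame_dt)
        return ts


def _timescale_from_eigenvalue(lam: complex, lag_time: float) -> float:
    if abs(lam.imag) > 1e-10:
        return np.nan  # complex process: undefined
    lam = lam.real
    if lam <= 0:
        return np.nan
    if lam >= 1.0 - 1e-15:
        return np.inf
    return -lag_time / np.log(lam)


def estimate_msm(C: CountMatrix, frame_dt: float = 1.0) -> MarkovStateModel:
    """Row-normalize counts on the largest strongly connected component.

    The active set is the largest SCC of the directed graph with an edge
    i -> j wherever C_ij > 0 (largest by state count, ties by frame count).
    """
    A = C.C
    n_comp, labels = connected_components(csr_matrix(A > 0), connection="strong")
    sizes = np.bincount(labels, minlength=n_comp)
    weights = np.bincount(labels, weights=A.sum(axis=1), minlength=n_comp)
    best = max(range(n_comp), key=lambda c: (sizes[c], weights[c]))
    active = np.flatnonzero(labels == best)
    if active.size == 0:
        raise ValueError("empty active set")
    sub = A[np.ix_(active, active)].astype(float)
    rowsums = sub.sum(axis=1)
    assert np.all(rowsums > 0), "zero row inside an SCC is impossible"
    T = sub / rowsums[:, None]
    pi = stationary_distribution(T)
    return MarkovStateModel(T=T, pi=pi, active_set=active, lag=C.lag, frame_dt=frame_dt, C=C)


def implied_timescales(
    dtrajs: Sequence[np.ndarray],
    lags: Sequence[int],
    n_timescales: int = 3,
    frame_dt: float = 1.0,
    mode: str = "sliding",
) -> pd.DataFrame:
    """Relaxation times t_i = -tau / ln(lambda_i) as a function of lag.

    The lag at which the slow timescales stop drifting (on a log scale) is
    the usual Markovianity diagnostic.  Complex or non-positive eigenvalues
    yield NaN; eigenvalues at 1 beyond the stationary process yield +inf.
    Returns a tidy table (lag_frames, lag_ns, process, eigenvalue,
    timescale_frames, timescale_ns).
    """
    rows = []
    for lag in lags:
        msm = estimate_msm(count_transitions(dtrajs, lag, mode=mode), frame_dt=frame_dt)
        vals = msm.eigenvalues()[1 : n_timescales + 1]
        for k, lam in enumerate(vals, start=2):
            t_frames = _timescale_from_eigenvalue(lam, float(lag))
            rows.append(
                {
                    "lag_frames": lag,
                    "lag_ns": lag * frame_dt,
                    "process": k,
                    "eigenvalue": lam.real if abs(lam.imag) <= 1e-10 else np.nan,
                    "timescale_frames": t_frames,
                    "timescale_ns": t_frames * frame_dt,
                }
            )
    return pd.DataFrame(rows)


def free_energy_of_states(
    pi: np.ndarray, temperature: float = DEFAULT_TEMPERATURE
) -> np.ndarray:
    """G_i = -k_B T ln(pi_i) in kcal/mol, shifted so the minimum is 0.

    States with pi_i = 0 are masked (NaN) rather than -inf-propagated.
    """
    pi = np.asarray(pi, dtype=float)
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    G = np.full(pi.shape, np.nan)
    pos = pi > 0
    G[pos] = -KB_KCAL_PER_MOL_K * temperature * np.log(pi[pos])
    if pos.any():
        G -= np.nanmin(G)
    return G


def frame_weights(
    msm: MarkovStateModel, assignments: Sequence[np.ndarray]
) -> list[np.ndarray]:
    """Equilibrium weight of every frame: pi_state / n_frames_in_state.

    Frames assigned to states outside the active set get weight 0.  Weights
    over all frames sum to 1 (up to states with frames absent from the
    provided assignments).
    """
    assignments = [np.asarray(a, dtype=int) for a in assignments]
    all_states = np.concatenate(assignments)
    n_full = max(int(all_states.max()), int(msm.active_set.max())) + 1
    counts = np.bincount(all_states, minlength=n_full)
    w_per_state = np.zeros(n_full)
    have = counts[msm.active_set] > 0
    w_per_state[msm.active_set[have]] = msm.pi[have] / counts[msm.active_set[have]]
    return [w_per_state[a] for a in assignments]


@dataclass
class FreeEnergySurface:
    """Binned free-energy landscape; 1-D profile when y_edges is None."""

    x_edges: np.ndarray
    G: np.ndarray
    y_edges: np.ndarray | None = None
    mask: np.ndarray | None = None
    temperature: float = DEFAULT_TEMPERATURE
    x_label: str = "x"
    y_label: str | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = ~np.isfinite(self.G)
        finite = self.G[~self.mask]
        if finite.size:
            assert abs(np.min(finite)) < 1e-9, "minimum must be shifted to 0"

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray | None:
        if self.y_edges is None:
            return None
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        if self.y_edges is None:
            return pd.DataFrame({self.x_label: self.x_centers, "G_kcal_mol": self.G})
        xg, yg = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return pd.DataFrame(
            {
                self.x_label: xg.ravel(),
                self.y_label or "y": yg.ravel(),
                "G_kcal_mol": self.G.ravel(),
            }
        )


def _gather_observable(trajs, obs) -> np.ndarray:
    if callable(obs):
        return np.concatenate([np.asarray(obs(t), dtype=float) for t in trajs])
    return np.concatenate([t.column(obs) for t in trajs])


def weighted_landscape(
    msm: MarkovStateModel,
    assignments: Sequence[np.ndarray],
    trajs: Sequence,
    obs_x: str,
    obs_y: str | None = None,
    bins: int | tuple[int, int] = 60,
    temperature: float = DEFAULT_TEMPERATURE,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> FreeEnergySurface:
    """MSM-weighted free-energy landscape over one or two observables.

    Each frame contributes its equilibrium weight pi_state / n_frames_in_state
    to its observable bin; bin free energies are
    G = -k_B T ln(w_bin / max_bin w), so the global minimum sits at 0 and
    empty bins are masked.
    """
    weights = np.concatenate(frame_weights(msm, assignments))
    x = _gather_observable(trajs, obs_x)
    if x.shape[0] != weights.shape[0]:
        raise ValueError("assignments do not align with trajectory frames")
    kT = KB_KCAL_PER_MOL_K * temperature
    if obs_y is None:
        hist, x_edges = np.histogram(x, bins=bins, range=x_range, weights=weights)
        G = np.full(hist.shape, np.nan)
        nz = hist > 0
        G[nz] = -kT * np.log(hist[nz] / hist.max())
        return FreeEnergySurface(
            x_edges=x_edges, G=G, temperature=temperature,
            x_label=obs_x if isinstance(obs_x, str) else "x",
        )
    y = _gather_observable(trajs, obs_y)
    rng = None if x_range is None and y_range is None else (x_range, y_range)
    hist, x_edges, y_edges = np.histogram2d(x, y, bins=bins, range=rng, weights=weights)
    G = np.full(hist.shape, np.nan)
    nz = hist > 0
    G[nz] = -kT * np.log(hist[nz] / hist.max())
    return FreeEnergySurface(
        x_edges=x_edges, y_edges=y_edges, G=G, temperature=temperature,
        x_label=obs_x if isinstance(obs_x, str) else "x",
        y_label=obs_y if isinstance(obs_y, str) else "y",
    )


def conditional_probability(
    msm: MarkovStateModel,
    assignments: Sequence[np.ndarray],
    trajs: Sequence,
    condition: Callable,
    outcome: Callable,
) -> float:
    """Equilibrium conditional probability P(outcome | condition).

    ``condition`` and ``outcome`` are per-trajectory frame predicates
    (callables mapping a trajectory to a boolean frame mask).  The
    probability is the ratio of MSM frame weights
    W(condition and outcome) / W(condition).
    """
    weights = np.concatenate(frame_weights(msm, assignments))
    cond = np.concatenate([np.asarray(condition(t), dtype=bool) for t in trajs])
    out = np.concatenate([np.asarray(outcome(t), dtype=bool) for t in trajs])
    if cond.shape[0] != weights.shape[0]:
        raise ValueError("predicates do not align with trajectory frames")
    w_cond = weights[cond].sum()
    if w_cond <= 0:
        raise ValueError("condition has zero equilibrium weight")
    return float(weights[cond & out].sum() / w_cond)
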