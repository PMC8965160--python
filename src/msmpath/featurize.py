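"""Slow-coordinate extraction (TICA), k-means discretization, VAMP2 scoring.

TICA solves the generalized eigenproblem  C_tau v = lambda C_0 v  with the
symmetrized time-lagged covariance C_tau and the (ridge-regularized)
instantaneous covariance C_0 after mean removal; eigenvectors ordered by
descending eigenvalue are the time-lagged independent components and the
squared eigenvalues measure kinetic variance.  VAMP2 scores a candidate
discretization by the summed squared singular values of the half-weighted
propagator estimated from the discrete trajectories; the stationary process
contributes 1, so the score of a useless discretization tends to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

__all__ = [
    "TicaModel",
    "Discretization",
    "fit_tica",
    "kmeans_discretize",
    "vamp2_score",
    "vamp2_cv_score",
    "select_hyperparameters",
]


def _traj_matrix(traj) -> np.ndarray:
    return traj.X if hasattr(traj, "X") else np.atleast_2d(np.asarray(traj, float))


@dataclass
class TicaModel:
    """Fitted TICA transform.

    ``components`` holds all generalized eigenvectors (F × F, orthonormal
    under the C_0 metric); ``n_retained`` is the smallest number of leading
    components whose cumulative squared eigenvalues reach the requested
    kinetic-variance fraction.
    """

    lag: int
    mean: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray
    kinetic_variance_fraction: float
    n_retained: int

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.eigenvalues) <= 1e-12), "eigenvalues must descend"

    def transform(self, X) -> np.ndarray:
        """Project onto the retained components."""
        X = _traj_matrix(X)
        return (X - self.mean) @ self.components[:, : self.n_retained]

    def transform_all(self, trajs: Sequence) -> list[np.ndarray]:
        return [self.transform(t) for t in trajs]


def fit_tica(
    trajs: Sequence,
    lag: int,
    variance_fraction: float = 0.95,
    epsilon: float = 1e-8,
) -> TicaModel:
    """Fit TICA on a list of trajectories (feature trajectories or arrays).

    Uses the symmetrized lagged-covariance estimator
    C_tau = (X0' Xt + Xt' X0) / 2N, which guarantees a real spectrum on
    finite data, and ridge-regularizes C_0 by epsilon * trace(C_0)/F on the
    diagonal so constant or collinear features are handled (with a warning
    when the regularization is actually load-bearing).
    """
    mats = [_traj_matrix(t) for t in trajs]
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if any(m.shape[0] <= lag for m in mats):
        raise ValueError("lag must be shorter than every trajectory")
    F = mats[0].shape[1]
    if F < 2:
        raise ValueError("TICA needs at least 2 features")
    n_pairs = sum(m.shape[0] - lag for m in mats)
    mean = sum(m[:-lag].sum(axis=0) + m[lag:].sum(axis=0) for m in mats) / (2 * n_pairs)
    C0 = np.zeros((F, F))
    Ct = np.zeros((F, F))
    for m in mats:
        a = m[:-lag] - mean
        b = m[lag:] - mean
        C0 += a.T @ a + b.T @ b
        Ct += a.T @ b
    C0 /= 2 * n_pairs
    Ct = (Ct + Ct.T) / (2 * n_pairs)
    ridge = epsilon * np.trace(C0) / F
    if np.linalg.cond(C0) > 1e10:
        warnings.warn(
            "instantaneous covariance is near-singular; ridge regularization applied",
            stacklevel=2,
        )
    C0_reg = C0 + ridge * np.eye(F)
    vals, vecs = scipy.linalg.eigh(Ct, C0_reg)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    kinvar = np.cumsum(vals**2) / np.sum(vals**2)
    n_retained = int(np.searchsorted(kinvar, variance_fraction - 1e-12) + 1)
    n_retained = min(n_retained, F)
    if variance_fraction >= 1.0:
        n_retained = F
    return TicaModel(
        lag=lag,
        mean=mean,
        eigenvalues=vals,
        components=vecs,
        kinetic_variance_fraction=variance_fraction,
        n_retained=n_retained,
    )


@dataclass
class Discretization:
    """k-means centers plus per-trajectory state assignments."""

    centers: np.ndarray
    assignments: list[np.ndarray]
    K: int
    seed: int

    def __post_init__(self) -> None:
        self.assignments = [np.asarray(a, dtype=int) for a in self.assignments]

    @property
    def n_frames(self) -> int:
        return sum(len(a) for a in self.assignments)

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Nearest-center (Euclidean) assignment of new frames."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def kmeans_discretize(
    trajs: Sequence,
    K: int,
    seed: int = 0,
    max_iter: int = 300,
    n_init: int = 10,
) -> Discretization:
    """Seeded k-means++ (best of ``n_init`` restarts) over all frames.

    Assignments are recomputed as exact nearest-center labels on the final
    centers so the stored discretization satisfies the Voronoi invariant.
    """
    mats = [_traj_matrix(t) for t in trajs]
    if not mats:
        raise ValueError("empty input")
    X = np.vstack(mats)
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds total frames {X.shape[0]}")
    km = KMeans(
        n_clusters=K, init="k-means++", n_init=n_init, max_iter=max_iter,
        random_state=seed,
    ).fit(X)
    centers = km.cluster_centers_
    disc = Discretization(centers=centers, assignments=[], K=K, seed=seed)
    disc.assignments = [disc.assign(m) for m in mats]
    return disc


def _split_counts(
    dtrajs: Sequence[np.ndarray], lag: int, n_states: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    C00 = np.zeros(n_states)
    Ctt = np.zeros(n_states)
    C0t = np.zeros((n_states, n_states))
    for d in dtrajs:
        d = np.asarray(d, dtype=int)
        if len(d) <= lag:
            continue
        a, b = d[:-lag], d[lag:]
        np.add.at(C0t, (a, b), 1.0)
        C00 += np.bincount(a, minlength=n_states)
        Ctt += np.bincount(b, minlength=n_states)
    return C00, C0t, Ctt


def vamp2_score(
    disc: Discretization | Sequence[np.ndarray],
    lag: int,
    n_processes: int = 10,
    dtrajs_test: Sequence[np.ndarray] | None = None,
) -> float:
    """VAMP2 score of a discretization at a lag.

    Estimates the half-weighted propagator K = C00^{-1/2} C0t Ctt^{-1/2}
    from indicator functions of the discrete states and returns the sum of
    its top ``n_processes`` squared singular values.  If the count graph is
    disconnected the score is computed on the largest connected set with a
    warning.  When ``dtrajs_test`` is given, counts come from the test
    trajectories (states unseen in them are dropped), which is the
    cross-validation path.
    """
    if isinstance(disc, Discretization):
        dtrajs = disc.assignments
        n_states = disc.K
    else:
        dtrajs = [np.asarray(d, dtype=int) for d in disc]
        n_states = int(max(d.max() for d in dtrajs)) + 1
    if dtrajs_test is not None:
        dtrajs = [np.asarray(d, dtype=int) for d in dtrajs_test]
    C00, C0t, Ctt = _split_counts(dtrajs, lag, n_states)
    keep = (C00 > 0) & (Ctt > 0)
    if keep.sum() < n_states:
        if keep.sum() == 0:
            raise ValueError("no populated states at this lag")
        C0t = C0t[np.ix_(keep, keep)]
        C00, Ctt = C00[keep], Ctt[keep]
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(
        csr_matrix((C0t + C0t.T) > 0), connection="weak"
    )
    if n_comp > 1:
        warnings.warn(
            "disconnected discretization; scoring the largest connected set",
            stacklevel=2,
        )
        sizes = np.bincount(labels)
        sel = labels == sizes.argmax()
        C0t = C0t[np.ix_(sel, sel)]
        C00, Ctt = C00[sel], Ctt[sel]
    N = C0t.sum()
    K = (C0t / N) / np.sqrt(C00 / C00.sum())[:, None] / np.sqrt(Ctt / Ctt.sum())[None, :]
    sv = scipy.linalg.svdvals(K)
    top = np.sort(sv)[::-1][: min(n_processes, len(sv))]
    return float(np.sum(top**2))


def vamp2_cv_score(
    trajs: Sequence,
    K: int,
    lag: int,
    n_processes: int = 5,
    n_splits: int = 2,
    seed: int = 0,
) -> float:
    """Trajectory-split cross-validated VAMP2 score.

    Trajectories are shuffled under the seed and split into ``n_splits``
    folds; for each fold, k-means is fitted on the remaining trajectories,
    the held-out trajectories are assigned to those centers, and the VAMP2
    score is computed on the held-out counts.  Returns the fold mean.
    """
    mats = [_traj_matrix(t) for t in trajs]
    if len(mats) < n_splits:
        raise ValueError("need at least n_splits trajectories")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = rng.permutation(len(mats))
    folds = np.array_split(order, n_splits)
    scores = []
    for f, test_idx in enumerate(folds):
        train = [mats[i] for i in order if i not in set(test_idx)]
        test = [mats[i] for i in test_idx]
        disc = kmeans_discretize(train, K=K, seed=seed + f, n_init=3)
        test_d = [disc.assign(m) for m in test]
        scores.append(
            vamp2_score(disc, lag=lag, n_processes=n_processes, dtrajs_test=test_d)
        )
    return float(np.mean(scores))


def select_hyperparameters(
    trajs: Sequence,
    lag: int,
    k_grid: Sequence[int] = (50, 100, 200, 400),
    variance_grid: Sequence[float] = (0.5, 0.65, 0.8, 0.95),
    tica_lag: int | None = None,
    n_processes: int = 4,
    plateau_fraction: float = 0.95,
    seed: int = 0,
) -> dict:
    """Grid search (K, TICA variance fraction) by cross-validated VAMP2.

    The CV score creeps upward with K even past the point where the slow
    processes are resolved, so plain argmax over-fragments the state space.
    Selection therefore uses a parsimony (plateau) rule: the smallest K
    (then the smallest variance fraction) whose score reaches
    ``plateau_fraction`` of the grid maximum.  Returns the selected point,
    the argmax point, and the full score table.
    """
    tica_lag = tica_lag or lag
    rows = []
    for vf in variance_grid:
        tica = fit_tica(trajs, lag=tica_lag, variance_fraction=vf)
        transformed = tica.transform_all(trajs)
        for K in k_grid:
            try:
                score = vamp2_cv_score(
                    transformed, K=K, lag=lag, n_processes=n_processes, seed=seed
                )
            except ValueError:
                continue
            rows.append({"K": K, "variance_fraction": vf, "vamp2_cv": score})
    if not rows:
        raise ValueError("no scorable grid point")
    argmax = max(rows, key=lambda r: r["vamp2_cv"])
    cutoff = plateau_fraction * argmax["vamp2_cv"]
    eligible = [r for r in rows if r["vamp2_cv"] >= cutoff]
    best = min(eligible, key=lambda r: (r["K"], r["variance_fraction"]))
    return {"best": best, "argmax": argmax, "grid": rows}
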