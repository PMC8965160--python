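"""Macrostates, transition-path-theory kinetics, and kinetic Monte Carlo.

Committors are obtained from the linear system q_i = sum_j T_ij q_j with
boundary conditions q=0 on the source and q=1 on the sink.  The reactive
flux is F_AB = sum_{i in A} sum_{j not in A} pi_i T_ij q_j+ and the mean
first-passage time is MFPT = tau * pi_A / F_AB (tau = MSM lag time).  The
docs note that other TPT conventions normalize the flux by sum_i pi_i q_i-
instead; the two agree for two-state systems.

All state arguments and results here use ORIGINAL discrete-state labels;
mapping onto the MSM active set happens internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .msm import MarkovStateModel

__all__ = [
    "MacrostateSet",
    "TPTResult",
    "KmcTrajectory",
    "define_macrostate",
    "committor",
    "backward_committor",
    "tpt",
    "reactive_flux",
    "mfpt",
    "kmc_run",
    "stitch_frames",
    "first_passage_times",
    "empirical_committor",
]


@dataclass(frozen=True)
class MacrostateSet:
    """A named group of MSM states with a record of how it was selected."""

    name: str
    states: frozenset[int]
    definition: str = ""

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("macrostate must contain at least one state")


def define_macrostate(
    msm: MarkovStateModel,
    region: Callable[[np.ndarray], bool],
    state_descriptors: np.ndarray,
    n_top: int = 5,
    name: str = "macrostate",
) -> MacrostateSet:
    """Select the ``n_top`` states by raw frame count inside a region.

    ``state_descriptors`` holds one row per original discrete state (e.g.
    cluster centers in observable coordinates); ``region`` is a predicate
    over such a row.  Among active states whose descriptor satisfies the
    region, the ``n_top`` with the highest raw transition-count row sums are
    kept (ties broken by lower state index).  If fewer than ``n_top``
    qualify, all are taken with a warning.
    """
    if msm.C is None:
        raise ValueError("MSM carries no count matrix; raw counts unavailable")
    raw = msm.C.C.sum(axis=1)
    qualifying = [
        int(s) for s in msm.active_set if region(np.asarray(state_descriptors[s]))
    ]
    if not qualifying:
        raise ValueError("region selects no active state")
    if len(qualifying) < n_top:
        warnings.warn(
            f"region contains only {len(qualifying)} states (< n_top={n_top}); "
            "taking all of them",
            stacklevel=2,
        )
    # sort by (count desc, index asc); python sort is stable
    ranked = sorted(qualifying, key=lambda s: (-raw[s], s))[:n_top]
    return MacrostateSet(
        name=name,
        states=frozenset(ranked),
        definition=f"top {n_top} states by raw count inside user region",
    )


def _as_state_set(states) -> frozenset[int]:
    if isinstance(states, MacrostateSet):
        return states.states
    return frozenset(int(s) for s in states)


def _active_indices(msm: MarkovStateModel, states: frozenset[int]) -> np.ndarray:
    idx = msm.to_active(sorted(states))
    if np.any(idx < 0):
        missing = [s for s, i in zip(sorted(states), idx) if i < 0]
        raise ValueError(f"states {missing} are outside the MSM active set")
    return idx


def _committor_solve(
    T: np.ndarray, source_idx: np.ndarray, sink_idx: np.ndarray
) -> np.ndarray:
    """Forward committor on internal indices via the interior linear system."""
    n = T.shape[0]
    src = np.zeros(n, dtype=bool)
    src[source_idx] = True
    snk = np.zeros(n, dtype=bool)
    snk[sink_idx] = True
    if np.any(src & snk):
        raise ValueError("source and sink must be disjoint")
    interior = ~(src | snk)
    q = np.zeros(n)
    q[snk] = 1.0
    if interior.any():
        # states that cannot reach the sink make the interior system singular
        reach = _reaches(T, snk)
        bad = np.flatnonzero(interior & ~reach)
        if bad.size:
            raise ValueError(
                f"sink unreachable from states {bad.tolist()}; committor undefined"
            )
        Tii = T[np.ix_(interior, interior)]
        b = T[np.ix_(interior, np.flatnonzero(snk))].sum(axis=1)
        q[interior] = np.linalg.solve(np.eye(Tii.shape[0]) - Tii, b)
    return np.clip(q, 0.0, 1.0)


def _reaches(T: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Boolean mask of states from which any target state is reachable."""
    adj = T > 0
    reach = targets.copy()
    while True:
        new = reach | adj[:, reach].any(axis=1)
        if np.array_equal(new, reach):
            return reach
        reach = new


def committor(
    msm: MarkovStateModel | np.ndarray,
    source,
    sink,
    frame_dt: float = 1.0,
) -> np.ndarray:
    """Forward committor q+ : probability of reaching the sink macrostate
    before the source macrostate, per state.

    Accepts an estimated MSM (original state labels, values returned over
    the active set in internal order) or a bare transition matrix.
    """
    src, snk = _as_state_set(source), _as_state_set(sink)
    if not src or not snk:
        raise ValueError("source and sink must be non-empty")
    if isinstance(msm, MarkovStateModel):
        T = msm.T
        si = _active_indices(msm, src)
        ki = _active_indices(msm, snk)
    else:
        T = np.asarray(msm, dtype=float)
        si = np.asarray(sorted(src), dtype=int)
        ki = np.asarray(sorted(snk), dtype=int)
    return _committor_solve(T, si, ki)


def backward_committor(
    msm: MarkovStateModel | np.ndarray,
    source,
    sink,
    pi: np.ndarray | None = None,
) -> np.ndarray:
    """Backward committor q-: probability the system last came from the
    source, computed as the forward committor toward the source on the
    time-reversed chain T~_ij = pi_j T_ji / pi_i.
    """
    if isinstance(msm, MarkovStateModel):
        T, pi_ = msm.T, msm.pi
        si = _active_indices(msm, _as_state_set(source))
        ki = _active_indices(msm, _as_state_set(sink))
    else:
        T = np.asarray(msm, dtype=float)
        from .msm import stationary_distribution

        pi_ = stationary_distribution(T) if pi is None else np.asarray(pi, float)
        si = np.asarray(sorted(_as_state_set(source)), dtype=int)
        ki = np.asarray(sorted(_as_state_set(sink)), dtype=int)
    T_rev = (pi_[None, :] * T.T) / pi_[:, None]
    # q-: reach source before sink under reversed dynamics
    return _committor_solve(T_rev, ki, si)


@dataclass
class TPTResult:
    """Committors, reactive flux and MFPT between two macrostates."""

    source: MacrostateSet
    sink: MacrostateSet
    q_plus: np.ndarray
    q_minus: np.ndarray
    flux_per_lag: float
    mfpt_frames: float
    mfpt_ns: float
    lag: int
    frame_dt: float

    def __post_init__(self) -> None:
        assert self.flux_per_lag >= 0
        assert np.all((self.q_plus >= 0) & (self.q_plus <= 1))

    def to_dict(self) -> dict:
        return {
            "source": sorted(self.source.states),
            "sink": sorted(self.sink.states),
            "q_plus": self.q_plus.tolist(),
            "q_minus": self.q_minus.tolist(),
            "flux_per_lag": self.flux_per_lag,
            "mfpt_frames": self.mfpt_frames,
            "mfpt_ns": self.mfpt_ns,
            "lag_frames": self.lag,
            "frame_dt_ns": self.frame_dt,
        }


def _flux_from_parts(
    T: np.ndarray, pi: np.ndarray, src_idx: np.ndarray, q_plus: np.ndarray
) -> float:
    in_A = np.zeros(T.shape[0], dtype=bool)
    in_A[src_idx] = True
    F = float(np.sum(pi[in_A, None] * T[in_A][:, ~in_A] * q_plus[None, ~in_A]))
    return max(F, 0.0)


def tpt(msm: MarkovStateModel, source, sink) -> TPTResult:
    """Full transition-path-theory summary between two macrostates."""
    src, snk = _as_state_set(source), _as_state_set(sink)
    si = _active_indices(msm, src)
    ki = _active_indices(msm, snk)
    q_plus = _committor_solve(msm.T, si, ki)
    T_rev = (msm.pi[None, :] * msm.T.T) / msm.pi[:, None]
    q_minus = _committor_solve(T_rev, ki, si)
    F = _flux_from_parts(msm.T, msm.pi, si, q_plus)
    pi_A = float(msm.pi[si].sum())
    if F <= 0:
        raise ValueError("zero reactive flux; MFPT undefined")
    mfpt_lags = pi_A / F
    src_ms = source if isinstance(source, MacrostateSet) else MacrostateSet("A", src)
    snk_ms = sink if isinstance(sink, MacrostateSet) else MacrostateSet("B", snk)
    return TPTResult(
        source=src_ms,
        sink=snk_ms,
        q_plus=q_plus,
        q_minus=q_minus,
        flux_per_lag=F,
        mfpt_frames=mfpt_lags * msm.lag,
        mfpt_ns=mfpt_lags * msm.lag * msm.frame_dt,
        lag=msm.lag,
        frame_dt=msm.frame_dt,
    )


def reactive_flux(msm: MarkovStateModel, source, sink) -> float:
    """Reactive flux F_AB = sum_{i in A, j not in A} pi_i T_ij q_j+ per lag."""
    src = _as_state_set(source)
    si = _active_indices(msm, src)
    ki = _active_indices(msm, _as_state_set(sink))
    q_plus = _committor_solve(msm.T, si, ki)
    return _flux_from_parts(msm.T, msm.pi, si, q_plus)


def mfpt(msm: MarkovStateModel, source, sink) -> tuple[float, float]:
    """Mean first-passage time MFPT = tau * pi_A / F_AB.

    Returns (frames, ns).
    """
    src = _as_state_set(source)
    si = _active_indices(msm, src)
    F = reactive_flux(msm, source, sink)
    if F <= 0:
        raise ValueError("zero reactive flux; MFPT undefined")
    pi_A = float(msm.pi[si].sum())
    frames = msm.lag * pi_A / F
    return frames, frames * msm.frame_dt


# ---------------------------------------------------------------------------
# kinetic Monte Carlo
# ---------------------------------------------------------------------------


@dataclass
class KmcTrajectory:
    """A state-hopping trajectory; each step advances time by the MSM lag."""

    states: np.ndarray
    step_time_ns: float
    seed: int
    frames: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(len(self.states)) * self.step_time_ns


def _cumulative_rows(T: np.ndarray) -> np.ndarray:
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    return cum


def kmc_run(
    msm: MarkovStateModel, start_state: int, n_steps: int, seed: int = 0
) -> KmcTrajectory:
    """Kinetic Monte Carlo on the MSM transition matrix.

    At each step a uniform R in [0,1) is drawn and the chain jumps to the
    state j whose cumulative-probability interval [s_{i,j-1}, s_{i,j})
    contains R (s_{i,-1} = 0).  Each step advances time by lag * frame_dt.
    States in the returned trajectory carry original labels.
    """
    internal = msm.to_active([start_state])[0]
    if internal < 0:
        raise ValueError(f"start_state {start_state} is outside the active set")
    cum = _cumulative_rows(msm.T)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    u = rng.random(n_steps)
    path = np.empty(n_steps + 1, dtype=int)
    path[0] = internal
    s = int(internal)
    for t in range(n_steps):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        path[t + 1] = s
    return KmcTrajectory(
        states=msm.active_set[path],
        step_time_ns=msm.lag * msm.frame_dt,
        seed=seed,
    )


def stitch_frames(
    kmc: KmcTrajectory,
    assignments: Sequence[np.ndarray],
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Attach one uniformly drawn (trajectory index, frame index) reference
    per kMC step from the visited state's frame pool."""
    pools: dict[int, list[tuple[int, int]]] = {}
    for ti, a in enumerate(assignments):
        for fi, s in enumerate(np.asarray(a, dtype=int)):
            pools.setdefault(int(s), []).append((ti, fi))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    refs: list[tuple[int, int]] = []
    for s in kmc.states:
        pool = pools.get(int(s))
        if not pool:
            raise ValueError(f"visited state {s} has no assigned frames")
        refs.append(pool[int(rng.integers(len(pool)))])
    kmc.frames = refs
    return refs


# ---------------------------------------------------------------------------
# Monte-Carlo oracles (ensembles of walkers, vectorized)
# ---------------------------------------------------------------------------


def _resolve_T(model) -> tuple[np.ndarray, Callable[[Sequence[int]], np.ndarray]]:
    if isinstance(model, MarkovStateModel):
        return model.T, lambda s: model.to_active(s)
    T = np.asarray(model, dtype=float)
    return T, lambda s: np.asarray(s, dtype=int)


def first_passage_times(
    model: MarkovStateModel | np.ndarray,
    start_state: int,
    targets,
    n_runs: int,
    seed: int = 0,
    max_steps: int = 10_000_000,
) -> np.ndarray:
    """First-passage step counts of ``n_runs`` independent kMC walkers from
    ``start_state`` to the target set (in lag units).

    Walkers are advanced in lockstep with vectorized jumps; raises if any
    walker survives ``max_steps``.
    """
    T, mapper = _resolve_T(model)
    tgt = np.zeros(T.shape[0], dtype=bool)
    tgt[mapper(sorted(_as_state_set(targets)))] = True
    s0 = int(mapper([start_state])[0])
    cum = _cumulative_rows(T)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    states = np.full(n_runs, s0, dtype=int)
    times = np.zeros(n_runs, dtype=np.int64)
    alive = ~tgt[states]
    step = 0
    while alive.any():
        step += 1
        if step > max_steps:
            raise RuntimeError(f"{alive.sum()} walkers not absorbed in {max_steps} steps")
        u = rng.random(alive.sum())
        cur = cum[states[alive]]
        states[alive] = (u[:, None] < cur).argmax(axis=1)
        hit = tgt[states[alive]]
        idx = np.flatnonzero(alive)
        times[idx[hit]] = step
        alive[idx[hit]] = False
    return times


def empirical_committor(
    model: MarkovStateModel | np.ndarray,
    source,
    sink,
    n_runs: int = 10_000,
    seed: int = 0,
    max_steps: int = 10_000_000,
) -> np.ndarray:
    """Hit-fraction committor estimate: from every state, the fraction of
    kMC walkers reaching the sink before the source."""
    T, mapper = _resolve_T(model)
    n = T.shape[0]
    src = np.zeros(n, dtype=bool)
    src[mapper(sorted(_as_state_set(source)))] = True
    snk = np.zeros(n, dtype=bool)
    snk[mapper(sorted(_as_state_set(sink)))] = True
    cum = _cumulative_rows(T)
    master = np.random.SeedSequence(seed)
    q = np.zeros(n)
    q[snk] = 1.0
    for i, child in enumerate(master.spawn(n)):
        if src[i] or snk[i]:
            continue
        rng = np.random.default_rng(child)
        states = np.full(n_runs, i, dtype=int)
        hit_sink = np.zeros(n_runs, dtype=bool)
        alive = np.ones(n_runs, dtype=bool)
        step = 0
        while alive.any():
            step += 1
            if step > max_steps:
                raise RuntimeError("walkers not absorbed")
            u = rng.random(alive.sum())
            cur = cum[states[alive]]
            states[alive] = (u[:, None] < cur).argmax(axis=1)
            idx = np.flatnonzero(alive)
            absorbed = src[states[idx]] | snk[states[idx]]
            hit_sink[idx[absorbed]] = snk[states[idx[absorbed]]]
            alive[idx[absorbed]] = False
        q[i] = hit_sink.mean()
    return q
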