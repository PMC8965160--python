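"""Bootstrap uncertainty for thermodynamic and kinetic pipeline statistics.

Each round draws N = round(fraction * n_trajs) trajectories (with
replacement by default, without in subsample mode), keeps the original
discretization labels fixed, re-estimates the MSM on the drawn set, and
evaluates the requested statistic.  Defaults follow the 200-round / 80%
protocol.  Rounds whose resampled active set breaks a statistic's
preconditions (disconnected source/sink, zero-weight condition ...) are
recorded as failures, not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .msm import (
    conditional_probability,
    count_transitions,
    estimate_msm,
    free_energy_of_states,
)

__all__ = ["BootstrapResult", "bootstrap_statistic", "STATISTICS"]


def _embed(values: np.ndarray, active_set: np.ndarray, n_full: int, fill=np.nan):
    out = np.full(n_full, fill, dtype=float)
    out[active_set] = values
    return out


def _stat_state_free_energy(msm, trajs, assignments, sel, *, temperature=300.0, **_):
    n_full = msm.C.n_states
    return _embed(free_energy_of_states(msm.pi, temperature), msm.active_set, n_full)


def _stat_stationary_distribution(msm, trajs, assignments, sel, **_):
    return _embed(msm.pi, msm.active_set, msm.C.n_states, fill=0.0)


def _stat_conditional_probability(
    msm, trajs, assignments, sel, *, condition, outcome, **_
):
    return conditional_probability(
        msm, [assignments[i] for i in sel], [trajs[i] for i in sel], condition, outcome
    )


def _stat_mfpt(msm, trajs, assignments, sel, *, source, sink, **_):
    from .kinetics import mfpt

    return mfpt(msm, source, sink)[1]  # ns


def _stat_flux(msm, trajs, assignments, sel, *, source, sink, **_):
    from .kinetics import reactive_flux

    return reactive_flux(msm, source, sink)


def _stat_landscape_bin(
    msm, trajs, assignments, sel, *, obs_x, bins, x_range, bin_index,
    temperature=300.0, **_,
):
    from .msm import weighted_landscape

    surf = weighted_landscape(
        msm, [assignments[i] for i in sel], [trajs[i] for i in sel],
        obs_x=obs_x, bins=bins, x_range=x_range, temperature=temperature,
    )
    return float(surf.G[bin_index])


#: Registered pipeline statistics available to :func:`bootstrap_statistic`.
STATISTICS: dict[str, Callable] = {
    "state_free_energy": _stat_state_free_energy,
    "stationary_distribution": _stat_stationary_distribution,
    "conditional_probability": _stat_conditional_probability,
    "mfpt": _stat_mfpt,
    "reactive_flux": _stat_flux,
    "landscape_bin_free_energy": _stat_landscape_bin,
}


@dataclass
class BootstrapResult:
    statistic_name: str
    samples: np.ndarray  # (n_success,) or (n_success, dim)
    mean: np.ndarray | float
    stdev: np.ndarray | float
    n_rounds: int
    n_failures: int
    fraction: float
    mode: str
    seed: int
    failure_log: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "mean": np.asarray(self.mean).tolist(),
            "stdev": np.asarray(self.stdev).tolist(),
            "n_success": int(self.n_rounds - self.n_failures),
            "n_fail": int(self.n_failures),
            "n_rounds": self.n_rounds,
            "fraction": self.fraction,
            "mode": self.mode,
            "seed": self.seed,
        }


def bootstrap_statistic(
    trajs: Sequence,
    assignments: Sequence[np.ndarray],
    statistic: str | Callable,
    lag: int,
    statistic_kwargs: dict | None = None,
    n_rounds: int = 200,
    fraction: float = 0.8,
    mode: str = "resample",
    counting_mode: str = "sliding",
    frame_dt: float = 1.0,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap a registered pipeline statistic over trajectories.

    Per-trajectory transition counts are precomputed once (state labels stay
    fixed across rounds); each round sums the counts of the drawn
    trajectories, re-estimates the MSM, and evaluates the statistic.
    """
    if len(trajs) < 2:
        raise ValueError("need at least 2 trajectories to bootstrap")
    if mode not in ("resample", "subsample"):
        raise ValueError("mode must be 'resample' or 'subsample'")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if callable(statistic):
        stat_fn, stat_name = statistic, getattr(statistic, "__name__", "custom")
    else:
        try:
            stat_fn = STATISTICS[statistic]
        except KeyError as err:
            raise ValueError(
                f"unknown statistic {statistic!r}; choose from {sorted(STATISTICS)}"
            ) from err
        stat_name = statistic
    kwargs = dict(statistic_kwargs or {})
    assignments = [np.asarray(a, dtype=int) for a in assignments]
    n_states = int(max(a.max() for a in assignments)) + 1
    per_traj_counts = []
    for a in assignments:
        if len(a) > lag:
            per_traj_counts.append(
                count_transitions([a], lag, mode=counting_mode, n_states=n_states).C
            )
        else:
            per_traj_counts.append(np.zeros((n_states, n_states), dtype=np.int64))
    per_traj_counts = np.stack(per_traj_counts)

    n_trajs = len(trajs)
    n_draw = max(1, round(fraction * n_trajs))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples: list = []
    failures: list[str] = []
    from .msm import CountMatrix

    for rnd in range(n_rounds):
        if mode == "resample":
            sel = rng.integers(n_trajs, size=n_draw)
        else:
            sel = rng.choice(n_trajs, size=n_draw, replace=False)
        C = per_traj_counts[sel].sum(axis=0)
        try:
            cm = CountMatrix(C=C, lag=lag, counting_mode=counting_mode)
            msm = estimate_msm(cm, frame_dt=frame_dt)
            samples.append(stat_fn(msm, trajs, assignments, sel, **kwargs))
        except (ValueError, RuntimeError) as err:
            failures.append(f"round {rnd}: {err}")
    if not samples:
        raise RuntimeError(
            "all bootstrap rounds failed; first failures: " + "; ".join(failures[:5])
        )
    arr = np.asarray(samples, dtype=float)
    mean = np.nanmean(arr, axis=0)
    stdev = np.nanstd(arr, axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros_like(mean)
    return BootstrapResult(
        statistic_name=stat_name,
        samples=arr,
        mean=mean if mean.ndim else float(mean),
        stdev=stdev if np.ndim(stdev) else float(stdev),
        n_rounds=n_rounds,
        n_failures=len(failures),
        fraction=fraction,
        mode=mode,
        seed=seed,
        failure_log=failures,
    )
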