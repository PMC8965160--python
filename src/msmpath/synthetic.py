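"""Synthetic ground-truth systems and trajectory generators.

Every downstream stage of the pipeline (TICA, clustering, MSM estimation,
transition-path theory, ensemble comparison) is exercised on data drawn from
the hidden Markov chains built here, so recovery can be checked against a
known answer.  The generative model is deliberately simple: a metastable
chain over a small number of hidden states, each state emitting features
from a diagonal-covariance Gaussian.  Scenario presets emulate the phenome-
nology of a ligand-binding study on a G-protein-coupled receptor: a
multi-basin landscape along a binding-distance coordinate (unbound → entry →
two antagonist-like poses → agonist-like pose), a ligand chain dihedral whose
sign distinguishes the two agonist-like sub-states, a toggle-switch-like
angle coupled to the bound pose, and a TM3–TM6-like intracellular distance
that opens partially on activation.

Units: distances in Å, angles in degrees, time in ns per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._util import (
    DEFAULT_TEMPERATURE,
    KB_KCAL_PER_MOL_K,
    spawn_rngs,
    wrap_degrees,
)

__all__ = [
    "GroundTruthSystem",
    "FeatureTrajectory",
    "DihedralEnsemble",
    "build_ground_truth_chain",
    "sample_chain_trajectory",
    "run_adaptive_sampling",
    "generate_dihedral_ensembles",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthSystem:
    """A hidden metastable chain with Gaussian feature emissions.

    Attributes
    ----------
    T_true
        Row-stochastic ``(n_states, n_states)`` transition matrix of the
        hidden chain at one frame of lag.
    pi_true
        Stationary distribution of ``T_true`` (left fixed point).
    emission_means, emission_stdevs
        ``(n_states, F)`` per-state Gaussian emission parameters; distances
        in Å, angles in degrees.
    macrostate_labels
        Named groups of hidden states (e.g. ``"unbound"``, ``"antagonist"``).
    frame_dt
        Time per frame in ns.
    metadata
        Scenario bookkeeping (configured basin gap, grid, preset name ...).
    """

    n_states: int
    T_true: np.ndarray
    pi_true: np.ndarray
    emission_means: np.ndarray
    emission_stdevs: np.ndarray
    feature_names: list[str]
    macrostate_labels: dict[str, frozenset[int]]
    frame_dt: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.T_true = np.asarray(self.T_true, dtype=float)
        self.pi_true = np.asarray(self.pi_true, dtype=float)
        self.emission_means = np.atleast_2d(np.asarray(self.emission_means, dtype=float))
        self.emission_stdevs = np.atleast_2d(np.asarray(self.emission_stdevs, dtype=float))
        n = self.n_states
        if self.T_true.shape != (n, n):
            raise ValueError(f"T_true must be {n}x{n}, got {self.T_true.shape}")
        rows = self.T_true.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("T_true rows must sum to 1 within 1e-12")
        if np.any(self.T_true < 0):
            raise ValueError("T_true entries must be non-negative")
        resid = np.max(np.abs(self.pi_true @ self.T_true - self.pi_true))
        if resid >= 1e-10:
            raise ValueError(f"pi_true is not a left fixed point of T_true (resid={resid:.2e})")
        if np.any(self.emission_stdevs <= 0):
            raise ValueError("emission_stdevs must be strictly positive")
        if len(self.feature_names) != self.emission_means.shape[1]:
            raise ValueError("feature_names length must match emission columns")
        seen: set[int] = set()
        for name, states in self.macrostate_labels.items():
            states = frozenset(states)
            if seen & states:
                raise ValueError(f"macrostate {name!r} overlaps another macrostate")
            seen |= states
            self.macrostate_labels[name] = states

    @property
    def n_features(self) -> int:
        return self.emission_means.shape[1]

    def free_energies(self, temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
        """True per-state free energies G_i = -k_B T ln pi_i, min-shifted to 0."""
        g = -KB_KCAL_PER_MOL_K * temperature * np.log(self.pi_true)
        return g - g.min()


@dataclass
class FeatureTrajectory:
    """One trajectory: a frames × features matrix with names and frame time."""

    trajectory_id: str
    frame_dt: float
    X: np.ndarray
    feature_names: list[str]
    hidden_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("trajectory contains non-finite values")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must equal number of columns")
        if self.hidden_states is not None:
            self.hidden_states = np.asarray(self.hidden_states, dtype=int)
            if self.hidden_states.shape[0] != self.X.shape[0]:
                raise ValueError("hidden_states must align with frames")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError as err:
            raise KeyError(f"unknown feature {name!r}") from err
        return self.X[:, j]


@dataclass
class DihedralEnsemble:
    """Per-residue dihedral time series plus a residue contact map.

    ``planted_path`` is the ground-truth coupling chain: each residue along
    it is a wrapped-noisy copy of its predecessor, so mutual information
    decays along the chain and vanishes off it.
    """

    n_residues: int
    D: np.ndarray
    contact_distances: np.ndarray
    planted_path: list[int]
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.contact_distances = np.asarray(self.contact_distances, dtype=float)
        if self.D.shape[1] != self.n_residues:
            raise ValueError("D must have n_residues columns")
        if np.any(self.D < -180.0) or np.any(self.D >= 180.0):
            raise ValueError("angles must lie in [-180, 180)")
        cd = self.contact_distances
        if cd.shape != (self.n_residues, self.n_residues):
            raise ValueError("contact_distances must be n_residues x n_residues")
        if not np.allclose(cd, cd.T) or np.any(np.diag(cd) != 0):
            raise ValueError("contact_distances must be symmetric with zero diagonal")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _two_state(escape: float = 0.1) -> dict:
    p = float(escape)
    if not 0 < p < 1:
        raise ValueError("escape probability must be in (0, 1)")
    T = np.array([[1 - p, p], [p, 1 - p]])
    return dict(
        T_true=T,
        emission_means=[[-1.0], [1.0]],
        emission_stdevs=[[0.2], [0.2]],
        feature_names=["x"],
        macrostate_labels={"A": frozenset({0}), "B": frozenset({1})},
        metadata={"preset": "two_state", "escape": p},
    )


def _double_well_1d(
    gap: float = 1.0,
    barrier: float = 2.2,
    temperature: float = DEFAULT_TEMPERATURE,
    n_bins: int = 17,
) -> dict:
    """Discretized 1-D double-well sampled by a Metropolis birth-death chain.

    The potential is the lower envelope of two parabolas whose minima sit on
    grid points, so the two basin minima differ by exactly ``gap`` kcal/mol
    (construction identity).  The Metropolis rule makes the Boltzmann weights
    of that potential the exact stationary law of the chain.  The default
    barrier and grid resolution are set so that a 500k-frame trajectory
    makes several hundred independent well-to-well crossings, which puts the
    statistical error of a recovered basin gap near 0.03 kcal/mol.
    """
    if gap < 0 or barrier <= gap:
        raise ValueError("need 0 <= gap < barrier")
    x = np.linspace(2.0, 10.0, n_bins)
    i1, i2 = n_bins // 4, 3 * n_bins // 4
    mu1, mu2 = x[i1], x[i2]
    k = barrier / ((mu2 - mu1) / 2.0) ** 2
    G = np.minimum(k * (x - mu1) ** 2, k * (x - mu2) ** 2 + gap)
    kT = KB_KCAL_PER_MOL_K * temperature
    w = np.exp(-G / kT)
    pi = w / w.sum()
    n = n_bins
    T = np.zeros((n, n))
    for i in range(n):
        for j in (i - 1, i + 1):
            if 0 <= j < n:
                T[i, j] = 0.5 * min(1.0, w[j] / w[i])
        T[i, i] = 1.0 - T[i].sum()
    sigma = 0.4 * (x[1] - x[0])
    return dict(
        T_true=T,
        pi_true=pi,
        emission_means=x[:, None],
        emission_stdevs=np.full((n, 1), sigma),
        feature_names=["binding_distance"],
        macrostate_labels={"well_1": frozenset({i1}), "well_2": frozenset({i2})},
        metadata={
            "preset": "double_well_1d",
            "basin_gap": float(gap),
            "barrier": float(barrier),
            "temperature": float(temperature),
            "grid": x,
            "true_G": G,
            "minima_indices": (int(i1), int(i2)),
            "minima_positions": (float(mu1), float(mu2)),
        },
    )


# Exchange rates set so the slowest relaxation is ~26 frames: metastable
# enough that the basins are real, fast enough that a 10^6-step trajectory
# holds tens of thousands of independent samples.
_BINDING_T = np.array(
    [
        # unbound  entry  antag1 antag2 ago+   ago-
        [0.900, 0.100, 0.000, 0.000, 0.000, 0.000],
        [0.080, 0.800, 0.120, 0.000, 0.000, 0.000],
        [0.000, 0.060, 0.840, 0.080, 0.020, 0.000],
        [0.000, 0.000, 0.080, 0.820, 0.080, 0.020],
        [0.000, 0.000, 0.020, 0.040, 0.900, 0.040],
        [0.000, 0.000, 0.000, 0.020, 0.080, 0.900],
    ]
)


def _binding_landscape() -> dict:
    """Six-state binding landscape: unbound → entry → antagonist-like pose
    1 ↔ pose 2 → agonist-like pose with positive/negative chain dihedral.

    Features: ligand binding distance (Å), ligand chain dihedral (deg),
    toggle-switch χ2-like angle (deg), TM3–TM6-like intracellular distance
    (Å).  Basin means loosely follow the axes of the binding study's
    landscapes; the exact numbers are configuration, not claims.
    """
    means = np.array(
        [
            [25.0, 0.0, 90.0, 7.5],    # unbound, toggle inactive
            [21.0, 0.0, 90.0, 7.5],    # pocket entry
            [17.5, -70.0, 90.0, 7.5],  # antagonist-like pose 1
            [14.5, 70.0, 90.0, 7.5],   # antagonist-like pose 2
            [11.0, 75.0, 0.0, 9.5],    # agonist-like, dihedral +
            [11.0, -75.0, -90.0, 9.0], # agonist-like, dihedral -
        ]
    )
    stdevs = np.array(
        [
            [0.5, 25.0, 15.0, 0.3],
            [0.5, 25.0, 15.0, 0.3],
            [0.5, 15.0, 15.0, 0.3],
            [0.5, 15.0, 15.0, 0.3],
            [0.4, 12.0, 12.0, 0.3],
            [0.4, 12.0, 12.0, 0.3],
        ]
    )
    return dict(
        T_true=_BINDING_T.copy(),
        emission_means=means,
        emission_stdevs=stdevs,
        feature_names=[
            "binding_distance",
            "chain_dihedral",
            "toggle_chi2",
            "tm3_tm6_distance",
        ],
        macrostate_labels={
            "unbound": frozenset({0}),
            "entry": frozenset({1}),
            "antagonist": frozenset({2, 3}),
            "agonist": frozenset({4, 5}),
        },
        metadata={"preset": "binding_landscape"},
    )


def _bottleneck(forward: float = 0.01, backward: float = 0.10, n_states: int = 6) -> dict:
    """Uphill linear chain: each forward step is 10x less likely than the
    fall back, so a single trajectory rarely progresses while least-counts
    restarts can push the frontier."""
    n = n_states
    T = np.zeros((n, n))
    for i in range(n):
        if i + 1 < n:
            T[i, i + 1] = forward
        if i - 1 >= 0:
            T[i, i - 1] = backward
        T[i, i] = 1.0 - T[i].sum()
    means = 5.0 * np.arange(n, dtype=float)[:, None]
    return dict(
        T_true=T,
        emission_means=means,
        emission_stdevs=np.full((n, 1), 0.5),
        feature_names=["x"],
        macrostate_labels={"unbound": frozenset({0}), "end": frozenset({n - 1})},
        metadata={"preset": "bottleneck", "forward": forward, "backward": backward},
    )


PRESETS = {
    "two_state": _two_state,
    "double_well_1d": _double_well_1d,
    "binding_landscape": _binding_landscape,
    "bottleneck": _bottleneck,
}


def _check_irreducible(T: np.ndarray) -> bool:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(csr_matrix(T > 0), connection="strong")
    return n_comp == 1


def build_ground_truth_chain(
    scenario: str | dict,
    seed: int = 0,
    **params,
) -> GroundTruthSystem:
    """Build a validated ground-truth system from a preset or explicit spec.

    Parameters
    ----------
    scenario
        A preset name (``"two_state"``, ``"double_well_1d"``,
        ``"binding_landscape"``, ``"bottleneck"``) or a dict supplying
        ``T_true``, ``emission_means``, ``emission_stdevs`` and
        ``feature_names`` explicitly.
    seed
        Recorded in metadata; presets are deterministic given it.
    **params
        Forwarded to the preset constructor (e.g. ``gap=`` for
        ``double_well_1d``, ``escape=`` for ``two_state``).
    """
    if isinstance(scenario, str):
        try:
            builder = PRESETS[scenario]
        except KeyError as err:
            raise ValueError(
                f"unknown preset {scenario!r}; choose from {sorted(PRESETS)}"
            ) from err
        spec = builder(**params)
        if not _check_irreducible(spec["T_true"]):
            raise ValueError(f"preset {scenario!r} produced a reducible chain")
    elif isinstance(scenario, dict):
        spec = dict(scenario)
        spec.setdefault("metadata", {"preset": "explicit"})
        spec.setdefault(
            "feature_names",
            [f"f{j}" for j in range(np.atleast_2d(spec["emission_means"]).shape[1])],
        )
        spec.setdefault("macrostate_labels", {})
    else:
        raise TypeError("scenario must be a preset name or an explicit dict")

    T = np.asarray(spec["T_true"], dtype=float)
    if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("T_true rows must be non-negative and sum to 1")
    if spec.get("pi_true") is None:
        from .msm import stationary_distribution

        spec["pi_true"] = stationary_distribution(T)
    meta = dict(spec.get("metadata", {}))
    meta["seed"] = int(seed)
    return GroundTruthSystem(
        n_states=T.shape[0],
        T_true=T,
        pi_true=spec["pi_true"],
        emission_means=spec["emission_means"],
        emission_stdevs=spec["emission_stdevs"],
        feature_names=list(spec["feature_names"]),
        macrostate_labels=dict(spec.get("macrostate_labels", {})),
        frame_dt=float(spec.get("frame_dt", 1.0)),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# trajectory sampling
# ---------------------------------------------------------------------------


def _sample_state_path(
    T: np.ndarray, n_steps: int, start_state: int, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0  # guard against round-off at the right edge
    u = rng.random(n_steps - 1)
    path = np.empty(n_steps, dtype=int)
    path[0] = start_state
    s = start_state
    for t in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[t - 1], side="right"))
        path[t] = s
    return path


def sample_chain_trajectory(
    system: GroundTruthSystem,
    n_steps: int,
    start_state: int = 0,
    seed: int = 0,
    trajectory_id: str | None = None,
) -> FeatureTrajectory:
    """Draw one trajectory: a hidden path from ``T_true`` plus Gaussian
    feature emissions from each visited state.  Bit-reproducible given seed.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if not 0 <= start_state < system.n_states:
        raise ValueError(f"invalid start_state {start_state}")
    rng_path, rng_emit = spawn_rngs(seed, 2)
    path = _sample_state_path(system.T_true, n_steps, start_state, rng_path)
    X = rng_emit.normal(system.emission_means[path], system.emission_stdevs[path])
    return FeatureTrajectory(
        trajectory_id=trajectory_id or f"traj-seed{seed}",
        frame_dt=system.frame_dt,
        X=X,
        feature_names=list(system.feature_names),
        hidden_states=path,
    )


def _unbound_state(system: GroundTruthSystem) -> int:
    if "unbound" in system.macrostate_labels:
        return min(system.macrostate_labels["unbound"])
    return 0


def run_adaptive_sampling(
    system: GroundTruthSystem,
    n_rounds: int,
    trajs_per_round: int,
    steps_per_traj: int,
    n_clusters: int,
    seed: int = 0,
) -> list[FeatureTrajectory]:
    """Least-counts adaptive sampling against the ground-truth chain.

    Round 1 starts every trajectory from the unbound state.  Each later
    round pools all frames collected so far, clusters them with k-means on
    the features, counts frames per cluster, and restarts one trajectory
    from a uniformly chosen frame of each of the least-populated clusters
    (count ties broken uniformly at random under the run seed).  A restart
    resumes the hidden chain from the hidden state of the selected frame.
    """
    if min(n_rounds, trajs_per_round, steps_per_traj, n_clusters) <= 0:
        raise ValueError("all counts must be positive")
    master = np.random.SeedSequence(seed)
    round_seeds = master.spawn(n_rounds)
    trajs: list[FeatureTrajectory] = []
    for rnd in range(n_rounds):
        children = round_seeds[rnd].spawn(trajs_per_round + 1)
        rng_restart = np.random.default_rng(children[-1])
        if rnd == 0:
            starts = [_unbound_state(system)] * trajs_per_round
        else:
            frames = np.vstack([t.X for t in trajs])
            hidden = np.concatenate([t.hidden_states for t in trajs])
            if n_clusters > frames.shape[0]:
                raise ValueError("n_clusters exceeds accumulated frames")
            km_seed = int(rng_restart.integers(2**31 - 1))
            labels = KMeans(
                n_clusters=n_clusters, n_init=5, random_state=km_seed
            ).fit_predict(frames)
            counts = np.bincount(labels, minlength=n_clusters)
            # ascending counts with random tie-break under the run seed
            order = np.lexsort((rng_restart.random(n_clusters), counts))
            starts = []
            for i in range(trajs_per_round):
                cluster = order[i % n_clusters]
                pool = np.flatnonzero(labels == cluster)
                frame = int(rng_restart.choice(pool))
                starts.append(int(hidden[frame]))
        for k, start in enumerate(starts):
            traj_seed = int(np.random.default_rng(children[k]).integers(2**31 - 1))
            traj = sample_chain_trajectory(
                system,
                steps_per_traj,
                start_state=start,
                seed=traj_seed,
                trajectory_id=f"round{rnd:03d}-traj{k:03d}",
            )
            trajs.append(traj)
    return trajs


# ---------------------------------------------------------------------------
# dihedral ensembles for the mutual-information network
# ---------------------------------------------------------------------------


def generate_dihedral_ensembles(
    n_residues: int,
    path_spec: list[int],
    coupling_strength: float,
    n_frames: int,
    seed: int = 0,
    differing_residues: list[int] | None = None,
    differing_shift: float = 70.0,
    n_decoys: int = 2,
) -> tuple[DihedralEnsemble, DihedralEnsemble]:
    """Generate a matched pair of dihedral ensembles with a planted coupling
    chain and a shared contact map.

    Residues along ``path_spec`` form a dependency chain: each angle is a
    wrapped-normal perturbation of its predecessor with noise stdev
    ``150 * (1 - coupling_strength)`` degrees, so ``coupling_strength=1``
    copies the angle exactly.  Off-path residues are mutually independent.
    The contact map places consecutive path residues at 4.5 Å, adds
    ``n_decoys`` short (4 Å) decoy contacts with zero statistical coupling
    (including an end-to-end shortcut when possible), and keeps every other
    pair beyond 6 Å.  The second ("partial-agonist-like") ensemble shifts
    the mean dihedral of ``differing_residues`` by ``differing_shift``
    degrees; by default three off-path residues are chosen under the seed.
    """
    path = [int(r) for r in path_spec]
    if len(set(path)) != len(path) or any(not 0 <= r < n_residues for r in path):
        raise ValueError("path_spec residues must be distinct and in range")
    if not 0 < coupling_strength <= 1:
        raise ValueError("coupling_strength must be in (0, 1]")
    rng_layout, rng_a, rng_b = spawn_rngs(seed, 3)

    off_path = [r for r in range(n_residues) if r not in path]
    if differing_residues is None:
        k = min(3, len(off_path))
        differing_residues = sorted(
            int(r) for r in rng_layout.choice(off_path, size=k, replace=False)
        )
    base_means = wrap_degrees(rng_layout.uniform(-180.0, 180.0, size=n_residues))
    off_sigma = 45.0
    noise_sigma = 150.0 * (1.0 - coupling_strength)

    # shared contact map
    cd = rng_layout.uniform(7.0, 15.0, size=(n_residues, n_residues))
    cd = (cd + cd.T) / 2.0
    np.fill_diagonal(cd, 0.0)
    for a, b in zip(path[:-1], path[1:]):
        cd[a, b] = cd[b, a] = 4.5
    # decoys: short contacts with zero statistical coupling.  Any two path
    # residues are coupled through the chain, so a decoy must involve at
    # least one off-path (independent) residue.
    decoys: list[tuple[int, int]] = []
    attempts = 0
    while len(decoys) < n_decoys and attempts < 200 and off_path:
        i = int(rng_layout.choice(off_path))
        j = int(rng_layout.integers(n_residues))
        attempts += 1
        if i == j or cd[i, j] < 6.0:
            continue
        decoys.append((i, j))
    for i, j in decoys:
        cd[i, j] = cd[j, i] = 4.0

    def _draw(rng: np.random.Generator, shifted: bool) -> np.ndarray:
        D = np.empty((n_frames, n_residues))
        means = base_means.copy()
        if shifted:
            means[differing_residues] = wrap_degrees(
                means[differing_residues] + differing_shift
            )
        for r in off_path:
            D[:, r] = wrap_degrees(rng.normal(means[r], off_sigma, size=n_frames))
        root = path[0]
        D[:, root] = wrap_degrees(rng.normal(means[root], off_sigma, size=n_frames))
        if shifted and root in differing_residues:
            pass  # shift already applied through means
        for prev, cur in zip(path[:-1], path[1:]):
            noisy = D[:, prev] + (
                rng.normal(0.0, noise_sigma, size=n_frames) if noise_sigma > 0 else 0.0
            )
            if shifted and cur in differing_residues:
                noisy = noisy + differing_shift
            D[:, cur] = wrap_degrees(noisy)
        return D

    meta = {
        "differing_residues": list(differing_residues),
        "decoy_contacts": decoys,
        "coupling_strength": float(coupling_strength),
        "seed": int(seed),
    }
    ens_a = DihedralEnsemble(
        n_residues=n_residues,
        D=_draw(rng_a, shifted=False),
        contact_distances=cd,
        planted_path=list(path),
        label="agonist-like",
        metadata=dict(meta),
    )
    ens_b = DihedralEnsemble(
        n_residues=n_residues,
        D=_draw(rng_b, shifted=True),
        contact_distances=cd.copy(),
        planted_path=list(path),
        label="partial-agonist-like",
        metadata=dict(meta),
    )
    return ens_a, ens_b
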