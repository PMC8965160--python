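# msmpath

Markov state model (MSM) thermodynamics and transition-path kinetics for
ligand-binding molecular simulations, with a synthetic ground-truth module
that makes every stage of the analysis testable.

## The problem

Ligand binding to a G-protein-coupled receptor is a rare event: even hundreds
of microseconds of molecular dynamics, collected as many short adaptively
restarted trajectories, sample the binding pathway unevenly. An MSM turns
such data back into equilibrium thermodynamics and kinetics: trajectories
are projected onto slow collective coordinates, discretized into microstates,
and a transition probability matrix is estimated at a lag time τ,

    T_ij = C_ij / Σ_j C_ij,

where C_ij counts observed i→j jumps at lag τ. The stationary distribution π
(leading left eigenvector of T) gives state populations and free energies
G_i = −k_B T ln π_i; eigenvalues λ give relaxation timescales t = −τ/ln λ.
Reweighting each frame by π_state/n_frames_in_state removes the adaptive-
sampling bias from free-energy landscapes and conditional probabilities.
Transition path theory supplies kinetics between macrostates A and B: the
committor q⁺ (probability of reaching B before A), the reactive flux
F_AB = Σ_{i∈A} Σ_{j∉A} π_i T_ij q_j⁺, and the mean first-passage time
MFPT = τ·π_A/F_AB. Kinetic Monte Carlo resimulates long state-hopping
trajectories from T. Two conformational ensembles (e.g. agonist-bound vs
partial-agonist-bound) are compared by pooled PCA, per-feature symmetrized
Kullback–Leibler divergence aggregated per residue, and a mutual-information
residue network (edges require spatial contact < 6 Å and significant
normalized MI) whose Dijkstra shortest paths trace allosteric pathways.
Uncertainty on any of these comes from bootstrap resampling of trajectories
with the state labeling held fixed.

This package is aimed at people building or validating such pipelines. Raw
MD feature matrices are rarely shareable, so `msmpath.synthetic` generates
trajectories from hidden metastable chains with known transition matrices,
emissions and macrostates — including a six-state ligand-binding landscape
(unbound → pocket entry → two antagonist-like poses → agonist-like pose with
a sign-flipping chain dihedral and a toggle-switch-like angle), a 1-D double
well with an exactly configured basin gap, and a bottlenecked chain for
adaptive-sampling experiments — so that recovery of T, π, free-energy gaps,
committors and MFPTs can be asserted against ground truth.

## Worked example

```python
import numpy as np
import msmpath as mp

system = mp.build_ground_truth_chain("binding_landscape")
trajs = [mp.sample_chain_trajectory(system, 5000, start_state=0, seed=s)
         for s in range(10)]

tica = mp.fit_tica(trajs, lag=5, variance_fraction=0.95)
disc = mp.kmeans_discretize(tica.transform_all(trajs), K=20, seed=0)
msm = mp.estimate_msm(mp.count_transitions(disc.assignments, lag=1),
                      frame_dt=1.0)
print(f"active states: {msm.n_states}")
print(f"slowest implied timescales (ns): {np.round(msm.timescales(3), 1)}")

G = mp.free_energy_of_states(msm.pi, temperature=300.0)
print(f"free-energy span: {np.nanmax(G):.2f} kcal/mol")

centers = np.array([np.vstack([t.X for t in trajs])
                    [np.concatenate(disc.assignments) == k].mean(axis=0)
                    for k in range(20)])
unbound = mp.define_macrostate(msm, lambda d: d[0] > 23, centers, name="unbound")
agonist = mp.define_macrostate(msm, lambda d: d[0] < 13, centers, name="agonist")
res = mp.tpt(msm, unbound, agonist)
print(f"unbound -> agonist flux: {res.flux_per_lag:.4f} per lag")
print(f"unbound -> agonist MFPT: {res.mfpt_ns:.0f} ns")

p = mp.conditional_probability(
    msm, disc.assignments, trajs,
    condition=lambda t: t.column("binding_distance") < 13,
    outcome=lambda t: t.column("chain_dihedral") > 0,
)
print(f"P(dihedral positive | agonist-bound): {p:.2f}")
```

Output:

```
active states: 20
slowest implied timescales (ns): [25.5  8.5  5.6]
free-energy span: 0.74 kcal/mol
unbound -> agonist flux: 0.0038 per lag
unbound -> agonist MFPT: 22 ns
P(dihedral positive | agonist-bound): 0.68
```

The slowest timescale (~26 ns at 1 ns frames) is the unbound↔bound exchange
of the generating chain; the 0.74 kcal/mol span is the population contrast
between the most and least occupied microstates; the MFPT is the equilibrium
time spent unbound per completed binding passage; and the conditional
probability reports how strongly the ligand prefers the positive-dihedral
orientation once it sits in the agonist-like pose.

A command-line interface mirrors the library
(`msmpath simulate | discretize | msm | landscape | tpt | kmc | compare |
allosteric-path | bootstrap | run`); `msmpath run --config cfg.yaml --out
rundir` executes the full pipeline from a validated YAML config and writes
all artifacts with provenance (config hash and seeds).

## Documentation

`docs/methods.md` describes the models, estimators, conventions and
numerical choices in detail, including what the synthetic generators do and
do not emulate about real MD data.
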