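"""End-to-end pipeline driver: simulate/ingest → TICA → cluster → MSM →
landscapes → TPT/kMC → bootstrap → compare, with provenance stamping.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import compare as cmp
from . import io as mio
from .bootstrap import bootstrap_statistic
from .config import PipelineConfig
from .featurize import fit_tica, kmeans_discretize, vamp2_score
from .kinetics import MacrostateSet, define_macrostate, kmc_run, tpt
from .msm import (
    count_transitions,
    estimate_msm,
    free_energy_of_states,
    implied_timescales,
    weighted_landscape,
)
from .synthetic import build_ground_truth_chain, run_adaptive_sampling, sample_chain_trajectory

__all__ = ["run_pipeline"]

log = logging.getLogger("msmpath")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
            log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("simulate")
def _simulate(cfg: PipelineConfig):
    sc = cfg.scenario
    if sc.input_path:
        return None, mio.load_trajectories(sc.input_path)
    system = build_ground_truth_chain(sc.name, seed=sc.seed, **sc.params)
    if sc.adaptive:
        trajs = run_adaptive_sampling(
            system, sc.n_rounds, sc.trajs_per_round, sc.n_steps,
            sc.adaptive_clusters, seed=sc.seed,
        )
    else:
        children = np.random.SeedSequence(sc.seed).spawn(sc.n_trajs)
        trajs = [
            sample_chain_trajectory(
                system, sc.n_steps, start_state=0,
                seed=int(np.random.default_rng(c).integers(2**31 - 1)),
                trajectory_id=f"traj-{k:04d}",
            )
            for k, c in enumerate(children)
        ]
    return system, trajs


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured stages and write artifacts under ``outdir``.

    Returns the machine-readable summary that is also written as
    ``summary.json``.  Deterministic given the config (and its seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = dict(config.provenance())
    summary["stages"] = []

    system, trajs = _simulate(config)
    mio.save_trajectories(
        trajs, outdir / "trajectories",
        extra_meta={"scenario": config.scenario.name, "seed": config.scenario.seed},
    )
    summary["stages"].append("simulate")
    summary["n_trajectories"] = len(trajs)
    summary["n_frames"] = int(sum(len(t) for t in trajs))

    fz = config.featurization
    if trajs[0].n_features >= 2:
        tica = _stage("tica")(fit_tica)(
            trajs, lag=fz.tica_lag, variance_fraction=fz.variance_fraction
        )
        transformed = tica.transform_all(trajs)
        summary["stages"].append("tica")
        summary["tica"] = {
            "n_retained": tica.n_retained,
            "eigenvalues": tica.eigenvalues[:5].tolist(),
        }
    else:  # a single feature has nothing to rotate
        transformed = [t.X for t in trajs]
        summary["stages"].append("tica_skipped")

    disc = _stage("cluster")(kmeans_discretize)(transformed, K=fz.k, seed=fz.kmeans_seed)
    summary["stages"].append("cluster")

    mb = config.msm
    C = count_transitions(disc.assignments, lag=mb.lag, mode=mb.mode)
    msm = _stage("msm")(estimate_msm)(C, frame_dt=trajs[0].frame_dt)
    summary["stages"].append("msm")
    summary["msm"] = {
        "n_active": msm.n_states,
        "lag_frames": msm.lag,
        "vamp2": vamp2_score(disc, lag=mb.lag, n_processes=min(5, fz.k)),
        "timescales_ns": [t for t in msm.timescales(5).tolist()],
    }
    its = implied_timescales(
        disc.assignments, lags=sorted({1, mb.lag, 2 * mb.lag}), frame_dt=trajs[0].frame_dt
    )
    its.to_csv(outdir / "implied_timescales.csv", index=False)

    G = free_energy_of_states(msm.pi, temperature=mb.temperature)
    np.savetxt(outdir / "state_free_energies.csv",
               np.column_stack([msm.active_set, msm.pi, G]),
               header="state,pi,G_kcal_mol", delimiter=",", comments="")
    summary["free_energy_range_kcal_mol"] = float(np.nanmax(G))

    x_name = trajs[0].feature_names[0]
    surf = _stage("landscape")(weighted_landscape)(
        msm, disc.assignments, trajs, obs_x=x_name,
        obs_y=trajs[0].feature_names[1] if trajs[0].n_features > 1 else None,
        temperature=mb.temperature,
    )
    surf.to_frame().to_csv(outdir / "landscape.csv", index=False)
    summary["stages"].append("landscape")

    # macrostates on cluster centers mapped back to feature space: descriptors
    # are per-state mean feature vectors
    kin = config.kinetics
    macrostates: dict[str, MacrostateSet] = {}
    if kin.macrostates:
        all_X = np.vstack([t.X for t in trajs])
        all_a = np.concatenate(disc.assignments)
        descriptors = np.zeros((disc.K, trajs[0].n_features))
        for s in range(disc.K):
            m = all_a == s
            if m.any():
                descriptors[s] = all_X[m].mean(axis=0)
        fnames = trajs[0].feature_names
        for region in kin.macrostates:
            j = fnames.index(region.feature)
            lo, hi = region.min, region.max
            macrostates[region.name] = _stage("macrostate")(define_macrostate)(
                msm,
                lambda d, j=j, lo=lo, hi=hi: lo <= d[j] <= hi,
                descriptors,
                n_top=kin.n_top,
                name=region.name,
            )
        summary["macrostates"] = {k: sorted(v.states) for k, v in macrostates.items()}
        tpt_out = {}
        for a, b in kin.tpt_pairs:
            res = _stage("tpt")(tpt)(msm, macrostates[a], macrostates[b])
            tpt_out[f"{a}->{b}"] = {
                "mfpt_ns": res.mfpt_ns, "flux_per_lag": res.flux_per_lag,
            }
            (outdir / f"tpt_{a}_to_{b}.json").write_text(json.dumps(res.to_dict(), indent=2))
        summary["tpt"] = tpt_out

    if kin.kmc_steps > 0:
        start_ms = kin.kmc_start_macrostate
        if start_ms and start_ms in macrostates:
            start = min(macrostates[start_ms].states)
        else:
            start = int(msm.active_set[np.argmax(msm.pi)])
        traj = _stage("kmc")(kmc_run)(msm, start, kin.kmc_steps, seed=config.scenario.seed)
        np.savetxt(outdir / "kmc_states.csv",
                   np.column_stack([np.arange(len(traj)), traj.states, traj.times_ns]),
                   header="step,state,time_ns", delimiter=",", comments="")
        summary["stages"].append("kmc")
    else:
        summary["stages"].append("kmc_skipped")

    if config.bootstrap.enabled:
        bs = config.bootstrap
        res = _stage("bootstrap")(bootstrap_statistic)(
            trajs, disc.assignments, bs.statistic, lag=mb.lag,
            n_rounds=bs.n_rounds, fraction=bs.fraction, mode=bs.mode,
            frame_dt=trajs[0].frame_dt, seed=config.scenario.seed,
        )
        (outdir / "bootstrap.json").write_text(json.dumps(res.to_dict(), indent=2))
        summary["stages"].append("bootstrap")

    if config.compare.enabled:
        cc = config.compare
        from .synthetic import generate_dihedral_ensembles

        ens_a, ens_b = generate_dihedral_ensembles(
            cc.n_residues, cc.path_spec, cc.coupling_strength, cc.n_frames,
            seed=config.scenario.seed,
        )
        kl = {
            f"res{r}": cmp.symmetrized_kl(ens_a.D[:, r], ens_b.D[:, r], cc.kl_bins)
            for r in range(cc.n_residues)
        }
        mi = cmp.mi_matrix(ens_a.D, n_bins=cc.mi_bins)
        thr = cmp.mi_significance_threshold(
            ens_a.D, n_bins=cc.mi_bins, n_shuffles=cc.mi_null_shuffles,
            seed=config.scenario.seed,
        )
        net = cmp.build_mi_graph(mi, ens_a.contact_distances,
                                 distance_cutoff=cc.distance_cutoff, mi_threshold=thr)
        path = cmp.shortest_allosteric_path(net, cc.path_spec[0], cc.path_spec[-1])
        net.edge_table().to_csv(outdir / "mi_edges.csv", index=False)
        summary["compare"] = {
            "per_residue_kl": kl,
            "allosteric_path": path,
            "planted_path": list(cc.path_spec),
        }
        summary["stages"].append("compare")

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
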