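"""End-to-end protocols: binding-surface prediction, AFM flexible fitting,
restraint-release closure, and the slide-off assay.

Each protocol runs a batch of independently seeded simulations, analyses
them, and returns a :class:`ProtocolResult` whose summary values are
recomputable from the stored trajectories.  Child seeds are spawned
deterministically from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as C
from .analysis import (contact_probability, detect_binding_events,
                       fit_dissociation_rate, hinge_angle_from_positions,
                       qscore, representative_structure)
from .dynamics import (SimulationConfig, place_random_dna,
                       release_restraint_protocol, run_simulation)
from .structures import build_bdna_duplex
from .system import BeadClass, CGSystem

__all__ = ["ProtocolResult", "run_binding_surface_prediction",
           "run_afm_fitting", "run_closure_protocol", "run_slideoff_assay"]


@dataclass
class ProtocolResult:
    summary: dict
    tables: dict = field(default_factory=dict)
    trajectories: list = field(default_factory=list)
    seed: int | None = None
    config: dict = field(default_factory=dict)


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([int(s.generate_state(1)[0] % (2 ** 31))
                     for s in ss.spawn(n)])


def _dna_selections(system: CGSystem) -> dict[str, np.ndarray]:
    """Bead indices per DNA copy (chains grouped by their copy suffix)."""
    is_dna = system.bead_classes != int(BeadClass.CA)
    groups: dict[str, list] = {}
    for i in np.flatnonzero(is_dna):
        cid = str(system.chain_ids[i])
        label = cid[1:] if len(cid) > 1 else cid
        groups.setdefault(label, []).append(i)
    return {k: np.array(v, dtype=int) for k, v in sorted(groups.items())}


# ---------------------------------------------------------------------------
# protocol 1: binding-surface prediction
# ---------------------------------------------------------------------------

def run_binding_surface_prediction(
        protein_system: CGSystem, dna_sequence: str, salt_list,
        n_runs: int = 1, steps: int = 100000, seed: int = 0,
        box=(200.0, 160.0, 200.0), n_dna: int = 5,
        save_interval: int = 100, contact_cutoff: float = 10.0,
        d_on: float = 10.0, d_off: float = 15.0,
        site_definitions: dict | None = None,
        keep_trajectories: bool = False) -> ProtocolResult:
    """Free binding runs: random DNA placement, simulation, then contact
    profiles, binding events, dissociation-rate fits and a representative
    frame, for each salt concentration in ``salt_list``.
    """
    duplex = build_bdna_duplex(dna_sequence)
    prot_idx = np.flatnonzero(protein_system.bead_classes
                              == int(BeadClass.CA))
    seeds = spawn_seeds(seed, len(salt_list) * n_runs)
    per_salt, profiles, event_tables, trajs = {}, {}, {}, []

    k = 0
    for salt in salt_list:
        salt_profiles, salt_events = [], []
        for _ in range(n_runs):
            run_seed = int(seeds[k]); k += 1
            system = place_random_dna(protein_system, duplex,
                                      n_copies=n_dna, seed=run_seed,
                                      box=box)
            config = SimulationConfig(n_steps=steps,
                                      save_interval=save_interval,
                                      seed=run_seed, salt=salt, box=box)
            traj = run_simulation(system, config)
            dna_sel = _dna_selections(system)
            all_dna = np.concatenate(list(dna_sel.values()))
            profile = contact_probability(traj, prot_idx, all_dna,
                                          cutoff=contact_cutoff)
            sites = site_definitions
            if sites is None:
                patch = protein_system.metadata.get("patch")
                sites = {"site": patch if patch is not None else prot_idx}
            events = detect_binding_events(traj, sites, dna_sel,
                                           d_on=d_on, d_off=d_off)
            salt_profiles.append(profile)
            salt_events.append(events)
            if keep_trajectories:
                trajs.append(traj)
            last_system, last_traj, last_sites = system, traj, sites

        probs = np.mean([p.probabilities for p in salt_profiles], axis=0)
        merged_events = pd.concat([e.events for e in salt_events],
                                  ignore_index=True)
        rates = {}
        for site_label in last_sites:
            sub = merged_events[merged_events["site"] == site_label]
            durations = (sub["end_step"] - sub["start_step"]).to_numpy(float)
            observed = (~sub["censored"]).to_numpy(bool)
            if observed.sum() >= 3:
                fit = fit_dissociation_rate((durations, observed))
                rates[site_label] = {"rate_per_step": fit.rate,
                                     "stderr": fit.stderr,
                                     "n_events": fit.n_events}
            else:
                rates[site_label] = {"rate_per_step": None,
                                     "stderr": None,
                                     "n_events": int(len(sub))}
        site_idx = np.asarray(next(iter(last_sites.values())), dtype=int)
        rep_frame, _ = representative_structure(
            last_traj, site_idx, np.concatenate(
                list(_dna_selections(last_system).values())))
        per_salt[salt] = {"rates": rates, "representative_frame": rep_frame}
        profiles[salt] = pd.DataFrame(
            {"bead_index": prot_idx, "contact_probability": probs})
        event_tables[salt] = merged_events

    return ProtocolResult(
        summary={"per_salt": per_salt},
        tables={"contact_profiles": profiles, "events": event_tables},
        trajectories=trajs, seed=seed,
        config={"salt_list": list(salt_list), "n_runs": n_runs,
                "steps": steps, "box": list(box), "n_dna": n_dna})


# ---------------------------------------------------------------------------
# protocol 2: AFM flexible fitting
# ---------------------------------------------------------------------------

def run_afm_fitting(start_system: CGSystem, reference_image, kappa: float,
                    n_runs: int = 20, steps: int = 3000, seed: int = 0,
                    save_interval: int = 100, beta: float = 2.0,
                    inter_q_band=(0.0, 0.6), intra_q_floor: float = 0.95,
                    keep_trajectories: bool = False) -> ProtocolResult:
    """Restrained fitting runs with per-frame similarity and Q-scores.

    Runs are selected as successfully fitted when their final
    inter-subunit Q lies inside ``inter_q_band`` (open structure) while the
    intra-subunit Q stays at or above ``intra_q_floor`` (undistorted
    subunits).
    """
    seeds = spawn_seeds(seed, n_runs)
    inter_mask = start_system.metadata.get("interarm_contact_mask")
    intra_mask = start_system.metadata.get("intraarm_contact_mask")
    arms = (start_system.metadata.get("arm_a"),
            start_system.metadata.get("arm_b"))
    rows, trajs = [], []
    for r in range(n_runs):
        config = SimulationConfig(n_steps=steps, save_interval=save_interval,
                                  seed=int(seeds[r]), kappa=kappa,
                                  reference_image=reference_image, beta=beta)
        traj = run_simulation(start_system, config)
        final = traj.positions[-1]
        row = {"run": r, "seed": int(seeds[r]),
               "final_cs": float(traj.logs["afm_cs"][-1])}
        if inter_mask is not None:
            row["inter_q"] = qscore(
                start_system.native_contacts[inter_mask],
                start_system.contact_r0[inter_mask], final)
            row["intra_q"] = qscore(
                start_system.native_contacts[intra_mask],
                start_system.contact_r0[intra_mask], final)
        if arms[0] is not None:
            row["fitted_angle_deg"] = hinge_angle_from_positions(
                final, arms[0], arms[1])
        rows.append(row)
        if keep_trajectories:
            trajs.append(traj)
    table = pd.DataFrame(rows)
    selected = table
    if "inter_q" in table:
        selected = table[(table["inter_q"] >= inter_q_band[0])
                         & (table["inter_q"] <= inter_q_band[1])
                         & (table["intra_q"] >= intra_q_floor)]
    summary = {"kappa": kappa, "n_runs": n_runs,
               "n_selected": int(len(selected)),
               "selected_runs": selected["run"].tolist(),
               "median_final_cs": float(table["final_cs"].median())}
    if "intra_q" in table:
        summary["n_distorted"] = int(np.sum(table["intra_q"]
                                            < intra_q_floor))
    return ProtocolResult(summary=summary, tables={"runs": table},
                          trajectories=trajs, seed=seed,
                          config={"kappa": kappa, "steps": steps,
                                  "beta": beta})


# ---------------------------------------------------------------------------
# protocol 3: closure after restraint release
# ---------------------------------------------------------------------------

def run_closure_protocol(open_system_with_dna: CGSystem,
                         low_salt: float = 0.01, steps: int = 6000,
                         n_runs: int = 20, seed: int = 0,
                         save_interval: int = 100,
                         close_q: float = 0.7,
                         retention_cutoff: float = 15.0,
                         keep_trajectories: bool = False) -> ProtocolResult:
    """Release the AFM restraint and watch the hinge reclose around DNA.

    Per run, the closure step is the first saved step with inter-subunit
    Q >= ``close_q``; DNA retention requires the DNA to stay within
    ``retention_cutoff`` of the inner-face beads at the final frame.
    """
    system = open_system_with_dna
    inner = np.asarray(system.metadata["inner_face"], dtype=int)
    dna_idx = np.flatnonzero(system.bead_classes != int(BeadClass.CA))
    seeds = spawn_seeds(seed, n_runs)
    rows, trajs = [], []
    for r in range(n_runs):
        config = SimulationConfig(n_steps=steps, save_interval=save_interval,
                                  seed=int(seeds[r]), salt=low_salt,
                                  kappa=0.0)
        traj = release_restraint_protocol(system, config)
        q = traj.logs["inter_subunit_q"]
        closed = np.flatnonzero(q >= close_q)
        closure_step = int(traj.steps[closed[0]]) if closed.size else None
        from scipy.spatial.distance import cdist
        final = traj.positions[-1]
        retained = bool(cdist(final[inner], final[dna_idx]).min()
                        <= retention_cutoff)
        rows.append({"run": r, "seed": int(seeds[r]),
                     "closure_step": closure_step,
                     "closed": closure_step is not None,
                     "dna_retained": retained,
                     "final_inter_q": float(q[-1])})
        if keep_trajectories:
            trajs.append(traj)
    table = pd.DataFrame(rows)
    closed_steps = table.loc[table["closed"], "closure_step"]
    summary = {
        "n_runs": n_runs,
        "closure_fraction": float(table["closed"].mean()),
        "retention_fraction": float(table["dna_retained"].mean()),
        "mean_closure_step": float(closed_steps.mean())
        if len(closed_steps) else None,
    }
    return ProtocolResult(summary=summary, tables={"runs": table},
                          trajectories=trajs, seed=seed,
                          config={"low_salt": low_salt, "steps": steps})


# ---------------------------------------------------------------------------
# protocol 4: slide-off assay
# ---------------------------------------------------------------------------

def run_slideoff_assay(closed_system_with_trapped_dna: CGSystem,
                       high_salt: float = 0.4, steps: int = 40000,
                       n_runs: int = 4, seed: int = 0,
                       save_interval: int = 100,
                       site_indices=None, d_on: float = 12.0,
                       d_off: float = 18.0, box=None,
                       keep_trajectories: bool = False) -> ProtocolResult:
    """Track DNA escape from a topologically trapped start structure.

    Binding events between the trapping site and the DNA are followed
    until the DNA exits through a duplex end (the only escape path); the
    dissociation rate is fitted from the pooled events.  With a periodic
    box matched to the duplex repeat the duplex is effectively endless and
    all events censor.
    """
    system = closed_system_with_trapped_dna
    if site_indices is None:
        site_indices = system.metadata.get(
            "site", np.flatnonzero(system.bead_classes
                                   == int(BeadClass.CA)))
    dna_idx = np.flatnonzero(system.bead_classes != int(BeadClass.CA))
    seeds = spawn_seeds(seed, n_runs)
    all_events, trajs = [], []
    for r in range(n_runs):
        config = SimulationConfig(n_steps=steps, save_interval=save_interval,
                                  seed=int(seeds[r]), salt=high_salt,
                                  box=box)
        traj = run_simulation(system, config)
        events = detect_binding_events(
            traj, {"trap": np.asarray(site_indices, dtype=int)},
            {"dna": dna_idx}, d_on=d_on, d_off=d_off)
        all_events.append(events.events)
        if keep_trajectories:
            trajs.append(traj)
    table = pd.concat(all_events, ignore_index=True)
    durations = (table["end_step"] - table["start_step"]).to_numpy(float)
    observed = (~table["censored"]).to_numpy(bool)
    summary = {"n_events": int(len(table)),
               "n_exits": int(observed.sum()),
               "all_censored": bool(len(table) and not observed.any())}
    if observed.sum() >= 2:
        fit = fit_dissociation_rate((durations, observed))
        summary["rate_per_step"] = fit.rate
        summary["rate_stderr"] = fit.stderr
    else:
        summary["rate_per_step"] = None
    return ProtocolResult(summary=summary, tables={"events": table},
                          trajectories=trajs, seed=seed,
                          config={"high_salt": high_salt, "steps": steps})
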