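"""Trajectory analyses against brute-force and hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

import hingeflex as hf
from hingeflex.analysis import (BindingEventTable, contact_probability,
                                detect_binding_events, derive_sites,
                                fit_dissociation_rate, qscore,
                                qscore_protein_dna, representative_structure,
                                survival_curve, conservation_profile,
                                hinge_angle_from_positions)
from hingeflex.system import Trajectory


def traj_from_frames(frames):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(steps=np.arange(frames.shape[0]) * 100,
                      positions=frames)


class TestContactProbability:
    def test_always_and_never_in_contact(self):
        prot = np.zeros((5, 3))
        prot[:, 0] = np.arange(5) * 30.0
        frames = []
        for _ in range(10):
            dna = np.array([[30.0, 5.0, 0.0]])   # 5 A from protein bead 1
            frames.append(np.vstack([prot, dna]))
        traj = traj_from_frames(frames)
        prof = contact_probability(traj, np.arange(5), np.array([5]),
                                   cutoff=10.0)
        assert prof.probabilities[1] == 1.0
        assert prof.probabilities[0] == 0.0

    def test_matches_brute_force_and_frame_order_invariance(self, rng):
        frames = rng.uniform(0, 40, size=(30, 8, 3))
        traj = traj_from_frames(frames)
        prot, dna = np.arange(5), np.arange(5, 8)
        prof = contact_probability(traj, prot, dna, cutoff=12.0)
        brute = np.zeros(5)
        for f in frames:
            for i, p in enumerate(prot):
                if any(np.linalg.norm(f[p] - f[d]) <= 12.0 for d in dna):
                    brute[i] += 1
        assert np.allclose(prof.probabilities, brute / 30)
        shuffled = traj_from_frames(frames[::-1])
        prof2 = contact_probability(shuffled, prot, dna, cutoff=12.0)
        assert np.allclose(prof2.probabilities, prof.probabilities)


class TestBindingEvents:
    def _distance_trajectory(self, dists):
        """Protein bead at origin; one DNA bead at the given distances."""
        frames = [np.array([[0.0, 0, 0], [d, 0, 0]]) for d in dists]
        return traj_from_frames(frames)

    def test_single_dip_gives_one_event(self):
        d = np.full(500, 30.0)
        d[100:200] = 5.0
        traj = self._distance_trajectory(d)
        table = detect_binding_events(traj, {"s": [0]}, {"d": [1]},
                                      d_on=10.0, d_off=15.0)
        assert len(table.events) == 1
        ev = table.events.iloc[0]
        assert ev.end_step - ev.start_step == 100 * 100
        assert not ev.censored

    def test_hysteresis_suppresses_chatter(self):
        d = np.full(200, 30.0)
        d[50:150] = np.where(np.arange(100) % 2 == 0, 9.0, 13.0)
        traj = self._distance_trajectory(d)
        table = detect_binding_events(traj, {"s": [0]}, {"d": [1]},
                                      d_on=10.0, d_off=15.0)
        assert len(table.events) == 1

    def test_censoring_at_trajectory_end(self):
        d = np.full(100, 30.0)
        d[60:] = 5.0
        traj = self._distance_trajectory(d)
        table = detect_binding_events(traj, {"s": [0]}, {"d": [1]})
        assert bool(table.events.iloc[0].censored)

    def test_matches_brute_force_state_machine(self, rng):
        dists = 12.0 + 8.0 * np.cumsum(rng.normal(size=400)) * 0.1
        dists = np.abs(dists) + 2.0
        traj = self._distance_trajectory(dists)
        table = detect_binding_events(traj, {"s": [0]}, {"d": [1]},
                                      d_on=10.0, d_off=15.0)
        # independent replay
        events = []
        bound, start = False, None
        for k, d in enumerate(dists):
            if not bound and d < 10.0:
                bound, start = True, k * 100
            elif bound and d > 15.0:
                events.append((start, k * 100, False))
                bound = False
        if bound:
            events.append((start, (len(dists) - 1) * 100, True))
        got = [(int(r.start_step), int(r.end_step), bool(r.censored))
               for r in table.events.itertuples()]
        assert got == events

    def test_overlapping_sites_flagged(self):
        traj = self._distance_trajectory(np.full(10, 30.0))
        table = detect_binding_events(traj, {"a": [0], "b": [0]}, {"d": [1]})
        assert table.flags


class TestSurvival:
    def test_counting_and_p0(self):
        curve = survival_curve((np.array([10.0, 20.0, 30.0]),
                                np.array([True, True, True])))
        assert curve.at(0.0) == 1.0
        assert curve.at(15.0) == pytest.approx(2.0 / 3.0)
        assert curve.at(31.0) == pytest.approx(0.0)

    def test_hand_computed_kaplan_meier_with_censoring(self):
        # durations 5, 8+, 12, 15+, 20 (+ censored):
        # S(5) = 4/5, S(12) = 4/5 * 2/3, S(20) = 4/5 * 2/3 * 0
        durations = np.array([5.0, 8.0, 12.0, 15.0, 20.0])
        observed = np.array([True, False, True, False, True])
        curve = survival_curve((durations, observed))
        assert curve.at(6.0) == pytest.approx(4 / 5)
        assert curve.at(13.0) == pytest.approx(4 / 5 * 2 / 3)
        assert curve.at(21.0) == pytest.approx(0.0)

    def test_matches_lifelines(self, rng):
        # independent oracle: lifelines' Kaplan-Meier fitter
        from lifelines import KaplanMeierFitter
        durations = rng.exponential(100.0, size=60)
        observed = rng.random(60) < 0.8
        curve = survival_curve((durations, observed))
        km = KaplanMeierFitter().fit(durations, event_observed=observed)
        for t in [10.0, 50.0, 120.0, 300.0]:
            assert curve.at(t) == pytest.approx(
                float(km.predict(t - 1e-9)), abs=1e-9)


class TestDissociationRate:
    def test_exact_on_analytic_curve(self):
        k = 1e-3
        t = np.linspace(0, 4000.0, 60)
        p = np.exp(-k * t)
        fit = fit_dissociation_rate((t, p))
        assert fit.rate == pytest.approx(k, rel=1e-6)

    def test_recovery_from_synthetic_dwells(self):
        durations, observed = hf.synth_dwell_times(1e-3, 1000, seed=8)
        fit = fit_dissociation_rate((durations, observed))
        mle = 1.0 / durations.mean()          # independent MLE oracle
        assert fit.rate == pytest.approx(1e-3, rel=0.10)
        assert fit.rate == pytest.approx(mle, rel=0.10)
        assert fit.stderr is not None and fit.stderr > 0

    def test_duration_scaling(self):
        durations, observed = hf.synth_dwell_times(1e-3, 400, seed=9)
        f1 = fit_dissociation_rate((durations, observed))
        f2 = fit_dissociation_rate((durations * 2.0, observed))
        assert f2.rate == pytest.approx(f1.rate / 2.0, rel=1e-9)


class TestQScores:
    def test_native_is_one_and_counting(self, toy_hinge):
        assert qscore(toy_hinge.native_contacts, toy_hinge.contact_r0,
                      toy_hinge.positions) == 1.0
        pairs = np.array([[0, i] for i in range(1, 11)])
        r0 = np.full(10, 10.0)
        pos = np.zeros((11, 3))
        pos[1:8, 0] = 10.0     # 7 pairs at r0 < 1.2 r0
        pos[8:, 0] = 50.0      # 3 pairs far
        assert qscore(pairs, r0, pos) == pytest.approx(0.7)

    def test_matches_brute_force_on_perturbations(self, toy_hinge, rng):
        pos = toy_hinge.positions + rng.normal(
            scale=1.0, size=toy_hinge.positions.shape)
        q = qscore(toy_hinge.native_contacts, toy_hinge.contact_r0, pos)
        formed = sum(
            np.linalg.norm(pos[j] - pos[i]) < 1.2 * r0
            for (i, j), r0 in zip(toy_hinge.native_contacts,
                                  toy_hinge.contact_r0))
        assert q == pytest.approx(formed / len(toy_hinge.contact_r0))

    def test_monotone_under_uniform_expansion(self, toy_hinge):
        qs = [qscore(toy_hinge.native_contacts, toy_hinge.contact_r0,
                     toy_hinge.positions * s) for s in (1.0, 1.15, 1.3, 2.0)]
        assert all(a >= b for a, b in zip(qs, qs[1:]))


class TestProteinDnaQScore:
    def _complex(self):
        duplex = hf.build_bdna_duplex("ATGCATGCAT")
        prot = np.array([[12.0, 0.0, z] for z in np.arange(0, 30, 3.8)])
        positions = np.vstack([prot, duplex.positions])
        residues = {r: r for r in range(len(prot))}
        dna_idx = np.arange(len(prot), len(positions))
        return duplex, prot, positions, residues, dna_idx

    def test_reference_frame_is_one_and_no_dna_zero(self):
        duplex, prot, positions, residues, dna_idx = self._complex()
        ref_residues = [r for r in range(len(prot))
                        if cdist(positions[r:r + 1],
                                 positions[dna_idx]).min() <= 15.0]
        q = qscore_protein_dna(ref_residues, positions, residues, dna_idx)
        assert q == 1.0
        gone = positions.copy()
        gone[dna_idx] += 500.0
        assert qscore_protein_dna(ref_residues, gone, residues,
                                  dna_idx) == 0.0

    def test_identity_neglect_under_sliding(self):
        # sliding the DNA one helical repeat barely changes the score
        duplex, prot, positions, residues, dna_idx = self._complex()
        ref_residues = [r for r in range(len(prot))
                        if cdist(positions[r:r + 1],
                                 positions[dna_idx]).min() <= 15.0]
        q0 = qscore_protein_dna(ref_residues, positions, residues, dna_idx)
        slid = positions.copy()
        slid[dna_idx, 2] += 3.38            # one bp rise along the axis
        q1 = qscore_protein_dna(ref_residues, slid, residues, dna_idx)
        assert abs(q1 - q0) < 0.2


class TestRepresentativeStructure:
    def test_identical_frames_return_first(self):
        frames = np.repeat(np.random.default_rng(0).uniform(
            0, 20, size=(1, 6, 3)), 8, axis=0)
        idx, info = representative_structure(frames, [0, 1], [4, 5])
        assert idx == 0

    def test_dense_cluster_beats_outliers(self, rng):
        base = rng.uniform(0, 30, size=(6, 3))
        frames = []
        for i in range(90):
            f = base + rng.normal(scale=0.2, size=base.shape)
            frames.append(f)
        for i in range(10):
            f = base.copy()
            f[3:] += 200.0 + 50.0 * i       # far outliers in d_min space
            frames.append(f)
        idx, info = representative_structure(np.array(frames), [0, 1, 2],
                                             [3, 4, 5])
        assert idx < 90

    def test_neighbor_counts_match_brute_force(self, rng):
        frames = rng.uniform(0, 60, size=(40, 5, 3))
        idx, info = representative_structure(frames, [0, 1], [3, 4],
                                             radius=10.0)
        proj = info["projection"]
        brute = np.array([np.sum(np.linalg.norm(proj - p, axis=1) <= 10.0)
                          for p in proj])
        assert np.array_equal(info["neighbor_counts"], brute)


class TestConservation:
    def test_identical_rows_give_one(self):
        msa = ["MKV", "MKV", "MKV"]
        assert np.allclose(conservation_profile(msa, 0), 1.0)

    def test_hand_counted_toy_msa(self):
        msa = ["MK-VA",
               "MKLVA",
               "MRLVA",
               "MKLV-",
               "AKLVA"]
        # query row 0 has a gap at column 2 -> positions map to cols 0,1,3,4
        scores = conservation_profile(msa, 0)
        assert scores == pytest.approx([4 / 5, 4 / 5, 5 / 5, 4 / 4])

    def test_fraction_with_gap_denominator_config(self):
        msa = ["AA", "A-", "AB"]
        incl = conservation_profile(msa, 0,
                                    exclude_gaps_from_denominator=False)
        assert incl[1] == pytest.approx(1 / 3)

    def test_missing_query_row(self):
        with pytest.raises(ValueError):
            conservation_profile(["AA", "AA"], 5)


class TestSites:
    def test_derive_sites_runs_above_threshold(self):
        from hingeflex.analysis import ContactProfile
        prof = ContactProfile(
            probabilities=np.array([0.1, 0.8, 0.9, 0.2, 0.7, 0.9, 0.95, 0.1]),
            bead_indices=np.arange(8), cutoff=10.0, n_frames=100)
        sites = derive_sites(prof, threshold=0.5)
        assert [s.tolist() for s in sites] == [[1, 2], [4, 5, 6]]


class TestHingeAngleFromPositions:
    def test_right_angle_arms(self):
        arm_a = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0],
                          [4.0, 0, 0], [5, 0, 0]])
        arm_b = np.array([[0, 0, 0], [0, 1, 0], [0, 2, 0], [0, 3, 0],
                          [0, 4.0, 0], [0, 5, 0]])
        pos = np.vstack([arm_a, arm_b])
        ang = hinge_angle_from_positions(pos, np.arange(6),
                                        np.arange(6, 12))
        assert ang == pytest.approx(90.0, abs=1e-9)
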