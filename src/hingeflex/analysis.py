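"""Trajectory analysis: DNA-contact probabilities, binding events and
survival curves, dissociation rates, Q-scores, representative-structure
clustering, and conservation mapping.

Conventions: distances in Angstrom, durations in integration steps,
dissociation rates in 1/step.  Tie-breaks are deterministic (earliest index
wins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .system import CGSystem, Trajectory

__all__ = [
    "ContactProfile", "BindingEventTable", "SurvivalCurve", "QScoreSeries",
    "contact_probability", "detect_binding_events", "survival_curve",
    "fit_dissociation_rate", "qscore", "qscore_series",
    "qscore_protein_dna", "representative_structure", "conservation_profile",
    "derive_sites", "hinge_angle_from_positions",
]


# ---------------------------------------------------------------------------
# contact probabilities
# ---------------------------------------------------------------------------

@dataclass
class ContactProfile:
    """Per-protein-bead probability of contacting any DNA bead."""

    probabilities: np.ndarray      # in [0, 1], one per selected protein bead
    bead_indices: np.ndarray       # protein bead indices the rows refer to
    cutoff: float                  # A
    n_frames: int

    def to_tsv(self, path, system: CGSystem | None = None):
        cols = {"bead_index": self.bead_indices,
                "contact_probability": self.probabilities}
        if system is not None:
            cols["residue_index"] = system.residue_indices[self.bead_indices]
            cols["chain_id"] = system.chain_ids[self.bead_indices]
        df = pd.DataFrame(cols)
        with open(path, "w") as fh:
            fh.write(f"# contact cutoff (A): {self.cutoff}\t"
                     f"frames: {self.n_frames}\n")
            df.to_csv(fh, sep="\t", index=False)


def contact_probability(trajectory: Trajectory, protein_selection,
                        dna_selection, cutoff: float = 10.0) -> ContactProfile:
    """Fraction of frames in which each protein bead has any DNA bead
    within ``cutoff``."""
    prot = np.asarray(protein_selection, dtype=int)
    dna = np.asarray(dna_selection, dtype=int)
    if prot.size == 0 or dna.size == 0:
        raise ValueError("protein and DNA selections must be nonempty")
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    counts = np.zeros(prot.size)
    for frame in trajectory.positions:
        d = cdist(frame[prot], frame[dna])
        counts += (d.min(axis=1) <= cutoff)
    return ContactProfile(probabilities=counts / trajectory.n_frames,
                          bead_indices=prot, cutoff=cutoff,
                          n_frames=trajectory.n_frames)


def derive_sites(profile: ContactProfile, threshold: float = 0.5,
                 min_length: int = 2) -> list[np.ndarray]:
    """Connected runs of beads with contact probability above ``threshold``
    (a helper for defining binding sites from a contact profile)."""
    above = profile.probabilities >= threshold
    sites, run = [], []
    for idx, flag in zip(profile.bead_indices, above):
        if flag:
            run.append(idx)
        elif run:
            if len(run) >= min_length:
                sites.append(np.array(run))
            run = []
    if len(run) >= min_length:
        sites.append(np.array(run))
    return sites


# ---------------------------------------------------------------------------
# binding events
# ---------------------------------------------------------------------------

@dataclass
class BindingEventTable:
    """Bound intervals per (site, DNA copy) with censoring flags."""

    events: pd.DataFrame           # columns: site, dna, start_step, end_step, censored
    site_definitions: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def durations(self) -> np.ndarray:
        return (self.events["end_step"] - self.events["start_step"]).to_numpy()

    @property
    def observed(self) -> np.ndarray:
        return (~self.events["censored"]).to_numpy()

    def for_site(self, site) -> "BindingEventTable":
        return BindingEventTable(
            self.events[self.events["site"] == site].reset_index(drop=True),
            self.site_definitions, list(self.flags))

    def to_tsv(self, path):
        self.events.to_csv(path, sep="\t", index=False)


def detect_binding_events(trajectory: Trajectory, site_definitions: dict,
                          dna_definitions: dict, d_on: float = 10.0,
                          d_off: float = 15.0) -> BindingEventTable:
    """Hysteretic binding-event detection.

    A DNA copy binds a site when the minimum bead-bead distance drops below
    ``d_on`` and unbinds when it exceeds ``d_off`` (d_off > d_on suppresses
    threshold chatter).  Events still bound at the last frame are censored.
    Overlapping site definitions are allowed but flagged.
    """
    if d_off <= d_on:
        raise ValueError("hysteresis requires d_off > d_on")
    flags = []
    site_items = list(site_definitions.items())
    for a in range(len(site_items)):
        for b in range(a + 1, len(site_items)):
            if np.intersect1d(site_items[a][1], site_items[b][1]).size:
                flags.append(f"sites {site_items[a][0]} and "
                             f"{site_items[b][0]} overlap")
    rows = []
    steps = trajectory.steps
    for site_label, site_idx in site_items:
        site_idx = np.asarray(site_idx, dtype=int)
        for dna_label, dna_idx in dna_definitions.items():
            dna_idx = np.asarray(dna_idx, dtype=int)
            dmin = np.array([cdist(f[site_idx], f[dna_idx]).min()
                             for f in trajectory.positions])
            bound = False
            start = None
            for k in range(len(steps)):
                if not bound and dmin[k] < d_on:
                    bound, start = True, steps[k]
                elif bound and dmin[k] > d_off:
                    rows.append((site_label, dna_label, int(start),
                                 int(steps[k]), False))
                    bound = False
            if bound:
                rows.append((site_label, dna_label, int(start),
                             int(steps[-1]), True))
    df = pd.DataFrame(rows, columns=["site", "dna", "start_step",
                                     "end_step", "censored"])
    return BindingEventTable(events=df, site_definitions=dict(site_definitions),
                             flags=flags)


# ---------------------------------------------------------------------------
# survival analysis
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Kaplan-Meier curve: P(duration >= t) with censoring support."""

    times: np.ndarray        # event times, ascending, prepended with 0
    probs: np.ndarray        # S(t+) right after each time; probs[0] = 1
    n_at_risk: np.ndarray    # at-risk counts at each event time (0 at t=0 slot)
    all_censored: bool = False

    def at(self, t) -> np.ndarray:
        """P(T >= t): the left-continuous Kaplan-Meier step function."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left") - 1
        return self.probs[np.clip(idx, 0, len(self.probs) - 1)]


def survival_curve(events) -> SurvivalCurve:
    """Kaplan-Meier survival of binding durations.

    ``events`` is a :class:`BindingEventTable` or a ``(durations,
    observed)`` pair; censored events contribute to the risk set while
    observed.
    """
    durations, observed = _durations_observed(events)
    if durations.size == 0:
        raise ValueError("empty event table")
    all_censored = not observed.any()
    order = np.argsort(durations, kind="stable")
    durations, observed = durations[order], observed[order]
    times, probs, at_risk = [0.0], [1.0], [0]
    s = 1.0
    for t in np.unique(durations[observed]):
        n_risk = int(np.sum(durations >= t))
        d = int(np.sum((durations == t) & observed))
        s *= 1.0 - d / n_risk
        times.append(float(t))
        probs.append(s)
        at_risk.append(n_risk)
    return SurvivalCurve(np.array(times), np.array(probs),
                         np.array(at_risk), all_censored=all_censored)


def _durations_observed(events):
    if isinstance(events, BindingEventTable):
        return events.durations.astype(float), events.observed
    durations, observed = events
    return (np.asarray(durations, dtype=float),
            np.asarray(observed, dtype=bool))


@dataclass
class RateFit:
    rate: float               # 1/step
    stderr: float | None
    n_events: int
    fit_points: int


def fit_dissociation_rate(events_or_curve, fit_window=(0.1, 1.0),
                          n_bootstrap: int = 200, seed: int = 0) -> RateFit:
    """Dissociation rate from the log-slope of the survival curve.

    Weighted least squares of ln P against t over curve points with P in
    ``fit_window`` (weights: at-risk counts); the rate is the negated
    slope.  When an event table (or durations) is given, the standard error
    comes from bootstrap resampling of events.
    """
    if isinstance(events_or_curve, tuple) and \
            not isinstance(events_or_curve[0], (int, float)) and \
            np.asarray(events_or_curve[1]).dtype.kind == "f":
        # raw (t, P) curve points
        t = np.asarray(events_or_curve[0], dtype=float)
        p = np.asarray(events_or_curve[1], dtype=float)
        rate = _wls_rate(t, p, np.ones_like(t), fit_window)
        return RateFit(rate=rate, stderr=None, n_events=0,
                       fit_points=int(np.sum((p >= fit_window[0])
                                             & (p <= fit_window[1]) & (p > 0))))
    durations, observed = _durations_observed(events_or_curve)
    curve = survival_curve((durations, observed))
    if np.any(np.diff(curve.probs) > 1e-12):
        raise AssertionError("survival curve must be non-increasing")
    rate = _wls_rate(curve.times, curve.probs,
                     np.maximum(curve.n_at_risk, 1), fit_window)
    rng = np.random.default_rng(seed)
    boot = []
    n = durations.size
    for _ in range(n_bootstrap):
        pick = rng.integers(0, n, size=n)
        d_b, o_b = durations[pick], observed[pick]
        if not o_b.any():
            continue
        c = survival_curve((d_b, o_b))
        try:
            boot.append(_wls_rate(c.times, c.probs,
                                  np.maximum(c.n_at_risk, 1), fit_window))
        except ValueError:
            continue
    stderr = float(np.std(boot, ddof=1)) if len(boot) > 2 else None
    return RateFit(rate=rate, stderr=stderr, n_events=int(n),
                   fit_points=len(curve.times))


def _wls_rate(t, p, w, fit_window):
    sel = (p >= fit_window[0]) & (p <= fit_window[1]) & (p > 0) & (t >= 0)
    if np.sum(sel) < 2:
        raise ValueError("need >= 2 curve points inside the fit window")
    x, y, wts = t[sel], np.log(p[sel]), np.asarray(w, dtype=float)[sel]
    W = np.sum(wts)
    xm = np.sum(wts * x) / W
    ym = np.sum(wts * y) / W
    denom = np.sum(wts * (x - xm) ** 2)
    if denom == 0:
        raise ValueError("degenerate time axis in rate fit")
    slope = np.sum(wts * (x - xm) * (y - ym)) / denom
    return float(-slope)


# ---------------------------------------------------------------------------
# Q-scores
# ---------------------------------------------------------------------------

@dataclass
class QScoreSeries:
    values: np.ndarray           # per frame, in [0, 1]
    definition: str              # "native_x1.2" or "protein_dna_15A"


def qscore(native_contacts, contact_r0, positions, tolerance: float = 1.2,
           box=None) -> float:
    """Fraction of native pairs currently within ``tolerance`` times their
    native distance."""
    pairs = np.asarray(native_contacts, dtype=int).reshape(-1, 2)
    if pairs.shape[0] == 0:
        raise ValueError("native contact list is empty")
    r0 = np.asarray(contact_r0, dtype=float)
    d = positions[pairs[:, 1]] - positions[pairs[:, 0]]
    if box is not None:
        d = d - box * np.round(d / box)
    r = np.linalg.norm(d, axis=1)
    return float(np.mean(r < tolerance * r0))


def qscore_series(system: CGSystem, trajectory: Trajectory,
                  contact_mask=None, tolerance: float = 1.2) -> QScoreSeries:
    """Per-frame Q over the (optionally masked) native-contact list."""
    pairs = system.native_contacts
    r0 = system.contact_r0
    if contact_mask is not None:
        mask = np.asarray(contact_mask, dtype=bool)
        pairs, r0 = pairs[mask], r0[mask]
    vals = np.array([qscore(pairs, r0, f, tolerance)
                     for f in trajectory.positions])
    return QScoreSeries(values=vals, definition="native_x1.2")


def qscore_protein_dna(reference_contact_residues, positions,
                       protein_bead_of_residue, dna_indices,
                       cutoff: float = 15.0) -> float:
    """Identity-neglected protein-DNA Q-score.

    ``reference_contact_residues`` lists the protein residues contacting
    DNA in the reference complex; the score is the fraction of them within
    ``cutoff`` of ANY DNA bead in the frame, making the measure robust to
    DNA sliding.
    """
    residues = list(reference_contact_residues)
    if not residues:
        raise ValueError("empty reference contact list")
    dna_idx = np.asarray(dna_indices, dtype=int)
    if dna_idx.size == 0:
        return 0.0
    prot_idx = np.asarray([protein_bead_of_residue[r] for r in residues],
                          dtype=int)
    d = cdist(positions[prot_idx], positions[dna_idx])
    return float(np.mean(d.min(axis=1) <= cutoff))


# ---------------------------------------------------------------------------
# representative structure (PCA-density clustering)
# ---------------------------------------------------------------------------

def representative_structure(trajectory_or_frames, site_residue_indices,
                             dna_indices, radius: float = 10.0,
                             n_components: int = 3):
    """Most-populated frame in PC space of site-to-DNA minimum distances.

    Per frame, the vector of minimum distances from each site residue to
    any DNA bead is computed; frames are projected onto the first
    ``n_components`` principal components (unitless); each frame's
    neighbours within ``radius`` are counted and the frame with the highest
    count is returned (ties: earliest frame).
    """
    from sklearn.decomposition import PCA

    frames = trajectory_or_frames.positions \
        if isinstance(trajectory_or_frames, Trajectory) else \
        np.asarray(trajectory_or_frames, dtype=float)
    if frames.shape[0] < 2:
        raise ValueError("need at least two frames")
    site = np.asarray(site_residue_indices, dtype=int)
    dna = np.asarray(dna_indices, dtype=int)
    dmin = np.array([cdist(f[site], f[dna]).min(axis=1) for f in frames])
    if np.allclose(dmin.std(axis=0), 0.0):
        return 0, {"flag": "degenerate distance vectors; returning frame 0",
                   "neighbor_counts": np.full(frames.shape[0],
                                              frames.shape[0])}
    k = min(n_components, dmin.shape[1], frames.shape[0])
    proj = PCA(n_components=k, svd_solver="full").fit_transform(dmin)
    dd = cdist(proj, proj)
    counts = np.sum(dd <= radius, axis=1)   # includes self, uniformly
    best = int(np.argmax(counts))           # argmax takes the earliest tie
    return best, {"neighbor_counts": counts, "projection": proj}


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def conservation_profile(msa, query_row, exclude_gaps_from_denominator=True):
    """Per-query-residue conservation: fraction of aligned sequences whose
    character matches the query at that column.

    ``msa`` is a list of equal-length aligned strings (or a Biopython
    alignment); ``query_row`` is the index of the query sequence.  Columns
    where the query has a gap are skipped; gap characters in other rows are
    excluded from the denominator unless configured otherwise.
    """
    rows = [str(getattr(r, "seq", r)).upper() for r in msa]
    if not rows or not 0 <= query_row < len(rows):
        raise ValueError("query row absent from the alignment")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("alignment rows differ in length")
    arr = np.array([list(r) for r in rows])
    gaps = (arr == "-") | (arr == ".")
    query = arr[query_row]
    scores = []
    for col in range(length):
        if gaps[query_row, col]:
            continue
        column = arr[:, col]
        if exclude_gaps_from_denominator:
            valid = ~gaps[:, col]
            denom = int(valid.sum())
            match = int(np.sum(column[valid] == query[col]))
        else:
            denom = len(rows)
            match = int(np.sum(column == query[col]))
        scores.append(match / denom if denom else 0.0)
    return np.array(scores)


# ---------------------------------------------------------------------------
# structural hinge angle
# ---------------------------------------------------------------------------

def hinge_angle_from_positions(positions, arm_a_indices, arm_b_indices,
                               n_end: int = 3) -> float:
    """Angle (degrees) between two arm axes.

    Each arm axis runs from the mean of its first ``n_end`` beads (base) to
    the mean of its last ``n_end`` beads (tip).
    """
    def axis(idx):
        idx = np.asarray(idx, dtype=int)
        base = positions[idx[:n_end]].mean(axis=0)
        tip = positions[idx[-n_end:]].mean(axis=0)
        v = tip - base
        return v / np.linalg.norm(v)

    cosv = float(np.clip(axis(arm_a_indices) @ axis(arm_b_indices), -1, 1))
    return float(np.degrees(np.arccos(cosv)))
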