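"""Energies and analytic forces for the coarse-grained model.

Intra-molecular terms are structure-based: harmonic bonds and angles and
periodic dihedrals about their native reference values, plus a 12-10 Go
contact well for native pairs.  Inter-molecular physics between protein and
DNA is screened Debye-Hueckel electrostatics plus excluded volume, which is
the physics that decides where DNA binds.  Energies are kcal/mol, lengths
Angstrom, charges in units of e.

All force routines are analytic and pass central-finite-difference checks
(see the test suite); pair terms obey Newton's third law exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import constants as _si

from . import constants as C
from .system import CGSystem

__all__ = [
    "ElectrostaticParams", "ChargeSet", "ChargeProvenance", "EnergyReport",
    "debye_length", "dh_energy_forces", "bonded_energy_forces",
    "go_contact_energy_forces", "excluded_volume_energy_forces",
    "build_native_contacts", "respac_fit_charges", "shuffle_charges",
    "EnergyModel", "total_energy_forces",
    "measure_angles", "measure_dihedrals",
]


# ---------------------------------------------------------------------------
# parameters / small containers
# ---------------------------------------------------------------------------

@dataclass
class ElectrostaticParams:
    """Salt, temperature and dielectric defining the screened potential."""

    ionic_strength: float = 0.1        # mol/L
    temperature: float = C.DEFAULT_TEMPERATURE   # K
    dielectric: float = C.DEFAULT_DIELECTRIC     # dimensionless
    cutoff_factor: float = C.DEFAULT_DH_CUTOFF_FACTOR  # cutoff = factor * lambda_D

    def __post_init__(self):
        if self.ionic_strength <= 0 or self.temperature <= 0 \
                or self.dielectric <= 0:
            raise ValueError("ionic strength, temperature and dielectric "
                             "must be positive")

    @property
    def debye_length(self) -> float:
        """Debye screening length, A (recomputed from current fields)."""
        return debye_length(self)

    @property
    def coulomb_prefactor(self) -> float:
        """k_e / dielectric, kcal A / (mol e^2)."""
        return C.COULOMB_KCAL / self.dielectric

    @property
    def cutoff(self) -> float:
        return self.cutoff_factor * self.debye_length


def debye_length(params: ElectrostaticParams) -> float:
    """Debye length lambda_D = sqrt(eps0 eps_k kB T / (2 NA e^2 I)), in A.

    ``I`` is the (monovalent) ionic strength in mol/L; SI constants are used
    and the result converted to Angstrom.
    """
    I_si = params.ionic_strength * 1000.0  # mol/m^3
    lam_m = np.sqrt(
        _si.epsilon_0 * params.dielectric * _si.k * params.temperature
        / (2.0 * _si.N_A * _si.e ** 2 * I_si))
    return lam_m * 1e10


class ChargeProvenance(Enum):
    UNIT = "unit"
    RESPAC_FIT = "respac_fit"
    SHUFFLED = "shuffled"


@dataclass
class ChargeSet:
    """Per-bead charges (e) with a provenance tag."""

    values: np.ndarray
    provenance: ChargeProvenance = ChargeProvenance.UNIT

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("charges must be finite")

    @property
    def total_charge(self) -> float:
        return float(self.values.sum())


@dataclass
class EnergyReport:
    """Per-term energies (kcal/mol) and per-bead forces (kcal/mol/A)."""

    terms: dict = field(default_factory=dict)
    forces: np.ndarray | None = None
    flags: list = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def measure_angles(positions, triples) -> np.ndarray:
    """Angles (radians) for index triples i-j-k."""
    triples = np.asarray(triples, dtype=int).reshape(-1, 3)
    if triples.size == 0:
        return np.zeros(0)
    rij = positions[triples[:, 0]] - positions[triples[:, 1]]
    rkj = positions[triples[:, 2]] - positions[triples[:, 1]]
    cosv = np.einsum("ij,ij->i", rij, rkj) / (
        np.linalg.norm(rij, axis=1) * np.linalg.norm(rkj, axis=1))
    return np.arccos(np.clip(cosv, -1.0, 1.0))


def measure_dihedrals(positions, quads) -> np.ndarray:
    """Signed dihedral angles (radians) for index quadruples i-j-k-l."""
    quads = np.asarray(quads, dtype=int).reshape(-1, 4)
    if quads.size == 0:
        return np.zeros(0)
    b1 = positions[quads[:, 1]] - positions[quads[:, 0]]
    b2 = positions[quads[:, 2]] - positions[quads[:, 1]]
    b3 = positions[quads[:, 3]] - positions[quads[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    return np.arctan2(y, x)


def _min_image(d: np.ndarray, box) -> np.ndarray:
    if box is not None:
        d = d - box * np.round(d / box)
    return d


def _cross(a, b):
    """Row-wise cross product (faster than np.cross for (N, 3) arrays)."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _rownorm(a):
    return np.sqrt(np.einsum("ij,ij->i", a, a))


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def bonded_energy_forces(system: CGSystem, positions) -> EnergyReport:
    """Harmonic bonds/angles and periodic dihedrals about native values.

    U_bond = k_b (r - r0)^2, U_angle = k_a (theta - theta0)^2,
    U_dih = k_d (1 - cos(phi - phi0)); all zero at the native structure.
    """
    positions = np.asarray(positions, dtype=float)
    forces = np.zeros_like(positions)
    report = EnergyReport(forces=forces)
    e_bond = e_angle = e_dih = 0.0

    if system.bonds.size:
        i, j = system.bonds[:, 0], system.bonds[:, 1]
        d = positions[j] - positions[i]
        r = _rownorm(d)
        dr = r - system.bond_r0
        e_bond = float(np.sum(system.bond_k * dr ** 2))
        # dU/dr = 2 k dr ; force on j along -dU/dr * u_ij
        f = (-2.0 * system.bond_k * dr / r)[:, None] * d
        np.add.at(forces, j, f)
        np.add.at(forces, i, -f)

    if system.angles.size:
        t = system.angles
        rij = positions[t[:, 0]] - positions[t[:, 1]]
        rkj = positions[t[:, 2]] - positions[t[:, 1]]
        nij = _rownorm(rij)
        nkj = _rownorm(rkj)
        uij = rij / nij[:, None]
        ukj = rkj / nkj[:, None]
        cosv = np.clip(np.einsum("ij,ij->i", uij, ukj), -1.0, 1.0)
        theta = np.arccos(cosv)
        sinv = np.sqrt(1.0 - cosv ** 2)
        collinear = sinv < 1e-8
        if np.any(collinear):
            report.flags.append("collinear angle regularized")
        sinv = np.maximum(sinv, 1e-8)
        dtheta = theta - system.angle_theta0
        e_angle = float(np.sum(system.angle_k * dtheta ** 2))
        dU = 2.0 * system.angle_k * dtheta
        dthe_di = (cosv[:, None] * uij - ukj) / (nij * sinv)[:, None]
        dthe_dk = (cosv[:, None] * ukj - uij) / (nkj * sinv)[:, None]
        fi = -dU[:, None] * dthe_di
        fk = -dU[:, None] * dthe_dk
        np.add.at(forces, t[:, 0], fi)
        np.add.at(forces, t[:, 2], fk)
        np.add.at(forces, t[:, 1], -(fi + fk))

    if system.dihedrals.size:
        q = system.dihedrals
        b1 = positions[q[:, 1]] - positions[q[:, 0]]
        b2 = positions[q[:, 2]] - positions[q[:, 1]]
        b3 = positions[q[:, 3]] - positions[q[:, 2]]
        n1 = _cross(b1, b2)
        n2 = _cross(b2, b3)
        nb2 = _rownorm(b2)
        m = _cross(n1, b2 / nb2[:, None])
        phi = np.arctan2(np.einsum("ij,ij->i", m, n2),
                         np.einsum("ij,ij->i", n1, n2))
        dphi = phi - system.dihedral_phi0
        e_dih = float(np.sum(system.dihedral_k * (1.0 - np.cos(dphi))))
        dU = system.dihedral_k * np.sin(dphi)
        n1sq = np.einsum("ij,ij->i", n1, n1)
        n2sq = np.einsum("ij,ij->i", n2, n2)
        # near-collinear triples make the torsion force singular; floor the
        # normal magnitudes (equivalent to sin(angle) >= ~0.05) and flag
        nb1 = _rownorm(b1)
        nb3 = _rownorm(b3)
        floor1 = (0.05 * nb1 * nb2) ** 2
        floor2 = (0.05 * nb3 * nb2) ** 2
        if np.any(n1sq < floor1) or np.any(n2sq < floor2):
            report.flags.append("near-collinear dihedral regularized")
        n1sq = np.maximum(n1sq, floor1)
        n2sq = np.maximum(n2sq, floor2)
        # gradient of phi (torsion-force expressions, FD-verified)
        dphi_di = (nb2 / n1sq)[:, None] * n1
        dphi_dl = (-nb2 / n2sq)[:, None] * n2
        c12 = np.einsum("ij,ij->i", b1, b2) / nb2 ** 2
        c32 = np.einsum("ij,ij->i", b3, b2) / nb2 ** 2
        dphi_dj = -dphi_di - c12[:, None] * dphi_di + c32[:, None] * dphi_dl
        dphi_dk = -dphi_dl + c12[:, None] * dphi_di - c32[:, None] * dphi_dl
        for col, grad in zip(range(4), (dphi_di, dphi_dj, dphi_dk, dphi_dl)):
            np.add.at(forces, q[:, col], -dU[:, None] * grad)

    report.terms["bond"] = e_bond
    report.terms["angle"] = e_angle
    report.terms["dihedral"] = e_dih
    return report


# ---------------------------------------------------------------------------
# Go contacts
# ---------------------------------------------------------------------------

def go_contact_energy_forces(system: CGSystem, positions,
                             contact_mask=None, box=None) -> EnergyReport:
    """12-10 native-contact well: U = eps [5 (r0/r)^12 - 6 (r0/r)^10].

    Minimum -eps at r = r0; decays to zero at large separation.
    ``contact_mask`` optionally restricts to a subset of the contact list.
    """
    positions = np.asarray(positions, dtype=float)
    forces = np.zeros_like(positions)
    report = EnergyReport(forces=forces)
    pairs = system.native_contacts
    r0 = system.contact_r0
    eps = system.contact_eps
    if contact_mask is not None:
        pairs, r0, eps = pairs[contact_mask], r0[contact_mask], eps[contact_mask]
    if pairs.size == 0:
        report.terms["contact"] = 0.0
        return report
    i, j = pairs[:, 0], pairs[:, 1]
    d = _min_image(positions[j] - positions[i], box)
    r = _rownorm(d)
    if np.any(r < 1e-6):
        raise FloatingPointError("overlapping beads in contact pair")
    s10 = (r0 / r) ** 10
    s12 = s10 * (r0 / r) ** 2
    energy = float(np.sum(eps * (5.0 * s12 - 6.0 * s10)))
    dU_dr = 60.0 * eps / r * (s10 - s12)
    f = (-dU_dr / r)[:, None] * d     # force on j
    np.add.at(forces, j, f)
    np.add.at(forces, i, -f)
    report.terms["contact"] = energy
    return report


# ---------------------------------------------------------------------------
# excluded volume
# ---------------------------------------------------------------------------

def excluded_volume_energy_forces(positions, radii, pairs,
                                  epsilon=C.DEFAULT_EXCLUDED_EPS,
                                  box=None) -> EnergyReport:
    """Purely repulsive core: U = eps [(sigma/r)^12 - 1] for r < sigma,
    zero beyond, with sigma_ij = r_i + r_j.

    ``pairs`` is an (M, 2) index array of the pairs to consider (exclusions
    already removed).
    """
    positions = np.asarray(positions, dtype=float)
    forces = np.zeros_like(positions)
    report = EnergyReport(forces=forces)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if pairs.size == 0:
        report.terms["excluded_volume"] = 0.0
        return report
    i, j = pairs[:, 0], pairs[:, 1]
    sigma = radii[i] + radii[j]
    d = _min_image(positions[j] - positions[i], box)
    r = _rownorm(d)
    if np.any(r < 1e-6):
        raise FloatingPointError("overlapping beads in excluded-volume pair")
    active = r < sigma
    if np.any(active):
        ra, sa, da = r[active], sigma[active], d[active]
        s12 = (sa / ra) ** 12
        energy = float(np.sum(epsilon * (s12 - 1.0)))
        dU_dr = -12.0 * epsilon * s12 / ra
        f = (-dU_dr / ra)[:, None] * da
        np.add.at(forces, j[active], f)
        np.add.at(forces, i[active], -f)
    else:
        energy = 0.0
    report.terms["excluded_volume"] = energy
    return report


# ---------------------------------------------------------------------------
# Debye-Hueckel electrostatics
# ---------------------------------------------------------------------------

def dh_energy_forces(positions, charges, params: ElectrostaticParams,
                     pairs, box=None) -> EnergyReport:
    """Screened Coulomb: U = k_e q_i q_j / (eps_k r) exp(-r / lambda_D),
    truncated at ``params.cutoff`` with an energy shift.

    ``pairs`` lists the interacting pairs (bonded 1-2/1-3 neighbours are
    excluded upstream).
    """
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    forces = np.zeros_like(positions)
    report = EnergyReport(forces=forces)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if pairs.size == 0:
        report.terms["electrostatic"] = 0.0
        return report
    lam = params.debye_length
    rc = params.cutoff
    pref = params.coulomb_prefactor
    i, j = pairs[:, 0], pairs[:, 1]
    qq = charges[i] * charges[j]
    d = _min_image(positions[j] - positions[i], box)
    r = _rownorm(d)
    if np.any(r < 1e-6):
        bad = int(np.argmin(r))
        raise FloatingPointError(
            f"singular charge pair {int(i[bad])}-{int(j[bad])} at r ~ 0")
    active = (r < rc) & (qq != 0.0)
    if np.any(active):
        ra, qa, da = r[active], qq[active], d[active]
        u = pref * qa / ra * np.exp(-ra / lam)
        u_shift = pref * qa / rc * np.exp(-rc / lam)
        energy = float(np.sum(u - u_shift))
        dU_dr = -u * (1.0 / ra + 1.0 / lam)
        f = (-dU_dr / ra)[:, None] * da
        np.add.at(forces, j[active], f)
        np.add.at(forces, i[active], -f)
    else:
        energy = 0.0
    report.terms["electrostatic"] = energy
    return report


# ---------------------------------------------------------------------------
# native contacts
# ---------------------------------------------------------------------------

def build_native_contacts(system: CGSystem, reference_positions,
                          cutoff=C.DEFAULT_CONTACT_CUTOFF,
                          min_sequence_separation=4,
                          cross_chain_separation=0):
    """Unordered unique bead pairs within ``cutoff`` in the reference.

    Pairs within one chain must satisfy |res_i - res_j| >=
    ``min_sequence_separation``; pairs across chains use
    ``cross_chain_separation`` (default 0, i.e. any pair).  Returns
    ``(pairs, r0)``.
    """
    ref = np.asarray(reference_positions, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference coordinates")
    from scipy.spatial.distance import pdist, squareform
    n = ref.shape[0]
    dist = squareform(pdist(ref))
    iu, ju = np.triu_indices(n, k=1)
    same_chain = system.chain_ids[iu] == system.chain_ids[ju]
    sep = np.abs(system.residue_indices[iu] - system.residue_indices[ju])
    min_sep = np.where(same_chain, min_sequence_separation,
                       cross_chain_separation)
    keep = (dist[iu, ju] <= cutoff) & (sep >= min_sep)
    pairs = np.stack([iu[keep], ju[keep]], axis=1)
    return pairs, dist[pairs[:, 0], pairs[:, 1]]


# ---------------------------------------------------------------------------
# surface-charge fitting (RESPAC-style) and the shuffle control
# ---------------------------------------------------------------------------

def respac_fit_charges(sample_points, sample_potentials, positions,
                       surface_bead_indices, total_charge,
                       params: ElectrostaticParams | None = None,
                       ridge=1e-6) -> ChargeSet:
    """Least-squares surface charges reproducing a reference potential.

    Fits per-bead charges q on the surface beads so that the screened
    potential sum_b k_e q_b exp(-r_sb/lambda)/ (eps_k r_sb) matches the
    reference samples, subject to an exact total-charge constraint
    (``total_charge=None`` drops the constraint).  A small ridge term
    guarantees a unique solution; non-surface beads get zero charge.
    """
    params = params or ElectrostaticParams()
    pts = np.asarray(sample_points, dtype=float).reshape(-1, 3)
    phi = np.asarray(sample_potentials, dtype=float)
    surf = np.asarray(surface_bead_indices, dtype=int)
    if surf.size == 0:
        raise ValueError("no surface beads")
    lam = params.debye_length
    pref = params.coulomb_prefactor
    r = np.linalg.norm(pts[:, None, :] - positions[surf][None, :, :], axis=2)
    r = np.maximum(r, 1e-6)
    A = pref * np.exp(-r / lam) / r            # (S, B)
    nb = surf.size
    if total_charge is None:
        sol = np.linalg.solve(A.T @ A + ridge * np.eye(nb), A.T @ phi)
    else:
        # KKT system: min ||A q - phi||^2 + ridge ||q||^2  s.t.  1^T q = Q
        kkt = np.zeros((nb + 1, nb + 1))
        kkt[:nb, :nb] = 2.0 * (A.T @ A + ridge * np.eye(nb))
        kkt[:nb, nb] = 1.0
        kkt[nb, :nb] = 1.0
        rhs = np.concatenate([2.0 * A.T @ phi, [float(total_charge)]])
        sol = np.linalg.solve(kkt, rhs)
    values = np.zeros(positions.shape[0])
    values[surf] = sol[:nb]
    return ChargeSet(values=values, provenance=ChargeProvenance.RESPAC_FIT)


def surface_beads_by_samples(positions, sample_points, radius=12.0):
    """Heuristic surface set: beads with >= 1 sample point within ``radius``."""
    pts = np.asarray(sample_points, dtype=float).reshape(-1, 3)
    d = np.linalg.norm(np.asarray(positions)[:, None, :] - pts[None, :, :],
                       axis=2)
    return np.flatnonzero((d <= radius).any(axis=1))


def shuffle_charges(charge_set: ChargeSet, seed, indices=None) -> ChargeSet:
    """Random permutation of the charge values among charged beads.

    Preserves the multiset of values (hence the total charge) exactly;
    deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    values = charge_set.values.copy()
    idx = np.flatnonzero(values != 0.0) if indices is None \
        else np.asarray(indices, dtype=int)
    values[idx] = values[idx][rng.permutation(idx.size)]
    return ChargeSet(values=values, provenance=ChargeProvenance.SHUFFLED)


# ---------------------------------------------------------------------------
# aggregated model
# ---------------------------------------------------------------------------

class EnergyModel:
    """Assembled energy/force evaluator for one system.

    Precomputes exclusion-aware nonbonded pair lists: Debye-Hueckel excludes
    1-2 and 1-3 bonded neighbours; excluded volume additionally skips native
    contact pairs (whose repulsive core lives in the 12-10 well).  An
    optional AFM restraint term is evaluated through :mod:`hingeflex.afm`.
    """

    def __init__(self, system: CGSystem, charges=None,
                 electrostatics: ElectrostaticParams | None = None,
                 restraint=None,
                 excluded_epsilon=C.DEFAULT_EXCLUDED_EPS,
                 temperature=C.DEFAULT_TEMPERATURE,
                 enable_electrostatics=True):
        self.system = system
        if charges is None:
            charge_values = system.charges
        elif isinstance(charges, ChargeSet):
            charge_values = charges.values
        else:
            charge_values = np.asarray(charges, dtype=float)
        self.charges = charge_values
        self.electrostatics = electrostatics
        self.restraint = restraint
        self.excluded_epsilon = excluded_epsilon
        self.temperature = temperature
        self.enable_electrostatics = enable_electrostatics and \
            electrostatics is not None
        self._build_pairs()

    def _build_pairs(self):
        sys_ = self.system
        n = sys_.n_beads
        excl = set()
        adj = [[] for _ in range(n)]
        for i, j in sys_.bonds:
            adj[i].append(j)
            adj[j].append(i)
            excl.add((min(i, j), max(i, j)))
        for i in range(n):                      # 1-3 neighbours
            for a in adj[i]:
                for b in adj[i]:
                    if a < b:
                        excl.add((a, b))
        excl14 = set()                          # 1-4 neighbours (EV only)
        for i, j in sys_.bonds:
            for a in adj[i]:
                for b in adj[j]:
                    if a != j and b != i and a != b:
                        excl14.add((min(a, b), max(a, b)))
        iu, ju = np.triu_indices(n, k=1)
        flat = iu.astype(np.int64) * n + ju
        keep = np.ones(iu.size, dtype=bool)
        if excl:
            excl_flat = np.array([a * n + b for a, b in excl], dtype=np.int64)
            keep &= ~np.isin(flat, excl_flat)
        pairs = np.stack([iu[keep], ju[keep]], axis=1)
        # DH acts on charged pairs beyond the 1-2/1-3 exclusions
        q = self.charges
        charged = (q[pairs[:, 0]] * q[pairs[:, 1]]) != 0.0
        self.dh_pairs = pairs[charged]
        # EV additionally skips 1-4 neighbours and native-contact pairs
        # (their repulsive core lives in the bonded terms / 12-10 well)
        ev_excl = set(excl14)
        if sys_.native_contacts.size:
            ev_excl.update((int(a), int(b))
                           for a, b in sys_.native_contacts)
        pflat = pairs[:, 0].astype(np.int64) * n + pairs[:, 1]
        if ev_excl:
            eflat = np.array([a * n + b for a, b in ev_excl],
                             dtype=np.int64)
            self.ev_pairs = pairs[~np.isin(pflat, eflat)]
        else:
            self.ev_pairs = pairs

    def energy_forces(self, positions, include_restraint=True) -> EnergyReport:
        sys_ = self.system
        box = sys_.box
        report = EnergyReport(forces=np.zeros_like(np.asarray(positions,
                                                              dtype=float)))
        parts = [bonded_energy_forces(sys_, positions),
                 go_contact_energy_forces(sys_, positions, box=box),
                 excluded_volume_energy_forces(
                     positions, sys_.radii, self.ev_pairs,
                     epsilon=self.excluded_epsilon, box=box)]
        if self.enable_electrostatics:
            parts.append(dh_energy_forces(positions, self.charges,
                                          self.electrostatics,
                                          self.dh_pairs, box=box))
        if self.restraint is not None and include_restraint:
            from .afm import afm_restraint_energy_forces
            parts.append(afm_restraint_energy_forces(
                positions, sys_.radii, self.restraint, self.temperature))
        for part in parts:
            report.terms.update(part.terms)
            report.forces += part.forces
            report.flags.extend(part.flags)
        return report


def total_energy_forces(system: CGSystem, positions, charge_set=None,
                        params: ElectrostaticParams | None = None,
                        afm_restraint=None,
                        temperature=C.DEFAULT_TEMPERATURE) -> EnergyReport:
    """One-shot sum of all enabled terms (convenience over EnergyModel)."""
    model = EnergyModel(system, charges=charge_set, electrostatics=params,
                        restraint=afm_restraint, temperature=temperature)
    return model.energy_forces(positions)
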