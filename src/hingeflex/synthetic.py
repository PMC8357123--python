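"""Synthetic fixtures with the statistical structure the analysis assumes.

Every generator embeds its ground truth in metadata so downstream recovery
tests read the truth rather than re-deriving it.  The toy systems are
deliberately small (tens of beads) so that build -> simulate -> analyze
loops run in seconds to minutes on one CPU; they mimic the topology of the
real systems (two arms joined at a globular junction, positively charged
inner faces, B-form duplexes) but not their size or sequence detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .afm import AFMImage
from .system import BeadClass, CGSystem
from .structures import rigid_transform

__all__ = ["ToyHingeSpec", "make_toy_hinge", "open_hinge", "synth_afm_image",
           "synth_dwell_times", "make_patch_protein", "make_torus",
           "grid_for", "render_reference_image"]


# ---------------------------------------------------------------------------
# toy hinge
# ---------------------------------------------------------------------------

@dataclass
class ToyHingeSpec:
    """Two helical arms joined by a soft junction loop (single chain).

    The closed (native) inter-arm angle, arm helix geometry and the charge
    decoration of the inner faces are configurable; charges are in e.
    """

    beads_per_arm: int = 10
    arm_rise: float = 1.7             # A per bead along the arm axis
    helix_radius: float = 2.3         # A
    twist_deg: float = 99.0           # deg per bead
    closed_angle_deg: float = 30.0    # native inter-arm angle
    junction_beads: int = 3
    junction_halfwidth: float = 3.2   # A, base separation / arc radius
    z_offset: float = 4.5             # A above the stage plane
    charge_decoration: list = field(default_factory=lambda: [
        ("A", 3, 0.5), ("A", 5, 0.5), ("A", 7, 0.5),
        ("B", 3, 0.5), ("B", 5, 0.5), ("B", 7, 0.5)])
    contact_cutoff: float = 8.0
    contact_eps: float = 1.5
    junction_angle_k: float = 2.0     # soft hinge loop
    junction_dihedral_k: float = 0.2
    arm_angle_k: float = 20.0
    arm_dihedral_k: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.beads_per_arm < 5:
            raise ValueError("need at least 5 beads per arm")
        if not 0.0 < self.closed_angle_deg < 180.0:
            raise ValueError("closed angle must be in (0, 180) degrees")


def make_toy_hinge(spec: ToyHingeSpec | None = None) -> CGSystem:
    """Build the toy hinge with native contacts and bonded topology.

    Bead order along the single chain is arm A (tip -> base), junction
    loop, arm B (base -> tip).  Inter-arm native contacts exist only near
    the junction interface, so opening the hinge breaks inter-arm contacts
    while intra-arm contacts persist.  Metadata records the arm/junction
    index sets, contact-class masks, charged (inner-face) beads, and the
    native angle.
    """
    spec = spec or ToyHingeSpec()
    half = np.deg2rad(spec.closed_angle_deg / 2.0)
    n = spec.beads_per_arm
    w = spec.junction_halfwidth

    def arm_positions(sign):
        u = np.array([sign * np.sin(half), np.cos(half), 0.0])
        e1 = np.cross([0.0, 0.0, 1.0], u)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        base = np.array([sign * w, 0.0, 0.0])
        out = []
        for j in range(n):
            phase = np.deg2rad(spec.twist_deg) * j
            out.append(base + u * (j + 1) * spec.arm_rise
                       + spec.helix_radius * (np.cos(phase) * e1
                                              + np.sin(phase) * e2))
        return np.array(out)

    arm_a = arm_positions(+1.0)
    arm_b = arm_positions(-1.0)
    # junction loop: arc below the bases from the A side to the B side
    arc_angles = np.linspace(0.0, -np.pi, spec.junction_beads + 2)[1:-1]
    junction = np.stack([w * np.cos(arc_angles),
                         w * np.sin(arc_angles) * 0.9,
                         np.zeros_like(arc_angles)], axis=1)

    positions = np.concatenate([arm_a[::-1], junction, arm_b], axis=0)
    positions[:, 2] += spec.z_offset
    n_total = positions.shape[0]
    arm_a_idx = np.arange(n)[::-1]               # base -> tip order
    junction_idx = np.arange(n, n + spec.junction_beads)
    arm_b_idx = np.arange(n + spec.junction_beads, n_total)

    system = CGSystem(
        positions=positions,
        chain_ids=np.full(n_total, "H", dtype="U4"),
        residue_indices=np.arange(1, n_total + 1),
        bead_classes=np.full(n_total, int(BeadClass.CA)),
        charges=np.zeros(n_total),
        radii=np.full(n_total, C.DEFAULT_RADIUS_CA),
    )

    bonds = [(i, i + 1) for i in range(n_total - 1)]
    angles = [(i, i + 1, i + 2) for i in range(n_total - 2)]
    dihedrals = [(i, i + 1, i + 2, i + 3) for i in range(n_total - 3)]
    junction_set = set(junction_idx.tolist())

    def stiffness(tuple_, soft, stiff):
        return soft if junction_set.intersection(tuple_) else stiff

    from .structures import _set_bonded_terms
    _set_bonded_terms(
        system, bonds, angles, dihedrals,
        angle_k=[stiffness(a, spec.junction_angle_k, spec.arm_angle_k)
                 for a in angles],
        dihedral_k=[stiffness(d, spec.junction_dihedral_k,
                              spec.arm_dihedral_k) for d in dihedrals])

    from .forcefield import build_native_contacts
    contacts, r0 = build_native_contacts(
        system, positions, cutoff=spec.contact_cutoff,
        min_sequence_separation=3)
    system.native_contacts = contacts
    system.contact_r0 = r0
    system.contact_eps = np.full(len(r0), spec.contact_eps)

    in_a = np.isin(contacts, arm_a_idx)
    in_b = np.isin(contacts, arm_b_idx)
    inter_mask = (in_a[:, 0] & in_b[:, 1]) | (in_b[:, 0] & in_a[:, 1])
    intra_mask = (in_a[:, 0] & in_a[:, 1]) | (in_b[:, 0] & in_b[:, 1])

    charged = []
    for arm, local_idx, q in spec.charge_decoration:
        idx = (arm_a_idx if arm == "A" else arm_b_idx)[local_idx]
        system.charges[idx] += q
        charged.append(int(idx))

    system.metadata.update({
        "arm_a": arm_a_idx, "arm_b": arm_b_idx, "junction": junction_idx,
        "interarm_contact_mask": inter_mask,
        "intraarm_contact_mask": intra_mask,
        "inner_face": np.array(charged, dtype=int),
        "truth": {"closed_angle_deg": spec.closed_angle_deg,
                  "total_charge": float(system.charges.sum()),
                  "seed": spec.seed},
    })
    return system


def add_dna_to_hinge(hinge: CGSystem, duplex: CGSystem,
                     center=(0.0, 14.0, 17.0)) -> CGSystem:
    """Merge a duplex (centred at ``center``, hovering over the junction
    mouth next to the charged inner faces) into a toy-hinge system, keeping
    the hinge metadata masks consistent.  The default places a short duplex
    clear of steric overlap with the open arms."""
    from .system import merge_systems

    dna = duplex.copy()
    dna.positions = duplex.positions - duplex.positions.mean(axis=0) \
        + np.asarray(center, dtype=float)
    merged = merge_systems(hinge, dna)
    pad = np.zeros(len(merged.contact_r0), dtype=bool)
    for key in ("interarm_contact_mask", "intraarm_contact_mask"):
        mask = pad.copy()
        mask[:len(hinge.contact_r0)] = hinge.metadata[key]
        merged.metadata[key] = mask
    for key in ("arm_a", "arm_b", "junction", "inner_face", "truth"):
        merged.metadata[key] = hinge.metadata[key]
    return merged


def open_hinge(system: CGSystem, delta_deg: float) -> CGSystem:
    """Open the toy hinge by rigidly rotating arm B about the junction.

    The rotation axis is z through the base bead of arm B, so the arm
    stays at its height above the stage; the inter-arm angle grows by
    ``delta_deg``.
    """
    arm_b = system.metadata["arm_b"]
    pivot = system.positions[arm_b[0]]
    a = np.deg2rad(delta_deg)
    Rz = np.array([[np.cos(a), -np.sin(a), 0.0],
                   [np.sin(a), np.cos(a), 0.0],
                   [0.0, 0.0, 1.0]])
    opened = rigid_transform(system, arm_b, Rz, np.zeros(3), center=pivot)
    truth = dict(opened.metadata.get("truth", {}))
    truth["opened_by_deg"] = float(delta_deg)
    opened.metadata["truth"] = truth
    return opened


# ---------------------------------------------------------------------------
# synthetic AFM images
# ---------------------------------------------------------------------------

def synth_afm_image(arm_angle_deg: float, arm_length_px: int = 12,
                    noise_sd: float = 0.0, pixel_size: float = 3.0,
                    seed=None, arm_height: float = 6.5,
                    arm_width_px: float = 1.2,
                    junction_bump: float = 1.5) -> AFMImage:
    """Two Gaussian-cross-section rod ridges meeting at a bright junction.

    The arms extend from the image centre at +/- half the requested angle
    about the +x axis; additive Gaussian noise with ``noise_sd`` (A) is
    applied and heights clipped at zero.  The ground-truth angle is stored
    in the image metadata.
    """
    if not 0.0 < arm_angle_deg <= 180.0:
        raise ValueError("angle must be in (0, 180] degrees")
    size = 2 * arm_length_px + 9
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    px = xx - c
    py = yy - c

    def ridge(theta_deg):
        t = np.deg2rad(theta_deg)
        u = np.array([np.cos(t), np.sin(t)])
        along = px * u[0] + py * u[1]
        perp = -px * u[1] + py * u[0]
        s = np.clip(along, 0.0, float(arm_length_px))
        d2 = (along - s) ** 2 + perp ** 2
        return arm_height * np.exp(-d2 / (2.0 * arm_width_px ** 2))

    h = np.maximum(ridge(arm_angle_deg / 2.0), ridge(-arm_angle_deg / 2.0))
    h += junction_bump * np.exp(-(px ** 2 + py ** 2) / (2.0 * 1.5 ** 2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        h = h + rng.normal(scale=noise_sd, size=h.shape)
    h = np.maximum(h, 0.0)
    return AFMImage(h, pixel_size,
                    origin=(-(size / 2.0) * pixel_size,
                            -(size / 2.0) * pixel_size),
                    metadata={"true_angle_deg": float(arm_angle_deg),
                              "noise_sd": float(noise_sd), "seed": seed})


def grid_for(center_xy, n_px: int, pixel_size: float) -> AFMImage:
    """An all-zero image grid of ``n_px`` x ``n_px`` centred on a point."""
    cx, cy = center_xy
    return AFMImage(np.zeros((n_px, n_px)) , pixel_size,
                    origin=(cx - n_px * pixel_size / 2.0,
                            cy - n_px * pixel_size / 2.0))


def render_reference_image(system: CGSystem, n_px: int = 24,
                           pixel_size: float = 3.0, beta: float = 2.0,
                           center_xy=None) -> AFMImage:
    """Render a (noise-free) pseudo-AFM image of a structure to use as a
    fitting reference; the grid is centred on the structure footprint."""
    from .afm import render_pseudo_afm, TipModel

    if center_xy is None:
        center_xy = system.positions[:, :2].mean(axis=0)
    grid = grid_for(center_xy, n_px, pixel_size)
    img = render_pseudo_afm(system.positions, system.radii, grid,
                            TipModel(), beta=beta)
    truth = system.metadata.get("truth", {})
    img.metadata = {"rendered_from_truth": dict(truth)}
    return img


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------

def synth_dwell_times(rate: float, n: int, censor_at: float | None = None,
                      seed=None):
    """Exponential dwell-time sample with optional right-censoring.

    Returns ``(durations, observed)``; censored draws are truncated at
    ``censor_at`` with ``observed = False``.  Deterministic per seed.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    durations = rng.exponential(scale=1.0 / rate, size=n)
    if censor_at is None:
        return durations, np.ones(n, dtype=bool)
    observed = durations < censor_at
    return np.minimum(durations, censor_at), observed


# ---------------------------------------------------------------------------
# other protocol toys
# ---------------------------------------------------------------------------

def make_patch_protein(side: int = 3, spacing: float = 4.5,
                       patch_charge: float = 0.6,
                       n_patch: int = 3) -> CGSystem:
    """A small rigid slab of beads with a cationic patch on one edge.

    ``side`` x ``side`` beads on a square grid, serpentine chain path,
    densely cross-linked by native contacts; the first ``n_patch`` beads of
    the top row carry ``patch_charge`` each.  Metadata records the patch.
    """
    n = side * side
    pos = np.zeros((n, 3))
    order = []
    for row in range(side):
        cols = range(side) if row % 2 == 0 else range(side - 1, -1, -1)
        for col in cols:
            order.append((row, col))
    for k, (row, col) in enumerate(order):
        pos[k] = (col * spacing, row * spacing, 0.0)
    system = CGSystem(
        positions=pos,
        chain_ids=np.full(n, "P", dtype="U4"),
        residue_indices=np.arange(1, n + 1),
        bead_classes=np.full(n, int(BeadClass.CA)),
        charges=np.zeros(n),
        radii=np.full(n, C.DEFAULT_RADIUS_CA),
    )
    bonds = [(i, i + 1) for i in range(n - 1)]
    angles = [(i, i + 1, i + 2) for i in range(n - 2)]
    dihedrals = [(i, i + 1, i + 2, i + 3) for i in range(n - 3)]
    from .structures import _set_bonded_terms
    _set_bonded_terms(system, bonds, angles, dihedrals)
    from .forcefield import build_native_contacts
    contacts, r0 = build_native_contacts(system, pos, cutoff=1.6 * spacing,
                                         min_sequence_separation=2)
    system.native_contacts = contacts
    system.contact_r0 = r0
    system.contact_eps = np.full(len(r0), 2.0)
    top_row = [k for k, (row, _) in enumerate(order) if row == side - 1]
    patch = np.array(top_row[:n_patch], dtype=int)
    system.charges[patch] = patch_charge
    system.metadata.update({"patch": patch,
                            "truth": {"patch_charge": patch_charge,
                                      "n_patch": int(n_patch)}})
    return system


def make_random_chain(n: int = 30, seed: int = 0,
                      charged_fraction: float = 0.5) -> CGSystem:
    """A random self-avoiding-ish bonded chain with contacts and charges.

    Used as a generic workbench for force/gradient checks: ~3.8 A steps,
    full bonded topology, native contacts from the generated geometry, and
    random unit charges on a fraction of the beads.
    """
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, 3))
    for i in range(1, n):
        step = rng.normal(size=3)
        pos[i] = pos[i - 1] + 3.8 * step / np.linalg.norm(step)
    charges = np.where(rng.random(n) < charged_fraction,
                       rng.choice([-1.0, 1.0], size=n), 0.0)
    system = CGSystem(
        positions=pos, chain_ids=np.full(n, "A", dtype="U4"),
        residue_indices=np.arange(1, n + 1),
        bead_classes=np.full(n, int(BeadClass.CA)),
        charges=charges, radii=np.full(n, C.DEFAULT_RADIUS_CA))
    from .structures import _set_bonded_terms
    bonds = [(i, i + 1) for i in range(n - 1)]
    angles = [(i, i + 1, i + 2) for i in range(n - 2)]
    dihedrals = [(i, i + 1, i + 2, i + 3) for i in range(n - 3)]
    _set_bonded_terms(system, bonds, angles, dihedrals)
    from .forcefield import build_native_contacts
    contacts, r0 = build_native_contacts(system, pos, cutoff=8.0,
                                         min_sequence_separation=4)
    system.native_contacts = contacts
    system.contact_r0 = r0
    system.contact_eps = np.full(len(r0), 1.0)
    return system


def make_bound_patch_complex(patch_charge: float = 1.5,
                             dna_sequence: str = "ATG",
                             offset: float = 12.5,
                             box_edge: float = 80.0):
    """A patch protein with a short duplex pre-bound at the cationic patch.

    Starting from the bound pose makes dissociation (rather than
    diffusion-limited association) the observable, which is what the
    salt-dependent dwell-time assays measure.  Returns the merged system;
    metadata carries the patch (site) bead indices and the DNA bead range.
    """
    from .system import merge_systems

    prot = make_patch_protein(patch_charge=patch_charge)
    from .structures import build_bdna_duplex
    dna = build_bdna_duplex(dna_sequence)
    dnac = dna.copy()
    R = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
    dnac.positions = dna.positions @ R.T      # duplex axis along x
    pc = prot.positions[prot.metadata["patch"]].mean(axis=0)
    dnac.positions += pc + np.array([0.0, offset, 0.0]) \
        - dnac.positions.mean(axis=0)
    merged = merge_systems(prot, dnac)
    merged.positions += box_edge / 2.0 - merged.positions.mean(axis=0)
    merged.metadata["site"] = prot.metadata["patch"]
    merged.metadata["dna_indices"] = np.arange(prot.n_beads, merged.n_beads)
    merged.metadata["box"] = (box_edge,) * 3
    return merged


def make_torus(n_beads: int = 8, ring_radius: float = 12.0,
               bead_charge: float = 0.4) -> CGSystem:
    """A closed bead ring in the x-y plane centred on the z axis.

    Threaded over a duplex built along z it traps the DNA topologically:
    it can only leave by sliding off an end.
    """
    ang = 2.0 * np.pi * np.arange(n_beads) / n_beads
    pos = np.stack([ring_radius * np.cos(ang), ring_radius * np.sin(ang),
                    np.zeros(n_beads)], axis=1)
    system = CGSystem(
        positions=pos,
        chain_ids=np.full(n_beads, "T", dtype="U4"),
        residue_indices=np.arange(1, n_beads + 1),
        bead_classes=np.full(n_beads, int(BeadClass.CA)),
        charges=np.full(n_beads, bead_charge),
        radii=np.full(n_beads, C.DEFAULT_RADIUS_CA),
    )
    bonds = [(i, (i + 1) % n_beads) for i in range(n_beads)]
    angles = [(i, (i + 1) % n_beads, (i + 2) % n_beads)
              for i in range(n_beads)]
    from .structures import _set_bonded_terms
    _set_bonded_terms(system, bonds, angles, [])
    # cross-ring contacts keep the ring from collapsing
    from .forcefield import build_native_contacts
    contacts, r0 = build_native_contacts(
        system, pos, cutoff=2.2 * ring_radius, min_sequence_separation=3)
    system.native_contacts = contacts
    system.contact_r0 = r0
    system.contact_eps = np.full(len(r0), 2.0)
    system.metadata["truth"] = {"ring_radius": ring_radius,
                                "bead_charge": bead_charge}
    return system
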