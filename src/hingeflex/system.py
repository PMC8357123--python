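"""Core containers: coarse-grained beads, systems, and trajectories.

A :class:`CGSystem` is a struct-of-arrays: positions, charges, radii and
identity arrays plus bonded topology (bonds / angles / dihedrals with
reference values) and a native-contact list.  One protein residue maps to a
single CA bead; one DNA nucleotide maps to a PHOSPHATE/SUGAR/BASE triplet
(the 5' terminal phosphate is omitted by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterator

import numpy as np

from . import constants as C


class BeadClass(IntEnum):
    CA = 0
    PHOSPHATE = 1
    SUGAR = 2
    BASE = 3


@dataclass(frozen=True)
class CGBead:
    """A single coarse-grained bead (a read-only view row of a CGSystem)."""

    index: int
    chain_id: str
    residue_index: int
    bead_class: BeadClass
    position: np.ndarray     # (3,) A
    charge: float            # e
    radius: float            # A


def _empty(shape, dtype=float):
    return np.zeros(shape, dtype=dtype)


@dataclass
class CGSystem:
    """Coarse-grained system: beads + bonded topology + native contacts.

    All index arrays refer to bead order.  ``bond_k`` etc. allow per-term
    coefficients; builders fill them with the package defaults.
    """

    positions: np.ndarray                     # (N, 3) A
    chain_ids: np.ndarray                     # (N,) unicode
    residue_indices: np.ndarray               # (N,) int
    bead_classes: np.ndarray                  # (N,) int (BeadClass)
    charges: np.ndarray                       # (N,) e
    radii: np.ndarray                         # (N,) A
    residue_names: np.ndarray | None = None   # (N,) unicode, optional

    bonds: np.ndarray = field(default_factory=lambda: _empty((0, 2), int))
    bond_r0: np.ndarray = field(default_factory=lambda: _empty(0))
    bond_k: np.ndarray = field(default_factory=lambda: _empty(0))
    angles: np.ndarray = field(default_factory=lambda: _empty((0, 3), int))
    angle_theta0: np.ndarray = field(default_factory=lambda: _empty(0))
    angle_k: np.ndarray = field(default_factory=lambda: _empty(0))
    dihedrals: np.ndarray = field(default_factory=lambda: _empty((0, 4), int))
    dihedral_phi0: np.ndarray = field(default_factory=lambda: _empty(0))
    dihedral_k: np.ndarray = field(default_factory=lambda: _empty(0))

    native_contacts: np.ndarray = field(default_factory=lambda: _empty((0, 2), int))
    contact_r0: np.ndarray = field(default_factory=lambda: _empty(0))
    contact_eps: np.ndarray = field(default_factory=lambda: _empty(0))

    box: np.ndarray | None = None             # (3,) edge lengths, A
    metadata: dict = field(default_factory=dict)

    # ------------------------------------------------------------------

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = self.positions.shape[0]
        self.chain_ids = np.asarray(self.chain_ids)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.bead_classes = np.asarray(self.bead_classes, dtype=int)
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        for name in ("chain_ids", "residue_indices", "bead_classes",
                     "charges", "radii"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match positions")
        if np.any(self.radii <= 0):
            raise ValueError("bead radii must be positive")
        self.validate_topology()

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def validate_topology(self) -> None:
        n = self.n_beads
        for name in ("bonds", "angles", "dihedrals", "native_contacts"):
            idx = getattr(self, name)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"{name} contain out-of-range bead indices")
        if self.contact_r0.size and np.any(self.contact_r0 <= 0):
            raise ValueError("native-contact r0 must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("box edges must be positive")

    # ------------------------------------------------------------------

    def beads(self) -> Iterator[CGBead]:
        """Iterate over beads as read-only records."""
        for i in range(self.n_beads):
            yield CGBead(
                index=i,
                chain_id=str(self.chain_ids[i]),
                residue_index=int(self.residue_indices[i]),
                bead_class=BeadClass(int(self.bead_classes[i])),
                position=self.positions[i].copy(),
                charge=float(self.charges[i]),
                radius=float(self.radii[i]),
            )

    def chain_indices(self, chain_id: str) -> np.ndarray:
        """Bead indices belonging to one chain."""
        return np.flatnonzero(self.chain_ids == chain_id)

    @property
    def chains(self) -> dict[str, np.ndarray]:
        return {str(c): self.chain_indices(c)
                for c in dict.fromkeys(self.chain_ids.tolist())}

    def select(self, chain_selection) -> np.ndarray:
        """Resolve a selection (chain id, list of chain ids, or index array)
        to a bead-index array."""
        if isinstance(chain_selection, str):
            idx = self.chain_indices(chain_selection)
        elif isinstance(chain_selection, (list, tuple)) and all(
                isinstance(c, str) for c in chain_selection):
            idx = np.flatnonzero(np.isin(self.chain_ids, chain_selection))
        else:
            idx = np.asarray(chain_selection, dtype=int)
        return idx

    def copy(self) -> "CGSystem":
        new = replace(self)
        for name in ("positions", "chain_ids", "residue_indices",
                     "bead_classes", "charges", "radii", "bonds", "bond_r0",
                     "bond_k", "angles", "angle_theta0", "angle_k",
                     "dihedrals", "dihedral_phi0", "dihedral_k",
                     "native_contacts", "contact_r0", "contact_eps"):
            setattr(new, name, getattr(self, name).copy())
        if self.residue_names is not None:
            new.residue_names = self.residue_names.copy()
        new.box = None if self.box is None else self.box.copy()
        new.metadata = dict(self.metadata)
        return new


def merge_systems(a: CGSystem, b: CGSystem) -> CGSystem:
    """Concatenate two systems (bead indices of ``b`` are offset)."""
    off = a.n_beads

    def cat(x, y):
        return np.concatenate([x, y], axis=0)

    names = None
    if a.residue_names is not None or b.residue_names is not None:
        na = a.residue_names if a.residue_names is not None else \
            np.full(a.n_beads, "UNK")
        nb = b.residue_names if b.residue_names is not None else \
            np.full(b.n_beads, "UNK")
        names = cat(np.asarray(na), np.asarray(nb))

    merged = CGSystem(
        positions=cat(a.positions, b.positions),
        chain_ids=cat(a.chain_ids, b.chain_ids),
        residue_indices=cat(a.residue_indices, b.residue_indices),
        bead_classes=cat(a.bead_classes, b.bead_classes),
        charges=cat(a.charges, b.charges),
        radii=cat(a.radii, b.radii),
        residue_names=names,
        bonds=cat(a.bonds, b.bonds + off),
        bond_r0=cat(a.bond_r0, b.bond_r0),
        bond_k=cat(a.bond_k, b.bond_k),
        angles=cat(a.angles, b.angles + off),
        angle_theta0=cat(a.angle_theta0, b.angle_theta0),
        angle_k=cat(a.angle_k, b.angle_k),
        dihedrals=cat(a.dihedrals, b.dihedrals + off),
        dihedral_phi0=cat(a.dihedral_phi0, b.dihedral_phi0),
        dihedral_k=cat(a.dihedral_k, b.dihedral_k),
        native_contacts=cat(a.native_contacts, b.native_contacts + off),
        contact_r0=cat(a.contact_r0, b.contact_r0),
        contact_eps=cat(a.contact_eps, b.contact_eps),
        box=None if a.box is None else a.box.copy(),
        metadata={**a.metadata, **b.metadata},
    )
    return merged


@dataclass
class Trajectory:
    """Saved frames of a simulation run.

    ``steps`` are strictly increasing integration step numbers and
    ``positions`` has one row of shape (n_beads, 3) per frame (unwrapped
    coordinates).  ``logs`` holds per-frame scalar series (energy terms,
    restraint similarity, ...).
    """

    steps: np.ndarray                 # (S,)
    positions: np.ndarray             # (S, N, 3)
    seed: int | None = None
    config: dict = field(default_factory=dict)
    logs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.steps = np.asarray(self.steps, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.steps.ndim != 1 or self.positions.ndim != 3 or \
                self.positions.shape[0] != self.steps.shape[0]:
            raise ValueError("frames and step numbers are inconsistent")
        if self.steps.size > 1 and np.any(np.diff(self.steps) <= 0):
            raise ValueError("step numbers must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.steps.shape[0]

    @property
    def save_interval(self) -> int:
        if self.n_frames < 2:
            return 1
        return int(self.steps[1] - self.steps[0])
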