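"""Structure I/O and builders: CA protein models, ideal B-DNA duplexes,
rigid placement, and PDB / trajectory round-trips.

PDB parsing and writing go through :mod:`biotite`; FASTA through Biopython.
Coordinates are Angstrom, right-handed axes.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from . import constants as C
from .system import BeadClass, CGSystem, Trajectory

__all__ = [
    "load_ca_model",
    "build_bdna_duplex",
    "rigid_transform",
    "write_structure",
    "read_structure",
    "write_trajectory",
    "read_trajectory",
    "read_fasta_sequence",
    "assign_unit_charges",
]

#: maximum Calpha-Calpha distance regarded as a peptide bond, A
CHAIN_BREAK_DISTANCE = 4.5

_POSITIVE = {"ARG", "LYS"}
_NEGATIVE = {"ASP", "GLU"}

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# protein CA model
# ---------------------------------------------------------------------------

def load_ca_model(pdb_source, chain_selection=None) -> CGSystem:
    """Build a one-bead-per-residue CA model from a PDB file.

    Each amino acid becomes one bead at its Calpha position.  Sequential
    residues of a chain are bonded; angles (triples) and dihedrals
    (quadruples) follow consecutive bonded runs.  A residue-numbering gap or
    a Calpha-Calpha distance above 4.5 A breaks the bonded run.  Alternate
    locations are resolved by highest occupancy.

    Parameters
    ----------
    pdb_source : path, str (path or PDB text), or file-like
    chain_selection : optional chain id or list of chain ids
    """
    pdb_file = _read_pdb(pdb_source)
    atoms = pdbio.get_structure(pdb_file, model=1, altloc="occupancy")
    mask = struc.filter_amino_acids(atoms) & (atoms.atom_name == "CA")
    if chain_selection is not None:
        chains = [chain_selection] if isinstance(chain_selection, str) \
            else list(chain_selection)
        mask &= np.isin(atoms.chain_id, chains)
    ca = atoms[mask]
    if ca.array_length() == 0:
        raise ValueError("no Calpha atoms in the selected chains")

    n = ca.array_length()
    system = CGSystem(
        positions=ca.coord.astype(float),
        chain_ids=ca.chain_id.astype("U4"),
        residue_indices=ca.res_id.astype(int),
        bead_classes=np.full(n, int(BeadClass.CA)),
        charges=np.zeros(n),
        radii=np.full(n, C.DEFAULT_RADIUS_CA),
        residue_names=ca.res_name.astype("U4"),
    )
    _build_backbone_topology(system)
    return system


def _read_pdb(source) -> pdbio.PDBFile:
    if hasattr(source, "read"):
        return pdbio.PDBFile.read(source)
    text_or_path = str(source)
    if "\nATOM" in text_or_path or text_or_path.startswith(("ATOM", "HETATM",
                                                            "HEADER", "MODEL")):
        return pdbio.PDBFile.read(io.StringIO(text_or_path))
    return pdbio.PDBFile.read(text_or_path)


def _build_backbone_topology(system: CGSystem) -> None:
    """Fill bonds/angles/dihedrals for consecutive CA beads chain by chain."""
    bonds, angles, dihedrals = [], [], []
    pos = system.positions
    for chain, idx in system.chains.items():
        idx = idx[np.argsort(system.residue_indices[idx], kind="stable")]
        runs = [[idx[0]]] if idx.size else []
        for prev, cur in zip(idx[:-1], idx[1:]):
            gap = system.residue_indices[cur] - system.residue_indices[prev]
            dist = np.linalg.norm(pos[cur] - pos[prev])
            if gap == 1 and dist <= CHAIN_BREAK_DISTANCE:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        for run in runs:
            bonds += [(run[i], run[i + 1]) for i in range(len(run) - 1)]
            angles += [tuple(run[i:i + 3]) for i in range(len(run) - 2)]
            dihedrals += [tuple(run[i:i + 4]) for i in range(len(run) - 3)]
    _set_bonded_terms(system, bonds, angles, dihedrals)


def _set_bonded_terms(system, bonds, angles, dihedrals,
                      bond_k=None, angle_k=None, dihedral_k=None):
    from .forcefield import measure_angles, measure_dihedrals  # local import

    system.bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
    d = system.positions[system.bonds[:, 1]] - system.positions[system.bonds[:, 0]]
    system.bond_r0 = np.linalg.norm(d, axis=1) if len(bonds) else np.zeros(0)
    system.bond_k = np.full(len(bonds), C.DEFAULT_BOND_K) \
        if bond_k is None else np.asarray(bond_k, dtype=float)
    system.angles = np.asarray(angles, dtype=int).reshape(-1, 3)
    system.angle_theta0 = measure_angles(system.positions, system.angles)
    system.angle_k = np.full(len(angles), C.DEFAULT_ANGLE_K) \
        if angle_k is None else np.asarray(angle_k, dtype=float)
    system.dihedrals = np.asarray(dihedrals, dtype=int).reshape(-1, 4)
    system.dihedral_phi0 = measure_dihedrals(system.positions, system.dihedrals)
    system.dihedral_k = np.full(len(dihedrals), C.DEFAULT_DIHEDRAL_K) \
        if dihedral_k is None else np.asarray(dihedral_k, dtype=float)


def assign_unit_charges(system: CGSystem) -> np.ndarray:
    """Unit charges from residue identity (+1 Arg/Lys, -1 Asp/Glu), e."""
    if system.residue_names is None:
        raise ValueError("system has no residue names")
    q = np.zeros(system.n_beads)
    q[np.isin(system.residue_names, list(_POSITIVE))] = 1.0
    q[np.isin(system.residue_names, list(_NEGATIVE))] = -1.0
    return q


# ---------------------------------------------------------------------------
# B-DNA duplex
# ---------------------------------------------------------------------------

def complement(sequence: str) -> str:
    """Complementary strand of ``sequence``, read 5'->3'."""
    return "".join(_COMPLEMENT[b] for b in reversed(sequence))


def build_bdna_duplex(
    sequence: str,
    *,
    rise: float = C.BDNA_RISE,
    twist_deg: float = C.BDNA_TWIST_DEG,
    phosphate_charge: float = C.DEFAULT_PHOSPHATE_CHARGE,
    include_terminal_phosphate: bool = False,
    chain_ids: tuple[str, str] = ("D", "E"),
    contact_cutoff: float = 9.0,
    contact_eps: float = 1.5,
) -> CGSystem:
    """Build a three-beads-per-nucleotide duplex on an ideal B-form helix.

    Each nucleotide contributes a SUGAR, a BASE and (except the 5' terminus,
    unless ``include_terminal_phosphate``) a PHOSPHATE bead.  The second
    strand is the reverse complement, threaded antiparallel on the same
    helix.  Intra-duplex native contacts (all non-bonded bead pairs within
    ``contact_cutoff``) keep the duplex shape-stable; there is no melting
    model.  Phosphates carry ``phosphate_charge`` (counterion-condensation
    convention).
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    if any(b not in _COMPLEMENT for b in sequence):
        raise ValueError("sequence must contain only A, C, G, T")

    n = len(sequence)
    twist = np.deg2rad(twist_deg)
    # cylindrical offsets of the three beads within a nucleotide (strand 1);
    # strand 2 uses the mirrored angular offsets (approximate C2 symmetry)
    geom = {
        BeadClass.PHOSPHATE: (C.BDNA_RADIUS_PHOSPHATE, np.deg2rad(95.0), -1.7),
        BeadClass.SUGAR: (C.BDNA_RADIUS_SUGAR, np.deg2rad(70.0), 0.0),
        BeadClass.BASE: (C.BDNA_RADIUS_BASE, np.deg2rad(35.0), 0.0),
    }

    positions, chain_ids_l, res_idx, classes, res_names = [], [], [], [], []

    def add_bead(strand: int, nt: int, cls: BeadClass, base_letter: str):
        # base-pair frame: pair index along the helix axis
        pair = nt if strand == 0 else n - 1 - nt
        phi0 = pair * twist
        radius, dphi, dz = geom[cls]
        sign = 1.0 if strand == 0 else -1.0
        # the 3'-direction of strand 2 runs down the axis: its phosphate
        # z-offset flips sign so P sits between its sugar and the previous one
        dz = dz * sign
        phi = phi0 + sign * dphi
        positions.append([radius * np.cos(phi), radius * np.sin(phi),
                          pair * rise + dz])
        chain_ids_l.append(chain_ids[strand])
        res_idx.append(nt + 1)
        classes.append(int(cls))
        res_names.append("D" + base_letter)

    strand_seqs = (sequence, complement(sequence))
    bead_of = {}  # (strand, nt, cls) -> bead index
    for strand, seq in enumerate(strand_seqs):
        for nt, letter in enumerate(seq):
            if nt > 0 or include_terminal_phosphate:
                bead_of[(strand, nt, BeadClass.PHOSPHATE)] = len(positions)
                add_bead(strand, nt, BeadClass.PHOSPHATE, letter)
            bead_of[(strand, nt, BeadClass.SUGAR)] = len(positions)
            add_bead(strand, nt, BeadClass.SUGAR, letter)
            bead_of[(strand, nt, BeadClass.BASE)] = len(positions)
            add_bead(strand, nt, BeadClass.BASE, letter)

    classes = np.asarray(classes)
    radii_by_class = {
        int(BeadClass.PHOSPHATE): C.DEFAULT_RADIUS_PHOSPHATE,
        int(BeadClass.SUGAR): C.DEFAULT_RADIUS_SUGAR,
        int(BeadClass.BASE): C.DEFAULT_RADIUS_BASE,
    }
    radii = np.array([radii_by_class[c] for c in classes])
    charges = np.where(classes == int(BeadClass.PHOSPHATE),
                       phosphate_charge, 0.0)

    system = CGSystem(
        positions=np.asarray(positions),
        chain_ids=np.asarray(chain_ids_l, dtype="U4"),
        residue_indices=np.asarray(res_idx),
        bead_classes=classes,
        charges=charges,
        radii=radii,
        residue_names=np.asarray(res_names, dtype="U4"),
    )

    # backbone / glycosidic bonds (3SPN-style connectivity)
    bonds, angles, dihedrals = [], [], []
    for strand in range(2):
        for nt in range(n):
            s = bead_of[(strand, nt, BeadClass.SUGAR)]
            b = bead_of[(strand, nt, BeadClass.BASE)]
            bonds.append((s, b))
            p = bead_of.get((strand, nt, BeadClass.PHOSPHATE))
            if p is not None:
                bonds.append((p, s))
            if nt + 1 < n:
                p_next = bead_of[(strand, nt + 1, BeadClass.PHOSPHATE)]
                s_next = bead_of[(strand, nt + 1, BeadClass.SUGAR)]
                bonds.append((s, p_next))
                angles.append((s, p_next, s_next))
                angles.append((b, s, p_next))
                if p is not None:
                    angles.append((p, s, p_next))
                    dihedrals.append((p, s, p_next, s_next))
    _set_bonded_terms(system, bonds, angles, dihedrals)

    # shape-stabilizing intra-duplex contacts
    from .forcefield import build_native_contacts
    contacts, r0 = build_native_contacts(
        system, system.positions, cutoff=contact_cutoff,
        min_sequence_separation=1, cross_chain_separation=0)
    system.native_contacts = contacts
    system.contact_r0 = r0
    system.contact_eps = np.full(len(r0), contact_eps)
    system.metadata["sequence"] = sequence
    system.metadata["duplex_chains"] = chain_ids
    return system


# ---------------------------------------------------------------------------
# rigid placement
# ---------------------------------------------------------------------------

def rigid_transform(system: CGSystem, chain_selection, rotation,
                    translation, center=None) -> CGSystem:
    """Apply a proper rigid rotation + translation to selected beads.

    ``rotation`` is a 3x3 proper orthonormal matrix applied about ``center``
    (default: origin); ``translation`` is added afterwards.  Intra-selection
    distances are preserved to numerical precision.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
            or not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise ValueError("rotation must be a proper orthonormal 3x3 matrix")
    idx = system.select(chain_selection)
    if idx.size == 0:
        raise ValueError("empty selection")
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    out = system.copy()
    out.positions[idx] = (out.positions[idx] - c) @ R.T + c + \
        np.asarray(translation, dtype=float)
    return out


# ---------------------------------------------------------------------------
# PDB / trajectory output
# ---------------------------------------------------------------------------

_ATOM_NAME = {int(BeadClass.CA): "CA", int(BeadClass.PHOSPHATE): "P",
              int(BeadClass.SUGAR): "S", int(BeadClass.BASE): "B"}
_ELEMENT = {int(BeadClass.CA): "C", int(BeadClass.PHOSPHATE): "P",
            int(BeadClass.SUGAR): "C", int(BeadClass.BASE): "C"}


def write_structure(system: CGSystem, path, b_factors=None) -> None:
    """Write the beads as PDB ATOM records (one atom per bead)."""
    n = system.n_beads
    arr = struc.AtomArray(n)
    arr.coord = system.positions.astype(np.float32)
    arr.chain_id = system.chain_ids.astype("U4")
    arr.res_id = system.residue_indices
    arr.atom_name = np.array([_ATOM_NAME[c] for c in system.bead_classes])
    if system.residue_names is not None:
        arr.res_name = system.residue_names.astype("U5")
    else:
        arr.res_name = np.where(system.bead_classes == int(BeadClass.CA),
                                "GLY", "DN")
    arr.element = np.array([_ELEMENT[c] for c in system.bead_classes])
    arr.hetero = np.zeros(n, dtype=bool)
    if b_factors is not None:
        arr.set_annotation("b_factor", np.asarray(b_factors, dtype=float))
    f = pdbio.PDBFile()
    pdbio.set_structure(f, arr)
    f.write(str(path))


def read_structure(path) -> CGSystem:
    """Read a PDB written by :func:`write_structure` back into a CGSystem.

    Only bead identity, chains and coordinates are stored in PDB; bonded
    topology and contacts are rebuilt by the model builders when needed.
    """
    f = pdbio.PDBFile.read(str(path))
    arr = pdbio.get_structure(f, model=1)
    name_to_class = {v: k for k, v in _ATOM_NAME.items()}
    classes = np.array([name_to_class.get(a, int(BeadClass.CA))
                        for a in arr.atom_name])
    radii_by_class = {
        int(BeadClass.CA): C.DEFAULT_RADIUS_CA,
        int(BeadClass.PHOSPHATE): C.DEFAULT_RADIUS_PHOSPHATE,
        int(BeadClass.SUGAR): C.DEFAULT_RADIUS_SUGAR,
        int(BeadClass.BASE): C.DEFAULT_RADIUS_BASE,
    }
    charges = np.where(classes == int(BeadClass.PHOSPHATE),
                       C.DEFAULT_PHOSPHATE_CHARGE, 0.0)
    return CGSystem(
        positions=arr.coord.astype(float),
        chain_ids=arr.chain_id.astype("U4"),
        residue_indices=arr.res_id.astype(int),
        bead_classes=classes,
        charges=charges,
        radii=np.array([radii_by_class[c] for c in classes]),
        residue_names=arr.res_name.astype("U4"),
    )


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as plain text with a step-number column."""
    n_beads = traj.positions.shape[1] if traj.n_frames else 0
    with open(path, "w") as fh:
        fh.write(f"# hingeflex-trajectory n_beads={n_beads} "
                 f"n_frames={traj.n_frames} seed={traj.seed}\n")
        for step, frame in zip(traj.steps, traj.positions):
            fh.write(f"# step {int(step)}\n")
            np.savetxt(fh, frame, fmt="%.6f")


def read_trajectory(path) -> Trajectory:
    steps, frames, current = [], [], []
    seed = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("# hingeflex-trajectory"):
                for tok in line.split():
                    if tok.startswith("seed="):
                        seed = None if tok[5:] == "None" else int(tok[5:])
            elif line.startswith("# step"):
                if current:
                    frames.append(current)
                    current = []
                steps.append(int(line.split()[-1]))
            else:
                current.append([float(x) for x in line.split()])
    if current:
        frames.append(current)
    if not steps:
        return Trajectory(steps=np.zeros(0, dtype=int),
                          positions=np.zeros((0, 0, 3)), seed=seed)
    return Trajectory(steps=np.array(steps), positions=np.array(frames),
                      seed=seed)


def read_fasta_sequence(path) -> str:
    """First sequence of a FASTA file, uppercased."""
    from Bio import SeqIO
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()
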