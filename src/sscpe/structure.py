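"""Protein structures and residue-residue contact maps.

A :class:`ProteinStructure` keeps, per residue, the coordinates of all heavy
(non-hydrogen) atoms.  Two contact-map flavors are derived from it with the
same closest-heavy-atom criterion (default cutoff 4.5 A):

* ``enm`` -- all contacts, including sequence neighbours; used to build the
  elastic network and the mutation forces;
* ``stability`` -- contacts with sequence separation ``|i-j| > 2`` only; used
  by the contact free-energy model, where short-range contacts are formed in
  essentially every compact conformation and cancel from free-energy
  differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .alphabet import (
    ELEMENT_MASS,
    NONSTANDARD_TO_ONE,
    THREE_TO_ONE,
    seq_to_indices,
)

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C")
DEFAULT_CUTOFF = 4.5
MIN_SEQSEP_STABILITY = 3


class EmptyStructureError(ValueError):
    """Raised when a file or chain contains no usable standard residues."""


@dataclass
class ProteinStructure:
    """Heavy-atom coordinates of one polypeptide chain.

    Residues are indexed 0-based internally; ``residue_ids`` retains the
    author-assigned identifiers for reporting.
    """

    sequence: str
    residue_ids: list[str]
    atom_names: list[list[str]]
    atom_coords: list[np.ndarray]          # per residue, (n_atoms, 3) in A
    atom_masses: list[np.ndarray]          # per residue, (n_atoms,) in Da
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise ValueError("a structure needs at least 3 residues")
        seq_to_indices(self.sequence)  # validates the alphabet
        for xyz in self.atom_coords:
            if not np.all(np.isfinite(xyz)):
                raise ValueError("non-finite coordinates")

    @property
    def L(self) -> int:
        return len(self.sequence)

    @property
    def ca_coords(self) -> np.ndarray:
        out = np.empty((self.L, 3))
        for i, names in enumerate(self.atom_names):
            out[i] = self.atom_coords[i][names.index("CA")]
        return out

    @property
    def residue_masses(self) -> np.ndarray:
        return np.array([m.sum() for m in self.atom_masses])

    def backbone_index(self, i: int, name: str) -> int:
        return self.atom_names[i].index(name)

    def flat_coords(self) -> np.ndarray:
        """All heavy-atom coordinates concatenated residue by residue."""
        return np.concatenate(self.atom_coords, axis=0)

    def flat_masses(self) -> np.ndarray:
        return np.concatenate(self.atom_masses)

    def atom_residue_index(self) -> np.ndarray:
        """Residue index of each flat atom."""
        return np.concatenate(
            [np.full(len(n), i, dtype=np.int64) for i, n in enumerate(self.atom_names)]
        )

    def flat_atom_offset(self, i: int) -> int:
        return int(sum(len(n) for n in self.atom_names[:i]))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Return a rigidly moved copy (used by invariance checks)."""
        coords = [xyz @ rotation.T + translation for xyz in self.atom_coords]
        return ProteinStructure(
            self.sequence, list(self.residue_ids),
            [list(n) for n in self.atom_names], coords,
            [m.copy() for m in self.atom_masses], self.chain_id,
        )


def _atom_mass(element: str, name: str) -> float:
    el = element.strip().upper() if element else ""
    if not el:
        el = name.strip()[0].upper()
    return ELEMENT_MASS.get(el, ELEMENT_MASS["C"])


def load_structure(path: str, chain: str | None = None) -> ProteinStructure:
    """Parse a PDB file and extract the heavy atoms of one chain.

    Only the first model is used.  Alternate locations keep the
    highest-occupancy conformer; MSE-style modified residues are mapped to
    their parent amino acid; unmapped or backbone-incomplete residues are
    dropped with a warning.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        model = parser.get_structure("s", path)[0]
    except (PDBConstructionException, ValueError, KeyError) as exc:
        raise ValueError(f"cannot parse PDB file {path!r}: {exc}") from exc

    chains = [c for c in model if chain is None or c.id == chain]
    if not chains:
        raise EmptyStructureError(f"chain {chain!r} not found in {path!r}")
    ch = chains[0]

    seq, rids, names, coords, masses = [], [], [], [], []
    for res in ch:
        resname = res.get_resname().strip()
        one = THREE_TO_ONE.get(resname) or NONSTANDARD_TO_ONE.get(resname)
        if one is None:
            if res.id[0] == " ":
                logger.warning("dropping unmapped residue %s %s", resname, res.id)
            continue
        atoms = {}
        for atom in res.get_unpacked_list():
            if atom.element and atom.element.strip().upper() in ("H", "D"):
                continue
            key = atom.get_name()
            if key not in atoms or (atom.get_occupancy() or 0) > (
                atoms[key].get_occupancy() or 0
            ):
                atoms[key] = atom
        if any(b not in atoms for b in BACKBONE_ATOMS):
            logger.warning("dropping residue %s%s with incomplete backbone",
                           resname, res.id[1])
            continue
        seq.append(one)
        icode = res.id[2].strip()
        rids.append(f"{res.id[1]}{icode}")
        names.append(list(atoms.keys()))
        coords.append(np.array([atoms[k].get_coord() for k in atoms], dtype=float))
        masses.append(np.array(
            [_atom_mass(atoms[k].element, k) for k in atoms], dtype=float
        ))

    if not seq:
        raise EmptyStructureError(f"no standard residues in {path!r} chain {ch.id!r}")
    return ProteinStructure("".join(seq), rids, names, coords, masses, chain_id=ch.id)


@dataclass
class ContactMap:
    """Binary residue-residue contacts with closest-heavy-atom geometry.

    ``vectors[(i, j)]`` (i < j) holds ``r_i' - r_j'``, the vector from the
    closest atom of residue j to the closest atom of residue i, its length,
    and the flat heavy-atom indices of the two atoms.
    """

    C: np.ndarray                       # (L, L) int8, symmetric, zero diagonal
    vectors: dict[tuple[int, int], tuple[np.ndarray, float, int, int]]
    flavor: str
    cutoff: float = DEFAULT_CUTOFF

    @property
    def L(self) -> int:
        return self.C.shape[0]

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.vectors)

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.C[i])


def build_contact_map(
    s: ProteinStructure,
    flavor: str = "enm",
    cutoff: float = DEFAULT_CUTOFF,
    min_seqsep_stability: int = MIN_SEQSEP_STABILITY,
) -> ContactMap:
    """Contacts between residues whose closest heavy atoms are within cutoff.

    ``flavor='stability'`` additionally zeroes contacts with sequence
    separation below ``min_seqsep_stability``.
    """
    if flavor not in ("enm", "stability"):
        raise ValueError(f"unknown contact-map flavor {flavor!r}")
    L = s.L
    xyz = s.flat_coords()
    res_of = s.atom_residue_index()
    d = cdist(xyz, xyz)
    C = np.zeros((L, L), dtype=np.int8)
    vectors: dict[tuple[int, int], tuple[np.ndarray, float, int, int]] = {}
    atom_idx = [np.flatnonzero(res_of == i) for i in range(L)]
    # closest atom pair per residue pair
    for i in range(L):
        ai = atom_idx[i]
        for j in range(i + 1, L):
            if flavor == "stability" and j - i < min_seqsep_stability:
                continue
            aj = atom_idx[j]
            block = d[np.ix_(ai, aj)]
            k = np.unravel_index(np.argmin(block), block.shape)
            dist = float(block[k])
            if dist < cutoff:
                C[i, j] = C[j, i] = 1
                p, q = int(ai[k[0]]), int(aj[k[1]])
                vectors[(i, j)] = (xyz[p] - xyz[q], dist, p, q)
    return ContactMap(C=C, vectors=vectors, flavor=flavor, cutoff=cutoff)


def contact_counts(cm: ContactMap) -> np.ndarray:
    """Number of contacts n_i of every residue (row sums of C)."""
    return cm.C.sum(axis=1).astype(np.int64)
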