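"""Default parameter sets and packaged parameter tables.

Three residue-level tables drive the mutation force and the stability model:

* ``s(a)`` -- heavy-atom count per amino acid (the size term),
* ``U(a,b)`` -- symmetric 20x20 contact free-energy table in kT units,
* ``d(a,b)`` -- symmetric 20x20 optimal closest-heavy-atom distance in Angstrom.

The packaged ``U`` and ``d`` defaults are synthetic stand-ins constructed from
amino-acid hydropathy and size (see the files' headers); both can be replaced
by any tab-separated 20x20 table in the canonical alphabet order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .alphabet import AMINO_ACIDS, HEAVY_ATOM_COUNT_VEC


def _read_matrix_tsv(text: str) -> np.ndarray:
    rows = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        rows[parts[0]] = [float(x) for x in parts[1:21]]
    mat = np.array([rows[a] for a in AMINO_ACIDS], dtype=float)
    if mat.shape != (20, 20):
        raise ValueError("expected a 20x20 amino-acid table")
    return mat


def load_table(name_or_path: str) -> np.ndarray:
    """Load a packaged (by name) or external (by path) 20x20 TSV table."""
    try:
        text = (resources.files("sscpe.data") / name_or_path).read_text()
    except (FileNotFoundError, TypeError):
        with open(name_or_path) as fh:
            text = fh.read()
    mat = _read_matrix_tsv(text)
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("amino-acid table must be symmetric")
    return mat


def default_contact_energies() -> np.ndarray:
    return load_table("contact_energies_synthetic.tsv")


def default_optimal_distances() -> np.ndarray:
    return load_table("optimal_distances_synthetic.tsv")


@dataclass
class ENMParameters:
    """Elastic-network parameters.

    K is the overall force constant (arbitrary units; every downstream
    observable is constructed to be K-independent), ``kappa_psi`` the
    torsional restraint coefficient, ``cutoff`` the closest-heavy-atom
    contact cutoff in Angstrom.
    """

    K: float = 1.0
    kappa_psi: float = 0.2
    cutoff: float = 4.5

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("force constant K must be positive")
        if self.kappa_psi < 0:
            raise ValueError("kappa_psi must be non-negative")


@dataclass
class MutationParameters:
    """Parameters of the mutation-as-force model.

    The weights multiply the size, contact-stability and optimal-distance
    force components; defaults are the values fitted on an experimental
    wild-type/mutant structure collection.  ``g`` is the distance exponent
    and ``R0`` the length scale of the ``K * R0**g`` prefactor that makes
    deformations independent of both K and g.
    """

    W_size: float = 3.05
    W_stab: float = 2.39
    W_dist: float = 15.6
    g: float = 2.0
    R0: float = 3.25
    size_table: np.ndarray = field(default_factory=lambda: HEAVY_ATOM_COUNT_VEC.copy())
    U: np.ndarray = field(default_factory=default_contact_energies)
    d: np.ndarray = field(default_factory=default_optimal_distances)

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.W_size, self.W_stab, self.W_dist], dtype=float)


@dataclass
class StabilityParameters:
    """Folding-stability parameters in kT = 1 units.

    ``S_U`` is the conformational entropy per residue of the unfolded chain
    and ``S_C`` the log-number of compact contact matrices per residue.  The
    defaults are chosen so that compact synthetic folds with
    hydrophobic-core sequences come out marginally stable (Delta G of a few
    kT below zero); no test depends on the specific values.
    """

    U: np.ndarray = field(default_factory=default_contact_energies)
    S_U: float = 0.16
    S_C: float = 0.06

    def __post_init__(self) -> None:
        if self.S_U <= 0 or self.S_C <= 0:
            raise ValueError("entropies per residue must be positive")
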