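"""Amino-acid alphabet, residue tables and element masses.

The canonical amino-acid order used throughout the package is the PAML order
``ARNDCQEGHILKMFPSTWYV`` so that empirical exchangeability files can be read
without permutation.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"
N_AA: int = 20
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Common modified residues mapped to their parent amino acid.
NONSTANDARD_TO_ONE: dict[str, str] = {
    "MSE": "M",  # selenomethionine
    "SEC": "C",  # selenocysteine
    "PYL": "K",  # pyrrolysine
    "HYP": "P",  # hydroxyproline
    "SEP": "S", "TPO": "T", "PTR": "Y",  # phosphorylated S/T/Y
    "CSO": "C", "MLY": "K", "KCX": "K",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: heavy (non-hydrogen) atom count per amino acid, side chain + backbone
HEAVY_ATOM_COUNT: dict[str, int] = {
    "A": 5, "R": 11, "N": 8, "D": 8, "C": 6, "Q": 9, "E": 9, "G": 4,
    "H": 10, "I": 8, "L": 8, "K": 9, "M": 8, "F": 11, "P": 7, "S": 6,
    "T": 7, "W": 14, "Y": 12, "V": 7,
}

HEAVY_ATOM_COUNT_VEC: np.ndarray = np.array(
    [HEAVY_ATOM_COUNT[a] for a in AMINO_ACIDS], dtype=float
)

#: standard atomic masses in Da for elements occurring in protein heavy atoms
ELEMENT_MASS: dict[str, float] = {
    "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "SE": 78.971,
    "P": 30.974, "H": 1.008,
}


def seq_to_indices(seq: str) -> np.ndarray:
    """Encode a one-letter amino-acid sequence as integer indices."""
    try:
        return np.array([AA_INDEX[a] for a in seq], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"non-standard amino acid in sequence: {exc}") from exc


def indices_to_seq(idx: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in idx)
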