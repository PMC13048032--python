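"""Synthetic test inputs: backbones, decoy contact libraries and MSAs.

Backbones are grown atom by atom with ideal bond lengths and angles from
given (or sampled) phi/psi dihedrals, so that the torsional network model's
degrees of freedom are exactly the generative ones.  Three geometries are
available:

* ``helix`` -- an ideal alpha-helix (phi, psi) = (-57, -47) degrees;
* ``helix_bundle`` -- helical segments joined by stochastic turns, selected
  among seeded candidates for compactness without steric clashes.  This
  yields contact numbers spanning roughly 2-12, like small globular folds;
* ``random_compact`` -- dihedrals sampled from Ramachandran-like basins with
  the same compactness selection; used for decoy contact libraries.

MSAs are sampled either independently per sequence from the site-specific
stationary distributions, or along a tree under the per-site substitution
process (root from P_i, branch transitions via the matrix exponential of the
reversible rate matrices).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AMINO_ACIDS, ELEMENT_MASS, HEAVY_ATOM_COUNT
from .structure import ContactMap, ProteinStructure, build_contact_map

# ideal backbone geometry (lengths in A, angles in degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8
HELIX_PHI, HELIX_PSI = -57.0, -47.0


@dataclass
class FixtureSpec:
    """Reproducible recipe for a synthetic fixture."""

    L: int
    geometry: str = "helix"
    seed: int = 0
    sequence: str | None = None
    n_candidates: int = 150      # stochastic geometries: candidates tried
    helix_len: int = 12          # helix_bundle: residues per helical segment
    turn_len: int = 4            # helix_bundle: residues per connecting turn


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural extension reference frame: position of atom d given a-b-c."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(angle),
                   bond * np.cos(torsion) * np.sin(angle),
                   bond * np.sin(torsion) * np.sin(angle)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_backbone(phi: np.ndarray, psi: np.ndarray) -> dict[str, np.ndarray]:
    """N/CA/C/O/CB coordinates for given dihedrals (omega fixed at 180)."""
    L = len(phi)
    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (B_N_CA, 0.0, 0.0)
    ang = np.deg2rad(A_N_CA_C)
    C[0] = CA[0] + (B_CA_C * np.cos(np.pi - ang), B_CA_C * np.sin(np.pi - ang), 0.0)
    for i in range(1, L):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], B_C_N, A_CA_C_N, psi[i - 1])
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], B_N_CA, A_C_N_CA, 180.0)
        C[i] = _place_atom(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, phi[i])
    O = np.zeros((L, 3))
    for i in range(L):
        psi_eff = psi[i] if i < L - 1 else HELIX_PSI
        O[i] = _place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi_eff + 180.0)
    # CB from the local N/CA/C frame (ideal tetrahedral geometry)
    b = CA - N
    c = C - CA
    a = np.cross(b, c)
    CB = CA - 0.58273431 * a + 0.56802827 * b - 0.54067466 * c
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


def _default_sequence(L: int, rng: np.random.Generator) -> str:
    """Random sequence biased toward a realistic composition (no Gly/Pro bias)."""
    return "".join(rng.choice(list(AMINO_ACIDS), size=L))


def _assemble(seq: str, bb: dict[str, np.ndarray]) -> ProteinStructure:
    """Pack backbone + CB coordinates into a ProteinStructure.

    Side chains beyond CB are not modeled; masses use a carbon-equivalent
    lump at CB scaled by the residue's remaining heavy-atom count so that
    residue masses track amino-acid size.
    """
    L = len(seq)
    names, coords, masses = [], [], []
    mC, mN, mO = ELEMENT_MASS["C"], ELEMENT_MASS["N"], ELEMENT_MASS["O"]
    for i, aa in enumerate(seq):
        nm = ["N", "CA", "C", "O"]
        xyz = [bb["N"][i], bb["CA"][i], bb["C"][i], bb["O"][i]]
        ms = [mN, mC, mC, mO]
        if aa != "G":
            nm.append("CB")
            xyz.append(bb["CB"][i])
            ms.append(mC * (HEAVY_ATOM_COUNT[aa] - 4))
        names.append(nm)
        coords.append(np.array(xyz))
        masses.append(np.array(ms))
    return ProteinStructure(seq, [str(i + 1) for i in range(L)],
                            names, coords, masses, chain_id="A")


def _clash_free(ca: np.ndarray, min_dist: float = 3.6) -> bool:
    L = ca.shape[0]
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    return bool(np.all(d[sep >= 2] > min_dist))


def _radius_of_gyration(ca: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((ca - ca.mean(0)) ** 2, axis=1))))


def _sample_dihedrals(spec: FixtureSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    L = spec.L
    if spec.geometry == "helix_bundle":
        phi = np.full(L, HELIX_PHI)
        psi = np.full(L, HELIX_PSI)
        i = spec.helix_len
        while i < L:
            n_turn = min(spec.turn_len, L - i)
            phi[i:i + n_turn] = rng.uniform(-150, 80, size=n_turn)
            psi[i:i + n_turn] = rng.uniform(-60, 170, size=n_turn)
            i += spec.helix_len + n_turn
        return phi, psi
    # random_compact: mixture of helical and extended basins
    basins = rng.random(L) < 0.65
    phi = np.where(basins, rng.normal(HELIX_PHI, 12, L), rng.normal(-120, 25, L))
    psi = np.where(basins, rng.normal(HELIX_PSI, 12, L), rng.normal(130, 25, L))
    return phi, psi


def make_backbone(spec: FixtureSpec) -> ProteinStructure:
    """Generate a reproducible synthetic backbone for the given spec."""
    if spec.L < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(spec.seed)
    seq = spec.sequence or _default_sequence(spec.L, rng)
    if len(seq) != spec.L:
        raise ValueError("sequence length does not match spec.L")
    if spec.geometry == "helix":
        bb = _build_backbone(np.full(spec.L, HELIX_PHI), np.full(spec.L, HELIX_PSI))
        return _assemble(seq, bb)
    if spec.geometry not in ("helix_bundle", "random_compact"):
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    best = None
    best_rg = np.inf
    for _ in range(spec.n_candidates):
        phi, psi = _sample_dihedrals(spec, rng)
        bb = _build_backbone(phi, psi)
        ca = bb["CA"]
        if not _clash_free(ca):
            continue
        rg = _radius_of_gyration(ca)
        if rg < best_rg:
            best_rg, best = rg, bb
    if best is None:  # extremely unlikely under the sampled basins
        bb = _build_backbone(np.full(spec.L, HELIX_PHI), np.full(spec.L, HELIX_PSI))
        return _assemble(seq, bb)
    return _assemble(seq, best)


def design_sequence(
    s: ProteinStructure,
    cs,
    sp=None,
    seed: int = 0,
    n_sweeps: int = 3,
) -> str:
    """Greedy stability design: sweep sites, replacing each amino acid by
    the one minimizing the folding free energy difference.

    Produces a hydrophobic-core-like sequence whose Delta G is comfortably
    negative on its own backbone, as a stand-in for a natural protein
    sequence.  Site order is shuffled per sweep with the given seed.
    """
    from .stability import DeltaGEvaluator

    rng = np.random.default_rng(seed)
    seq = list(s.sequence)
    cm = build_contact_map(s, flavor="stability")
    for _ in range(n_sweeps):
        ev = DeltaGEvaluator("".join(seq), cm, cs, sp)
        order = rng.permutation(s.L)
        changed = False
        for i in order:
            ddgs = np.array([ev.ddg(int(i), b) for b in range(20)])
            best = int(np.argmin(ddgs))
            if AMINO_ACIDS[best] != seq[i] and ddgs[best] < -1e-9:
                seq[i] = AMINO_ACIDS[best]
                changed = True
                ev = DeltaGEvaluator("".join(seq), cm, cs, sp)
        if not changed:
            break
    return "".join(seq)


def rebuilt_with_sequence(s: ProteinStructure, seq: str) -> ProteinStructure:
    """Same backbone geometry with a new sequence (CB masses re-lumped)."""
    bb = {
        "N": np.array([s.atom_coords[i][s.atom_names[i].index("N")] for i in range(s.L)]),
        "CA": np.array([s.atom_coords[i][s.atom_names[i].index("CA")] for i in range(s.L)]),
        "C": np.array([s.atom_coords[i][s.atom_names[i].index("C")] for i in range(s.L)]),
        "O": np.array([s.atom_coords[i][s.atom_names[i].index("O")] for i in range(s.L)]),
    }
    b = bb["CA"] - bb["N"]
    c = bb["C"] - bb["CA"]
    a = np.cross(b, c)
    bb["CB"] = bb["CA"] - 0.58273431 * a + 0.56802827 * b - 0.54067466 * c
    return _assemble(seq, bb)


def make_decoy_library(
    n: int, L: int, seed: int = 0, geometry: str = "random_compact"
) -> list[ContactMap]:
    """Stability-flavor contact maps of n seeded compact backbones.

    Stands in for contact statistics gathered from a nonredundant structure
    collection; decoys share the native-like compactness selection so their
    mean contact count tracks that of the generated folds.
    """
    if n < 2:
        raise ValueError("a decoy library needs at least 2 maps")
    maps = []
    for k in range(n):
        s = make_backbone(FixtureSpec(L=L, geometry=geometry, seed=seed * 100003 + k,
                                      n_candidates=60))
        maps.append(build_contact_map(s, flavor="stability"))
    return maps


def make_pooled_statistics(L: int, seed: int = 0, n_per_length: int = 7):
    """Separation-pooled decoy contact statistics around length L.

    Pools compact decoys of lengths L-4, L and L+4 so the moment estimates
    are smooth functions of sequence separation rather than noisy per-pair
    values, which is what large nonredundant structure collections provide.
    """
    from .stability import build_contact_statistics

    maps = []
    for ll in (max(L - 4, 8), L, L + 4):
        for k in range(n_per_length):
            s = make_backbone(FixtureSpec(L=ll, geometry="random_compact",
                                          seed=seed * 9973 + ll * 10 + k,
                                          n_candidates=60))
            maps.append(build_contact_map(s, flavor="stability"))
    return build_contact_statistics(maps, keep_explicit=False)


def write_pdb(s: ProteinStructure, path: str) -> None:
    """Write a minimal single-chain PDB file for a synthetic structure."""
    from .alphabet import ONE_TO_THREE

    with open(path, "w") as fh:
        serial = 1
        for i, aa in enumerate(s.sequence):
            res3 = ONE_TO_THREE[aa]
            for name, xyz in zip(s.atom_names[i], s.atom_coords[i]):
                el = name[0]
                padded = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {serial:5d} {padded:<4s} {res3} {s.chain_id}{i + 1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"          {el:>2s}\n"
                )
                serial += 1
        fh.write("TER\nEND\n")


@dataclass
class SimulatedMSA:
    names: list[str]
    sequences: list[str]
    seed: int

    def __iter__(self):
        return iter(zip(self.names, self.sequences))


def sample_msa_iid(P: np.ndarray, n_seq: int, seed: int = 0) -> SimulatedMSA:
    """n_seq sequences drawn independently, site by site, from rows of P."""
    rng = np.random.default_rng(seed)
    L = P.shape[0]
    cols = np.empty((n_seq, L), dtype=np.int64)
    for i in range(L):
        cols[:, i] = rng.choice(20, size=n_seq, p=P[i] / P[i].sum())
    seqs = ["".join(AMINO_ACIDS[a] for a in row) for row in cols]
    names = [f"seq{k + 1}" for k in range(n_seq)]
    return SimulatedMSA(names, seqs, seed)


def sample_msa_tree(models, tree, seed: int = 0) -> SimulatedMSA:
    """Evolve sequences along a dendropy tree under per-site rate matrices.

    ``models`` must provide ``P`` (L x 20 root frequencies) and
    ``transition_matrices(t)`` returning (L, 20, 20) probabilities.
    """
    rng = np.random.default_rng(seed)
    P = models.P
    L = P.shape[0]
    root_state = np.array([rng.choice(20, p=P[i] / P[i].sum()) for i in range(L)])
    states = {}
    tree_root = tree.seed_node
    states[tree_root] = root_state
    names, seqs = [], []
    for node in tree_root.preorder_iter():
        if node is tree_root:
            continue
        t = node.edge.length or 0.0
        parent_state = states[node.parent_node]
        if t <= 0:
            child = parent_state.copy()
        else:
            T = models.transition_matrices(t)  # (L, 20, 20)
            child = np.empty(L, dtype=np.int64)
            for i in range(L):
                probs = T[i, parent_state[i]]
                probs = np.clip(probs, 0.0, None)
                child[i] = rng.choice(20, p=probs / probs.sum())
        states[node] = child
        if node.is_leaf():
            names.append(node.taxon.label)
            seqs.append("".join(AMINO_ACIDS[a] for a in child))
    return SimulatedMSA(names, seqs, seed)
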