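"""Point mutations as perturbing forces and their predicted structural effects.

A mutation (a -> b) at site m exerts, on each contacting residue k, a force
along the closest-heavy-atom axis of the contact, proportional to the changes
in amino-acid size s, contact energy U and optimal contact distance d:

    F_k = K R0^g / |r_mk|^(1+g) * r_mk *
          [W_size (s(b)-s(a)) + W_stab (U(b,A_k)-U(a,A_k)) + W_dist (d(b,A_k)-d(a,A_k))]

with the reaction force -sum_k F_k applied at the mutated residue, so the
total force vanishes.  The linear response of the elastic network gives the
deformation dr = sum_a v_a F'_a / omega_a^2 (F'_a the mode projection), from
which the per-mutation RMSD and the harmonic energy change
DE = sum_a (F'_a/omega_a)^2 follow.  Both are independent of the overall
force constant K because the force carries an explicit K prefactor while the
response carries 1/K.

The observed deformation of a real mutant additionally contains a mutation-
independent component; the total mean-square deviation is modeled as
MSD = MSD_mut + MSD_nomut + MSD_cross with MSD_nomut = sum_a 1/omega_a^2 and
a cross term of fitted sign sigma_p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .alphabet import AA_INDEX, AMINO_ACIDS, seq_to_indices
from .enm import ModeBasis
from .params import MutationParameters
from .structure import ContactMap, ProteinStructure

_COMPONENTS = ("size", "stab", "dist")


@dataclass
class MutationForce:
    site: int
    aa_from: str
    aa_to: str
    cartesian_force: np.ndarray      # flat over the mode basis' coordinate set
    mode_projections: np.ndarray     # F'_alpha


@dataclass
class MutationEffectTable:
    """Per-site x per-amino-acid predicted RMSD (A) and harmonic energy DE."""

    rmsd: np.ndarray                 # (L, 20)
    de: np.ndarray                   # (L, 20)
    wild_type: str


@dataclass
class DeformationPrediction:
    msd_mut: float
    msd_nomut: float
    msd_cross_magnitude: float
    sigma_p: int

    @property
    def total(self) -> float:
        return self.msd_mut + self.msd_nomut + self.sigma_p * self.msd_cross_magnitude


def _site_contact_geometry(
    s: ProteinStructure, cm: ContactMap, mb: ModeBasis, m: int
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Neighbors of m plus, per contact, the distance-scaled axis and the
    mode projection of a unit force pair (+axis at k', -axis at m')."""
    neighbors, axes, projs = [], [], []
    for k in cm.neighbors(m):
        i, j = (m, k) if m < k else (k, m)
        vec, dist, p, q = cm.vectors[(i, j)]
        r_mk = vec if m < k else -vec          # r_m' - r_k'
        atom_m, atom_k = (p, q) if m < k else (q, p)
        neighbors.append(int(k))
        axes.append(r_mk)
        if mb.variant == "torsional":
            vm = mb.modes[:, 3 * atom_m : 3 * atom_m + 3]
            vk = mb.modes[:, 3 * atom_k : 3 * atom_k + 3]
        else:
            vm = mb.modes[:, 3 * m : 3 * m + 3]
            vk = mb.modes[:, 3 * int(k) : 3 * int(k) + 3]
        projs.append((vk - vm))
    return neighbors, np.array(axes), projs


def _force_coefficients(
    mp: MutationParameters, a_idx: int, b_idx: int, neighbor_aas: np.ndarray
) -> np.ndarray:
    """Scalar weight of the force on each contacting residue."""
    d_size = mp.size_table[b_idx] - mp.size_table[a_idx]
    d_stab = mp.U[b_idx, neighbor_aas] - mp.U[a_idx, neighbor_aas]
    d_dist = mp.d[b_idx, neighbor_aas] - mp.d[a_idx, neighbor_aas]
    return mp.W_size * d_size + mp.W_stab * d_stab + mp.W_dist * d_dist


def mutation_force(
    s: ProteinStructure,
    cm: ContactMap,
    mp: MutationParameters,
    m: int,
    a: str,
    b: str,
    wt: str | None = None,
    mb: ModeBasis | None = None,
    K: float = 1.0,
) -> MutationForce:
    """Cartesian mutation force for (a -> b) at site m, with mode projections.

    The force acts on the closest heavy atom of every contact partner and the
    reaction on the mutated residue's closest atoms, so it sums to zero.  For
    a Cartesian (C-alpha) mode basis the per-atom forces are transferred to
    the residues' C-alpha points.
    """
    if a not in AA_INDEX or b not in AA_INDEX:
        raise ValueError(f"non-standard amino acid in mutation {a}->{b}")
    if cm.flavor != "enm":
        raise ValueError("mutation forces require the enm-flavor contact map")
    wt = wt if wt is not None else s.sequence
    n_pts = mb.n_points if mb is not None else (
        sum(len(n) for n in s.atom_names)
    )
    force = np.zeros(3 * n_pts)
    n_modes = mb.n_dof if mb is not None else 0
    proj = np.zeros(n_modes)
    if a == b:
        return MutationForce(m, a, b, force, proj)
    neighbor_aas = np.array([AA_INDEX[wt[k]] for k in cm.neighbors(m)], dtype=np.int64)
    coeffs = _force_coefficients(mp, AA_INDEX[a], AA_INDEX[b], neighbor_aas)
    pref = K * mp.R0 ** mp.g
    for k, c in zip(cm.neighbors(m), coeffs):
        i, j = (m, k) if m < k else (k, m)
        vec, dist, p, q = cm.vectors[(i, j)]
        r_mk = vec if m < k else -vec
        atom_m, atom_k = (p, q) if m < k else (q, p)
        f_k = pref * c * r_mk / dist ** (1.0 + mp.g)
        if mb is not None and mb.variant == "cartesian":
            force[3 * int(k) : 3 * int(k) + 3] += f_k
            force[3 * m : 3 * m + 3] -= f_k
        else:
            force[3 * atom_k : 3 * atom_k + 3] += f_k
            force[3 * atom_m : 3 * atom_m + 3] -= f_k
    if mb is not None:
        proj = mb.project_force(force)
    return MutationForce(m, a, b, force, proj)


def predict_deformation(mf: MutationForce, mb: ModeBasis) -> tuple[float, float]:
    """(RMSD in A, harmonic energy DE) of the linear response to the force."""
    if mf.mode_projections.shape[0] != mb.n_dof:
        raise ValueError("force projections do not match the mode basis")
    fp = mf.mode_projections
    msd_mass = np.sum((fp / mb.omegas**2) ** 2)     # = sum_i m_i dr_i^2
    rmsd = np.sqrt(msd_mass / mb.total_mass)
    de = float(np.sum((fp / mb.omegas) ** 2))
    return float(rmsd), de


def total_msd_model(mf: MutationForce, mb: ModeBasis, sigma_p: int) -> DeformationPrediction:
    """Three-term model of the observed mutant MSD."""
    fp = mf.mode_projections
    msd_mut = float(np.sum((fp / mb.omegas**2) ** 2))
    msd_nomut = float(np.sum(1.0 / mb.omegas**2))
    cross = 2.0 * float(np.sqrt(np.sum((fp / mb.omegas**3) ** 2)))
    return DeformationPrediction(msd_mut, msd_nomut, cross, int(sigma_p))


def fit_sigma_p(observed_msd: float, dp: DeformationPrediction) -> int:
    """Sign of the cross term: +1 iff the observed MSD is at least the
    mutation-plus-null expectation (ties break to +1)."""
    return 1 if observed_msd >= dp.msd_mut + dp.msd_nomut else -1


def functional_change_filter(
    mb: ModeBasis, observed_dr: np.ndarray, threshold: float = 0.5
) -> bool:
    """True (keep) unless the observed change has an anomalously low barrier.

    The harmonic energy of the observed change, sum_a omega_a^2 c_a^2 with
    c_a the mass-weighted mode amplitudes, is compared with the null
    expectation (c_a^2 proportional to 1/omega_a^2) rescaled to the same
    total mean-square amplitude.  Changes with a ratio below ``threshold``
    are flagged as likely functional transitions and discarded; a zero
    change keeps by convention (ratio treated as 1).
    """
    c = mb.modes @ (mb.masses * observed_dr)
    total = float(np.sum(c**2))
    if total == 0.0:
        return True
    e_obs = float(np.sum(mb.omegas**2 * c**2))
    e_null = total * mb.n_dof / float(np.sum(1.0 / mb.omegas**2))
    return (e_obs / e_null) >= threshold


def wild_type_average(values: np.ndarray, lambda_str: float) -> float:
    """Deformation assigned to the wild-type residue: average of the 19
    mutant deformations weighted by exp(lambda * phi) with phi = -value, so
    small deformations dominate at positive selection strength."""
    phi = -np.asarray(values, dtype=float)
    w = np.exp(lambda_str * (phi - phi.max()))
    return float(np.sum(values * w) / np.sum(w))


def build_effect_table(
    s: ProteinStructure,
    cm: ContactMap,
    mb: ModeBasis,
    mp: MutationParameters | None = None,
    wt: str | None = None,
    lambda_str: float = 0.0,
    K: float = 1.0,
) -> MutationEffectTable:
    """Predicted RMSD and DE for every point mutation of the sequence.

    The wild-type entries hold the exp(lambda*phi)-weighted average of the
    19 mutant deformations (arithmetic mean at lambda_str = 0).
    """
    mp = mp or MutationParameters()
    wt = wt if wt is not None else s.sequence
    wt_idx = seq_to_indices(wt)
    L = s.L
    rmsd = np.zeros((L, 20))
    de = np.zeros((L, 20))
    pref = K * mp.R0 ** mp.g
    inv_w2 = 1.0 / mb.omegas**2
    inv_w1 = 1.0 / mb.omegas
    for m in range(L):
        neighbors, axes, projs = _site_contact_geometry(s, cm, mb, m)
        if neighbors:
            dists = np.linalg.norm(axes, axis=1)
            scaled_axes = axes / dists[:, None] ** (1.0 + mp.g)
            # per contact: mode projection of the unit force pair along axis
            unit_proj = np.array(
                [pr @ ax for pr, ax in zip(projs, scaled_axes)]
            )  # (n_contacts, n_modes)
            n_aas = wt_idx[neighbors]
        a_idx = int(wt_idx[m])
        for b_idx in range(20):
            if b_idx == a_idx or not neighbors:
                continue
            coeffs = pref * _force_coefficients(mp, a_idx, b_idx, n_aas)
            fp = coeffs @ unit_proj
            rmsd[m, b_idx] = np.sqrt(np.sum((fp * inv_w2) ** 2) / mb.total_mass)
            de[m, b_idx] = np.sum((fp * inv_w1) ** 2)
        others = [b for b in range(20) if b != a_idx]
        rmsd[m, a_idx] = wild_type_average(rmsd[m, others], lambda_str)
        de[m, a_idx] = wild_type_average(de[m, others], lambda_str)
    return MutationEffectTable(rmsd=rmsd, de=de, wild_type=wt)


def write_effect_table(table: MutationEffectTable, path: str, kind: str = "rmsd") -> None:
    """TSV export: site, wild-type amino acid, 20 predicted values."""
    mat = table.rmsd if kind == "rmsd" else table.de
    with open(path, "w") as fh:
        fh.write("#site\twt\t" + "\t".join(AMINO_ACIDS) + "\n")
        for i in range(mat.shape[0]):
            row = "\t".join(f"{x:.6g}" for x in mat[i])
            fh.write(f"{i + 1}\t{table.wild_type[i]}\t{row}\n")


def _component_projections(
    s: ProteinStructure,
    cm: ContactMap,
    mb: ModeBasis,
    mp: MutationParameters,
    m: int,
    a: str,
    b: str,
    wt: str,
) -> np.ndarray:
    """(3, n_modes) mode projections of the size/stab/dist force components
    (unit weights, including the K R0^g prefactor with K = 1)."""
    neighbors, axes, projs = _site_contact_geometry(s, cm, mb, m)
    out = np.zeros((3, mb.n_dof))
    if not neighbors:
        return out
    dists = np.linalg.norm(axes, axis=1)
    scaled_axes = axes / dists[:, None] ** (1.0 + mp.g)
    unit_proj = np.array([pr @ ax for pr, ax in zip(projs, scaled_axes)])
    wt_idx = seq_to_indices(wt)
    n_aas = wt_idx[neighbors]
    ai, bi = AA_INDEX[a], AA_INDEX[b]
    pref = mp.R0 ** mp.g
    comp = np.stack([
        np.full(len(neighbors), mp.size_table[bi] - mp.size_table[ai]),
        mp.U[bi, n_aas] - mp.U[ai, n_aas],
        mp.d[bi, n_aas] - mp.d[ai, n_aas],
    ])
    return pref * comp @ unit_proj


def fit_weights(
    training_pairs: list[tuple[ProteinStructure, ContactMap, ModeBasis, tuple[int, str, str], float]],
    mp: MutationParameters | None = None,
) -> tuple[np.ndarray, float]:
    """Fit (W_size, W_stab, W_dist) by maximizing the Pearson correlation
    between the mutation-only predicted RMSD and observed RMSDs.

    Each training pair is (structure, enm contact map, mode basis,
    (site, aa_from, aa_to), observed rmsd).  The predicted RMSD is
    sqrt(W^T A W) with a precomputed 3x3 Gram matrix A per pair, so the fit
    is deterministic and scale-invariant; the returned weights have unit
    Euclidean norm.  Returns (weights, correlation).
    """
    mp = mp or MutationParameters()
    if len(training_pairs) < 3:
        raise ValueError("need at least 3 training pairs")
    obs = np.array([t[4] for t in training_pairs], dtype=float)
    if np.allclose(obs, obs[0]):
        raise ValueError("observed RMSDs are constant; correlation undefined")
    grams = []
    for s, cm, mb, (m, a, b), _o in training_pairs:
        G = _component_projections(s, cm, mb, mp, m, a, b, s.sequence)
        Gw = G / mb.omegas[None, :] ** 2
        grams.append((Gw @ Gw.T) / mb.total_mass)
    grams = np.array(grams)

    def predicted(w: np.ndarray) -> np.ndarray:
        q = np.einsum("pij,i,j->p", grams, w, w)
        return np.sqrt(np.clip(q, 0.0, None))

    def neg_corr(w: np.ndarray) -> float:
        pred = predicted(w)
        if pred.std() == 0:
            return 1.0
        return -float(np.corrcoef(pred, obs)[0, 1])

    w0 = mp.weights / np.linalg.norm(mp.weights)
    best = None
    for start in (w0, np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)):
        res = scipy.optimize.minimize(
            neg_corr, start, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    w = best.x / np.linalg.norm(best.x)
    if np.sum(w) < 0:
        w = -w
    return w, -float(best.fun)
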