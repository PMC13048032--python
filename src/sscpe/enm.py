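"""Elastic network models and their normal modes.

Two variants are provided.  The Cartesian variant is the standard anisotropic
network model (ANM) on C-alpha coordinates: a harmonic spring of uniform
constant K acts along the C-alpha/C-alpha axis of every contact pair.  The
torsional variant (TNM) keeps all heavy atoms but restricts motion to the
backbone phi/psi dihedrals; springs act along the closest-heavy-atom axis of
each contact, and a quadratic restraint ``kappa_psi * K * sum_a (d theta_a)^2``
keeps torsional fluctuations finite.  Rigid-body motion is removed by
mass-weighted Eckart conditions, leaving ``3L - 6`` Cartesian or ``2L - 2``
torsional modes for a single chain.

Normal modes are returned as Cartesian displacement vectors ``v_alpha`` over
the model's coordinate set, mass-orthonormalized so that
``sum_i m_i v_alpha_i v_beta_i = delta_ab``; frequencies satisfy
``H v = omega^2 M v``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .params import ENMParameters
from .structure import ContactMap, ProteinStructure

_RIGID_TOL = 1e-7


class DisconnectedNetworkError(ValueError):
    """The contact network leaves internal zero-frequency motions."""


@dataclass
class ModeBasis:
    """Normal modes of an elastic network.

    ``modes[alpha]`` is the Cartesian displacement of mode alpha over the
    flattened coordinate set (C-alpha atoms for the Cartesian variant, all
    heavy atoms for the torsional one); ``masses`` is the matching
    per-coordinate mass vector.  ``atom_residue`` maps each point of the
    coordinate set to its residue.
    """

    omegas: np.ndarray            # (n_modes,)
    modes: np.ndarray             # (n_modes, 3N)
    masses: np.ndarray            # (3N,)
    variant: str                  # "cartesian" | "torsional"
    atom_residue: np.ndarray      # (N,)
    coords: np.ndarray            # (N, 3) equilibrium coordinates
    jacobian: np.ndarray | None = None   # (3N, n_dof), torsional variant only

    @property
    def n_dof(self) -> int:
        return len(self.omegas)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def total_mass(self) -> float:
        return float(self.masses[::3].sum())

    def project_force(self, force: np.ndarray) -> np.ndarray:
        """Projections F'_alpha = sum_j v_alpha_j F_j of a flat force vector."""
        return self.modes @ force


def thermal_msd(mb: ModeBasis) -> float:
    """Thermal mean-square displacement of the null model, sum_a 1/omega_a^2."""
    return float(np.sum(1.0 / mb.omegas**2))


def _contact_springs(cm: ContactMap, use_atoms: bool) -> list[tuple[int, int, np.ndarray]]:
    """(point_i, point_j, unit vector) per contact; points are atoms or residues."""
    springs = []
    for (i, j), (vec, dist, p, q) in cm.vectors.items():
        if use_atoms:
            springs.append((p, q, vec / dist))
        else:
            springs.append((i, j, None))  # direction filled by caller from CA coords
    return springs


def cartesian_hessian(
    coords: np.ndarray,
    springs: list[tuple[int, int, np.ndarray]],
    K: float,
) -> np.ndarray:
    """Dense ANM Hessian over the points of ``coords`` (oracle-friendly)."""
    n = coords.shape[0]
    H = np.zeros((3 * n, 3 * n))
    for p, q, e in springs:
        if e is None:
            d = coords[p] - coords[q]
            e = d / np.linalg.norm(d)
        blk = K * np.outer(e, e)
        sp, sq = slice(3 * p, 3 * p + 3), slice(3 * q, 3 * q + 3)
        H[sp, sp] += blk
        H[sq, sq] += blk
        H[sp, sq] -= blk
        H[sq, sp] -= blk
    return H


def build_cartesian_enm(
    s: ProteinStructure, cm: ContactMap, p: ENMParameters | None = None
) -> ModeBasis:
    """ANM over C-alpha coordinates; six rigid-body modes removed."""
    p = p or ENMParameters()
    if cm.flavor != "enm":
        raise ValueError("the elastic network requires an enm-flavor contact map")
    ca = s.ca_coords
    L = s.L
    springs = [(i, j, None) for (i, j) in cm.vectors]
    H = cartesian_hessian(ca, springs, p.K)
    m_res = s.residue_masses
    masses = np.repeat(m_res, 3)
    inv_sqrt_m = 1.0 / np.sqrt(masses)
    Hw = H * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    evals, evecs = scipy.linalg.eigh(Hw)
    scale = max(evals.max(), 1.0)
    n_zero = int(np.sum(evals < _RIGID_TOL * scale))
    if n_zero > 6:
        raise DisconnectedNetworkError(
            f"{n_zero} near-zero modes (expected 6): disconnected contact network"
        )
    keep = slice(6, None)
    omegas = np.sqrt(np.clip(evals[keep], 0.0, None))
    modes = (evecs[:, keep] * inv_sqrt_m[:, None]).T
    return ModeBasis(
        omegas=omegas, modes=modes, masses=masses, variant="cartesian",
        atom_residue=np.arange(L), coords=ca,
    )


def _torsion_axes(s: ProteinStructure) -> list[tuple[str, int, np.ndarray, np.ndarray, int]]:
    """Retained phi/psi dihedrals as (kind, residue, axis point, axis unit, first moving atom).

    ``first moving atom`` is the flat index from which all atoms move for phi
    (N of the residue stays put, so the moving set starts at the residue's
    non-N atoms); for psi only the carbonyl O of the residue and everything
    downstream moves.  Atom ordering within a residue is as parsed; the
    moving sets are returned explicitly by :func:`_moving_sets`.
    """
    axes = []
    for i in range(s.L):
        off = s.flat_atom_offset(i)
        n_idx = off + s.backbone_index(i, "N")
        ca_idx = off + s.backbone_index(i, "CA")
        c_idx = off + s.backbone_index(i, "C")
        if i > 0:
            axes.append(("phi", i, n_idx, ca_idx, off))
        if i < s.L - 1:
            axes.append(("psi", i, ca_idx, c_idx, off))
    return axes


def _moving_mask(s: ProteinStructure, kind: str, i: int) -> np.ndarray:
    """Boolean mask over flat atoms moved by the torsion (kind, residue i)."""
    n_atoms = sum(len(n) for n in s.atom_names)
    mask = np.zeros(n_atoms, dtype=bool)
    off = s.flat_atom_offset(i)
    names = s.atom_names[i]
    if kind == "phi":
        # everything bonded through CA: all atoms of residue i except N,
        # plus all downstream residues
        for k, nm in enumerate(names):
            if nm != "N":
                mask[off + k] = True
    else:  # psi: only the carbonyl O of residue i, plus downstream residues
        for k, nm in enumerate(names):
            if nm in ("O", "OXT"):
                mask[off + k] = True
    end = off + len(names)
    mask[end:] = True
    return mask


def torsion_jacobian(s: ProteinStructure) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Raw (pre-Eckart) Jacobian d r_j / d theta_a over all heavy atoms.

    Columns are ordered (phi_2, psi_1, phi_3, psi_2, ...) by residue; rotating
    torsion a by d theta displaces the downstream atoms by
    ``e_a x (r_j - p_a) * d theta``.
    """
    xyz = s.flat_coords()
    n_atoms = xyz.shape[0]
    axes = _torsion_axes(s)
    J = np.zeros((3 * n_atoms, len(axes)))
    labels = []
    for col, (kind, i, a_idx, b_idx, _off) in enumerate(axes):
        axis = xyz[b_idx] - xyz[a_idx]
        axis = axis / np.linalg.norm(axis)
        mask = _moving_mask(s, kind, i)
        disp = np.cross(axis[None, :], xyz[mask] - xyz[b_idx][None, :])
        block = np.zeros((n_atoms, 3))
        block[mask] = disp
        J[:, col] = block.ravel()
        labels.append((kind, i))
    return J, labels


def _eckart_project(J: np.ndarray, xyz: np.ndarray, masses3: np.ndarray) -> np.ndarray:
    """Remove mass-weighted rigid-body components from each Jacobian column."""
    n_atoms = xyz.shape[0]
    com = np.average(xyz, axis=0, weights=masses3[::3])
    rigid = []
    for k in range(3):
        t = np.zeros((n_atoms, 3))
        t[:, k] = 1.0
        rigid.append(t.ravel())
    for k in range(3):
        w = np.zeros(3)
        w[k] = 1.0
        rigid.append(np.cross(w[None, :], xyz - com[None, :]).ravel())
    B = np.array(rigid).T  # (3N, 6)
    # mass-orthonormalize the rigid basis
    G = B.T @ (masses3[:, None] * B)
    Binv = scipy.linalg.cholesky(G, lower=False)
    Bo = B @ np.linalg.inv(Binv)
    return J - Bo @ (Bo.T @ (masses3[:, None] * J))


def build_torsional_enm(
    s: ProteinStructure, cm: ContactMap, p: ENMParameters | None = None
) -> ModeBasis:
    """Torsional network model over backbone phi/psi dihedrals.

    The potential is the contact ENM energy (springs on closest-heavy-atom
    pairs) restricted to torsional motion via the Eckart-projected Jacobian,
    plus the ``kappa_psi`` restraint applied to every retained torsion.
    """
    p = p or ENMParameters()
    if cm.flavor != "enm":
        raise ValueError("the elastic network requires an enm-flavor contact map")
    xyz = s.flat_coords()
    masses3 = np.repeat(s.flat_masses(), 3)
    J_raw, labels = torsion_jacobian(s)
    J = _eckart_project(J_raw, xyz, masses3)
    n_dof = J.shape[1]
    if n_dof != 2 * s.L - 2:
        raise ValueError("unexpected torsional degree-of-freedom count")

    # H_tors = J^T H_cart J assembled spring by spring: for a spring on atoms
    # (q1, q2) with unit axis e, the energy is K/2 (e . (dr_q1 - dr_q2))^2.
    G = np.zeros((len(cm.vectors), n_dof))
    for row, ((_i, _j), (vec, dist, q1, q2)) in enumerate(cm.vectors.items()):
        e = vec / dist
        d1 = J[3 * q1 : 3 * q1 + 3, :]
        d2 = J[3 * q2 : 3 * q2 + 3, :]
        G[row] = e @ (d1 - d2)
    H_tors = p.K * (G.T @ G) + p.kappa_psi * p.K * np.eye(n_dof)
    T = J.T @ (masses3[:, None] * J)
    # guard against numerically singular kinetic metrics
    T = T + 1e-12 * np.trace(T) / n_dof * np.eye(n_dof)
    evals, theta = scipy.linalg.eigh(H_tors, T)
    if evals[0] <= 0:
        raise DisconnectedNetworkError("non-positive torsional spectrum")
    omegas = np.sqrt(evals)
    modes = (J @ theta).T
    return ModeBasis(
        omegas=omegas, modes=modes, masses=masses3, variant="torsional",
        atom_residue=s.atom_residue_index(), coords=xyz, jacobian=J,
    )
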