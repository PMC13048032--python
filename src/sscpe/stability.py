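"""Contact-based folding free energy against unfolded and misfolded ensembles.

The native free energy of sequence A on contact matrix C is the sum of
contact energies ``E(C, A) = sum_{i<j} C_ij U(A_i, A_j)`` (stability-flavor
contacts only, |i-j| > 2).  The unfolded state contributes
``G_U = -L S_U`` (kT = 1) and the misfolded ensemble of compact decoy
conformations is treated with the random energy model,

    G_misf = <E> - var(E)/2 - L S_C        (above the freezing point)

with the moments of the decoy contact energies taken over a library of
compact contact matrices.  Below freezing (var > 2 L S_C) the free energy is
clamped at ``<E> - sqrt(2 L S_C var)``.  The nonnative free energy combines
both channels through a Boltzmann average,
``G_nonnat = -log(exp(-G_misf) + exp(-G_U))``, and
``Delta G = G_nat - G_nonnat``.

Decoy moments come in two modes: *explicit*, computed exactly over a stored
library of equal-length contact matrices, and *pooled*, where the mean
contact probability is factorized as ``<C_ij> = a(L) f(|i-j|)`` and the
variance assembled from three separation-pooled covariance summaries
(per-pair Bernoulli variance; contact-number covariance between sites;
covariance of each contact with the total contact count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alphabet import seq_to_indices
from .params import StabilityParameters
from .structure import ContactMap

logger = logging.getLogger(__name__)

_MAX_SEP_POOL = 400


@dataclass
class StabilityResult:
    g_nat: float
    g_unf: float
    g_misf: float
    delta_g: float
    frozen: bool


def native_energy(seq: str | np.ndarray, cm: ContactMap, U: np.ndarray) -> float:
    """E(C, A) = sum_{i<j} C_ij U(A_i, A_j) over stability contacts."""
    idx = seq if isinstance(seq, np.ndarray) else seq_to_indices(seq)
    if len(idx) != cm.L:
        raise ValueError("sequence length does not match the contact map")
    e = 0.0
    for (i, j) in cm.vectors:
        e += U[idx[i], idx[j]]
    return float(e)


class ContactStatistics:
    """Decoy-ensemble contact moments, explicit or pooled by separation."""

    def __init__(
        self,
        f_seqsep: np.ndarray,
        contacts_per_residue: float,
        cov_nn_by_sep: np.ndarray,
        cov_cn_by_sep: np.ndarray,
        explicit: dict[int, list[np.ndarray]] | None = None,
        min_seqsep: int = 3,
    ) -> None:
        self.f_seqsep = f_seqsep                  # P(contact | |i-j|)
        self.contacts_per_residue = contacts_per_residue
        self.cov_nn_by_sep = cov_nn_by_sep
        self.cov_cn_by_sep = cov_cn_by_sep
        self.explicit = explicit or {}
        self.min_seqsep = min_seqsep
        self._mean_cache: dict[int, np.ndarray] = {}

    # -- mean contact probability ------------------------------------------
    def a_of_L(self, L: int) -> float:
        """Scale factor so that the expected contact count matches natives."""
        sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
        f = self._f_of_sep(sep)
        total_f = np.triu(f, k=self.min_seqsep).sum()
        if total_f <= 0:
            raise ValueError(f"no contact statistics applicable to length {L}")
        return float(self.contacts_per_residue * L / total_f)

    def _f_of_sep(self, sep: np.ndarray) -> np.ndarray:
        s = np.clip(sep, 0, len(self.f_seqsep) - 1)
        f = self.f_seqsep[s]
        f[sep < self.min_seqsep] = 0.0
        return f

    def mean_contact_matrix(self, L: int) -> np.ndarray:
        """<C_ij> for length L: a(L) f(|i-j|), clipped to probabilities."""
        if L not in self._mean_cache:
            if L in self.explicit:
                self._mean_cache[L] = np.mean(self.explicit[L], axis=0)
            else:
                sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
                mc = np.clip(self.a_of_L(L) * self._f_of_sep(sep), 0.0, 1.0)
                np.fill_diagonal(mc, 0.0)
                self._mean_cache[L] = mc
        return self._mean_cache[L]

    # -- second moments ----------------------------------------------------
    def covariance_matrices(self, L: int) -> tuple[np.ndarray, np.ndarray]:
        """(cov(n_i, n_k), cov(C_ij, N_c)) matrices for length L."""
        if L in self.explicit:
            maps = np.array(self.explicit[L], dtype=float)
            n = maps.sum(axis=2)                         # (n_maps, L)
            cov_nn = np.einsum("mi,mk->ik", n, n) / len(maps) - np.outer(
                n.mean(0), n.mean(0)
            )
            Nc = maps.sum(axis=(1, 2)) / 2.0
            cov_cn = (
                np.einsum("mij,m->ij", maps, Nc) / len(maps)
                - maps.mean(0) * Nc.mean()
            )
            return cov_nn, cov_cn
        sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
        s = np.clip(sep, 0, len(self.cov_nn_by_sep) - 1)
        cov_nn = self.cov_nn_by_sep[s]
        s2 = np.clip(sep, 0, len(self.cov_cn_by_sep) - 1)
        cov_cn = self.cov_cn_by_sep[s2]
        cov_cn = np.where(sep < self.min_seqsep, 0.0, cov_cn)
        return cov_nn, cov_cn

    def explicit_maps(self, L: int) -> list[np.ndarray] | None:
        return self.explicit.get(L)


def build_contact_statistics(
    structure_library: list[ContactMap], keep_explicit: bool = True
) -> ContactStatistics:
    """Empirical contact statistics from a library of stability-flavor maps."""
    if len(structure_library) < 2:
        raise ValueError("need at least 2 contact maps")
    min_seqsep = 3
    hits = np.zeros(_MAX_SEP_POOL)
    trials = np.zeros(_MAX_SEP_POOL)
    total_contacts, total_res = 0.0, 0
    lengths: dict[int, list[np.ndarray]] = {}
    for cm in structure_library:
        C = np.asarray(cm.C, dtype=float)
        L = cm.L
        lengths.setdefault(L, []).append(C)
        total_contacts += C.sum() / 2.0
        total_res += L
        sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
        for s in range(min_seqsep, min(L, _MAX_SEP_POOL)):
            mask = sep == s
            trials[s] += mask.sum() / 2
            hits[s] += C[mask].sum() / 2
    f = np.where(trials > 0, hits / np.maximum(trials, 1), 0.0)
    # across-decoy covariances, estimated within equal-length groups and
    # pooled by sequence separation (lengths with a single map carry no
    # across-ensemble variance information)
    max_sep = max(cm.L for cm in structure_library)
    cov_nn_sum = np.zeros(max_sep)
    cov_nn_cnt = np.zeros(max_sep)
    cov_cn_sum = np.zeros(max_sep)
    cov_cn_cnt = np.zeros(max_sep)
    for L, group in lengths.items():
        if len(group) < 2:
            continue
        arr = np.array(group)                      # (m, L, L)
        n = arr.sum(axis=2)                        # (m, L)
        cov_nn_mat = np.einsum("mi,mk->ik", n, n) / len(arr) - np.outer(
            n.mean(0), n.mean(0)
        )
        Nc = arr.sum(axis=(1, 2)) / 2.0
        cov_cn_mat = (
            np.einsum("mij,m->ij", arr, Nc) / len(arr) - arr.mean(0) * Nc.mean()
        )
        sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
        for s in range(L):
            mask = sep == s
            cov_nn_sum[s] += cov_nn_mat[mask].sum()
            cov_nn_cnt[s] += mask.sum()
            if s >= min_seqsep:
                cov_cn_sum[s] += cov_cn_mat[mask].sum()
                cov_cn_cnt[s] += mask.sum()
    cov_nn = np.where(cov_nn_cnt > 0, cov_nn_sum / np.maximum(cov_nn_cnt, 1), 0.0)
    cov_cn = np.where(cov_cn_cnt > 0, cov_cn_sum / np.maximum(cov_cn_cnt, 1), 0.0)
    return ContactStatistics(
        f_seqsep=f,
        contacts_per_residue=total_contacts / total_res,
        cov_nn_by_sep=cov_nn,
        cov_cn_by_sep=cov_cn,
        explicit=lengths if keep_explicit else None,
        min_seqsep=min_seqsep,
    )


def _energy_moments(
    idx: np.ndarray, cs: ContactStatistics, U: np.ndarray, exact: bool
) -> tuple[float, float]:
    """(<E>, var(E)) over the decoy ensemble for the given sequence."""
    L = len(idx)
    Useq = U[np.ix_(idx, idx)]
    maps = cs.explicit_maps(L)
    if exact and maps is not None:
        E = np.array([np.sum(np.triu(C, 1) * Useq) for C in maps])
        return float(E.mean()), float(E.var())
    mc = cs.mean_contact_matrix(L)
    mean_e = 0.5 * float(np.sum(mc * Useq))
    # term 1: per-pair Bernoulli variance, <C^2> = <C>
    t1 = 0.5 * float(np.sum((mc - mc**2) * Useq**2))
    # term 2: contact-number covariance with per-site mean contact energies
    cov_nn, cov_cn = cs.covariance_matrices(L)
    nbar = mc.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Ui = np.where(nbar > 0, (mc * Useq).sum(axis=1) / np.maximum(nbar, 1e-12), 0.0)
    t2 = float(Ui @ cov_nn @ Ui)
    # term 3: covariance of each contact with the total contact count
    Nc_bar = mc.sum() / 2.0
    Ubar = float(np.sum(mc * Useq)) / (2.0 * max(Nc_bar, 1e-12))
    t3 = 0.5 * float(np.sum(cov_cn * Useq)) * Ubar
    var = max(t1 + t2 + t3, 0.0)
    return mean_e, var


def misfold_free_energy(
    seq: str | np.ndarray,
    cs: ContactStatistics,
    U: np.ndarray,
    S_C: float,
    L: int | None = None,
    exact: bool = False,
) -> tuple[float, bool]:
    """Random-energy-model misfolding free energy and the freezing flag."""
    idx = seq if isinstance(seq, np.ndarray) else seq_to_indices(seq)
    L = L if L is not None else len(idx)
    mean_e, var = _energy_moments(idx, cs, U, exact)
    s_conf = L * S_C
    if var > 2.0 * s_conf:
        return float(mean_e - np.sqrt(2.0 * s_conf * var)), True
    return float(mean_e - var / 2.0 - s_conf), False


def delta_g(
    seq: str | np.ndarray,
    cm: ContactMap,
    cs: ContactStatistics | None,
    sp: StabilityParameters | None = None,
    use_misfold: bool = True,
    exact_moments: bool = False,
) -> StabilityResult:
    """Folding free energy difference Delta G = G_nat - G_nonnative (kT).

    With ``use_misfold=False`` (the all-hydrophilic assumption) the nonnative
    state is the unfolded chain only and Delta G = G_nat + L * S_U exactly.
    """
    sp = sp or StabilityParameters()
    idx = seq if isinstance(seq, np.ndarray) else seq_to_indices(seq)
    L = cm.L
    g_nat = native_energy(idx, cm, sp.U)
    g_unf = -L * sp.S_U
    if not use_misfold or cs is None:
        return StabilityResult(g_nat, g_unf, np.inf, g_nat - g_unf, False)
    g_misf, frozen = misfold_free_energy(idx, cs, sp.U, sp.S_C, L, exact=exact_moments)
    g_nonnat = -np.logaddexp(-g_misf, -g_unf)
    return StabilityResult(g_nat, g_unf, g_misf, float(g_nat - g_nonnat), frozen)


class DeltaGEvaluator:
    """Cached Delta-Delta-G evaluation for all point mutants of a sequence.

    Keeps the wild-type contact sums so a single mutation updates only the
    terms touching the mutated site; ``full_recompute`` provides the
    independent slow path.
    """

    def __init__(
        self,
        seq: str | np.ndarray,
        cm: ContactMap,
        cs: ContactStatistics | None,
        sp: StabilityParameters | None = None,
        use_misfold: bool = True,
    ) -> None:
        self.sp = sp or StabilityParameters()
        self.cm = cm
        self.cs = cs
        self.use_misfold = use_misfold and cs is not None
        self.idx = seq if isinstance(seq, np.ndarray) else seq_to_indices(seq)
        self.L = cm.L
        self.wt_result = delta_g(self.idx, cm, cs if self.use_misfold else None,
                                 self.sp, use_misfold=self.use_misfold)
        if self.use_misfold:
            self._mc = cs.mean_contact_matrix(self.L)
            self._cov_nn, self._cov_cn = cs.covariance_matrices(self.L)
            nbar = self._mc.sum(axis=1)
            self._nbar = np.maximum(nbar, 1e-12)
            U = self.sp.U
            Useq = U[np.ix_(self.idx, self.idx)]
            self._sum_e = float(np.sum(self._mc * Useq))        # = 2 <E>
            self._t1_mat_sum = float(np.sum((self._mc - self._mc**2) * Useq**2))
            self._Ui = (self._mc * Useq).sum(axis=1) / self._nbar
            self._covnn_Ui = self._cov_nn @ self._Ui
            self._s3 = float(np.sum(self._cov_cn * Useq))
            self._nc_bar = max(self._mc.sum() / 2.0, 1e-12)

    def _mutant_result(self, i: int, b: int) -> StabilityResult:
        idx = self.idx.copy()
        idx[i] = b
        return delta_g(idx, self.cm, self.cs if self.use_misfold else None,
                       self.sp, use_misfold=self.use_misfold)

    def _incremental_moments(self, i: int, b_idx: int) -> tuple[float, float]:
        """Mutant (<E>, var) from cached wild-type contact sums."""
        U = self.sp.U
        a_idx = int(self.idx[i])
        dU = U[b_idx, self.idx] - U[a_idx, self.idx]     # (L,)
        dU[i] = 0.0
        dU2 = U[b_idx, self.idx] ** 2 - U[a_idx, self.idx] ** 2
        dU2[i] = 0.0
        mc_i = self._mc[i]
        sum_e = self._sum_e + 2.0 * float(mc_i @ dU)
        t1 = 0.5 * (self._t1_mat_sum + 2.0 * float((mc_i - mc_i**2) @ dU2))
        # per-site mean energies: row i changes fully, every other row via
        # its coupling to site i
        dUi_vec = mc_i * dU / self._nbar                 # change of U_k, k != i
        dUi_vec[i] = float(mc_i @ dU) / self._nbar[i]
        Ui_new_dot = (
            float(self._Ui @ self._covnn_Ui)
            + 2.0 * float(dUi_vec @ self._covnn_Ui)
            + float(dUi_vec @ (self._cov_nn @ dUi_vec))
        )
        s3 = self._s3 + 2.0 * float(self._cov_cn[i] @ dU)
        ubar = sum_e / (2.0 * self._nc_bar)
        var = max(t1 + Ui_new_dot + 0.5 * s3 * ubar, 0.0)
        return sum_e / 2.0, var

    def _misfold_from_moments(self, mean_e: float, var: float) -> float:
        s_conf = self.L * self.sp.S_C
        if var > 2.0 * s_conf:
            return float(mean_e - np.sqrt(2.0 * s_conf * var))
        return float(mean_e - var / 2.0 - s_conf)

    def ddg(self, i: int, b: int | str) -> float:
        """Delta G(mutant with site i -> b) - Delta G(wild type).

        Incremental: only the contact sums touching site i are updated.
        """
        from .alphabet import AA_INDEX

        b_idx = AA_INDEX[b] if isinstance(b, str) else int(b)
        a_idx = int(self.idx[i])
        if b_idx == a_idx:
            return 0.0
        U = self.sp.U
        d_nat = 0.0
        for j in self.cm.neighbors(i):
            d_nat += U[b_idx, self.idx[j]] - U[a_idx, self.idx[j]]
        if not self.use_misfold:
            return float(d_nat)
        mean_e, var = self._incremental_moments(i, b_idx)
        g_misf = self._misfold_from_moments(mean_e, var)
        g_nonnat = -np.logaddexp(-g_misf, -self.wt_result.g_unf)
        mutant_dg = (self.wt_result.g_nat + d_nat) - g_nonnat
        return float(mutant_dg - self.wt_result.delta_g)

    def full_recompute(self, i: int, b: int | str) -> float:
        from .alphabet import AA_INDEX

        b_idx = AA_INDEX[b] if isinstance(b, str) else int(b)
        return float(self._mutant_result(i, b_idx).delta_g - self.wt_result.delta_g)

    def all_mutations(self) -> np.ndarray:
        """(L, 20) Delta-Delta-G table; zero at the wild-type amino acid."""
        out = np.zeros((self.L, 20))
        for i in range(self.L):
            for b in range(20):
                if b != self.idx[i]:
                    out[i, b] = self.ddg(i, b)
        return out


def delta_delta_g(
    evaluator: DeltaGEvaluator, i: int, b: int | str
) -> float:
    """Functional wrapper around :meth:`DeltaGEvaluator.ddg`."""
    return evaluator.ddg(i, b)
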