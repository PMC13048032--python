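"""Site-specific stationary amino-acid distributions and selection fitting.

Every model is of the exponential-family form

    P_i(a) = P_glob(a) exp(Lambda_stab phi_stab_i(a) + Lambda_str phi_str_i(a)) / Z_i

where the log-fitness matrices phi derive from folding stability (mean-field
or wild-type Delta-Delta-G) and/or from the predicted structural deformation
(RMSD or harmonic energy DE) of every point mutation.  The global
frequencies P_glob are fitted so the model's summed frequencies match the
alignment's; the selection parameters Lambda are fitted by minimizing the
symmetric Kullback-Leibler divergence (or maximizing a site log-likelihood)
between model and alignment, ridge-penalized by R * Lambda^2, with R chosen
at the maximum of the specific heat dKL/dR.  Fitted frequencies are floored
at epsilon = 0.001 and renormalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, N_AA, seq_to_indices
from .mutation import MutationEffectTable, wild_type_average
from .stability import ContactStatistics, DeltaGEvaluator
from .params import StabilityParameters
from .structure import ContactMap

logger = logging.getLogger(__name__)

EPSILON = 0.001

MODEL_NAMES = ("GLOB", "MF", "WT", "DE", "RMSD", "DEMF", "DEWT", "RMSDMF", "RMSDWT")

#: which fitness channels each model uses (stability component, structure kind)
MODEL_CHANNELS: dict[str, tuple[str | None, str | None]] = {
    "GLOB": (None, None),
    "MF": ("MF", None),
    "WT": ("WT", None),
    "DE": (None, "DE"),
    "RMSD": (None, "RMSD"),
    "DEMF": ("MF", "DE"),
    "DEWT": ("WT", "DE"),
    "RMSDMF": ("MF", "RMSD"),
    "RMSDWT": ("WT", "RMSD"),
}


@dataclass
class MSAProfile:
    """Observed site frequencies of an alignment, floored at epsilon."""

    f: np.ndarray                  # (L, 20), rows sum to 1, min >= eps
    n_seq: int
    column_map: np.ndarray | None = None   # MSA column of each site
    epsilon: float = EPSILON

    @classmethod
    def from_sequences(
        cls,
        sequences: list[str],
        columns: np.ndarray | None = None,
        epsilon: float = EPSILON,
    ) -> "MSAProfile":
        """Count amino acids per column; gaps and unknowns are excluded."""
        n_col = len(sequences[0])
        cols = columns if columns is not None else np.arange(n_col)
        counts = np.zeros((len(cols), N_AA))
        for seq in sequences:
            for out_i, c in enumerate(cols):
                aa = seq[c]
                if aa in AA_INDEX:
                    counts[out_i, AA_INDEX[aa]] += 1
        totals = counts.sum(axis=1, keepdims=True)
        f = np.where(totals > 0, counts / np.maximum(totals, 1), 1.0 / N_AA)
        return cls(
            f=floor_frequencies(f, epsilon),
            n_seq=len(sequences),
            column_map=np.asarray(cols),
            epsilon=epsilon,
        )

    @property
    def mean_frequencies(self) -> np.ndarray:
        return self.f.mean(axis=0)


@dataclass
class SiteProfileSet:
    """Fitted site-specific stationary distribution of one model."""

    model: str
    P: np.ndarray                        # (L, 20) floored stationary frequencies
    p_glob: np.ndarray                   # (20,)
    Z: np.ndarray                        # (L,) pre-floor normalizers
    lambda_stab: float = 0.0
    lambda_str: float = 0.0
    phi_stab: np.ndarray | None = None   # (L, 20)
    phi_str: np.ndarray | None = None
    epsilon: float = EPSILON

    @property
    def L(self) -> int:
        return self.P.shape[0]

    def combined_log_fitness(self) -> np.ndarray:
        """x_i(a) = Lambda_stab phi_stab + Lambda_str phi_str (zeros if absent)."""
        x = np.zeros_like(self.P)
        if self.phi_stab is not None:
            x = x + self.lambda_stab * self.phi_stab
        if self.phi_str is not None:
            x = x + self.lambda_str * self.phi_str
        return x


def floor_frequencies(P: np.ndarray, epsilon: float = EPSILON) -> np.ndarray:
    """Clamp every frequency at epsilon, renormalizing the rest of each row.

    Entries at the floor keep the value epsilon exactly; iterates in case
    renormalization pushes further entries below the floor.
    """
    P = np.array(P, dtype=float)
    for _ in range(N_AA):
        low = P < epsilon
        if not low.any():
            break
        P[low] = epsilon
        free = ~low
        budget = 1.0 - low.sum(axis=1) * epsilon
        denom = np.where(free, P, 0.0).sum(axis=1)
        scale = np.where(denom > 0, budget / np.maximum(denom, 1e-300), 0.0)
        P = np.where(free, P * scale[:, None], P)
        if np.all(P[free] >= epsilon - 1e-15):
            break
    return P


# ---------------------------------------------------------------------------
# fitness matrices
# ---------------------------------------------------------------------------

def wt_fitness(evaluator: DeltaGEvaluator) -> np.ndarray:
    """phi_i(a) = -DeltaDeltaG(wt_i -> a); zero at the wild-type residue."""
    return -evaluator.all_mutations()


def str_fitness(effects: MutationEffectTable, kind: str = "RMSD") -> np.ndarray:
    """phi = -RMSD or -DE, with the wild-type entries already averaged in."""
    if kind not in ("RMSD", "DE"):
        raise ValueError("kind must be 'RMSD' or 'DE'")
    return -(effects.rmsd if kind == "RMSD" else effects.de)


def str_fitness_at_lambda(
    effects: MutationEffectTable, kind: str, lambda_str: float
) -> np.ndarray:
    """Structure fitness with the wild-type averages recomputed at Lambda.

    The deformation assigned to the wild-type amino acid is the
    stationary-weighted average of the 19 mutant deformations and therefore
    depends on the selection strength; this refreshes those entries without
    rebuilding the deformation table.
    """
    mat = np.array(effects.rmsd if kind == "RMSD" else effects.de)
    wt_idx = seq_to_indices(effects.wild_type)
    for i, a in enumerate(wt_idx):
        others = [b for b in range(N_AA) if b != a]
        mat[i, a] = wild_type_average(mat[i, others], lambda_str)
    return -mat


def mf_fitness(
    seq: str,
    cm: ContactMap,
    cs: ContactStatistics | None,
    sp: StabilityParameters | None = None,
    lam: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    damping: float = 0.5,
    use_misfold: bool = True,
) -> np.ndarray:
    """Mean-field stability fitness, determined self-consistently.

    At each sweep the fitness of amino acid a at site i is minus the folding
    free energy with site i fixed to a and every other site averaged over its
    current distribution: native contacts contribute the exact exponential
    average ``log sum_b P_j(b) exp(-lam U(a,b)) / lam`` per contact, while
    the misfold channel is closed at first order by averaging the contact
    energies over the site distributions.  Distributions are updated with
    uniform global frequencies and damping until the largest frequency
    change falls below ``tol``.
    """
    sp = sp or StabilityParameters()
    idx = seq_to_indices(seq)
    L = cm.L
    U = sp.U
    use_misfold = use_misfold and cs is not None
    P = np.full((L, N_AA), 1.0 / N_AA)
    if use_misfold:
        mc = cs.mean_contact_matrix(L)
        cov_nn, cov_cn = cs.covariance_matrices(L)
        nbar = np.maximum(mc.sum(axis=1), 1e-12)
        nc_bar = max(mc.sum() / 2.0, 1e-12)
    expU = np.exp(-lam * U)            # (20, 20)
    phi = np.zeros((L, N_AA))
    for sweep in range(max_iter):
        # native channel: exact exponential average over contact partners
        phi_nat = np.zeros((L, N_AA))
        for i in range(L):
            for j in cm.neighbors(i):
                avg = expU @ P[j]                      # (20,)
                phi_nat[i] += np.log(np.maximum(avg, 1e-300)) / lam
        if use_misfold:
            # mean-sequence closure of the misfold + unfold channels
            Ubar_site = P @ U @ P.T                     # (L, L) <U(A_i, A_j)>
            U2bar_site = P @ (U**2) @ P.T
            Ua = U @ P.T                                # (20, L): <U(a, A_j)>
            U2a = (U**2) @ P.T
            phi_misf = np.zeros((L, N_AA))
            sum_e_base = float(np.sum(mc * Ubar_site))
            t1_base = float(np.sum((mc - mc**2) * U2bar_site))
            Ui_base = (mc * Ubar_site).sum(axis=1) / nbar
            s3_base = float(np.sum(cov_cn * Ubar_site))
            covnn_Ui = cov_nn @ Ui_base
            for i in range(L):
                d_e = Ua[:, :] @ mc[i] - float(mc[i] @ Ubar_site[i])   # (20,)
                sum_e = sum_e_base + 2.0 * d_e
                t1 = 0.5 * (
                    t1_base
                    + 2.0 * (U2a @ (mc[i] - mc[i] ** 2) - float((mc[i] - mc[i] ** 2) @ U2bar_site[i]))
                )
                # per-amino-acid changes of the site-energy vector
                dUi_vec = (mc[i][None, :] * (Ua - Ubar_site[i][None, :])) / nbar[None, :]
                dUi_vec[:, i] = d_e / nbar[i]
                t2 = (
                    float(Ui_base @ covnn_Ui)
                    + 2.0 * dUi_vec @ covnn_Ui
                    + np.einsum("al,lk,ak->a", dUi_vec, cov_nn, dUi_vec)
                )
                s3 = s3_base + 2.0 * ((Ua - Ubar_site[i][None, :]) @ cov_cn[i])
                ubar = sum_e / (2.0 * nc_bar)
                var = np.maximum(t1 + t2 + 0.5 * s3 * ubar, 0.0)
                mean_e = sum_e / 2.0
                s_conf = L * sp.S_C
                g_misf = np.where(
                    var > 2.0 * s_conf,
                    mean_e - np.sqrt(2.0 * s_conf * np.maximum(var, 0.0)),
                    mean_e - var / 2.0 - s_conf,
                )
                g_unf = -L * sp.S_U
                g_nonnat = -np.logaddexp(-g_misf, -g_unf)
                phi_misf[i] = g_nonnat
            phi_new = phi_nat + phi_misf
        else:
            phi_new = phi_nat
        phi_new = phi_new - phi_new.max(axis=1, keepdims=True)
        w = np.exp(lam * phi_new)
        P_new = w / w.sum(axis=1, keepdims=True)
        delta = np.abs(P_new - P).max()
        P = damping * P_new + (1.0 - damping) * P
        phi = phi_new
        if delta < tol:
            return phi
    raise RuntimeError(
        f"mean-field iteration did not converge (residual {delta:.2e})"
    )


# ---------------------------------------------------------------------------
# stationary distribution and fitting
# ---------------------------------------------------------------------------

def stationary_distribution(
    x: np.ndarray,
    p_glob: np.ndarray,
    epsilon: float = EPSILON,
) -> tuple[np.ndarray, np.ndarray]:
    """(P floored, pre-floor Z) for combined log-fitness x_i(a)."""
    logits = np.log(np.maximum(p_glob, 1e-300))[None, :] + x
    m = logits.max(axis=1, keepdims=True)
    w = np.exp(logits - m)
    Z = w.sum(axis=1) * np.exp(m[:, 0])
    P_raw = w / w.sum(axis=1, keepdims=True)
    return floor_frequencies(P_raw, epsilon), Z


def fit_global_frequencies(
    x: np.ndarray,
    msa: MSAProfile,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> np.ndarray:
    """Global frequencies such that the model's frequencies, summed over
    sites, equal the alignment's (the +F analogue); solved iteratively."""
    target = msa.f.sum(axis=0)
    ex = np.exp(x - x.max(axis=1, keepdims=True))
    p = target / target.sum()
    for it in range(max_iter):
        Z = ex @ p
        denom = (ex / Z[:, None]).sum(axis=0)
        p_new = target / np.maximum(denom, 1e-300)
        p_new = p_new / p_new.sum()
        if np.abs(p_new * denom - target).max() < tol * max(1.0, target.max()):
            return p_new
        # geometric-mean damping guards against oscillation at strong selection
        p = np.sqrt(p_new * p) if it > 50 else p_new
        p = p / p.sum()
    logger.warning("global-frequency fit: slow convergence, returning last iterate")
    return p


def loglik_score(P: np.ndarray, msa: MSAProfile) -> float:
    """Mean per-site log-likelihood of the observed frequencies."""
    return float(np.mean(np.sum(msa.f * np.log(np.maximum(P, 1e-300)), axis=1)))


def kl_symmetric(P: np.ndarray, msa: MSAProfile) -> float:
    """Mean per-site symmetric KL divergence between model and alignment."""
    f = msa.f
    Ps = np.maximum(P, 1e-300)
    fw = np.maximum(f, 1e-300)
    kl_fp = np.sum(f * (np.log(fw) - np.log(Ps)), axis=1)
    kl_pf = np.sum(P * (np.log(Ps) - np.log(fw)), axis=1)
    return float(np.mean(kl_fp + kl_pf))


def _profile_at(
    phi_fn,
    lambdas: tuple[float, float],
    msa: MSAProfile,
    epsilon: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(P, p_glob, Z) at given selection parameters; refits p_glob."""
    x = phi_fn(lambdas)
    p_glob = fit_global_frequencies(x, msa)
    logits = np.log(np.maximum(p_glob, 1e-300))[None, :] + x
    m = logits.max(axis=1, keepdims=True)
    w = np.exp(logits - m)
    Z = (w.sum(axis=1)) * np.exp(m[:, 0])
    P = floor_frequencies(w / w.sum(axis=1, keepdims=True), epsilon)
    return P, p_glob, Z


def _objective(
    phi_fn, lambdas, msa, criterion, R, epsilon
) -> float:
    P, _pg, _Z = _profile_at(phi_fn, lambdas, msa, epsilon)
    penalty = R * (lambdas[0] ** 2 + lambdas[1] ** 2)
    if criterion == "KLsymm":
        return kl_symmetric(P, msa) + penalty
    if criterion == "LL":
        return -loglik_score(P, msa) + penalty
    raise ValueError(f"unknown criterion {criterion!r}")


def _refine_minimum(fn, lo: float, hi: float) -> tuple[float, float]:
    """Bounded 1-D refinement of a bracketed minimum (deterministic)."""
    import scipy.optimize

    res = scipy.optimize.minimize_scalar(
        fn, bounds=(lo, hi), method="bounded", options={"xatol": 1e-5}
    )
    return float(res.x), float(res.fun)


def fit_lambda(
    phi_fn,
    msa: MSAProfile,
    criterion: str = "KLsymm",
    R: float = 0.0,
    lambda_max: float = 30.0,
    n_grid: int = 16,
    epsilon: float = EPSILON,
    channel: int = 0,
    fixed_other: float = 0.0,
) -> tuple[float, float]:
    """Fit one selection parameter on [0, lambda_max].

    ``phi_fn((lam_stab, lam_str))`` must return the combined log-fitness
    matrix at those selection strengths (re-deriving any Lambda-dependent
    entries).  Scans a grid, warns if the score is not unimodal, and refines
    the best point by quadratic interpolation.  Returns (lambda, score).
    """
    grid = np.concatenate([[0.0], np.geomspace(lambda_max / 256, lambda_max, n_grid - 1)])

    def pack(lam: float) -> tuple[float, float]:
        return (lam, fixed_other) if channel == 0 else (fixed_other, lam)

    def fn(lam: float) -> float:
        return _objective(phi_fn, pack(abs(lam)), msa, criterion, R, epsilon)

    scores = np.array([fn(l) for l in grid])
    k = int(np.argmin(scores))
    interior_minima = sum(
        1 for i in range(1, len(grid) - 1)
        if scores[i] < scores[i - 1] and scores[i] < scores[i + 1]
    )
    if interior_minima > 1:
        logger.warning("selection-parameter score not unimodal; using best grid point")
        return float(grid[k]), float(scores[k])
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi <= lo:
        return float(grid[k]), float(scores[k])
    lam, score = _refine_minimum(fn, lo, hi)
    if scores[k] < score:
        lam, score = float(grid[k]), float(scores[k])
    return abs(float(lam)), float(score)


def fit_lambdas_joint(
    phi_fn,
    msa: MSAProfile,
    criterion: str = "KLsymm",
    R: float = 0.0,
    lambda_max: float = 30.0,
    n_grid: int = 7,
    epsilon: float = EPSILON,
    n_cycles: int = 3,
) -> tuple[tuple[float, float], float]:
    """Two selection parameters: coarse 2-D grid, then coordinate-wise
    quadratic refinement."""
    grid = np.concatenate([[0.0], np.geomspace(lambda_max / 64, lambda_max, n_grid - 1)])
    best = (0.0, 0.0)
    best_score = np.inf
    for ls in grid:
        for lt in grid:
            sc = _objective(phi_fn, (ls, lt), msa, criterion, R, epsilon)
            if sc < best_score:
                best_score, best = sc, (float(ls), float(lt))
    lam_stab, lam_str = best
    for _ in range(n_cycles):
        lam_stab, _ = fit_lambda(
            phi_fn, msa, criterion, R, lambda_max, 9, epsilon,
            channel=0, fixed_other=lam_str,
        )
        lam_str, best_score = fit_lambda(
            phi_fn, msa, criterion, R, lambda_max, 9, epsilon,
            channel=1, fixed_other=lam_stab,
        )
    return (lam_stab, lam_str), float(best_score)


@dataclass
class RegularizationPath:
    R_grid: np.ndarray
    lambda_at_R: np.ndarray
    kl_at_R: np.ndarray
    cv_at_R: np.ndarray
    chosen_R: float
    chosen_lambda: float


def regularization_path(
    phi_fn,
    msa: MSAProfile,
    criterion: str = "KLsymm",
    R_grid: np.ndarray | None = None,
    epsilon: float = EPSILON,
    channel: int = 0,
    fixed_other: float = 0.0,
) -> RegularizationPath:
    """Scan ridge strengths and pick R at the maximum of the specific heat.

    The specific heat C_V = dKL/dR is estimated by central finite differences
    of the unpenalized divergence at the fitted Lambda(R); the location of
    its maximum is refined by quadratic interpolation on the log-R grid.
    """
    if R_grid is None:
        R_grid = np.geomspace(1e-4, 10.0, 13)
    lams, kls = [], []
    for R in R_grid:
        lam, _ = fit_lambda(phi_fn, msa, criterion, R, epsilon=epsilon,
                            channel=channel, fixed_other=fixed_other)
        lams.append(lam)
        pair = (lam, fixed_other) if channel == 0 else (fixed_other, lam)
        P, _pg, _Z = _profile_at(phi_fn, pair, msa, epsilon)
        kls.append(kl_symmetric(P, msa) if criterion == "KLsymm"
                   else -loglik_score(P, msa))
    lams = np.array(lams)
    kls = np.array(kls)
    cv = np.gradient(kls, R_grid)
    k = int(np.argmax(cv))
    if k in (0, len(R_grid) - 1):
        logger.warning("specific heat has no interior maximum; using boundary R")
        chosen_R = float(R_grid[k])
    else:
        # parabola through the three points in log-R
        xs = np.log(R_grid[k - 1 : k + 2])
        ys = cv[k - 1 : k + 2]
        denom = (xs[0] - xs[1]) * (xs[1] - xs[2]) * (xs[0] - xs[2])
        a = (xs[2] * (ys[1] - ys[0]) + xs[1] * (ys[0] - ys[2]) + xs[0] * (ys[2] - ys[1])) / denom
        b = (xs[2] ** 2 * (ys[0] - ys[1]) + xs[1] ** 2 * (ys[2] - ys[0]) + xs[0] ** 2 * (ys[1] - ys[2])) / denom
        x_star = -b / (2 * a) if a < 0 else xs[1]
        x_star = float(np.clip(x_star, xs[0], xs[2]))
        chosen_R = float(np.exp(x_star))
    chosen_lambda, _ = fit_lambda(phi_fn, msa, criterion, chosen_R, epsilon=epsilon,
                                  channel=channel, fixed_other=fixed_other)
    return RegularizationPath(
        R_grid=R_grid, lambda_at_R=lams, kl_at_R=kls, cv_at_R=cv,
        chosen_R=chosen_R, chosen_lambda=float(chosen_lambda),
    )


def entropy_and_rate(P: np.ndarray, E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site sequence entropy S_i = -sum P log P and substitution rate
    R_i = sum_{a != b} P_i(a) P_i(b) E_i(a,b).

    ``E`` may be a single 20x20 exchangeability or a per-site (L, 20, 20)
    stack.
    """
    S = -np.sum(P * np.log(np.maximum(P, 1e-300)), axis=1)
    E = np.asarray(E, dtype=float)
    if E.ndim == 2:
        E = np.broadcast_to(E, (P.shape[0],) + E.shape)
    Eoff = E.copy()
    for i in range(Eoff.shape[0]):
        np.fill_diagonal(Eoff[i], 0.0)
    R = np.einsum("ia,ib,iab->i", P, P, Eoff)
    return S, R
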