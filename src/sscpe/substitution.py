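"""Site-specific exchangeability and rate matrices.

Starting from an empirical exchangeability model (JTT, LG or WAG, in the
PAML lower-triangle format), per-site matrices are derived by three binary
options:

* **HB / noHB** -- multiply the global exchangeability by the fixation
  factor of the mutation-selection process,
  ``E_i(a,b) = E_glob(a,b) * Z_i (x_ib - x_ia) / (exp(x_ib) - exp(x_ia))``
  with ``x_ia`` the combined log-fitness; the equal-fitness limit is the
  analytic value ``Z_i exp(-x_ia)``.
* **FL / noFL** -- rescale the global exchangeability so the model's
  site-averaged flux per amino-acid pair equals the empirical flux
  ``P_emp(a) P_emp(b) E_emp(a,b)``.
* **rate1 / rate0** -- per-site exchangeabilities are normalized so each
  site's substitution rate is one; rate1 additionally records the
  model-predicted rate as a per-site scale factor.

An approximate, tree-free pair likelihood ranks empirical models and option
combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .alphabet import AA_INDEX, N_AA
from .profiles import SiteProfileSet

logger = logging.getLogger(__name__)

BUILTIN_MODELS = ("JTT", "LG", "WAG")


@dataclass
class EmpiricalModel:
    name: str
    E: np.ndarray                  # (20, 20) symmetric, zero diagonal
    P: np.ndarray                  # (20,) frequencies summing to 1

    def __post_init__(self) -> None:
        if not np.allclose(self.E, self.E.T, atol=1e-8):
            raise ValueError("empirical exchangeability must be symmetric")
        if np.any(self.E < 0) or np.any(self.P < 0):
            raise ValueError("negative entries in empirical model")
        self.E = (self.E + self.E.T) / 2.0
        np.fill_diagonal(self.E, 0.0)
        self.P = self.P / self.P.sum()


def load_empirical(name_or_path: str) -> EmpiricalModel:
    """Load a builtin model by name or any PAML-style .dat file by path.

    The format is 19 lower-triangle rows of exchangeabilities followed by 20
    stationary frequencies, whitespace separated, in the order
    ``ARNDCQEGHILKMFPSTWYV``.
    """
    name = name_or_path.upper()
    if name in BUILTIN_MODELS:
        text = (resources.files("sscpe.data") / f"{name.lower()}.dat").read_text()
    else:
        with open(name_or_path) as fh:
            text = fh.read()
        name = name_or_path
    values = []
    for line in text.splitlines():
        line = line.split("#")[0].split("!")[0]
        values.extend(float(tok) for tok in line.split())
    if len(values) < 210:
        raise ValueError("PAML matrix file needs 190 exchangeabilities + 20 frequencies")
    tri, freqs = values[:190], values[190:210]
    E = np.zeros((N_AA, N_AA))
    k = 0
    for i in range(1, N_AA):
        for j in range(i):
            E[i, j] = E[j, i] = tri[k]
            k += 1
    return EmpiricalModel(name=name, E=E, P=np.array(freqs))


def write_empirical(model: EmpiricalModel, path: str) -> None:
    with open(path, "w") as fh:
        for i in range(1, N_AA):
            fh.write(" ".join(f"{model.E[i, j]:.17g}" for j in range(i)) + "\n")
        fh.write("\n" + " ".join(f"{p:.17g}" for p in model.P) + "\n")


def _fixation_ratio(dx: np.ndarray) -> np.ndarray:
    """x / (exp(x) - 1), the relative-fixation function, with f(0) = 1."""
    out = np.ones_like(dx)
    nz = np.abs(dx) > 1e-12
    out[nz] = dx[nz] / np.expm1(dx[nz])
    return out


def hb_exchangeability(
    E_glob: np.ndarray, x: np.ndarray, Z: np.ndarray
) -> np.ndarray:
    """Per-site exchangeabilities with the fixation factor applied.

    ``x`` is the (L, 20) combined log-fitness (selection parameters already
    multiplied in) and ``Z`` the pre-floor normalizers of the stationary
    distribution.  Returns (L, 20, 20); the factor is symmetric in (a, b).
    """
    L = x.shape[0]
    out = np.empty((L, N_AA, N_AA))
    for i in range(L):
        dx = x[i][None, :] - x[i][:, None]           # x_b - x_a
        factor = Z[i] * np.exp(-x[i])[:, None] * _fixation_ratio(dx)
        out[i] = E_glob * factor
    return out


def hb_factor(x_row: np.ndarray, Z_i: float) -> np.ndarray:
    """The 20x20 fixation factor of one site (exchangeability multiplier)."""
    dx = x_row[None, :] - x_row[:, None]
    return Z_i * np.exp(-x_row)[:, None] * _fixation_ratio(dx)


def flux_match(
    emp: EmpiricalModel,
    x: np.ndarray,
    Z: np.ndarray,
    p_glob: np.ndarray,
    hb: bool,
) -> np.ndarray:
    """Global exchangeability whose site-averaged flux matches the empirical.

    The model flux at site i is ``P_i(a) P_i(b) E_i(a,b)`` with
    ``P_i(a) = p_glob(a) exp(x_ia)/Z_i``; averaging over sites and equating
    with ``P_emp(a) P_emp(b) E_emp(a,b)`` fixes ``E_glob`` per pair.
    """
    L = x.shape[0]
    denom = np.zeros((N_AA, N_AA))
    for i in range(L):
        w = np.exp(x[i][:, None] + x[i][None, :]) / Z[i] ** 2
        if hb:
            w = w * hb_factor(x[i], Z[i])
        denom += w
    denom /= L
    if np.any(denom <= 0):
        raise ValueError("degenerate flux denominator (all fitnesses at the floor?)")
    E_glob = (np.outer(emp.P, emp.P) * emp.E) / (np.outer(p_glob, p_glob) * denom)
    np.fill_diagonal(E_glob, 0.0)
    return (E_glob + E_glob.T) / 2.0


@dataclass
class SiteModelSet:
    """Per-site substitution processes Q_i(a,b) = E_i(a,b) P_i(b).

    ``E`` is normalized so every site's substitution rate is one; ``scale``
    carries the model-predicted rate under the rate1 convention (all ones
    under rate0).  ``rates`` always stores the predicted rates.
    """

    E: np.ndarray                   # (L, 20, 20) normalized exchangeabilities
    P: np.ndarray                   # (L, 20)
    scale: np.ndarray               # (L,) rate multipliers used by Q
    rates: np.ndarray               # (L,) model-predicted rates
    options: dict = field(default_factory=dict)
    _eig: tuple | None = None

    @property
    def L(self) -> int:
        return self.P.shape[0]

    def site_Q(self, i: int) -> np.ndarray:
        Q = self.E[i] * self.P[i][None, :] * self.scale[i]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def Q_stack(self) -> np.ndarray:
        Q = self.E * self.P[:, None, :] * self.scale[:, None, None]
        for i in range(self.L):
            np.fill_diagonal(Q[i], 0.0)
            np.fill_diagonal(Q[i], -Q[i].sum(axis=1))
        return Q

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-site symmetric eigendecomposition of the reversible Q.

        Returns (eigenvalues (L,20), left factors (L,20,20), right factors)
        such that ``exp(tQ_i) = right_i @ diag(exp(t w_i)) @ left_i``.
        """
        if self._eig is None:
            Q = self.Q_stack()
            sqp = np.sqrt(np.maximum(self.P, 1e-300))
            S = Q * (sqp[:, :, None] / sqp[:, None, :])
            S = (S + np.transpose(S, (0, 2, 1))) / 2.0
            w, V = np.linalg.eigh(S)
            right = V / sqp[:, :, None]
            left = np.transpose(V, (0, 2, 1)) * sqp[:, None, :]
            self._eig = (w, left, right)
        return self._eig

    def transition_matrices(self, t: float) -> np.ndarray:
        """(L, 20, 20) transition probabilities exp(t Q_i)."""
        w, left, right = self.eigensystem()
        ew = np.exp(t * w)
        T = np.einsum("iab,ib,ibc->iac", right, ew, left)
        return np.clip(T, 0.0, None)


def predicted_site_rates(E_site: np.ndarray, P: np.ndarray) -> np.ndarray:
    """R_i = sum_{a != b} P_i(a) P_i(b) E_i(a,b)."""
    Eoff = E_site.copy()
    for i in range(Eoff.shape[0]):
        np.fill_diagonal(Eoff[i], 0.0)
    return np.einsum("ia,ib,iab->i", P, P, Eoff)


def assemble_site_models(
    profiles: SiteProfileSet,
    emp: EmpiricalModel,
    hb: bool = True,
    fl: bool = True,
    rate1: bool = True,
) -> SiteModelSet:
    """Build the per-site substitution processes for one option combination."""
    x = profiles.combined_log_fitness()
    Z = profiles.Z
    p_glob = profiles.p_glob
    E_glob = flux_match(emp, x, Z, p_glob, hb) if fl else emp.E
    if hb:
        E_site = hb_exchangeability(E_glob, x, Z)
    else:
        E_site = np.broadcast_to(E_glob, (profiles.L, N_AA, N_AA)).copy()
    rates = predicted_site_rates(E_site, profiles.P)
    safe = np.maximum(rates, 1e-300)
    E_norm = E_site / safe[:, None, None]
    scale = rates.copy() if rate1 else np.ones_like(rates)
    return SiteModelSet(
        E=E_norm, P=profiles.P.copy(), scale=scale, rates=rates,
        options={"hb": hb, "fl": fl, "rate1": rate1,
                 "empirical": emp.name, "model": profiles.model},
    )


# ---------------------------------------------------------------------------
# approximate, tree-free likelihood
# ---------------------------------------------------------------------------

@dataclass
class PairCounts:
    """Aligned-pair substitution counts, symmetrized over the two sequences."""

    N_ab: np.ndarray                # (20, 20), N_ab = N_ba
    N_a: np.ndarray                 # (20,) = row sums

    @classmethod
    def from_pair(cls, seq1: str, seq2: str) -> "PairCounts":
        if len(seq1) != len(seq2):
            raise ValueError("aligned sequences must have equal length")
        N = np.zeros((N_AA, N_AA))
        for a, b in zip(seq1, seq2):
            if a in AA_INDEX and b in AA_INDEX:
                N[AA_INDEX[a], AA_INDEX[b]] += 1.0
        if N.sum() == 0:
            raise ValueError("no aligned non-gap positions in the pair")
        N = (N + N.T) / 2.0
        return cls(N_ab=N, N_a=N.sum(axis=1))

    def __add__(self, other: "PairCounts") -> "PairCounts":
        return PairCounts(self.N_ab + other.N_ab, self.N_a + other.N_a)


def approx_loglik(
    counts: PairCounts, E: np.ndarray, P: np.ndarray
) -> tuple[float, float]:
    """Short-branch pair likelihood with the divergence time optimized out.

    loglik = sum_{a != b} N(a,b) log E_ab + sum_a N(a) log P(a)
             + log(t) sum_a (N(a) - N(a,a)) + t sum_a N(a,a) P(a) E_aa
    with ``E_aa = -sum_{b != a} E_ab P(b)`` and the closed-form optimum
    ``t = sum_a (N(a)-N(a,a)) / (-sum_a N(a,a) P(a) E_aa)``.  Returns
    (loglik, t).  An identical pair has t = 0 and only the frequency term.
    """
    N = counts.N_ab
    Na = counts.N_a
    off = ~np.eye(N_AA, dtype=bool)
    n_subs = float(np.sum(Na) - np.trace(N))
    logP = np.log(np.maximum(P, 1e-300))
    base = float(np.sum(Na * logP))
    if n_subs <= 0:
        return base, 0.0
    with np.errstate(divide="ignore"):
        logE = np.log(np.maximum(E, 1e-300))
    base += float(np.sum(N[off] * logE[off]))
    E_diag = -np.sum(E * P[None, :] * off, axis=1)     # E_aa < 0
    denom = float(np.sum(np.diag(N) * P * E_diag))
    if denom >= 0:
        # no conserved positions to calibrate t: treat one substitution per
        # unit time (t = 1) and skip the degenerate terms
        return base, 1.0
    t_opt = -n_subs / denom
    loglik = base + n_subs * np.log(t_opt) + t_opt * denom
    return float(loglik), float(t_opt)


def site_pair_counts(
    sequences: list[str], reference: int = 0, columns: np.ndarray | None = None
) -> list[PairCounts]:
    """Per-site counts pairing every sequence with a reference sequence."""
    cols = columns if columns is not None else np.arange(len(sequences[0]))
    out = []
    for c in cols:
        N = np.zeros((N_AA, N_AA))
        ref = sequences[reference][c]
        for s_idx, seq in enumerate(sequences):
            if s_idx == reference:
                continue
            a, b = ref, seq[c]
            if a in AA_INDEX and b in AA_INDEX:
                N[AA_INDEX[a], AA_INDEX[b]] += 1.0
        N = (N + N.T) / 2.0
        out.append(PairCounts(N_ab=N, N_a=N.sum(axis=1)))
    return out


def approx_loglik_sites(
    counts_per_site: list[PairCounts], models: SiteModelSet
) -> float:
    """Sum of the approximate pair likelihood over sites, with each site's
    divergence time optimized under its own (scaled) exchangeability."""
    total = 0.0
    for i, counts in enumerate(counts_per_site):
        if counts.N_a.sum() == 0:
            continue
        E_eff = models.E[i] * models.scale[i]
        ll, _t = approx_loglik(counts, E_eff, models.P[i])
        total += ll
    return float(total)


def select_best(
    candidates: list[tuple[str, object]],
    score_fn,
) -> list[tuple[str, float]]:
    """Rank candidate models by a likelihood score (descending).

    Ties are broken by input order, which callers fix as
    JTT < LG < WAG then option tuples.  Returns [(name, score), ...].
    """
    if not candidates:
        raise ValueError("no candidate models")
    scored = [(name, float(score_fn(obj))) for name, obj in candidates]
    order = sorted(range(len(scored)), key=lambda k: (-scored[k][1], k))
    return [scored[k] for k in order]


def best_empirical(
    sequences: list[str], models: tuple[str, ...] = BUILTIN_MODELS
) -> tuple[str, list[tuple[str, float]]]:
    """Choose the empirical matrix with the best pooled pair likelihood."""
    pooled = None
    ref = sequences[0]
    for seq in sequences[1:]:
        pc = PairCounts.from_pair(ref, seq)
        pooled = pc if pooled is None else pooled + pc
    if pooled is None:
        raise ValueError("need at least two sequences")
    cands = [(nm, load_empirical(nm)) for nm in models]
    ranked = select_best(cands, lambda m: approx_loglik(pooled, m.E, m.P)[0])
    return ranked[0][0], ranked
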