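"""Desk-scale phylogenetic likelihood, RegMLaME scoring and tree comparison.

The pruning likelihood supports per-site reversible rate matrices (the
site-specific models assembled by :mod:`sscpe.substitution`) or a single
global matrix.  Tree comparison offers the topological Robinson-Foulds
distance (normalized by ``2 (n - 3)``) and the K / K2 branch-length scores:
matched bipartitions of a comparison tree are fitted as the reference
branches times one (K) or two (K2) scaling factors; the score is the root
mean square residual normalized by the reference tree's squared branch
lengths, with unmatched bipartitions contributing their full length.

The RegMLaME score, ``-loglik + mu * sum_b t_b``, blends maximum likelihood
with minimum evolution; the natural ``mu`` is the least-squares slope of
log-likelihood against total branch length across candidate trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import scipy.optimize

from .alphabet import AA_INDEX, N_AA

logger = logging.getLogger(__name__)


def read_tree(newick: str, taxon_namespace=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", taxon_namespace=taxon_namespace,
        preserve_underscores=True,
    )


@dataclass
class TreeScore:
    loglik: float
    branch_sum: float
    mu: float

    @property
    def regmlame(self) -> float:
        return -self.loglik + self.mu * self.branch_sum


@dataclass
class TreeComparison:
    k_score: float
    k2_score: float
    rf_norm: float
    scale_1param: float
    scale_slow: float
    scale_fast: float
    branch_class: dict


class _GlobalModelAdapter:
    """Present a single (Q, P) pair with the SiteModelSet interface."""

    def __init__(self, Q: np.ndarray, P: np.ndarray, L: int):
        self.P = np.broadcast_to(P, (L, Q.shape[0])).copy()
        self._Q = Q
        self.L = L
        self._eig = None

    def eigensystem(self):
        if self._eig is None:
            P = self.P[0]
            sqp = np.sqrt(np.maximum(P, 1e-300))
            S = self._Q * (sqp[:, None] / sqp[None, :])
            S = (S + S.T) / 2.0
            w, V = np.linalg.eigh(S)
            right = (V / sqp[:, None])[None, ...]
            left = (V.T * sqp[None, :])[None, ...]
            self._eig = (w[None, :], left, right)
        return self._eig

    def transition_matrices(self, t: float) -> np.ndarray:
        w, left, right = self.eigensystem()
        ew = np.exp(t * w)
        T = np.einsum("iab,ib,ibc->iac", right, ew, left)
        return np.clip(np.broadcast_to(T, (self.L, T.shape[1], T.shape[2])), 0.0, None)


def _leaf_partials(msa: dict[str, str], taxa: list[str], L: int, n_states: int,
                   state_index: dict[str, int]) -> dict[str, np.ndarray]:
    partials = {}
    for name in taxa:
        seq = msa[name]
        arr = np.ones((L, n_states))
        for i in range(L):
            a = seq[i]
            if a in state_index:
                arr[i] = 0.0
                arr[i, state_index[a]] = 1.0
        partials[name] = arr
    return partials


def pruning_loglik(
    tree: dendropy.Tree,
    msa: dict[str, str],
    models,
    columns: np.ndarray | None = None,
) -> float:
    """Felsenstein pruning log-likelihood with per-site models.

    ``models`` needs ``P`` (L x 20) and ``transition_matrices(t)``; gaps and
    unknown characters are treated as missing data.  The root is placed at
    the tree's seed node; reversibility makes the value root-invariant.
    """
    P = models.P
    L = P.shape[0]
    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [t for t in taxa if t not in msa]
    if missing:
        raise ValueError(f"leaves missing from the alignment: {missing}")
    seqs = msa
    if columns is not None:
        seqs = {k: "".join(v[c] for c in columns) for k, v in msa.items()}
    leaf_p = _leaf_partials(seqs, taxa, L, N_AA, AA_INDEX)
    logscale = np.zeros(L)
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            partial[id(node)] = leaf_p[node.taxon.label]
            continue
        prod = np.ones((L, N_AA))
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            T = models.transition_matrices(max(t, 0.0))
            prod *= np.einsum("iab,ib->ia", T, partial[id(child)])
        mx = prod.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        logscale += np.log(mx)
        partial[id(node)] = prod / mx[:, None]
    root = partial[id(tree.seed_node)]
    site_l = np.sum(P * root, axis=1)
    return float(np.sum(np.log(np.maximum(site_l, 1e-300))) + logscale.sum())


def branch_sum(tree: dendropy.Tree) -> float:
    return float(sum(e.length or 0.0 for e in tree.preorder_edge_iter()
                     if e.head_node is not tree.seed_node))


def fit_mu(points: list[tuple[float, float]]) -> float:
    """Least-squares slope of log-likelihood vs total branch length."""
    if len(points) < 2:
        raise ValueError("need at least two trees")
    sums = np.array([p[1] for p in points])
    lls = np.array([p[0] for p in points])
    if np.allclose(sums, sums[0]):
        raise ValueError("branch sums are identical; slope undefined")
    slope, _intercept = np.polyfit(sums, lls, 1)
    return float(slope)


def regmlame(
    tree: dendropy.Tree, msa: dict[str, str], models, mu: float,
    columns: np.ndarray | None = None,
) -> TreeScore:
    """Regularized score -loglik + mu * sum of branch lengths."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    ll = pruning_loglik(tree, msa, models, columns)
    return TreeScore(loglik=ll, branch_sum=branch_sum(tree), mu=mu)


# ---------------------------------------------------------------------------
# tree comparison
# ---------------------------------------------------------------------------

def _bipartition_lengths(tree: dendropy.Tree) -> dict[int, float]:
    """Branch length per leaf-set bitmask (trivial and internal bipartitions)."""
    tree.encode_bipartitions()
    out: dict[int, float] = {}
    all_mask = tree.taxon_namespace.all_taxa_bitmask()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.bipartition is None:
            continue
        mask = edge.bipartition.split_bitmask
        norm = min(mask & all_mask, ~mask & all_mask)
        if norm == 0:
            continue
        out[norm] = out.get(norm, 0.0) + (edge.length or 0.0)
    return out


def _check_same_taxa(t1: dendropy.Tree, t2: dendropy.Tree) -> None:
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")


def _shared_namespace(reference: dendropy.Tree, comparison: dendropy.Tree):
    ns = dendropy.TaxonNamespace()
    r = read_tree(reference.as_string(schema="newick"), ns)
    c = read_tree(comparison.as_string(schema="newick"), ns)
    return r, c


def k_score(reference: dendropy.Tree, comparison: dendropy.Tree) -> tuple[float, float]:
    """One-parameter branch-length fit of comparison against reference.

    Matched bipartitions contribute ``(t_comp - s * t_ref)^2``; bipartitions
    private to one tree contribute their (scaled) length squared.  The score
    is ``sqrt(SSE / sum t_ref^2)``.  Returns (k, scale).
    """
    _check_same_taxa(reference, comparison)
    r, c = _shared_namespace(reference, comparison)
    br = _bipartition_lengths(r)
    bc = _bipartition_lengths(c)
    matched = sorted(set(br) & set(bc))
    only_r = [m for m in br if m not in bc]
    only_c = [m for m in bc if m not in br]
    tr = np.array([br[m] for m in matched])
    tc = np.array([bc[m] for m in matched])
    tr2_all = sum(v**2 for v in br.values())
    denom = float(np.sum(tr**2) + sum(br[m] ** 2 for m in only_r))
    s = float(np.sum(tr * tc) / denom) if denom > 0 else 0.0
    sse = float(np.sum((tc - s * tr) ** 2))
    sse += sum((s * br[m]) ** 2 for m in only_r)
    sse += sum(bc[m] ** 2 for m in only_c)
    k = np.sqrt(sse / tr2_all) if tr2_all > 0 else 0.0
    return float(k), s


def _two_class_fit(
    tr: np.ndarray, tc: np.ndarray, labels: np.ndarray,
    n_iter: int = 50, fix_labels: bool = False,
) -> tuple[float, np.ndarray, float, float]:
    """Alternating two-scale / assignment least squares; returns
    (sse, labels, s_slow, s_fast)."""
    labels = labels.copy()
    for _ in range(n_iter):
        scales = []
        for cls in (0, 1):
            sel = labels == cls
            d = float(np.sum(tr[sel] ** 2))
            scales.append(float(np.sum(tr[sel] * tc[sel]) / d) if d > 0 else 0.0)
        if fix_labels:
            break
        resid = np.stack([(tc - s * tr) ** 2 for s in scales])
        new_labels = np.argmin(resid, axis=0)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    s0, s1 = scales
    sse = float(np.sum((tc - np.where(labels == 0, s0, s1) * tr) ** 2))
    slow, fast = sorted((s0, s1))
    return sse, labels, slow, fast


def k2_score(
    reference: dendropy.Tree,
    comparison: dendropy.Tree,
    branch_classes: dict[int, int] | None = None,
) -> TreeComparison:
    """Two-scale branch-length fit (slow vs fast classes of branches).

    Classes may be supplied per bipartition bitmask; otherwise the
    assignment is fitted jointly with the scales by alternating least
    squares, seeded from the single-scale residual split.  The single-scale
    solution is always a candidate, so K2 <= K.
    """
    _check_same_taxa(reference, comparison)
    k, s1 = k_score(reference, comparison)
    r, c = _shared_namespace(reference, comparison)
    br = _bipartition_lengths(r)
    bc = _bipartition_lengths(c)
    matched = sorted(set(br) & set(bc))
    only_r = [m for m in br if m not in bc]
    only_c = [m for m in bc if m not in br]
    tr = np.array([br[m] for m in matched])
    tc = np.array([bc[m] for m in matched])
    tr2_all = sum(v**2 for v in br.values())
    unmatched_sse = sum((s1 * br[m]) ** 2 for m in only_r) + sum(
        bc[m] ** 2 for m in only_c
    )
    n_eff = len(matched)
    rf = rf_normalized(reference, comparison) if len(br) > 3 else 0.0
    if n_eff < 4 or (branch_classes is None and np.allclose(tr, 0)):
        logger.warning("too few matched branches for a two-class fit; using K")
        return TreeComparison(k, k, rf, s1, s1, s1, {})
    if branch_classes is not None:
        labels = np.array([branch_classes.get(m, 0) for m in matched])
        sse, labels, slow, fast = _two_class_fit(tr, tc, labels, fix_labels=True)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(tr > 0, tc / np.maximum(tr, 1e-300), s1)
        best = None
        seeds = [
            (ratio > np.median(ratio)).astype(int),
            (tc - s1 * tr > 0).astype(int),
            np.zeros(n_eff, dtype=int),
        ]
        for seed_labels in seeds:
            fit = _two_class_fit(tr, tc, seed_labels)
            if best is None or fit[0] < best[0]:
                best = fit
        sse, labels, slow, fast = best
    k2 = float(np.sqrt((sse + unmatched_sse) / tr2_all)) if tr2_all > 0 else 0.0
    k2 = min(k2, k)
    classes = {m: int(l) for m, l in zip(matched, labels)}
    return TreeComparison(k, k2, rf, s1, slow, fast, classes)


def rf_normalized(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Robinson-Foulds bipartition distance normalized to [0, 1]."""
    _check_same_taxa(t1, t2)
    n = len(t1.leaf_nodes())
    if n < 4:
        raise ValueError("RF distance needs at least 4 leaves")
    a, b = _shared_namespace(t1, t2)
    d = dendropy.calculate.treecompare.symmetric_difference(a, b)
    return float(d) / (2.0 * (n - 3))


def optimize_branch_lengths(
    tree: dendropy.Tree,
    msa: dict[str, str],
    models,
    mu: float = 0.0,
    t_max: float = 10.0,
    n_cycles: int = 20,
    tol: float = 1e-6,
    columns: np.ndarray | None = None,
) -> dendropy.Tree:
    """Coordinate-wise optimization of branch lengths at fixed topology.

    Minimizes ``-loglik + mu * sum t_b`` (maximum likelihood at mu = 0) by
    bounded scalar optimization of one branch at a time, cycling until the
    objective improves by less than ``tol``.
    """
    tree = tree.clone(depth=1)
    edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    for e in edges:
        if e.length is None:
            e.length = 0.1

    def objective() -> float:
        return -pruning_loglik(tree, msa, models, columns) + mu * branch_sum(tree)

    prev = objective()
    for _cycle in range(n_cycles):
        for e in edges:
            def f(t: float) -> float:
                e.length = t
                return objective()

            res = scipy.optimize.minimize_scalar(
                f, bounds=(0.0, t_max), method="bounded",
                options={"xatol": 1e-8},
            )
            e.length = float(res.x)
        cur = objective()
        if prev - cur < tol:
            break
        prev = cur
    else:
        logger.warning("branch-length optimization: cycle limit reached "
                       f"(last improvement {prev - cur:.2e})")
    return tree
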