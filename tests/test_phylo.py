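"""Pruning likelihood, RegMLaME, K/K2 branch fits, Robinson-Foulds."""

import numpy as np
import pytest

from sscpe.alphabet import AA_INDEX, AMINO_ACIDS
from sscpe.phylo import (
    _GlobalModelAdapter,
    branch_sum,
    fit_mu,
    k2_score,
    k_score,
    optimize_branch_lengths,
    pruning_loglik,
    read_tree,
    regmlame,
    rf_normalized,
)
from sscpe.profiles import SiteProfileSet, stationary_distribution
from sscpe.substitution import assemble_site_models, load_empirical


@pytest.fixture(scope="module")
def site_models():
    rng = np.random.default_rng(1)
    L = 3
    phi = rng.normal(0, 0.5, (L, 20))
    pg = np.full(20, 0.05)
    P, Z = stationary_distribution(0.7 * phi, pg)
    prof = SiteProfileSet(model="WT", P=P, p_glob=pg, Z=Z,
                          lambda_stab=0.7, phi_stab=phi)
    return assemble_site_models(prof, load_empirical("LG"))


def _jc20_adapter(L):
    """20-state equal-exchangeability model (analytically tractable)."""
    E = np.ones((20, 20))
    P = np.full(20, 0.05)
    Q = E * P[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return _GlobalModelAdapter(Q, P, L)


class TestPruning:
    def test_identical_pair_zero_branches(self, site_models):
        tree = read_tree("(A:0.0,B:0.0);")
        msa = {"A": "ACD", "B": "ACD"}
        ll = pruning_loglik(tree, msa, site_models)
        expect = sum(
            np.log(site_models.P[i, AA_INDEX[c]]) for i, c in enumerate("ACD")
        )
        assert np.isclose(ll, expect, atol=1e-10)

    def test_matches_exhaustive_state_summation(self, site_models):
        tree = read_tree("(A:0.3,B:0.5,C:0.2);")
        msa = {"A": "ACW", "B": "ADW", "C": "WCW"}
        ll = pruning_loglik(tree, msa, site_models)
        total = 0.0
        for i in range(3):
            Ts = {nm: site_models.transition_matrices(t)[i]
                  for nm, t in (("A", 0.3), ("B", 0.5), ("C", 0.2))}
            site = 0.0
            for root in range(20):
                p = site_models.P[i][root]
                for nm in "ABC":
                    p *= Ts[nm][root, AA_INDEX[msa[nm][i]]]
                site += p
            total += np.log(site)
        assert abs(ll - total) < 1e-12

    def test_rerooting_invariance(self, site_models):
        msa = {"A": "ACW", "B": "ADW", "C": "WCW"}
        t1 = read_tree("(A:0.3,B:0.5,C:0.2);")
        t2 = read_tree("(B:0.5,(C:0.2,A:0.3):0.0);")
        assert abs(pruning_loglik(t1, msa, site_models)
                   - pruning_loglik(t2, msa, site_models)) < 1e-10

    def test_gaps_treated_as_missing(self, site_models):
        tree = read_tree("(A:0.3,B:0.5);")
        ll_obs = pruning_loglik(tree, {"A": "A-D", "B": "ACD"}, site_models)
        # marginalizing the gap equals summing the likelihood over all states
        total = 0.0
        for aa in AMINO_ACIDS:
            total += np.exp(pruning_loglik(
                tree, {"A": f"A{aa}D", "B": "ACD"}, site_models))
        assert np.isclose(np.exp(ll_obs), total, rtol=1e-8)

    def test_unmatched_leaf_raises(self, site_models):
        tree = read_tree("(A:0.1,Z:0.1);")
        with pytest.raises(ValueError):
            pruning_loglik(tree, {"A": "ACD"}, site_models)


class TestMuAndRegmlame:
    def test_two_point_slope(self):
        assert fit_mu([(-10.0, 1.0), (-8.0, 2.0)]) == pytest.approx(2.0)

    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        sums = rng.uniform(0.5, 3.0, 20)
        lls = 4.2 * sums - 7.0
        assert fit_mu(list(zip(lls, sums))) == pytest.approx(4.2, abs=1e-10)

    def test_noisy_slope_within_three_se(self):
        rng = np.random.default_rng(7)
        n, sigma, mu_true = 50, 0.3, 2.5
        sums = rng.uniform(0.5, 4.0, n)
        lls = mu_true * sums - 3.0 + rng.normal(0, sigma, n)
        se = sigma / (np.std(sums) * np.sqrt(n))
        assert abs(fit_mu(list(zip(lls, sums))) - mu_true) < 3 * se

    def test_identical_sums_rejected(self):
        with pytest.raises(ValueError):
            fit_mu([(-10.0, 1.0), (-8.0, 1.0)])

    def test_regmlame_reduces_to_negative_loglik(self, site_models):
        tree = read_tree("(A:0.3,B:0.5,C:0.2);")
        msa = {"A": "ACW", "B": "ADW", "C": "WCW"}
        sc = regmlame(tree, msa, site_models, mu=0.0)
        assert sc.regmlame == -sc.loglik

    def test_branch_addition_adds_mu(self, site_models):
        msa = {"A": "ACW", "B": "ADW", "C": "WCW"}
        t1 = read_tree("(A:0.3,B:0.5,C:0.2);")
        mu = 1.7
        s1 = regmlame(t1, msa, site_models, mu=mu)
        assert np.isclose(
            s1.regmlame, -s1.loglik + mu * 1.0, atol=1e-12
        )
        # monotone in mu at fixed tree
        s2 = regmlame(t1, msa, site_models, mu=2 * mu)
        assert s2.regmlame >= s1.regmlame


class TestKScores:
    NWK = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.07,E:0.2);"

    def test_identical_trees(self):
        t1, t2 = read_tree(self.NWK), read_tree(self.NWK)
        k, s = k_score(t1, t2)
        assert k == 0.0 and s == 1.0
        comp = k2_score(t1, read_tree(self.NWK))
        assert comp.k2_score == 0.0 and comp.rf_norm == 0.0

    def test_uniform_rescaling_recovered_exactly(self):
        t1 = read_tree(self.NWK)
        t2 = read_tree(self.NWK)
        for e in t2.preorder_edge_iter():
            if e.length is not None:
                e.length *= 0.37
        k, s = k_score(t1, t2)
        assert k < 1e-12
        assert s == pytest.approx(0.37)

    def test_k_equals_grid_search_minimum(self):
        rng = np.random.default_rng(3)
        t1 = read_tree(self.NWK)
        t2 = read_tree(self.NWK)
        for e in t2.preorder_edge_iter():
            if e.length is not None:
                e.length = max(e.length + rng.normal(0, 0.05), 0.001)
        k, s = k_score(t1, t2)
        br = [e.length for e in t1.preorder_edge_iter() if e.length]
        # brute-force scan over the scale factor
        grid = np.linspace(0.0, 3.0, 30001)
        t1b, t2b = read_tree(self.NWK), t2
        from sscpe.phylo import _bipartition_lengths, _shared_namespace
        r, c = _shared_namespace(t1b, t2b)
        br_map, bc_map = _bipartition_lengths(r), _bipartition_lengths(c)
        tr = np.array([br_map[m] for m in br_map])
        tc = np.array([bc_map[m] for m in br_map])
        sse_grid = ((tc[None, :] - grid[:, None] * tr[None, :]) ** 2).sum(axis=1)
        k_grid = np.sqrt(sse_grid.min() / np.sum(tr**2))
        assert k == pytest.approx(k_grid, abs=1e-4)

    def test_two_class_construction_recovered(self):
        t1 = read_tree(self.NWK)
        t2 = read_tree(self.NWK)
        for i, e in enumerate(t2.preorder_edge_iter()):
            if e.length is not None:
                e.length *= 0.2 if i % 2 == 0 else 1.0
        comp = k2_score(t1, t2)
        assert comp.k2_score < 1e-10
        assert comp.scale_slow == pytest.approx(0.2)
        assert comp.scale_fast == pytest.approx(1.0)

    def test_k2_never_exceeds_k_on_random_pairs(self, random_tree_factory):
        rng = np.random.default_rng(11)
        labels = [f"T{i}" for i in range(8)]
        for _ in range(100):
            t1 = random_tree_factory(labels, rng)
            t2 = random_tree_factory(labels, rng)
            comp = k2_score(t1, t2)
            assert comp.k2_score <= comp.k_score + 1e-12

    def test_user_supplied_branch_classes(self):
        t1 = read_tree(self.NWK)
        t2 = read_tree(self.NWK)
        for e in t2.preorder_edge_iter():
            if e.length is not None:
                e.length *= 0.5
        from sscpe.phylo import _bipartition_lengths, _shared_namespace
        r, _c = _shared_namespace(t1, t2)
        classes = {m: 0 for m in _bipartition_lengths(r)}
        comp = k2_score(t1, t2, branch_classes=classes)
        assert comp.k2_score < 1e-12


class TestRobinsonFoulds:
    def test_identical_topologies(self):
        t = "((A:1,B:1):1,(C:1,D:1):1,E:1);"
        assert rf_normalized(read_tree(t), read_tree(t)) == 0.0

    def test_maximally_different(self):
        t1 = read_tree("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t2 = read_tree("((A:1,C:1):1,(B:1,E:1):1,D:1);")
        assert rf_normalized(t1, t2) == 1.0

    def test_too_few_leaves_rejected(self):
        t = "(A:1,B:1,C:1);"
        with pytest.raises(ValueError):
            rf_normalized(read_tree(t), read_tree(t))

    def test_matches_bipartition_enumeration_on_six_leaves(self):
        """Independent oracle: enumerate internal bipartitions with a
        hand-written newick walker."""
        def bipartitions(newick):
            # leaf sets of internal edges via a tiny recursive parser
            import re

            tokens = re.findall(r"[(),]|[^(),:;]+(?::[0-9.eE+-]+)?", newick)
            stack = [[]]
            splits = set()
            all_leaves = set()
            for tok in tokens:
                if tok == "(":
                    stack.append([])
                elif tok == ")":
                    grp = stack.pop()
                    leaves = frozenset().union(*grp)
                    stack[-1].append(leaves)
                    splits.add(leaves)
                elif tok == ",":
                    continue
                else:
                    name = tok.split(":")[0]
                    if name:
                        stack[-1].append(frozenset([name]))
                        all_leaves.add(name)
            out = set()
            for sp in splits:
                if 1 < len(sp) < len(all_leaves) - 1:
                    comp = frozenset(all_leaves - sp)
                    out.add(min(sp, comp, key=sorted))
            return out

        n1 = "(((A:1,B:1):1,(C:1,D:1):1):1,E:1,F:1);"
        n2 = "((A:1,C:1):1,(B:1,(D:1,F:1):1):1,E:1);"
        b1, b2 = bipartitions(n1), bipartitions(n2)
        expected = len(b1 ^ b2) / (2.0 * (6 - 3))
        got = rf_normalized(read_tree(n1), read_tree(n2))
        assert got == pytest.approx(expected)


class TestBranchOptimization:
    def test_two_leaf_matches_closed_form(self):
        """Equal-exchangeability model: the ML pairwise distance has the
        analytic form -log((p_same - 1/20)/(19/20)) at unit rate."""
        adapter = _jc20_adapter(200)
        rng = np.random.default_rng(5)
        anc = rng.choice(20, size=200)
        t_true = 0.6
        T = adapter.transition_matrices(t_true)[0]
        der = np.array([rng.choice(20, p=T[a] / T[a].sum()) for a in anc])
        s1 = "".join(AMINO_ACIDS[i] for i in anc)
        s2 = "".join(AMINO_ACIDS[i] for i in der)
        p_same = np.mean(anc == der)
        # rate of the adapter's Q: sum_a P_a * (-Q_aa) = 19/20
        rate = 19.0 / 20.0
        t_hat = -np.log((p_same - 1 / 20) / (19 / 20)) / (20 / 19) / rate
        tree = optimize_branch_lengths(
            read_tree("(A:0.1,B:0.1);"), {"A": s1, "B": s2}, adapter
        )
        assert branch_sum(tree) == pytest.approx(t_hat, abs=1e-4)

    def test_large_mu_collapses_branches(self, site_models):
        msa = {"A": "ACW", "B": "ADW", "C": "WCW"}
        tree = optimize_branch_lengths(
            read_tree("(A:0.3,B:0.5,C:0.2);"), msa, site_models, mu=1e6
        )
        assert branch_sum(tree) < 1e-4
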