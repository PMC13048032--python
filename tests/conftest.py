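"""Shared synthetic fixtures (session-scoped: several are expensive)."""

import numpy as np
import pytest

from sscpe.enm import build_cartesian_enm, build_torsional_enm
from sscpe.fixtures import (
    FixtureSpec,
    design_sequence,
    make_backbone,
    make_decoy_library,
    make_pooled_statistics,
    rebuilt_with_sequence,
)
from sscpe.params import StabilityParameters
from sscpe.structure import build_contact_map


@pytest.fixture(scope="session")
def helix20():
    s = make_backbone(FixtureSpec(L=20, geometry="helix", seed=1))
    cm = build_contact_map(s, "enm")
    return s, cm


@pytest.fixture(scope="session")
def helix20_tnm(helix20):
    s, cm = helix20
    return build_torsional_enm(s, cm)


@pytest.fixture(scope="session")
def helix20_anm(helix20):
    s, cm = helix20
    return build_cartesian_enm(s, cm)


@pytest.fixture(scope="session")
def bundle30():
    """Compact 30-residue bundle with a stability-designed sequence."""
    s0 = make_backbone(FixtureSpec(L=30, geometry="helix_bundle", seed=4,
                                   helix_len=8, turn_len=3))
    cs = make_pooled_statistics(30, seed=4)
    seq = design_sequence(s0, cs, seed=0, n_sweeps=5)
    s = rebuilt_with_sequence(s0, seq)
    cm_stab = build_contact_map(s, "stability")
    cm_enm = build_contact_map(s, "enm")
    return {"structure": s, "cm_stab": cm_stab, "cm_enm": cm_enm, "cs": cs,
            "sp": StabilityParameters()}


@pytest.fixture(scope="session")
def bundle60():
    """Larger bundle (>=50 sites) for trend tests, with modes and contacts."""
    s = make_backbone(FixtureSpec(L=60, geometry="helix_bundle", seed=3))
    cm_enm = build_contact_map(s, "enm")
    cm_stab = build_contact_map(s, "stability")
    mb = build_torsional_enm(s, cm_enm)
    return {"structure": s, "cm_enm": cm_enm, "cm_stab": cm_stab, "tnm": mb}


@pytest.fixture(scope="session")
def decoys30():
    return make_decoy_library(8, 30, seed=1)


def random_binary_tree(labels, rng):
    """Random topology by sequential attachment, exponential branch lengths."""
    from sscpe.phylo import read_tree

    taxa = list(labels)
    rng.shuffle(taxa)
    newick = (f"({taxa[0]}:{rng.exponential(0.3):.6f},"
              f"{taxa[1]}:{rng.exponential(0.3):.6f},"
              f"{taxa[2]}:{rng.exponential(0.3):.6f});")
    tree = read_tree(newick)
    for label in taxa[3:]:
        edges = [e for e in tree.preorder_edge_iter()
                 if e.head_node is not tree.seed_node]
        edge = edges[rng.integers(0, len(edges))]
        old_len = edge.length or 0.1
        parent = edge.tail_node
        child = edge.head_node
        new_node = parent.new_child(edge_length=old_len / 2)
        parent.remove_child(child)
        new_node.add_child(child)
        child.edge.length = old_len / 2
        taxon = tree.taxon_namespace.new_taxon(label)
        new_node.new_child(taxon=taxon, edge_length=float(rng.exponential(0.3)))
    return tree


@pytest.fixture(scope="session")
def random_tree_factory():
    return random_binary_tree


@pytest.fixture(scope="session")
def bundle_ensemble():
    """Pooled per-site observables over three bundle fixtures (180 sites):
    contact number, mean mutation-induced RMSD of the mutated site, and mean
    squared deformation measured at each monitored site."""
    from sscpe.alphabet import AA_INDEX
    from sscpe.mutation import (MutationParameters, build_effect_table,
                                mutation_force)

    counts_all, rmsd_all, msd_all, tabs = [], [], [], []
    mp = MutationParameters()
    for seed in (3, 8, 13):
        s = make_backbone(FixtureSpec(L=60, geometry="helix_bundle", seed=seed))
        cm = build_contact_map(s, "enm")
        mb = build_torsional_enm(s, cm)
        counts = cm.C.sum(axis=1)
        tab = build_effect_table(s, cm, mb)
        tabs.append((s, cm, mb, tab, counts))
        mean_rmsd = np.array([
            np.mean([tab.rmsd[i, b] for b in range(20)
                     if b != AA_INDEX[s.sequence[i]]])
            for i in range(s.L)
        ])
        per_res = np.zeros(s.L)
        n_mut = 0
        atom_res = mb.atom_residue
        for m in range(0, s.L, 2):
            for b in "AWDK":
                if b == s.sequence[m]:
                    continue
                mf = mutation_force(s, cm, mp, m, s.sequence[m], b, mb=mb)
                dr = mb.modes.T @ (mf.mode_projections / mb.omegas**2)
                dr2 = (dr.reshape(-1, 3) ** 2).sum(axis=1)
                per_res += np.array([dr2[atom_res == i].mean()
                                     for i in range(s.L)])
                n_mut += 1
        counts_all += counts.tolist()
        rmsd_all += mean_rmsd.tolist()
        msd_all += (per_res / n_mut).tolist()
    return {"counts": np.array(counts_all), "mean_rmsd": np.array(rmsd_all),
            "monitored_msd": np.array(msd_all), "fixtures": tabs}
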