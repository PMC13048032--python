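"""Mutation forces, linear-response deformations and weight fitting."""

import numpy as np
import pytest
import scipy.linalg
import scipy.stats

from sscpe.alphabet import AA_INDEX, AMINO_ACIDS
from sscpe.enm import (
    ModeBasis,
    build_cartesian_enm,
    build_torsional_enm,
    cartesian_hessian,
    torsion_jacobian,
    _eckart_project,
)
from sscpe.fixtures import FixtureSpec, make_backbone
from sscpe.mutation import (
    DeformationPrediction,
    build_effect_table,
    fit_sigma_p,
    fit_weights,
    functional_change_filter,
    mutation_force,
    predict_deformation,
    total_msd_model,
    wild_type_average,
)
from sscpe.params import ENMParameters, MutationParameters
from sscpe.structure import build_contact_map, contact_counts


@pytest.fixture(scope="module")
def helix6():
    s = make_backbone(FixtureSpec(L=6, geometry="helix", seed=11))
    cm = build_contact_map(s, "enm")
    return s, cm, build_torsional_enm(s, cm)


def _toy_basis(omegas, n_points=2):
    """Mode basis with unit masses and canonical-axis modes."""
    n = len(omegas)
    modes = np.zeros((n, 3 * n_points))
    for a in range(n):
        modes[a, a % (3 * n_points)] = 1.0
    return ModeBasis(omegas=np.asarray(omegas, float), modes=modes,
                     masses=np.ones(3 * n_points), variant="cartesian",
                     atom_residue=np.arange(n_points),
                     coords=np.zeros((n_points, 3)))


class TestMutationForce:
    def test_identity_mutation_is_zero(self, helix6):
        s, cm, mb = helix6
        mf = mutation_force(s, cm, MutationParameters(), 2, s.sequence[2],
                            s.sequence[2], mb=mb)
        assert not np.any(mf.cartesian_force)
        assert not np.any(mf.mode_projections)

    def test_site_without_contacts_gives_zero_force(self, helix6):
        s, cm, mb = helix6
        isolated = type(cm)(C=np.zeros_like(cm.C), vectors={}, flavor="enm")
        mf = mutation_force(s, isolated, MutationParameters(), 2,
                            s.sequence[2], "W", mb=mb)
        assert not np.any(mf.cartesian_force)

    def test_total_force_vanishes(self, helix6):
        s, cm, mb = helix6
        for b in "WGD":
            mf = mutation_force(s, cm, MutationParameters(), 3, s.sequence[3],
                                b, mb=mb)
            np.testing.assert_allclose(
                mf.cartesian_force.reshape(-1, 3).sum(axis=0), 0.0, atol=1e-10
            )

    def test_nonstandard_amino_acid_rejected(self, helix6):
        s, cm, mb = helix6
        with pytest.raises(ValueError):
            mutation_force(s, cm, MutationParameters(), 0, s.sequence[0], "X", mb=mb)


class TestPredictDeformation:
    def test_zero_force_zero_deformation(self, helix6):
        s, cm, mb = helix6
        mf = mutation_force(s, cm, MutationParameters(), 1, s.sequence[1],
                            s.sequence[1], mb=mb)
        assert predict_deformation(mf, mb) == (0.0, 0.0)

    def test_de_matches_explicit_pseudo_inverse(self, helix6):
        """Mode-sum DE equals F^T J (J^T H J)^-1 J^T F built from the
        explicit Cartesian Hessian and torsion Jacobian."""
        s, cm, mb = helix6
        mf = mutation_force(s, cm, MutationParameters(), 3, s.sequence[3],
                            "W", mb=mb)
        _r, de = predict_deformation(mf, mb)
        springs = [(p, q, vec / dist) for (vec, dist, p, q) in cm.vectors.values()]
        H = cartesian_hessian(s.flat_coords(), springs, 1.0)
        masses3 = np.repeat(s.flat_masses(), 3)
        J_raw, _ = torsion_jacobian(s)
        J = _eckart_project(J_raw, s.flat_coords(), masses3)
        Ht = J.T @ H @ J + 0.2 * np.eye(J.shape[1])
        de_oracle = mf.cartesian_force @ J @ np.linalg.solve(
            Ht, J.T @ mf.cartesian_force
        )
        assert np.isclose(de, de_oracle, rtol=1e-6)

    def test_de_matches_pinv_for_cartesian_variant(self, helix6):
        s, cm, _ = helix6
        mb = build_cartesian_enm(s, cm)
        mf = mutation_force(s, cm, MutationParameters(), 3, s.sequence[3],
                            "W", mb=mb)
        _r, de = predict_deformation(mf, mb)
        springs = [(i, j, None) for (i, j) in cm.vectors]
        H = cartesian_hessian(s.ca_coords, springs, 1.0)
        m = np.repeat(s.residue_masses, 3)
        Hw = H / np.sqrt(np.outer(m, m))
        Fw = mf.cartesian_force / np.sqrt(m)
        de_oracle = Fw @ np.linalg.pinv(Hw, rcond=1e-8) @ Fw
        assert np.isclose(de, de_oracle, rtol=1e-6)

    def test_rmsd_invariant_under_force_constant(self, helix6):
        s, cm, _ = helix6
        r = {}
        for K in (1.0, 10.0):
            mb = build_torsional_enm(s, cm, ENMParameters(K=K))
            mf = mutation_force(s, cm, MutationParameters(), 2, s.sequence[2],
                                "W", mb=mb, K=K)
            r[K], _ = predict_deformation(mf, mb)
        assert np.isclose(r[1.0], r[10.0], rtol=1e-8)

    def test_rmsd_invariant_under_rotation(self, helix6):
        from scipy.spatial.transform import Rotation

        s, cm, mb = helix6
        mf = mutation_force(s, cm, MutationParameters(), 2, s.sequence[2],
                            "F", mb=mb)
        r1, de1 = predict_deformation(mf, mb)
        rot = Rotation.from_euler("xyz", [0.4, 1.3, -0.2]).as_matrix()
        s2 = s.transformed(rot, np.array([1.0, 2.0, 3.0]))
        cm2 = build_contact_map(s2, "enm")
        mb2 = build_torsional_enm(s2, cm2)
        mf2 = mutation_force(s2, cm2, MutationParameters(), 2, s2.sequence[2],
                             "F", mb=mb2)
        r2, de2 = predict_deformation(mf2, mb2)
        assert np.isclose(r1, r2, rtol=1e-8)
        assert np.isclose(de1, de2, rtol=1e-8)

    def test_mismatched_basis_raises(self, helix6):
        s, cm, mb = helix6
        mf = mutation_force(s, cm, MutationParameters(), 2, s.sequence[2],
                            "W", mb=mb)
        other = _toy_basis([1.0, 2.0])
        with pytest.raises(ValueError):
            predict_deformation(mf, other)


class TestEffectTable:
    def test_wild_type_entry_is_mean_at_zero_lambda(self, helix6):
        s, cm, mb = helix6
        tab = build_effect_table(s, cm, mb, lambda_str=0.0)
        for i in range(s.L):
            a = AA_INDEX[s.sequence[i]]
            others = [b for b in range(20) if b != a]
            assert np.isclose(tab.rmsd[i, a], tab.rmsd[i, others].mean())
            assert tab.rmsd[i, others].min() > 0

    def test_wild_type_average_limits(self):
        vals = np.array([1.0, 2.0, 5.0])
        assert np.isclose(wild_type_average(vals, 0.0), vals.mean())
        assert np.isclose(wild_type_average(np.full(19, 3.3), 7.0), 3.3)
        # strongly negative selection weight concentrates on the largest
        # deformation (phi = -value, lambda < 0)
        assert np.isclose(wild_type_average(vals, -10.0), 5.0, atol=0.01)
        # direct weighted-average oracle at lambda = -10
        w = np.exp(-10.0 * -vals)
        assert np.isclose(wild_type_average(vals, -10.0), np.sum(vals * w) / w.sum())

    def test_nonnegative_and_positive_selection_prefers_small(self):
        vals = np.array([1.0, 2.0, 5.0])
        assert wild_type_average(vals, 5.0) < vals.mean() < wild_type_average(vals, -5.0)


class TestTotalMSD:
    def test_zero_force_reduces_to_null_model(self):
        mb = _toy_basis([1.0, 2.0])
        mf = type("MF", (), {"mode_projections": np.zeros(2)})()
        dp = total_msd_model(mf, mb, sigma_p=1)
        assert dp.msd_mut == 0 and dp.msd_cross_magnitude == 0
        assert np.isclose(dp.total, 1.0 + 0.25)

    def test_single_mode_arithmetic(self):
        mb = _toy_basis([1.0])
        mf = type("MF", (), {"mode_projections": np.array([1.0])})()
        dp = total_msd_model(mf, mb, sigma_p=1)
        assert (dp.msd_mut, dp.msd_nomut, dp.msd_cross_magnitude) == (1.0, 1.0, 2.0)
        assert dp.total == 4.0

    def test_sigma_flip_linearity(self):
        mb = _toy_basis([1.0, 0.5])
        mf = type("MF", (), {"mode_projections": np.array([0.3, -0.7])})()
        up = total_msd_model(mf, mb, sigma_p=1)
        down = total_msd_model(mf, mb, sigma_p=-1)
        assert np.isclose(up.total - down.total, 2 * up.msd_cross_magnitude)

    @pytest.mark.parametrize("observed,expected", [
        (2.1, 1), (1.9, -1), (2.0, 1),   # tie breaks to +1
    ])
    def test_fit_sigma_p(self, observed, expected):
        dp = DeformationPrediction(msd_mut=1.0, msd_nomut=1.0,
                                   msd_cross_magnitude=0.5, sigma_p=1)
        assert fit_sigma_p(observed, dp) == expected


class TestFunctionalChangeFilter:
    def test_null_profile_kept(self):
        mb = _toy_basis([1.0, 2.0])
        # amplitudes proportional to the null model: c_a^2 ~ 1/omega_a^2
        dr = (mb.modes.T @ (1.0 / mb.omegas)).ravel()
        assert functional_change_filter(mb, dr)

    def test_zero_change_kept(self):
        mb = _toy_basis([1.0, 2.0])
        assert functional_change_filter(mb, np.zeros(mb.modes.shape[1]))

    def test_low_barrier_change_discarded(self):
        # one soft and two stiff modes; motion purely on the soft mode has a
        # barrier far below the null expectation (closed form:
        # ratio = omega_min^2 * sum 1/omega^2 / n < 0.5)
        mb = _toy_basis([1.0, 10.0, 10.0])
        dr = mb.modes[0]
        c2 = np.array([1.0, 0.0, 0.0])
        e_obs = float(np.sum(mb.omegas**2 * c2))
        e_null = c2.sum() * 3 / np.sum(1 / mb.omegas**2)
        assert e_obs / e_null < 0.5
        assert not functional_change_filter(mb, dr)


class TestFitWeights:
    def _training_set(self, true_w, seed=0, n=40, permute=False):
        s = make_backbone(FixtureSpec(L=12, geometry="helix", seed=7))
        cm = build_contact_map(s, "enm")
        mb = build_torsional_enm(s, cm)
        mp = MutationParameters(W_size=true_w[0], W_stab=true_w[1],
                                W_dist=true_w[2])
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(n):
            m = int(rng.integers(0, s.L))
            b = AMINO_ACIDS[int(rng.integers(0, 20))]
            if b == s.sequence[m]:
                continue
            mf = mutation_force(s, cm, mp, m, s.sequence[m], b, mb=mb)
            obs, _ = predict_deformation(mf, mb)
            pairs.append((s, cm, mb, (m, s.sequence[m], b), obs))
        if permute:
            obs_perm = rng.permutation([p[4] for p in pairs])
            pairs = [(a, b_, c, d, o) for (a, b_, c, d, _), o in zip(pairs, obs_perm)]
        return pairs

    def test_recovers_noiseless_weights(self):
        pairs = self._training_set((3.0, 2.0, 15.0))
        w, corr = fit_weights(pairs)
        assert corr > 0.999

    def test_permuted_labels_flagged_by_low_correlation(self):
        pairs = self._training_set((3.0, 2.0, 15.0), permute=True)
        _w, corr = fit_weights(pairs)
        assert corr < 0.6

    def test_size_only_data_recovers_size_direction(self):
        # observations generated with the size channel only; the fit (with
        # all three channels available) must concentrate on W_size
        s = make_backbone(FixtureSpec(L=12, geometry="helix", seed=7))
        cm = build_contact_map(s, "enm")
        mb = build_torsional_enm(s, cm)
        gen = MutationParameters(W_size=1.0, W_stab=0.0, W_dist=0.0)
        rng = np.random.default_rng(1)
        pairs = []
        for _ in range(60):
            m = int(rng.integers(0, s.L))
            b = AMINO_ACIDS[int(rng.integers(0, 20))]
            if b == s.sequence[m]:
                continue
            mf = mutation_force(s, cm, gen, m, s.sequence[m], b, mb=mb)
            obs, _ = predict_deformation(mf, mb)
            pairs.append((s, cm, mb, (m, s.sequence[m], b), obs))
        w, corr = fit_weights(pairs)
        assert corr > 0.999
        assert abs(w[0]) > 0.99
        assert np.abs(w[1:]).max() < 0.01

    def test_constant_observations_rejected(self):
        pairs = self._training_set((3.0, 2.0, 15.0))
        pairs = [(a, b, c, d, 1.0) for (a, b, c, d, _o) in pairs]
        with pytest.raises(ValueError):
            fit_weights(pairs)


class TestContactNumberTrends:
    def test_mutated_site_trend(self, bundle_ensemble):
        """Mutating well-connected sites perturbs the structure more
        (positive rank correlation pooled over three bundles)."""
        rho, p = scipy.stats.spearmanr(bundle_ensemble["counts"],
                                       bundle_ensemble["mean_rmsd"])
        assert rho > 0 and p < 0.01

    def test_monitored_site_trend(self, bundle_ensemble):
        """Well-connected sites are themselves deformed less by mutations
        elsewhere (negative rank correlation)."""
        rho, p = scipy.stats.spearmanr(bundle_ensemble["counts"],
                                       bundle_ensemble["monitored_msd"])
        assert rho < 0 and p < 0.01
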