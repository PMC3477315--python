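"""Rigid-transform algebra, superposition, screw decomposition, chains."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from discstoich.errors import DegeneracyError, InterfaceNotSimilarError
from discstoich.geometry import (
    ChainModel,
    DomainCoordinates,
    RigidTransform,
    clash_check,
    derive_interface_transform,
    jitter_sensitivity,
    propagate_chain,
    screw_decompose,
    superpose,
)
from discstoich.simulate import make_toy_domain


def random_transform(rng):
    R = Rotation.random(rng=rng).as_matrix()
    return RigidTransform(R, rng.normal(0, 10, 3))


def random_cloud(rng, n=50):
    return rng.normal(0, 5, (n, 3))


def quaternion_search_rmsd(P, Q, n_coarse=20_000, seed=7):
    """Independent oracle: quaternion-sampling search for the best
    superposition RMSD. A coarse global sample over unit quaternions is
    refined by annealed local resampling around the incumbent; no
    Kabsch/SVD step is involved, and the translation is handled by
    centering (optimal for any rotation)."""
    rng = np.random.default_rng(seed)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def batch_rmsd(quats):
        mats = Rotation.from_quat(quats).as_matrix()
        diff = np.einsum("nij,kj->nki", mats, Pc) - Qc
        return np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1))

    quats = rng.normal(size=(n_coarse, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    scores = batch_rmsd(quats)
    best_q = quats[scores.argmin()]
    best = scores.min()
    scale = 0.3
    while scale > 1e-8:
        cand = best_q + rng.normal(0, scale, (500, 4))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        scores = batch_rmsd(cand)
        if scores.min() < best:
            best = scores.min()
            best_q = cand[scores.argmin()]
        scale *= 0.5
    return float(best)


class TestRigidTransform:
    def test_reflection_rejected(self):
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_composition_matches_matrix_product(self, rng):
        a, b = random_transform(rng), random_transform(rng)
        pts = random_cloud(rng, 10)
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)),
                           atol=1e-9)

    def test_power_composition_law(self, rng):
        """op^m ∘ op^k equals op^(m+k) on test points."""
        op = random_transform(rng)
        pts = random_cloud(rng, 20)
        lhs = op.power(4).compose(op.power(3)).apply(pts)
        assert np.allclose(lhs, op.power(7).apply(pts), atol=1e-6)

    def test_inverse_round_trip(self, rng):
        op = random_transform(rng)
        pts = random_cloud(rng, 20)
        back = op.power(5).inverse().apply(op.power(5).apply(pts))
        assert np.allclose(back, pts, atol=1e-6)


class TestSuperpose:
    def test_identical_sets_give_identity(self, rng):
        pts = random_cloud(rng)
        op, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(op.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(op.translation, 0.0, atol=1e-6)

    def test_pure_translation_recovered(self, rng):
        pts = random_cloud(rng)
        op, rmsd = superpose(pts, pts + np.array([1.0, 2.0, 3.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(op.translation, [1, 2, 3], atol=1e-6)

    def test_matches_quaternion_search_oracle(self, rng):
        """Kabsch RMSD on noisy 20-point clouds agrees with an
        exhaustive quaternion-sampling search to 1e-4 A (the oracle can
        only be slightly worse, never better)."""
        P = random_cloud(rng, 20)
        op = random_transform(rng)
        Q = op.apply(P) + rng.normal(0, 0.5, P.shape)
        _, rmsd = superpose(P, Q)
        oracle = quaternion_search_rmsd(P, Q)
        assert rmsd <= oracle + 1e-12
        assert abs(rmsd - oracle) < 1e-4

    def test_optimality_under_rotation_perturbation(self, rng):
        """Perturbing the returned rotation never lowers the RMSD."""
        P = random_cloud(rng, 30)
        Q = random_transform(rng).apply(P) + rng.normal(0, 1.0, P.shape)
        op, rmsd = superpose(P, Q)
        Qc = Q - Q.mean(axis=0)
        Pc = P - P.mean(axis=0)
        for _ in range(50):
            pert = Rotation.from_rotvec(rng.normal(0, 0.05, 3)).as_matrix()
            rmsd_p = np.sqrt(
                np.mean(np.sum((Pc @ (pert @ op.rotation).T - Qc) ** 2,
                               axis=1))
            )
            assert rmsd_p >= rmsd - 1e-12

    def test_proper_rotation_even_for_mirrored_input(self, rng):
        """A mirrored cloud is never silently reflected: the result is a
        proper rotation with a large residual."""
        P = random_cloud(rng, 30)
        op, rmsd = superpose(P, P * np.array([1, 1, -1]))
        assert np.linalg.det(op.rotation) == pytest.approx(1.0)
        assert rmsd > 1.0

    @pytest.mark.parametrize(
        "pts",
        [np.array([[0.0, 0, 0], [1, 0, 0]]),
         np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])],
        ids=["too_few", "collinear"],
    )
    def test_degenerate_inputs_rejected(self, pts):
        with pytest.raises(DegeneracyError):
            superpose(pts, pts)


class TestInterfaceTransform:
    def test_known_transform_recovered_exactly(self, rng):
        domain = make_toy_domain(25)
        op_true = random_transform(rng)
        ded2 = domain.transformed(op_true)
        pairing = [(r, r) for r, _ in domain.labels]
        op, rmsd = derive_interface_transform(domain, ded2, pairing)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(op.as_matrix(), op_true.as_matrix(), atol=1e-6)

    def test_two_residue_correspondence_rejected(self):
        domain = make_toy_domain(10)
        with pytest.raises(DegeneracyError):
            derive_interface_transform(domain, domain, [(1, 1), (2, 2)])

    def test_dissimilar_interface_refused(self, rng):
        domain = make_toy_domain(20)
        noisy = DomainCoordinates(
            domain.labels, domain.coords + rng.normal(0, 5, domain.coords.shape)
        )
        pairing = [(r, r) for r, _ in domain.labels]
        with pytest.raises(InterfaceNotSimilarError):
            derive_interface_transform(domain, noisy, pairing,
                                       rmsd_threshold=0.5)


class TestChainPropagation:
    def test_single_copy_is_input(self):
        domain = make_toy_domain(10)
        model = propagate_chain(domain, RigidTransform.identity(), 1)
        assert model.n_copies == 1
        assert np.allclose(model.copies[0].coords, domain.coords)

    def test_pure_translation_gives_arithmetic_progression(self):
        domain = make_toy_domain(10)
        op = RigidTransform(np.eye(3), np.array([0.0, 0.0, 10.0]))
        model = propagate_chain(domain, op, 4)
        for k, copy in enumerate(model.copies):
            assert np.allclose(copy.coords, domain.coords + [0, 0, 10.0 * k])

    def test_copies_match_matrix_power_oracle(self, rng):
        """Copy k equals the k-th homogeneous matrix power applied to
        copy 0."""
        domain = make_toy_domain(15)
        op = random_transform(rng)
        model = propagate_chain(domain, op, 6)
        homog = np.hstack([domain.coords, np.ones((len(domain), 1))])
        for k, copy in enumerate(model.copies):
            Mk = np.linalg.matrix_power(op.as_matrix(), k)
            assert np.allclose(copy.coords, (homog @ Mk.T)[:, :3], atol=1e-6)

    def test_zero_copies_rejected(self):
        with pytest.raises(ValueError):
            propagate_chain(make_toy_domain(5), RigidTransform.identity(), 0)


class TestScrewDecomposition:
    def test_identity_is_null_screw(self):
        s = screw_decompose(RigidTransform.identity())
        assert s.twist == 0.0
        assert s.rise == 0.0

    def test_constructed_helix_recovered(self):
        """60 degrees about z plus (0,0,5) is a twist-60, rise-5 screw
        along z."""
        R = Rotation.from_euler("z", 60, degrees=True).as_matrix()
        s = screw_decompose(RigidTransform(R, np.array([0.0, 0.0, 5.0])))
        assert s.twist == pytest.approx(60.0)
        assert s.rise == pytest.approx(5.0)
        assert np.allclose(np.abs(s.axis), [0, 0, 1], atol=1e-9)

    def test_round_trip_reconstruction(self, rng):
        """from_screw(screw_decompose(op)) reproduces op exactly."""
        for _ in range(20):
            op = random_transform(rng)
            s = screw_decompose(op)
            rebuilt = RigidTransform.from_screw(s.axis, s.point, s.twist,
                                                s.rise)
            assert np.allclose(rebuilt.as_matrix(), op.as_matrix(), atol=1e-9)

    def test_pure_translation_reports_translation_axis(self):
        op = RigidTransform(np.eye(3), np.array([3.0, 4.0, 0.0]))
        s = screw_decompose(op)
        assert s.twist == 0.0
        assert s.rise == pytest.approx(5.0)
        assert np.allclose(s.axis, [0.6, 0.8, 0.0])

    def test_chain_advances_rise_per_repeat(self, rng):
        """Projected copy-to-copy spacing along the screw axis equals
        the rise, for every consecutive pair in a 10-copy chain."""
        op = random_transform(rng)
        s = screw_decompose(op)
        domain = make_toy_domain(12)
        model = propagate_chain(domain, op, 10)
        centroids = [c.coords.mean(axis=0) for c in model.copies]
        for a, b in zip(centroids, centroids[1:]):
            assert (b - a) @ s.axis == pytest.approx(s.rise, abs=1e-6)


class TestClashCheck:
    def test_long_rise_has_no_clashes(self):
        domain = make_toy_domain(10)
        op = RigidTransform(np.eye(3), np.array([0.0, 0.0, 500.0]))
        report = clash_check(propagate_chain(domain, op, 5))
        assert report.nonadjacent_clashes == 0
        assert report.adjacent_contacts == 0

    def test_superposed_copies_flag_every_pair(self):
        domain = make_toy_domain(8)
        model = propagate_chain(domain, RigidTransform.identity(), 3)
        report = clash_check(model, cutoff=4.0)
        # identity operator: every atom pair between copies is at distance 0
        tree_pairs = sum(
            1
            for i in range(8)
            for j in range(8)
            if np.linalg.norm(domain.coords[i] - domain.coords[j]) < 4.0
        )
        assert report.nonadjacent_clashes == tree_pairs  # one nonadjacent pair (0,2)
        assert report.adjacent_contacts == 2 * tree_pairs

    def test_matches_all_pairs_bruteforce(self, rng):
        domain = make_toy_domain(15)
        op = random_transform(rng)
        model = propagate_chain(domain, op, 5)
        report = clash_check(model, cutoff=6.0)
        nonadj = adj = 0
        for i in range(5):
            for j in range(i + 1, 5):
                d = np.linalg.norm(
                    model.copies[i].coords[:, None, :]
                    - model.copies[j].coords[None, :, :],
                    axis=2,
                )
                n = int((d < 6.0).sum())
                if j == i + 1:
                    adj += n
                else:
                    nonadj += n
        assert report.nonadjacent_clashes == nonadj
        assert report.adjacent_contacts == adj

    def test_single_copy_rejected(self):
        model = ChainModel([make_toy_domain(5)], RigidTransform.identity())
        with pytest.raises(ValueError):
            clash_check(model)


class TestJitterSensitivity:
    def test_noiseless_interface_has_zero_spread_at_zero_sd(self):
        domain = make_toy_domain(20)
        op = RigidTransform.from_screw([0, 0, 1], [0, 0, 0], 80.0, 12.0)
        ded2 = domain.transformed(op)
        pairing = [(r, r) for r, _ in domain.labels]
        out = jitter_sensitivity(domain, ded2, pairing, sd=0.0, n_reps=5,
                                 seed=1)
        assert out["twist_sd"] == pytest.approx(0.0, abs=1e-9)
        assert out["twist_mean"] == pytest.approx(80.0)
        assert out["rise_mean"] == pytest.approx(12.0)

    def test_jitter_widens_twist_distribution_deterministically(self):
        domain = make_toy_domain(20)
        op = RigidTransform.from_screw([0, 0, 1], [0, 0, 0], 80.0, 12.0)
        ded2 = domain.transformed(op)
        pairing = [(r, r) for r, _ in domain.labels]
        a = jitter_sensitivity(domain, ded2, pairing, sd=0.5, n_reps=20,
                               seed=3)
        b = jitter_sensitivity(domain, ded2, pairing, sd=0.5, n_reps=20,
                               seed=3)
        assert a == b
        assert a["twist_sd"] > 0
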