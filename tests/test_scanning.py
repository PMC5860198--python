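import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import _reference as ref
from dfscan.enm import build_network, normal_modes, pseudo_inverse
from dfscan.fixtures import FixtureSpec, make_structure
from dfscan.forces import ForceBasis, assemble_force_vector
from dfscan.scanning import (
    DEFAULT_PERCENTILE,
    RescuabilityMatrix,
    classify_rescue_sites,
    compensatory_motion,
    compensatory_power,
    pair_score,
    rescuability,
    scan,
    score_from_rho_grid,
    structural_distance,
)
from dfscan.structures import CoarseGrainedStructure, ResidueKey


class TestStructuralDistance:
    def test_zero_displacement(self):
        assert structural_distance(np.zeros(12)) == 0.0

    def test_single_residue_closed_form(self):
        v = np.zeros(12)
        v[0] = 1.0  # one residue of 4 displaced by 1 Å
        assert structural_distance(v) == pytest.approx(0.5)

    def test_matches_per_residue_loop(self, rng):
        v = rng.normal(size=30)
        per_res = [np.linalg.norm(v[3 * i:3 * i + 3]) ** 2 for i in range(10)]
        assert structural_distance(v) == pytest.approx(np.sqrt(np.mean(per_res)))


class TestRescuability:
    @pytest.mark.parametrize(
        "d_i,d_ij,expected", [(2.0, 2.0, 0.0), (2.0, 0.0, 1.0), (2.0, 3.0, -0.5)]
    )
    def test_closed_form_cases(self, d_i, d_ij, expected):
        assert rescuability(d_i, d_ij) == expected

    def test_zero_first_site_deformation_is_error(self):
        with pytest.raises(ValueError):
            rescuability(0.0, 1.0)


class TestPairScore:
    def test_max_then_mean_arithmetic(self):
        rho = np.array([[0.2, -0.1], [0.4, 0.3]])
        assert score_from_rho_grid(rho) == pytest.approx(0.3)

    def test_single_orientation_degenerates_to_single_rho(
        self, helix20_net, helix20_invH
    ):
        basis = ForceBasis(1)
        s_ij = pair_score(helix20_invH, 2, 9, basis, "FF")
        n = helix20_net.n_nodes
        o = basis.orientations[0]
        dr_i = helix20_invH @ assemble_force_vector(n, 2, o, 1.0)
        dr_ij = dr_i + helix20_invH @ assemble_force_vector(n, 9, o, 1.0)
        expected = rescuability(
            structural_distance(dr_i), structural_distance(dr_ij)
        )
        assert s_ij == pytest.approx(expected, rel=1e-10)

    def test_self_pair_rejected(self, helix20_invH):
        with pytest.raises(ValueError):
            pair_score(helix20_invH, 3, 3, ForceBasis(2), "FF")


class TestScanAgainstNaiveReference:
    @pytest.mark.parametrize("scheme", ["FF", "FR"])
    def test_tetrahedron_matches_from_scratch_reference(self, tetra_net, scheme):
        basis = ForceBasis(6, magnitude=1.7)
        engine = scan(tetra_net, basis, (scheme,))[scheme].S
        naive = ref.naive_scan(
            tetra_net.hessian, basis.orientations, 1.7, scheme
        )
        np.testing.assert_allclose(engine, naive, atol=1e-10)

    def test_pipeline_matches_naive_on_six_residue_fixture(self):
        s = make_structure(FixtureSpec("helix", 6))
        net = build_network(s)
        basis = ForceBasis(6)
        mats = scan(net, basis)
        for sch in ("FF", "FR"):
            naive = ref.naive_scan(net.hessian, basis.orientations, 1.0, sch)
            np.testing.assert_allclose(mats[sch].S, naive, atol=1e-10)
        profile = compensatory_power(mats, net.degree)
        p_naive = ref.naive_compensatory_power(
            {sch: mats[sch].S for sch in mats}, net.degree
        )
        np.testing.assert_allclose(profile.P, p_naive, atol=1e-10)


class TestScanInvariances:
    def test_shape_and_masked_diagonal(self, tetra_net):
        mats = scan(tetra_net, ForceBasis(4))
        for mat in mats.values():
            assert mat.S.shape == (4, 4)
            assert np.isnan(np.diag(mat.S)).all()
            assert np.isfinite(mat.S[~np.eye(4, dtype=bool)]).all()
            assert np.nanmax(mat.S) <= 1.0

    def test_ff_invariant_to_base_magnitude(self, helix20_net, helix20_invH):
        n = helix20_net.n_nodes
        g = helix20_invH
        o = ForceBasis(4).orientations
        for mag in (0.1, 1.0, 10.0):
            # explicit response path at this magnitude
            dr_i = g @ assemble_force_vector(n, 5, o[1], mag)
            dr_ij = dr_i + g @ assemble_force_vector(n, 11, o[2], mag)
            rho = rescuability(
                structural_distance(dr_i), structural_distance(dr_ij)
            )
            if mag == 0.1:
                first = rho
            else:
                assert rho == pytest.approx(first, rel=1e-10)
        s_a = scan(helix20_net, ForceBasis(4, magnitude=1.0))["FF"].S
        s_b = scan(helix20_net, ForceBasis(4, magnitude=10.0))["FF"].S
        np.testing.assert_allclose(s_a, s_b, atol=1e-10)

    def test_gamma_invariance(self, helix20):
        net1 = build_network(helix20, gamma=1.0)
        net2 = build_network(helix20, gamma=3.7)
        basis = ForceBasis(4)
        m1 = scan(net1, basis)
        m2 = scan(net2, basis)
        for sch in ("FF", "FR"):
            np.testing.assert_allclose(m1[sch].S, m2[sch].S, atol=1e-10)
        p1 = compensatory_power(m1, net1.degree).P
        p2 = compensatory_power(m2, net2.degree).P
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_equivariance_under_rigid_rotation(self, tetrahedron, tetra_net):
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        rotated = CoarseGrainedStructure(
            list(tetrahedron.keys), list(tetrahedron.aa), tetrahedron.coords @ rot.T
        )
        net_rot = build_network(rotated, r_c=5.0)
        basis = ForceBasis(5)
        basis_rot = ForceBasis(5)
        basis_rot.orientations = basis.orientations @ rot.T  # co-rotated forces
        m = scan(tetra_net, basis)
        m_rot = scan(net_rot, basis_rot)
        for sch in ("FF", "FR"):
            np.testing.assert_allclose(m[sch].S, m_rot[sch].S, atol=1e-8)


class TestExactCancellation:
    def test_constructed_counter_force_gives_rho_one(self, helix20_net, helix20_invH):
        n = helix20_net.n_nodes
        g = helix20_invH
        f_i = assemble_force_vector(n, 4, np.array([0.0, 1.0, 0.0]), 1.0)
        dr_i = g @ f_i
        d_i = structural_distance(dr_i)
        # second force whose response exactly cancels the first response
        f_j = helix20_net.hessian @ (-dr_i)
        dr_ij = dr_i + g @ f_j
        d_ij = structural_distance(dr_ij)
        assert d_ij < 1e-10
        assert rescuability(d_i, d_ij) == pytest.approx(1.0, abs=1e-10)


class TestCompensatoryPower:
    def test_worked_three_residue_example(self):
        # counts_FF = [2,1,0] with degrees [2,1,1] -> ratios [1,1,0]
        s_ff = np.array(
            [[np.nan, 0.2, -0.1],
             [0.5, np.nan, -0.2],
             [0.3, -0.4, np.nan]]
        )
        # counts_FR = [0,1,1] -> ratios [0,1,1]
        s_fr = np.array(
            [[np.nan, -0.1, 0.6],
             [-0.5, np.nan, -0.2],
             [-0.3, 0.4, np.nan]]
        )
        profile = compensatory_power(
            {"FF": RescuabilityMatrix("FF", s_ff), "FR": RescuabilityMatrix("FR", s_fr)},
            np.array([2, 1, 1]),
        )
        assert profile.counts["FF"].tolist() == [2, 1, 0]
        assert profile.counts["FR"].tolist() == [0, 1, 1]
        np.testing.assert_allclose(profile.components["FF"], [1, 1, 0])
        np.testing.assert_allclose(profile.components["FR"], [0, 1, 1])
        np.testing.assert_allclose(profile.P, [0.5, 1.0, 0.5])

    def test_all_nonpositive_scores_give_flat_zero_power(self):
        s = -np.abs(np.random.default_rng(0).normal(size=(4, 4)))
        np.fill_diagonal(s, np.nan)
        mats = {
            "FF": RescuabilityMatrix("FF", s),
            "FR": RescuabilityMatrix("FR", s.copy()),
        }
        profile = compensatory_power(mats, np.array([3, 3, 3, 3]))
        np.testing.assert_array_equal(profile.P, 0.0)

    def test_random_matrices_match_naive_loop(self, rng):
        n = 7
        mats = {}
        for sch in ("FF", "FR"):
            s = rng.normal(size=(n, n))
            np.fill_diagonal(s, np.nan)
            mats[sch] = RescuabilityMatrix(sch, s)
        degree = rng.integers(1, 6, size=n)
        profile = compensatory_power(mats, degree)
        p_naive = ref.naive_compensatory_power(
            {sch: mats[sch].S for sch in mats}, degree
        )
        np.testing.assert_allclose(profile.P, p_naive, atol=1e-12)
        assert np.all(profile.P >= 0) and np.all(profile.P <= 1)

    def test_isolated_node_is_error(self):
        s = np.full((3, 3), 0.5)
        np.fill_diagonal(s, np.nan)
        with pytest.raises(ValueError, match="isolated"):
            compensatory_power(
                {"FF": RescuabilityMatrix("FF", s)}, np.array([2, 0, 2])
            )


class TestClassifyRescueSites:
    def test_quantile_arithmetic(self):
        picked = classify_rescue_sites(np.array([0.9, 0.1, 0.5, 0.3]), 0.25)
        assert picked.tolist() == [0]

    def test_shipped_default_is_top_28_percent(self):
        assert DEFAULT_PERCENTILE == 0.28

    def test_flat_profile_predicts_nothing(self):
        assert classify_rescue_sites(np.full(10, 0.4), 0.28).size == 0


class TestCompensatoryMotion:
    def test_single_orientation_pair_returns_unique_displacement(
        self, helix20_net, helix20_invH
    ):
        n = helix20_net.n_nodes
        basis = ForceBasis(1, magnitude=2.0)
        motion = compensatory_motion(helix20_invH, 3, 8, basis, "FF")
        o = basis.orientations[0]
        expected = helix20_invH @ (
            assemble_force_vector(n, 3, o, 2.0) + assemble_force_vector(n, 8, o, 2.0)
        )
        np.testing.assert_allclose(motion, expected, atol=1e-12)

    @pytest.mark.parametrize("scheme", ["FF", "FR"])
    def test_argmax_matches_exhaustive_grid_search(self, tetra_net, scheme):
        basis = ForceBasis(6)
        g = pseudo_inverse(tetra_net)
        motion = compensatory_motion(g, 0, 2, basis, scheme)
        # brute force over the full orientation grid, from scratch
        hp = ref.naive_pinv(tetra_net.hessian)
        best = (-np.inf, None)
        for oa in basis.orientations:
            f_i = ref.naive_force(4, 0, oa, 1.0)
            d_i = ref.rms_distance(hp @ f_i)
            for ob in basis.orientations:
                f_j = ref.naive_force(4, 2, ob, 1.0)
                if scheme == "FR":
                    f_j = f_j * (d_i / ref.rms_distance(hp @ f_j))
                dr = hp @ (f_i + f_j)
                rho = (d_i - ref.rms_distance(dr)) / d_i
                if rho > best[0]:
                    best = (rho, dr)
        np.testing.assert_allclose(motion, best[1], atol=1e-9)

    def test_motion_orthogonal_to_rigid_modes(self, helix20_net, helix20_invH):
        motion = compensatory_motion(helix20_invH, 1, 15, ForceBasis(4), "FR")
        rigid = ref.rigid_body_basis(helix20_net.structure.coords)
        np.testing.assert_allclose(rigid.T @ motion, 0, atol=1e-8)


def test_rmsip_of_compensatory_motion_against_modes(helix20_net, helix20_invH):
    """Compensatory motions live in the non-rigid space spanned by all modes."""
    from dfscan.evaluation import rmsip

    motion = compensatory_motion(helix20_invH, 2, 17, ForceBasis(6), "FF")
    all_modes = normal_modes(helix20_net, 3 * helix20_net.n_nodes - 6)
    total, per_mode = rmsip(motion, all_modes)
    assert total == pytest.approx(1.0, abs=1e-8)
    assert np.all(per_mode >= 0)
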