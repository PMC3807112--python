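import numpy as np
import pytest

from subflux.geometry import (
    BlockedReactionError,
    angle,
    angle_matrix,
    compute_geometry,
    coupling_class_of,
    full_coupling_sets,
)
from subflux.model import MetabolicModel, Metabolite, Reaction

import oracles
from conftest import simple_model


class TestKernelBasis:
    def test_chain_kernel_is_uniform_flux(self, chain3):
        # hand result on the 2x3 chain: steady state forces equal raw fluxes,
        # so undoing the column normalization must give (1,1,1)/sqrt(3)
        geom = compute_geometry(chain3)
        assert geom.nullity == 1
        v = geom.K[:, 0] / geom.column_norms
        v = v / np.linalg.norm(v)
        np.testing.assert_allclose(np.abs(v), 1 / np.sqrt(3), atol=1e-12)
        assert geom.blocked == frozenset()

    def test_dead_end_reaction_is_blocked(self, dead_end):
        geom = compute_geometry(dead_end)
        assert geom.nullity == 0
        assert geom.blocked == {"R1"}

    def test_basis_orthonormal_and_in_kernel(self, scenario):
        S = scenario.model.S
        geom = compute_geometry(scenario.model)
        K = geom.K
        # K spans ker of the column-normalized S; rows/column_norms are raw fluxes
        assert (
            np.linalg.norm(S @ (K / geom.column_norms[:, None]))
            <= 1e-9 * max(np.linalg.norm(S), 1.0)
        )
        np.testing.assert_allclose(K.T @ K, np.eye(geom.nullity), atol=1e-9)
        assert np.all(geom.norms <= 1 + 1e-12) and np.all(geom.norms >= 0)

    def test_cache_roundtrip(self, chain3, tmp_path):
        g1 = compute_geometry(chain3, cache_dir=tmp_path)
        g2 = compute_geometry(chain3, cache_dir=tmp_path)
        np.testing.assert_array_equal(g1.K, g2.K)
        assert g1.reaction_ids == g2.reaction_ids


class TestAngles:
    def test_fully_coupled_chain_has_zero_angles(self, chain3):
        geom = compute_geometry(chain3)
        for i in range(3):
            for j in range(3):
                assert angle(geom, i, j) == pytest.approx(0.0, abs=1e-6)

    def test_self_angle_zero(self, diamond):
        # arccos near cos=1 amplifies eps-level error to ~1e-6 degrees
        geom = compute_geometry(diamond)
        for i in range(4):
            assert angle(geom, i, i) == pytest.approx(0.0, abs=1e-5)

    def test_parallel_branches_have_positive_angle(self, diamond):
        geom = compute_geometry(diamond)
        i, j = (diamond.reaction_index("R2"), diamond.reaction_index("R3"))
        theta = angle(geom, i, j)
        assert theta > 1.0
        assert not oracles.lp_fully_coupled(diamond.S, i, j)

    def test_blocked_reaction_raises(self, dead_end):
        geom = compute_geometry(dead_end)
        with pytest.raises(BlockedReactionError, match="R1"):
            angle(geom, 0, 0)

    def test_angle_folding_on_reversed_reaction(self, chain3):
        # rewriting B→ as ←B flips the column sign; the angle must stay 0
        flipped = simple_model(
            {
                "EX_A": {"x_in": -1, "A": 1},
                "R_AB": {"A": -1, "B": 1},
                "EX_B": {"x_out": -1, "B": 1},
            },
            boundary={"x_in", "x_out"},
            reversible={"EX_B"},
        )
        geom = compute_geometry(flipped)
        assert angle(geom, 0, 2) == pytest.approx(0.0, abs=1e-6)

    def test_matrix_symmetric_with_zero_diagonal(self, scenario):
        geom = compute_geometry(scenario.model)
        theta = angle_matrix(geom)
        np.testing.assert_allclose(theta, theta.T, atol=1e-9)
        np.testing.assert_allclose(np.diag(theta), 0.0, atol=1e-9)

    def test_permutation_invariance(self, diamond):
        geom = compute_geometry(diamond)
        theta = angle_matrix(geom)
        perm = [2, 0, 3, 1]
        permuted = MetabolicModel(
            diamond.metabolites, [diamond.reactions[k] for k in perm]
        )
        theta_p = angle_matrix(compute_geometry(permuted))
        np.testing.assert_allclose(theta_p, theta[np.ix_(perm, perm)], atol=1e-5)

    def test_scale_invariance(self, scenario):
        model = scenario.model
        theta = angle_matrix(compute_geometry(model))
        scaled_rxns = []
        rng = np.random.default_rng(11)
        for r in model.reactions:
            c = float(rng.choice([-3.0, 0.5, 2.0, 7.0]))
            scaled_rxns.append(
                Reaction(r.id, {m: c * v for m, v in r.stoichiometry.items()},
                         reversible=r.reversible, gpr=r.gpr)
            )
        scaled = MetabolicModel(model.metabolites, scaled_rxns)
        np.testing.assert_allclose(
            angle_matrix(compute_geometry(scaled)), theta, atol=1e-5
        )

    def test_duplicate_reaction_forms_uncoupled_parallel_route(self, chain3):
        # a duplicated column is an alternative route: the flux ratio between
        # original and copy is free, so the angle is positive — exactly what
        # the LP flux-coupling oracle reports
        rxns = list(chain3.reactions)
        middle = rxns[1]
        rxns.append(Reaction("COPY", dict(middle.stoichiometry)))
        dup = MetabolicModel(chain3.metabolites, rxns)
        geom = compute_geometry(dup)
        assert angle(geom, 1, 3) > 1.0
        assert not oracles.lp_fully_coupled(dup.S, 1, 3)


class TestCouplingClasses:
    def test_linear_chain_is_one_class(self, chain3):
        classes = full_coupling_sets(compute_geometry(chain3))
        assert classes == [frozenset({"EX_A", "R_AB", "EX_B"})]

    def test_disconnected_chains_give_two_classes(self):
        two = simple_model(
            {
                "A_EX1": {"xa": -1, "A": 1},
                "A_R": {"A": -1, "B": 1},
                "A_EX2": {"B": -1, "xb": 1},
                "C_EX1": {"xc": -1, "C": 1},
                "C_R": {"C": -1, "D": 1},
                "C_EX2": {"D": -1, "xd": 1},
            },
            boundary={"xa", "xb", "xc", "xd"},
        )
        classes = full_coupling_sets(compute_geometry(two))
        assert sorted(map(sorted, classes)) == [
            ["A_EX1", "A_EX2", "A_R"],
            ["C_EX1", "C_EX2", "C_R"],
        ]

    def test_diamond_branches_not_coupled(self, diamond):
        classes = full_coupling_sets(compute_geometry(diamond))
        assert frozenset({"EX_A", "EX_B"}) in classes
        assert frozenset({"R2"}) in classes and frozenset({"R3"}) in classes

    @pytest.mark.parametrize(
        "fixture", ["chain3", "diamond", "chain4_embedded", "fa_cycle"]
    )
    def test_classes_match_lp_oracle(self, fixture, request):
        model = request.getfixturevalue(fixture)
        geom = compute_geometry(model)
        got = full_coupling_sets(geom)
        idx = {r: k for k, r in enumerate(model.reaction_ids)}
        got_idx = sorted(
            (frozenset(idx[r] for r in c) for c in got),
            key=lambda c: (-len(c), min(c)),
        )
        expected = oracles.lp_coupling_classes(model.S)
        assert got_idx == expected

    def test_coupling_class_of_matches_partition(self, scenario):
        geom = compute_geometry(scenario.model)
        classes = full_coupling_sets(geom)
        for cls in classes:
            for rid in cls:
                assert coupling_class_of(geom, rid) == cls
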