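"""Single-step MME operators, dense oracles and cross-formulation identities."""

import numpy as np
import pandas as pd
import pytest

from ssblup.genomic import RegularizationSpec, build_gc_dense
from ssblup.mme import (
    ModelSpec, SingleStepOperator, assemble_dataset, build_gu_dense,
    dense_mme_common, dense_mme_trait_specific, dense_operator_matrix, dense_ssgblup_solve,
    hg_identity_check, split_solution, var_u_full, woodbury_gu_inverse,
    _hc_inv_dense,
)
from ssblup.pedigree import inbreeding_and_a_inverse, tabular_a, validate_and_sort
from conftest import G0_2TRAIT, R0_2TRAIT, make_random_pedigree, make_small_system


def _classical_equal_weight_solution(sys, b_diag):
    """Classical single-step oracle: H⁻¹ = A⁻¹ + [0,0;0,G_C⁻¹−A_gg⁻¹]."""
    gc = build_gc_dense(sys.z_c, b_diag, sys.spec.cspec, sys.kin.a_gg)
    perm = sys.dataset.order
    h_inv = sys.kin.a_inverse[perm][:, perm].toarray()
    nn = sys.ped.nongenotyped_index.size
    h_inv[nn:, nn:] += np.linalg.inv(gc) - sys.kin.a_gg_inverse
    var_u = np.kron(np.linalg.inv(h_inv), sys.spec.g0)
    return dense_ssgblup_solve(sys.dataset, sys.kin, var_u)


class TestAssembleDataset:
    def test_single_trait_intercept_block(self):
        ped = validate_and_sort(make_random_pedigree(4, 4, seed=0))
        spec = ModelSpec(np.array([[0.3]]), np.array([[0.7]]))
        phen = pd.DataFrame({"animal": ped.labels[:2], "trait1": [1.0, 2.0]})
        data = assemble_dataset(ped, phen, spec)
        assert data.xtrx[0, 0] == pytest.approx(2.0 / 0.7)

    def test_missing_trait_contributes_observed_only(self):
        ped = validate_and_sort(make_random_pedigree(4, 4, seed=0))
        spec = ModelSpec(G0_2TRAIT, R0_2TRAIT)
        phen = pd.DataFrame({"animal": [ped.labels[0]], "trait1": [1.0],
                             "trait2": [np.nan]})
        data = assemble_dataset(ped, phen, spec)
        slot = data.inv_order[0]
        expected = np.zeros((2, 2))
        expected[0, 0] = 1.0 / R0_2TRAIT[0, 0]
        assert np.allclose(data.s_blocks[slot], expected)

    def test_rhs_matches_dense_assembly(self):
        sys = make_small_system(seed=5)
        # independent dense X'R⁻¹y over scalar observation rows
        phen_rhs = np.zeros(2)
        for i in range(sys.dataset.n_animals):
            phen_rhs += sys.dataset.rhs_animal[i]
        assert np.allclose(sys.dataset.rhs_fixed, phen_rhs)

    def test_unknown_animal_errors(self):
        ped = validate_and_sort(make_random_pedigree(4, 4, seed=0))
        spec = ModelSpec(G0_2TRAIT, R0_2TRAIT)
        phen = pd.DataFrame({"animal": [999], "trait1": [1.0], "trait2": [1.0]})
        with pytest.raises(Exception, match="unknown animal"):
            assemble_dataset(ped, phen, spec)


class TestOperators:
    @pytest.mark.parametrize("kind", ["Cw", "Ce"])
    def test_common_operator_matches_dense(self, kind):
        sys = make_small_system(n=25, m=12, seed=1, kind=kind)
        op = SingleStepOperator(sys.dataset, sys.kin, sys.z_c, "common", b_diag=sys.b_equal)
        dense, _ = dense_mme_common(sys.dataset, sys.kin, sys.z_c, sys.b_equal)
        assert np.abs(dense_operator_matrix(op) - dense).max() < 1e-10

    @pytest.mark.parametrize("kind", ["Cw", "Ce"])
    def test_trait_specific_operator_matches_dense(self, kind):
        sys = make_small_system(n=25, m=12, seed=2, kind=kind)
        op = SingleStepOperator(sys.dataset, sys.kin, sys.z_c, "trait_specific", vg=sys.vg)
        dense, _ = dense_mme_trait_specific(sys.dataset, sys.kin, sys.z_c, sys.vg)
        assert np.abs(dense_operator_matrix(op) - dense).max() < 1e-10

    def test_operator_symmetry_probes(self, small_system):
        sys = small_system
        rng = np.random.default_rng(0)
        for form, kw in (("common", {"b_diag": sys.b_equal}), ("trait_specific", {"vg": sys.vg}),
                         ("pedigree", {})):
            op = SingleStepOperator(sys.dataset, sys.kin,
                                    sys.z_c if form != "pedigree" else None, form, **kw)
            for _ in range(5):
                x = rng.standard_normal(op.n_eq)
                y = rng.standard_normal(op.n_eq)
                lhs, rhs = x @ op(y), y @ op(x)
                assert abs(lhs - rhs) < 1e-9 * np.linalg.norm(x) * np.linalg.norm(y)

    def test_unit_weights_reduce_trait_specific_to_common(self, small_system):
        sys = small_system
        op4 = SingleStepOperator(sys.dataset, sys.kin, sys.z_c, "common", b_diag=sys.b_equal)
        op8 = SingleStepOperator(sys.dataset, sys.kin, sys.z_c, "trait_specific", vg=sys.vg_unit)
        x = np.random.default_rng(1).standard_normal(op4.n_eq)
        assert np.abs(op8(x) - op4(x)).max() < 1e-12 * max(1.0, np.abs(op4(x)).max())

    def test_no_genotypes_reduces_to_pedigree_blup(self):
        sys = make_small_system(seed=4)
        ped = sys.ped
        ped.genotyped[:] = False
        kin = inbreeding_and_a_inverse(ped)
        data = assemble_dataset(ped, pd.DataFrame({
            "animal": ped.labels, "trait1": np.ones(ped.n), "trait2": np.ones(ped.n)
        }), sys.spec)
        op = SingleStepOperator(data, kin, None, "pedigree")
        t = 2
        dense = dense_operator_matrix(op)
        perm = data.order
        a_inv = kin.a_inverse[perm][:, perm].toarray()
        genetic = dense[t:, t:] - np.kron(a_inv, sys.spec.g0_inv)
        # what remains is purely the data part (block diagonal S_i)
        for i in range(ped.n):
            for j in range(ped.n):
                blk = genetic[i * t:(i + 1) * t, j * t:(j + 1) * t]
                if i != j:
                    assert np.allclose(blk, 0.0)


class TestSolutionEquivalences:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_common_snpblup_equals_classical_ssgblup(self, seed):
        sys = make_small_system(n=30, m=15, seed=seed)
        dense, rhs = dense_mme_common(sys.dataset, sys.kin, sys.z_c, sys.b_equal)
        sol4 = split_solution(np.linalg.solve(dense, rhs), sys.dataset, sys.z_c.shape[1])
        sol3 = split_solution(_classical_equal_weight_solution(sys, sys.b_equal), sys.dataset)
        scale = np.abs(sol3["u"]).max()
        assert np.abs(sol4["u"] - sol3["u"]).max() / scale < 1e-6
        assert np.abs(sol4["fixed"] - sol3["fixed"]).max() < 1e-6

    @pytest.mark.parametrize("seed", [0, 1])
    def test_trait_specific_snpblup_equals_gu_oracle(self, seed):
        sys = make_small_system(n=30, m=15, seed=seed)
        dense, rhs = dense_mme_trait_specific(sys.dataset, sys.kin, sys.z_c, sys.vg)
        sol8 = split_solution(np.linalg.solve(dense, rhs), sys.dataset, sys.z_c.shape[1])
        vu = var_u_full(sys.dataset, sys.kin, sys.z_c, sys.vg)
        solg = split_solution(dense_ssgblup_solve(sys.dataset, sys.kin, vu), sys.dataset)
        scale = np.abs(solg["u"]).max()
        assert np.abs(sol8["u"] - solg["u"]).max() / scale < 1e-6

    def test_unit_weight_solutions_coincide(self, small_system):
        sys = small_system
        d4, r4 = dense_mme_common(sys.dataset, sys.kin, sys.z_c, sys.b_equal)
        d8, r8 = dense_mme_trait_specific(sys.dataset, sys.kin, sys.z_c, sys.vg_unit)
        s4 = np.linalg.solve(d4, r4)
        s8 = np.linalg.solve(d8, r8)
        assert np.abs(s4 - s8).max() / np.abs(s4).max() < 1e-6

    def test_marker_effects_consistent_with_gebv(self, small_system):
        # ĝ = B Z_c' G_C⁻¹ û_g : marker effects are the G_C-projection of GEBV
        sys = small_system
        dense, rhs = dense_mme_common(sys.dataset, sys.kin, sys.z_c, sys.b_equal)
        sol = split_solution(np.linalg.solve(dense, rhs), sys.dataset, sys.z_c.shape[1])
        gc = build_gc_dense(sys.z_c, sys.b_equal, sys.spec.cspec, sys.kin.a_gg)
        u_g = sol["u"][sys.ped.genotyped_index]
        g_hat = (sys.b_equal[:, None] * sys.z_c.T) @ np.linalg.solve(gc, u_g)
        assert np.abs(g_hat - sol["g"]).max() < 1e-8


class TestGuAndHg:
    def test_equal_weights_gu_is_kronecker(self, small_system):
        sys = small_system
        cd = sys.spec.cspec.c_dense(sys.kin.a_gg)
        gu = build_gu_dense(sys.z_c, sys.vg_unit, sys.spec.g0, cd)
        gc = build_gc_dense(sys.z_c, sys.b_equal, sys.spec.cspec, sys.kin.a_gg)
        assert np.abs(gu - np.kron(gc, sys.spec.g0)).max() < 1e-10

    def test_woodbury_gu_inverse_matches_dense(self):
        sys = make_small_system(n=16, m=10, seed=3)
        cd = sys.spec.cspec.c_dense(sys.kin.a_gg)
        gu = build_gu_dense(sys.z_c, sys.vg, sys.spec.g0, cd)
        gui = woodbury_gu_inverse(sys.z_c, sys.vg, sys.spec.g0,
                                  sys.spec.cspec.c_inverse_dense(sys.kin.a_gg_inverse))
        assert np.abs(gui - np.linalg.inv(gu)).max() < 1e-8

    @pytest.mark.parametrize("kind", ["Cw", "Ce"])
    def test_hg_closed_form_inverse(self, kind):
        sys = make_small_system(n=20, m=10, seed=6, kind=kind)
        assert hg_identity_check(sys.dataset, sys.kin, sys.z_c, sys.vg) < 1e-7

    def test_equal_weights_nongenotyped_variance_block(self, small_system):
        # Var(u_n) = G0 ⊗ (A_nn + A_ng A_gg⁻¹ (G_C − A_gg) A_gg⁻¹ A_gn)
        sys = small_system
        vu = var_u_full(sys.dataset, sys.kin, sys.z_c, sys.vg_unit)
        a = tabular_a(sys.ped)
        nidx, gidx = sys.ped.nongenotyped_index, sys.ped.genotyped_index
        gc = build_gc_dense(sys.z_c, sys.b_equal, sys.spec.cspec, sys.kin.a_gg)
        t_mat = a[np.ix_(nidx, gidx)] @ sys.kin.a_gg_inverse
        expected = a[np.ix_(nidx, nidx)] + t_mat @ (gc - sys.kin.a_gg) @ t_mat.T
        nn = nidx.size
        assert np.abs(vu[: nn * 2, : nn * 2] - np.kron(expected, sys.spec.g0)).max() < 1e-8
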