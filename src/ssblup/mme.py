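"""Mixed model equations for multi-trait single-step genomic evaluation.

Three formulations of the same model are provided:

* the classical single-step GBLUP system (breeding values only) with a
  relationship matrix ``H`` combining pedigree and genomic information —
  kept dense, as a desk-scale oracle;
* the single-step SNPBLUP system with common marker weights, whose
  marker block is ``G0⁻¹ ⊗ K`` with ``K = Z_c'C⁻¹Z_c + B⁻¹``;
* the trait-specific-weights system, identical except that the marker
  block becomes ``G0⁻¹ ⊗ Z_c'C⁻¹Z_c + V_g⁻¹`` with the block-diagonal
  marker covariance V_g.

The SNPBLUP coefficient matrices are never formed: a matrix-free
operator applies them using the sparse A⁻¹, the dense A_gg⁻¹ (through
C⁻¹), and products with Z_c.

Equation layout is level-major: T consecutive equations per effect
level, ordered [fixed | animals, non-genotyped then genotyped | markers].
A Kronecker product written ``G0⁻¹ ⊗ M`` in trait-major notation is
therefore ``kron(M, G0⁻¹)`` here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genomic import RegularizationSpec
from .markercov import MarkerCovarianceBlocks
from .pedigree import KinshipComponents, Pedigree, a_cross_block

__all__ = [
    "ModelSpec",
    "Dataset",
    "assemble_dataset",
    "SingleStepOperator",
    "dense_operator_matrix",
    "dense_mme_common",
    "dense_mme_trait_specific",
    "build_gu_dense",
    "woodbury_gu_inverse",
    "dense_ssgblup_solve",
    "var_u_full",
    "hg_matrix",
    "hg_inverse_closed_form",
    "hg_identity_check",
    "split_solution",
]


def lift(m: np.ndarray, t: int) -> np.ndarray:
    """kron(M, I_T): apply M over levels, identity over traits."""
    return np.kron(m, np.eye(t))


@dataclass
class ModelSpec:
    """Variance structure and fixed effects of the multi-trait model.

    Fixed effects default to a general mean per trait.  R0 is typically
    diagonal (zero residual correlation) but dense R0 is supported via
    per-missing-pattern inversion.
    """

    g0: np.ndarray
    r0: np.ndarray
    cspec: RegularizationSpec = field(default_factory=RegularizationSpec)
    trait_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.g0 = np.atleast_2d(np.asarray(self.g0, dtype=float))
        self.r0 = np.atleast_2d(np.asarray(self.r0, dtype=float))
        for name, m in (("G0", self.g0), ("R0", self.r0)):
            if np.linalg.eigvalsh(m)[0] <= 0:
                raise ValueError(f"{name} must be positive definite")
        if self.trait_names is None:
            self.trait_names = [f"trait{i + 1}" for i in range(self.n_traits)]

    @property
    def n_traits(self) -> int:
        return self.g0.shape[0]

    @property
    def g0_inv(self) -> np.ndarray:
        return np.linalg.inv(self.g0)


@dataclass
class Dataset:
    """Assembled design: per-animal residual-precision blocks and RHS.

    With a general mean per trait as the only fixed effect, the data
    enter the MME through one T×T block per animal,
    S_i = Σ_records (R0 restricted to observed traits)⁻¹ embedded in T×T,
    which serves simultaneously as the W'R⁻¹W diagonal block and the
    X'R⁻¹W coupling of animal i to the mean level.
    """

    ped: Pedigree
    spec: ModelSpec
    order: np.ndarray          # MME animal slot -> pedigree position
    inv_order: np.ndarray      # pedigree position -> MME animal slot
    s_blocks: np.ndarray       # (n, T, T) in MME animal order
    rhs_animal: np.ndarray     # (n, T)
    xtrx: np.ndarray           # (T, T)
    rhs_fixed: np.ndarray      # (T,)

    @property
    def n_animals(self) -> int:
        return self.order.shape[0]

    @property
    def n_genotyped(self) -> int:
        return int(self.ped.genotyped.sum())


def assemble_dataset(ped: Pedigree, phenotypes: pd.DataFrame, spec: ModelSpec) -> Dataset:
    """Build the data-dependent MME pieces from a phenotype table.

    ``phenotypes`` has an ``animal`` column plus one column per trait
    (NaN = unobserved).  Each row is one record; a trait observed in a
    record contributes through the inverse of R0 restricted to that
    record's observed traits.
    """
    t = spec.n_traits
    order = np.concatenate([ped.nongenotyped_index, ped.genotyped_index])
    inv_order = np.empty(ped.n, dtype=np.int64)
    inv_order[order] = np.arange(ped.n)

    s_blocks = np.zeros((ped.n, t, t))
    rhs_animal = np.zeros((ped.n, t))
    pat_cache: dict[tuple[bool, ...], np.ndarray] = {}

    animals = ped.position_of(phenotypes["animal"].to_numpy())
    y = phenotypes[spec.trait_names].to_numpy(dtype=float)
    obs = ~np.isnan(y)
    for rec in range(len(phenotypes)):
        mask = obs[rec]
        if not mask.any():
            continue
        key = tuple(mask.tolist())
        if key not in pat_cache:
            emb = np.zeros((t, t))
            idx = np.flatnonzero(mask)
            emb[np.ix_(idx, idx)] = np.linalg.inv(spec.r0[np.ix_(idx, idx)])
            pat_cache[key] = emb
        rinv = pat_cache[key]
        slot = inv_order[animals[rec]]
        s_blocks[slot] += rinv
        yv = np.where(mask, y[rec], 0.0)
        rhs_animal[slot] += rinv @ yv

    xtrx = s_blocks.sum(axis=0)
    rhs_fixed = rhs_animal.sum(axis=0)
    return Dataset(
        ped=ped, spec=spec, order=order, inv_order=inv_order,
        s_blocks=s_blocks, rhs_animal=rhs_animal, xtrx=xtrx, rhs_fixed=rhs_fixed,
    )


class SingleStepOperator:
    """Matrix-free application of the single-step SNPBLUP coefficient matrix.

    ``formulation`` selects the marker block: "common" (common weights via
    the diagonal B) or "trait_specific" (trait-specific V_g blocks); "pedigree"
    omits genomic terms entirely (multi-trait animal model).  All
    genomic products are computed on the fly from Z_c, A⁻¹ and A_gg⁻¹.
    """

    def __init__(
        self,
        dataset: Dataset,
        kin: KinshipComponents,
        z_c: np.ndarray | None = None,
        formulation: str = "trait_specific",
        vg: MarkerCovarianceBlocks | None = None,
        b_diag: np.ndarray | None = None,
    ) -> None:
        if formulation not in ("pedigree", "common", "trait_specific"):
            raise ValueError(f"unknown formulation {formulation!r}")
        if formulation == "common" and b_diag is None:
            raise ValueError("common-weight formulation needs the diagonal B")
        if formulation == "trait_specific" and vg is None:
            raise ValueError("trait-specific formulation needs marker covariance blocks")
        self.data = dataset
        self.kin = kin
        self.spec = dataset.spec
        self.formulation = formulation
        self.vg = vg
        self.b_diag = None if b_diag is None else np.asarray(b_diag, dtype=float)
        self.g0_inv = self.spec.g0_inv

        perm = dataset.order
        self.a_inv = kin.a_inverse[perm][:, perm].tocsr()
        self.n_non = dataset.n_animals - dataset.n_genotyped
        self.n_gen = dataset.n_genotyped

        if formulation == "pedigree":
            self.z_c = np.zeros((self.n_gen, 0))
        else:
            if z_c is None:
                raise ValueError("genomic formulations need Z_c")
            if z_c.shape[0] != self.n_gen:
                raise ValueError("Z_c rows must match genotyped animals")
            self.z_c = np.asarray(z_c, dtype=float)
        self.m = self.z_c.shape[1]
        t = self.spec.n_traits
        self.n_eq = t * (1 + dataset.n_animals + self.m)

    # -- helpers ---------------------------------------------------------
    def _c_inv(self, v: np.ndarray) -> np.ndarray:
        cs = self.spec.cspec
        if cs.kind == "Ce":
            return v / cs.e
        return (self.kin.a_gg_inverse @ v) / cs.w

    def split(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = self.spec.n_traits
        n = self.data.n_animals
        xf = x[:t]
        xa = x[t: t * (1 + n)].reshape(n, t)
        xm = x[t * (1 + n):].reshape(self.m, t)
        return xf, xa, xm

    @property
    def rhs(self) -> np.ndarray:
        t = self.spec.n_traits
        return np.concatenate([
            self.data.rhs_fixed,
            self.data.rhs_animal.ravel(),
            np.zeros(self.m * t),
        ])

    # -- application -----------------------------------------------------
    def __call__(self, x: np.ndarray) -> np.ndarray:
        xf, xa, xm = self.split(x)
        s = self.data.s_blocks
        g0i = self.g0_inv

        yf = self.data.xtrx @ xf + np.einsum("nij,nj->i", s, xa)
        ya = np.einsum("nij,j->ni", s, xf) + np.einsum("nij,nj->ni", s, xa)

        # genetic precision on animals: G0⁻¹ ⊗ H_C⁻¹ (or A⁻¹ for pedigree model)
        ga = self.a_inv @ xa
        if self.formulation != "pedigree" and self.n_gen:
            xg = xa[self.n_non:]
            ga[self.n_non:] += self._c_inv(xg) - self.kin.a_gg_inverse @ xg
        ya += ga @ g0i

        ym = np.zeros((self.m, self.spec.n_traits))
        if self.formulation != "pedigree" and self.m:
            xg = xa[self.n_non:]
            czm = self._c_inv(self.z_c @ xm)          # C⁻¹ Z_c x_m  (n_g, T)
            ya[self.n_non:] -= czm @ g0i              # −(G0⁻¹ ⊗ K_C) coupling
            ym = (self.z_c.T @ self._c_inv(self.z_c @ xm - xg)) @ g0i
            if self.formulation == "common":
                ym += (xm / self.b_diag[:, None]) @ g0i
            else:
                ym += np.einsum("kij,kj->ki", self.vg.inv_blocks, xm)
        return np.concatenate([yf, ya.ravel(), ym.ravel()])


def dense_operator_matrix(op: SingleStepOperator) -> np.ndarray:
    """Materialize the operator column by column (desk-scale oracle)."""
    n = op.n_eq
    out = np.empty((n, n))
    e = np.zeros(n)
    for j in range(n):
        e[j] = 1.0
        out[:, j] = op(e)
        e[j] = 0.0
    return out


# -------------------------------------------------------- dense assemblies

def _dense_data_blocks(dataset: Dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X'R⁻¹X, X'R⁻¹W, W'R⁻¹W) dense, level-major, from the S blocks."""
    t = dataset.spec.n_traits
    n = dataset.n_animals
    xtrw = dataset.s_blocks.transpose(1, 0, 2).reshape(t, n * t)
    wtrw = np.zeros((n * t, n * t))
    for i in range(n):
        wtrw[i * t:(i + 1) * t, i * t:(i + 1) * t] = dataset.s_blocks[i]
    return dataset.xtrx, xtrw, wtrw


def _hc_inv_dense(dataset: Dataset, kin: KinshipComponents) -> np.ndarray:
    perm = dataset.order
    a_inv = kin.a_inverse[perm][:, perm].toarray()
    ng = dataset.n_genotyped
    if ng:
        cinv = dataset.spec.cspec.c_inverse_dense(kin.a_gg_inverse)
        a_inv[-ng:, -ng:] += cinv - kin.a_gg_inverse
    return a_inv


def _dense_snpblup(
    dataset: Dataset,
    kin: KinshipComponents,
    z_c: np.ndarray,
    marker_block: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared assembly of the SNPBLUP coefficient matrix and RHS."""
    t = dataset.spec.n_traits
    n = dataset.n_animals
    ng = dataset.n_genotyped
    m = z_c.shape[1]
    g0i = dataset.spec.g0_inv
    xtrx, xtrw, wtrw = _dense_data_blocks(dataset)

    cmat = np.zeros((t * (1 + n + m), t * (1 + n + m)))
    f, a, g = slice(0, t), slice(t, t * (1 + n)), slice(t * (1 + n), None)
    cmat[f, f] = xtrx
    cmat[f, a] = xtrw
    cmat[a, f] = xtrw.T
    cmat[a, a] = wtrw + np.kron(_hc_inv_dense(dataset, kin), g0i)
    cinv = dataset.spec.cspec.c_inverse_dense(kin.a_gg_inverse)
    kc = np.zeros((n, m))
    kc[n - ng:] = cinv @ z_c
    cmat[a, g] = -np.kron(kc, g0i)
    cmat[g, a] = cmat[a, g].T
    cmat[g, g] = marker_block
    rhs = np.concatenate([dataset.rhs_fixed, dataset.rhs_animal.ravel(), np.zeros(m * t)])
    return cmat, rhs


def dense_mme_common(
    dataset: Dataset, kin: KinshipComponents, z_c: np.ndarray, b_diag: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Dense common-weights single-step SNPBLUP system (oracle)."""
    cinv = dataset.spec.cspec.c_inverse_dense(kin.a_gg_inverse)
    k = z_c.T @ cinv @ z_c + np.diag(1.0 / np.asarray(b_diag, dtype=float))
    return _dense_snpblup(dataset, kin, z_c, np.kron(k, dataset.spec.g0_inv))


def dense_mme_trait_specific(
    dataset: Dataset, kin: KinshipComponents, z_c: np.ndarray, vg: MarkerCovarianceBlocks
) -> tuple[np.ndarray, np.ndarray]:
    """Dense trait-specific-weights single-step SNPBLUP system (oracle)."""
    t = dataset.spec.n_traits
    cinv = dataset.spec.cspec.c_inverse_dense(kin.a_gg_inverse)
    zcz = z_c.T @ cinv @ z_c
    block = np.kron(zcz, dataset.spec.g0_inv)
    m = z_c.shape[1]
    for k in range(m):
        block[k * t:(k + 1) * t, k * t:(k + 1) * t] += vg.inv_blocks[k]
    return _dense_snpblup(dataset, kin, z_c, block)


# ------------------------------------------------- trait-specific ssGBLUP

def build_gu_dense(z_c: np.ndarray, vg: MarkerCovarianceBlocks, g0: np.ndarray,
                   c_dense: np.ndarray) -> np.ndarray:
    """Genetic covariance of the genotyped animals with trait-specific V_g.

    G_u = (I⊗Z_c) V_g (I⊗Z_c') + G0⊗C, level-major; with equal weights
    this reduces to the Kronecker-separable G0 ⊗ G_C.
    """
    t = g0.shape[0]
    ggg = np.einsum("ik,jk,kab->iajb", z_c, z_c, vg.blocks)
    n = z_c.shape[0]
    return ggg.reshape(n * t, n * t) + np.kron(c_dense, g0)


def woodbury_gu_inverse(z_c: np.ndarray, vg: MarkerCovarianceBlocks, g0: np.ndarray,
                        c_inv_dense: np.ndarray) -> np.ndarray:
    """G_u⁻¹ without inverting the Tn×Tn covariance directly.

    Uses the Woodbury identity with the Tm×Tm inner matrix
    (I⊗Z_c'C⁻¹Z_c) + V_g⁻¹.
    """
    t = g0.shape[0]
    m = z_c.shape[1]
    g0i = np.linalg.inv(g0)
    outer = np.kron(c_inv_dense, g0i)                      # G0⁻¹ ⊗ C⁻¹
    liftz = lift(z_c, t)
    inner = np.kron(z_c.T @ c_inv_dense @ z_c, g0i)
    for k in range(m):
        inner[k * t:(k + 1) * t, k * t:(k + 1) * t] += vg.inv_blocks[k]
    u = outer @ liftz
    return outer - u @ np.linalg.solve(inner, u.T)


def dense_ssgblup_solve(
    dataset: Dataset,
    kin: KinshipComponents,
    var_u: np.ndarray,
) -> np.ndarray:
    """Solve the breeding-value-only single-step MME given Var(u) dense.

    ``var_u`` is the full-pedigree genetic covariance, level-major
    (animals in MME order).  This is the generic multi-trait form of the
    classical system — the desk-scale oracle the SNPBLUP formulations
    are tested against.
    """
    t = dataset.spec.n_traits
    xtrx, xtrw, wtrw = _dense_data_blocks(dataset)
    prec = np.linalg.inv(var_u)
    top = np.hstack([xtrx, xtrw])
    bottom = np.hstack([xtrw.T, wtrw + prec])
    cmat = np.vstack([top, bottom])
    rhs = np.concatenate([dataset.rhs_fixed, dataset.rhs_animal.ravel()])
    return np.linalg.solve(cmat, rhs)


def var_u_full(dataset: Dataset, kin: KinshipComponents, z_c: np.ndarray,
               vg: MarkerCovarianceBlocks) -> np.ndarray:
    """Var(u) over all animals with trait-specific marker weights.

    Assembled from the covariance of breeding values and SNP effects:
    Var(u_g) = G_gg = (I⊗Z_c)V_g(I⊗Z_c') + G0⊗C, the non-genotyped part
    projected through T = A_ng A_gg⁻¹ with conditional covariance
    G0 ⊗ (A^nn)⁻¹.
    """
    spec = dataset.spec
    t = spec.n_traits
    ped = dataset.ped
    nidx, gidx = ped.nongenotyped_index, ped.genotyped_index
    c_dense = spec.cspec.c_dense(kin.a_gg)
    ggg = build_gu_dense(z_c, vg, spec.g0, c_dense)
    if nidx.size == 0:
        return ggg
    a_ng = a_cross_block(ped, nidx, gidx)
    t_mat = a_ng @ kin.a_gg_inverse
    perm = dataset.order
    a_inv = kin.a_inverse[perm][:, perm].toarray()
    nn = nidx.size
    a_nn_inv = np.linalg.inv(a_inv[:nn, :nn])
    lt = lift(t_mat, t)
    v_nn = lt @ ggg @ lt.T + np.kron(a_nn_inv, spec.g0)
    v_ng = lt @ ggg
    n = dataset.n_animals
    out = np.empty((n * t, n * t))
    out[: nn * t, : nn * t] = v_nn
    out[: nn * t, nn * t:] = v_ng
    out[nn * t:, : nn * t] = v_ng.T
    out[nn * t:, nn * t:] = ggg
    return out


# ------------------------------------------------------- H_g identities

def hg_matrix(dataset: Dataset, kin: KinshipComponents, z_c: np.ndarray,
              vg: MarkerCovarianceBlocks) -> np.ndarray:
    """Joint covariance of (u_n, u_g, g): breeding values plus SNP effects."""
    spec = dataset.spec
    t = spec.n_traits
    ped = dataset.ped
    nidx, gidx = ped.nongenotyped_index, ped.genotyped_index
    vu = var_u_full(dataset, kin, z_c, vg)
    m = z_c.shape[1]
    # Cov(u_g, g) = (I⊗Z_c) V_g ; Cov(u_n, g) = (I⊗T Z_c) V_g
    vg_lm = np.zeros((m * t, m * t))
    for k in range(m):
        vg_lm[k * t:(k + 1) * t, k * t:(k + 1) * t] = vg.blocks[k]
    cov_ug_g = lift(z_c, t) @ vg_lm
    n_eq_u = dataset.n_animals * t
    nn = nidx.size
    out = np.empty((n_eq_u + m * t, n_eq_u + m * t))
    out[:n_eq_u, :n_eq_u] = vu
    if nn:
        a_ng = a_cross_block(ped, nidx, gidx)
        t_mat = a_ng @ kin.a_gg_inverse
        cov_un_g = lift(t_mat @ z_c, t) @ vg_lm
        out[: nn * t, n_eq_u:] = cov_un_g
        out[n_eq_u:, : nn * t] = cov_un_g.T
    out[nn * t: n_eq_u, n_eq_u:] = cov_ug_g
    out[n_eq_u:, nn * t: n_eq_u] = cov_ug_g.T
    out[n_eq_u:, n_eq_u:] = vg_lm
    return out


def hg_inverse_closed_form(dataset: Dataset, kin: KinshipComponents, z_c: np.ndarray,
                           vg: MarkerCovarianceBlocks) -> np.ndarray:
    """Closed-form inverse of the joint (u, g) covariance.

    The animal block is G0⁻¹ ⊗ H_C⁻¹, the coupling −G0⁻¹ ⊗ K_C, and the
    marker block G0⁻¹ ⊗ Z_c'C⁻¹Z_c + V_g⁻¹ — exactly the random-effect
    part of the trait-specific MME coefficient matrix.  For C_w,
    C⁻¹ = (1/w) A_gg⁻¹, recovering the (1/w − 1)A_gg⁻¹ adjustment.
    """
    spec = dataset.spec
    t = spec.n_traits
    g0i = spec.g0_inv
    n = dataset.n_animals
    ng = dataset.n_genotyped
    m = z_c.shape[1]
    cinv = spec.cspec.c_inverse_dense(kin.a_gg_inverse)
    hc_inv = _hc_inv_dense(dataset, kin)
    kc = np.zeros((n, m))
    kc[n - ng:] = cinv @ z_c
    marker = np.kron(z_c.T @ cinv @ z_c, g0i)
    for k in range(m):
        marker[k * t:(k + 1) * t, k * t:(k + 1) * t] += vg.inv_blocks[k]
    top = np.hstack([np.kron(hc_inv, g0i), -np.kron(kc, g0i)])
    bottom = np.hstack([-np.kron(kc, g0i).T, marker])
    return np.vstack([top, bottom])


def hg_identity_check(dataset: Dataset, kin: KinshipComponents, z_c: np.ndarray,
                      vg: MarkerCovarianceBlocks) -> float:
    """max |H_g · H_g⁻¹ − I| for the closed-form inverse (desk scale)."""
    hg = hg_matrix(dataset, kin, z_c, vg)
    hg_inv = hg_inverse_closed_form(dataset, kin, z_c, vg)
    prod = hg @ hg_inv
    return float(np.max(np.abs(prod - np.eye(prod.shape[0]))))


# ------------------------------------------------------------- solutions

def split_solution(x: np.ndarray, dataset: Dataset, m: int = 0) -> dict[str, np.ndarray]:
    """Split a solution vector into fixed effects, breeding values and
    marker effects; breeding values are returned in pedigree order."""
    t = dataset.spec.n_traits
    n = dataset.n_animals
    fixed = x[:t]
    u_mme = x[t: t * (1 + n)].reshape(n, t)
    u = np.empty_like(u_mme)
    u[dataset.order, :] = u_mme
    g = x[t * (1 + n):].reshape(m, t) if m else np.zeros((0, t))
    return {"fixed": fixed, "u": u, "g": g}
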