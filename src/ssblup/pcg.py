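"""Preconditioned conjugate gradients with a trait-block preconditioner.

The preconditioner is block diagonal with one T×T block per equation
level.  Fixed-effect and animal blocks are the exact diagonal blocks of
the coefficient matrix.  The marker-k block is

    G0⁻¹ c_k + V_{g,k}⁻¹,   c_k = (1/w) Z_{c,k}' D_A Z_{c,k},

with D_A the diagonal of A_gg⁻¹ — a diagonal approximation of the
Z_c'C⁻¹Z_c contribution that is exact when A_gg⁻¹ is diagonal.

Convergence is monitored with the relative residual

    C_r = ‖C_MME s − r‖ / ‖r‖,

evaluated every iteration from the recursively updated residual, with a
true-residual recomputation every 100 iterations to guard against
drift.  The default tolerance is C_r < 1e−7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mme import SingleStepOperator

log = logging.getLogger(__name__)

__all__ = ["BlockPreconditioner", "PCGTrace", "build_block_preconditioner",
           "pcg_solve", "relative_residual"]


@dataclass
class BlockPreconditioner:
    """One symmetric PD T×T block per level, stored pre-inverted."""

    inv_blocks: np.ndarray  # (n_levels, T, T)

    def __post_init__(self) -> None:
        self.inv_blocks = np.asarray(self.inv_blocks)

    def apply(self, r: np.ndarray) -> np.ndarray:
        t = self.inv_blocks.shape[1]
        return np.einsum("nij,nj->ni", self.inv_blocks, r.reshape(-1, t)).ravel()

    @classmethod
    def identity(cls, n_levels: int, t: int) -> "BlockPreconditioner":
        return cls(np.broadcast_to(np.eye(t), (n_levels, t, t)).copy())


def build_block_preconditioner(op: SingleStepOperator) -> BlockPreconditioner:
    """Level-wise T×T blocks of the single-step coefficient matrix.

    Fixed and animal blocks are exact; marker blocks use the diagonal-of-
    A_gg⁻¹ approximation c_k (for C_e, c_k = Z_{c,k}'Z_{c,k}/e exactly).
    """
    data = op.data
    spec = op.spec
    t = spec.n_traits
    g0i = op.g0_inv
    n = data.n_animals
    blocks = np.zeros((1 + n + op.m, t, t))

    blocks[0] = data.xtrx
    # animal blocks: S_i + (H_C⁻¹)_ii · G0⁻¹
    perm = data.order
    a_inv_diag = op.a_inv.diagonal()
    hdiag = a_inv_diag.copy()
    if op.formulation != "pedigree" and op.n_gen:
        agg_inv_diag = np.diag(op.kin.a_gg_inverse)
        cs = spec.cspec
        cdiag = (1.0 / cs.e) * np.ones(op.n_gen) if cs.kind == "Ce" else agg_inv_diag / cs.w
        hdiag[op.n_non:] += cdiag - agg_inv_diag
    blocks[1: 1 + n] = data.s_blocks + hdiag[:, None, None] * g0i

    if op.formulation != "pedigree" and op.m:
        cs = spec.cspec
        if cs.kind == "Ce":
            c_k = np.einsum("ik,ik->k", op.z_c, op.z_c) / cs.e
        else:
            d_a = np.diag(op.kin.a_gg_inverse)
            c_k = np.einsum("ik,i,ik->k", op.z_c, d_a, op.z_c) / cs.w
        if op.formulation == "common":
            vg_inv = g0i[None, :, :] / op.b_diag[:, None, None]
        else:
            vg_inv = op.vg.inv_blocks
        blocks[1 + n:] = c_k[:, None, None] * g0i + vg_inv

    ev = np.linalg.eigvalsh(blocks)
    if (ev[:, 0] <= 0).any():
        raise ValueError("non-positive-definite preconditioner block")
    return BlockPreconditioner(np.linalg.inv(blocks))


@dataclass
class PCGTrace:
    solution: np.ndarray
    iterations: int
    cr_history: np.ndarray
    converged: bool


def relative_residual(operator, s: np.ndarray, rhs: np.ndarray) -> float:
    """C_r = ‖C·s − r‖ / ‖r‖ (Euclidean norms)."""
    rnorm = float(np.linalg.norm(rhs))
    if rnorm == 0.0:
        raise ValueError("zero right-hand side")
    return float(np.linalg.norm(operator(s) - rhs)) / rnorm


def pcg_solve(
    operator,
    rhs: np.ndarray,
    preconditioner: BlockPreconditioner | None = None,
    tol: float = 1e-7,
    maxiter: int = 50_000,
    x0: np.ndarray | None = None,
    true_residual_every: int = 100,
) -> PCGTrace:
    """Classical Hestenes–Stiefel PCG on a symmetric PD operator.

    Returns the first iterate with C_r < ``tol``; deterministic given
    its inputs.  Raises if ``maxiter`` is exceeded, reporting the final
    C_r in the message.
    """
    rnorm = float(np.linalg.norm(rhs))
    if rnorm == 0.0:
        raise ValueError("zero right-hand side")
    x = np.zeros_like(rhs) if x0 is None else x0.astype(float).copy()
    r = rhs - operator(x)
    cr_hist = [float(np.linalg.norm(r)) / rnorm]
    if cr_hist[0] < tol:
        return PCGTrace(x, 0, np.array(cr_hist), True)
    z = preconditioner.apply(r) if preconditioner is not None else r.copy()
    p = z.copy()
    rz = float(r @ z)
    for it in range(1, maxiter + 1):
        ap = operator(p)
        alpha = rz / float(p @ ap)
        x += alpha * p
        r -= alpha * ap
        if true_residual_every and it % true_residual_every == 0:
            r = rhs - operator(x)
        cr = float(np.linalg.norm(r)) / rnorm
        cr_hist.append(cr)
        log.debug("iter %d C_r %.3e", it, cr)
        if cr < tol:
            log.info("PCG converged in %d iterations (C_r = %.3e)", it, cr)
            return PCGTrace(x, it, np.array(cr_hist), True)
        z = preconditioner.apply(r) if preconditioner is not None else r.copy()
        rz_new = float(r @ z)
        beta = rz_new / rz
        rz = rz_new
        p = z + beta * p
    raise RuntimeError(f"PCG did not converge in {maxiter} iterations (final C_r = {cr_hist[-1]:.3e})")
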