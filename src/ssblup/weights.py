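"""Two-step marker-weight estimation.

The weighted single-step models take precomputed per-trait marker
weights.  The pipeline that produces them is:

1. multi-trait pedigree BLUP (animal model, no genomic information)
   giving EBV and, from the direct inverse of the MME coefficient
   matrix, exact prediction error variances and reliabilities;
2. deregression of the EBV of animals with own or progeny phenotypes,
   removing shrinkage and the parent-average contribution, with
   information-based record weights;
3. single-trait BayesA (Gibbs sampling) on the deregressed proofs, with
   each record's residual variance divided by its deregression weight;
   the posterior means of the marker-specific variances, scaled to mean
   one, are the marker weights.

Reliability here uses exact PEV from a dense inverse rather than a
production-scale approximation, which is valid at the pedigree sizes
this package runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mme import Dataset, ModelSpec, assemble_dataset, _dense_data_blocks
from .pedigree import Pedigree, KinshipComponents, UNKNOWN

__all__ = [
    "BayesAConfig",
    "DeregressedRecord",
    "animal_model_ebv_and_reliability",
    "deregress",
    "bayesa_gibbs",
    "weights_from_variances",
    "bayesa_prior_scale",
]


@dataclass
class BayesAConfig:
    """BayesA hyperparameters.

    ``nu``/``scale`` parameterize the scaled-inverse-χ² prior on marker
    variances; ``scale`` is usually derived with :func:`bayesa_prior_scale`
    so the prior mean marker variance matches genetic variance / s.
    """

    nu: float = 4.2
    scale: float = 1e-4
    chain: int = 20_000
    burn_in: int = 4_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chain <= self.burn_in:
            raise ValueError("chain length must exceed burn-in")
        if self.nu <= 2:
            raise ValueError("nu must exceed 2 for a finite prior mean")


def bayesa_prior_scale(genetic_variance: float, s: float, nu: float = 4.2) -> float:
    """Prior scale S with prior mean marker variance = genetic variance / s."""
    return (nu - 2.0) / nu * genetic_variance / s


@dataclass
class DeregressedRecord:
    animal: object          # external label
    trait: str
    drp: float
    weight: float
    reliability: float


def animal_model_ebv_and_reliability(
    ped: Pedigree,
    phenotypes: pd.DataFrame,
    kin: KinshipComponents,
    spec: ModelSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Pedigree-BLUP EBV and exact reliabilities, both (n_animals, T).

    Solves the multi-trait animal model MME densely and takes prediction
    error variances from the inverse coefficient matrix:
    r²_it = 1 − PEV_it / ((1 + F_i)·G0[t,t]).
    """
    data = assemble_dataset(ped, phenotypes, spec)
    if not data.s_blocks.any():
        raise ValueError("no phenotype records at all")
    t = spec.n_traits
    n = data.n_animals
    xtrx, xtrw, wtrw = _dense_data_blocks(data)
    perm = data.order
    a_inv = kin.a_inverse[perm][:, perm].toarray()
    cmat = np.zeros((t * (1 + n), t * (1 + n)))
    cmat[:t, :t] = xtrx
    cmat[:t, t:] = xtrw
    cmat[t:, :t] = xtrw.T
    cmat[t:, t:] = wtrw + np.kron(a_inv, spec.g0_inv)
    rhs = np.concatenate([data.rhs_fixed, data.rhs_animal.ravel()])
    cinv = np.linalg.inv(cmat)
    sol = cinv @ rhs

    ebv_mme = sol[t:].reshape(n, t)
    pev_mme = np.diagonal(cinv)[t:].reshape(n, t)
    ebv = np.empty_like(ebv_mme)
    pev = np.empty_like(pev_mme)
    ebv[perm] = ebv_mme
    pev[perm] = pev_mme
    denom = (1.0 + kin.F)[:, None] * np.diag(spec.g0)[None, :]
    rel = np.clip(1.0 - pev / denom, 0.0, 1.0)
    return ebv, rel


def _garrick_information(r2_i: float, r2_pa: float, lam: float) -> tuple[float, float]:
    """Effective own (l_i) and parent-average (l_pa) information contents.

    Inverts the reliabilities of the two-equation (parent average,
    animal) BLUP system with λ-scaled pedigree precision [[4,−2],[−2,2]]
    to recover the record information each equation carried.
    """
    r2_i = min(r2_i, 1.0 - 1e-8)
    r2_pa = min(r2_pa, 1.0 - 1e-8)
    k = (1.0 - r2_i) / (1.0 - r2_pa)
    q = lam / (1.0 - r2_i)
    b = 0.5 * (q + np.sqrt(q * q + 8.0 * lam * lam / k))
    a = 2.0 * b * k
    return b - 2.0 * lam, a - 4.0 * lam


def deregress(
    ebv: np.ndarray,
    reliability: np.ndarray,
    ped: Pedigree,
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
    c: float = 0.5,
) -> list[DeregressedRecord]:
    """Garrick-style deregressed proofs with information weights.

    Only animals with own or progeny phenotypes are returned.  For each,
    the parent-average contribution is removed by solving the
    two-equation system backwards:  r_i = −2λ·PA + (l_i + 2λ)·EBV_i and
    DRP = r_i / l_i.  The record weight is
    (1 − h²) / ((c + (1 − r²_DRP)/r²_DRP)·h²).
    """
    recs: list[DeregressedRecord] = []
    pheno_pos = set(ped.position_of(phenotypes["animal"].to_numpy()).tolist())
    has_own = np.zeros(ped.n, dtype=bool)
    has_own[list(pheno_pos)] = True
    # progeny phenotypes: parent of any phenotyped animal
    has_prog = np.zeros(ped.n, dtype=bool)
    for i in pheno_pos:
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                has_prog[p] = True
    eligible = has_own | has_prog

    g_var = np.diag(spec.g0)
    r_var = np.diag(spec.r0)
    for t, trait in enumerate(spec.trait_names):
        h2 = g_var[t] / (g_var[t] + r_var[t])
        lam = (1.0 - h2) / h2
        for i in np.flatnonzero(eligible):
            r2 = reliability[i, t]
            if r2 <= 0.0:
                warnings.warn(f"animal {ped.labels[i]!r} trait {trait}: zero reliability, skipped")
                continue
            s_, d_ = ped.sire[i], ped.dam[i]
            pa = 0.5 * ((ebv[s_, t] if s_ != UNKNOWN else 0.0) + (ebv[d_, t] if d_ != UNKNOWN else 0.0))
            r2_pa = 0.25 * ((reliability[s_, t] if s_ != UNKNOWN else 0.0)
                            + (reliability[d_, t] if d_ != UNKNOWN else 0.0))
            l_i, _ = _garrick_information(r2, r2_pa, lam)
            if l_i <= 0.0:
                warnings.warn(f"animal {ped.labels[i]!r} trait {trait}: no own information, skipped")
                continue
            drp = (-2.0 * lam * pa + (l_i + 2.0 * lam) * ebv[i, t]) / l_i
            r2_drp = l_i / (l_i + lam)
            w = (1.0 - h2) / ((c + (1.0 - r2_drp) / r2_drp) * h2)
            recs.append(DeregressedRecord(ped.labels[i], trait, float(drp), float(w), float(r2_drp)))
    return recs


# ------------------------------------------------------------- BayesA

def _gibbs_python(y, w, z, nu, scale, nu_e, scale_e, chain, burn_in, seed):
    rng = np.random.RandomState(seed)
    n, m = z.shape
    g = np.zeros(m)
    mu = 0.0
    sig2k = np.full(m, nu * scale / (nu - 2.0))
    sig2e = max(float(np.var(y)), 1e-8)
    e = y - mu
    zwz = np.einsum("ik,i,ik->k", z, w, z)
    wsum = float(w.sum())
    sum_sig2k = np.zeros(m)
    sum_g = np.zeros(m)
    kept = 0
    for it in range(chain):
        # general mean
        e += mu
        mu = float(w @ e) / wsum + rng.standard_normal() * np.sqrt(sig2e / wsum)
        e -= mu
        # marker effects and variances
        for k in range(m):
            zk = z[:, k]
            e += zk * g[k]
            rhs = float((w * zk) @ e)
            prec = zwz[k] / sig2e + 1.0 / sig2k[k]
            mean = rhs / sig2e / prec
            g[k] = mean + rng.standard_normal() / np.sqrt(prec)
            e -= zk * g[k]
            sig2k[k] = (nu * scale + g[k] ** 2) / rng.chisquare(nu + 1.0)
        sig2e = (float((w * e) @ e) + nu_e * scale_e) / rng.chisquare(n + nu_e)
        if it >= burn_in:
            sum_sig2k += sig2k
            sum_g += g
            kept += 1
    return sum_sig2k / kept, sum_g / kept


try:  # hot loop: identical algorithm, numba-compiled
    import numba

    @numba.njit(cache=True)
    def _gibbs_numba(y, w, z, nu, scale, nu_e, scale_e, chain, burn_in, seed):  # pragma: no cover
        np.random.seed(seed)
        n, m = z.shape
        g = np.zeros(m)
        mu = 0.0
        sig2k = np.full(m, nu * scale / (nu - 2.0))
        sig2e = max(np.var(y), 1e-8)
        e = y - mu
        zwz = np.zeros(m)
        for k in range(m):
            acc = 0.0
            for i in range(n):
                acc += z[i, k] * w[i] * z[i, k]
            zwz[k] = acc
        wsum = w.sum()
        sum_sig2k = np.zeros(m)
        sum_g = np.zeros(m)
        kept = 0
        for it in range(chain):
            we = 0.0
            for i in range(n):
                e[i] += mu
                we += w[i] * e[i]
            mu = we / wsum + np.random.standard_normal() * np.sqrt(sig2e / wsum)
            for i in range(n):
                e[i] -= mu
            for k in range(m):
                gk = g[k]
                rhs = 0.0
                for i in range(n):
                    e[i] += z[i, k] * gk
                    rhs += w[i] * z[i, k] * e[i]
                prec = zwz[k] / sig2e + 1.0 / sig2k[k]
                mean = rhs / sig2e / prec
                gk = mean + np.random.standard_normal() / np.sqrt(prec)
                g[k] = gk
                for i in range(n):
                    e[i] -= z[i, k] * gk
                sig2k[k] = (nu * scale + gk * gk) / np.random.chisquare(nu + 1.0)
            see = 0.0
            for i in range(n):
                see += w[i] * e[i] * e[i]
            sig2e = (see + nu_e * scale_e) / np.random.chisquare(n + nu_e)
            if it >= burn_in:
                for k in range(m):
                    sum_sig2k[k] += sig2k[k]
                    sum_g[k] += g[k]
                kept += 1
        return sum_sig2k / kept, sum_g / kept

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def bayesa_gibbs(
    drp: np.ndarray,
    weights: np.ndarray,
    z_c: np.ndarray,
    config: BayesAConfig,
    use_numba: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-trait weighted BayesA; returns posterior mean marker
    variances and effects.

    Model: drp = μ + Z_c g + e with Var(e_i) = σ²_e / weight_i, marker
    variances σ²_k ~ scaled-inv-χ²(ν, S) updated with ν+1 degrees of
    freedom each cycle.  The residual variance carries a weakly
    informative scaled-inv-χ²(4, var(drp)/2) prior.  Deterministic given
    ``config.seed``.
    """
    y = np.asarray(drp, dtype=float)
    w = np.asarray(weights, dtype=float)
    z = np.asarray(z_c, dtype=float)
    if (w <= 0).any():
        raise ValueError("deregression weights must be positive")
    nu_e, scale_e = 4.0, float(np.var(y)) / 2.0
    args = (y.copy(), w, z, float(config.nu), float(config.scale), nu_e, scale_e,
            int(config.chain), int(config.burn_in), int(config.seed))
    fn = _gibbs_numba if (use_numba and _HAVE_NUMBA) else _gibbs_python
    sig2k, g = fn(*args)
    return sig2k, g


def weights_from_variances(sigma2: np.ndarray) -> np.ndarray:
    """Scale posterior marker variances to mean 1 (rank-preserving)."""
    sigma2 = np.asarray(sigma2, dtype=float)
    if (sigma2 < 0).any():
        raise ValueError("variances must be non-negative")
    mean = sigma2.mean()
    if mean == 0:
        raise ValueError("all-zero variances")
    return sigma2 / mean


def drp_table(recs: list[DeregressedRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in recs])
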