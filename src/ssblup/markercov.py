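"""Trait-specific marker (co)variance blocks V_g.

With trait-specific weights the covariance of the k-th marker's effects
across T traits is a T×T block

    V_{g,k}[i,j] = g0_{ij} · D_{ij,k} · scale,

where D_{ii,k} is marker k's weight for trait i (column mean 1) and the
cross-trait weight defaults to the correlation-one rule
D_{ij} = (D_ii D_jj)^0.5, which gives the closed form

    V_{g,k} = D_(k)^0.5 G0 D_(k)^0.5 · scale.

``scale`` is (1−w)/s for the residual-polygenic regularization C_w and
1/s for C_e.  Marker effects are independent across markers, so V_g is
block diagonal: memory is m·T², never (mT)².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic import RegularizationSpec

WEIGHT_FLOOR = 1e-6

__all__ = [
    "TraitWeights",
    "MarkerCovarianceBlocks",
    "standardize_and_floor",
    "average_weight_columns",
    "build_vg_blocks",
    "invert_vg_blocks",
    "read_weights_tsv",
    "write_weights_tsv",
]


@dataclass
class TraitWeights:
    """m×T per-marker, per-trait weights; every column has mean 1."""

    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.atleast_2d(np.asarray(self.d, dtype=float))
        if (self.d <= 0).any():
            raise ValueError("weights must be positive (floor zeros first)")
        if not np.allclose(self.d.mean(axis=0), 1.0, atol=1e-12):
            raise ValueError("each trait's weight column must have mean 1")

    @property
    def m(self) -> int:
        return self.d.shape[0]

    @property
    def n_traits(self) -> int:
        return self.d.shape[1]

    @classmethod
    def ones(cls, m: int, n_traits: int) -> "TraitWeights":
        return cls(np.ones((m, n_traits)))


@dataclass
class MarkerCovarianceBlocks:
    """Stacked V_{g,k} blocks (m, T, T), their inverses and the scale used."""

    blocks: np.ndarray
    inv_blocks: np.ndarray
    scale: float


def standardize_and_floor(raw: np.ndarray, eps: float = WEIGHT_FLOOR) -> np.ndarray:
    """One trait's weight column: floor zeros at ``eps``, rescale to mean 1."""
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("weights must be finite")
    if (raw < 0).any():
        raise ValueError("weights must be non-negative")
    if (raw == 0).all():
        raise ValueError("all-zero weight vector")
    floored = np.where(raw < eps, eps, raw)
    out = floored / floored.mean()
    # exact mean 1 to numerical precision
    return out / out.mean()


def average_weight_columns(*columns: np.ndarray) -> np.ndarray:
    """Elementwise mean of standardized columns, re-standardized to mean 1.

    Used for the combined weighting scenario where one common weight per
    marker averages the per-trait weights.
    """
    cols = [standardize_and_floor(c) for c in columns]
    return standardize_and_floor(np.mean(cols, axis=0))


def _check_pd(block: np.ndarray, k: int) -> None:
    ev = np.linalg.eigvalsh(block)
    if ev[0] <= 1e-12 * np.trace(block):
        raise ValueError(f"marker block {k} not positive definite")


def build_vg_blocks(
    g0: np.ndarray,
    weights: TraitWeights,
    s: float,
    cspec: RegularizationSpec,
    cross_weights: dict[tuple[int, int], np.ndarray] | None = None,
) -> MarkerCovarianceBlocks:
    """V_{g,k} blocks for all markers.

    By default the cross-trait weight follows the correlation-one rule,
    so each block is sqrt(D_k) G0 sqrt(D_k) · scale and inherits G0's
    correlation structure.  ``cross_weights`` optionally supplies
    explicit off-diagonal weight vectors keyed by trait pair (i, j); a
    block that fails the positive-definiteness check is rejected.
    """
    g0 = np.asarray(g0, dtype=float)
    if np.linalg.eigvalsh(g0)[0] <= 0:
        raise ValueError("G0 must be positive definite")
    t = g0.shape[0]
    if weights.n_traits != t:
        raise ValueError("weight columns must match number of traits")
    scale = cspec.marker_scale(s)
    sq = np.sqrt(weights.d)  # (m, T)
    blocks = scale * np.einsum("ki,ij,kj->kij", sq, g0, sq)
    if cross_weights:
        for (i, j), dij in cross_weights.items():
            blocks[:, i, j] = blocks[:, j, i] = g0[i, j] * np.asarray(dij) * scale
        for k in range(weights.m):
            _check_pd(blocks[k], k)
    inv = invert_vg_blocks(blocks)
    return MarkerCovarianceBlocks(blocks=blocks, inv_blocks=inv, scale=scale)


def invert_vg_blocks(blocks: np.ndarray) -> np.ndarray:
    """Blockwise inverses of the stacked (m, T, T) V_{g,k}."""
    ev = np.linalg.eigvalsh(blocks)
    if (ev[:, 0] <= 0).any():
        k = int(np.argmax(ev[:, 0] <= 0))
        raise ValueError(f"marker block {k} not positive definite (was weight flooring skipped?)")
    return np.linalg.inv(blocks)


# ---------------------------------------------------------------- I/O

def read_weights_tsv(path, m: int, trait_names: list[str]) -> TraitWeights:
    """Long-format TSV (marker, trait, weight); a missing trait = all ones."""
    df = pd.read_csv(path, sep="\t")
    d = np.ones((m, len(trait_names)))
    for t, name in enumerate(trait_names):
        sub = df[df["trait"] == name]
        if len(sub) == 0:
            continue
        if len(sub) != m:
            raise ValueError(f"trait {name!r}: expected {m} weights, got {len(sub)}")
        d[:, t] = standardize_and_floor(sub.sort_values("marker")["weight"].to_numpy())
    return TraitWeights(d)


def write_weights_tsv(weights: TraitWeights, trait_names: list[str], path) -> None:
    rows = []
    for t, name in enumerate(trait_names):
        for k in range(weights.m):
            rows.append((k, name, weights.d[k, t]))
    pd.DataFrame(rows, columns=["marker", "trait", "weight"]).to_csv(path, sep="\t", index=False)
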