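"""Genotype storage, VanRaden centering/scaling and genomic relationship algebra.

The genomic relationship matrix used throughout is ``G_C = Z_c B Z_c' + C``
with ``Z_c`` the column-centered 0/1/2 allele counts (center 2p_k, p_k a
base-population allele frequency), ``B`` a diagonal scaling/weighting
matrix and ``C`` a regularization matrix — either ``C_e = eI`` or the
residual-polygenic form ``C_w = w A_gg``.  With equal marker weights,
``B = I(1−w)/s`` (or ``I/s`` for C_e) and ``s = 2Σ p_k(1−p_k)``.

Dense G_C and its Woodbury inverse

    G_C⁻¹ = C⁻¹ − C⁻¹ Z_c K⁻¹ Z_c' C⁻¹,   K = Z_c' C⁻¹ Z_c + B⁻¹

exist here as desk-scale oracles; the production solver never forms an
n×n genomic matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

P_CLIP = 1e-6

__all__ = [
    "GenotypeMatrix",
    "RegularizationSpec",
    "base_allele_frequencies",
    "center_and_scale",
    "build_gc_dense",
    "woodbury_gc_inverse",
    "read_genotypes",
    "write_plink_raw",
    "read_frequencies_tsv",
    "write_frequencies_tsv",
]


@dataclass
class RegularizationSpec:
    """Choice of regularization C: ``C_e = eI`` or ``C_w = w A_gg``.

    ``w`` is the residual polygenic proportion — the fraction of genetic
    variance not attributed to the markers.
    """

    kind: str = "Cw"          # "Ce" | "Cw"
    e: float = 0.01
    w: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("Ce", "Cw"):
            raise ValueError(f"unknown regularization kind {self.kind!r}")
        if self.kind == "Cw" and not (0.0 < self.w < 1.0):
            raise ValueError("residual polygenic proportion w must be in (0,1)")
        if self.kind == "Ce" and self.e <= 0:
            raise ValueError("e must be positive")

    def c_dense(self, a_gg: np.ndarray) -> np.ndarray:
        if self.kind == "Ce":
            return self.e * np.eye(a_gg.shape[0])
        return self.w * a_gg

    def c_inverse_dense(self, a_gg_inverse: np.ndarray) -> np.ndarray:
        if self.kind == "Ce":
            return np.eye(a_gg_inverse.shape[0]) / self.e
        return a_gg_inverse / self.w

    def marker_scale(self, s: float) -> float:
        """Variance scale per unit weight: (1−w)/s for C_w, 1/s for C_e."""
        return (1.0 - self.w) / s if self.kind == "Cw" else 1.0 / s


@dataclass
class GenotypeMatrix:
    """n×m allele counts (0/1/2, complete) with base allele frequencies."""

    ids: np.ndarray
    counts: np.ndarray
    p: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.isin(self.counts, (0, 1, 2)).all():
            raise ValueError("genotype counts must be 0/1/2 with no missing values")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]


def base_allele_frequencies(
    counts: np.ndarray,
    method: str = "observed_mean",
    known_p: np.ndarray | float | None = None,
) -> np.ndarray:
    """Per-marker base-population allele frequencies, clipped to (0,1).

    ``known`` passes through externally supplied frequencies (in a
    simulation study, the recorded truth); ``observed_mean`` estimates
    p = mean(count)/2 from the genotyped animals themselves.
    """
    counts = np.asarray(counts)
    m = counts.shape[1]
    if method == "known":
        if known_p is None:
            raise ValueError("method='known' requires known_p")
        p = np.broadcast_to(np.asarray(known_p, dtype=float), (m,)).copy()
    elif method == "observed_mean":
        p = counts.mean(axis=0) / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    if (p <= P_CLIP).any() or (p >= 1 - P_CLIP).any():
        warnings.warn("allele frequencies clipped away from 0/1 (monomorphic markers kept)")
    return np.clip(p, P_CLIP, 1 - P_CLIP)


def center_and_scale(geno: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """Centered genotypes Z_c = counts − 2p and scaling s = 2Σp(1−p)."""
    if geno.p is None:
        raise ValueError("allele frequencies not set")
    z_c = geno.counts.astype(float) - 2.0 * geno.p
    s = float(2.0 * np.sum(geno.p * (1.0 - geno.p)))
    return z_c, s


def build_gc_dense(
    z_c: np.ndarray,
    b_diag: np.ndarray,
    cspec: RegularizationSpec,
    a_gg: np.ndarray,
) -> np.ndarray:
    """Dense G_C = Z_c diag(b) Z_c' + C (oracle; desk scale only)."""
    b_diag = np.asarray(b_diag, dtype=float)
    if b_diag.shape[0] != z_c.shape[1]:
        raise ValueError("B diagonal length must equal number of markers")
    gm = (z_c * b_diag) @ z_c.T
    return gm + cspec.c_dense(a_gg)


def woodbury_gc_inverse(
    z_c: np.ndarray,
    b_diag: np.ndarray,
    cspec: RegularizationSpec,
    a_gg_inverse: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(K, G_C⁻¹) by the Woodbury identity.

    K = Z_c'C⁻¹Z_c + B⁻¹ and G_C⁻¹ = C⁻¹ − C⁻¹ Z_c K⁻¹ Z_c' C⁻¹; avoids
    forming or inverting the n×n genomic matrix.
    """
    b_diag = np.asarray(b_diag, dtype=float)
    if (b_diag <= 0).any():
        raise ValueError("B diagonal must be positive")
    c_inv = cspec.c_inverse_dense(a_gg_inverse)
    cz = c_inv @ z_c
    k = z_c.T @ cz + np.diag(1.0 / b_diag)
    gc_inv = c_inv - cz @ np.linalg.solve(k, cz.T)
    return k, gc_inv


# ---------------------------------------------------------------- I/O

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotypes(path) -> GenotypeMatrix:
    """Read genotypes from a PLINK .raw-style file or a plain TSV.

    A .raw file is whitespace-separated with the six standard meta
    columns then one 0/1/2 column per SNP; a plain TSV has an ``id``
    column followed by marker columns.
    """
    with open(path) as fh:
        header = fh.readline().split()
    if header[: len(_RAW_META)] == _RAW_META:
        df = pd.read_csv(path, sep=r"\s+")
        ids = df["IID"].to_numpy()
        counts = df.drop(columns=_RAW_META).to_numpy(dtype=np.int8)
    else:
        df = pd.read_csv(path, sep="\t")
        ids = df.iloc[:, 0].to_numpy()
        counts = df.iloc[:, 1:].to_numpy(dtype=np.int8)
    return GenotypeMatrix(ids=ids, counts=counts)


def write_plink_raw(geno: GenotypeMatrix, path, marker_names=None) -> None:
    if marker_names is None:
        marker_names = [f"SNP{k}_A" for k in range(geno.m)]
    df = pd.DataFrame(geno.counts, columns=list(marker_names))
    for col, val in zip(reversed(_RAW_META), ["-9", "0", "0", "0", geno.ids, geno.ids]):
        df.insert(0, col, val)
    df.to_csv(path, sep=" ", index=False)


def read_frequencies_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_frequencies_tsv(p: np.ndarray, path, marker_names=None) -> None:
    if marker_names is None:
        marker_names = [f"SNP{k}" for k in range(len(p))]
    pd.DataFrame({"marker": marker_names, "p": p}).to_csv(path, sep="\t", index=False)
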