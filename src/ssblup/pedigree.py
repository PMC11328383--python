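"""Pedigree container and numerator-relationship-matrix (A) algebra.

The additive genetic covariance among animals in a closed breeding
population is ``G0 ⊗ A`` where A is Wright's numerator relationship
matrix.  Single-step models need several pieces of A-algebra:

* per-animal inbreeding coefficients F (diag(A) = 1 + F),
* the sparse inverse A⁻¹ assembled directly by Henderson's rules,
* dense submatrices of A over the genotyped animals (A_gg) and between
  non-genotyped and genotyped animals (A_ng),
* the projection T = A_ng A_gg⁻¹ used by desk-scale variance oracles.

Unknown parents are treated as unrelated, non-inbred base-population
draws (no genetic groups / metafounders).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = -1

__all__ = [
    "UNKNOWN",
    "Pedigree",
    "KinshipComponents",
    "validate_and_sort",
    "inbreeding_and_a_inverse",
    "a_submatrix",
    "t_matrix",
    "read_pedigree_tsv",
    "write_pedigree_tsv",
]


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered pedigree over ``n`` animals.

    Parents are stored as 0-based positions into the same pedigree
    (``UNKNOWN`` = -1 for a base-population parent).  ``labels`` keeps
    the original external identifiers; all internal algebra is on
    positions.
    """

    labels: np.ndarray          # external ids, shape (n,)
    sire: np.ndarray            # int positions or UNKNOWN
    dam: np.ndarray
    sex: np.ndarray             # "M"/"F"
    generation: np.ndarray      # non-negative int
    genotyped: np.ndarray       # bool
    phenotyped: np.ndarray      # bool

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        for name in ("sire", "dam", "generation"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        self.sex = np.asarray(self.sex, dtype=object)
        self.genotyped = np.asarray(self.genotyped, dtype=bool)
        self.phenotyped = np.asarray(self.phenotyped, dtype=bool)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def genotyped_index(self) -> np.ndarray:
        return np.flatnonzero(self.genotyped)

    @property
    def nongenotyped_index(self) -> np.ndarray:
        return np.flatnonzero(~self.genotyped)

    def position_of(self, labels) -> np.ndarray:
        """Map external labels to 0-based positions."""
        lut = {lab: i for i, lab in enumerate(self.labels.tolist())}
        try:
            return np.array([lut[l] for l in np.asarray(labels).tolist()], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise PedigreeError(f"unknown animal label {exc.args[0]!r}") from None


@dataclass
class KinshipComponents:
    """Inbreeding, sparse A⁻¹ and the genotyped-block algebra of A."""

    F: np.ndarray
    a_inverse: sp.csr_matrix
    a_gg: np.ndarray
    a_gg_inverse: np.ndarray
    ped: Pedigree = field(repr=False)


def validate_and_sort(ped: Pedigree) -> Pedigree:
    """Return a pedigree reordered so every parent precedes its offspring.

    The sort is stable: an already-sorted pedigree comes back unchanged.
    Raises on duplicate ids, dangling parent references and cycles.
    """
    labels = ped.labels
    if len(set(labels.tolist())) != ped.n:
        raise PedigreeError("duplicate animal id in pedigree")
    for name, par in (("sire", ped.sire), ("dam", ped.dam)):
        bad = (par != UNKNOWN) & ((par < 0) | (par >= ped.n))
        if bad.any():
            raise PedigreeError(f"{name} reference outside pedigree")
    if ((ped.sire == np.arange(ped.n)) | (ped.dam == np.arange(ped.n))).any():
        raise PedigreeError("pedigree cycle: animal is its own parent")

    n = ped.n
    indeg = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                indeg[i] += 1
                children[p].append(i)
    # Kahn's algorithm with a min-heap on the original position: an already
    # topologically ordered pedigree comes back in identical order.
    import heapq

    order: list[int] = []
    heap = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    while heap:
        i = heapq.heappop(heap)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    if len(order) != n:
        raise PedigreeError("pedigree cycle detected")
    order_arr = np.array(order, dtype=np.int64)
    new_pos = np.empty(n, dtype=np.int64)
    new_pos[order_arr] = np.arange(n)

    # remap parent positions then permute rows into the new order
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    ks = ped.sire != UNKNOWN
    kd = ped.dam != UNKNOWN
    sire[ks] = new_pos[ped.sire[ks]]
    dam[kd] = new_pos[ped.dam[kd]]
    return Pedigree(
        labels=labels[order_arr],
        sire=sire[order_arr],
        dam=dam[order_arr],
        sex=ped.sex[order_arr],
        generation=ped.generation[order_arr],
        genotyped=ped.genotyped[order_arr],
        phenotyped=ped.phenotyped[order_arr],
    )


def tabular_a(ped: Pedigree) -> np.ndarray:
    """Dense A by the tabular method (oracle; O(n²) memory)."""
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        asd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    return A


def _inbreeding_meuwissen_luo(ped: Pedigree) -> np.ndarray:
    """Meuwissen & Luo (1992) O(n·depth) inbreeding recursion."""
    n = ped.n
    F = np.zeros(n)
    # diagonal of the Cholesky-related D: mendelian sampling variances
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            F[i] = 0.0
            continue
        # accumulate L row of animal i over its ancestors
        AN: dict[int, float] = {i: 1.0}
        f_ii = 0.0
        # process ancestors from youngest to oldest
        pending = dict(AN)
        while pending:
            j = max(pending)
            lj = pending.pop(j)
            sj, dj = ped.sire[j], ped.dam[j]
            if sj != UNKNOWN:
                pending[sj] = pending.get(sj, 0.0) + 0.5 * lj
            if dj != UNKNOWN:
                pending[dj] = pending.get(dj, 0.0) + 0.5 * lj
            # mendelian sampling variance of j
            if sj != UNKNOWN and dj != UNKNOWN:
                dj_var = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj != UNKNOWN or dj != UNKNOWN:
                fk = F[sj] if sj != UNKNOWN else F[dj]
                dj_var = 0.75 - 0.25 * fk
            else:
                dj_var = 1.0
            f_ii += lj * lj * dj_var
        F[i] = f_ii - 1.0
    return F


def inbreeding(ped: Pedigree, dense_threshold: int = 5000) -> np.ndarray:
    """Per-animal inbreeding coefficients.

    Uses the dense tabular method for small pedigrees and the
    Meuwissen–Luo recursion above ``dense_threshold`` animals; the two
    agree exactly on overlapping sizes.
    """
    if ped.n <= dense_threshold:
        return np.diag(tabular_a(ped)) - 1.0
    return _inbreeding_meuwissen_luo(ped)


def inbreeding_and_a_inverse(ped: Pedigree, dense_threshold: int = 5000) -> KinshipComponents:
    """F, sparse A⁻¹ (Henderson's rules with inbreeding) and the A_gg block.

    Henderson's rules: for animal i with mendelian sampling variance
    m_i = 0.5 − 0.25(F_s + F_d) (known parents; 0.75 − 0.25 F_p with one
    known, 1 with none), add α = 1/m_i at (i,i), −α/2 at (i,parent) and
    α/4 between parents.
    """
    F = inbreeding(ped, dense_threshold)
    n = ped.n
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            m = 0.5 - 0.25 * (F[s] + F[d])
        elif s != UNKNOWN or d != UNKNOWN:
            fp = F[s] if s != UNKNOWN else F[d]
            m = 0.75 - 0.25 * fp
        else:
            m = 1.0
        alpha = 1.0 / m
        add(i, i, alpha)
        for p in (s, d):
            if p != UNKNOWN:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p in (s, d):
            for q in (s, d):
                if p != UNKNOWN and q != UNKNOWN:
                    add(p, q, 0.25 * alpha)
    a_inv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    gidx = ped.genotyped_index
    if gidx.size:
        a_gg = a_submatrix(ped, positions=gidx)
        a_gg_inv = np.linalg.inv(a_gg)
    else:
        a_gg = np.zeros((0, 0))
        a_gg_inv = np.zeros((0, 0))
    return KinshipComponents(F=F, a_inverse=a_inv, a_gg=a_gg, a_gg_inverse=a_gg_inv, ped=ped)


def _ancestor_closure(ped: Pedigree, positions: np.ndarray) -> np.ndarray:
    keep = np.zeros(ped.n, dtype=bool)
    stack = list(positions)
    while stack:
        i = stack.pop()
        if keep[i]:
            continue
        keep[i] = True
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN and not keep[p]:
                stack.append(p)
    return np.flatnonzero(keep)


def a_submatrix(ped: Pedigree, labels=None, positions=None) -> np.ndarray:
    """Dense block of A over a subset of animals.

    Builds tabular A restricted to the ancestor closure of the subset
    (the only animals that can contribute), then slices — the full A is
    never materialized.
    """
    if positions is None:
        positions = ped.position_of(labels)
    positions = np.asarray(positions, dtype=np.int64)
    closure = _ancestor_closure(ped, positions)  # sorted ascending
    # local tabular A over the closure; parents always inside the closure
    local = np.full(ped.n, -1, dtype=np.int64)
    local[closure] = np.arange(closure.size)
    m = closure.size
    A = np.zeros((m, m))
    for li, i in enumerate(closure):
        s, d = ped.sire[i], ped.dam[i]
        ls = local[s] if s != UNKNOWN else -1
        ld = local[d] if d != UNKNOWN else -1
        row = np.zeros(li)
        if ls >= 0:
            row += 0.5 * A[ls, :li]
        if ld >= 0:
            row += 0.5 * A[ld, :li]
        A[li, :li] = row
        A[:li, li] = row
        asd = A[ls, ld] if (ls >= 0 and ld >= 0) else 0.0
        A[li, li] = 1.0 + 0.5 * asd
    sub = local[positions]
    return A[np.ix_(sub, sub)]


def a_cross_block(ped: Pedigree, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """A restricted to rows × cols (used for A_ng)."""
    both = np.concatenate([rows, cols])
    A = a_submatrix(ped, positions=both)
    return A[: rows.size, rows.size:]


def t_matrix(ped: Pedigree, kin: KinshipComponents | None = None) -> np.ndarray:
    """T = A_ng A_gg⁻¹, the regression of non-genotyped on genotyped animals."""
    gidx = ped.genotyped_index
    if gidx.size == 0:
        raise PedigreeError("no genotyped animals")
    nidx = ped.nongenotyped_index
    if nidx.size == 0:
        return np.zeros((0, gidx.size))
    a_ng = a_cross_block(ped, nidx, gidx)
    a_gg_inv = kin.a_gg_inverse if kin is not None else np.linalg.inv(a_submatrix(ped, positions=gidx))
    return a_ng @ a_gg_inv


# ---------------------------------------------------------------- I/O

_SENTINEL = "0"  # unknown-parent marker in files


def read_pedigree_tsv(path) -> Pedigree:
    """Read animal/sire/dam/sex/generation TSV ("0" = unknown parent).

    Optional boolean columns ``genotyped`` and ``phenotyped`` default to
    False.  The result is validated and topologically sorted.
    """
    df = pd.read_csv(path, sep="\t", dtype={"animal": str, "sire": str, "dam": str})
    labels = df["animal"].to_numpy()
    lut = {lab: i for i, lab in enumerate(labels.tolist())}

    def parents(col: pd.Series) -> np.ndarray:
        out = np.full(len(df), UNKNOWN, dtype=np.int64)
        for i, v in enumerate(col.tolist()):
            if v != _SENTINEL and not pd.isna(v):
                if v not in lut:
                    raise PedigreeError(f"parent {v!r} not in pedigree")
                out[i] = lut[v]
        return out

    ped = Pedigree(
        labels=labels,
        sire=parents(df["sire"]),
        dam=parents(df["dam"]),
        sex=df["sex"].to_numpy(),
        generation=df["generation"].to_numpy(),
        genotyped=df["genotyped"].to_numpy(dtype=bool) if "genotyped" in df else np.zeros(len(df), bool),
        phenotyped=df["phenotyped"].to_numpy(dtype=bool) if "phenotyped" in df else np.zeros(len(df), bool),
    )
    return validate_and_sort(ped)


def write_pedigree_tsv(ped: Pedigree, path) -> None:
    lab = ped.labels

    def parent_labels(par: np.ndarray) -> list[str]:
        return [str(lab[p]) if p != UNKNOWN else _SENTINEL for p in par]

    pd.DataFrame(
        {
            "animal": lab,
            "sire": parent_labels(ped.sire),
            "dam": parent_labels(ped.dam),
            "sex": ped.sex,
            "generation": ped.generation,
            "genotyped": ped.genotyped.astype(int),
            "phenotyped": ped.phenotyped.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)
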