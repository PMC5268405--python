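"""Pedigree handling and relationship-matrix algebra.

The additive (numerator) relationship matrix ``A`` encodes the expected
proportion of alleles shared identically by descent between every pair of
individuals in a pedigree.  It is the covariance structure of breeding
values in the animal model: ``a ~ N(0, A * V_A)`` for a single trait, or
``N(0, A kron G)`` for several.  This module validates raw pedigree
tables, builds ``A`` by the tabular method, builds its sparse inverse by
Henderson's rules with Quaas' inbreeding adjustment, and computes simple
demographic summaries (inbreeding coefficients, generation time, depth).

Unknown parents are treated as draws from an unrelated, non-inbred base
population; individuals with both parents unknown are founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PedigreeError",
    "Pedigree",
    "validate_pedigree",
    "additive_relationship",
    "inbreeding_coefficients",
    "a_inverse",
    "generation_time",
]

#: sentinel index for an unknown parent
UNKNOWN = -1

_MISSING_TOKENS = {"", "na", "nan", "none", "0", "*"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, sex conflicts...)."""


@dataclass
class Pedigree:
    """A validated, topologically sorted pedigree.

    Attributes
    ----------
    ids : list of str
        Individual identifiers, parents always before offspring.
    sire, dam : ndarray of int
        Positional index of each individual's sire/dam, ``-1`` if unknown.
    sex : ndarray of str ("F"/"M")
    cohort : ndarray of int
        Birth-cohort year.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    cohort: np.ndarray
    index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {i: k for k, i in enumerate(self.ids)}

    def __len__(self):
        return len(self.ids)

    @property
    def n_maternities(self) -> int:
        return int(np.sum(self.dam >= 0))

    @property
    def n_paternities(self) -> int:
        return int(np.sum(self.sire >= 0))

    @property
    def founders(self) -> np.ndarray:
        """Boolean mask of individuals with both parents unknown."""
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def depths(self) -> np.ndarray:
        """Generation depth of each individual (founders = 1)."""
        d = np.ones(len(self), dtype=int)
        for i in range(len(self)):
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN:
                    d[i] = max(d[i], d[p] + 1)
        return d

    @property
    def max_depth(self) -> int:
        return int(self.depths().max()) if len(self) else 0

    def to_frame(self) -> pd.DataFrame:
        def name(ix):
            return [self.ids[j] if j != UNKNOWN else "" for j in ix]

        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": name(self.sire),
                "dam": name(self.dam),
                "sex": self.sex,
                "cohort": self.cohort,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return validate_pedigree(pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str}))


def _clean_parent(x) -> str | None:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    s = str(x).strip()
    return None if s.lower() in _MISSING_TOKENS else s


def validate_pedigree(raw: pd.DataFrame) -> Pedigree:
    """Validate a raw pedigree table and return a topologically sorted Pedigree.

    Checks: required columns; every named parent has its own record; sires
    are male and dams female; no individual is its own ancestor; parents
    are not born after their offspring (same-cohort parentage is allowed,
    as happens with females breeding in their year of birth).

    Ties in the topological (Kahn) sort are broken by cohort then id, so
    the resulting order — and every matrix built from it — is deterministic.
    """
    required = {"id", "sire", "dam", "sex", "cohort"}
    missing = required - set(raw.columns)
    if missing:
        raise PedigreeError(f"pedigree table is missing columns: {sorted(missing)}")

    ids = [str(x).strip() for x in raw["id"]]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        raise PedigreeError(f"duplicate ids: {list(dup[dup > 1].index[:5])}")
    pos = {i: k for k, i in enumerate(ids)}

    sires = [_clean_parent(x) for x in raw["sire"]]
    dams = [_clean_parent(x) for x in raw["dam"]]
    for role, parents in (("sire", sires), ("dam", dams)):
        unknown_parents = {p for p in parents if p is not None and p not in pos}
        if unknown_parents:
            raise PedigreeError(
                f"{role}s without their own record: {sorted(unknown_parents)[:5]}"
            )

    sex = np.array([str(s).strip().upper()[:1] for s in raw["sex"]])
    bad_sex = [ids[k] for k in range(len(ids)) if sex[k] not in ("F", "M")]
    if bad_sex:
        raise PedigreeError(f"sex must be F or M; offenders: {bad_sex[:5]}")
    offenders = sorted(
        {p for p in sires if p is not None and sex[pos[p]] != "M"}
        | {p for p in dams if p is not None and sex[pos[p]] != "F"}
    )
    if offenders:
        raise PedigreeError(f"sex-inconsistent parentage: {offenders[:10]}")

    cohort = np.asarray(raw["cohort"], dtype=int)
    for k in range(len(ids)):
        for p in (sires[k], dams[k]):
            if p is not None and cohort[pos[p]] > cohort[k]:
                raise PedigreeError(
                    f"parent {p} (cohort {cohort[pos[p]]}) born after "
                    f"offspring {ids[k]} (cohort {cohort[k]})"
                )

    # Kahn topological sort, ties by (cohort, id)
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for k in range(n):
        for p in (sires[k], dams[k]):
            if p is not None:
                children[pos[p]].append(k)
                indeg[k] += 1
    import heapq

    heap = [(cohort[k], ids[k], k) for k in range(n) if indeg[k] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        _, _, k = heapq.heappop(heap)
        order.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, (cohort[c], ids[c], c))
    if len(order) != n:
        on_cycle = [ids[k] for k in range(n) if indeg[k] > 0]
        raise PedigreeError(
            f"pedigree contains a cycle involving (e.g.) individual {on_cycle[0]!r}"
        )

    newpos = {old: new for new, old in enumerate(order)}
    sorted_ids = [ids[k] for k in order]
    sire_ix = np.array(
        [newpos[pos[sires[k]]] if sires[k] is not None else UNKNOWN for k in order]
    )
    dam_ix = np.array(
        [newpos[pos[dams[k]]] if dams[k] is not None else UNKNOWN for k in order]
    )
    return Pedigree(
        ids=sorted_ids,
        sire=sire_ix,
        dam=dam_ix,
        sex=sex[order],
        cohort=cohort[order],
    )


def additive_relationship(ped: Pedigree) -> np.ndarray:
    """Dense additive relationship matrix A by the tabular method.

    Founder diagonal is 1; for individual ``o`` with parents ``s, d``:
    ``A[o, j] = (A[s, j] + A[d, j]) / 2`` for prior ``j`` and
    ``A[o, o] = 1 + A[s, d] / 2``.  Unknown parents contribute zero.
    Rows/columns follow ``ped.ids`` (topological) order.
    """
    n = len(ped)
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
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0)
    return A


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficient F per individual (= diag(A) - 1)."""
    return np.diag(additive_relationship(ped)) - 1.0


def mendelian_sampling_variance(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Variance (relative to V_A) of the Mendelian-sampling deviation.

    0.5 - 0.25 (F_s + F_d) with both parents known, 0.75 - 0.25 F_p with
    one, and 1 for founders.
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    n = len(ped)
    d = np.ones(n)
    for i in range(n):
        s, dm = ped.sire[i], ped.dam[i]
        if s != UNKNOWN and dm != UNKNOWN:
            d[i] = 0.5 - 0.25 * (F[s] + F[dm])
        elif s != UNKNOWN:
            d[i] = 0.75 - 0.25 * F[s]
        elif dm != UNKNOWN:
            d[i] = 0.75 - 0.25 * F[dm]
    return d


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding accounted for.

    For each individual ``i`` with Mendelian-sampling variance ``d_i``,
    add ``1/d_i`` at (i,i), ``-1/(2 d_i)`` between i and each known
    parent, and ``1/(4 d_i)`` among the known parents.
    """
    d = mendelian_sampling_variance(ped, F)
    rows, cols, vals = [], [], []
    for i in range(len(ped)):
        alpha = 1.0 / d[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-alpha / 2.0, -alpha / 2.0]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(alpha / 4.0)
    n = len(ped)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def generation_time(ped: Pedigree) -> float:
    """Mean age of parents at the birth of their offspring, in years.

    Averaged over every parent-offspring link (a link per known sire and
    per known dam); used to convert per-generation rates to per-year.
    """
    ages = []
    for i in range(len(ped)):
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                ages.append(ped.cohort[i] - ped.cohort[p])
    if not ages:
        raise PedigreeError("generation time undefined: pedigree has no parent links")
    return float(np.mean(ages))


def write_sparse_coo_csv(mat: sparse.spmatrix, ids: list, path, index_path=None) -> None:
    """Write a sparse matrix as coordinate CSV (i,j,value) plus an id map."""
    coo = sparse.coo_matrix(mat)
    pd.DataFrame({"i": coo.row, "j": coo.col, "value": coo.data}).to_csv(path, index=False)
    if index_path is not None:
        import json

        with open(index_path, "w") as fh:
            json.dump({str(k): int(v) for v, k in enumerate(ids)}, fh)
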