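"""Pedigree handling: loading, topological ordering, inbreeding and relationship matrices.

Internally animals are renumbered 1..n after a topological sort so that every
parent precedes its offspring; index 0 denotes an unknown parent.  All matrix
routines operate on this internal ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse


class PedigreeError(ValueError):
    """Raised for structural pedigree problems (cycles, unknown labels, duplicates)."""


@dataclass
class Pedigree:
    """A topologically sorted pedigree.

    Attributes
    ----------
    labels : array of original animal labels, position ``k`` = internal index ``k+1``.
    sire, dam : int arrays (length n) of internal parent indices, 0 = unknown.
    birth_year : float array (NaN = missing).
    sex : object array ('M', 'F' or 'U').
    F : inbreeding coefficients (filled by :func:`compute_inbreeding`).
    """

    labels: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray
    sex: np.ndarray
    F: np.ndarray | None = None
    _index_of: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index_of:
            self._index_of = {lab: k + 1 for k, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label) -> int:
        """1-based internal index of an animal label."""
        try:
            return self._index_of[label]
        except KeyError:
            raise PedigreeError(f"unknown animal label: {label!r}") from None

    def is_founder(self) -> np.ndarray:
        return (self.sire == 0) & (self.dam == 0)

    def to_frame(self) -> pd.DataFrame:
        lab = np.concatenate([["0"], self.labels.astype(object)])
        return pd.DataFrame(
            {
                "animal": self.labels,
                "sire": lab[self.sire],
                "dam": lab[self.dam],
                "birth_year": self.birth_year,
                "sex": self.sex,
                "F": self.F if self.F is not None else np.nan,
            }
        )


_MISSING = {"", "0", "NA", "na", "NaN", "nan", ".", "-", "None"}


def _parse_parent(value) -> object | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s in _MISSING:
        return None
    return s


def load_and_sort(pedigree_file) -> Pedigree:
    """Read a pedigree CSV (``animal,sire,dam[,birth_year,sex]``) and sort it.

    Unknown parents may be coded ``0``, empty, ``NA`` or ``-``.  Raises
    :class:`PedigreeError` on duplicated ids, parent labels that never appear
    as animals, or cycles (an animal that is its own ancestor).
    """
    df = pd.read_csv(pedigree_file, dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    for required in ("animal", "sire", "dam"):
        if required not in cols:
            raise PedigreeError(f"pedigree file lacks column {required!r}")
    animals = df[cols["animal"]].astype(str).str.strip().to_numpy()
    if len(set(animals)) != len(animals):
        dup = pd.Series(animals)
        dups = dup[dup.duplicated()].unique()
        raise PedigreeError(f"duplicated animal ids: {list(dups)[:5]}")
    sires = [_parse_parent(v) for v in df[cols["sire"]]]
    dams = [_parse_parent(v) for v in df[cols["dam"]]]
    known = set(animals)
    bad = sorted({p for p in sires + dams if p is not None and p not in known})
    if bad:
        raise PedigreeError(f"parent labels not present as animals: {bad[:10]}")

    if "birth_year" in cols:
        by = pd.to_numeric(df[cols["birth_year"]], errors="coerce").to_numpy(float)
    else:
        by = np.full(len(animals), np.nan)
    if "sex" in cols:
        sx = (
            df[cols["sex"]]
            .fillna("U")
            .astype(str)
            .str.strip()
            .str.upper()
            .str[:1]
            .replace({"": "U"})
            .to_numpy(object)
        )
        sx = np.where(np.isin(sx, ["M", "F"]), sx, "U")
    else:
        sx = np.full(len(animals), "U", dtype=object)

    order = _topological_order(animals, sires, dams, by)
    animals_s = animals[order]
    idx = {lab: k + 1 for k, lab in enumerate(animals_s)}
    sire_i = np.array([0 if sires[o] is None else idx[sires[o]] for o in order], dtype=np.int64)
    dam_i = np.array([0 if dams[o] is None else idx[dams[o]] for o in order], dtype=np.int64)
    return Pedigree(
        labels=animals_s,
        sire=sire_i,
        dam=dam_i,
        birth_year=by[order],
        sex=sx[order],
        _index_of=idx,
    )


def _topological_order(animals, sires, dams, birth_year) -> np.ndarray:
    """Kahn topological sort; ties broken by birth year then input order."""
    n = len(animals)
    pos = {lab: k for k, lab in enumerate(animals)}
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for k in range(n):
        for p in (sires[k], dams[k]):
            if p is not None:
                children[pos[p]].append(k)
                indeg[k] += 1
    by = np.where(np.isnan(birth_year), np.inf, birth_year)
    import heapq

    heap = [(by[k], k) for k in range(n) if indeg[k] == 0]
    heapq.heapify(heap)
    out = []
    while heap:
        _, k = heapq.heappop(heap)
        out.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, (by[c], c))
    if len(out) < n:
        stuck = next(k for k in range(n) if indeg[k] > 0)
        raise PedigreeError(
            f"pedigree contains a cycle (animal {animals[stuck]!r} is its own ancestor)"
        )
    return np.array(out, dtype=np.int64)


@njit(cache=True)
def _meuwissen_luo(sire, dam):  # pragma: no cover - exercised through wrapper
    n = sire.shape[0] - 1
    F = np.zeros(n + 1)
    F[0] = -1.0
    L = np.zeros(n + 1)
    point = np.zeros(n + 1, dtype=np.int64)
    for i in range(1, n + 1):
        s = sire[i]
        d = dam[i]
        if s == 0 or d == 0:
            F[i] = 0.0
            continue
        Fi = -1.0
        L[i] = 1.0
        j = i
        while j != 0:
            k = j
            r = 0.5 * L[k]
            # insert the larger-indexed parent first: the list is kept in
            # descending order and the pointer only moves forward
            if sire[k] >= dam[k]:
                ks = sire[k]
                kd = dam[k]
            else:
                ks = dam[k]
                kd = sire[k]
            if ks > 0:
                while point[k] > ks:
                    k = point[k]
                L[ks] += r
                if ks != point[k]:
                    point[ks] = point[k]
                    point[k] = ks
                if kd > 0:
                    while point[k] > kd:
                        k = point[k]
                    L[kd] += r
                    if kd != point[k]:
                        point[kd] = point[k]
                        point[k] = kd
            dj = 0.5 - 0.25 * (F[sire[j]] + F[dam[j]])
            Fi += L[j] * L[j] * dj
            L[j] = 0.0
            nxt = point[j]
            point[j] = 0
            j = nxt
        F[i] = Fi
    return F[1:]


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen–Luo algorithm.

    Stores the result on ``ped.F`` and returns it.  Requires the pedigree to be
    topologically sorted (guaranteed by :func:`load_and_sort`).
    """
    _check_sorted(ped)
    sire = np.concatenate([[0], ped.sire]).astype(np.int64)
    dam = np.concatenate([[0], ped.dam]).astype(np.int64)
    F = _meuwissen_luo(sire, dam)
    ped.F = F
    return F


def _check_sorted(ped: Pedigree):
    ids = np.arange(1, ped.n + 1)
    if np.any(ped.sire >= ids) or np.any(ped.dam >= ids):
        raise PedigreeError("pedigree is not topologically sorted (parent index >= offspring)")


def mendelian_variance(ped: Pedigree) -> np.ndarray:
    """Mendelian-sampling variance d_x per animal.

    1 for founders, 0.75 - 0.25 F_p with one known parent, and
    0.5 - 0.25 (F_s + F_d) with both known.
    """
    if ped.F is None:
        compute_inbreeding(ped)
    Fx = np.concatenate([[-1.0], ped.F])
    return 0.5 - 0.25 * (Fx[ped.sire] + Fx[ped.dam])


def parent_matrix(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse P with 0.5 at (animal, known parent); zero diagonal; strictly lower triangular."""
    _check_sorted(ped)
    rows, cols, vals = [], [], []
    for i in range(ped.n):
        for p in (ped.sire[i], ped.dam[i]):
            if p > 0:
                rows.append(i)
                cols.append(p - 1)
                vals.append(0.5)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(ped.n, ped.n))


def a_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Inverse of the numerator relationship matrix A by Henderson's rules with inbreeding."""
    if ped.F is None:
        compute_inbreeding(ped)
    d = mendelian_variance(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(ped.n):
        alpha = 1.0 / d[i]
        add(i, i, alpha)
        for p in (ped.sire[i], ped.dam[i]):
            if p > 0:
                add(i, p - 1, -0.5 * alpha)
                add(p - 1, i, -0.5 * alpha)
        parents = [p - 1 for p in (ped.sire[i], ped.dam[i]) if p > 0]
        for a in parents:
            for b in parents:
                add(a, b, 0.25 * alpha)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(ped.n, ped.n))


@njit(cache=True)
def _tabular_a(sire, dam):  # pragma: no cover
    n = sire.shape[0] - 1
    A = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        s = sire[i]
        d = dam[i]
        A[i, i] = 1.0 + 0.5 * A[s, d]
        for j in range(1, i):
            v = 0.5 * (A[j, s] + A[j, d])
            A[j, i] = v
            A[i, j] = v
    return A[1:, 1:]


def tabular_a(ped: Pedigree) -> np.ndarray:
    """Dense A by the tabular method (row 0 / col 0 of the working array absorb unknowns)."""
    _check_sorted(ped)
    sire = np.concatenate([[0], ped.sire]).astype(np.int64)
    dam = np.concatenate([[0], ped.dam]).astype(np.int64)
    return _tabular_a(sire, dam)


def ancestors_of(ped: Pedigree, internal_ids) -> np.ndarray:
    """All internal indices that are in ``internal_ids`` or ancestral to them (sorted)."""
    keep = np.zeros(ped.n + 1, dtype=bool)
    stack = list(internal_ids)
    while stack:
        i = stack.pop()
        if i == 0 or keep[i]:
            continue
        keep[i] = True
        stack.append(ped.sire[i - 1])
        stack.append(ped.dam[i - 1])
    return np.nonzero(keep)[0]


def relationship_submatrix(ped: Pedigree, ids) -> np.ndarray:
    """Exact A restricted to ``ids`` (animal labels), via the tabular method on
    the ancestor-pruned pedigree."""
    internal = np.array([ped.index_of(lab) for lab in ids], dtype=np.int64)
    keep = ancestors_of(ped, internal)
    remap = np.zeros(ped.n + 1, dtype=np.int64)
    remap[keep] = np.arange(1, len(keep) + 1)
    sire = np.concatenate([[0], remap[ped.sire[keep - 1]]])
    dam = np.concatenate([[0], remap[ped.dam[keep - 1]]])
    A = _tabular_a(sire.astype(np.int64), dam.astype(np.int64))
    pos = remap[internal] - 1
    return A[np.ix_(pos, pos)]


def pedigree_depth(ped: Pedigree) -> np.ndarray:
    """Generation count per animal: 0 for founders, 1 + max(parent depths) otherwise.

    An approximate 'pedigree completeness' style statistic; no claim of
    equivalence with any particular software definition.
    """
    depth = np.zeros(ped.n)
    for i in range(ped.n):
        d = 0.0
        if ped.sire[i] > 0:
            d = max(d, depth[ped.sire[i] - 1] + 1)
        if ped.dam[i] > 0:
            d = max(d, depth[ped.dam[i] - 1] + 1)
        depth[i] = d
    return depth


#: bin edges used for the inbreeding distribution table: 0, (0,0.05], ..., >0.4
INBREEDING_BIN_EDGES = [0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40]


def inbreeding_bins(F: np.ndarray) -> pd.DataFrame:
    """Counts of animals per inbreeding-coefficient bin (first bin = exactly zero)."""
    eps = 1e-12
    rows = [("0", int(np.sum(F <= eps)))]
    edges = INBREEDING_BIN_EDGES
    for lo, hi in zip(edges[:-1], edges[1:]):
        rows.append((f"{lo:g}-{hi:g}", int(np.sum((F > lo + eps) & (F <= hi + eps)))))
    rows.append((f">{edges[-1]:g}", int(np.sum(F > edges[-1] + eps))))
    return pd.DataFrame(rows, columns=["bin", "n"])


def ped_stats(ped: Pedigree) -> dict:
    """Summary statistics: counts, % known parents, F mean/SD among inbred, depth."""
    if ped.F is None:
        compute_inbreeding(ped)
    F = ped.F
    inbred = F > 1e-12
    depth = pedigree_depth(ped)
    return {
        "n_animals": ped.n,
        "pct_known_sire": 100.0 * float(np.mean(ped.sire > 0)),
        "pct_known_dam": 100.0 * float(np.mean(ped.dam > 0)),
        "n_inbred": int(inbred.sum()),
        "mean_F_inbred": float(F[inbred].mean()) if inbred.any() else 0.0,
        "sd_F_inbred": float(F[inbred].std()) if inbred.any() else 0.0,
        "mean_F_all": float(F.mean()),
        "mean_depth": float(depth.mean()),
        "max_depth": float(depth.max()),
        "bins": inbreeding_bins(F),
    }
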