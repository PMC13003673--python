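"""Mendelian decomposition of inbreeding into per-ancestor partial coefficients.

An individual x is autozygous when its two gametic lineages coalesce in a
common ancestor of its parents; the partial inbreeding coefficient F_x^(j) is
the probability that the first (most recent) shared allele-copy node of the
two lineages resides in ancestor j.  It is computed exactly by a per-ancestor
tabular recursion over j's descendants:

    r_j(j, j)  = 1
    r_j(x, y)  = 0.5 (r_j(s_x, y) + r_j(d_x, y))        for descendants x, y != x
    r_j(x, x)  = 0.5 r_j(s_x, d_x)                      (no own-coalescence term:
                                                         coalescence at x is x's event)
    F_x^(j)    = 0.5 r_j(s_x, d_x)

The partials are nonnegative, vanish unless j is a common ancestor of x's
parents, and sum over j exactly to the Meuwissen-Luo inbreeding F_x (every
coalescence event is attributed to exactly one ancestor).

A gene-dropping Monte-Carlo oracle (uniquely labelled allele copies; an
autozygosity event is attributed to the animal holding the most recent shared
allele-copy node of the two lineages) provides an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

from .pedigree import Pedigree, compute_inbreeding


@dataclass
class PartialInbreedingTable:
    """Sparse table of partial inbreeding coefficients.

    ``individual`` and ``ancestor`` are 1-based internal pedigree indices;
    ``partial_F`` the coefficient F_x^(j).  ``n`` is the pedigree size.
    """

    individual: np.ndarray
    ancestor: np.ndarray
    partial_F: np.ndarray
    n: int

    def to_sparse(self) -> sparse.csr_matrix:
        """Matrix T with T[x-1, j-1] = F_x^(j) (n x n)."""
        return sparse.csr_matrix(
            (self.partial_F, (self.individual - 1, self.ancestor - 1)),
            shape=(self.n, self.n),
        )

    def row_sums(self) -> np.ndarray:
        """Per-individual total of partial coefficients (should equal F)."""
        out = np.zeros(self.n)
        np.add.at(out, self.individual - 1, self.partial_F)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "individual": self.individual,
                "ancestor": self.ancestor,
                "partial_F": self.partial_F,
            }
        )
        return df.sort_values(["individual", "ancestor"], kind="stable").reset_index(drop=True)


@njit(cache=True)
def _decompose(sire, dam, inbred_mask):  # pragma: no cover
    n = sire.shape[0] - 1
    t = np.zeros(n + 1)
    pos = np.full(n + 1, -1, dtype=np.int64)
    nodes = np.empty(n + 1, dtype=np.int64)
    r = np.zeros((n + 1, n + 1))
    cap = 4 * n + 16
    ind = np.empty(cap, dtype=np.int64)
    anc = np.empty(cap, dtype=np.int64)
    val = np.empty(cap)
    cnt = 0
    for j in range(1, n + 1):
        # gene-flow pass: descendants of j, and does any inbred animal have j
        # on both parental ancestries?
        t[:] = 0.0
        t[j] = 1.0
        useful = False
        for x in range(j + 1, n + 1):
            t[x] = 0.5 * (t[sire[x]] + t[dam[x]])
            if inbred_mask[x] and t[sire[x]] > 0.0 and t[dam[x]] > 0.0:
                useful = True
        if not useful:
            continue
        # compact index over {j} + descendants (ascending pedigree order)
        m = 0
        nodes[m] = j
        pos[j] = 0
        m = 1
        for x in range(j + 1, n + 1):
            if t[x] > 0.0:
                nodes[m] = x
                pos[x] = m
                m += 1
        # partial-coancestry tabular recursion
        r[0, 0] = 1.0
        for a in range(1, m):
            x = nodes[a]
            ps = pos[sire[x]] if sire[x] > 0 else -1
            pd = pos[dam[x]] if dam[x] > 0 else -1
            for b in range(a):
                v = 0.0
                if ps >= 0:
                    v += 0.5 * r[ps, b]
                if pd >= 0:
                    v += 0.5 * r[pd, b]
                r[a, b] = v
                r[b, a] = v
            if ps >= 0 and pd >= 0:
                r[a, a] = 0.5 * r[ps, pd]
            else:
                r[a, a] = 0.0
        # emit F_x^(j) = 0.5 r(s_x, d_x) for inbred descendants
        for a in range(1, m):
            x = nodes[a]
            if not inbred_mask[x]:
                continue
            ps = pos[sire[x]] if sire[x] > 0 else -1
            pd = pos[dam[x]] if dam[x] > 0 else -1
            if ps >= 0 and pd >= 0 and r[ps, pd] > 0.0:
                if cnt == cap:
                    cap *= 2
                    ind2 = np.empty(cap, dtype=np.int64)
                    anc2 = np.empty(cap, dtype=np.int64)
                    val2 = np.empty(cap)
                    ind2[:cnt] = ind
                    anc2[:cnt] = anc
                    val2[:cnt] = val
                    ind = ind2
                    anc = anc2
                    val = val2
                ind[cnt] = x
                anc[cnt] = j
                val[cnt] = 0.5 * r[ps, pd]
                cnt += 1
        # reset compact positions
        for a in range(m):
            pos[nodes[a]] = -1
    return ind[:cnt], anc[:cnt], val[:cnt]


def mendelian_decomposition(ped: Pedigree) -> PartialInbreedingTable:
    """Exact per-ancestor partial inbreeding coefficients for every inbred animal."""
    if ped.F is None:
        compute_inbreeding(ped)
    sire = np.concatenate([[0], ped.sire]).astype(np.int64)
    dam = np.concatenate([[0], ped.dam]).astype(np.int64)
    inbred_mask = np.zeros(ped.n + 1, dtype=np.bool_)
    inbred_mask[1:] = ped.F > 1e-14
    ind, anc, val = _decompose(sire, dam, inbred_mask)
    order = np.lexsort((anc, ind))
    return PartialInbreedingTable(
        individual=ind[order], ancestor=anc[order], partial_F=val[order], n=ped.n
    )


@njit(cache=True)
def _gene_drop(sire, dam, n_rep, seed):  # pragma: no cover
    np.random.seed(seed)
    n = sire.shape[0] - 1
    counts = np.zeros((n + 1, n + 1))
    par = np.zeros(2 * n + 1, dtype=np.int64)
    stamp = np.zeros(2 * n + 1, dtype=np.int64)
    tick = 0
    for _ in range(n_rep):
        for i in range(1, n + 1):
            s = sire[i]
            dm = dam[i]
            if s == 0:
                par[2 * i - 1] = 0
            else:
                par[2 * i - 1] = 2 * s - 1 + (1 if np.random.random() < 0.5 else 0)
            if dm == 0:
                par[2 * i] = 0
            else:
                par[2 * i] = 2 * dm - 1 + (1 if np.random.random() < 0.5 else 0)
        for i in range(1, n + 1):
            if sire[i] == 0 or dam[i] == 0:
                continue
            tick += 1
            cur = par[2 * i - 1]
            while cur != 0:
                stamp[cur] = tick
                cur = par[cur]
            cur = par[2 * i]
            while cur != 0:
                if stamp[cur] == tick:
                    owner = (cur + 1) // 2
                    counts[i, owner] += 1.0
                    break
                cur = par[cur]
    return counts


def gene_drop_oracle(ped: Pedigree, n_rep: int, seed: int) -> pd.DataFrame:
    """Monte-Carlo estimate of partial inbreeding coefficients by gene dropping.

    Returns a frame with one row per (individual, ancestor) pair observed in
    either the simulation or the exact decomposition, with the estimated
    frequency and its binomial standard error.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    sire = np.concatenate([[0], ped.sire]).astype(np.int64)
    dam = np.concatenate([[0], ped.dam]).astype(np.int64)
    counts = _gene_drop(sire, dam, int(n_rep), int(seed) % (2**31))
    exact = mendelian_decomposition(ped)
    pairs = {(int(i), int(j)) for i, j in zip(exact.individual, exact.ancestor)}
    obs = np.nonzero(counts)
    pairs.update((int(i), int(j)) for i, j in zip(*obs))
    rows = []
    for i, j in sorted(pairs):
        f = counts[i, j] / n_rep
        se = np.sqrt(max(f * (1 - f), 1.0 / n_rep) / n_rep)
        rows.append((i, j, f, se))
    return pd.DataFrame(rows, columns=["individual", "ancestor", "freq", "se"])


def build_K(
    table: PartialInbreedingTable,
    P: sparse.spmatrix,
    record_animals: np.ndarray,
) -> sparse.csr_matrix:
    """Incidence of record phenotypes on ancestral inbreeding loads: K = R T (I - P).

    ``record_animals`` holds the 1-based internal index of each record's animal.
    Rows of non-inbred animals are all zero.
    """
    n = table.n
    if P.shape != (n, n):
        raise ValueError(f"P has shape {P.shape}, expected {(n, n)}")
    record_animals = np.asarray(record_animals, dtype=np.int64)
    if record_animals.min(initial=1) < 1 or record_animals.max(initial=1) > n:
        raise ValueError("record_animals out of pedigree range")
    T = table.to_sparse()
    ImP = sparse.identity(n, format="csr") - P.tocsr()
    K_full = (T @ ImP).tocsr()
    R = sparse.csr_matrix(
        (np.ones(len(record_animals)), (np.arange(len(record_animals)), record_animals - 1)),
        shape=(len(record_animals), n),
    )
    return (R @ K_full).tocsr()


def ancestor_summary(table: PartialInbreedingTable, ped: Pedigree) -> dict:
    """Per-ancestor descendant counts, birth-year cohorts and global coefficient stats."""
    if len(table.partial_F) == 0:
        per = pd.DataFrame(columns=["ancestor", "n_individuals", "birth_year"])
    else:
        df = table.to_frame()
        per = (
            df.groupby("ancestor", as_index=False)
            .agg(n_individuals=("individual", "nunique"))
            .astype({"ancestor": int})
        )
        per["birth_year"] = ped.birth_year[per["ancestor"].to_numpy() - 1]
    vals = table.partial_F
    n_coef = len(vals)
    summary = {
        "per_ancestor": per,
        "n_coefficients": int(n_coef),
        "n_ancestors": int(per.shape[0]),
        "frac_below_0.001": float(np.mean(vals < 0.001)) if n_coef else 0.0,
        "frac_above_0.01": float(np.mean(vals > 0.01)) if n_coef else 0.0,
        "mean_coefficients_per_inbred": (
            float(n_coef / np.unique(table.individual).size) if n_coef else 0.0
        ),
    }
    if per.shape[0]:
        by = per.dropna(subset=["birth_year"])
        if len(by):
            summary["by_cohort"] = (
                by.assign(cohort=by["birth_year"].astype(int))
                .groupby("cohort", as_index=False)
                .agg(n_ancestors=("ancestor", "size"), mean_individuals=("n_individuals", "mean"))
            )
    return summary
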