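"""Phenotype filtering and design assembly for the inbreeding-load animal model.

The observation model is

    y = f d [+ t c] + X b + W h + Z u + K i [+ L p] + e

with f the animal's pedigree inbreeding, d the depression regression (phenotypic
change at F = 1), t the centred age at recording, b fixed effects, h random
herd-year-season effects, u additive genetic effects, i ancestral inbreeding
loads (incidence K = T(I - P)), p permanent environment for repeated records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .decomposition import PartialInbreedingTable, build_K
from .pedigree import Pedigree, compute_inbreeding, parent_matrix


def filter_outliers(records: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Remove records deviating more than 3 SD from the mean (single pass;
    mean and SD computed on the input set)."""
    y = records[value_col].to_numpy(float)
    if len(y) < 2:
        return records
    mu, sd = y.mean(), y.std()
    if sd == 0:
        return records
    keep = np.abs(y - mu) <= 3.0 * sd
    return records.loc[keep].reset_index(drop=True)


@dataclass
class ModelSpec:
    """Configuration of one trait's model."""

    trait: str
    fixed_factors: list[str] = field(default_factory=lambda: ["mean"])
    include_age_covariate: bool = False
    include_permanent_env: bool = False
    hys_col: str = "hys"
    age_col: str = "age"
    animal_col: str = "animal"
    value_col: str = "value"


@dataclass
class DesignBundle:
    """Everything the sampler needs, in record order."""

    y: np.ndarray
    f: np.ndarray  # total pedigree inbreeding per record
    t: np.ndarray | None  # centred age, or None
    fixed_codes: np.ndarray  # (n_records, n_factors) 0-based level codes
    fixed_levels: list[np.ndarray]  # level labels per factor
    hys_codes: np.ndarray  # 0-based
    n_hys: int
    animal_codes: np.ndarray  # 0-based pedigree index per record (Z)
    pe_codes: np.ndarray | None  # 0-based permanent-environment level, or None
    n_pe: int
    K: sparse.csr_matrix  # records x animals
    n_animals: int
    spec: ModelSpec
    record_labels: np.ndarray

    @property
    def n_records(self) -> int:
        return len(self.y)


def assemble_design(
    records: pd.DataFrame,
    spec: ModelSpec,
    ped: Pedigree,
    table: PartialInbreedingTable | None = None,
    K: sparse.spmatrix | None = None,
) -> DesignBundle:
    """Build the design bundle for one trait.

    ``records`` must contain ``spec.animal_col`` and ``spec.value_col``, a
    column per fixed factor (other than the implicit overall mean), the
    herd-year-season column and, if requested, the age column.  Either a
    partial-inbreeding table or a precomputed K (record x animal) is required.
    """
    if ped.F is None:
        compute_inbreeding(ped)
    animals = records[spec.animal_col].astype(str).to_numpy()
    animal_codes = np.array([ped.index_of(a) - 1 for a in animals], dtype=np.int64)
    y = records[spec.value_col].to_numpy(float)
    f = ped.F[animal_codes]

    t = None
    if spec.include_age_covariate:
        age = records[spec.age_col].to_numpy(float)
        t = age - age.mean()

    fixed_codes = []
    fixed_levels = []
    for fac in spec.fixed_factors:
        if fac == "mean":
            fixed_codes.append(np.zeros(len(y), dtype=np.int64))
            fixed_levels.append(np.array(["mean"], dtype=object))
        else:
            vals = records[fac].astype(str).to_numpy()
            levels, codes = np.unique(vals, return_inverse=True)
            fixed_codes.append(codes.astype(np.int64))
            fixed_levels.append(levels)
    fixed_codes = np.column_stack(fixed_codes) if fixed_codes else np.zeros((len(y), 0), np.int64)

    hys_vals = records[spec.hys_col].astype(str).to_numpy()
    hys_levels, hys_codes = np.unique(hys_vals, return_inverse=True)

    pe_codes, n_pe = None, 0
    if spec.include_permanent_env:
        pe_levels, pe_codes = np.unique(animals, return_inverse=True)
        pe_codes = pe_codes.astype(np.int64)
        n_pe = len(pe_levels)

    if K is None:
        if table is None:
            raise ValueError("provide either a PartialInbreedingTable or a precomputed K")
        K = build_K(table, parent_matrix(ped), animal_codes + 1)
    K = sparse.csr_matrix(K)
    if K.shape[0] != len(y):
        raise ValueError(f"K has {K.shape[0]} rows for {len(y)} records")

    return DesignBundle(
        y=y,
        f=f,
        t=t,
        fixed_codes=fixed_codes,
        fixed_levels=fixed_levels,
        hys_codes=hys_codes.astype(np.int64),
        n_hys=len(hys_levels),
        animal_codes=animal_codes,
        pe_codes=pe_codes,
        n_pe=n_pe,
        K=K,
        n_animals=ped.n,
        spec=spec,
        record_labels=animals,
    )
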