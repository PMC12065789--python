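"""Screening-space encoding and generalized subset designs.

The screen varies five reaction factors — magnesium glutamate, potassium
glutamate, PEG 8000, SecYE plasmid, and liposome lipid type — each
discretized to a small number of ordered levels.  Lipid type is ordered by
acyl-chain carbon count (DMPC 14 < DPPC 16 < DOPC 18) so that it behaves as
an ordinal factor like the chemical concentrations.

A generalized subset design (GSD) selects a balanced 1/``reduction``
fraction of the multilevel full factorial: each factor's ordered levels are
dealt round-robin into ``reduction`` interleaved groups, and a run is kept
iff the sum of its per-factor group indices is congruent to a fixed residue
modulo ``reduction``.  The ``reduction`` complementary residue classes
partition the full factorial.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LIPID_CARBONS",
    "Factor",
    "FactorGrid",
    "DesignMatrix",
    "encode_lipid",
    "full_factorial",
    "gsd",
    "default_grid",
    "randomize_wells",
]

#: Acyl-chain carbon counts of the supported phosphatidylcholine lipids.
LIPID_CARBONS = {"DMPC": 14, "DPPC": 16, "DOPC": 18}


def encode_lipid(name: str) -> float:
    """Min-max scaled carbon-tail encoding of a lipid type.

    DMPC (14 C) -> 0.0, DPPC (16 C) -> 0.5, DOPC (18 C) -> 1.0.
    """
    try:
        carbons = LIPID_CARBONS[name]
    except KeyError:
        raise ValueError(
            f"unknown lipid {name!r}; supported: {sorted(LIPID_CARBONS)}"
        ) from None
    lo, hi = min(LIPID_CARBONS.values()), max(LIPID_CARBONS.values())
    return (carbons - lo) / (hi - lo)


@dataclass(frozen=True)
class Factor:
    """One screening factor with its ordered physical levels."""

    name: str
    levels: tuple  # ordered physical values (numbers or lipid names)

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ValueError(f"factor {self.name!r} needs >= 2 levels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def encodings(self) -> np.ndarray:
        """Min-max scaled numeric encoding of the ordered levels in [0, 1]."""
        if all(isinstance(v, str) for v in self.levels):
            vals = np.array([LIPID_CARBONS[v] for v in self.levels], float)
        else:
            vals = np.asarray(self.levels, float)
        if np.any(np.diff(vals) <= 0):
            raise ValueError(f"factor {self.name!r} levels must be strictly increasing")
        return (vals - vals.min()) / (vals.max() - vals.min())


@dataclass(frozen=True)
class FactorGrid:
    """Ordered collection of screening factors."""

    factors: tuple

    def __post_init__(self):
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names")

    @property
    def names(self) -> list:
        return [f.name for f in self.factors]

    @property
    def shape(self) -> tuple:
        return tuple(f.n_levels for f in self.factors)

    @property
    def n_conditions(self) -> int:
        return int(np.prod(self.shape))

    def encode(self, index_rows: np.ndarray) -> np.ndarray:
        """Map level-index rows to min-max scaled numeric rows in [0, 1]."""
        index_rows = np.asarray(index_rows, int)
        cols = [f.encodings[index_rows[:, j]] for j, f in enumerate(self.factors)]
        return np.column_stack(cols)

    def to_frame(self, index_rows: np.ndarray) -> pd.DataFrame:
        """Design rows as a table of level indices plus physical values."""
        index_rows = np.asarray(index_rows, int)
        out = {}
        for j, f in enumerate(self.factors):
            out[f"{f.name}_idx"] = index_rows[:, j]
            out[f.name] = [f.levels[i] for i in index_rows[:, j]]
        return pd.DataFrame(out)


@dataclass(frozen=True)
class DesignMatrix:
    """Selected conditions as unique rows of per-factor level indices."""

    grid: FactorGrid
    rows: np.ndarray = field(repr=False)

    def __post_init__(self):
        rows = np.asarray(self.rows, int)
        object.__setattr__(self, "rows", rows)
        if rows.ndim != 2 or rows.shape[1] != len(self.grid.factors):
            raise ValueError("rows must be (n, n_factors)")
        if len({tuple(r) for r in rows}) != len(rows):
            raise ValueError("design rows must be unique")
        for j, f in enumerate(self.grid.factors):
            if rows[:, j].min() < 0 or rows[:, j].max() >= f.n_levels:
                raise ValueError(f"level index out of range for factor {f.name!r}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def encoded(self) -> np.ndarray:
        return self.grid.encode(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return self.grid.to_frame(self.rows)


def full_factorial(grid: FactorGrid) -> DesignMatrix:
    """All combinations of level indices (Cartesian product)."""
    rows = np.array(list(itertools.product(*[range(n) for n in grid.shape])), int)
    return DesignMatrix(grid, rows)


def gsd(grid: FactorGrid, reduction: int, residue: int = 0) -> DesignMatrix:
    """Generalized subset design: a balanced 1/reduction fraction.

    Level i of every factor is assigned to group ``i % reduction``; a run
    survives iff the sum of its group indices == ``residue`` (mod
    reduction).  With every level count divisible by ``reduction`` the
    subset has exactly ``full/reduction`` runs and perfect level balance,
    and the ``reduction`` residue classes partition the full factorial.
    """
    if reduction < 1:
        raise ValueError("reduction must be >= 1")
    for f in grid.factors:
        if reduction > f.n_levels:
            raise ValueError(
                f"reduction {reduction} exceeds level count of factor {f.name!r}"
            )
    if not 0 <= residue < reduction:
        raise ValueError("residue must be in [0, reduction)")
    full = full_factorial(grid).rows
    groups = full % reduction
    keep = groups.sum(axis=1) % reduction == residue
    return DesignMatrix(grid, full[keep])


def default_grid(n_levels: int = 3) -> FactorGrid:
    """Shipped default: 3 levels per factor.

    Physical values span the screened concentration ranges (mM for the
    salts, % w/v for PEG, relative plasmid dose for SecYE); lipid levels
    are ordered by carbon tail length.  The level counts that the original
    screen used to reach its 432-condition grid are a required input when
    reproducing that screen; they are not part of this default.
    """
    if n_levels != 3:
        raise NotImplementedError("default grid ships with 3 levels per factor")
    return FactorGrid(
        (
            Factor("Mg", (8.0, 12.0, 16.0)),
            Factor("K", (85.0, 135.0, 185.0)),
            Factor("PEG", (0.0, 1.0, 2.0)),
            Factor("SecYE", (0.0, 0.5, 1.0)),
            Factor("lipid", ("DMPC", "DPPC", "DOPC")),
        )
    )


def randomize_wells(design: DesignMatrix, seed: int) -> pd.DataFrame:
    """Seeded shuffle of condition-to-well assignment (provenance only)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(design))
    frame = design.to_frame()
    frame["well"] = np.argsort(order)
    return frame
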