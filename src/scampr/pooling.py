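"""Row/column superpool design for combinatorial pool deconvolution.

The screen's layout: plants are pooled 8 at a time (480 pools for 3840
plants), the pools are arrayed on a 20×24 grid, and PCR product from each
grid row and each grid column is combined into a superpool — 20 row + 24
column = 44 superpools.  A variant present in exactly one row and one
column superpool localizes to the single pool at their intersection, i.e.
to 8 candidate plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class Superpool:
    id: str
    axis: str                      # "row" | "col"
    member_pools: tuple[int, ...]


@dataclass(frozen=True)
class PoolDesign:
    n_plants: int
    pool_size: int
    n_rows: int
    n_cols: int
    plant_to_pool: dict[int, int]
    pool_to_cell: dict[int, tuple[int, int]]   # pool_id -> (row_idx, col_idx), 0-based
    superpools: tuple[Superpool, ...]
    seed: int | None = None

    @property
    def n_pools(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def superpool_ids(self) -> list[str]:
        return [sp.id for sp in self.superpools]

    def superpool(self, superpool_id: str) -> Superpool:
        for sp in self.superpools:
            if sp.id == superpool_id:
                return sp
        raise KeyError(f"unknown superpool {superpool_id!r}")

    def axis_of(self, superpool_id: str) -> str:
        return self.superpool(superpool_id).axis

    def pool_members(self, pool_id: int) -> frozenset[int]:
        if not 1 <= pool_id <= self.n_pools:
            raise KeyError(f"unknown pool {pool_id}")
        return frozenset(p for p, pool in self.plant_to_pool.items() if pool == pool_id)

    def cell_to_pool(self, row_idx: int, col_idx: int) -> int:
        for pool, cell in self.pool_to_cell.items():
            if cell == (row_idx, col_idx):
                return pool
        raise KeyError(f"no pool at cell ({row_idx}, {col_idx})")

    def superpools_of_pool(self, pool_id: int) -> tuple[str, str]:
        """(row superpool id, column superpool id) containing a pool."""
        r, c = self.pool_to_cell[pool_id]
        return f"R{r + 1:02d}", f"C{c + 1:02d}"

    def plants_per_superpool(self, axis: str) -> int:
        if axis == "row":
            return self.pool_size * self.n_cols
        if axis == "col":
            return self.pool_size * self.n_rows
        raise ValueError(f"axis must be row|col, got {axis!r}")


def build_design(n_plants: int = 3840, pool_size: int = 8,
                 n_rows: int = 20, n_cols: int = 24,
                 seed: int | None = None) -> PoolDesign:
    """Assign plants to pools and pools to the row/column superpool grid.

    Plants fill pools in contiguous blocks (plants 1–8 form pool 1) unless
    ``seed`` is given, in which case the plant order is a seeded shuffle.
    Pools fill the grid row-major: pool 1 is cell (0, 0).
    """
    for name, v in [("n_plants", n_plants), ("pool_size", pool_size),
                    ("n_rows", n_rows), ("n_cols", n_cols)]:
        if not (isinstance(v, (int, np.integer)) and v > 0):
            raise DesignError(f"{name} must be a positive integer, got {v!r}")
    expected = pool_size * n_rows * n_cols
    if n_plants != expected:
        raise DesignError(
            f"n_plants must equal pool_size × n_rows × n_cols: "
            f"expected {expected}, got {n_plants}")

    order = np.arange(1, n_plants + 1)
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    plant_to_pool = {int(plant): i // pool_size + 1 for i, plant in enumerate(order)}
    pool_to_cell = {p: ((p - 1) // n_cols, (p - 1) % n_cols)
                    for p in range(1, n_rows * n_cols + 1)}

    superpools = []
    for r in range(n_rows):
        pools = tuple(p for p, (pr, _) in pool_to_cell.items() if pr == r)
        superpools.append(Superpool(f"R{r + 1:02d}", "row", pools))
    for c in range(n_cols):
        pools = tuple(p for p, (_, pc) in pool_to_cell.items() if pc == c)
        superpools.append(Superpool(f"C{c + 1:02d}", "col", pools))

    return PoolDesign(n_plants=n_plants, pool_size=pool_size, n_rows=n_rows,
                      n_cols=n_cols, plant_to_pool=plant_to_pool,
                      pool_to_cell=pool_to_cell, superpools=tuple(superpools),
                      seed=seed)


def superpool_members(design: PoolDesign, superpool_id: str) -> frozenset[int]:
    """All plant ids whose pool belongs to the superpool."""
    sp = design.superpool(superpool_id)
    pools = set(sp.member_pools)
    return frozenset(p for p, pool in design.plant_to_pool.items() if pool in pools)


def expected_allele_fraction(design: PoolDesign, axis: str,
                             zygosity: str = "het") -> float:
    """Alternate-allele fraction contributed by one carrier to a superpool.

    A superpool of N diploid plants holds 2N allele copies; a heterozygote
    contributes 1, a homozygote 2.
    """
    n = design.plants_per_superpool(axis)
    if zygosity == "het":
        return 1.0 / (2 * n)
    if zygosity == "hom":
        return 1.0 / n
    raise ValueError(f"zygosity must be het|hom, got {zygosity!r}")


# -- serialization ---------------------------------------------------------

def design_frame(design: PoolDesign) -> pd.DataFrame:
    rows = []
    for plant in sorted(design.plant_to_pool):
        pool = design.plant_to_pool[plant]
        rsp, csp = design.superpools_of_pool(pool)
        rows.append((plant, pool, rsp, csp))
    return pd.DataFrame(rows, columns=["plant_id", "pool_id",
                                       "row_superpool", "col_superpool"])


def write_design(design: PoolDesign, path: str | Path) -> None:
    design_frame(design).to_csv(path, sep="\t", index=False)


def load_design(path: str | Path) -> PoolDesign:
    df = pd.read_csv(path, sep="\t")
    plant_to_pool = dict(zip(df.plant_id.astype(int), df.pool_id.astype(int)))
    n_rows = df.row_superpool.nunique()
    n_cols = df.col_superpool.nunique()
    pool_sizes = df.groupby("pool_id").size().unique()
    if len(pool_sizes) != 1:
        raise DesignError("pools are not all the same size")
    rebuilt = build_design(len(df), int(pool_sizes[0]), n_rows, n_cols)
    if rebuilt.plant_to_pool != plant_to_pool:
        rebuilt = PoolDesign(
            n_plants=rebuilt.n_plants, pool_size=rebuilt.pool_size,
            n_rows=n_rows, n_cols=n_cols, plant_to_pool=plant_to_pool,
            pool_to_cell=rebuilt.pool_to_cell, superpools=rebuilt.superpools)
    return rebuilt
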