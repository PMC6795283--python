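"""Row × column intersection decoding of superpool variant calls.

A variant carried by one plant appears in exactly one row superpool and one
column superpool; the intersection of those two superpools is a single
8-plant pool.  Variants are keyed by (position, ref, alt): two carriers of
the same change light up ≥2 rows and ≥2 columns and are reported
ambiguous — the honest limit of two-axis pooling — with the full cross
product of candidate pools for Sanger follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import pandas as pd

from .detect import VariantCall
from .pooling import PoolDesign

STATUSES = ("unique", "ambiguous", "row_only", "col_only")


class ConsistencyError(ValueError):
    pass


@dataclass(frozen=True)
class DecodedHit:
    position: int
    ref: str
    alt: str
    row_superpools: frozenset[str]
    col_superpools: frozenset[str]
    candidate_pools: frozenset[int]
    candidate_plants: frozenset[int]
    status: str


def _group_calls(calls: list[VariantCall], design: PoolDesign,
                 require_significant: bool):
    axes = {sp.id: sp.axis for sp in design.superpools}
    groups: dict[tuple[int, str, str], tuple[set, set]] = {}
    for c in calls:
        if require_significant and not c.significant:
            continue
        if c.superpool_id not in axes:
            raise ConsistencyError(f"call names unknown superpool {c.superpool_id!r}")
        rows, cols = groups.setdefault((c.position, c.ref, c.alt), (set(), set()))
        (rows if axes[c.superpool_id] == "row" else cols).add(c.superpool_id)
    return groups


def _status(rows: set[str], cols: set[str]) -> str:
    if rows and not cols:
        return "row_only"
    if cols and not rows:
        return "col_only"
    if len(rows) == 1 and len(cols) == 1:
        return "unique"
    return "ambiguous"


def _finish(key, rows, cols, pools, design) -> DecodedHit:
    pos, ref, alt = key
    plants = frozenset(p for p, pool in design.plant_to_pool.items()
                       if pool in pools)
    return DecodedHit(pos, ref, alt, frozenset(rows), frozenset(cols),
                      frozenset(pools), plants, _status(rows, cols))


def deconvolve(calls: list[VariantCall], design: PoolDesign,
               require_significant: bool = True) -> list[DecodedHit]:
    """Resolve calls to candidate pools by exact row × column intersection."""
    hits = []
    for key, (rows, cols) in sorted(_group_calls(
            calls, design, require_significant).items()):
        pools = set()
        for r, c in product(rows, cols):
            r_idx = int(r[1:]) - 1
            c_idx = int(c[1:]) - 1
            pools.add(design.cell_to_pool(r_idx, c_idx))
        hits.append(_finish(key, rows, cols, pools, design))
    return hits


def brute_force_decode(calls: list[VariantCall], design: PoolDesign,
                       require_significant: bool = True) -> list[DecodedHit]:
    """Independent oracle: enumerate every pool and keep those whose row and
    column superpools both carry the call.  Small designs only."""
    hits = []
    for key, (rows, cols) in sorted(_group_calls(
            calls, design, require_significant).items()):
        pools = set()
        for pool in range(1, design.n_pools + 1):
            rsp, csp = design.superpools_of_pool(pool)
            if rsp in rows and csp in cols:
                pools.add(pool)
        hits.append(_finish(key, rows, cols, pools, design))
    return hits


# -- reporting -------------------------------------------------------------

def summarize_screen(hits: list[DecodedHit], design: PoolDesign,
                     effects: dict[tuple[int, str], object] | None = None,
                     outdir: str | Path | None = None) -> tuple[pd.DataFrame, str]:
    """Tabulate decoded hits with optional effect annotations.

    Returns (table, human-readable summary); when ``outdir`` is given the
    table is written as decode_report.tsv and the summary as summary.txt.
    Ambiguous hits are flagged for Sanger sequencing of individuals from
    every candidate pool.
    """
    effects = effects or {}
    rows = []
    for h in sorted(hits, key=lambda h: (h.position, h.alt)):
        eff = effects.get((h.position, h.alt))
        rows.append({
            "position": h.position, "ref": h.ref, "alt": h.alt,
            "status": h.status,
            "row_ids": ",".join(sorted(h.row_superpools)) or ".",
            "col_ids": ",".join(sorted(h.col_superpools)) or ".",
            "pool_ids": ",".join(map(str, sorted(h.candidate_pools))) or ".",
            "plant_ids": ",".join(map(str, sorted(h.candidate_plants))) or ".",
            "effect": getattr(eff, "effect_class", "."),
            "aa_change": _aa_change(eff),
            "motif_offset": getattr(eff, "motif_offset", None) or ".",
        })
    table = pd.DataFrame(rows, columns=[
        "position", "ref", "alt", "status", "row_ids", "col_ids",
        "pool_ids", "plant_ids", "effect", "aa_change", "motif_offset"])

    by_status = {s: sum(h.status == s for h in hits) for s in STATUSES}
    lines = [f"Screen summary: {len(hits)} decoded candidate(s) "
             f"across {design.n_pools} pools "
             f"({design.n_rows}x{design.n_cols} grid, "
             f"pool size {design.pool_size}).",
             "Counts by status: " + ", ".join(
                 f"{s}={n}" for s, n in by_status.items())]
    if not hits:
        lines.append("0 candidates; no follow-up required.")
    for h in sorted(hits, key=lambda h: (h.position, h.alt)):
        eff = effects.get((h.position, h.alt))
        desc = (f"  pos {h.position} {h.ref}>{h.alt} [{h.status}] -> "
                f"pools {sorted(h.candidate_pools) or 'none'}, "
                f"{len(h.candidate_plants)} candidate plant(s)")
        if eff is not None:
            desc += f"; {getattr(eff, 'effect_class', '?')} {_aa_change(eff)}"
        lines.append(desc)
        if h.status == "ambiguous":
            lines.append("    ambiguous: Sanger-sequence individuals from "
                         "ALL candidate pools to disambiguate.")
        elif h.status in ("row_only", "col_only"):
            lines.append("    single-axis signal: no intersection; confirm "
                         "by Sanger across the positive superpool or rerun.")
        elif h.status == "unique":
            lines.append("    unique: Sanger-sequence the "
                         f"{design.pool_size} individuals of pool "
                         f"{min(h.candidate_pools)} to identify the carrier.")
    text = "\n".join(lines) + "\n"

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "decode_report.tsv", sep="\t", index=False)
        (outdir / "summary.txt").write_text(text)
    return table, text


def _aa_change(eff) -> str:
    if eff is None or getattr(eff, "ref_aa", None) is None:
        return "."
    return f"{eff.ref_aa}{eff.codon_index}{eff.alt_aa}"
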