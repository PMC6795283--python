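"""Per-superpool amplicon sequencing simulator.

Sequencing is abstracted to base-count pileups over the amplicon: coverage
at each position is Poisson(depth) and each read base is drawn from the
superpool's true allele mix with a symmetric substitution error — a read
sampling allele a shows base b with probability (1−e) if b = a, else e/3.
Mapping, trimming and demultiplexing are out of scope; FASTQ emission
exists so the pipeline can also be exercised from raw reads at reduced
depth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fixture import GeneModel
from .pooling import PoolDesign, superpool_members
from .population import Population

log = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SequencingModel:
    """Mean per-position coverage per superpool, substitution error rate,
    and (FASTQ mode) read length.

    The study's achieved per-superpool depth is not printed; the default of
    1e5 is what one HiSeq single-end lane spread over 44 indexed superpools
    × 1.1 kb supports, and every depth-dependent quantity here is exposed as
    a function of this parameter.
    """

    depth: float = 1e5
    error_rate: float = 1e-3
    read_length: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ValueError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if self.depth <= 0:
            raise ValueError(f"depth must be positive, got {self.depth}")


@dataclass
class PileupCounts:
    superpool_id: str
    positions: np.ndarray       # genomic, 1-based, ascending
    refs: np.ndarray            # reference base per position
    counts: np.ndarray          # (n_positions, 4) ints, columns A,C,G,T

    @property
    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __eq__(self, other) -> bool:
        return (isinstance(other, PileupCounts)
                and self.superpool_id == other.superpool_id
                and np.array_equal(self.positions, other.positions)
                and np.array_equal(self.refs, other.refs)
                and np.array_equal(self.counts, other.counts))


def _allele_fractions(design: PoolDesign, population: Population,
                      gene: GeneModel, superpool_id: str) -> np.ndarray:
    """(L, 4) matrix of true allele fractions in one superpool."""
    a0, a1 = gene.amplicon
    L = a1 - a0 + 1
    members = superpool_members(design, superpool_id)
    n_copies = 2 * len(members)
    frac = np.zeros((L, 4))
    ref_idx = np.array([BASE_INDEX[gene.base_at(p)] for p in range(a0, a1 + 1)])
    frac[np.arange(L), ref_idx] = 1.0
    for m in population.mutations:
        if not a0 <= m.position <= a1:
            log.warning("mutation at %d outside amplicon [%d, %d]; skipped",
                        m.position, a0, a1)
            continue
        if m.plant_id not in members:
            continue
        i = m.position - a0
        w = m.dosage / n_copies
        frac[i, BASE_INDEX[m.alt]] += w
        frac[i, BASE_INDEX[m.ref]] -= w
    return frac


def _observation_probs(frac: np.ndarray, e: float) -> np.ndarray:
    """Map true allele fractions to observed base probabilities under the
    symmetric substitution-error channel."""
    return frac * (1 - e) + (1 - frac) * (e / 3)


def simulate_pileup(design: PoolDesign, population: Population,
                    gene: GeneModel, model: SequencingModel) -> list[PileupCounts]:
    """Simulate base counts for every superpool over the amplicon."""
    population.validate(gene=gene)
    a0, a1 = gene.amplicon
    positions = np.arange(a0, a1 + 1)
    refs = np.array([gene.base_at(p) for p in positions])
    seeds = np.random.SeedSequence(model.seed).spawn(len(design.superpools))
    pileups = []
    for sp, ss in zip(design.superpools, seeds):
        rng = np.random.default_rng(ss)
        frac = _allele_fractions(design, population, gene, sp.id)
        probs = _observation_probs(frac, model.error_rate)
        cov = rng.poisson(model.depth, size=len(positions))
        counts = rng.multinomial(cov, probs)
        pileups.append(PileupCounts(sp.id, positions, refs, counts))
    return pileups


# -- FASTQ mode ------------------------------------------------------------

def _quality_char(e: float) -> str:
    q = 40 if e <= 0 else min(40, max(2, round(-10 * math.log10(e))))
    return chr(q + 33)


def emit_fastq(design: PoolDesign, population: Population, gene: GeneModel,
               model: SequencingModel, path: str | Path) -> list[PileupCounts]:
    """Write single-end reads tiled across the amplicon and return the
    pileup counted from those same reads.

    Per superpool, a deterministic tiling pass guarantees every amplicon
    position is covered at least once; the remaining reads start uniformly
    at random.  Each read samples one chromosome of one member plant, so
    allele fractions follow the pool composition; substitution errors are
    applied per base at the model's rate.  Intended for reduced depth —
    read count scales as depth × amplicon / read_length.
    """
    population.validate(gene=gene)
    a0, a1 = gene.amplicon
    L = a1 - a0 + 1
    rl = min(model.read_length, L)
    amplicon_seq = gene.genomic_seq[a0 - 1:a1]
    qual = _quality_char(model.error_rate) * rl
    seeds = np.random.SeedSequence(model.seed).spawn(len(design.superpools))
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)

    # per-plant haplotype edits: plant -> list of (offset, alt, dosage)
    edits: dict[int, list[tuple[int, str, int]]] = {}
    for m in population.mutations:
        if a0 <= m.position <= a1:
            edits.setdefault(m.plant_id, []).append(
                (m.position - a0, m.alt, m.dosage))

    path = Path(path)
    pileups = []
    with path.open("w") as fh:
        for sp, ss in zip(design.superpools, seeds):
            rng = np.random.default_rng(ss)
            members = sorted(superpool_members(design, sp.id))
            n_reads = max(1, round(model.depth * L / rl))
            tile_starts = list(range(0, L - rl + 1, rl))
            if tile_starts[-1] != L - rl:
                tile_starts.append(L - rl)
            extra = max(0, n_reads - len(tile_starts))
            starts = np.concatenate([
                np.array(tile_starts, dtype=int),
                rng.integers(0, L - rl + 1, size=extra)])
            counts = np.zeros((L, 4), dtype=int)
            for ridx, start in enumerate(starts):
                plant = members[rng.integers(len(members))]
                hap = rng.integers(2)   # which chromosome
                read = list(amplicon_seq[start:start + rl])
                for off, alt, dosage in edits.get(plant, ()):
                    if start <= off < start + rl and (dosage == 2 or hap == 0):
                        read[off - start] = alt
                if model.error_rate > 0:
                    err = np.nonzero(rng.random(rl) < model.error_rate)[0]
                    for i in err:
                        choices = [b for b in BASES if b != read[i]]
                        read[i] = choices[rng.integers(3)]
                read_str = "".join(read)
                fh.write(f"@{sp.id}:{ridx} sp={sp.id} start={int(start) + a0}\n"
                         f"{read_str}\n+\n{qual}\n")
                idx = np.frombuffer(read_str.encode(), dtype=np.uint8)
                for b in range(4):
                    sel = np.nonzero(idx == base_arr[b])[0]
                    np.add.at(counts[:, b], sel + start, 1)
            positions = np.arange(a0, a1 + 1)
            refs = np.frombuffer(amplicon_seq.encode(), dtype="S1").astype(str)
            pileups.append(PileupCounts(sp.id, positions, refs, counts))
    return pileups


def pileup_from_fastq(path: str | Path, gene: GeneModel) -> list[PileupCounts]:
    """Recount base pileups from a FASTQ written by :func:`emit_fastq`."""
    a0, a1 = gene.amplicon
    L = a1 - a0 + 1
    per_sp: dict[str, np.ndarray] = {}
    with Path(path).open() as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            fields = dict(tok.split("=", 1) for tok in header.split()[1:])
            sp, start = fields["sp"], int(fields["start"]) - a0
            counts = per_sp.setdefault(sp, np.zeros((L, 4), dtype=int))
            for i, b in enumerate(seq):
                counts[start + i, BASE_INDEX[b]] += 1
    positions = np.arange(a0, a1 + 1)
    refs = np.array([gene.base_at(p) for p in positions])
    return [PileupCounts(sp, positions, refs, counts)
            for sp, counts in sorted(per_sp.items())]


# -- serialization ---------------------------------------------------------

_SCHEMA = ["superpool_id", "position", "ref",
           "count_A", "count_C", "count_G", "count_T"]


class PileupParseError(ValueError):
    pass


def write_counts(pileups: list[PileupCounts], path: str | Path) -> None:
    frames = []
    for p in pileups:
        frames.append(pd.DataFrame({
            "superpool_id": p.superpool_id, "position": p.positions,
            "ref": p.refs,
            "count_A": p.counts[:, 0], "count_C": p.counts[:, 1],
            "count_G": p.counts[:, 2], "count_T": p.counts[:, 3]}))
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def load_counts(path: str | Path) -> list[PileupCounts]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"ref": str})
    except Exception as exc:
        raise PileupParseError(f"{path}: unreadable TSV: {exc}") from exc
    missing = [c for c in _SCHEMA if c not in df.columns]
    if missing:
        raise PileupParseError(f"{path}: missing columns {missing}")
    count_cols = ["count_A", "count_C", "count_G", "count_T"]
    for col in ["position"] + count_cols:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise PileupParseError(
                f"{path}: non-numeric {col} at line {int(bad[0]) + 2}")
    neg = df.index[(df[count_cols] < 0).any(axis=1)]
    if len(neg):
        raise PileupParseError(f"{path}: negative count at line {int(neg[0]) + 2}")
    pileups = []
    for sp, grp in df.groupby("superpool_id", sort=True):
        grp = grp.sort_values("position")
        pileups.append(PileupCounts(
            str(sp), grp.position.to_numpy(int),
            grp.ref.to_numpy(str), grp[count_cols].to_numpy(int)))
    return pileups
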