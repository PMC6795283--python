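"""Protein-level consequences of decoded hits and conservation context.

Covers exon-aware codon effect annotation (missense / nonsense /
synonymous / noncoding / splice-adjacent), exhaustive enumeration of the
codon substitutions reachable by EMS transitions, and frequency-
proportional sequence logos over a multiple alignment of CESA catalytic
regions.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import AlignIO
from Bio.Seq import Seq

from .fixture import MOTIF_NAME, GeneModel

GAP_CHARS = set("-.")
VALID_BASES = set("ACGT")
EFFECT_CLASSES = ("missense", "nonsense", "synonymous", "noncoding",
                  "splice_adjacent")


@dataclass(frozen=True)
class Effect:
    genomic_position: int
    cds_position: int | None
    codon_index: int | None        # protein position, 1-based
    ref_codon: str | None
    alt_codon: str | None
    ref_aa: str | None
    alt_aa: str | None
    effect_class: str
    motif_offset: int | None       # residues downstream of QXXRW's last residue


def annotate_effect(gene: GeneModel, position: int, alt: str) -> Effect:
    """Exon-aware annotation of a single-base substitution.

    Intronic positions are ``noncoding``; within 2 bp of an exon boundary
    they are ``splice_adjacent``.  ``motif_offset`` is filled when the
    affected codon lies downstream of the anchored QXXRW motif.
    """
    if not 1 <= position <= len(gene.genomic_seq):
        raise IndexError(f"position {position} outside gene span")
    if alt not in VALID_BASES:
        raise ValueError(f"invalid alternate base {alt!r}")
    if alt == gene.base_at(position):
        raise ValueError(f"alt equals reference base at {position}")

    cds_pos = gene.genomic_to_cds(position)
    if cds_pos is None:
        klass = ("splice_adjacent"
                 if gene.distance_to_exon_boundary(position) <= 2 else "noncoding")
        return Effect(position, None, None, None, None, None, None, klass, None)

    cds = gene.cds_sequence()
    codon_index = math.ceil(cds_pos / 3)
    codon_start = 3 * (codon_index - 1)
    ref_codon = cds[codon_start:codon_start + 3]
    within = cds_pos - codon_start - 1
    alt_base = alt if gene.strand == "+" else str(Seq(alt).complement())
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*":
        klass = "nonsense"
    elif alt_aa == ref_aa:
        klass = "synonymous"
    else:
        klass = "missense"

    offset = None
    anchor = gene.motif_anchors.get(MOTIF_NAME)
    if anchor is not None:
        motif_end = anchor + 4
        if codon_index > motif_end:
            offset = codon_index - motif_end
    return Effect(position, cds_pos, codon_index, ref_codon, alt_codon,
                  ref_aa, alt_aa, klass, offset)


def ems_reachable_substitutions(codon: str) -> set[tuple[str, str, str]]:
    """All codons reachable by one EMS transition (G→A or C→T), with the
    resulting amino acid and effect class.  Complete and duplicate-free."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in VALID_BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    ref_aa = str(Seq(codon).translate())
    out = set()
    for i, base in enumerate(codon):
        alt = {"G": "A", "C": "T"}.get(base)
        if alt is None:
            continue
        alt_codon = codon[:i] + alt + codon[i + 1:]
        alt_aa = str(Seq(alt_codon).translate())
        klass = ("nonsense" if alt_aa == "*"
                 else "synonymous" if alt_aa == ref_aa else "missense")
        out.add((alt_codon, alt_aa, klass))
    return out


# -- conservation / sequence logo -----------------------------------------

@dataclass(frozen=True)
class LogoColumn:
    column_index: int                       # 1-based alignment column
    residue_frequencies: dict[str, float]   # over non-gap characters
    letter_heights: dict[str, float]


def compute_logo(alignment: list[str], mode: str = "frequency") -> list[LogoColumn]:
    """Per-column residue frequencies over non-gap characters.

    ``mode="frequency"`` makes letter heights equal the frequencies (the
    logo convention where total column height is the conservation
    fraction); ``mode="information"`` scales by Shannon information
    content for comparison with standard logo tools.
    """
    if len(alignment) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    lengths = {len(s) for s in alignment}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    if mode not in ("frequency", "information"):
        raise ValueError(f"mode must be frequency|information, got {mode!r}")
    ncol = lengths.pop()
    columns = []
    for j in range(ncol):
        residues = [s[j].upper() for s in alignment if s[j] not in GAP_CHARS]
        freqs: dict[str, float] = {}
        for r in residues:
            freqs[r] = freqs.get(r, 0.0) + 1.0
        total = sum(freqs.values())
        freqs = {r: v / total for r, v in sorted(freqs.items())}
        if not freqs:
            heights = {}
        elif mode == "frequency":
            heights = dict(freqs)
        else:
            entropy = -sum(f * math.log2(f) for f in freqs.values())
            ic = math.log2(20) - entropy
            heights = {r: f * ic for r, f in freqs.items()}
        columns.append(LogoColumn(j + 1, freqs, heights))
    return columns


def conservation_at(alignment: list[str], column_index: int, residue: str) -> float:
    """Frequency of ``residue`` among non-gap characters at a 1-based column."""
    if not alignment:
        raise IndexError("empty alignment")
    if not 1 <= column_index <= len(alignment[0]):
        raise IndexError(f"column {column_index} out of range")
    residues = [s[column_index - 1].upper() for s in alignment
                if s[column_index - 1] not in GAP_CHARS]
    if not residues:
        return 0.0
    return residues.count(residue.upper()) / len(residues)


_MOTIF_RE = re.compile(r"E[KR].FG.S")


def conserved_serine_column(alignment: list[str], row: int = 0) -> int:
    """1-based alignment column of the motif serine of E(K/R)xFGxS.

    The motif is located in the ungapped sequence of ``row`` (default: the
    first record, the screened isoform) and the column of its final serine
    is mapped back through the gaps.
    """
    seq = alignment[row]
    ungapped = "".join(c for c in seq if c not in GAP_CHARS)
    m = _MOTIF_RE.search(ungapped)
    if m is None:
        raise ValueError("E(K/R)xFGxS motif not found")
    target = m.end()  # 1-based ungapped position of the serine
    count = 0
    for j, c in enumerate(seq, start=1):
        if c not in GAP_CHARS:
            count += 1
            if count == target:
                return j
    raise AssertionError("unreachable")


# -- alignment IO ----------------------------------------------------------

def load_alignment(path: str | Path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA (or 'name sequence' text block).

    Returns (names, sequences).
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        aln = AlignIO.read(str(path), "fasta")
        return [r.id for r in aln], [str(r.seq) for r in aln]
    names, seqs = [], []
    for line in text.splitlines():
        if not line.strip():
            continue
        name, seq = line.split(None, 1)
        names.append(name)
        seqs.append(seq.strip())
    return names, seqs


def bdcesa_alignment() -> tuple[list[str], list[str]]:
    """The packaged 7-isoform BdCESA catalytic-region alignment
    (the published block containing the conserved E(K/R)xFGxS region)."""
    ref = resources.files("scampr").joinpath("data/bdcesa_catalytic_region.fasta")
    with resources.as_file(ref) as path:
        return load_alignment(path)


def logo_frame(columns: list[LogoColumn]) -> pd.DataFrame:
    rows = [(c.column_index, r, c.residue_frequencies[r], c.letter_heights[r])
            for c in columns for r in c.residue_frequencies]
    return pd.DataFrame(rows, columns=["column", "residue", "frequency", "height"])


def write_logo_tsv(columns: list[LogoColumn], path: str | Path) -> None:
    logo_frame(columns).to_csv(path, sep="\t", index=False)


def plot_logo(columns: list[LogoColumn], path: str | Path | None = None,
              highlight: int | None = None):
    """Draw a simple stacked-letter logo with matplotlib.

    Letters in each column are stacked by height (most frequent on top);
    ``highlight`` marks a 1-based column (e.g. the mutated residue) with
    an asterisk.  Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(columns) * 0.22), 2.5))
    for col in columns:
        y = 0.0
        for res, h in sorted(col.letter_heights.items(), key=lambda kv: kv[1]):
            if h <= 0:
                continue
            ax.text(col.column_index, y + h / 2, res, ha="center", va="center",
                    fontsize=6 + 10 * h, family="monospace")
            y += h
    if highlight is not None:
        top = max((sum(c.letter_heights.values()) for c in columns), default=1.0)
        ax.text(highlight, top * 1.05, "*", ha="center", fontsize=14)
    ax.set_xlim(0, len(columns) + 1)
    ax.set_ylim(0, 1.15 * max(
        (sum(c.letter_heights.values()) for c in columns), default=1.0))
    ax.set_xlabel("alignment column")
    ax.set_ylabel("height")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
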