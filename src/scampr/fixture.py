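"""Synthetic gene-model fixture shaped like the BdCESA1 TILLING target.

No nucleotide sequence for the screened gene was ever deposited, so the
fixture is constructed, not parsed.  It is nonetheless pinned to the printed
facts about the target: a 1096-bp amplicon; a serine at protein position 830
sitting 10 residues downstream of the last residue of the QXXRW
glycosyltransferase motif; the local protein context LEKRFGQSPIFTA around
that serine (the BdCESA1 row of the published catalytic-region alignment);
and the serine encoded by AGC, the one serine codon from which a single
EMS-type transition (G→A at the middle base) yields asparagine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.Data.CodonTable import unambiguous_dna_by_id

PROTEIN_LEN = 1040
MOTIF_NAME = "QXXRW"
MOTIF_START = 816          # protein position of Q (1-based)
SER_POSITION = 830         # conserved serine, 10 aa past W at 820
LOCAL_CONTEXT = "LEKRFGQSPIFTA"   # published BdCESA1 residues 823-835
SER_CODON = "AGC"
AMPLICON_LEN = 1096

_STANDARD_TABLE = unambiguous_dna_by_id[1]
# codons per amino acid, stop codons excluded
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in _STANDARD_TABLE.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _v in _CODONS_BY_AA.values():
    _v.sort()

_AA_ALPHABET = sorted(_CODONS_BY_AA)


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure, CDS/protein, motif anchors and an amplicon.

    Coordinates are 1-based inclusive genomic positions (GFF3/VCF
    convention).  ``exons`` are ordered, non-overlapping, and their
    concatenation is the CDS; ``motif_anchors`` maps a motif name to the
    protein position of its first residue.
    """

    name: str
    genomic_seq: str
    exons: tuple[tuple[int, int], ...]
    strand: str
    amplicon: tuple[int, int]
    protein_seq: str
    motif_anchors: dict[str, int] = field(default_factory=dict)

    # -- derived sequence views -------------------------------------------

    def cds_sequence(self) -> str:
        """Concatenated exonic sequence, reverse-complemented on '-'."""
        spliced = "".join(self.genomic_seq[s - 1:e] for s, e in self.exons)
        if self.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        return spliced

    @property
    def amplicon_length(self) -> int:
        return self.amplicon[1] - self.amplicon[0] + 1

    def base_at(self, position: int) -> str:
        return self.genomic_seq[position - 1]

    # -- coordinate mapping ------------------------------------------------

    def genomic_to_cds(self, position: int) -> int | None:
        """Map a genomic position to a 1-based CDS position, None in introns."""
        offset = 0
        for s, e in self.exons:
            if s <= position <= e:
                fwd = offset + (position - s) + 1
                if self.strand == "-":
                    return len(self.cds_sequence()) - fwd + 1
                return fwd
            offset += e - s + 1
        return None

    def cds_to_genomic(self, cds_position: int) -> int:
        pos = cds_position
        if self.strand == "-":
            pos = len(self.cds_sequence()) - cds_position + 1
        offset = 0
        for s, e in self.exons:
            length = e - s + 1
            if pos <= offset + length:
                return s + (pos - offset - 1)
            offset += length
        raise IndexError(f"CDS position {cds_position} outside CDS")

    def distance_to_exon_boundary(self, position: int) -> int:
        """Smallest distance from an intronic position to an exon edge."""
        best = math.inf
        for s, e in self.exons:
            best = min(best, abs(position - s), abs(position - e))
        return int(best)

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        prev_end = 0
        for s, e in self.exons:
            if not (prev_end < s <= e <= len(self.genomic_seq)):
                raise ValueError(f"exon ({s},{e}) out of order or out of range")
            prev_end = e
        cds = self.cds_sequence()
        if len(cds) % 3:
            raise ValueError("CDS length not divisible by 3")
        if str(Seq(cds).translate()) != self.protein_seq:
            raise ValueError("CDS translation does not match protein_seq")
        a0, a1 = self.amplicon
        if not (1 <= a0 <= a1 <= len(self.genomic_seq)):
            raise ValueError("amplicon outside gene span")
        anchor = self.motif_anchors.get(MOTIF_NAME)
        if anchor is None:
            raise ValueError("QXXRW anchor missing")
        window = self.protein_seq[anchor - 1:anchor + 4]
        if not (len(window) == 5 and window[0] == "Q"
                and window[3] == "R" and window[4] == "W"):
            raise ValueError(f"QXXRW not found at anchored position {anchor}")


def build_gene_fixture(seed: int = 1, name: str = "BdCESA1_fixture") -> GeneModel:
    """Construct the deterministic BdCESA1-like fixture for a seed.

    The random portions (filler residues, synonymous codon choice, intron
    sequence and lengths) are drawn from ``seed``; the constrained portions
    (motif placement, serine-830 AGC codon, local alignment context,
    amplicon width) are fixed.
    """
    rng = np.random.default_rng(seed)

    protein = list(rng.choice(_AA_ALPHABET, size=PROTEIN_LEN))
    protein[0] = "M"
    motif = ["Q", str(rng.choice(_AA_ALPHABET)), str(rng.choice(_AA_ALPHABET)), "R", "W"]
    protein[MOTIF_START - 1:MOTIF_START + 4] = motif
    ctx_start = SER_POSITION - LOCAL_CONTEXT.index("S", 6)  # 823, 1-based
    protein[ctx_start - 1:ctx_start - 1 + len(LOCAL_CONTEXT)] = list(LOCAL_CONTEXT)
    protein_seq = "".join(protein)
    assert protein_seq[SER_POSITION - 1] == "S"

    codons = [str(rng.choice(_CODONS_BY_AA[aa])) for aa in protein_seq]
    codons[SER_POSITION - 1] = SER_CODON
    cds = "".join(codons)

    # split the CDS into 5 exons; codon 830 sits in the fourth
    splits = [600, 1300, 2100, 2800]
    pieces, prev = [], 0
    for cut in splits + [len(cds)]:
        pieces.append(cds[prev:cut])
        prev = cut
    intron_lens = rng.integers(120, 281, size=len(splits))
    bases = np.array(list("ACGT"))
    introns = ["GT" + "".join(rng.choice(bases, size=n - 4)) + "AG"
               for n in intron_lens]

    flank5 = "".join(rng.choice(bases, size=150))
    flank3 = "".join(rng.choice(bases, size=150))
    genomic, exons = flank5, []
    for i, piece in enumerate(pieces):
        start = len(genomic) + 1
        genomic += piece
        exons.append((start, len(genomic)))
        if i < len(introns):
            genomic += introns[i]
    genomic += flank3

    gene = GeneModel(
        name=name,
        genomic_seq=genomic,
        exons=tuple(exons),
        strand="+",
        amplicon=(0, 0),  # placeholder, fixed below
        protein_seq=protein_seq,
        motif_anchors={MOTIF_NAME: MOTIF_START},
    )
    ser_codon_g = gene.cds_to_genomic(3 * (SER_POSITION - 1) + 1)
    amp_start = ser_codon_g - 547
    gene = GeneModel(
        name=gene.name, genomic_seq=gene.genomic_seq, exons=gene.exons,
        strand=gene.strand, amplicon=(amp_start, amp_start + AMPLICON_LEN - 1),
        protein_seq=gene.protein_seq, motif_anchors=gene.motif_anchors,
    )
    gene.validate()
    assert gene.amplicon_length == AMPLICON_LEN
    return gene


def s830n_site(gene: GeneModel) -> tuple[int, str]:
    """Genomic position and alternate base of the canonical Ser→Asn lesion.

    The middle base of the AGC serine codon; G→A turns AGC into AAC (Asn),
    the only missense reachable from AGC by an EMS transition.
    """
    pos = gene.cds_to_genomic(3 * (SER_POSITION - 1) + 2)
    assert gene.base_at(pos) == "G"
    return pos, "A"


# -- serialization ---------------------------------------------------------

def write_fixture(gene: GeneModel, outdir: str | Path) -> dict[str, Path]:
    """Write genomic FASTA, protein FASTA and GFF3 for the fixture."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomic": outdir / f"{gene.name}.genomic.fa",
        "protein": outdir / f"{gene.name}.protein.fa",
        "gff3": outdir / f"{gene.name}.gff3",
    }
    _write_fasta(paths["genomic"], gene.name, gene.genomic_seq)
    _write_fasta(paths["protein"], f"{gene.name}_protein", gene.protein_seq)

    lines = ["##gff-version 3",
             f"##sequence-region {gene.name} 1 {len(gene.genomic_seq)}"]
    span = (gene.exons[0][0], gene.exons[-1][1])
    gid = f"gene:{gene.name}"

    def row(ftype, start, end, attrs, phase="."):
        return "\t".join([gene.name, "scampr", ftype, str(start), str(end),
                          ".", gene.strand, phase, attrs])

    lines.append(row("gene", span[0], span[1], f"ID={gid}"))
    phase_acc = 0
    for i, (s, e) in enumerate(gene.exons, 1):
        lines.append(row("exon", s, e, f"ID=exon:{gene.name}.{i};Parent={gid}"))
        lines.append(row("CDS", s, e, f"ID=cds:{gene.name};Parent={gid}",
                         phase=str((3 - phase_acc % 3) % 3)))
        phase_acc += e - s + 1
    lines.append(row("amplicon", gene.amplicon[0], gene.amplicon[1],
                     f"ID=amplicon:{gene.name};length={gene.amplicon_length}"))
    paths["gff3"].write_text("\n".join(lines) + "\n")
    return paths


def _write_fasta(path: Path, name: str, seq: str, width: int = 70) -> None:
    chunks = [seq[i:i + width] for i in range(0, len(seq), width)]
    path.write_text(f">{name}\n" + "\n".join(chunks) + "\n")
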