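# Methods

## Scope and model

`scampr` simulates and decodes a pooled-amplicon TILLING screen of the kind
used to recover `Bdcesa1^S830N`. Five components chain together: a
constrained synthetic gene fixture, an EMS population model, the row/column
pooling design, a count-level sequencing model with an exact-binomial
detector, and intersection decoding with codon-level annotation. Everything
downstream derives from the design and model objects — no screen constant
is hard-coded past the configuration layer.

## The gene fixture

No nucleotide sequence for the screened *BdCESA1* region is publicly
deposited, so the fixture is synthesized, pinned to the published facts:

- a 1096-bp amplicon window containing the targeted exon;
- a protein with the QXXRW glycosyltransferase motif anchored at residue
  816, so its last residue (W820) sits 10 positions upstream of the
  conserved serine at 830;
- the published local context `LEKRFGQSPIFTA` (residues 823–835 of the
  screened isoform, containing the conserved E(K/R)xFGxS region);
- serine-830 encoded by **AGC** — the serine codon whose only EMS-reachable
  missense is AAC (Asn), which is what makes the recovered allele the
  unique outcome of the enumeration in `ems_reachable_substitutions`.

Filler residues, synonymous codon choices and intron sequence are drawn
from the seed; the CDS is split into 5 exons with canonical GT…AG introns
of 120–280 bp so the amplicon also contains intronic and splice-adjacent
positions for annotation tests. Coordinates are 1-based inclusive
throughout (GFF3/VCF convention); the fixture is emitted as FASTA + GFF3.

## Population model

Each M2 plant carries Poisson(`density`) induced mutations at uniformly
drawn amplicon positions whose reference base admits an EMS change; the
spectrum is fixed to coding-strand G→A and C→T (G:C→A:T on either strand),
which is the textbook EMS signature. Zygosity defaults to (2/3 het,
1/3 hom), the conditional segregation among carriers from a selfed
heterozygous M1. The default `density = 0.003` per plant per amplicon
corresponds to a typical grass EMS load of roughly one mutation per 400 kb
scaled to the 1096-bp window — the study does not print its realized
density. M2 plants are treated as independent (no M1 family structure or
chimerism).

## Sequencing and detection

Count-level simulation is the primary path: per superpool and position,
coverage ~ Poisson(depth) and base counts are multinomial over the
observation probabilities `f(1−e) + (1−f)e/3`. Errors are strand-agnostic
and uniform over the three non-reference bases; no indels or PCR
duplicates. The default depth of 10⁵ per superpool is a configuration
value consistent with one single-end HiSeq lane over 44 indexed superpools;
the detector and power model make the depth/error trade-off explicit rather
than relying on that choice. FASTQ emission (tiled single-end reads with a
deterministic covering pass plus uniform random starts, constant Phred
quality matching `e`) exists for exercising the pipeline from raw reads at
reduced depth; its pileup is defined as the exact base count of the emitted
reads.

Detection tests each (superpool, position, alternate) with a one-sided
exact binomial tail against the null `p0 = e/3` — per *specific* alternate,
not per error event; this moves thresholds threefold and is therefore
stated explicitly everywhere. Family-wise error is controlled by Bonferroni
over positions × superpools × 3 (Benjamini–Hochberg optional). The error
rate can be supplied or estimated robustly as 3 × the median non-reference
fraction after discarding the top 1 % of fractions (true variants occupy
the extreme tail, so a single real variant perturbs the estimate by well
under 5 %).

Analytic power: with carrier fraction `f` from the design and observed
alternate probability `q`, power is the binomial tail above the Bonferroni
critical count. By default it is marginalized over the simulator's
Poisson(depth) coverage so that Monte-Carlo detection rates from the
simulator are an unbiased check of the analytic value; `coverage="fixed"`
gives the plain fixed-n binomial, which is what the brute-force summation
oracle in the tests verifies to 12 digits.

## Decoding and annotation

Variants are keyed by (position, ref, alt) and the row-axis and column-axis
significant calls are intersected exactly; statuses are `unique` (one row ×
one column → one pool, 8 candidate plants), `ambiguous` (cross product of
multiple rows/columns — the honest limit of two-axis pooling, reported with
a Sanger-follow-up instruction across all candidate pools), or
`row_only`/`col_only`. Promotion policy defaults to intersected hits;
single-axis signals are surfaced, never promoted. A brute-force
pool-enumeration decoder serves as the independent oracle in the tests.
Sanger confirmation within the 8-plant pool is a report instruction only.

Annotation maps genomic position → CDS position through the exon list,
substitutes the codon, and classifies the effect under the standard genetic
code; intronic positions are `noncoding`, or `splice_adjacent` within 2 bp
of an exon boundary. The motif offset is reported for codons downstream of
the QXXRW anchor. Conservation logos compute per-column residue frequencies
over non-gap characters (gaps are ragged-end padding in the packaged
7-isoform alignment, so they are excluded from the denominator); letter
heights equal frequencies by default — the frequency-proportional
convention — with Shannon information-content mode available for comparison
with standard logo tools.

## Numerical and design choices

- The "(24 + 20)" superpool split is read as 24 column + 20 row superpools
  (a 20×24 grid): row superpools hold 192 plants, column superpools 160.
  The orientation is a config option; all arithmetic derives from the
  design object.
- Plant→pool assignment defaults to contiguous blocks for readability; a
  seeded shuffle is available.
- All randomness descends from one master seed via `SeedSequence.spawn`;
  identical config + seed gives byte-identical output files (logs carry
  timestamps, result files do not).
- Zero-depth positions are skipped with a log message; `e = 0` makes the
  null degenerate and any alternate observation significant (p = 0).
- Ties at the Bonferroni boundary resolve conservatively: the critical
  count is the smallest k with tail ≤ α/m.

## What the simulation does and does not show

The generator emulates the screen's combinatorics, EMS spectrum, zygosity
segregation and shot-noise sequencing with uniform substitution errors. It
does not model PCR amplification bias, per-pool DNA concentration
imbalance, mapping artefacts, strand-biased or position-dependent error
profiles, indels, or M1 family structure. Passing tests therefore
demonstrate the correctness of the decoding/detection machinery and its
calibration under the stated error model, not performance on any real
sequencing run.

Test problem sizes: the exhaustive decode round-trip covers all 480 pools
in batches of 60 planted lesions with distinct (position, alt) keys (which
decode independently) at depth 3000 with e = 0; the family-wise error and
power Monte-Carlo suites use a reduced 128-plant 4×4 design with 200–250
replicate screens at depths 500–800, compared against the analytic values
within binomial Monte-Carlo error.
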