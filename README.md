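# scampr

Simulation and decoding toolkit for **TILLING by sequencing** screens —
reverse-genetics discovery of induced point mutations by pooled amplicon
sequencing (SCAMPRing: Sequencing Candidate Amplicons in Multiple Parallel
Reactions).

The package models the screen that recovered the *Brachypodium distachyon*
`Bdcesa1^S830N` allele: 3840 EMS-mutagenized M2 plants pooled 8 at a time
into 480 DNA pools, the pools arrayed on a 20×24 grid, and each grid row
and column combined into a superpool (20 + 24 = 44). A 1096-bp amplicon of
the *BdCESA1* cellulose-synthase gene is sequenced per superpool; a variant
significant in exactly one row and one column superpool localizes to a
single 8-plant pool for Sanger follow-up.

It is aimed at anyone designing or analysing a pooled TILLING screen: how
deep to sequence, what error rate is tolerable, what the decode ambiguity
looks like, and how a recovered lesion annotates at the protein level.

## The statistics at the core

For a superpool of $N$ diploid plants, a heterozygous carrier contributes
allele fraction $f = 1/(2N)$ (hom: $1/N$) — 1/384 in a row superpool of
192 plants. Under a symmetric substitution-error channel with per-base
error $e$, a specific alternate base is observed with probability

$$q = f(1-e) + (1-f)\,\tfrac{e}{3},$$

and with no carrier the null is $p_0 = e/3$. Each (superpool, position,
alternate) is tested with a one-sided exact binomial test
$p = P(X \ge k \mid n = \text{depth},\, p_0)$, Bonferroni-corrected over
$m = \text{positions} \times \text{superpools} \times 3$ tests. Analytic
detection power is the binomial tail above the Bonferroni critical count at
$q$, marginalized over Poisson coverage. Decoding intersects row-axis and
column-axis significant calls per (position, alt) key; annotation maps the
genomic hit through the exon structure to a codon and reports
missense/nonsense/synonymous status, EMS reachability, and the residue
offset from the catalytic QXXRW motif.

## Worked example

```python
from scampr import ScreenConfig, run_screen
from scampr.pipeline import PlantedMutation

cfg = ScreenConfig(
    depth=1e5, error_rate=1e-3, density=0.0,
    planted=[PlantedMutation(plant_id=1337, site="s830n")],
    outdir="screen_out", seed=20)
result = run_screen(cfg)
print(result.summary)
```

prints

```
Screen summary: 1 decoded candidate(s) across 480 pools (20x24 grid, pool size 8).
Counts by status: unique=1, ambiguous=0, row_only=0, col_only=0
  pos 3160 G>A [unique] -> pools [168], 8 candidate plant(s); missense S830N
    unique: Sanger-sequence the 8 individuals of pool 168 to identify the carrier.
```

The heterozygous G→A planted in plant 1337 (the middle base of the AGC
serine-830 codon) was detected in one row and one column superpool at
depth 10⁵ against a 10⁻³ error rate, decoded to its 8-plant pool, and
annotated as missense Ser→Asn at protein position 830 — 10 residues
downstream of the QXXRW motif. The same pipeline is available from the
shell: `scampr run --config cfg.yaml`, with per-stage subcommands
(`fixture`, `simulate`, `detect`, `decode`, `annotate`, `power`).

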