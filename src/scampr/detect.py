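"""Pooled rare-variant detection within superpools.

Each (superpool, position, alternate base) is tested independently with a
one-sided exact binomial test against the sequencing-error null: under no
true variant, a specific alternate base appears with probability e/3 (the
error channel is uniform over the three non-reference bases, so the null
probability for one named alternate is a third of the total error rate).
Family-wise error is controlled by Bonferroni over positions × superpools
× 3 alternates; Benjamini–Hochberg is available as an alternative.  The
default EMS filter keeps only G→A / C→T calls, the transitions EMS
produces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pooling import PoolDesign, expected_allele_fraction
from .readsim import BASES, BASE_INDEX, PileupCounts, SequencingModel

log = logging.getLogger(__name__)

EMS_CHANGES = {("G", "A"), ("C", "T")}


@dataclass(frozen=True)
class VariantCall:
    superpool_id: str
    position: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    p_value: float
    passes_ems_filter: bool
    significant: bool


class ErrorEstimationError(RuntimeError):
    pass


def estimate_error_rate(pileups: list[PileupCounts],
                        trim_fraction: float = 0.01) -> float:
    """Robust substitution-error estimate from pileups.

    Takes the median of per-(superpool, position, alternate) count
    fractions after discarding the top ``trim_fraction`` (true variants
    live in the extreme tail), and multiplies by 3 to convert a
    specific-alternate rate back to the total error rate.
    """
    fracs = []
    for p in pileups:
        depths = p.depths.astype(float)
        ok = depths > 0
        if not ok.any():
            continue
        ref_idx = np.array([BASE_INDEX[r] for r in p.refs])
        for b in range(4):
            sel = ok & (ref_idx != b)
            fracs.append(p.counts[sel, b] / depths[sel])
    if not fracs:
        raise ErrorEstimationError("no covered positions; cannot estimate e")
    fracs = np.sort(np.concatenate(fracs))
    keep = len(fracs) - int(np.ceil(trim_fraction * len(fracs)))
    if keep <= 0:
        raise ErrorEstimationError("trim removed all observations")
    return float(3.0 * np.median(fracs[:keep]))


def bonferroni_m(n_positions: int, n_superpools: int) -> int:
    """Number of tests in a screen: positions × superpools × 3 alternates."""
    return n_positions * n_superpools * 3


def call_variants(pileups: list[PileupCounts], e: float, alpha: float = 0.05,
                  ems_only: bool = True, correction: str = "bonferroni",
                  m: int | None = None,
                  keep: str = "nonzero") -> list[VariantCall]:
    """Test every (superpool, position, alternate) against the error null.

    ``keep`` selects which calls are materialized: "significant" only,
    "nonzero" (any alternate observed; default), or "all".  Zero-depth
    positions are skipped with a log message.  ``m`` overrides the
    Bonferroni test count (e.g. when calling on a subset of superpools
    from a larger screen).
    """
    if e < 0:
        raise ValueError(f"error rate must be >= 0, got {e}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"correction must be bonferroni|bh, got {correction!r}")
    if keep not in ("significant", "nonzero", "all"):
        raise ValueError(f"keep must be significant|nonzero|all, got {keep!r}")

    n_positions = max((len(p.positions) for p in pileups), default=0)
    if m is None:
        m = bonferroni_m(n_positions, len(pileups))
    p0 = e / 3.0

    records = []   # (sp, pos, ref, alt, k, n, p)
    pvals = []
    for p in pileups:
        depths = p.depths
        zero = depths == 0
        if zero.any():
            log.info("superpool %s: %d zero-depth positions skipped",
                     p.superpool_id, int(zero.sum()))
        ref_idx = np.array([BASE_INDEX[r] for r in p.refs])
        for b, base in enumerate(BASES):
            sel = (~zero) & (ref_idx != b)
            if keep != "all":
                # zero-count tests have p = 1 and can never be rejected
                sel &= p.counts[:, b] > 0
            k = p.counts[sel, b]
            n = depths[sel]
            pv = stats.binom.sf(k - 1, n, p0)
            for pos, ref, kk, nn, pp in zip(
                    p.positions[sel], p.refs[sel], k, n, pv):
                records.append((p.superpool_id, int(pos), str(ref), base,
                                int(kk), int(nn)))
                pvals.append(float(pp))
    pvals = np.array(pvals)

    if correction == "bonferroni":
        sig = pvals <= alpha / m
    else:
        order = np.argsort(pvals)
        ranked = pvals[order]
        thresh = alpha * np.arange(1, len(ranked) + 1) / m
        below = np.nonzero(ranked <= thresh)[0]
        sig = np.zeros(len(pvals), dtype=bool)
        if len(below):
            sig[order[:below[-1] + 1]] = True

    calls = []
    for (sp, pos, ref, alt, k, n), pv, s in zip(records, pvals, sig):
        ems_ok = (ref, alt) in EMS_CHANGES
        if ems_only and not ems_ok:
            continue
        if keep == "significant" and not s:
            continue
        if keep == "nonzero" and k == 0 and not s:
            continue
        calls.append(VariantCall(sp, pos, ref, alt, k, n, pv, ems_ok, bool(s)))
    return calls


# -- analytic power --------------------------------------------------------

def _critical_count(n: int, p0: float, threshold: float) -> int:
    """Smallest k with P(X >= k | n, p0) <= threshold."""
    if p0 <= 0:
        return 1
    k = int(stats.binom.isf(threshold, n, p0))
    while k > 0 and stats.binom.sf(k - 1, n, p0) <= threshold:
        k -= 1
    while stats.binom.sf(k - 1, n, p0) > threshold:
        k += 1
    return k


def detection_power(design: PoolDesign, model: SequencingModel,
                    alpha: float = 0.05, zygosity: str = "het",
                    n_positions: int = 1096,
                    coverage: str = "poisson") -> dict[str, float]:
    """Probability that a single carrier's variant is called in its superpool.

    The observed alternate probability for a carrier at allele fraction f is
    q = f(1−e) + (1−f)e/3; power is the binomial tail above the Bonferroni
    critical count.  ``coverage="poisson"`` (default) marginalizes over the
    simulator's Poisson(depth) coverage; "fixed" evaluates at n = depth
    exactly.
    """
    if coverage not in ("poisson", "fixed"):
        raise ValueError(f"coverage must be poisson|fixed, got {coverage!r}")
    e = model.error_rate
    p0 = e / 3.0
    m = bonferroni_m(n_positions, len(design.superpools))
    threshold = alpha / m
    out = {}
    for axis in ("row", "col"):
        f = expected_allele_fraction(design, axis, zygosity)
        q = f * (1 - e) + (1 - f) * p0
        if coverage == "fixed":
            n = int(round(model.depth))
            k = _critical_count(n, p0, threshold)
            out[axis] = float(stats.binom.sf(k - 1, n, q))
        else:
            mu = model.depth
            half = int(np.ceil(8 * np.sqrt(mu))) + 1
            ns = np.arange(max(0, int(mu) - half), int(mu) + half + 1)
            w = stats.poisson.pmf(ns, mu)
            power = 0.0
            for n, wn in zip(ns, w):
                if n == 0 or wn < 1e-16:
                    continue
                k = _critical_count(int(n), p0, threshold)
                power += wn * stats.binom.sf(k - 1, int(n), q)
            out[axis] = float(power)
    return out


# -- VCF export ------------------------------------------------------------

def write_vcf(calls: list[VariantCall], gene_name: str, path,
              only_significant: bool = True) -> None:
    """Minimal VCF 4.2 with one record per (significant) call.

    CHROM is the amplicon/gene name; INFO carries SP (superpool), DP, AC
    and PV.  The header documents the binomial error-null model.
    """
    header = [
        "##fileformat=VCFv4.2",
        "##source=scampr",
        '##INFO=<ID=SP,Number=1,Type=String,Description="Superpool id">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Pileup depth">',
        '##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternate base count">',
        '##INFO=<ID=PV,Number=1,Type=Float,Description='
        '"One-sided exact binomial tail P(X>=AC | DP, e/3) under the '
        'sequencing-error null">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    rows = []
    for c in sorted(calls, key=lambda c: (c.position, c.alt, c.superpool_id)):
        if only_significant and not c.significant:
            continue
        info = f"SP={c.superpool_id};DP={c.depth};AC={c.alt_count};PV={c.p_value:.3e}"
        rows.append(f"{gene_name}\t{c.position}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}")
    from pathlib import Path
    Path(path).write_text("\n".join(header + rows) + "\n")
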