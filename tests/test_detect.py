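"""Pooled detection: error estimation, exact binomial calls, power."""

import numpy as np
import pytest
from scipy import stats

from scampr import (SequencingModel, call_variants, detection_power,
                    estimate_error_rate, plant_mutation, s830n_site,
                    simulate_pileup, write_vcf)
from scampr.detect import ErrorEstimationError, bonferroni_m, _critical_count
from scampr.population import Population
from scampr.readsim import BASE_INDEX, PileupCounts


def _pileup(sp="R01", depth=1000, alt_counts=None, ref="G", n_pos=10):
    """Synthetic pileup: all-reference except specified {position_index: count}
    of base A."""
    positions = np.arange(101, 101 + n_pos)
    refs = np.array([ref] * n_pos)
    counts = np.zeros((n_pos, 4), dtype=int)
    counts[:, BASE_INDEX[ref]] = depth
    for i, k in (alt_counts or {}).items():
        counts[i, BASE_INDEX["A"]] = k
        counts[i, BASE_INDEX[ref]] = depth - k
    return PileupCounts(sp, positions, refs, counts)


class TestErrorEstimation:
    def test_recovers_simulated_error_rate(self, gene, small_design):
        e = 0.003
        model = SequencingModel(depth=10_000, error_rate=e, seed=11)
        pileups = simulate_pileup(small_design, Population(n_plants=128),
                                  gene, model)
        e_hat = estimate_error_rate(pileups)
        assert abs(e_hat - e) / e < 0.20

    def test_error_free_input_gives_zero(self, gene, small_design):
        model = SequencingModel(depth=1000, error_rate=0.0, seed=12)
        pileups = simulate_pileup(small_design, Population(n_plants=128),
                                  gene, model)
        assert estimate_error_rate(pileups) == 0.0

    def test_median_robust_to_planted_variant(self, gene, small_design):
        e = 0.003
        pos, alt = s830n_site(gene)
        pop = plant_mutation(Population(n_plants=128), gene, 1, pos, alt, "hom")
        model = SequencingModel(depth=10_000, error_rate=e, seed=13)
        clean = estimate_error_rate(simulate_pileup(
            small_design, Population(n_plants=128), gene, model))
        with_variant = estimate_error_rate(simulate_pileup(
            small_design, pop, gene, model))
        assert abs(with_variant - clean) / clean < 0.05

    def test_zero_depth_raises(self):
        empty = _pileup(depth=0)
        empty.counts[:] = 0
        with pytest.raises(ErrorEstimationError):
            estimate_error_rate([empty])


class TestCallVariants:
    def test_strong_signal_is_significant(self):
        # alt_count 300 at depth 1e5 vs e=1e-3: error mean is ~33, far below
        m = bonferroni_m(1096, 44)
        p = _pileup(depth=100_000, alt_counts={3: 300})
        calls = call_variants([p], e=1e-3, alpha=0.05, m=m)
        hit = next(c for c in calls if c.alt_count == 300)
        assert hit.p_value < 0.05 / m
        assert hit.significant

    def test_count_at_error_mean_not_significant(self):
        m = bonferroni_m(1096, 44)
        p = _pileup(depth=100_000, alt_counts={3: 33})
        calls = call_variants([p], e=1e-3, alpha=0.05, m=m)
        hit = next(c for c in calls if c.alt_count == 33)
        assert not hit.significant
        assert hit.p_value > 0.05 / m

    def test_zero_count_never_significant(self):
        p = _pileup(depth=1000)
        calls = call_variants([p], e=1e-3, keep="all")
        assert calls
        for c in calls:
            assert c.p_value == pytest.approx(1.0)
            assert not c.significant

    def test_ems_filter_drops_exactly_non_transitions(self):
        p = _pileup(depth=1000, ref="G")
        p.counts[2, BASE_INDEX["A"]] = 500  # G->A, transition
        p.counts[5, BASE_INDEX["C"]] = 500  # G->C, not EMS
        unfiltered = call_variants([p], e=0.0, ems_only=False)
        filtered = call_variants([p], e=0.0, ems_only=True)
        assert {(c.ref, c.alt) for c in unfiltered} == {("G", "A"), ("G", "C")}
        assert {(c.ref, c.alt) for c in filtered} == {("G", "A")}
        assert all(c.passes_ems_filter for c in filtered)

    def test_zero_error_null_flags_any_alt(self):
        p = _pileup(depth=100, alt_counts={0: 1})
        calls = call_variants([p], e=0.0)
        assert calls[0].p_value == 0.0
        assert calls[0].significant

    def test_parameter_validation(self):
        p = _pileup()
        with pytest.raises(ValueError):
            call_variants([p], e=-0.1)
        with pytest.raises(ValueError):
            call_variants([p], e=0.001, alpha=1.5)
        with pytest.raises(ValueError):
            call_variants([p], e=0.001, correction="fdr_tsbh")

    def test_bh_rejects_at_least_bonferroni(self):
        p = _pileup(depth=100_000, alt_counts={1: 300, 4: 120, 7: 80})
        m = bonferroni_m(10, 1)
        bon = {(c.position, c.alt) for c in call_variants(
            [p], e=1e-3, m=m, keep="significant")}
        bh = {(c.position, c.alt) for c in call_variants(
            [p], e=1e-3, m=m, correction="bh", keep="significant")}
        assert bon <= bh


class TestDetectionPower:
    def test_fixed_coverage_matches_brute_force(self, default_design):
        # direct summation oracle for the binomial tail at n = depth
        model = SequencingModel(depth=2000, error_rate=1e-3)
        alpha, n_positions = 0.05, 1096
        got = detection_power(default_design, model, alpha=alpha,
                              n_positions=n_positions, coverage="fixed")
        m = bonferroni_m(n_positions, 44)
        for axis, n_sp_plants in [("row", 384), ("col", 320)]:
            e = model.error_rate
            q = (1 / n_sp_plants) * (1 - e) + (1 - 1 / n_sp_plants) * e / 3
            n = int(model.depth)
            p0 = e / 3
            # brute force: smallest critical count, then direct pmf summation
            k_star = next(k for k in range(n + 1)
                          if stats.binom.sf(k - 1, n, p0) <= alpha / m)
            power = float(sum(stats.binom.pmf(k, n, q)
                              for k in range(k_star, n + 1)))
            assert got[axis] == pytest.approx(power, abs=1e-12)

    def test_zero_error_power_is_one_minus_miss(self, default_design):
        model = SequencingModel(depth=500, error_rate=0.0)
        got = detection_power(default_design, model, coverage="fixed")
        q = 1 / 384
        assert got["row"] == pytest.approx(1 - (1 - q) ** 500, rel=1e-12)

    def test_power_monotone_in_depth(self, default_design):
        lo = detection_power(default_design,
                             SequencingModel(depth=1e4, error_rate=1e-3))
        hi = detection_power(default_design,
                             SequencingModel(depth=2e5, error_rate=1e-3))
        for axis in ("row", "col"):
            assert hi[axis] > lo[axis]
        assert hi["row"] > 0.999

    def test_hom_power_at_least_het(self, default_design):
        model = SequencingModel(depth=5000, error_rate=1e-3)
        het = detection_power(default_design, model, zygosity="het")
        hom = detection_power(default_design, model, zygosity="hom")
        for axis in ("row", "col"):
            assert hom[axis] >= het[axis]


def test_critical_count_definition():
    n, p0, thr = 1000, 0.01, 1e-4
    k = _critical_count(n, p0, thr)
    assert stats.binom.sf(k - 1, n, p0) <= thr
    assert stats.binom.sf(k - 2, n, p0) > thr


def test_vcf_export(tmp_path):
    p = _pileup(depth=100_000, alt_counts={3: 300})
    calls = call_variants([p], e=1e-3, m=bonferroni_m(10, 1))
    path = tmp_path / "calls.vcf"
    write_vcf(calls, "amplicon", path)
    text = path.read_text()
    assert text.startswith("##fileformat=VCFv4.2")
    records = [l for l in text.splitlines() if not l.startswith("#")]
    assert len(records) == 1
    fields = records[0].split("\t")
    assert fields[3] == "G" and fields[4] == "A"
    assert "SP=R01" in fields[7] and "AC=300" in fields[7]
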