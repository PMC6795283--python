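"""End-to-end screen orchestration: fixture → population → design → pileup
→ detect → deconvolve → annotate → report, from a validated config.

All randomness is derived from a single master seed so identical configs
produce byte-identical outputs; logs (which carry timestamps) go to the
logging system, never into result files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, detect, fixture, pooling, population, readsim
from .deconvolve import deconvolve as _deconvolve
from .deconvolve import summarize_screen

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PlantedMutation:
    plant_id: int
    zygosity: str = "het"
    site: str | None = None         # "s830n" for the canonical lesion
    position: int | None = None
    alt: str | None = None


@dataclass
class ScreenConfig:
    # population
    n_plants: int = 3840
    density: float = 0.003
    p_het: float = 2 / 3
    p_hom: float = 1 / 3
    # design
    pool_size: int = 8
    n_rows: int = 20
    n_cols: int = 24
    shuffle_plants: bool = False
    # sequencing
    depth: float = 1e5
    error_rate: float = 1e-3
    read_length: int = 100
    fastq: bool = False
    # detection
    alpha: float = 0.05
    correction: str = "bonferroni"
    ems_only: bool = True
    estimate_error: bool = False    # else use the configured error_rate
    # misc
    planted: list[PlantedMutation] = field(default_factory=list)
    outdir: str = "screen_out"
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_plants <= 0:
            errors.append("n_plants must be positive")
        if self.density < 0:
            errors.append("density must be >= 0")
        if abs(self.p_het + self.p_hom - 1) > 1e-9:
            errors.append("p_het + p_hom must equal 1")
        if not 0 < self.alpha < 1:
            errors.append(f"alpha must be in (0, 1), got {self.alpha}")
        if self.correction not in ("bonferroni", "bh"):
            errors.append(f"unknown correction {self.correction!r}")
        if not 0 <= self.error_rate < 1:
            errors.append(f"error_rate must be in [0, 1), got {self.error_rate}")
        if self.depth <= 0:
            errors.append("depth must be positive")
        seen = set()
        for p in self.planted:
            if p.zygosity not in population.ZYGOSITIES:
                errors.append(f"planted zygosity {p.zygosity!r} invalid")
            if p.site is None and (p.position is None or p.alt is None):
                errors.append("planted mutation needs site=s830n or position+alt")
            key = (p.plant_id, p.site or p.position)
            if key in seen:
                errors.append(f"duplicate planted mutation for plant "
                              f"{p.plant_id} at {p.site or p.position}")
            seen.add(key)
        if errors:
            raise ConfigError("invalid config:\n  " + "\n  ".join(errors))


_CONFIG_KEYS = {f for f in ScreenConfig.__dataclass_fields__}
_PLANT_KEYS = {f for f in PlantedMutation.__dataclass_fields__}


def validate_config(path: str | Path) -> ScreenConfig:
    """Load a flat YAML/key-value config, apply defaults, reject unknown
    keys, and report every violation at once."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of key: value")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    planted_raw = raw.pop("planted", [])
    planted = []
    for i, entry in enumerate(planted_raw):
        bad = set(entry) - _PLANT_KEYS
        if bad:
            raise ConfigError(f"planted[{i}]: unknown keys {sorted(bad)}")
        planted.append(PlantedMutation(**entry))
    cfg = ScreenConfig(planted=planted, **raw)
    cfg.validate()
    return cfg


@dataclass
class ScreenResult:
    config: ScreenConfig
    gene: fixture.GeneModel
    design: pooling.PoolDesign
    population: population.Population
    calls: list
    hits: list
    effects: dict
    report: pd.DataFrame
    summary: str
    paths: dict[str, Path]


def run_screen(config: ScreenConfig) -> ScreenResult:
    """Execute the full screen; every stage's output is persisted under
    ``config.outdir``.  Any stage failure aborts with the stage name."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    pop_seed, pileup_seed, shuffle_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    paths: dict[str, Path] = {}

    def stage(name):
        log.info("stage %s", name)
        return name

    try:
        name = stage("fixture")
        gene = fixture.build_gene_fixture(seed=1)
        paths.update(fixture.write_fixture(gene, outdir))

        name = stage("population")
        spectrum = population.EmsSpectrum(density=config.density)
        pop = population.generate_population(
            gene, config.n_plants, spectrum,
            (config.p_het, config.p_hom), seed=pop_seed)
        for pm in config.planted:
            if pm.site == "s830n":
                pos, alt = fixture.s830n_site(gene)
            else:
                pos, alt = pm.position, pm.alt
            pop = population.plant_mutation(pop, gene, pm.plant_id, pos, alt,
                                            pm.zygosity)
        paths["population"] = outdir / "population.tsv"
        population.write_population(pop, paths["population"])

        name = stage("design")
        design = pooling.build_design(
            config.n_plants, config.pool_size, config.n_rows, config.n_cols,
            seed=shuffle_seed if config.shuffle_plants else None)
        paths["design"] = outdir / "design.tsv"
        pooling.write_design(design, paths["design"])

        name = stage("pileup")
        model = readsim.SequencingModel(
            depth=config.depth, error_rate=config.error_rate,
            read_length=config.read_length, seed=pileup_seed)
        if config.fastq:
            paths["fastq"] = outdir / "reads.fastq"
            pileups = readsim.emit_fastq(design, pop, gene, model,
                                         paths["fastq"])
        else:
            pileups = readsim.simulate_pileup(design, pop, gene, model)
        paths["pileup"] = outdir / "pileup.tsv"
        readsim.write_counts(pileups, paths["pileup"])

        name = stage("detect")
        e = (detect.estimate_error_rate(pileups) if config.estimate_error
             else config.error_rate)
        log.info("error rate used for testing: %g", e)
        calls = detect.call_variants(
            pileups, e, alpha=config.alpha, ems_only=config.ems_only,
            correction=config.correction, keep="significant")
        log.info("%d significant call(s)", len(calls))
        paths["vcf"] = outdir / "calls.vcf"
        detect.write_vcf(calls, gene.name, paths["vcf"])

        name = stage("decode")
        hits = _deconvolve(calls, design)

        name = stage("annotate")
        effects = {(h.position, h.alt): annotate.annotate_effect(
            gene, h.position, h.alt) for h in hits}

        name = stage("report")
        report, summary = summarize_screen(hits, design, effects, outdir=outdir)
        paths["report"] = outdir / "decode_report.tsv"
        paths["summary"] = outdir / "summary.txt"
    except Exception as exc:  # noqa: BLE001 - stage context is the point
        log.error("aborted at stage %s (partial outputs in %s): %s",
                  name, outdir, exc)
        raise StageError(name, exc) from exc

    return ScreenResult(config, gene, design, pop, calls, hits, effects,
                        report, summary, paths)
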