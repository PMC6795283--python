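"""EMS-mutagenized M2 population simulator restricted to the amplicon window.

EMS alkylates guanine, so essentially all induced point mutations are
G:C→A:T transitions; on the coding strand that is G→A or C→T.  M2 plants
descend from selfed M1 individuals, so a mutation segregates 1:2:1 and a
carrier plant is heterozygous with probability 2/3, homozygous 1/3.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fixture import GeneModel

ZYGOSITIES = ("het", "hom")


@dataclass(frozen=True)
class EmsSpectrum:
    """Allowed base changes and the expected mutation load per plant.

    ``density`` is the expected number of induced mutations per plant
    within the amplicon window (Poisson mean).  The default of 0.003
    corresponds to a typical grass EMS load of roughly one mutation per
    400 kb scaled to a ~1.1 kb amplicon.
    """

    allowed_changes: frozenset[tuple[str, str]] = frozenset({("G", "A"), ("C", "T")})
    density: float = 0.003

    def __post_init__(self):
        if self.density < 0:
            raise ValueError(f"density must be >= 0, got {self.density}")
        for ref, alt in self.allowed_changes:
            if ref == alt:
                raise ValueError(f"degenerate change {ref}->{alt}")

    def alts_for(self, ref: str) -> tuple[str, ...]:
        return tuple(sorted(a for r, a in self.allowed_changes if r == ref))


EMS_DEFAULT = EmsSpectrum()


@dataclass(frozen=True)
class Mutation:
    plant_id: int
    position: int          # genomic, 1-based
    ref: str
    alt: str
    zygosity: str          # "het" | "hom"

    def __post_init__(self):
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at position {self.position}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"zygosity must be het|hom, got {self.zygosity!r}")

    @property
    def dosage(self) -> int:
        """Alternate-allele copies in a diploid plant."""
        return 1 if self.zygosity == "het" else 2


@dataclass(frozen=True)
class Population:
    n_plants: int
    mutations: tuple[Mutation, ...] = ()
    seed: int | None = None

    def validate(self, gene: GeneModel | None = None,
                 spectrum: EmsSpectrum | None = None) -> None:
        seen = set()
        for m in self.mutations:
            if not 1 <= m.plant_id <= self.n_plants:
                raise IndexError(f"plant_id {m.plant_id} outside [1, {self.n_plants}]")
            if (m.plant_id, m.position) in seen:
                raise ValueError(f"duplicate mutation at plant {m.plant_id}, "
                                 f"position {m.position}")
            seen.add((m.plant_id, m.position))
            if gene is not None and gene.base_at(m.position) != m.ref:
                raise ValueError(f"ref mismatch at {m.position}: fixture has "
                                 f"{gene.base_at(m.position)}, mutation says {m.ref}")
            if spectrum is not None and (m.ref, m.alt) not in spectrum.allowed_changes:
                raise ValueError(f"{m.ref}->{m.alt} not in EMS spectrum")


def mutable_positions(gene: GeneModel, spectrum: EmsSpectrum) -> np.ndarray:
    """Amplicon positions whose reference base admits an allowed change."""
    a0, a1 = gene.amplicon
    refs = {r for r, _ in spectrum.allowed_changes}
    return np.array([p for p in range(a0, a1 + 1) if gene.base_at(p) in refs],
                    dtype=int)


def generate_population(gene: GeneModel, n_plants: int,
                        spectrum: EmsSpectrum = EMS_DEFAULT,
                        zygosity_probs: tuple[float, float] = (2 / 3, 1 / 3),
                        seed: int = 0) -> Population:
    """Draw an M2 population: per plant, Poisson(density) mutations at
    uniformly chosen mutable amplicon positions, zygosity per mutation."""
    if n_plants <= 0:
        raise ValueError("n_plants must be positive")
    p_het, p_hom = zygosity_probs
    if not (p_het >= 0 and p_hom >= 0 and abs(p_het + p_hom - 1) < 1e-9):
        raise ValueError(f"zygosity probabilities must sum to 1, got {zygosity_probs}")

    rng = np.random.default_rng(seed)
    sites = mutable_positions(gene, spectrum)
    counts = rng.poisson(spectrum.density, size=n_plants)
    mutations: list[Mutation] = []
    for plant_idx in np.nonzero(counts)[0]:
        k = min(counts[plant_idx], len(sites))
        chosen = rng.choice(sites, size=k, replace=False)
        for pos in np.sort(chosen):
            ref = gene.base_at(int(pos))
            alts = spectrum.alts_for(ref)
            alt = alts[0] if len(alts) == 1 else str(rng.choice(list(alts)))
            zyg = "het" if rng.random() < p_het else "hom"
            mutations.append(Mutation(int(plant_idx) + 1, int(pos), ref, alt, zyg))
    pop = Population(n_plants=n_plants, mutations=tuple(mutations), seed=seed)
    pop.validate(gene=gene, spectrum=spectrum)
    return pop


def plant_mutation(pop: Population, gene: GeneModel, plant_id: int,
                   position: int, alt: str, zygosity: str = "het") -> Population:
    """Return a population with one controlled mutation added.

    Used to plant the Ser830→Asn analogue (or any lesion) for end-to-end
    tests; refuses duplicates at the same (plant, position).
    """
    if not 1 <= plant_id <= pop.n_plants:
        raise IndexError(f"plant_id {plant_id} outside [1, {pop.n_plants}]")
    a0, a1 = gene.amplicon
    if not a0 <= position <= a1:
        raise ValueError(f"position {position} outside amplicon [{a0}, {a1}]")
    ref = gene.base_at(position)
    if alt == ref:
        raise ValueError(f"alt {alt} equals reference base at {position}")
    for m in pop.mutations:
        if m.plant_id == plant_id and m.position == position:
            raise ValueError(f"plant {plant_id} already mutated at {position}")
    new = Mutation(plant_id, position, ref, alt, zygosity)
    return replace(pop, mutations=pop.mutations + (new,))


# -- serialization ---------------------------------------------------------

_COLUMNS = ["plant_id", "position", "ref", "alt", "zygosity"]


def population_frame(pop: Population) -> pd.DataFrame:
    return pd.DataFrame([(m.plant_id, m.position, m.ref, m.alt, m.zygosity)
                         for m in pop.mutations], columns=_COLUMNS)


def write_population(pop: Population, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n_plants={pop.n_plants}\tseed={pop.seed}\n")
        population_frame(pop).to_csv(fh, sep="\t", index=False)


def load_population(path: str | Path) -> Population:
    path = Path(path)
    text = path.read_text()
    header, _, body = text.partition("\n")
    meta = dict(item.split("=", 1) for item in header.lstrip("# ").split("\t"))
    df = pd.read_csv(io.StringIO(body), sep="\t", dtype={"ref": str, "alt": str})
    muts = tuple(Mutation(int(r.plant_id), int(r.position), r.ref, r.alt, r.zygosity)
                 for r in df.itertuples())
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return Population(n_plants=int(meta["n_plants"]), mutations=muts, seed=seed)
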