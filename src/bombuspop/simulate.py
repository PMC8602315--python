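"""Forward simulator of two-subspecies bumblebee population genetics.

Generates every input the pipeline consumes -- microsatellite genotypes,
specimen metadata, mitochondrial sequences -- with per-specimen truth labels
for recovery tests.  The model:

* two subspecies allele pools per locus, drawn from a shared Dirichlet base
  with a configurable concentration (lower concentration = more divergence);
* colony (full-sib) structure: each colony is founded by a singly-mated
  queen (the species is predominantly monandrous), so workers are full
  sisters;
* introgression: with probability q a colony descends from a commercial
  matriline -- an F1 queen (or, with a configurable fraction, a pure
  foreign queen) mated locally -- so its offspring carry the
  central-European mitochondrial haplotype under native-looking morphology:
  the discrepant-hybrid mechanism;
* strict maternal mitochondrial inheritance;
* single-locus complementary sex determination: fertilized eggs homozygous
  at the csd locus develop as diploid males (probability 1/k under random
  mating with k csd alleles);
* measurement noise applied last: missing calls and per-locus null-allele
  dropout (a null copy renders a heterozygote an apparent homozygote and a
  double-null missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haplotyping import HaplotypeScheme, revcomp
from .types import (
    Era,
    GenotypeCall,
    Haplotype,
    Morphotype,
    PopulationSample,
    Sex,
    Specimen,
)

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Study-design parameters for one simulated survey."""

    seed: int
    n_loci: int = 9
    alleles_per_locus: int = 8
    pool_concentration: float = 10.0  # Dirichlet concentration; lower = more diverged
    n_locations: int = 5
    introgression: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.45)  # q per location
    colonies_per_location: int = 10
    workers_sampled: int = 5
    males_sampled: int = 2
    csd_alleles: int = 10
    foreign_queen_fraction: float = 0.2  # of introgressed colonies: pure foreign queen
    morph_misclassification: float = 0.0
    missing_rate: float = 0.02
    null_allele_rate: dict[int, float] = field(default_factory=dict)  # locus idx -> rate
    allele_size_base: int = 120
    motif: int = 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if len(self.introgression) != self.n_locations:
            raise ValueError("one introgression fraction per location required")
        for q in self.introgression:
            if not 0.0 <= q <= 1.0:
                raise ValueError("introgression fractions must lie in [0, 1]")
        if self.csd_alleles < 2:
            raise ValueError("csd needs >= 2 alleles")

    @property
    def locus_names(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_loci)]

    def allele_sizes(self, locus_index: int) -> list[int]:
        start = self.allele_size_base + 30 * locus_index
        return [start + self.motif * j for j in range(self.alleles_per_locus)]


@dataclass
class SimTruth:
    specimen_id: str
    origin: str  # pure_lus | pure_terr | F1 | backcross
    maternal_haplotype: str
    ploidy: int
    csd_genotype: tuple[int, ...]
    colony: str


@dataclass
class SimStudy:
    config: SimConfig
    pools: dict[str, dict[str, dict[int, float]]]  # subspecies -> locus -> freqs
    populations: list[PopulationSample]
    truth: dict[str, SimTruth]
    mito_sequences: dict[str, str]  # specimen id -> template sequence


def draw_pools(
    config: SimConfig, rng: np.random.Generator
) -> dict[str, dict[str, dict[int, float]]]:
    """Two subspecies allele-frequency pools per locus.

    Per locus a base frequency vector is drawn from a flat Dirichlet; each
    pool is then Dirichlet(base * concentration), so a small concentration
    lets the pools drift far apart (high FST) while a huge one makes them
    identical.
    """
    pools: dict[str, dict[str, dict[int, float]]] = {"lus": {}, "terr": {}}
    for li, locus in enumerate(config.locus_names):
        sizes = config.allele_sizes(li)
        base = rng.dirichlet(np.ones(len(sizes)))
        for pool in ("lus", "terr"):
            freqs = rng.dirichlet(base * config.pool_concentration * len(sizes))
            pools[pool][locus] = dict(zip(sizes, freqs.tolist()))
    return pools


def _draw_allele(freqs: dict[int, float], rng: np.random.Generator) -> int:
    alleles = list(freqs)
    return alleles[rng.choice(len(alleles), p=np.array(list(freqs.values())))]


def _queen_genome(
    origin: str,
    pools: dict[str, dict[str, dict[int, float]]],
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, tuple[int, int]]:
    genome = {}
    for locus in config.locus_names:
        if origin == "pure_lus":
            pair = (_draw_allele(pools["lus"][locus], rng),
                    _draw_allele(pools["lus"][locus], rng))
        elif origin == "pure_terr":
            pair = (_draw_allele(pools["terr"][locus], rng),
                    _draw_allele(pools["terr"][locus], rng))
        else:  # F1 queen: one copy from each subspecies
            pair = (_draw_allele(pools["lus"][locus], rng),
                    _draw_allele(pools["terr"][locus], rng))
        genome[locus] = pair
    return genome


def _offspring_origin(queen_origin: str) -> str:
    # drones are always local (lusitanicus)
    return {"pure_lus": "pure_lus", "pure_terr": "F1", "F1": "backcross"}[queen_origin]


_MORPH_BY_ORIGIN = {
    "pure_lus": Morphotype.LUSITANICUS,
    "pure_terr": Morphotype.TERRESTRIS,
    "F1": Morphotype.MORPH_HYBRID,
    "backcross": Morphotype.LUSITANICUS,
}


def _apply_noise(
    alleles: tuple[int, ...],
    locus_index: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    null_rate = config.null_allele_rate.get(locus_index, 0.0)
    if null_rate > 0.0:
        kept = tuple(a for a in alleles if rng.random() >= null_rate)
        if len(alleles) == 2 and len(kept) == 1:
            kept = (kept[0], kept[0])  # null heterozygote scores as a homozygote
        alleles = kept
    if config.missing_rate > 0.0 and rng.random() < config.missing_rate:
        alleles = ()
    return alleles


def simulate_location(
    config: SimConfig,
    location_index: int,
    pools: dict[str, dict[str, dict[int, float]]],
    rng: np.random.Generator,
) -> tuple[PopulationSample, dict[str, SimTruth]]:
    """One location: colonies of full sibs under the colony's csd genetics.

    Fertilized eggs homozygous at csd emerge as diploid males within the
    worker cohort; the male cohort adds haploid sons.  Morphotype is the
    origin label (with an optional misclassification rate); haplotype is
    strictly maternal.
    """
    q = config.introgression[location_index]
    code = f"LOC{location_index + 1:02d}"
    specimens: list[Specimen] = []
    truth: dict[str, SimTruth] = {}
    counter = 0
    for colony_i in range(config.colonies_per_location):
        colony = f"{code}_C{colony_i + 1:02d}"
        if rng.random() < q:
            queen_origin = (
                "pure_terr" if rng.random() < config.foreign_queen_fraction else "F1"
            )
            haplotype = Haplotype.H2_CENTRAL_EUROPEAN
        else:
            queen_origin = "pure_lus"
            haplotype = Haplotype.H1_IBERIAN
        queen = _queen_genome(queen_origin, pools, config, rng)
        queen_csd = tuple(
            rng.choice(config.csd_alleles, size=2, replace=False).tolist()
        )
        drone = {
            locus: _draw_allele(pools["lus"][locus], rng)
            for locus in config.locus_names
        }
        drone_csd = int(rng.integers(config.csd_alleles))
        child_origin = _offspring_origin(queen_origin)

        def make_specimen(ploidy: int, fertilized: bool) -> None:
            nonlocal counter
            counter += 1
            sid = f"{code}_{counter:03d}"
            genotypes = []
            for li, locus in enumerate(config.locus_names):
                maternal = queen[locus][int(rng.integers(2))]
                alleles = (maternal, drone[locus]) if fertilized else (maternal,)
                genotypes.append(
                    GenotypeCall(locus=locus, alleles=_apply_noise(alleles, li, config, rng))
                )
            if fertilized:
                csd = (queen_csd[int(rng.integers(2))], drone_csd)
                diploid_male = csd[0] == csd[1]
                sex = Sex.MALE if diploid_male else Sex.FEMALE
                origin = child_origin
            else:
                csd = (queen_csd[int(rng.integers(2))],)
                sex = Sex.MALE
                origin = queen_origin if queen_origin != "pure_terr" else "pure_terr"
            morph = _MORPH_BY_ORIGIN[origin]
            if (
                config.morph_misclassification > 0.0
                and rng.random() < config.morph_misclassification
            ):
                others = [m for m in
                          (Morphotype.LUSITANICUS, Morphotype.TERRESTRIS, Morphotype.MORPH_HYBRID)
                          if m != morph]
                morph = others[int(rng.integers(len(others)))]
            specimens.append(
                Specimen(
                    id=sid, location=code, sex=sex, morphotype=morph,
                    haplotype=haplotype, era=Era.CURRENT, genotypes=genotypes,
                )
            )
            truth[sid] = SimTruth(
                specimen_id=sid, origin=origin,
                maternal_haplotype=haplotype.value,
                ploidy=2 if fertilized else 1,
                csd_genotype=csd, colony=colony,
            )

        for _ in range(config.workers_sampled):
            make_specimen(ploidy=2, fertilized=True)
        for _ in range(config.males_sampled):
            make_specimen(ploidy=1, fertilized=False)
    return PopulationSample(code=code, specimens=specimens), truth


def synthetic_templates(
    scheme: HaplotypeScheme, rng: np.random.Generator, pad: int = 30
) -> dict[str, str]:
    """Mitochondrial template sequences consistent with a haplotype scheme.

    Builds one template per haplotype: random padding, the forward primer,
    an insert sized so the amplicon matches the scheme's expected length,
    and the reverse-complemented reverse primer.  Diagnostic SNP bases are
    written at their amplicon positions and restriction sites are inserted
    (or scrubbed) per haplotype.
    """
    insert_len = (
        scheme.expected_amplicon_length
        - len(scheme.primer_fwd)
        - len(scheme.primer_rev)
    )
    if insert_len < 10:
        raise ValueError("amplicon length leaves no room for an insert")
    out: dict[str, str] = {}
    for label in (Haplotype.H1_IBERIAN.value, Haplotype.H2_CENTRAL_EUROPEAN.value):
        insert = list(rng.choice(list(_BASES), size=insert_len))
        amplicon = list(scheme.primer_fwd) + insert + list(revcomp(scheme.primer_rev))
        # restriction edits first, then SNP bases, so a scrub cannot undo a
        # diagnostic base (rules must not overlap positionally)
        ordered = sorted(scheme.diagnostic_rules, key=lambda r: r.kind != "restriction")
        for rule in ordered:
            if rule.kind == "snp":
                wanted = [b for b, lab in rule.bases.items() if lab == label]
                if not wanted:
                    raise ValueError(f"SNP rule lacks a base for {label}")
                amplicon[rule.position] = wanted[0]
            elif rule.kind == "restriction":
                site = rule.site
                lo = len(scheme.primer_fwd)
                hi = scheme.expected_amplicon_length - len(scheme.primer_rev) - len(site)
                seq = "".join(amplicon)
                # scrub accidental occurrences on both strands within the insert
                for target in (site, revcomp(site)):
                    start = 0
                    while (pos := seq.find(target, start)) != -1:
                        amplicon[pos] = "A" if amplicon[pos] != "A" else "C"
                        seq = "".join(amplicon)
                        start = pos + 1
                if rule.present == label:
                    mid = (lo + hi) // 2
                    amplicon[mid : mid + len(site)] = list(site)
        pad_l = "".join(rng.choice(list(_BASES), size=pad))
        pad_r = "".join(rng.choice(list(_BASES), size=pad))
        out[label] = pad_l + "".join(amplicon) + pad_r
    return out


def simulate_study(config: SimConfig, scheme: HaplotypeScheme | None = None) -> SimStudy:
    """Run the full simulator: pools, every location, mito sequences."""
    rng = np.random.default_rng(config.seed)
    pools = draw_pools(config, rng)
    populations: list[PopulationSample] = []
    truth: dict[str, SimTruth] = {}
    for li in range(config.n_locations):
        pop, t = simulate_location(config, li, pools, rng)
        populations.append(pop)
        truth.update(t)
    mito: dict[str, str] = {}
    if scheme is not None:
        templates = synthetic_templates(scheme, rng)
        for pop in populations:
            for s in pop.specimens:
                mito[s.id] = templates[s.haplotype.value]
    return SimStudy(
        config=config, pools=pools, populations=populations,
        truth=truth, mito_sequences=mito,
    )


def emit_study(study: SimStudy, outdir) -> dict[str, str]:
    """Write GenePop, metadata CSV, truth CSV (and FASTA when present).

    The files round-trip through the package's own readers; the truth table
    is for tests only and is never consumed by the analysis path.
    """
    import csv
    from pathlib import Path

    from .io import write_fasta, write_genepop, write_metadata
    from .types import LocusDef

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = [LocusDef(name=n) for n in study.config.locus_names]
    paths = {
        "genepop": str(outdir / "genotypes.gen"),
        "metadata": str(outdir / "metadata.csv"),
        "truth": str(outdir / "truth.csv"),
    }
    title = f"bombuspop simulated study (seed={study.config.seed})"
    write_genepop(paths["genepop"], panel, study.populations, title=title)
    write_metadata(
        paths["metadata"], [s for p in study.populations for s in p.specimens]
    )
    with open(paths["truth"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["specimen_id", "origin", "maternal_haplotype", "ploidy", "csd_genotype", "colony"]
        )
        for sid in sorted(study.truth):
            t = study.truth[sid]
            writer.writerow(
                [t.specimen_id, t.origin, t.maternal_haplotype, t.ploidy,
                 "/".join(map(str, t.csd_genotype)), t.colony]
            )
    if study.mito_sequences:
        paths["fasta"] = str(outdir / "mito.fasta")
        write_fasta(paths["fasta"], study.mito_sequences)
    return paths
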