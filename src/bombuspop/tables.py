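"""Bundled summary data from the Iberian bumblebee hybridization survey.

Two small tables ship with the package:

* per-location specimen counts (sex, morphotype group, hybrid and diploid-
  male tallies) for the peninsular survey, its Pyrenean and north-European
  reference groups and the pre-1990s historical reference;
* per-population diversity summaries (N, Ar, pAr, Ho, He, Fis) under the
  hIN and hOUT dataset variants.

The count table expands into specimen-level records: haplotypes follow the
morphology/haplotype discrepancy logic (a hybrid-flagged *lusitanicus* row
member carries the central-European haplotype and vice versa) and male
genotypes are synthesized minimally so the ploidy caller reproduces the
tallied diploid and triploid calls.  Genotype-level data for females is not
part of the bundle; the expansion is for haplotype, hybrid and ploidy
accounting, not for allele-frequency statistics.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

from .diversity import DiversitySummary
from .types import (
    Era,
    GenotypeCall,
    Haplotype,
    Morphotype,
    PopulationSample,
    Sex,
    Specimen,
)

_PLOIDY_LOCI = [f"L{i + 1:02d}" for i in range(9)]


def _read_packaged(name: str) -> pd.DataFrame:
    text = resources.files("bombuspop.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text))


def survey_counts() -> pd.DataFrame:
    """The per-location count table (one row per location x morphotype group)."""
    return _read_packaged("iberian_survey_counts.csv")


def _male_genotypes(kind: str) -> list[GenotypeCall]:
    """Minimal multilocus genotypes that drive the ploidy caller.

    haploid: one allele everywhere; diploid: heterozygous at every locus;
    triploid: three distinct alleles at two loci.
    """
    calls = []
    for i, locus in enumerate(_PLOIDY_LOCI):
        if kind == "haploid":
            alleles: tuple[int, ...] = (100,)
        elif kind == "diploid":
            alleles = (100, 102)
        elif kind == "triploid" and i < 2:
            alleles = (100, 102, 104)
        else:
            alleles = (100,)
        calls.append(GenotypeCall(locus=locus, alleles=alleles))
    return calls


_GROUP_MORPH = {
    "lusitanicus": Morphotype.LUSITANICUS,
    "terrestris": Morphotype.TERRESTRIS,
    "morph_hybrid": Morphotype.MORPH_HYBRID,
}

_EXPECTED_HAPLO = {
    "lusitanicus": Haplotype.H1_IBERIAN,
    "terrestris": Haplotype.H2_CENTRAL_EUROPEAN,
}

_DISCREPANT_HAPLO = {
    "lusitanicus": Haplotype.H2_CENTRAL_EUROPEAN,
    "terrestris": Haplotype.H1_IBERIAN,
}


def survey_specimens(regions: set[str] | None = None) -> list[PopulationSample]:
    """Expand the count table into specimen-level population samples."""
    df = survey_counts()
    if regions:
        df = df[df.region.isin(regions)]
    populations: dict[str, PopulationSample] = {}
    for _, row in df.iterrows():
        code = row.location
        pop = populations.setdefault(code, PopulationSample(code=code))
        group = row.group
        morph = _GROUP_MORPH[group]
        era = Era.HISTORICAL if row.region == "historical" else Era.CURRENT
        serial = len(pop.specimens)

        def add(sex: Sex, haplotype: Haplotype, genotypes: list[GenotypeCall]) -> None:
            nonlocal serial
            serial += 1
            pop.specimens.append(
                Specimen(
                    id=f"{code}_{serial:03d}", location=code, sex=sex,
                    morphotype=morph, haplotype=haplotype, era=era,
                    genotypes=genotypes,
                )
            )

        if group == "morph_hybrid":
            expected = discrepant = Haplotype.UNKNOWN
        else:
            expected = _EXPECTED_HAPLO[group]
            discrepant = _DISCREPANT_HAPLO[group]
        for i in range(int(row.n_female)):
            h = discrepant if i < int(row.n_hybrid_female) else expected
            add(Sex.FEMALE, h, [])
        n_dip, n_tri = int(row.n_diploid_male), int(row.n_triploid_male)
        for i in range(int(row.n_male)):
            h = discrepant if i < int(row.n_hybrid_male) else expected
            if i < n_dip:
                kind = "diploid"
            elif i < n_dip + n_tri:
                kind = "triploid"
            else:
                kind = "haploid"
            add(Sex.MALE, h, _male_genotypes(kind))
    return list(populations.values())


def diversity_summaries() -> dict[str, list[DiversitySummary]]:
    """Per-population diversity summaries keyed by dataset variant."""
    df = _read_packaged("iberian_diversity_summaries.csv")
    out: dict[str, list[DiversitySummary]] = {}
    for _, row in df.iterrows():
        out.setdefault(row.variant, []).append(
            DiversitySummary(
                code=row.location, variant=row.variant, n=int(row.n),
                ar=float(row.ar), par=float(row.par),
                ho=float(row.ho), he=float(row.he), fis=float(row.fis),
            )
        )
    return out
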