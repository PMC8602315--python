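"""Domain types for codominant microsatellite data with colony structure.

Alleles are identified by their integer fragment size in base pairs, exactly
as scored against a size standard; no binning is applied.  A missing genotype
is an empty allele tuple, never a size-0 allele.  Haploid (hemizygous) male
calls carry a single allele, diploid calls two, and a triple-peak call --
the signature of a triploid -- three.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Morphotype(str, enum.Enum):
    LUSITANICUS = "lusitanicus"
    TERRESTRIS = "terrestris"
    MORPH_HYBRID = "morph_hybrid"
    UNKNOWN = "unknown"


class Haplotype(str, enum.Enum):
    H1_IBERIAN = "H1_iberian"
    H2_CENTRAL_EUROPEAN = "H2_central_european"
    UNKNOWN = "unknown"


class Era(str, enum.Enum):
    CURRENT = "current"
    HISTORICAL = "historical"


@dataclass(frozen=True)
class LocusDef:
    """One microsatellite locus of the panel."""

    name: str
    allele_domain: frozenset[int] = frozenset()
    motif_length: int | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("locus name must be non-empty")


@dataclass(frozen=True)
class GenotypeCall:
    """Multiset of scored alleles at one locus for one specimen.

    0 alleles = missing, 1 = hemizygous/haploid, 2 = diploid,
    3 = triple-peak (triploid candidate).
    """

    locus: str
    alleles: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.alleles) > 3:
            raise ValueError(
                f"at most 3 alleles per call, got {len(self.alleles)} at {self.locus}"
            )
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def is_missing(self) -> bool:
        return len(self.alleles) == 0

    @property
    def is_heterozygous(self) -> bool:
        return len(set(self.alleles)) >= 2

    @property
    def n_distinct(self) -> int:
        return len(set(self.alleles))

    def counter(self) -> Counter[int]:
        return Counter(self.alleles)


@dataclass
class Specimen:
    """One sampled bumblebee with metadata and its multilocus genotype."""

    id: str
    location: str
    sex: Sex
    morphotype: Morphotype = Morphotype.UNKNOWN
    haplotype: Haplotype = Haplotype.UNKNOWN
    era: Era = Era.CURRENT
    genotypes: list[GenotypeCall] = field(default_factory=list)

    def genotype_at(self, locus: str) -> GenotypeCall | None:
        for g in self.genotypes:
            if g.locus == locus:
                return g
        return None

    def missing_fraction(self, panel_size: int | None = None) -> float:
        n = panel_size if panel_size is not None else len(self.genotypes)
        if n == 0:
            raise ValueError("empty panel: missing fraction undefined")
        return sum(g.is_missing for g in self.genotypes) / n


class ReferenceRole(str, enum.Enum):
    LUSITANICUS_REF = "lusitanicus_ref"
    TERRESTRIS_REF = "terrestris_ref"
    NONE = "none"


@dataclass
class PopulationSample:
    """All specimens pooled under one location code (10 km radius rule)."""

    code: str
    specimens: list[Specimen] = field(default_factory=list)
    is_reference: bool = False
    reference_role: ReferenceRole = ReferenceRole.NONE

    def __len__(self) -> int:
        return len(self.specimens)

    def females(self) -> list[Specimen]:
        return [s for s in self.specimens if s.sex == Sex.FEMALE]

    def males(self) -> list[Specimen]:
        return [s for s in self.specimens if s.sex == Sex.MALE]

    def subset(self, ids: set[str], code: str | None = None) -> "PopulationSample":
        return PopulationSample(
            code=code or self.code,
            specimens=[s for s in self.specimens if s.id in ids],
            is_reference=self.is_reference,
            reference_role=self.reference_role,
        )


class VariantLabel(str, enum.Enum):
    HIN = "hIN"
    HOUT = "hOUT"
    ROUT = "rOUT"


@dataclass
class DatasetVariant:
    """A population under one filtering regime.

    hIN keeps everyone, hOUT removes detected hybrids and naturalized
    foreign individuals, rOUT removes a random set of the same size as a
    null for the paired comparison.
    """

    label: VariantLabel
    parent: PopulationSample
    retained_ids: set[str]
    removal_seed: int | None = None

    def sample(self) -> PopulationSample:
        return self.parent.subset(self.retained_ids)

    def __len__(self) -> int:
        return len(self.retained_ids)
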