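"""Diploid and triploid male detection from multilocus genotypes.

In haplodiploid bees, males homozygous at the complementary sex-determination
locus develop from fertilized (diploid) eggs.  A male heterozygous at two or
more microsatellite loci cannot be haploid and is called diploid; a male
showing three distinct alleles at two or more loci is called triploid.  The
diploid-male proportion phi = (diploid males) / (all sampled males) is an
inbreeding indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

from .types import PopulationSample, Sex, Specimen

logger = logging.getLogger(__name__)


@dataclass
class PloidyCall:
    specimen_id: str
    call: str  # "haploid" | "diploid" | "triploid"
    n_het_loci: int
    n_triple_loci: int
    n_typed_loci: int
    low_confidence: bool = False


def call_male_ploidy(specimen: Specimen, min_triple_loci: int = 2) -> PloidyCall:
    """Classify a male as haploid, diploid or triploid.

    Two or more heterozygous loci make a diploid; ``min_triple_loci`` loci
    with three distinct alleles make a triploid (overriding diploid).  Males
    with fewer than two typed loci stay in downstream denominators but are
    flagged low-confidence.
    """
    if specimen.sex != Sex.MALE:
        raise ValueError(f"{specimen.id}: ploidy calling applies to males only")
    typed = [g for g in specimen.genotypes if not g.is_missing]
    n_het = sum(g.n_distinct >= 2 for g in typed)
    n_triple = sum(g.n_distinct >= 3 for g in typed)
    if n_triple >= min_triple_loci:
        call = "triploid"
    elif n_het >= 2:
        call = "diploid"
    else:
        call = "haploid"
    low_conf = len(typed) < 2
    if low_conf:
        logger.warning("%s: only %d typed loci, low-confidence %s call",
                       specimen.id, len(typed), call)
    return PloidyCall(
        specimen_id=specimen.id, call=call,
        n_het_loci=n_het, n_triple_loci=n_triple,
        n_typed_loci=len(typed), low_confidence=low_conf,
    )


@dataclass
class PhiResult:
    n_males: int
    n_diploid: int
    n_triploid: int
    phi_exact: Fraction
    phi: float  # half-up to 2 decimals

    @property
    def value(self) -> float:
        return float(self.phi_exact)


def phi(calls: list[PloidyCall]) -> PhiResult:
    """Diploid-male proportion: diploid calls over all sampled males.

    Triploids are excluded from the numerator and reported separately.  The
    exact fraction is kept alongside the conventional 2-decimal rounding
    (half-up).
    """
    if not calls:
        raise ValueError("phi undefined: no males")
    n = len(calls)
    n_dip = sum(c.call == "diploid" for c in calls)
    n_tri = sum(c.call == "triploid" for c in calls)
    frac = Fraction(n_dip, n)
    rounded = int(float(frac) * 100 + 0.5) / 100  # half-up
    return PhiResult(n_males=n, n_diploid=n_dip, n_triploid=n_tri,
                     phi_exact=frac, phi=rounded)


def phi_for_population(population: PopulationSample) -> PhiResult:
    calls = [call_male_ploidy(s) for s in population.males()]
    if not calls:
        raise ValueError(f"{population.code}: no males sampled, phi undefined")
    return phi(calls)


def phi_pooled(populations: list[PopulationSample]) -> PhiResult:
    """Pooled phi = sum of numerators over sum of denominators (never the
    mean of per-site values)."""
    calls = [call_male_ploidy(s) for p in populations for s in p.males()]
    if not calls:
        raise ValueError("no males sampled in any population")
    return phi(calls)
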