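"""Allele frequencies, diversity statistics and marker validation screens.

Implements the per-population summary statistics used throughout the
analysis -- observed/expected heterozygosity, rarefied allelic richness and
private allelic richness (rarefaction to a fixed number of gene copies, so
populations of unequal size are comparable), and the Weir–Cockerham
within-population inbreeding coefficient -- plus the marker validation
screens: closed-form null-allele estimators from homozygote excess, an exact
conditional Hardy–Weinberg test, and a permutation test of linkage
disequilibrium.

Conventions follow the desktop tools classically used for microsatellite
surveys: expected heterozygosity is the uncorrected 1 - sum(p^2) (an
unbiased small-sample variant is available behind a flag), and multilocus
summaries are unweighted means across loci.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .types import GenotypeCall, PopulationSample, Sex, Specimen

logger = logging.getLogger(__name__)


class AlleleFrequencyTable:
    """Per-locus allele -> gene-copy counts for one population.

    Missing calls contribute no copies; haploid calls contribute one copy
    when included.  Frequencies always sum to one per locus.
    """

    def __init__(self, counts: dict[str, Counter[int]]):
        self.counts = {locus: Counter(c) for locus, c in counts.items()}
        for locus, c in self.counts.items():
            if any(n < 0 for n in c.values()):
                raise ValueError(f"negative allele count at {locus}")

    @classmethod
    def from_specimens(
        cls,
        specimens: list[Specimen],
        females_only: bool = False,
        diploid_only: bool = False,
    ) -> "AlleleFrequencyTable":
        counts: dict[str, Counter[int]] = {}
        for s in specimens:
            if females_only and s.sex != Sex.FEMALE:
                continue
            for g in s.genotypes:
                if diploid_only and len(g.alleles) != 2:
                    continue
                counts.setdefault(g.locus, Counter()).update(g.alleles)
        return cls(counts)

    @property
    def loci(self) -> list[str]:
        return list(self.counts)

    def n_copies(self, locus: str) -> int:
        return sum(self.counts[locus].values())

    def freqs(self, locus: str) -> dict[int, float]:
        total = self.n_copies(locus)
        if total == 0:
            return {}
        return {a: n / total for a, n in sorted(self.counts[locus].items())}

    def alleles(self, locus: str) -> set[int]:
        return {a for a, n in self.counts[locus].items() if n > 0}

    def minus(self, specimen: Specimen) -> "AlleleFrequencyTable":
        """Leave-one-out copy of the table with one specimen's alleles removed."""
        out = {locus: Counter(c) for locus, c in self.counts.items()}
        for g in specimen.genotypes:
            if g.locus in out:
                out[g.locus].subtract(g.counter())
                if any(n < 0 for n in out[g.locus].values()):
                    raise ValueError(
                        f"specimen {specimen.id} not contained in table at {g.locus}"
                    )
        return AlleleFrequencyTable(out)


# ---------------------------------------------------------------------------
# heterozygosity


@dataclass
class HetResult:
    ho_per_locus: dict[str, float]
    he_per_locus: dict[str, float]
    ho: float
    he: float
    excluded_loci: list[str] = field(default_factory=list)


def observed_expected_het(
    population: PopulationSample,
    females_only: bool = True,
    unbiased: bool = False,
) -> HetResult:
    """Observed and expected heterozygosity per locus and their means.

    Ho is the fraction of heterozygotes among typed diploid genotypes; He is
    1 - sum(p^2) from the same genotypes (multiplied by 2n/(2n-1) when
    ``unbiased``).  Loci with no typed diploid genotype are excluded from
    the multilocus means and logged.  Only female genotypes enter by
    default, avoiding the haplodiploid male bias.
    """
    specimens = population.females() if females_only else population.specimens
    calls: dict[str, list[GenotypeCall]] = {}
    for s in specimens:
        for g in s.genotypes:
            if len(g.alleles) == 2:
                calls.setdefault(g.locus, []).append(g)
    loci = sorted({g.locus for s in specimens for g in s.genotypes})
    ho_l: dict[str, float] = {}
    he_l: dict[str, float] = {}
    excluded = []
    for locus in loci:
        diploids = calls.get(locus, [])
        if not diploids:
            excluded.append(locus)
            logger.warning("locus %s: no typed diploid genotypes, excluded", locus)
            continue
        ho_l[locus] = sum(g.is_heterozygous for g in diploids) / len(diploids)
        freq = Counter(a for g in diploids for a in g.alleles)
        total = sum(freq.values())
        he = 1.0 - sum((n / total) ** 2 for n in freq.values())
        if unbiased and total > 1:
            he *= total / (total - 1)
        he_l[locus] = he
    if not ho_l:
        raise ValueError(f"{population.code}: no locus with diploid genotypes")
    return HetResult(
        ho_per_locus=ho_l,
        he_per_locus=he_l,
        ho=float(np.mean(list(ho_l.values()))),
        he=float(np.mean(list(he_l.values()))),
        excluded_loci=excluded,
    )


# ---------------------------------------------------------------------------
# rarefaction


def _q_present(n_total: int, n_allele: int, g: int) -> float:
    """P(allele with n_allele of n_total copies appears in a g-subsample)."""
    if n_allele == 0:
        return 0.0
    return 1.0 - math.comb(n_total - n_allele, g) / math.comb(n_total, g)


@dataclass
class RarefactionResult:
    per_locus: dict[str, float]
    mean: float
    skipped_loci: list[str] = field(default_factory=list)


def rarefied_allelic_richness(table: AlleleFrequencyTable, g: int) -> RarefactionResult:
    """Expected number of distinct alleles in a subsample of g gene copies.

    Ar_g = sum over alleles of the probability that the allele is present in
    a random g-subset of the locus's copies.  Loci with fewer than g copies
    are skipped with a warning rather than shrinking g, so the rarefaction
    depth stays comparable across populations.
    """
    if g < 2:
        raise ValueError("rarefaction depth g must be >= 2")
    per_locus: dict[str, float] = {}
    skipped = []
    for locus in table.loci:
        n = table.n_copies(locus)
        if n < g:
            skipped.append(locus)
            logger.warning("locus %s: %d copies < g=%d, skipped", locus, n, g)
            continue
        per_locus[locus] = sum(
            _q_present(n, na, g) for na in table.counts[locus].values() if na > 0
        )
    if not per_locus:
        raise ValueError(f"no locus with >= {g} gene copies")
    return RarefactionResult(per_locus, float(np.mean(list(per_locus.values()))), skipped)


def rarefied_private_allelic_richness(
    tables: dict[str, AlleleFrequencyTable], focal: str, g: int
) -> RarefactionResult:
    """Rarefied richness of alleles expected in the focal population only.

    Each allele contributes Q_focal(a, g) * prod over other populations of
    (1 - Q_j(a, g)): the probability it shows up in a g-copy subsample of
    the focal population and in no other population's subsample.
    """
    if focal not in tables:
        raise KeyError(f"focal population {focal!r} not among tables")
    if len(tables) < 2:
        raise ValueError("private allelic richness needs >= 2 populations")
    others = [t for code, t in tables.items() if code != focal]
    ftab = tables[focal]
    per_locus: dict[str, float] = {}
    skipped = []
    for locus in ftab.loci:
        pops = [ftab] + [t for t in others if locus in t.counts]
        if any(t.n_copies(locus) < g for t in pops):
            skipped.append(locus)
            logger.warning("locus %s: a population has < g=%d copies, skipped", locus, g)
            continue
        alleles = set().union(*(t.alleles(locus) for t in pops))
        total = 0.0
        for a in alleles:
            qf = _q_present(ftab.n_copies(locus), ftab.counts[locus].get(a, 0), g)
            prod = 1.0
            for t in pops[1:]:
                prod *= 1.0 - _q_present(t.n_copies(locus), t.counts[locus].get(a, 0), g)
            total += qf * prod
        per_locus[locus] = total
    if not per_locus:
        raise ValueError(f"no locus with >= {g} copies in every population")
    return RarefactionResult(per_locus, float(np.mean(list(per_locus.values()))), skipped)


# ---------------------------------------------------------------------------
# inbreeding


def fis(population: PopulationSample, females_only: bool = True) -> float:
    """Weir & Cockerham (1984) within-population inbreeding coefficient f.

    Variance components are summed over alleles and loci before the final
    ratio (the convention of the classic FSTAT implementation), not averaged
    per locus.
    """
    specimens = population.females() if females_only else population.specimens
    calls: dict[str, list[GenotypeCall]] = {}
    for s in specimens:
        for g in s.genotypes:
            if len(g.alleles) == 2:
                calls.setdefault(g.locus, []).append(g)
    sum_b = sum_c = 0.0
    informative = False
    for locus, genos in calls.items():
        n = len(genos)
        if n < 2:
            continue
        freq = Counter(a for g in genos for a in g.alleles)
        if len(freq) < 2:
            continue
        informative = True
        total = 2 * n
        for allele, copies in freq.items():
            p = copies / total
            h_bar = sum(
                g.is_heterozygous and allele in g.alleles for g in genos
            ) / n
            b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h_bar)
            c = h_bar / 2
            sum_b += b
            sum_c += c
    if not informative:
        raise ValueError(f"{population.code}: all loci monomorphic, Fis undefined")
    return 1.0 - sum_c / (sum_b + sum_c)


# ---------------------------------------------------------------------------
# null alleles


@dataclass
class NullAlleleResult:
    chakraborty: dict[str, float]
    brookfield1: dict[str, float]
    homozygote_excess_flag: dict[str, bool]
    threshold: float


def null_allele_estimates(
    population: PopulationSample,
    females_only: bool = True,
    threshold: float = 0.05,
) -> NullAlleleResult:
    """Closed-form null-allele frequency estimates from homozygote excess.

    Chakraborty: r = (He - Ho) / (He + Ho); Brookfield-1: r = (He - Ho) /
    (1 + He).  A locus is flagged when either estimate exceeds the
    configurable threshold.  (The iterative van-Oosterhout estimator is not
    reproduced; these two estimators serve the homozygote-excess screen.)
    """
    het = observed_expected_het(population, females_only=females_only)
    chak: dict[str, float] = {}
    brook: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for locus, he in het.he_per_locus.items():
        ho = het.ho_per_locus[locus]
        if he <= 0:
            logger.warning("locus %s: He = 0, null-allele estimate skipped", locus)
            continue
        if he + ho > 0:
            chak[locus] = (he - ho) / (he + ho)
        brook[locus] = (he - ho) / (1 + he)
        flags[locus] = max(chak.get(locus, 0.0), brook[locus]) > threshold
    return NullAlleleResult(chak, brook, flags, threshold)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def _log_table_prob(table: Counter[tuple[int, int]]) -> float:
    """log P(genotype array | allele counts) under Hardy-Weinberg."""
    n = sum(table.values())
    allele_counts: Counter[int] = Counter()
    n_het = 0
    for (a, b), k in table.items():
        allele_counts[a] += k
        allele_counts[b] += k
        if a != b:
            n_het += k
    logp = (
        math.lgamma(n + 1)
        + sum(math.lgamma(c + 1) for c in allele_counts.values())
        + n_het * math.log(2)
        - math.lgamma(2 * n + 1)
        - sum(math.lgamma(k + 1) for k in table.values())
    )
    return logp


def hwe_exact_test(
    genotype_counts: dict[tuple[int, int], int],
    mc_reps: int = 10_000,
    seed: int = 0,
    enumeration_limit: int = 12,
) -> float:
    """Exact conditional Hardy-Weinberg test (probability-ordering criterion).

    Conditions on the observed allele counts.  When the total number of gene
    copies is at or below ``enumeration_limit`` all gene-copy pairings are
    enumerated; otherwise the null is sampled by Monte-Carlo shuffling of
    the gene copies (``(exceedances + 1) / (reps + 1)`` estimator).
    Monomorphic input returns p = 1 by convention.
    """
    table = Counter({tuple(sorted(k)): v for k, v in genotype_counts.items() if v > 0})
    n = sum(table.values())
    copies: list[int] = []
    for (a, b), k in table.items():
        copies.extend([a, b] * k)
    if len(set(copies)) < 2:
        return 1.0
    if n < 3:
        logger.warning("HWE test on fewer than 3 individuals is weak")
    obs_logp = _log_table_prob(table)
    tol = 1e-9

    if len(copies) <= enumeration_limit:
        hits = total = 0
        copies_sorted = sorted(copies)

        def recurse(remaining: list[int], acc: Counter) -> None:
            nonlocal hits, total
            if not remaining:
                total += 1
                if _log_table_prob(acc) <= obs_logp + tol:
                    hits += 1
                return
            first = remaining[0]
            tried = set()
            for i in range(1, len(remaining)):
                if remaining[i] in tried:
                    continue
                tried.add(remaining[i])
                mult = remaining[1:].count(remaining[i])
                pair = tuple(sorted((first, remaining[i])))
                acc[pair] += 1
                sub_before = (hits, total)
                recurse(remaining[1:i] + remaining[i + 1 :], acc)
                dh, dt = hits - sub_before[0], total - sub_before[1]
                hits += dh * (mult - 1)
                total += dt * (mult - 1)
                acc[pair] -= 1

        recurse(copies_sorted, Counter())
        return hits / total

    rng = np.random.default_rng(seed)
    arr = np.array(copies)
    exceed = 0
    for _ in range(mc_reps):
        rng.shuffle(arr)
        perm = Counter(
            tuple(sorted((int(arr[2 * i]), int(arr[2 * i + 1])))) for i in range(n)
        )
        if _log_table_prob(perm) <= obs_logp + tol:
            exceed += 1
    return (exceed + 1) / (mc_reps + 1)


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_test(
    population: PopulationSample,
    locus_a: str,
    locus_b: str,
    permutations: int = 1_000,
    seed: int = 0,
    females_only: bool = True,
) -> float:
    """Permutation test of association between two loci's genotypes.

    The statistic is the G (log-likelihood-ratio) statistic of the two-locus
    genotype contingency table; the null distribution is generated by
    permuting one locus's genotypes across individuals, which preserves both
    single-locus genotype distributions.
    """
    specimens = population.females() if females_only else population.specimens
    pairs = []
    for s in specimens:
        ga, gb = s.genotype_at(locus_a), s.genotype_at(locus_b)
        if ga and gb and not ga.is_missing and not gb.is_missing:
            pairs.append((ga.alleles, gb.alleles))
    if len(pairs) < 3:
        raise ValueError(f"fewer than 3 individuals typed at both {locus_a} and {locus_b}")
    col_a = [p[0] for p in pairs]
    col_b = [p[1] for p in pairs]
    if len(set(col_a)) < 2 or len(set(col_b)) < 2:
        return 1.0

    def g_stat(xs, ys) -> float:
        joint = Counter(zip(xs, ys))
        ca, cb = Counter(xs), Counter(ys)
        n = len(xs)
        g = 0.0
        for (x, y), k in joint.items():
            expected = ca[x] * cb[y] / n
            g += 2 * k * math.log(k / expected)
        return g

    obs = g_stat(col_a, col_b)
    rng = np.random.default_rng(seed)
    perm_b = list(col_b)
    exceed = 0
    for _ in range(permutations):
        rng.shuffle(perm_b)
        if g_stat(col_a, perm_b) >= obs - 1e-12:
            exceed += 1
    return (exceed + 1) / (permutations + 1)


# ---------------------------------------------------------------------------
# population summary


@dataclass
class DiversitySummary:
    """One row of the diversity table: one population under one variant."""

    code: str
    variant: str
    n: int
    ar: float | None
    par: float | None
    ho: float
    he: float
    fis: float | None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ho <= 1.0 or not 0.0 <= self.he < 1.0:
            raise ValueError(f"{self.code}: heterozygosities out of range")


def summarize_populations(
    populations: list[PopulationSample],
    variant: str = "hIN",
    g: int = 10,
    females_only: bool = True,
) -> list[DiversitySummary]:
    """Full diversity table: N, Ar, pAr, Ho, He, Fis for every population.

    Private allelic richness for each population is computed against all the
    others in the list.
    """
    tables = {
        p.code: AlleleFrequencyTable.from_specimens(
            p.specimens, females_only=females_only, diploid_only=True
        )
        for p in populations
    }
    rows = []
    for pop in populations:
        het = observed_expected_het(pop, females_only=females_only)
        try:
            ar = rarefied_allelic_richness(tables[pop.code], g).mean
        except ValueError:
            ar = None
        par = None
        if len(tables) >= 2:
            try:
                par = rarefied_private_allelic_richness(tables, pop.code, g).mean
            except ValueError:
                par = None
        try:
            f = fis(pop, females_only=females_only)
        except ValueError:
            f = None
        n = len(pop.females()) if females_only else len(pop)
        rows.append(
            DiversitySummary(
                code=pop.code, variant=variant, n=n, ar=ar, par=par,
                ho=het.ho, he=het.he, fis=f,
            )
        )
    return rows
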