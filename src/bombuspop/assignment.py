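"""Individual assignment of specimens to subspecies reference pools.

Three scoring criteria are provided, mirroring the classic assignment-test
toolbox for codominant markers:

* a frequency log-likelihood (product over loci of the genotype probability
  under the pool's allele frequencies, with a small substitute frequency for
  alleles unseen in the pool);
* Nei's standard genetic distance between the individual (treated as a
  population with frequencies 1 or 0.5) and the pool;
* the Bayesian posterior-predictive likelihood with a Dirichlet prior of
  total weight one spread over the alleles observed anywhere (weight 1/k per
  allele).  No Markov chain is required: the marginal likelihood of a
  genotype given the pool's counts has the closed form of two sequential
  draws.

Significance is attached by a Monte-Carlo exclusion test: genotypes are
simulated from the pool and the observed score's rank gives the p-value.
Leave-one-out is always applied when scoring a pool member against its own
pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .diversity import AlleleFrequencyTable
from .types import PopulationSample, Specimen

logger = logging.getLogger(__name__)

LOG10 = math.log(10.0)


@dataclass
class ReferencePool:
    """A purified subspecies reference: allele counts plus member ids."""

    label: str  # "lusitanicus_ref" | "terrestris_ref"
    table: AlleleFrequencyTable
    member_ids: set[str] = field(default_factory=set)

    def scoring_table(self, specimen: Specimen) -> AlleleFrequencyTable:
        """Leave-one-out table when the specimen belongs to this pool."""
        if specimen.id in self.member_ids:
            return self.table.minus(specimen)
        return self.table


def frequency_loglik(
    specimen: Specimen,
    pool: ReferencePool,
    zero_freq_substitute: float = 0.01,
) -> float:
    """log10 likelihood of the multilocus genotype under pool frequencies.

    Homozygotes contribute p^2, heterozygotes 2*p_i*p_j; alleles absent from
    the pool are given the substitute frequency.  Missing loci are skipped.
    """
    table = pool.scoring_table(specimen)
    total = 0.0
    used = 0
    for g in specimen.genotypes:
        if g.is_missing or g.locus not in table.counts:
            continue
        freqs = table.freqs(g.locus)

        def f(a: int) -> float:
            return freqs.get(a, 0.0) or zero_freq_substitute

        if len(g.alleles) == 1:
            p = f(g.alleles[0])
        else:
            a, b = g.alleles[:2]
            p = f(a) ** 2 if a == b else 2 * f(a) * f(b)
        total += math.log10(p)
        used += 1
    if used == 0:
        raise ValueError(f"{specimen.id}: no locus scorable against {pool.label}")
    return total


def nei_distance_score(specimen: Specimen, pool: ReferencePool) -> float:
    """Nei's standard distance between the individual and the pool.

    The individual is treated as a population whose allele frequencies are 1
    (homozygote) or 0.5 each (heterozygote).  Identities J are summed across
    loci before the ratio: Ds = -ln( sum Jxy / sqrt(sum Jx * sum Jy) ).
    Smaller distance means better fit.
    """
    table = pool.scoring_table(specimen)
    jx = jy = jxy = 0.0
    used = 0
    for g in specimen.genotypes:
        if g.is_missing or g.locus not in table.counts:
            continue
        pool_freqs = table.freqs(g.locus)
        if not pool_freqs:
            continue
        if len(g.alleles) == 1:
            ind = {g.alleles[0]: 1.0}
        else:
            a, b = g.alleles[:2]
            ind = {a: 1.0} if a == b else {a: 0.5, b: 0.5}
        jx += sum(v * v for v in ind.values())
        jy += sum(v * v for v in pool_freqs.values())
        jxy += sum(ind[a] * pool_freqs.get(a, 0.0) for a in ind)
        used += 1
    if used == 0:
        raise ValueError(f"{specimen.id}: no shared typed loci with {pool.label}")
    if jxy <= 0:
        return math.inf
    return -math.log(jxy / math.sqrt(jx * jy))


def rannala_mountain_loglik(
    specimen: Specimen,
    pool: ReferencePool,
    k_per_locus: dict[str, int] | None = None,
) -> float:
    """log10 posterior-predictive likelihood with Dirichlet(1/k) prior.

    k is the number of distinct alleles observed at the locus across all
    pools (defaults to the pool's own allele count when not supplied).  The
    two gene copies are drawn sequentially:

        P(first = i)           = (n_i + 1/k) / (n + 1)
        P(second = j | i)      = (n_j + d_ij + 1/k) / (n + 2)

    with a factor 2 for heterozygotes.  As the pool grows this converges to
    the plain frequency likelihood.
    """
    table = pool.scoring_table(specimen)
    total = 0.0
    used = 0
    for g in specimen.genotypes:
        if g.is_missing or g.locus not in table.counts:
            continue
        counts = table.counts[g.locus]
        n = sum(counts.values())
        k = (k_per_locus or {}).get(g.locus) or max(len(table.alleles(g.locus)), 1)
        tau = 1.0 / k
        if len(g.alleles) == 1:
            p = (counts.get(g.alleles[0], 0) + tau) / (n + 1)
        else:
            a, b = g.alleles[:2]
            p_first = (counts.get(a, 0) + tau) / (n + 1)
            p_second = (counts.get(b, 0) + (a == b) + tau) / (n + 2)
            p = p_first * p_second * (1 if a == b else 2)
        total += math.log10(p)
        used += 1
    if used == 0:
        raise ValueError(f"{specimen.id}: no locus scorable against {pool.label}")
    return total


def simulate_genotype(
    pool: ReferencePool,
    loci: list[str],
    rng: np.random.Generator,
    specimen_id: str = "sim",
) -> Specimen:
    """Draw one diploid genotype by i.i.d. sampling from pool frequencies."""
    from .types import GenotypeCall, Sex

    genotypes = []
    for locus in loci:
        freqs = pool.table.freqs(locus)
        if not freqs:
            continue
        alleles = list(freqs)
        probs = np.array([freqs[a] for a in alleles])
        draw = rng.choice(len(alleles), size=2, p=probs)
        genotypes.append(
            GenotypeCall(locus=locus, alleles=(alleles[draw[0]], alleles[draw[1]]))
        )
    return Specimen(
        id=specimen_id, location="sim", sex=Sex.FEMALE, genotypes=genotypes
    )


def exclusion_test(
    specimen: Specimen,
    pool: ReferencePool,
    n_sim: int = 1_000,
    seed: int = 0,
    score_fn=frequency_loglik,
) -> float:
    """Monte-Carlo exclusion probability of the specimen from the pool.

    ``n_sim`` genotypes are simulated from the pool's posterior-mean
    frequencies and scored; p = (1 + #{simulated <= observed}) / (n_sim + 1)
    for likelihood-type scores, where lower means worse fit.  Distance
    scores are negated so the same ordering applies.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for a stable exclusion p")
    rng = np.random.default_rng(seed)
    loci = [g.locus for g in specimen.genotypes if not g.is_missing]
    sign = -1.0 if score_fn is nei_distance_score else 1.0
    observed = sign * score_fn(specimen, pool)
    worse = 0
    for i in range(n_sim):
        sim = simulate_genotype(pool, loci, rng, specimen_id=f"sim{i}")
        if sign * score_fn(sim, pool) <= observed:
            worse += 1
    return (1 + worse) / (n_sim + 1)


def purify_references(
    lusitanicus_candidates: PopulationSample,
    terrestris_candidates: PopulationSample,
    margin: float = 0.0,
    zero_freq_substitute: float = 0.01,
) -> tuple[ReferencePool, ReferencePool]:
    """Retain the candidates confidently assigned to their own group.

    Each candidate is scored leave-one-out against its own pool and against
    the other; it is retained when the log10 likelihood ratio toward its own
    group is at least ``margin``.  Pools are then rebuilt from the retained
    members only.
    """
    if not lusitanicus_candidates.specimens or not terrestris_candidates.specimens:
        raise ValueError("both candidate sets must be non-empty")

    def build(pop: PopulationSample, label: str) -> ReferencePool:
        return ReferencePool(
            label=label,
            table=AlleleFrequencyTable.from_specimens(pop.specimens),
            member_ids={s.id for s in pop.specimens},
        )

    lus = build(lusitanicus_candidates, "lusitanicus_ref")
    terr = build(terrestris_candidates, "terrestris_ref")
    retained: dict[str, list[Specimen]] = {"lusitanicus_ref": [], "terrestris_ref": []}
    for own, other in ((lus, terr), (terr, lus)):
        pop = (
            lusitanicus_candidates
            if own.label == "lusitanicus_ref"
            else terrestris_candidates
        )
        for s in pop.specimens:
            ratio = frequency_loglik(s, own, zero_freq_substitute) - frequency_loglik(
                s, other, zero_freq_substitute
            )
            if ratio >= margin:
                retained[own.label].append(s)
            else:
                logger.info("purify: dropped %s from %s (ratio %.2f)", s.id, own.label, ratio)
    for label, members in retained.items():
        if not members:
            raise ValueError(
                f"purification emptied {label}; reduce the margin (was {margin})"
            )
    lus_pure = ReferencePool(
        "lusitanicus_ref",
        AlleleFrequencyTable.from_specimens(retained["lusitanicus_ref"]),
        {s.id for s in retained["lusitanicus_ref"]},
    )
    terr_pure = ReferencePool(
        "terrestris_ref",
        AlleleFrequencyTable.from_specimens(retained["terrestris_ref"]),
        {s.id for s in retained["terrestris_ref"]},
    )
    return lus_pure, terr_pure


def categorize(
    score_lusitanicus: float,
    score_terrestris: float,
    threshold: float = 1.0,
    higher_is_better: bool = True,
) -> str:
    """Assign a category from two pool scores.

    The specimen goes to the better-scoring pool unless the absolute log10
    ratio (score difference) is below the threshold, in which case it is
    called a hybrid.  For distance scores pass ``higher_is_better=False``.
    """
    diff = score_lusitanicus - score_terrestris
    if not higher_is_better:
        diff = -diff
    if abs(diff) < threshold:
        return "hybrid"
    return "lusitanicus" if diff > 0 else "terrestris"


@dataclass
class AssignmentResult:
    specimen_id: str
    method: str
    score_lusitanicus: float
    score_terrestris: float
    category: str
    exclusion_p: float | None = None


def assign_population(
    population: PopulationSample,
    lus_pool: ReferencePool,
    terr_pool: ReferencePool,
    method: str = "frequency",
    threshold: float = 1.0,
    zero_freq_substitute: float = 0.01,
    k_per_locus: dict[str, int] | None = None,
    exclusion_sims: int = 0,
    seed: int = 0,
) -> list[AssignmentResult]:
    """Score every specimen of a population against both reference pools."""
    scorers = {
        "frequency": lambda s, p: frequency_loglik(s, p, zero_freq_substitute),
        "nei_distance": nei_distance_score,
        "rannala_mountain": lambda s, p: rannala_mountain_loglik(s, p, k_per_locus),
    }
    if method not in scorers:
        raise ValueError(f"unknown assignment method {method!r}")
    score = scorers[method]
    higher_better = method != "nei_distance"
    results = []
    for i, s in enumerate(population.specimens):
        sl = score(s, lus_pool)
        st = score(s, terr_pool)
        cat = categorize(sl, st, threshold, higher_is_better=higher_better)
        excl = None
        if exclusion_sims:
            best = lus_pool if (sl > st) == higher_better else terr_pool
            excl = exclusion_test(
                s, best, n_sim=exclusion_sims, seed=seed + i,
                score_fn=scorers["frequency"] if method == "rannala_mountain" else score,
            )
        results.append(
            AssignmentResult(
                specimen_id=s.id, method=method,
                score_lusitanicus=sl, score_terrestris=st,
                category=cat, exclusion_p=excl,
            )
        )
    return results
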