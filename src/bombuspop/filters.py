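"""Pre-analysis validation filters: missing-data screen and sibship reduction.

The sibship reduction is a deliberately simple substitute for full-likelihood
pedigree reconstruction: pairwise Queller–Goodnight moment relatedness is
estimated from sample allele frequencies, pairs above a threshold are linked,
and each connected component of the resulting graph is reduced to a single
retained specimen.  It is not equivalent to a likelihood sibship model and is
documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import PopulationSample, Specimen


@dataclass
class FilterReport:
    retained: list[Specimen] = field(default_factory=list)
    discarded: list[Specimen] = field(default_factory=list)
    reasons: dict[str, str] = field(default_factory=dict)


def filter_missing(
    specimens: list[Specimen], max_missing_fraction: float, panel_size: int
) -> FilterReport:
    """Discard specimens whose missing-locus fraction strictly exceeds the cap.

    The comparison is a strict ``>`` so a specimen sitting exactly on the
    threshold is retained.
    """
    if panel_size <= 0:
        raise ValueError("empty panel: cannot compute missing fractions")
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    report = FilterReport()
    for s in specimens:
        frac = s.missing_fraction(panel_size)
        if frac > max_missing_fraction:
            report.discarded.append(s)
            report.reasons[s.id] = (
                f"missing fraction {frac:.3f} > {max_missing_fraction:.3f}"
            )
        else:
            report.retained.append(s)
    return report


def _allele_freqs(specimens: list[Specimen]) -> dict[str, dict[int, float]]:
    counts: dict[str, dict[int, int]] = {}
    for s in specimens:
        for g in s.genotypes:
            d = counts.setdefault(g.locus, {})
            for a in g.alleles:
                d[a] = d.get(a, 0) + 1
    freqs: dict[str, dict[int, float]] = {}
    for locus, d in counts.items():
        total = sum(d.values())
        if total:
            freqs[locus] = {a: n / total for a, n in d.items()}
    return freqs


def queller_goodnight(
    x: Specimen, y: Specimen, freqs: dict[str, dict[int, float]]
) -> float:
    """Symmetrized Queller–Goodnight moment estimator of pairwise relatedness.

    Numerators and denominators are summed across loci before taking the
    ratio; the two directed estimates are averaged.  Loci missing in either
    specimen, or monomorphic, are skipped.
    """

    def directed(a: Specimen, b: Specimen) -> tuple[float, float]:
        num = den = 0.0
        for ga in a.genotypes:
            p = freqs.get(ga.locus)
            gb = b.genotype_at(ga.locus)
            if p is None or len(p) < 2 or gb is None:
                continue
            if len(ga.alleles) != 2 or len(gb.alleles) != 2:
                continue
            a1, a2 = ga.alleles
            b1, b2 = gb.alleles
            sim = 0.5 * ((a1 == b1) + (a1 == b2) + (a2 == b1) + (a2 == b2))
            num += sim - p[a1] - p[a2]
            den += 1 + (a1 == a2) - p[a1] - p[a2]
        return num, den

    n1, d1 = directed(x, y)
    n2, d2 = directed(y, x)
    if d1 == 0 and d2 == 0:
        raise ValueError(
            f"relatedness undefined for pair ({x.id}, {y.id}): "
            "no shared polymorphic diploid loci"
        )
    parts = [n / d for n, d in ((n1, d1), (n2, d2)) if d != 0]
    return float(np.mean(parts))


def relatedness_filter(
    population: PopulationSample,
    threshold: float = 0.25,
    seed: int = 0,
) -> set[str]:
    """Reduce putative sib groups to one member each; returns retained ids.

    Connected components of the over-threshold relatedness graph are each
    collapsed to a single specimen.  The retained member is chosen as the one
    with the fewest missing loci, ties broken by a seeded draw, so the result
    is deterministic for a given seed.
    """
    specimens = [s for s in population.specimens if any(not g.is_missing for g in s.genotypes)]
    if len(specimens) < 2:
        return {s.id for s in population.specimens}
    freqs = _allele_freqs(specimens)
    if all(len(p) < 2 for p in freqs.values()):
        raise ValueError("monomorphic panel: relatedness undefined")

    parent = {s.id: s.id for s in specimens}

    def find(i: str) -> str:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(specimens)):
        for j in range(i + 1, len(specimens)):
            try:
                r = queller_goodnight(specimens[i], specimens[j], freqs)
            except ValueError:
                continue
            if r >= threshold:
                parent[find(specimens[i].id)] = find(specimens[j].id)

    rng = np.random.default_rng(seed)
    components: dict[str, list[Specimen]] = {}
    for s in specimens:
        components.setdefault(find(s.id), []).append(s)
    retained: set[str] = set()
    for members in components.values():
        members.sort(key=lambda s: (sum(g.is_missing for g in s.genotypes), s.id))
        best_missing = sum(g.is_missing for g in members[0].genotypes)
        candidates = [
            m for m in members
            if sum(g.is_missing for g in m.genotypes) == best_missing
        ]
        retained.add(candidates[int(rng.integers(len(candidates)))].id)
    # specimens with fully missing genotypes pass through untouched
    retained |= {s.id for s in population.specimens} - {s.id for s in specimens}
    return retained
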