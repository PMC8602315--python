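"""Diversity statistics against hand counts and exhaustive oracles."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bombuspop.diversity import (
    AlleleFrequencyTable,
    fis,
    hwe_exact_test,
    ld_test,
    null_allele_estimates,
    observed_expected_het,
    rarefied_allelic_richness,
    rarefied_private_allelic_richness,
)
from bombuspop.types import GenotypeCall, PopulationSample, Sex, Specimen


def _pop(genotypes_per_locus, code="P"):
    """Population from {locus: [allele-pair, ...]} with aligned individuals."""
    n = max(len(v) for v in genotypes_per_locus.values())
    specimens = []
    for i in range(n):
        calls = []
        for locus, pairs in genotypes_per_locus.items():
            if i < len(pairs):
                calls.append(GenotypeCall(locus=locus, alleles=tuple(pairs[i])))
        specimens.append(
            Specimen(id=f"{code}{i}", location=code, sex=Sex.FEMALE, genotypes=calls)
        )
    return PopulationSample(code=code, specimens=specimens)


# ---------------------------------------------------------------------------
# heterozygosity


def test_het_hand_count():
    pop = _pop({"L1": [(1, 1), (1, 2), (1, 2), (2, 2)]})
    res = observed_expected_het(pop)
    assert res.ho == pytest.approx(0.5)
    assert res.he == pytest.approx(0.5)


def test_monomorphic_locus_is_zero():
    pop = _pop({"L1": [(1, 1), (1, 1)]})
    res = observed_expected_het(pop)
    assert res.ho == 0.0 and res.he == 0.0


def test_he_invariant_under_relabeling():
    pop1 = _pop({"L1": [(1, 2), (2, 3), (1, 3), (3, 3)]})
    pop2 = _pop({"L1": [(9, 7), (7, 5), (9, 5), (5, 5)]})  # same pattern, new labels
    a = observed_expected_het(pop1)
    b = observed_expected_het(pop2)
    assert a.he == pytest.approx(b.he)
    assert a.ho == pytest.approx(b.ho)


def test_females_only_convention():
    """Male hemizygous calls never contaminate Ho/He when the flag is set."""
    pop = _pop({"L1": [(1, 2), (1, 2)]})
    pop.specimens.append(
        Specimen(id="m1", location="P", sex=Sex.MALE,
                 genotypes=[GenotypeCall(locus="L1", alleles=(3,))])
    )
    res = observed_expected_het(pop, females_only=True)
    assert 3 not in {1, 2} and res.he == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# rarefaction, with exhaustive subset enumeration as the oracle


def _ar_brute(counts: dict[int, int], g: int) -> float:
    copies = [a for a, n in counts.items() for _ in range(n)]
    subsets = list(itertools.combinations(range(len(copies)), g))
    total = sum(len({copies[i] for i in sub}) for sub in subsets)
    return total / len(subsets)


def test_ar_worked_example():
    table = AlleleFrequencyTable({"L1": Counter({1: 9, 2: 1})})
    res = rarefied_allelic_richness(table, g=2)
    assert res.mean == pytest.approx(1.2)
    assert res.mean == pytest.approx(_ar_brute({1: 9, 2: 1}, 2))


def test_ar_equals_allele_count_at_full_depth():
    counts = {1: 4, 2: 3, 3: 3}
    table = AlleleFrequencyTable({"L1": Counter(counts)})
    assert rarefied_allelic_richness(table, g=10).mean == pytest.approx(3.0)


def test_ar_monomorphic_is_one():
    table = AlleleFrequencyTable({"L1": Counter({1: 8})})
    for g in (2, 5, 8):
        assert rarefied_allelic_richness(table, g).mean == pytest.approx(1.0)


@settings(deadline=None, max_examples=40)
@given(
    counts=st.lists(st.integers(1, 6), min_size=2, max_size=4).filter(
        lambda c: 4 <= sum(c) <= 12
    ),
    g=st.integers(2, 4),
)
def test_ar_matches_enumeration(counts, g):
    cdict = {100 + i: c for i, c in enumerate(counts)}
    table = AlleleFrequencyTable({"L1": Counter(cdict)})
    assert rarefied_allelic_richness(table, g).mean == pytest.approx(
        _ar_brute(cdict, g), abs=1e-12
    )


def test_ar_nondecreasing_in_g():
    table = AlleleFrequencyTable({"L1": Counter({1: 5, 2: 4, 3: 3})})
    values = [rarefied_allelic_richness(table, g).mean for g in range(2, 13)]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


def _par_brute(focal: dict[int, int], other: dict[int, int], g: int) -> float:
    fc = [a for a, n in focal.items() for _ in range(n)]
    oc = [a for a, n in other.items() for _ in range(n)]
    fsubs = list(itertools.combinations(range(len(fc)), g))
    osubs = list(itertools.combinations(range(len(oc)), g))
    total = 0
    for fs in fsubs:
        fset = {fc[i] for i in fs}
        for os_ in osubs:
            oset = {oc[i] for i in os_}
            total += len(fset - oset)
    return total / (len(fsubs) * len(osubs))


def test_par_worked_example_vs_enumeration():
    focal = {1: 3, 2: 1}
    other = {1: 4}
    tables = {
        "F": AlleleFrequencyTable({"L1": Counter(focal)}),
        "O": AlleleFrequencyTable({"L1": Counter(other)}),
    }
    res = rarefied_private_allelic_richness(tables, "F", g=2)
    assert res.mean == pytest.approx(_par_brute(focal, other, 2), abs=1e-12)


def test_par_private_allele_contributes_fully():
    # allele 2 exists only in the focal population
    tables = {
        "F": AlleleFrequencyTable({"L1": Counter({1: 5, 2: 5})}),
        "O": AlleleFrequencyTable({"L1": Counter({1: 10})}),
    }
    res = rarefied_private_allelic_richness(tables, "F", g=2)
    from bombuspop.diversity import _q_present

    assert res.mean == pytest.approx(_q_present(10, 5, 2), abs=1e-12)


def test_par_fixed_everywhere_vanishes():
    tables = {
        "F": AlleleFrequencyTable({"L1": Counter({1: 10})}),
        "O": AlleleFrequencyTable({"L1": Counter({1: 10})}),
    }
    assert rarefied_private_allelic_richness(tables, "F", g=4).mean == pytest.approx(0.0)


@settings(deadline=None, max_examples=25)
@given(
    focal=st.lists(st.integers(1, 4), min_size=1, max_size=3).filter(
        lambda c: 3 <= sum(c) <= 8
    ),
    other=st.lists(st.integers(1, 4), min_size=1, max_size=3).filter(
        lambda c: 3 <= sum(c) <= 8
    ),
    g=st.integers(2, 3),
)
def test_par_matches_enumeration(focal, other, g):
    fdict = {100 + i: c for i, c in enumerate(focal)}
    odict = {100 + i: c for i, c in enumerate(other)}  # overlapping labels
    tables = {
        "F": AlleleFrequencyTable({"L1": Counter(fdict)}),
        "O": AlleleFrequencyTable({"L1": Counter(odict)}),
    }
    assert rarefied_private_allelic_richness(tables, "F", g).mean == pytest.approx(
        _par_brute(fdict, odict, g), abs=1e-12
    )


def test_par_bounded_by_ar(sim_study):
    tables = {
        p.code: AlleleFrequencyTable.from_specimens(p.specimens, females_only=True)
        for p in sim_study.populations
    }
    for code in tables:
        ar = rarefied_allelic_richness(tables[code], 10).mean
        par = rarefied_private_allelic_richness(tables, code, 10).mean
        assert 0.0 <= par <= ar


# ---------------------------------------------------------------------------
# inbreeding


def test_fis_all_homozygotes_is_one():
    pop = _pop({"L1": [(1, 1), (1, 1), (2, 2), (2, 2)]})
    assert fis(pop) == pytest.approx(1.0)


def test_fis_hardy_weinberg_simulation_near_zero():
    rng = np.random.default_rng(42)
    genotypes = {}
    for locus in range(5):
        freqs = rng.dirichlet(np.ones(4))
        draws = rng.choice(4, size=(600, 2), p=freqs)
        genotypes[f"L{locus}"] = [tuple(sorted(d)) for d in draws]
    pop = _pop(genotypes)
    assert abs(fis(pop)) < 0.05


def test_fis_monomorphic_undefined():
    pop = _pop({"L1": [(1, 1), (1, 1)]})
    with pytest.raises(ValueError, match="monomorphic"):
        fis(pop)


# ---------------------------------------------------------------------------
# null alleles


def test_null_allele_formulas():
    # He=0.5, Ho=0.25 at one locus: chakraborty 1/3, brookfield 1/6
    pop = _pop({"L1": [(1, 2), (1, 2), (1, 1), (1, 1), (1, 1), (2, 2), (2, 2), (2, 2)]})
    het = observed_expected_het(pop)
    assert het.ho == pytest.approx(0.25)
    assert het.he == pytest.approx(0.5)
    res = null_allele_estimates(pop)
    assert res.chakraborty["L1"] == pytest.approx(0.25 / 0.75)
    assert res.brookfield1["L1"] == pytest.approx(0.25 / 1.5)
    assert res.homozygote_excess_flag["L1"]


def test_null_estimates_zero_when_ho_equals_he():
    pop = _pop({"L1": [(1, 2), (1, 2), (1, 1), (2, 2)]})
    res = null_allele_estimates(pop)
    assert res.chakraborty["L1"] == pytest.approx(0.0)
    assert res.brookfield1["L1"] == pytest.approx(0.0)
    assert not res.homozygote_excess_flag["L1"]


def test_chakraborty_dominates_brookfield():
    """(He-Ho)/(He+Ho) >= (He-Ho)/(1+He) whenever He > Ho > 0."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        he = rng.uniform(0.05, 0.95)
        ho = rng.uniform(0.01, he)
        assert (he - ho) / (he + ho) >= (he - ho) / (1 + he) - 1e-12


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def _hwe_brute(genotype_counts):
    """Independent oracle: enumerate all pairings of labeled gene copies."""
    copies = []
    for (a, b), k in genotype_counts.items():
        copies.extend([a, b] * k)

    def all_matchings(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for i in range(len(rest)):
            pair = tuple(sorted((first, rest[i])))
            for sub in all_matchings(rest[:i] + rest[i + 1 :]):
                yield [pair] + sub

    def log_prob(table):
        n = sum(table.values())
        ac = Counter()
        n_het = 0
        for (a, b), k in table.items():
            ac[a] += k
            ac[b] += k
            if a != b:
                n_het += k
        return (
            math.lgamma(n + 1)
            + sum(math.lgamma(c + 1) for c in ac.values())
            + n_het * math.log(2)
            - math.lgamma(2 * n + 1)
            - sum(math.lgamma(k + 1) for k in table.values())
        )

    obs = log_prob(Counter({tuple(sorted(k)): v for k, v in genotype_counts.items() if v}))
    tables = [Counter(m) for m in all_matchings(copies)]
    hits = sum(log_prob(t) <= obs + 1e-9 for t in tables)
    return hits / len(tables)


@pytest.mark.parametrize(
    "counts",
    [
        {(1, 1): 1, (2, 2): 1},
        {(1, 2): 2, (1, 1): 1},
        {(1, 1): 2, (1, 2): 1, (2, 2): 1},
        {(1, 2): 1, (1, 3): 1, (2, 3): 1},
    ],
)
def test_hwe_enumeration_matches_bruteforce(counts):
    p = hwe_exact_test(counts)
    assert 0.0 < p <= 1.0
    assert p == pytest.approx(_hwe_brute(counts), abs=1e-9)


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test({(1, 1): 10}) == 1.0


def test_hwe_perfect_proportions_not_rejected():
    rng = np.random.default_rng(1)
    draws = rng.choice([1, 2], size=(400, 2), p=[0.5, 0.5])
    counts = Counter(tuple(sorted(d)) for d in draws)
    p = hwe_exact_test(dict(counts), mc_reps=2_000, seed=3)
    assert p >= 0.05


def test_hwe_mc_deterministic_under_seed():
    rng = np.random.default_rng(2)
    draws = rng.choice([1, 2, 3], size=(60, 2), p=[0.5, 0.3, 0.2])
    counts = dict(Counter(tuple(sorted(d)) for d in draws))
    assert hwe_exact_test(counts, mc_reps=500, seed=9) == hwe_exact_test(
        counts, mc_reps=500, seed=9
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium


def test_ld_duplicated_locus_detected():
    rng = np.random.default_rng(5)
    pairs = [tuple(sorted(rng.choice([1, 2, 3], size=2))) for _ in range(30)]
    pop = _pop({"L1": pairs, "L2": pairs})  # perfect dependence
    assert ld_test(pop, "L1", "L2", permutations=500, seed=0) <= 0.01


def test_ld_monomorphic_partner_is_one():
    rng = np.random.default_rng(6)
    pairs = [tuple(sorted(rng.choice([1, 2], size=2))) for _ in range(20)]
    pop = _pop({"L1": pairs, "L2": [(7, 7)] * 20})
    assert ld_test(pop, "L1", "L2", permutations=100, seed=0) == 1.0


def test_ld_independent_loci_calibrated():
    """p-values roughly uniform for independently simulated loci."""
    from scipy import stats

    rng = np.random.default_rng(7)
    pvals = []
    for _ in range(40):
        a = [tuple(sorted(rng.choice([1, 2, 3], size=2))) for _ in range(40)]
        b = [tuple(sorted(rng.choice([1, 2, 3], size=2))) for _ in range(40)]
        pop = _pop({"L1": a, "L2": b})
        pvals.append(ld_test(pop, "L1", "L2", permutations=120,
                             seed=int(rng.integers(2**31))))
    assert stats.kstest(pvals, "uniform").pvalue > 0.001
    assert 0.3 < np.mean(pvals) < 0.7
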