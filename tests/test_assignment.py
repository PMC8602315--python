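"""Assignment criteria, exclusion calibration and reference purification."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from bombuspop.assignment import (
    ReferencePool,
    assign_population,
    categorize,
    exclusion_test,
    frequency_loglik,
    nei_distance_score,
    purify_references,
    rannala_mountain_loglik,
    simulate_genotype,
)
from bombuspop.diversity import AlleleFrequencyTable
from bombuspop.types import GenotypeCall, PopulationSample, Sex, Specimen

from conftest import draw_individuals


def _pool(counts_per_locus, label="lusitanicus_ref"):
    return ReferencePool(
        label=label,
        table=AlleleFrequencyTable(
            {locus: Counter(c) for locus, c in counts_per_locus.items()}
        ),
    )


def _spec(alleles_per_locus, sid="x"):
    return Specimen(
        id=sid, location="X", sex=Sex.FEMALE,
        genotypes=[
            GenotypeCall(locus=locus, alleles=tuple(a))
            for locus, a in alleles_per_locus.items()
        ],
    )


# ---------------------------------------------------------------------------
# frequency likelihood


def test_fixed_pool_gives_zero_loglik():
    pool = _pool({"L1": {1: 20}, "L2": {5: 20}})
    s = _spec({"L1": (1, 1), "L2": (5, 5)})
    assert frequency_loglik(s, pool) == pytest.approx(0.0)


def test_het_at_half_frequencies():
    pool = _pool({"L1": {1: 10, 2: 10}})
    s = _spec({"L1": (1, 2)})
    assert frequency_loglik(s, pool) == pytest.approx(math.log10(0.5))


def test_unseen_allele_uses_substitute():
    pool = _pool({"L1": {1: 10}})
    s = _spec({"L1": (1, 9)})
    assert frequency_loglik(s, pool, zero_freq_substitute=0.01) == pytest.approx(
        math.log10(2 * 0.01 * 1.0)
    )


def test_all_loci_missing_errors():
    pool = _pool({"L1": {1: 10}})
    s = _spec({"L1": ()})
    with pytest.raises(ValueError, match="scorable"):
        frequency_loglik(s, pool)


# ---------------------------------------------------------------------------
# Nei standard distance


def test_nei_zero_for_matching_fixed_pool():
    pool = _pool({"L1": {1: 10}, "L2": {7: 10}})
    s = _spec({"L1": (1, 1), "L2": (7, 7)})
    assert nei_distance_score(s, pool) == pytest.approx(0.0)


def test_nei_direct_formula():
    pool = _pool({"L1": {1: 6, 2: 4}})
    s = _spec({"L1": (1, 2)})
    jx = 0.5
    jy = 0.6**2 + 0.4**2
    jxy = 0.5 * 0.6 + 0.5 * 0.4
    assert nei_distance_score(s, pool) == pytest.approx(
        -math.log(jxy / math.sqrt(jx * jy))
    )


def test_nei_symmetric_pools_equidistant():
    a = _pool({"L1": {1: 5, 2: 5}})
    b = _pool({"L1": {1: 5, 2: 5}}, label="terrestris_ref")
    s = _spec({"L1": (1, 2)})
    assert nei_distance_score(s, a) == pytest.approx(nei_distance_score(s, b))


def test_nei_maximally_distinct_pools():
    near = _pool({"L1": {1: 10}})
    far = _pool({"L1": {2: 10}}, label="terrestris_ref")
    s = _spec({"L1": (1, 1)})
    assert nei_distance_score(s, near) == pytest.approx(0.0)
    assert nei_distance_score(s, far) == math.inf


# ---------------------------------------------------------------------------
# Rannala-Mountain posterior predictive


def test_rm_empty_pool_worked_example():
    pool = _pool({"L1": {}})
    pool.table.counts["L1"] = Counter()
    s = _spec({"L1": (1, 1)})
    lik = rannala_mountain_loglik(s, pool, k_per_locus={"L1": 2})
    assert 10**lik == pytest.approx(0.375)  # (1/2) * (3/2)/2


def test_rm_converges_to_frequency_likelihood():
    n = 100_000
    pool = _pool({"L1": {1: int(0.7 * n), 2: int(0.3 * n)}})
    for genotype in [(1, 1), (1, 2), (2, 2)]:
        s = _spec({"L1": genotype})
        assert rannala_mountain_loglik(s, pool) == pytest.approx(
            frequency_loglik(s, pool), abs=1e-3
        )


def test_rm_symmetric_pools_equal():
    a = _pool({"L1": {1: 8, 2: 8}})
    b = _pool({"L1": {2: 8, 1: 8}}, label="terrestris_ref")
    s = _spec({"L1": (1, 2)})
    assert rannala_mountain_loglik(s, a) == pytest.approx(rannala_mountain_loglik(s, b))


def test_scores_invariant_under_relabeling_and_reordering():
    """Renaming alleles and shuffling locus order changes no criterion."""
    pool1 = _pool({"L1": {1: 6, 2: 4}, "L2": {3: 5, 4: 5}})
    pool2 = _pool({"L2": {30: 5, 40: 5}, "L1": {10: 6, 20: 4}})
    s1 = _spec({"L1": (1, 2), "L2": (3, 3)})
    s2 = _spec({"L2": (30, 30), "L1": (10, 20)})
    for fn in (frequency_loglik, nei_distance_score, rannala_mountain_loglik):
        assert fn(s1, pool1) == pytest.approx(fn(s2, pool2))


# ---------------------------------------------------------------------------
# exclusion test


def test_exclusion_counting_rule():
    # degenerate single-allele pool: every simulated score equals the
    # specimen's, so the count hits n_sim and p = 1
    pool = _pool({"L1": {1: 50}})
    s = _spec({"L1": (1, 1)})
    assert exclusion_test(s, pool, n_sim=100, seed=0) == pytest.approx(1.0)


def test_exclusion_rejects_foreign_specimen(diverged_pools):
    lus = ReferencePool("lusitanicus_ref", AlleleFrequencyTable(
        {l: Counter({a: int(round(f * 200)) for a, f in fr.items() if f > 0})
         for l, fr in diverged_pools["lus"].items()}
    ))
    rng = np.random.default_rng(0)
    (foreign,) = draw_individuals(diverged_pools["terr"], 1, rng, prefix="terr")
    assert exclusion_test(foreign, lus, n_sim=1_000, seed=1) <= 0.01


def test_exclusion_uniform_under_null(diverged_pools):
    """Specimens simulated from the pool itself get uniform p-values."""
    pool = ReferencePool("lusitanicus_ref", AlleleFrequencyTable(
        {l: Counter({a: int(round(f * 400)) for a, f in fr.items() if f > 0})
         for l, fr in diverged_pools["lus"].items()}
    ))
    rng = np.random.default_rng(3)
    loci = list(diverged_pools["lus"])
    pvals = [
        exclusion_test(simulate_genotype(pool, loci, rng, f"n{i}"), pool,
                       n_sim=200, seed=1000 + i)
        for i in range(200)
    ]
    assert stats.kstest(pvals, "uniform").pvalue > 0.001


def test_exclusion_requires_enough_sims():
    pool = _pool({"L1": {1: 10}})
    with pytest.raises(ValueError, match="n_sim"):
        exclusion_test(_spec({"L1": (1, 1)}), pool, n_sim=10)


# ---------------------------------------------------------------------------
# reference purification and categorization


def _candidate_pops(diverged_pools, n=15, with_f1=0, seed=21):
    rng = np.random.default_rng(seed)
    lus = draw_individuals(diverged_pools["lus"], n, rng, prefix="lus")
    terr = draw_individuals(diverged_pools["terr"], n, rng, prefix="terr")
    f1 = draw_individuals(
        diverged_pools["lus"], with_f1, rng, prefix="f1",
        hybrid_with=diverged_pools["terr"],
    )
    return (
        PopulationSample(code="LREF", specimens=lus + f1),
        PopulationSample(code="TREF", specimens=terr),
    )


def test_purify_retains_diverged_members(diverged_pools):
    lpop, tpop = _candidate_pops(diverged_pools)
    lus, terr = purify_references(lpop, tpop, margin=0.0)
    assert len(lus.member_ids) >= 13
    assert len(terr.member_ids) >= 13


def test_purify_removes_f1_preferentially(diverged_pools):
    lpop, tpop = _candidate_pops(diverged_pools, with_f1=6)
    lus, _ = purify_references(lpop, tpop, margin=1.0)
    f1_kept = sum(i.startswith("f1") for i in lus.member_ids)
    pure_kept = sum(i.startswith("lus") for i in lus.member_ids)
    assert f1_kept / 6 < pure_kept / 15


def test_purify_infinite_margin_errors(diverged_pools):
    lpop, tpop = _candidate_pops(diverged_pools)
    with pytest.raises(ValueError, match="margin"):
        purify_references(lpop, tpop, margin=math.inf)


def test_categorize_rules():
    assert categorize(-2.0, -5.0, threshold=1.0) == "lusitanicus"
    assert categorize(-5.0, -2.0, threshold=1.0) == "terrestris"
    assert categorize(-3.0, -3.0, threshold=1.0) == "hybrid"
    # distance scores: smaller is better
    assert categorize(0.1, 2.5, threshold=1.0, higher_is_better=False) == "lusitanicus"


def test_f1_hybrids_mostly_called_hybrid(diverged_pools):
    lpop, tpop = _candidate_pops(diverged_pools, n=40, seed=8)
    lus, terr = purify_references(lpop, tpop)
    rng = np.random.default_rng(9)
    f1 = draw_individuals(diverged_pools["lus"], 40, rng, prefix="f1",
                          hybrid_with=diverged_pools["terr"])
    results = assign_population(
        PopulationSample(code="F1", specimens=f1), lus, terr, threshold=1.0
    )
    share_hybrid = np.mean([r.category == "hybrid" for r in results])
    pure = assign_population(
        PopulationSample(code="L", specimens=draw_individuals(
            diverged_pools["lus"], 40, rng, prefix="pl")), lus, terr, threshold=1.0)
    share_lus = np.mean([r.category == "lusitanicus" for r in pure])
    # F1s land in the hybrid band far more often than pure specimens do
    assert share_hybrid > np.mean([r.category == "hybrid" for r in pure])
    assert share_lus > 0.5
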