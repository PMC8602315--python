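"""Effect of hybridization on genetic diversity: the study's core inference.

Every population is analysed under three dataset variants: *hIN* (all
specimens), *hOUT* (detected hybrids -- morphological and discrepant -- and
naturalized foreign individuals removed) and *rOUT* (a random removal of the
same size, the null for the paired comparison).  Diversity summaries of the
variants are compared metric-by-metric with a paired Wilcoxon signed-rank
test under Bonferroni control, and diversity (or its change, DHE = He_hIN -
He_hOUT) is regressed on the per-location hybrid percentage.

The Wilcoxon conventions deliberately reproduce the behaviour of the
standard R implementation: zero differences are dropped before ranking,
midranks are used for tied absolute differences, the exact distribution is
enumerated when there are no ties and at most 25 pairs, and otherwise a
normal approximation with continuity correction and tie-corrected variance
is used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diversity import DiversitySummary
from .haplotyping import HybridCall
from .types import DatasetVariant, PopulationSample, VariantLabel

logger = logging.getLogger(__name__)

REMOVED_CATEGORIES = {"morph_hybrid", "discrepant_hybrid", "naturalized_foreign"}


def build_variants(
    population: PopulationSample,
    hybrid_calls: dict[str, HybridCall],
    seed: int = 0,
) -> dict[str, DatasetVariant]:
    """Build the hIN / hOUT / rOUT variants of one population.

    hOUT removes every specimen whose hybrid call is a morphological hybrid,
    a discrepant hybrid or a naturalized foreign individual; rOUT removes a
    uniformly random subset of identical size (reproducible from the seed).
    """
    all_ids = [s.id for s in population.specimens]
    missing = [i for i in all_ids if i not in hybrid_calls]
    if missing:
        raise ValueError(f"{population.code}: no hybrid call for {missing[:5]}")
    removed = {
        i for i in all_ids if hybrid_calls[i].category in REMOVED_CATEGORIES
    }
    hout_ids = set(all_ids) - removed
    if not hout_ids:
        raise ValueError(f"{population.code}: hOUT would be empty")
    rng = np.random.default_rng(seed)
    random_removed = set(
        rng.choice(all_ids, size=len(removed), replace=False).tolist()
    ) if removed else set()
    logger.info(
        "%s: removed %d hybrids (hOUT), %d random (rOUT) of %d",
        population.code, len(removed), len(random_removed), len(all_ids),
    )
    return {
        "hIN": DatasetVariant(VariantLabel.HIN, population, set(all_ids)),
        "hOUT": DatasetVariant(VariantLabel.HOUT, population, hout_ids),
        "rOUT": DatasetVariant(
            VariantLabel.ROUT, population, set(all_ids) - random_removed, removal_seed=seed
        ),
    }


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass
class WilcoxonResult:
    metric: str
    n_pairs_nonzero: int
    v: float  # sum of positive ranks
    p: float
    method: str  # "exact" | "normal_approx"


def _exact_signed_rank_p(v: float, n: int) -> float:
    """Two-sided exact p for integer ranks 1..n without ties (2^n enumeration
    via dynamic programming over the distribution of the positive-rank sum)."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    counts /= counts.sum()
    vi = int(round(v))
    p_le = counts[: vi + 1].sum()
    p_ge = counts[vi:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def paired_wilcoxon(x, y, metric: str = "") -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    V is the sum of the ranks of positive differences x - y.  Zeros are
    dropped; midranks are assigned to tied absolute differences.  The exact
    path (full sign enumeration) is used when there are no ties among the
    absolute differences and n <= 25; otherwise the normal approximation
    with continuity correction and tie-corrected variance applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: test undefined")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)  # midranks
    v = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n
    if not has_ties and n <= 25:
        p = _exact_signed_rank_p(v, n)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        tie_counts = np.unique(absd, return_counts=True)[1]
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        z = v - mu
        z -= math.copysign(0.5, z) if z != 0 else 0.0
        z /= math.sqrt(sigma2)
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        method = "normal_approx"
    return WilcoxonResult(metric=metric, n_pairs_nonzero=n, v=v, p=p, method=method)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance level alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# regressions


@dataclass
class EffectRow:
    code: str
    hybrid_pct: float  # 0-100 scale
    he_hin: float
    he_hout: float

    @property
    def delta_he(self) -> float:
        """DHE = He_hIN - He_hOUT (positive when hybrids raise diversity)."""
        return self.he_hin - self.he_hout


@dataclass
class EffectResult:
    rows: list[EffectRow]
    use_delta: bool
    slope: float
    intercept: float
    r_squared: float
    p: float


def regress_effect(rows: list[EffectRow], use_delta: bool = True) -> EffectResult:
    """OLS of He_hIN (or DHE) on the hybrid percentage across locations.

    The slope p-value is the two-sided t test with n - 2 degrees of
    freedom.  Hybrid percentage is on the 0-100 scale (r^2 is unaffected;
    slope units are per percentage point).
    """
    if len(rows) < 3:
        raise ValueError("regression needs >= 3 locations")
    x = np.array([r.hybrid_pct for r in rows])
    y = np.array([r.delta_he if use_delta else r.he_hin for r in rows])
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in hybrid percentage: regression undefined")
    fit = stats.linregress(x, y)
    return EffectResult(
        rows=rows,
        use_delta=use_delta,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
    )


# ---------------------------------------------------------------------------
# full comparison table


METRICS = ["n", "ar", "par", "ho", "he", "fis"]


@dataclass
class ComparisonReport:
    """Wilcoxon V and p per metric for hIN/hOUT and hIN/rOUT."""

    results: dict[str, dict[str, WilcoxonResult]]  # pair -> metric -> result
    alpha: float
    m: int
    populations: list[str]

    @property
    def adjusted_level(self) -> float:
        return bonferroni(self.alpha, self.m)

    def significant(self, pair: str, metric: str) -> bool:
        return self.results[pair][metric].p < self.adjusted_level


def compare_all(
    summaries: dict[str, list[DiversitySummary]],
    exclude_codes: set[str] | None = None,
    alpha: float = 0.05,
    metrics: list[str] | None = None,
) -> ComparisonReport:
    """Paired Wilcoxon tests of every diversity metric across variants.

    ``summaries`` maps variant label -> list of per-population summaries.
    Pooled rows (e.g. a whole-peninsula aggregate) should be excluded via
    ``exclude_codes`` to avoid oversampling.  Metrics missing for any
    population are skipped with a warning.
    """
    metrics = metrics or METRICS
    exclude = exclude_codes or set()
    byv = {
        label: {s.code: s for s in rows if s.code not in exclude}
        for label, rows in summaries.items()
    }
    if "hIN" not in byv:
        raise ValueError("summaries must include the hIN variant")
    codes = sorted(byv["hIN"])
    results: dict[str, dict[str, WilcoxonResult]] = {}
    for other in ("hOUT", "rOUT"):
        if other not in byv:
            continue
        shared = [c for c in codes if c in byv[other]]
        if len(shared) < 3:
            raise ValueError(f"hIN/{other}: fewer than 3 shared populations")
        pair_key = f"hIN/{other}"
        results[pair_key] = {}
        for metric in metrics:
            x = [getattr(byv["hIN"][c], metric) for c in shared]
            y = [getattr(byv[other][c], metric) for c in shared]
            if any(v is None for v in x + y):
                logger.warning("%s: metric %s missing for a population, skipped", pair_key, metric)
                continue
            try:
                results[pair_key][metric] = paired_wilcoxon(x, y, metric=metric)
            except ValueError as err:
                logger.warning("%s %s: %s", pair_key, metric, err)
    return ComparisonReport(
        results=results, alpha=alpha, m=len(metrics), populations=codes
    )
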