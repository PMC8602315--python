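import numpy as np
import pytest

from bombuspop import tables
from bombuspop.haplotyping import default_scheme
from bombuspop.simulate import SimConfig, draw_pools, simulate_study
from bombuspop.types import GenotypeCall, Sex, Specimen


@pytest.fixture(scope="session")
def sim_study():
    """Default-sized synthetic survey with mitochondrial sequences."""
    return simulate_study(SimConfig(seed=7), scheme=default_scheme())


@pytest.fixture(scope="session")
def survey_pops():
    """Specimen-level expansion of the bundled survey count table."""
    return {p.code: p for p in tables.survey_specimens()}


def draw_individuals(pool_freqs, n, rng, prefix="ind", hybrid_with=None):
    """Diploid individuals drawn i.i.d. from per-locus allele frequencies.

    With ``hybrid_with`` set to a second pool, one gene copy per locus comes
    from each pool (F1 individuals).
    """
    out = []
    for i in range(n):
        genotypes = []
        for locus, freqs in pool_freqs.items():
            alleles = list(freqs)
            p = np.array(list(freqs.values()))
            a = alleles[rng.choice(len(alleles), p=p)]
            if hybrid_with is not None:
                freqs2 = hybrid_with[locus]
                alleles2 = list(freqs2)
                p2 = np.array(list(freqs2.values()))
                b = alleles2[rng.choice(len(alleles2), p=p2)]
            else:
                b = alleles[rng.choice(len(alleles), p=p)]
            genotypes.append(GenotypeCall(locus=locus, alleles=(a, b)))
        out.append(
            Specimen(id=f"{prefix}{i:03d}", location=prefix, sex=Sex.FEMALE,
                     genotypes=genotypes)
        )
    return out


@pytest.fixture(scope="session")
def diverged_pools():
    """Two strongly diverged subspecies allele pools (9 loci)."""
    cfg = SimConfig(seed=11, pool_concentration=0.4)
    rng = np.random.default_rng(cfg.seed)
    return draw_pools(cfg, rng)
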