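"""Mitochondrial haplotype calling and morphology/haplotype hybrid screening.

Two subspecies are distinguished by their mitochondrial lineage: an Iberian
haplotype (H1) carried by the endemic *B. t. lusitanicus* matriline and a
central-European haplotype (H2) carried by *B. t. terrestris*, the subspecies
used in commercial rearing.  A specimen whose haplotype contradicts the
subspecies expected from its morphology is a *discrepant hybrid* -- the
primary introgression signal.

Haplotypes are called from sequence by extracting an in-silico amplicon
between a primer pair and applying diagnostic rules (SNP states and/or
restriction-site presence).  The diagnostic content ships as an editable
configuration; the packaged defaults are illustrative placeholders, since
published schemes define their diagnostic sites in external references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import Haplotype, Morphotype, PopulationSample, Sex, Specimen

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _mismatches(primer: str, window: str) -> int:
    return sum(w not in _IUPAC.get(p, p) for p, w in zip(primer, window))


def _find_matches(template: str, primer: str, max_mismatches: int) -> list[int]:
    k = len(primer)
    return [
        i
        for i in range(len(template) - k + 1)
        if _mismatches(primer, template[i : i + k]) <= max_mismatches
    ]


@dataclass
class DiagnosticRule:
    """One diagnostic: a SNP position or a restriction recognition site.

    SNP rule: ``position`` (0-based on the amplicon) with a base->label map.
    Restriction rule: ``site`` sequence; ``present`` / ``absent`` labels
    according to whether in-silico digestion cuts the amplicon.
    """

    kind: str  # "snp" | "restriction"
    position: int | None = None
    bases: dict[str, str] = field(default_factory=dict)
    site: str | None = None
    present: str | None = None
    absent: str | None = None

    def apply(self, amplicon: str) -> str | None:
        if self.kind == "snp":
            assert self.position is not None
            if self.position >= len(amplicon):
                raise ValueError(
                    f"diagnostic position {self.position} beyond amplicon "
                    f"length {len(amplicon)}"
                )
            return self.bases.get(amplicon[self.position])
        if self.kind == "restriction":
            assert self.site
            cut = self.site in amplicon or self.site in revcomp(amplicon)
            return self.present if cut else self.absent
        raise ValueError(f"unknown diagnostic rule kind {self.kind!r}")


@dataclass
class HaplotypeScheme:
    """Primer pair plus diagnostic rules for one mitochondrial marker."""

    marker_name: str
    primer_fwd: str
    primer_rev: str
    expected_amplicon_length: int
    diagnostic_rules: list[DiagnosticRule]

    def __post_init__(self) -> None:
        for p in (self.primer_fwd, self.primer_rev):
            if not p or any(c not in _IUPAC for c in p.upper()):
                raise ValueError(f"primer {p!r} is not a non-empty IUPAC DNA string")
        self.primer_fwd = self.primer_fwd.upper()
        self.primer_rev = self.primer_rev.upper()
        labels = set()
        for r in self.diagnostic_rules:
            labels.update(v for v in r.bases.values())
            labels.update(v for v in (r.present, r.absent) if v)
        allowed = {Haplotype.H1_IBERIAN.value, Haplotype.H2_CENTRAL_EUROPEAN.value}
        if labels - allowed:
            raise ValueError(f"diagnostic rules map to unknown labels {labels - allowed}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HaplotypeScheme":
        cfg = yaml.safe_load(Path(path).read_text())
        rules = [DiagnosticRule(**r) for r in cfg.pop("diagnostic_rules")]
        return cls(diagnostic_rules=rules, **cfg)


def default_scheme() -> HaplotypeScheme:
    path = Path(__file__).parent / "data" / "rrnl_scheme.yaml"
    return HaplotypeScheme.from_yaml(path)


@dataclass
class AmpliconResult:
    status: str  # "amplified" | "no_amplification"
    sequence: str = ""
    strand: str = "+"
    start: int = -1  # 0-based half-open on the searched strand
    end: int = -1

    @property
    def length(self) -> int:
        return len(self.sequence)


def extract_amplicon(
    template: str, scheme: HaplotypeScheme, max_mismatches: int = 2
) -> AmpliconResult:
    """In-silico PCR: locate the primer pair and return the amplicon.

    Primer matching is Hamming-distance only (no indels) with IUPAC
    degeneracy; both strands are searched.  The amplicon includes both primer
    annealing sites.  A template that does not contain a plausible pair
    yields a ``no_amplification`` result rather than an exception; several
    non-overlapping candidate pairs raise an ambiguity error.
    """
    template = template.upper()
    if len(template) < len(scheme.primer_fwd) + len(scheme.primer_rev):
        raise ValueError("template shorter than the combined primer length")
    rev_site = revcomp(scheme.primer_rev)
    candidates: list[tuple[str, int, int]] = []
    for strand, seq in (("+", template), ("-", revcomp(template))):
        fwd_hits = _find_matches(seq, scheme.primer_fwd, max_mismatches)
        rev_hits = _find_matches(seq, rev_site, max_mismatches)
        for f in fwd_hits:
            for r in rev_hits:
                end = r + len(rev_site)
                if end > f + len(scheme.primer_fwd):
                    candidates.append((strand, f, end))
    if not candidates:
        return AmpliconResult(status="no_amplification")
    # keep the shortest product per strand start (PCR favors the shortest);
    # distinct non-overlapping products are ambiguous
    best = min(candidates, key=lambda c: (c[2] - c[1], c[0], c[1]))
    disjoint = [
        c
        for c in candidates
        if c[0] == best[0] and (c[1] >= best[2] or c[2] <= best[1])
    ]
    if disjoint:
        coords = [(best[1], best[2])] + [(c[1], c[2]) for c in disjoint]
        raise ValueError(f"ambiguous amplification; candidate products at {coords}")
    strand, start, end = best
    seq = template if strand == "+" else revcomp(template)
    return AmpliconResult(
        status="amplified", sequence=seq[start:end], strand=strand, start=start, end=end
    )


def call_haplotype(amplicon: str, scheme: HaplotypeScheme) -> Haplotype:
    """Apply every diagnostic rule; all rules must agree, else ``unknown``."""
    if not amplicon:
        raise ValueError("empty amplicon")
    labels = set()
    for rule in scheme.diagnostic_rules:
        label = rule.apply(amplicon.upper())
        labels.add(label)
    if len(labels) == 1 and None not in labels:
        return Haplotype(labels.pop())
    return Haplotype.UNKNOWN


def call_specimen_haplotypes(
    sequences: dict[str, str],
    scheme: HaplotypeScheme,
    max_mismatches: int = 2,
) -> dict[str, Haplotype]:
    """Amplify and call every sequence; failures call as ``unknown``."""
    calls: dict[str, Haplotype] = {}
    for sid, seq in sequences.items():
        amp = extract_amplicon(seq, scheme, max_mismatches)
        calls[sid] = (
            call_haplotype(amp.sequence, scheme)
            if amp.status == "amplified"
            else Haplotype.UNKNOWN
        )
    return calls


@dataclass
class HybridCall:
    specimen_id: str
    category: str  # consistent | discrepant_hybrid | morph_hybrid | naturalized_foreign
    basis: str

    @property
    def is_hybrid(self) -> bool:
        return self.category in ("morph_hybrid", "discrepant_hybrid")


def classify_hybrid(specimen: Specimen, outside_terrestris_range: bool = False) -> HybridCall:
    """Categorize one specimen from morphology, haplotype and location context.

    Morphological hybrids rank first; then morphology/haplotype discrepancy;
    *B. t. terrestris* morphology at a location outside that subspecies'
    native range marks a naturalized foreign individual (recorded in the
    basis even when the haplotype also makes it a discrepant hybrid).  An
    unknown haplotype on a non-hybrid morphotype is conservatively
    consistent.
    """
    m, h = specimen.morphotype, specimen.haplotype
    if m == Morphotype.UNKNOWN:
        raise ValueError(f"{specimen.id}: morphotype unknown, cannot classify")
    if m == Morphotype.MORPH_HYBRID:
        return HybridCall(specimen.id, "morph_hybrid", "hybrid morphology")
    foreign = m == Morphotype.TERRESTRIS and outside_terrestris_range
    discrepant = (m, h) in (
        (Morphotype.LUSITANICUS, Haplotype.H2_CENTRAL_EUROPEAN),
        (Morphotype.TERRESTRIS, Haplotype.H1_IBERIAN),
    )
    if discrepant:
        basis = f"morphology {m.value} with haplotype {h.value}"
        if foreign:
            basis += "; naturalized foreign morphotype"
        return HybridCall(specimen.id, "discrepant_hybrid", basis)
    if foreign:
        return HybridCall(
            specimen.id, "naturalized_foreign",
            "terrestris morphology outside native range",
        )
    return HybridCall(specimen.id, "consistent", f"{m.value} with {h.value}")


@dataclass
class LocationSummary:
    code: str
    n: int
    n_female: int
    n_male: int
    n_morph_hybrid: int
    n_discrepant_hybrid: int
    n_hybrid: int  # deduplicated per specimen
    pct_hybrid: float  # 0-100, exact
    haplotype_freqs: dict[str, float]

    @property
    def pct_hybrid_2dp(self) -> float:
        return round(self.pct_hybrid, 2)


def location_summary(
    population: PopulationSample, outside_terrestris_range: bool = False
) -> LocationSummary:
    """Per-location tally of sexes, hybrid categories and haplotype frequencies.

    The hybrid percentage counts morphological and discrepant hybrids, each
    specimen at most once, over all specimens at the location.  Haplotype
    frequencies are over specimens with a called haplotype and sum to one.
    """
    if not population.specimens:
        raise ValueError(f"{population.code}: empty population")
    calls = [
        classify_hybrid(s, outside_terrestris_range)
        for s in population.specimens
        if s.morphotype != Morphotype.UNKNOWN
    ]
    n = len(population.specimens)
    n_morph = sum(c.category == "morph_hybrid" for c in calls)
    n_disc = sum(c.category == "discrepant_hybrid" for c in calls)
    n_hybrid = sum(c.is_hybrid for c in calls)
    typed = [s for s in population.specimens if s.haplotype != Haplotype.UNKNOWN]
    freqs: dict[str, float] = {}
    if typed:
        for h in (Haplotype.H1_IBERIAN, Haplotype.H2_CENTRAL_EUROPEAN):
            freqs[h.value] = sum(s.haplotype == h for s in typed) / len(typed)
    return LocationSummary(
        code=population.code,
        n=n,
        n_female=sum(s.sex == Sex.FEMALE for s in population.specimens),
        n_male=sum(s.sex == Sex.MALE for s in population.specimens),
        n_morph_hybrid=n_morph,
        n_discrepant_hybrid=n_disc,
        n_hybrid=n_hybrid,
        pct_hybrid=100.0 * n_hybrid / n,
        haplotype_freqs=freqs,
    )
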