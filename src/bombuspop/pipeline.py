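"""End-to-end orchestration of the hybridization study on one input bundle.

Stages run in the order of the underlying survey design: marker validation
filters, the mitochondrial haplotype screen, hybrid classification, nuclear
assignment, diversity under the hIN/hOUT/rOUT variants, the paired Wilcoxon
comparison and effect regressions, diploid-male monitoring, and clustering.
Every filter decision is logged at item level and each stage writes its
report before the next starts, so partial output survives a failing stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import assignment as asg
from . import cluster as clu
from . import diversity as div
from . import haplotyping as hap
from . import introgression as intro
from . import ploidy as plo
from .filters import filter_missing, relatedness_filter
from .io import attach_metadata, read_fasta, read_genepop, read_metadata
from .types import Haplotype, PopulationSample

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genepop_path: str
    metadata_path: str
    outdir: str
    fasta_path: str | None = None
    scheme_path: str | None = None
    lusitanicus_ref: str | None = None  # population code
    terrestris_ref: str | None = None
    southern_codes: set[str] = field(default_factory=set)  # outside terrestris range
    max_missing_fraction: float = 0.30
    relatedness_threshold: float = 0.25
    sibship_filter: bool = False
    rarefaction_g: int = 10
    alpha: float = 0.05
    metrics: list[str] = field(default_factory=lambda: list(intro.METRICS))
    assignment_method: str = "frequency"
    assignment_threshold: float = 1.0
    purify_margin: float = 0.0
    k_range: tuple[int, int] = (1, 6)
    dapc_pcs: int = 10
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["southern_codes"] = sorted(self.southern_codes)
        return json.dumps(d, indent=2)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunResult:
    populations: list[PopulationSample]
    hybrid_calls: dict[str, hap.HybridCall]
    location_summaries: list[hap.LocationSummary]
    diversity: dict[str, list[div.DiversitySummary]]
    comparison: intro.ComparisonReport | None
    phi_by_location: dict[str, plo.PhiResult]
    outputs: dict[str, str]


def run_full(config: RunConfig) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())
    outputs: dict[str, str] = {}
    stage = "load"
    try:
        panel, populations = read_genepop(config.genepop_path)
        metadata = read_metadata(config.metadata_path)
        attach_metadata(populations, metadata)
        logger.info("loaded %d populations, %d loci", len(populations), len(panel))

        stage = "validation_filters"
        for pop in populations:
            report = filter_missing(pop.specimens, config.max_missing_fraction, len(panel))
            for sid, reason in report.reasons.items():
                logger.info("%s: discarded %s (%s)", pop.code, sid, reason)
            pop.specimens = report.retained
            if config.sibship_filter and len(pop.specimens) >= 2:
                keep = relatedness_filter(pop, config.relatedness_threshold, config.seed)
                dropped = {s.id for s in pop.specimens} - keep
                for sid in sorted(dropped):
                    logger.info("%s: sibship filter removed %s", pop.code, sid)
                pop.specimens = [s for s in pop.specimens if s.id in keep]
        populations = [p for p in populations if p.specimens]

        stage = "haplotype_screen"
        if config.fasta_path:
            scheme = (
                hap.HaplotypeScheme.from_yaml(config.scheme_path)
                if config.scheme_path
                else hap.default_scheme()
            )
            calls = hap.call_specimen_haplotypes(read_fasta(config.fasta_path), scheme)
            for pop in populations:
                for s in pop.specimens:
                    if s.id in calls and s.haplotype == Haplotype.UNKNOWN:
                        s.haplotype = calls[s.id]

        stage = "hybrid_classification"
        hybrid_calls: dict[str, hap.HybridCall] = {}
        summaries: list[hap.LocationSummary] = []
        for pop in populations:
            southern = pop.code in config.southern_codes
            for s in pop.specimens:
                hybrid_calls[s.id] = hap.classify_hybrid(s, southern)
            summaries.append(hap.location_summary(pop, southern))
        table1 = pd.DataFrame(
            [
                {
                    "location": s.code, "N": s.n, "females": s.n_female,
                    "males": s.n_male, "morph_hybrids": s.n_morph_hybrid,
                    "discrepant_hybrids": s.n_discrepant_hybrid,
                    "pct_hybrid": s.pct_hybrid_2dp,
                    **{f"freq_{k}": round(v, 4) for k, v in s.haplotype_freqs.items()},
                }
                for s in summaries
            ]
        )
        outputs["locations"] = str(outdir / "location_summary.csv")
        table1.to_csv(outputs["locations"], index=False)

        stage = "assignment"
        by_code = {p.code: p for p in populations}
        if config.lusitanicus_ref and config.terrestris_ref:
            lus_pool, terr_pool = asg.purify_references(
                by_code[config.lusitanicus_ref],
                by_code[config.terrestris_ref],
                margin=config.purify_margin,
            )
            rows = []
            for pop in populations:
                for r in asg.assign_population(
                    pop, lus_pool, terr_pool,
                    method=config.assignment_method,
                    threshold=config.assignment_threshold,
                    seed=config.seed,
                ):
                    rows.append(
                        {
                            "location": pop.code, "specimen": r.specimen_id,
                            "method": r.method,
                            "score_lusitanicus": r.score_lusitanicus,
                            "score_terrestris": r.score_terrestris,
                            "category": r.category,
                        }
                    )
            outputs["assignment"] = str(outdir / "assignment.csv")
            pd.DataFrame(rows).to_csv(outputs["assignment"], index=False)

        stage = "diversity_variants"
        variant_pops: dict[str, list[PopulationSample]] = {"hIN": [], "hOUT": [], "rOUT": []}
        for pop in populations:
            variants = intro.build_variants(pop, hybrid_calls, seed=config.seed)
            for label, var in variants.items():
                variant_pops[label].append(var.sample())
        diversity_summaries = {
            label: div.summarize_populations(pops, variant=label, g=config.rarefaction_g)
            for label, pops in variant_pops.items()
            if pops
        }
        table2 = pd.DataFrame(
            [dataclasses.asdict(s) for rows in diversity_summaries.values() for s in rows]
        )
        outputs["diversity"] = str(outdir / "diversity_summary.csv")
        table2.to_csv(outputs["diversity"], index=False)

        stage = "wilcoxon_comparison"
        comparison = None
        if len(populations) >= 3:
            comparison = intro.compare_all(
                diversity_summaries, alpha=config.alpha, metrics=config.metrics
            )
            rows = []
            for pair, per_metric in comparison.results.items():
                for metric, res in per_metric.items():
                    rows.append(
                        {
                            "pair": pair, "metric": metric, "V": res.v, "p": res.p,
                            "method": res.method,
                            "significant": res.p < comparison.adjusted_level,
                        }
                    )
            outputs["comparison"] = str(outdir / "wilcoxon_comparison.csv")
            pd.DataFrame(rows).to_csv(outputs["comparison"], index=False)

        stage = "ploidy"
        phi_by_location: dict[str, plo.PhiResult] = {}
        rows = []
        for pop in populations:
            if not pop.males():
                continue
            res = plo.phi_for_population(pop)
            phi_by_location[pop.code] = res
            rows.append(
                {
                    "location": pop.code, "males": res.n_males,
                    "diploid_males": res.n_diploid, "triploid_males": res.n_triploid,
                    "phi_exact": str(res.phi_exact), "phi": res.phi,
                }
            )
        outputs["ploidy"] = str(outdir / "ploidy.csv")
        pd.DataFrame(rows).to_csv(outputs["ploidy"], index=False)

        stage = "clustering"
        genotyped = [
            p for p in populations
            if any(not g.is_missing for s in p.specimens for g in s.genotypes)
        ]
        if sum(len(p) for p in genotyped) >= 10:
            matrix, ids, _ = clu.genotypes_to_matrix(genotyped)
            scan = clu.find_clusters(
                matrix, range(config.k_range[0], config.k_range[1] + 1),
                n_pcs=min(config.dapc_pcs, matrix.shape[0] - 2), seed=config.seed,
            )
            pd.DataFrame(
                {"K": list(scan.bic), "BIC": list(scan.bic.values())}
            ).to_csv(outdir / "bic_curve.csv", index=False)
            outputs["bic"] = str(outdir / "bic_curve.csv")
    except Exception as err:  # noqa: BLE001 - annotate with the failing stage
        raise StageError(stage, err) from err

    return RunResult(
        populations=populations,
        hybrid_calls=hybrid_calls,
        location_summaries=summaries,
        diversity=diversity_summaries,
        comparison=comparison,
        phi_by_location=phi_by_location,
        outputs=outputs,
    )
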