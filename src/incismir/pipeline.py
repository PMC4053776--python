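"""End-to-end orchestration: preprocess -> segment -> call -> detect -> report.

`process_cohort` turns a raw cohort bundle into per-locus matrices and an
aberration matrix; `run_pipeline` adds in-cis detection, family scoring and
(optionally) replication against a second processed cohort, writing
versioned tab-separated reports and a run log with the parameters, seed and
stage-by-stage counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .aberration import (
    AberrationMatrix,
    CallingThresholds,
    call_copy_number_state,
    call_methylation_state,
    fit_normal_reference,
    write_aberration_matrix,
)
from .errors import PipelineStageError
from .incis import (
    InCisConfig,
    ReplicationData,
    detect_incis,
    family_complementarity,
    incis_summary_table,
    replicate_incis,
    replicated_set,
    results_table,
)
from .locus_model import assign_methylation_probes, expand_to_loci, group_families
from .matrix import LocusSampleMatrix
from .preprocess import (
    NormalizationConfig,
    center_log_ratios,
    normalize_mirna_expression,
    summarize_locus_methylation,
)
from .segmentation import SegmentationConfig, assign_locus_copy_number, segment_cohort, write_seg

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All tunable thresholds of the pipeline, surfaced in one place."""

    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    thresholds: CallingThresholds = field(default_factory=CallingThresholds)
    k: float = 2.0                      # normal-reference SD multiplier
    incis: InCisConfig = field(default_factory=InCisConfig)
    rho_threshold: float = 0.3
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "percentile": self.normalization.percentile,
            "detection_fraction": self.normalization.detection_fraction,
            "gamma": self.segmentation.gamma,
            "gain_cutoff": self.thresholds.gain_cutoff,
            "loss_cutoff": self.thresholds.loss_cutoff,
            "k": self.k,
            "fdr_alpha": self.incis.fdr_alpha,
            "replication_alpha": self.incis.replication_alpha,
            "min_group_size": self.incis.min_group_size,
            "rho_threshold": self.rho_threshold,
            "seed": self.seed,
        }


@dataclass
class ProcessedCohort:
    """Per-locus matrices and aberration calls for one cohort."""

    name: str
    annotations: list
    expression: LocusSampleMatrix        # loci x tumors, normalized
    locus_cn: LocusSampleMatrix          # loci x tumors, segment means
    locus_beta: LocusSampleMatrix        # loci x tumors, median beta
    locus_beta_normal: LocusSampleMatrix
    aberrations: AberrationMatrix
    segments: dict
    assignments: list
    refs: list
    counts: dict = field(default_factory=dict)

    def as_replication_data(self, paired_meth_states=None) -> ReplicationData:
        return ReplicationData(
            expression=self.expression,
            aberrations=self.aberrations,
            locus_cn=self.locus_cn,
            locus_beta=self.locus_beta,
            paired_meth_states=paired_meth_states,
        )


@dataclass
class PipelineResult:
    discovery: ProcessedCohort
    results: list
    incis: list
    families: dict
    profiles: list
    replication_outcomes: list = field(default_factory=list)
    replicated_loci: set = field(default_factory=set)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


@_stage("process_cohort")
def process_cohort(bundle, params: PipelineParams | None = None) -> ProcessedCohort:
    """Normalize, expand, summarize, segment and call one cohort."""
    params = params or PipelineParams()
    counts = {}

    normalized = normalize_mirna_expression(
        bundle.mature_expression, bundle.detected, params.normalization
    )
    counts["matures_raw"] = bundle.mature_expression.shape[0]
    counts["matures_detected"] = normalized.shape[0]
    expression = expand_to_loci(normalized, bundle.annotations)
    counts["loci_expressed"] = expression.shape[0]
    log.info(
        "%s: %d/%d matures pass detection; expanded to %d loci",
        bundle.name, counts["matures_detected"], counts["matures_raw"],
        counts["loci_expressed"],
    )

    retained = set(expression.data.index)
    annotations = [a for a in bundle.annotations if a.locus_id in retained]

    assignments = assign_methylation_probes(annotations, bundle.probes)
    counts["assignments"] = {
        tier: sum(1 for a in assignments if a.tier == tier)
        for tier in ("designated", "host_promoter", "nearest")
    }
    locus_beta = summarize_locus_methylation(bundle.tumor_beta, assignments)
    locus_beta_normal = summarize_locus_methylation(bundle.normal_beta, assignments)

    centered = center_log_ratios(bundle.cn_probes)
    segments = segment_cohort(centered, bundle.cn_probe_positions, params.segmentation)
    counts["segments_total"] = sum(len(s) for s in segments.values())
    locus_cn = assign_locus_copy_number(
        segments, annotations, samples=list(centered.data.columns)
    )

    refs = fit_normal_reference(locus_beta_normal, k=params.k)
    meth_state = call_methylation_state(locus_beta, refs)
    cn_state = call_copy_number_state(locus_cn, params.thresholds)
    meth_state = meth_state.reindex(index=cn_state.index, columns=cn_state.columns, fill_value="missing")
    aberrations = AberrationMatrix(cn_state=cn_state, meth_state=meth_state)
    counts["cn_calls"] = int((cn_state.isin(["gain", "loss"])).to_numpy().sum())
    counts["meth_calls"] = int((meth_state.isin(["hypo", "hyper"])).to_numpy().sum())
    log.info(
        "%s: %d segments, %d CN calls, %d methylation calls",
        bundle.name, counts["segments_total"], counts["cn_calls"], counts["meth_calls"],
    )

    return ProcessedCohort(
        name=bundle.name,
        annotations=annotations,
        expression=expression,
        locus_cn=locus_cn,
        locus_beta=locus_beta,
        locus_beta_normal=locus_beta_normal,
        aberrations=aberrations,
        segments=segments,
        assignments=assignments,
        refs=refs,
        counts=counts,
    )


def run_pipeline(
    bundle,
    params: PipelineParams | None = None,
    replication_bundle=None,
    outdir=None,
) -> PipelineResult:
    """Full pipeline on a discovery cohort, optionally replicating in a second.

    When ``outdir`` is given, writes the per-spec results table, in-cis
    summary, SEG file, aberration matrix, family profiles, replication
    table and a JSON run log; on failure, partial outputs are retained
    beside a FAILED marker naming the stage.
    """
    params = params or PipelineParams()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    try:
        disc = process_cohort(bundle, params)
        results, incis = detect_incis(
            disc.expression, disc.locus_cn, disc.locus_beta, disc.aberrations,
            params.incis,
        )
        disc.counts["incis_loci"] = len(incis)
        log.info("%s: %d in-cis loci", bundle.name, len(incis))
        families = group_families(disc.annotations)
        profiles = family_complementarity(families, disc.aberrations, incis)
        outcomes, repl_loci = [], set()
        if replication_bundle is not None:
            repl = process_cohort(replication_bundle, params)
            outcomes = replicate_incis(
                incis, results, repl.as_replication_data(), params.incis
            )
            repl_loci = replicated_set(outcomes)
            disc.counts["replicated_loci"] = len(repl_loci)
            log.info("replication: %d/%d loci replicated", len(repl_loci), len(incis))
        result = PipelineResult(disc, results, incis, families, profiles, outcomes, repl_loci)
    except Exception as exc:
        if out is not None:
            (out / "FAILED").write_text(str(exc) + "\n")
        raise
    if out is not None:
        _write_reports(result, params, out)
    return result


def _write_reports(result: PipelineResult, params: PipelineParams, out: Path) -> None:
    disc = result.discovery
    results_table(result.results).to_csv(out / "incis_results.tsv", sep="\t", index=False)
    incis_summary_table(result.incis, result.results, disc.annotations).to_csv(
        out / "incis_summary.tsv", sep="\t", index=False
    )
    write_seg(disc.segments, out / "segments.seg")
    write_aberration_matrix(
        disc.aberrations, out / "aberrations.tsv", out / "aberrations.legend"
    )
    if result.profiles:
        rows = []
        for p in result.profiles:
            rows.append(
                f"{p.family_id}\t{','.join(p.locus_ids)}\t{p.fraction_altered:.4f}"
            )
        (out / "family_profiles.tsv").write_text(
            "family_id\tmembers\tfraction_samples_altered\n" + "\n".join(rows) + "\n"
        )
    if result.replication_outcomes:
        lines = ["locus_id\tscenario\tcategory\tp\treplicated\tassessable\tnote"]
        for o in result.replication_outcomes:
            lines.append(
                f"{o.locus_id}\t{o.spec.scenario}\t{o.spec.category}\t"
                f"{o.p:.6g}\t{int(o.replicated)}\t{int(o.assessable)}\t{o.note}"
            )
        (out / "replication.tsv").write_text("\n".join(lines) + "\n")
    run_log = {"params": params.to_dict(), "counts": disc.counts}
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1) + "\n")
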