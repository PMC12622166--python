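"""End-to-end orchestration: cohort inputs -> features -> classifier -> MRD.

Runs the full analysis on either an in-memory :class:`SyntheticCohort`
or a cohort directory written by it (manifest + per-sample VCF/BEDPE/bin
files), mirroring how the components chain on real data: background-panel
genotyping, per-sample SNV filtering and severity summaries, healthy
reference and gene-level CNA z-scores, multi-caller SV consensus with
control removal, feature assembly, LOOCV classification against the
genome-wide CNA-burden baseline, and per-patient MRD timelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import cna, features, mrd, snv, sv
from .classify import MalignancyClassifier, MalignancyResults, cna_burden_baseline, roc_auc
from .core import GenomicInterval, GeneRegistry, Material, Role, SampleRecord, read_manifest
from .mrd import ClinicalEvent, EventType, MrdTimeline, Observation
from .simulate import SyntheticCohort
from .snv import FilterThresholds, VariantCall
from .sv import ConsensusSv, MergeConfig, SvCall

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "analyze_cohort", "load_cohort_dir"]


@dataclass
class CohortInputs:
    """Raw per-sample inputs plus the manifest, source-agnostic."""

    manifest: list[SampleRecord]
    variants: dict[str, list[VariantCall]]
    sv_calls: dict[str, list[SvCall]]
    bins: dict[str, pd.DataFrame]
    events: list[tuple[str, ClinicalEvent]]
    tracked_svs: dict[str, ConsensusSv] = field(default_factory=dict)


@dataclass
class PipelineResult:
    feature_matrix: pd.DataFrame
    classifier: MalignancyResults
    baseline_scores: pd.Series
    baseline_auc: float
    mrd_reports: dict[str, dict]
    retained_variants: dict[str, list[VariantCall]]
    consensus_svs: dict[str, list[ConsensusSv]]


def load_cohort_dir(path: str | Path) -> CohortInputs:
    """Read a cohort directory written by :meth:`SyntheticCohort.write`."""
    path = Path(path)
    manifest = read_manifest(path / "manifest.tsv")
    variants, sv_calls, bins = {}, {}, {}
    for rec in manifest:
        sid = rec.sample_id
        variants[sid] = snv.read_vcf(path / "snv" / f"{sid}.vcf", sid)
        sv_calls[sid] = sv.read_bedpe(path / "sv" / f"{sid}.bedpe", sid)
        bins[sid] = cna.read_bins(path / "bins" / f"{sid}.tsv")
    events = []
    ev_path = path / "events.tsv"
    if ev_path.exists():
        ev_df = pd.read_csv(ev_path, sep="\t")
        events = [
            (r.patient_id, ClinicalEvent(int(r.timepoint_days), EventType(r.event)))
            for r in ev_df.itertuples(index=False)
        ]
    tracked = {}
    tr_path = path / "tracked_svs.tsv"
    if tr_path.exists():
        for r in pd.read_csv(tr_path, sep="\t").itertuples(index=False):
            tracked[r.patient_id] = ConsensusSv(
                chrom1=str(r.chrom1), pos1=int(r.pos1),
                chrom2=str(r.chrom2), pos2=int(r.pos2),
                svtype=r.svtype, supporting_callers=frozenset(),
            )
    return CohortInputs(manifest=manifest, variants=variants, sv_calls=sv_calls,
                        bins=bins, events=events, tracked_svs=tracked)


def _inputs_from_cohort(cohort: SyntheticCohort) -> CohortInputs:
    return CohortInputs(
        manifest=cohort.manifest,
        variants={sid: s.variants for sid, s in cohort.samples.items()},
        sv_calls={sid: s.sv_calls for sid, s in cohort.samples.items()},
        bins={sid: s.bins for sid, s in cohort.samples.items()},
        events=cohort.events,
        tracked_svs=cohort.tracked_svs,
    )


def _process_svs(
    inputs: CohortInputs,
    registry: GeneRegistry,
    merge_cfg: MergeConfig,
) -> tuple[dict[str, list[ConsensusSv]], list[ConsensusSv]]:
    """Merge, evidence-filter, blacklist and control-polish per sample."""
    panel_ids = [r.sample_id for r in inputs.manifest if r.role is Role.BACKGROUND_PANEL]
    control_events: list[ConsensusSv] = []
    for sid in panel_ids:
        control_events += sv.merge_calls(
            inputs.sv_calls.get(sid, []), merge_cfg.max_bp_dist,
            merge_cfg.min_size, merge_cfg.min_callers,
        )
    consensus: dict[str, list[ConsensusSv]] = {}
    for rec in inputs.manifest:
        if rec.role is not Role.CASE:
            continue
        sid = rec.sample_id
        merged = sv.merge_calls(inputs.sv_calls.get(sid, []), merge_cfg.max_bp_dist,
                                merge_cfg.min_size, merge_cfg.min_callers)
        is_tumor = rec.material is Material.TUMOR
        merged = [
            ev for ev in merged
            if sv.cfdna_evidence_filter(ev, merge_cfg.min_split, merge_cfg.min_disc,
                                        is_tumor=is_tumor)[0]
        ]
        merged = sv.apply_blacklist(merged, registry)
        merged = sv.remove_control_events(merged, control_events, merge_cfg.max_bp_dist)
        consensus[sid] = merged
    return consensus, control_events


def _mrd_for_patient(
    pid: str,
    records: list[SampleRecord],
    retained: Mapping[str, list[VariantCall]],
    consensus: Mapping[str, list[ConsensusSv]],
    tracked_sv: ConsensusSv | None,
    events: list[ClinicalEvent],
) -> dict | None:
    plasma = sorted(
        (r for r in records if r.material is Material.CFDNA and r.timepoint_days is not None),
        key=lambda r: r.timepoint_days,
    )
    if len(plasma) < 2:
        return None
    tumor_recs = [r for r in records if r.material is Material.TUMOR]
    tumor_keys = []
    for r in tumor_recs:
        tumor_keys += [v.key for v in retained.get(r.sample_id, [])]
    pre = [r for r in plasma if r.timepoint_days <= 0]
    pre_keys = []
    for r in pre:
        pre_keys += [v.key for v in retained.get(r.sample_id, [])]
    tracked = mrd.derive_tracked_set(tumor_keys, pre_keys)
    tracked_names = [str(k) for k, _ in tracked]
    if tracked_sv is not None:
        tracked_names.append(f"SV:{tracked_sv.svtype}:{tracked_sv.chrom1}:{tracked_sv.pos1}")
    if not tracked_names:
        return mrd.timeline_report(
            MrdTimeline(pid, [], [Observation(r.timepoint_days, {}) for r in plasma],
                        events),
            mrd.MrdCall(status=mrd.MrdStatus.INDETERMINATE),
        )
    observations = []
    for r in plasma:
        sample_keys = {v.key for v in retained.get(r.sample_id, [])}
        detected = {str(k): (k in sample_keys) for k, _ in tracked}
        if tracked_sv is not None:
            detected[tracked_names[-1]] = mrd.match_sv_key(
                tracked_sv, consensus.get(r.sample_id, [])
            )
        observations.append(Observation(r.timepoint_days, detected))
    timeline = MrdTimeline(pid, tracked_names, observations, events)
    call = mrd.call_mrd_status(timeline)
    mrd.lead_time(call, events)
    return mrd.timeline_report(timeline, call)


def analyze_cohort(
    cohort: SyntheticCohort | str | Path | CohortInputs,
    registry: GeneRegistry | None = None,
    thresholds: FilterThresholds | None = None,
    cna_config: cna.CnaConfig | None = None,
    merge_config: MergeConfig | None = None,
    seed: int = 0,
    n_boot: int | None = 2000,
) -> PipelineResult:
    """Run the full analysis and return features, evaluation, and MRD calls."""
    registry = registry or GeneRegistry.default()
    thresholds = thresholds or FilterThresholds()
    cna_cfg = cna_config or cna.CnaConfig()
    merge_cfg = merge_config or MergeConfig()
    if isinstance(cohort, (str, Path)):
        inputs = load_cohort_dir(cohort)
    elif isinstance(cohort, SyntheticCohort):
        inputs = _inputs_from_cohort(cohort)
    else:
        inputs = cohort

    panel_ids = [r.sample_id for r in inputs.manifest if r.role is Role.BACKGROUND_PANEL]
    if not panel_ids:
        raise ValueError("cohort has no background-panel samples")

    # background-panel genotyping: raw presence across panel samples
    panel_genotypes = snv.panel_genotype_map(
        {sid: inputs.variants.get(sid, []) for sid in panel_ids}
    )

    # per-sample SNV filtering + severity summaries
    retained: dict[str, list[VariantCall]] = {}
    snv_summaries: dict[str, dict] = {}
    for rec in inputs.manifest:
        if rec.role is not Role.CASE:
            continue
        sid = rec.sample_id
        mode = "tumor" if rec.material is Material.TUMOR else "cfdna"
        decisions = snv.filter_variants(
            inputs.variants.get(sid, []), mode, thresholds,
            panel_genotypes=panel_genotypes, panel_size=len(panel_ids),
            registry=registry,
        )
        kept = [d.variant for d in decisions if d.retained]
        retained[sid] = kept
        if rec.material is Material.CFDNA:
            snv_summaries[sid] = snv.gene_severity_summary(kept, registry)

    # CNA: healthy reference from panel, z-scores for cases
    panel_profiles = {
        sid: cna.gene_profiles(inputs.bins[sid], registry, sid, cna_cfg)
        for sid in panel_ids
    }
    panel_log2: dict[str, list[float]] = {}
    for profs in panel_profiles.values():
        for gene, p in profs.items():
            panel_log2.setdefault(gene, []).append(p.log2)
    reference = cna.healthy_reference(panel_log2, cna_cfg)
    cna_profiles: dict[str, dict] = {}
    for rec in inputs.manifest:
        if rec.role is not Role.CASE or rec.material is not Material.CFDNA:
            continue
        profs = cna.gene_profiles(inputs.bins[rec.sample_id], registry,
                                  rec.sample_id, cna_cfg)
        profs = {g: p for g, p in profs.items() if g in reference}
        cna.attach_zscores(profs, reference)
        cna_profiles[rec.sample_id] = profs

    # SV consensus + per-gene categories
    consensus, _ = _process_svs(inputs, registry, merge_cfg)
    sv_summaries = {
        rec.sample_id: sv.gene_sv_category(consensus.get(rec.sample_id, []), registry)
        for rec in inputs.manifest
        if rec.role is Role.CASE and rec.material is Material.CFDNA
    }

    # feature matrix over case cfDNA samples
    case_cfdna = [r for r in inputs.manifest
                  if r.role is Role.CASE and r.material is Material.CFDNA]
    matrix = features.build_feature_matrix(
        case_cfdna, cna_profiles, snv_summaries, sv_summaries, registry
    )

    # integrated classifier vs genome-wide burden baseline
    model = MalignancyClassifier(matrix)
    results = model.fit(seed=seed, n_boot=n_boot)
    case_ids = [r.sample_id for r in case_cfdna]
    offtarget = {}
    for sid in case_ids + panel_ids:
        df = inputs.bins[sid]
        if "on_target" in df.columns:
            off = df[~df["on_target"].astype(bool)]
        else:
            off = df[[
                not registry.genes_overlapping(
                    GenomicInterval(str(r.chrom), int(r.start), int(r.end))
                )
                for r in df.itertuples(index=False)
            ]]
        offtarget[sid] = off
    burden = cna_burden_baseline(offtarget, panel_ids)
    baseline_scores = burden.loc[case_ids]
    y = (matrix["label"] == "MPNST").to_numpy()
    baseline_auc = roc_auc(baseline_scores.loc[matrix.index].to_numpy(), y).auc

    # per-patient MRD
    by_patient: dict[str, list[SampleRecord]] = {}
    for rec in inputs.manifest:
        if rec.role is Role.CASE:
            by_patient.setdefault(rec.patient_id, []).append(rec)
    events_by_patient: dict[str, list[ClinicalEvent]] = {}
    for pid, ev in inputs.events:
        events_by_patient.setdefault(pid, []).append(ev)
    mrd_reports = {}
    for pid, recs in by_patient.items():
        report = _mrd_for_patient(
            pid, recs, retained, consensus,
            inputs.tracked_svs.get(pid), events_by_patient.get(pid, []),
        )
        if report is not None:
            mrd_reports[pid] = report

    return PipelineResult(
        feature_matrix=matrix,
        classifier=results,
        baseline_scores=baseline_scores,
        baseline_auc=baseline_auc,
        mrd_reports=mrd_reports,
        retained_variants=retained,
        consensus_svs=consensus,
    )
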