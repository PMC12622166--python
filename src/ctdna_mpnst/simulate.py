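"""Synthetic cfDNA cohort generator.

Emulates a targeted-panel liquid-biopsy study of NF1 patients: healthy
plasma, plexiform neurofibroma (PN) plasma, serial MPNST plasma with
matched tumors, and a healthy background panel for artifact polishing.
The default cohort shape is 12 healthy + 44 PN + 26 MPNST patients
contributing 44 cfDNA samples (including serial draws) + 19 tumors, with
a 12-sample background panel.

The generative model is the standard clonal mixture: at tumor fraction
TF, a clonal heterozygous SNV has expected allele fraction TF/2 with
alt-read counts Binomial(depth, AF); a single-copy loss shifts gene-bin
log2 ratios by log2(1 - TF/2) and a single-copy gain by log2(1 + TF/2),
on top of Gaussian bin noise.  Each patient's tumor genome (lesion set,
variant coordinates, SV breakpoints) is drawn once and shared by that
patient's serial plasma draws and matched tumor, so plasma recapitulates
tissue.  Structural variants are observed by three pseudo-callers
independently (jittered breakpoints, tumor-fraction-scaled split and
discordant support).  Class-independent artifact channels — shared
low-AF SNV sites (also sprinkled into panel samples to exercise the >10%
panel rule), CHIP-gene variants, and recurrent artifact SVs present in
controls — are layered onto every class.

Two scripted MPNST patients provide deterministic MRD trajectories: a
relapse case (tracked TP53 deletion redetected at day 100, clinical
recurrence at day 180) and a clearance case (three tumor-informed
variants absent from every post-operative draw).

Simulation starts at caller/bin outputs; no read-level data is generated,
because the analysis pipeline's inputs begin there too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ClassLabel,
    GeneRegistry,
    GenomicInterval,
    Material,
    Role,
    SampleRecord,
    write_manifest,
)
from .cna import expected_gain_log2, expected_loss_log2
from .mrd import ClinicalEvent, EventType
from .snv import VariantCall, write_vcf
from .sv import ConsensusSv, SvCall, write_bedpe

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SyntheticCohort", "simulate_cohort", "simulate_sample"]

_BASES = ("A", "C", "G", "T")
_SNV_CALLERS = ("mutect", "strelka", "varscan")
_SV_CALLERS = ("delly", "lumpy", "manta")

#: per-lesion probabilities for an MPNST tumor genome
DEFAULT_MPNST_MENU = {
    "cdkn2ab_loss": 0.70,
    "tp53_loss": 0.50,
    "tp53_snv": 0.50,
    "tp53_sv": 0.25,
    "suz12_loss": 0.55,
    "suz12_sv": 0.25,
    "eed_loss": 0.40,
    "eed_snv": 0.20,
    "eed_sv": 0.15,
    "chr8q_gain": 0.60,
    "nf1_loss": 0.50,
    "mtap_loss": 0.50,
    "genome_instability": 0.50,
}

_LOSS_GENES = {
    "cdkn2ab_loss": ("CDKN2A", "CDKN2B"),
    "tp53_loss": ("TP53",),
    "suz12_loss": ("SUZ12",),
    "eed_loss": ("EED",),
    "nf1_loss": ("NF1",),
    "mtap_loss": ("MTAP",),
}
_SV_LESIONS = {"tp53_sv": "TP53", "suz12_sv": "SUZ12", "eed_sv": "EED"}
_SNV_LESIONS = {"tp53_snv": "TP53", "eed_snv": "EED"}


@dataclass
class SimConfig:
    """Cohort-shape and noise parameters; the seed determines everything."""

    seed: int = 0
    n_healthy: int = 12
    n_pn: int = 44
    n_mpnst_patients: int = 26
    n_mpnst_cfdna: int = 44
    n_tumors: int = 19
    panel_size: int = 12
    tf_low: float = 0.05
    tf_high: float = 0.5
    tumor_purity: float = 0.6
    mean_depth: int = 1000
    bin_noise_sd: float = 0.08
    artifact_rate: float = 2.0
    n_artifact_sites: int = 30
    n_artifact_svs: int = 4
    bins_per_gene: int = 12
    n_offtarget_bins: int = 200
    pn_nf1_snv_prob: float = 0.2
    chip_prob: float = 0.15
    caller_sensitivity: float = 0.85
    lesion_menu: dict = field(default_factory=lambda: dict(DEFAULT_MPNST_MENU))
    scripted_mrd: bool = True

    def validate(self):
        for k, v in self.lesion_menu.items():
            if not 0 <= v <= 1:
                raise ValueError(f"lesion probability {k}={v} outside [0, 1]")
        if not 0 <= self.tf_low <= self.tf_high < 1:
            raise ValueError("need 0 <= tf_low <= tf_high < 1")

    @property
    def has_signal(self) -> bool:
        return any(p > 0 for p in self.lesion_menu.values())


@dataclass
class PatientGenome:
    """A patient's tumor genome, shared by serial draws and matched tumor."""

    lesions: dict[str, bool]
    snv_specs: list[dict] = field(default_factory=list)
    sv_specs: list[dict] = field(default_factory=list)
    cdkn2a_copies: int = 1
    instability_chroms: tuple = ()
    instability_signs: tuple = ()

    @classmethod
    def null(cls) -> "PatientGenome":
        return cls(lesions={})


@dataclass
class SampleData:
    record: SampleRecord
    tf: float
    variants: list[VariantCall]
    sv_calls: list[SvCall]
    bins: pd.DataFrame
    genome: PatientGenome = field(default_factory=PatientGenome.null)


@dataclass
class SyntheticCohort:
    """In-memory cohort; ``write`` emits the file tree the pipeline reads."""

    config: SimConfig
    samples: dict[str, SampleData]
    events: list[tuple[str, ClinicalEvent]]
    tracked_svs: dict[str, ConsensusSv]

    @property
    def manifest(self) -> list[SampleRecord]:
        return [s.record for s in self.samples.values()]

    def panel_ids(self) -> list[str]:
        return [s.record.sample_id for s in self.samples.values()
                if s.record.role is Role.BACKGROUND_PANEL]

    def write(self, outdir: str | Path, force: bool = False) -> Path:
        out = Path(outdir)
        if out.exists() and any(out.iterdir()) and not force:
            raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
        for sub in ("snv", "sv", "bins"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        write_manifest(self.manifest, out / "manifest.tsv")
        ev_rows = [
            {"patient_id": pid, "timepoint_days": e.timepoint_days, "event": e.event.value}
            for pid, e in self.events
        ]
        pd.DataFrame(ev_rows, columns=["patient_id", "timepoint_days", "event"]).to_csv(
            out / "events.tsv", sep="\t", index=False
        )
        for sid, data in self.samples.items():
            write_vcf(data.variants, out / "snv" / f"{sid}.vcf", sid)
            write_bedpe(data.sv_calls, out / "sv" / f"{sid}.bedpe")
            data.bins.to_csv(out / "bins" / f"{sid}.tsv", sep="\t", index=False)
        if self.tracked_svs:
            rows = []
            for pid, sv in self.tracked_svs.items():
                rows.append({"patient_id": pid, "chrom1": sv.chrom1, "pos1": sv.pos1,
                             "chrom2": sv.chrom2, "pos2": sv.pos2, "svtype": sv.svtype})
            pd.DataFrame(rows).to_csv(out / "tracked_svs.tsv", sep="\t", index=False)
        return out


# --- bin grid ----------------------------------------------------------------

def _bin_grid(registry: GeneRegistry, cfg: SimConfig) -> pd.DataFrame:
    """Deterministic bin layout: on-target gene bins + off-target 1 Mb grid."""
    rows = []
    for gene, iv in registry.genes.items():
        edges = np.linspace(iv.start, iv.end, cfg.bins_per_gene + 1).astype(int)
        for i in range(cfg.bins_per_gene):
            if edges[i] < edges[i + 1]:
                rows.append({"chrom": iv.chrom, "start": int(edges[i]),
                             "end": int(edges[i + 1]), "on_target": True, "gene": gene})
    chroms = [str(c) for c in range(1, 23)]
    for k in range(cfg.n_offtarget_bins):
        chrom = chroms[k % len(chroms)]
        start = 10_000_000 + (k // len(chroms)) * 10_000_000
        rows.append({"chrom": chrom, "start": start, "end": start + 1_000_000,
                     "on_target": False, "gene": ""})
    return pd.DataFrame(rows)


# --- low-level draws ---------------------------------------------------------

def _rand_snv(rng, iv: GenomicInterval) -> tuple[int, str, str]:
    pos = int(rng.integers(iv.start, iv.end))
    ref = _BASES[rng.integers(4)]
    alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
    return pos, ref, alt


_DRIVER_CSQ = [
    ("stop_gained", None, None, 0.40),
    ("frameshift_variant", None, None, 0.30),
    ("missense_variant", True, True, 0.20),
    ("splice_donor_variant", None, None, 0.10),
]


def _driver_consequence(rng) -> tuple[str, bool | None, bool | None]:
    r = rng.random()
    acc = 0.0
    for csq, pp, sift, w in _DRIVER_CSQ:
        acc += w
        if r < acc:
            return csq, pp, sift
    return _DRIVER_CSQ[-1][:3]


def _snv_spec(rng, registry: GeneRegistry, gene: str) -> dict:
    iv = registry.genes[gene]
    pos, ref, alt = _rand_snv(rng, iv)
    csq, pp, sift = _driver_consequence(rng)
    return {"chrom": iv.chrom, "pos": pos, "ref": ref, "alt": alt, "gene": gene,
            "consequence": csq, "polyphen": pp, "sift": sift}


def _observed_call(
    rng, cfg: SimConfig, spec: dict, sample_id: str, true_af: float,
    is_coding: bool = True, flags: frozenset = frozenset(),
) -> VariantCall | None:
    """Draw the read-level observation of a variant; None if unseen."""
    total = max(1, int(rng.poisson(cfg.mean_depth)))
    alt_depth = int(rng.binomial(total, min(true_af, 1.0)))
    if alt_depth == 0:
        return None
    n_callers = 2 + int(rng.random() < 0.6)
    callers = frozenset(rng.choice(_SNV_CALLERS, size=n_callers, replace=False).tolist())
    ref = spec["ref"]
    return VariantCall(
        interval=GenomicInterval(spec["chrom"], spec["pos"], spec["pos"] + len(ref)),
        ref=ref, alt=spec["alt"], sample_id=sample_id,
        af=alt_depth / total, alt_depth=alt_depth, total_depth=total,
        callers=callers, consequence=spec.get("consequence", ""),
        polyphen_damaging=spec.get("polyphen"), sift_deleterious=spec.get("sift"),
        gene=spec.get("gene"), is_coding=is_coding, filter_flags=flags,
    )


def _emit_sv(
    rng, cfg: SimConfig, spec: dict, sample_id: str, tf: float,
    scripted: bool = False,
) -> list[SvCall]:
    """One true SV as seen by the three pseudo-callers."""
    calls = []
    for caller in _SV_CALLERS:
        if not scripted and rng.random() > cfg.caller_sensitivity:
            continue
        j1 = int(rng.integers(-50, 51))
        j2 = int(rng.integers(-50, 51))
        if scripted:
            split, disc = 6, 5
        else:
            split = int(rng.poisson(2 + 25 * tf))
            disc = int(rng.poisson(2 + 25 * tf))
        calls.append(
            SvCall(
                chrom1=spec["chrom1"], pos1=spec["pos1"] + j1,
                chrom2=spec["chrom2"], pos2=spec["pos2"] + j2,
                svtype=spec["svtype"], caller=caller, sample_id=sample_id,
                split_reads=split, discordant_pairs=disc,
            )
        )
    return calls


# --- artifact channels -------------------------------------------------------

@dataclass
class _ArtifactSite:
    spec: dict
    prevalence: float
    af_scale: float
    is_coding: bool


def _artifact_catalog(rng, registry: GeneRegistry, cfg: SimConfig) -> list[_ArtifactSite]:
    """Shared low-AF artifact sites spread across the panel footprint."""
    genes = list(registry.genes)
    sites = []
    for _ in range(cfg.n_artifact_sites):
        gene = genes[int(rng.integers(len(genes)))]
        iv = registry.genes[gene]
        pos, ref, alt = _rand_snv(rng, iv)
        coding = bool(rng.random() < 0.5)
        spec = {"chrom": iv.chrom, "pos": pos, "ref": ref, "alt": alt, "gene": gene,
                "consequence": "synonymous_variant" if coding else "intron_variant"}
        sites.append(_ArtifactSite(
            spec=spec,
            prevalence=float(rng.uniform(0.02, 0.25)),
            af_scale=float(rng.uniform(0.001, 0.02)),
            is_coding=coding,
        ))
    return sites


def _artifact_sv_catalog(rng, cfg: SimConfig) -> list[dict]:
    svs = []
    for _ in range(cfg.n_artifact_svs):
        chrom = str(int(rng.integers(1, 23)))
        pos1 = int(rng.integers(30_000_000, 80_000_000))
        svs.append({"chrom1": chrom, "pos1": pos1, "chrom2": chrom,
                    "pos2": pos1 + int(rng.integers(500, 5000)), "svtype": "DEL"})
    return svs


# --- patient genomes ---------------------------------------------------------

def _patient_genome(rng, cfg: SimConfig, registry: GeneRegistry) -> PatientGenome:
    """Draw one MPNST patient's lesion set and fixed variant coordinates."""
    if not cfg.has_signal:
        return PatientGenome.null()
    lesions = {k: bool(rng.random() < p) for k, p in cfg.lesion_menu.items()}
    if not any(lesions.values()):
        # every MPNST carries at least the characteristic 9p21 loss
        key = "cdkn2ab_loss" if cfg.lesion_menu.get("cdkn2ab_loss", 0) > 0 else max(
            cfg.lesion_menu, key=cfg.lesion_menu.get)
        lesions[key] = True
    snv_specs = [_snv_spec(rng, registry, gene)
                 for lesion, gene in _SNV_LESIONS.items() if lesions.get(lesion)]
    sv_specs = []
    for lesion, gene in _SV_LESIONS.items():
        if not lesions.get(lesion):
            continue
        iv = registry.genes[gene]
        pos1 = int(rng.integers(iv.start, iv.end))
        size = int(rng.integers(5_000, 40_000))
        sv_specs.append({"chrom1": iv.chrom, "pos1": pos1, "chrom2": iv.chrom,
                         "pos2": pos1 + size, "svtype": "DEL"})
    if lesions.get("chr8q_gain") and rng.random() < 0.7:
        pos1 = int(rng.integers(60_000_000, 130_000_000))
        size = int(rng.integers(1_000_000, 10_000_000))
        sv_specs.append({"chrom1": "8", "pos1": pos1, "chrom2": "8",
                         "pos2": pos1 + size, "svtype": "DUP"})
    n_arms = 1 + int(rng.integers(0, 3))
    chroms = tuple(rng.choice([str(c) for c in range(1, 23)], size=n_arms, replace=False))
    signs = tuple(1 if rng.random() < 0.5 else -1 for _ in range(n_arms))
    return PatientGenome(
        lesions=lesions,
        snv_specs=snv_specs,
        sv_specs=sv_specs,
        cdkn2a_copies=2 if rng.random() < 0.5 else 1,
        instability_chroms=chroms if lesions.get("genome_instability") else (),
        instability_signs=signs if lesions.get("genome_instability") else (),
    )


# --- per-sample generation ---------------------------------------------------

def simulate_sample(
    rng: np.random.Generator,
    cfg: SimConfig,
    registry: GeneRegistry,
    record: SampleRecord,
    tf: float,
    genome: PatientGenome | None = None,
    artifact_sites: Sequence[_ArtifactSite] = (),
    artifact_svs: Sequence[dict] = (),
    bin_grid: pd.DataFrame | None = None,
    forced_snvs: Sequence[dict] = (),
    forced_svs: Sequence[dict] = (),
) -> SampleData:
    """Generate one sample's variant, SV, and coverage-bin observations.

    ``tf`` must be 0 for healthy/PN plasma and in (0, 1) for tumor-bearing
    material; the patient ``genome`` is shared across that patient's
    serial samples and matched tumor.  A tf of 0 silences every tumor
    lesion regardless of the genome (molecularly cleared draw).
    """
    if not 0 <= tf < 1:
        raise ValueError(f"tumor fraction {tf} outside [0, 1)")
    genome = genome or PatientGenome.null()
    is_tumor = record.material is Material.TUMOR
    eff_tf = cfg.tumor_purity if is_tumor else tf
    active = genome.lesions if eff_tf > 0 else {}
    grid = bin_grid if bin_grid is not None else _bin_grid(registry, cfg)

    # --- coverage bins
    shifts = np.zeros(len(grid))
    gene_col = grid["gene"].to_numpy()
    chrom_col = grid["chrom"].to_numpy()
    on_target = grid["on_target"].to_numpy()
    if eff_tf > 0:
        for lesion, genes in _LOSS_GENES.items():
            if not active.get(lesion):
                continue
            for g in genes:
                copies = genome.cdkn2a_copies if g == "CDKN2A" else 1
                shifts[gene_col == g] += expected_loss_log2(eff_tf, copies)
        if active.get("chr8q_gain"):
            for g in registry.chr8q_genes:
                shifts[gene_col == g] += expected_gain_log2(eff_tf)
            shifts[(~on_target) & (chrom_col == "8")] += expected_gain_log2(eff_tf)
        for c, sign in zip(genome.instability_chroms, genome.instability_signs):
            shift = expected_gain_log2(eff_tf) if sign > 0 else expected_loss_log2(eff_tf)
            shifts[(~on_target) & (chrom_col == c)] += shift
    log2 = shifts + rng.normal(0.0, cfg.bin_noise_sd, size=len(grid))
    outliers = rng.random(len(grid)) < 0.02
    log2 = log2 + outliers * rng.uniform(-2.5, 2.5, size=len(grid))
    n_reads = rng.poisson(np.where(on_target, 500, 120)).astype(int)
    lowdepth = rng.random(len(grid)) < 0.01
    n_reads = np.where(lowdepth, rng.poisson(10, size=len(grid)), n_reads)
    bins = grid.assign(log2_ratio=np.round(log2, 6), n_reads=n_reads)[
        ["chrom", "start", "end", "log2_ratio", "n_reads", "on_target"]
    ]

    # --- SNVs / indels
    variants: list[VariantCall] = []
    var_af = eff_tf / 2.0
    if eff_tf > 0:
        for spec in genome.snv_specs:
            call = _observed_call(rng, cfg, spec, record.sample_id, var_af)
            if call:
                variants.append(call)
    for fv in forced_snvs:
        call = _observed_call(rng, cfg, fv, record.sample_id, fv.get("af", var_af))
        if call:
            variants.append(call)
    if record.class_label is ClassLabel.PN and not is_tumor:
        if rng.random() < cfg.pn_nf1_snv_prob:
            spec = _snv_spec(rng, registry, "NF1")
            call = _observed_call(rng, cfg, spec, record.sample_id,
                                  float(rng.uniform(0.005, 0.02)))
            if call:
                variants.append(call)
    # CHIP channel: blood-derived, class-independent
    if rng.random() < cfg.chip_prob:
        gene = registry.chip_genes[int(rng.integers(len(registry.chip_genes)))]
        spec = _snv_spec(rng, registry, gene)
        spec.update(consequence="missense_variant", polyphen=True, sift=False)
        call = _observed_call(rng, cfg, spec, record.sample_id,
                              float(rng.uniform(0.005, 0.05)))
        if call:
            variants.append(call)
    # shared artifact sites (also exercise the >10%-of-panel rule)
    for site in artifact_sites:
        if rng.random() >= site.prevalence:
            continue
        call = _observed_call(rng, cfg, site.spec, record.sample_id,
                              site.af_scale * float(rng.uniform(0.5, 2.0)),
                              is_coding=site.is_coding)
        if call:
            variants.append(call)

    # --- SVs
    sv_calls: list[SvCall] = []
    if eff_tf > 0:
        for spec in genome.sv_specs:
            sv_calls += _emit_sv(rng, cfg, spec, record.sample_id, eff_tf)
    for fs in forced_svs:
        sv_calls += _emit_sv(rng, cfg, fs, record.sample_id, eff_tf, scripted=True)
    for asv in artifact_svs:
        prev = 0.5 if record.role is Role.BACKGROUND_PANEL else 0.3
        if rng.random() >= prev:
            continue
        sv_calls += _emit_sv(rng, cfg, asv, record.sample_id, max(eff_tf, 0.2))

    return SampleData(record=record, tf=tf, variants=variants,
                      sv_calls=sv_calls, bins=bins, genome=genome)


# --- cohort assembly ---------------------------------------------------------

def _scripted_patients(rng, cfg: SimConfig, registry: GeneRegistry):
    """Fixed MRD trajectories: MP01 relapse (lead time 80 d), MP02 clearance."""
    tp53 = registry.genes["TP53"]
    del_start = int(rng.integers(tp53.start, tp53.end - 12_000))
    tracked_sv = ConsensusSv(
        chrom1=tp53.chrom, pos1=del_start, chrom2=tp53.chrom, pos2=del_start + 12_000,
        svtype="DEL", supporting_callers=frozenset(_SV_CALLERS),
    )
    clearance_snvs = [_snv_spec(rng, registry, gene)
                      for gene in ("TERT", "COA3", "NCOA2")]
    relapse = {
        "patient_id": "MP01",
        "timepoints": [(0, 0.30, True), (10, 0.0, False), (100, 0.12, True)],
        "tracked_sv": tracked_sv,
        "events": [ClinicalEvent(0, EventType.RESECTION),
                   ClinicalEvent(180, EventType.CLINICAL_RECURRENCE)],
    }
    clearance = {
        "patient_id": "MP02",
        "timepoints": [(0, 0.35, True), (10, 0.0, False), (100, 0.0, False),
                       (365, 0.0, False)],
        "tracked_snvs": clearance_snvs,
        "events": [ClinicalEvent(0, EventType.RESECTION),
                   ClinicalEvent(365, EventType.IMAGING_NED)],
    }
    return relapse, clearance


def simulate_cohort(
    cfg: SimConfig | None = None, registry: GeneRegistry | None = None
) -> SyntheticCohort:
    """Generate the full synthetic cohort, deterministic under the seed."""
    cfg = cfg or SimConfig()
    cfg.validate()
    registry = registry or GeneRegistry.default()
    rng = np.random.default_rng(cfg.seed)
    grid = _bin_grid(registry, cfg)
    artifact_sites = _artifact_catalog(rng, registry, cfg)
    artifact_svs = _artifact_sv_catalog(rng, cfg)

    samples: dict[str, SampleData] = {}
    events: list[tuple[str, ClinicalEvent]] = []
    tracked_svs: dict[str, ConsensusSv] = {}

    def add(record, tf, genome=None, **kw):
        samples[record.sample_id] = simulate_sample(
            rng, cfg, registry, record, tf, genome,
            artifact_sites=artifact_sites, artifact_svs=artifact_svs,
            bin_grid=grid, **kw,
        )

    for i in range(cfg.panel_size):
        sid = f"PANEL{i + 1:02d}"
        add(SampleRecord(sid, sid, ClassLabel.HEALTHY, Material.CFDNA,
                         Role.BACKGROUND_PANEL), 0.0)
    for i in range(cfg.n_healthy):
        sid = f"H{i + 1:02d}"
        add(SampleRecord(sid, sid, ClassLabel.HEALTHY, Material.CFDNA, Role.CASE), 0.0)
    for i in range(cfg.n_pn):
        sid = f"PN{i + 1:02d}"
        add(SampleRecord(sid, f"PNP{i + 1:02d}", ClassLabel.PN, Material.CFDNA,
                         Role.CASE), 0.0)

    # MPNST patients: scripted MRD trajectories first, then the rest
    relapse, clearance = _scripted_patients(rng, cfg, registry)
    scripted = [relapse, clearance] if cfg.scripted_mrd else []
    n_scripted_samples = sum(len(s["timepoints"]) for s in scripted)
    signal = cfg.has_signal

    for script in scripted:
        pid = script["patient_id"]
        genome = _patient_genome(rng, cfg, registry)
        if "tracked_sv" in script:
            # the tracked deletion is scripted explicitly, not drawn from the menu
            genome.lesions["tp53_sv"] = False
            genome.sv_specs = [s for s in genome.sv_specs
                               if not (s["svtype"] == "DEL" and s["chrom1"] == "17")]
        events.extend((pid, e) for e in script["events"])
        if signal and "tracked_sv" in script:
            tracked_svs[pid] = script["tracked_sv"]
        for t_idx, (day, tf, detected) in enumerate(script["timepoints"]):
            sid = f"{pid}_T{t_idx}"
            rec = SampleRecord(sid, pid, ClassLabel.MPNST, Material.CFDNA,
                               Role.CASE, timepoint_days=day)
            forced_svs, forced_snvs = [], []
            if detected and signal:
                if "tracked_sv" in script:
                    sv = script["tracked_sv"]
                    forced_svs = [{"chrom1": sv.chrom1, "pos1": sv.pos1,
                                   "chrom2": sv.chrom2, "pos2": sv.pos2,
                                   "svtype": sv.svtype}]
                if "tracked_snvs" in script:
                    forced_snvs = [dict(s, af=tf / 2) for s in script["tracked_snvs"]]
            add(rec, tf if signal else 0.0, genome,
                forced_snvs=forced_snvs, forced_svs=forced_svs)
        # matched tumor
        tum_rec = SampleRecord(f"{pid}_TUM", pid, ClassLabel.MPNST, Material.TUMOR,
                               Role.CASE, timepoint_days=0)
        forced_svs, forced_snvs = [], []
        if signal and "tracked_sv" in script:
            sv = script["tracked_sv"]
            forced_svs = [{"chrom1": sv.chrom1, "pos1": sv.pos1, "chrom2": sv.chrom2,
                           "pos2": sv.pos2, "svtype": sv.svtype}]
        if signal and "tracked_snvs" in script:
            forced_snvs = [dict(s, af=cfg.tumor_purity / 2)
                           for s in script["tracked_snvs"]]
        add(tum_rec, cfg.tumor_purity if signal else 0.0, genome,
            forced_snvs=forced_snvs, forced_svs=forced_svs)

    n_rest_patients = cfg.n_mpnst_patients - len(scripted)
    n_rest_samples = cfg.n_mpnst_cfdna - n_scripted_samples
    n_serial = max(0, n_rest_samples - n_rest_patients)  # patients with 2 draws
    n_rest_tumors = max(0, cfg.n_tumors - len(scripted))
    for i in range(n_rest_patients):
        pid = f"MP{len(scripted) + i + 1:02d}"
        genome = _patient_genome(rng, cfg, registry)
        n_draws = 2 if i < n_serial else 1
        for t_idx in range(n_draws):
            sid = f"{pid}_T{t_idx}"
            tf = float(rng.uniform(cfg.tf_low, cfg.tf_high)) if signal else 0.0
            day = t_idx * 90 if n_draws > 1 else None
            add(SampleRecord(sid, pid, ClassLabel.MPNST, Material.CFDNA, Role.CASE,
                             timepoint_days=day), tf, genome)
        if i < n_rest_tumors:
            add(SampleRecord(f"{pid}_TUM", pid, ClassLabel.MPNST, Material.TUMOR,
                             Role.CASE, timepoint_days=0),
                cfg.tumor_purity if signal else 0.0, genome)

    return SyntheticCohort(config=cfg, samples=samples, events=events,
                           tracked_svs=tracked_svs)
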