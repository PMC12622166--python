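"""Shared domain types: samples, intervals, and the gene/region registry.

Coordinates are 0-based half-open internally; VCF positions are converted
at the reader boundary.  Chromosome names are normalized to a single
dialect per run (bare names by default, i.e. ``"17"`` not ``"chr17"``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClassLabel",
    "Material",
    "Role",
    "Dialect",
    "ChromosomeError",
    "ManifestError",
    "GenomicInterval",
    "SampleRecord",
    "GeneRegistry",
    "normalize_chrom",
    "read_manifest",
    "write_manifest",
]


class ClassLabel(str, Enum):
    HEALTHY = "healthy"
    PN = "PN"
    MPNST = "MPNST"


class Material(str, Enum):
    CFDNA = "cfDNA"
    TUMOR = "tumor"
    GERMLINE = "germline"


class Role(str, Enum):
    CASE = "case"
    BACKGROUND_PANEL = "background_panel"
    CONTROL = "control"


class Dialect(str, Enum):
    """Chromosome naming dialect: bare ("17") or UCSC-prefixed ("chr17")."""

    BARE = "bare"
    CHR = "chr"


_CANONICAL = {str(i) for i in range(1, 23)} | {"X", "Y", "MT"}


class ChromosomeError(ValueError):
    """Raised for unplaced/alt contigs or unrecognized chromosome names."""

    def __init__(self, name: str, reason: str):
        self.name = name
        self.reason = reason
        super().__init__(f"chromosome {name!r} rejected: {reason}")


class ManifestError(ValueError):
    """Schema or validation failure while reading a sample manifest."""


def normalize_chrom(name: str, dialect: Dialect | str = Dialect.BARE) -> str:
    """Normalize a chromosome name to the declared dialect.

    Idempotent: ``chr8`` and ``8`` map to the same canonical name.
    Unplaced, alt, and random contigs are rejected with a reason code.
    """
    dialect = Dialect(dialect)
    raw = name.strip()
    bare = raw[3:] if raw.lower().startswith("chr") else raw
    if bare in ("M", "chrM"):
        bare = "MT"
    bare = bare.upper() if bare in ("x", "y", "mt", "X", "Y", "MT") else bare
    if "_" in bare or bare.lower().startswith(("un", "gl", "hs")):
        raise ChromosomeError(name, "UNPLACED_OR_ALT_CONTIG")
    if bare not in _CANONICAL:
        raise ChromosomeError(name, "UNRECOGNIZED_NAME")
    return f"chr{bare}" if dialect is Dialect.CHR else bare


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval: 0-based start (inclusive), end (exclusive)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SampleRecord:
    """One row of the sample manifest.

    ``timepoint_days`` is relative to first treatment and is required only
    for longitudinal MRD analysis; it is ``None`` for single-draw samples.
    """

    sample_id: str
    patient_id: str
    class_label: ClassLabel
    material: Material
    role: Role
    timepoint_days: int | None = None

    def __post_init__(self):
        self.class_label = ClassLabel(self.class_label)
        self.material = Material(self.material)
        self.role = Role(self.role)
        if self.role is Role.BACKGROUND_PANEL:
            if self.class_label is not ClassLabel.HEALTHY or self.material is not Material.CFDNA:
                raise ManifestError(
                    f"background_panel sample {self.sample_id} must be healthy cfDNA"
                )


_MANIFEST_COLUMNS = [
    "sample_id",
    "patient_id",
    "class_label",
    "material",
    "role",
    "timepoint_days",
]
_REQUIRED_COLUMNS = _MANIFEST_COLUMNS[:-1]


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Read and validate a tab-separated sample manifest.

    Raises :class:`ManifestError` naming the missing column or listing
    duplicate sample ids; records a warning when the manifest declares no
    background-panel samples (panel-dependent filters will fail loudly
    later rather than silently pass).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing required column(s): {', '.join(missing)}")
    dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
    if dupes:
        raise ManifestError(f"duplicate sample_id(s): {', '.join(sorted(set(dupes)))}")
    records = []
    for row in df.itertuples(index=False):
        tp = getattr(row, "timepoint_days", None)
        tp = None if tp is None or pd.isna(tp) or tp == "" else int(float(tp))
        try:
            records.append(
                SampleRecord(
                    sample_id=row.sample_id,
                    patient_id=row.patient_id,
                    class_label=ClassLabel(row.class_label),
                    material=Material(row.material),
                    role=Role(row.role),
                    timepoint_days=tp,
                )
            )
        except ValueError as exc:
            raise ManifestError(f"invalid manifest row for {row.sample_id!r}: {exc}") from exc
    if not any(r.role is Role.BACKGROUND_PANEL for r in records):
        warnings.warn(
            "manifest declares no background_panel samples; panel-dependent "
            "filters will raise when invoked",
            stacklevel=2,
        )
    return records


def write_manifest(records: Sequence[SampleRecord], path: str | Path) -> None:
    """Write records as TSV in canonical column order (round-trips with read)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "patient_id": r.patient_id,
            "class_label": r.class_label.value,
            "material": r.material.value,
            "role": r.role.value,
            "timepoint_days": "" if r.timepoint_days is None else r.timepoint_days,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


# --- gene registry -----------------------------------------------------------

FEATURE_GENES = ("CDKN2A", "CDKN2B", "TP53", "SUZ12", "EED")
SV_FEATURE_GENES = ("TP53", "SUZ12", "EED")
#: merged locus name used for SNV/SV summaries (shared CDKN2A/B promoter region)
CDKN2AB = "CDKN2AB"


@dataclass
class GeneRegistry:
    """Registry of panel genes, their hg19 intervals, and role assignments.

    Roles: ``feature`` (tumor-suppressor CNA/SNV feature genes), ``chr8q``
    (candidate oncogenes averaged into the chr8q composite), ``chip``
    (clonal-hematopoiesis genes masked from features), ``excluded``
    (never emitted, e.g. ATRX for X-chromosome effects), ``other``
    (on-panel, tracked but not a classifier feature).
    """

    genes: dict[str, GenomicInterval]
    roles: dict[str, str]
    blacklist: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        for g in FEATURE_GENES:
            if g not in self.genes or self.roles.get(g) != "feature":
                raise ValueError(f"feature gene {g} must be present with role 'feature'")
        overlap = set(self.feature_genes) & set(self.chip_genes)
        if overlap:
            raise ValueError(f"feature genes may not be CHIP-masked: {sorted(overlap)}")
        if "ATRX" in set(self.feature_genes) | set(self.chr8q_genes):
            raise ValueError("ATRX is excluded and may not appear in any feature set")

    @classmethod
    def default(cls) -> "GeneRegistry":
        """Load the packaged hg19 registry and blacklist."""
        pkg = resources.files("ctdna_mpnst.data")
        genes_df = pd.read_csv(pkg / "gene_registry_hg19.tsv", sep="\t")
        bl_df = pd.read_csv(pkg / "blacklist_hg19.tsv", sep="\t")
        return cls.from_frames(genes_df, bl_df)

    @classmethod
    def from_frames(cls, genes_df: pd.DataFrame, blacklist_df: pd.DataFrame | None = None):
        genes, roles = {}, {}
        for row in genes_df.itertuples(index=False):
            chrom = normalize_chrom(str(row.chrom))
            genes[row.gene] = GenomicInterval(chrom, int(row.start), int(row.end))
            roles[row.gene] = row.role
        blacklist = []
        if blacklist_df is not None:
            blacklist = [
                GenomicInterval(normalize_chrom(str(r.chrom)), int(r.start), int(r.end))
                for r in blacklist_df.itertuples(index=False)
            ]
        return cls(genes=genes, roles=roles, blacklist=blacklist)

    def _by_role(self, role: str) -> list[str]:
        return [g for g, r in self.roles.items() if r == role]

    @property
    def feature_genes(self) -> list[str]:
        return [g for g in FEATURE_GENES]

    @property
    def chr8q_genes(self) -> list[str]:
        return self._by_role("chr8q")

    @property
    def chip_genes(self) -> list[str]:
        return self._by_role("chip")

    @property
    def excluded_genes(self) -> list[str]:
        return self._by_role("excluded")

    @property
    def sv_feature_genes(self) -> list[str]:
        return [g for g in SV_FEATURE_GENES]

    def interval(self, gene: str) -> GenomicInterval:
        return self.genes[gene]

    def genes_overlapping(self, interval: GenomicInterval) -> list[str]:
        return [g for g, iv in self.genes.items() if iv.overlaps(interval)]

    def gene_at(self, chrom: str, pos: int) -> str | None:
        """First registered gene containing the point, or None."""
        for g, iv in self.genes.items():
            if iv.contains_point(chrom, pos):
                return g
        return None

    def in_blacklist(self, interval: GenomicInterval) -> bool:
        return any(interval.overlaps(bl) for bl in self.blacklist)

    def snv_gene(self, gene: str | None) -> str | None:
        """Map a gene symbol to its SNV-summary locus (CDKN2A/B merged)."""
        if gene in ("CDKN2A", "CDKN2B"):
            return CDKN2AB
        return gene
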