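"""Gene-level copy-number profiling from bin-level log2 coverage ratios.

Bin ratios (CNVkit-style ``.cnr`` rows) are aggregated per gene with a
symmetric trimmed mean, then normalized two ways: a z-score against the
healthy background panel (per-gene mean/SD over panel samples) and a
cohort-scaled value (log2 divided by the per-gene SD across the case
cohort).  Both normalizations feed the classifier.  A clonal single-copy
loss at tumor fraction TF shifts the expected gene log2 by log2(1 - TF/2);
a single-copy gain by log2(1 + TF/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneRegistry, GenomicInterval, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "CnaConfig",
    "GeneCnaProfile",
    "read_bins",
    "flag_bins",
    "trimmed_gene_log2",
    "gene_profiles",
    "healthy_reference",
    "gene_zscore",
    "chr8q_composite",
]

BIN_COLUMNS = ["chrom", "start", "end", "log2_ratio", "n_reads"]


@dataclass
class CnaConfig:
    """Aggregation and normalization knobs.

    ``trim_frac`` is trimmed per tail.  Bins with fewer than ``min_reads``
    reads or |log2| above ``max_abs_log2`` are flagged and never contribute
    to gene aggregation.  ``sd_floor`` prevents z-score blow-ups when the
    panel is degenerate.  ``recenter`` subtracts each sample's median bin
    log2 before aggregation to absorb global technical shifts.
    """

    trim_frac: float = 0.10
    min_reads: int = 30
    max_abs_log2: float = 3.0
    sd_floor: float = 0.01
    min_panel_samples: int = 3
    recenter: bool = True


@dataclass
class GeneCnaProfile:
    """Per-sample, per-gene copy-number summary."""

    sample_id: str
    gene: str
    log2: float
    z: float | None = None
    scaled: float | None = None
    n_bins_used: int = 0


def read_bins(path: str | Path) -> pd.DataFrame:
    """Read a BED-like bin TSV (chrom, start, end, log2_ratio, n_reads)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bin file {path} missing column(s): {missing}")
    df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)
    return df


def flag_bins(bins: pd.DataFrame, config: CnaConfig | None = None) -> pd.DataFrame:
    """Mark low-depth and high-variance bins; flagged bins are excluded."""
    cfg = config or CnaConfig()
    out = bins.copy()
    out["flagged_low_depth"] = out["n_reads"] < cfg.min_reads
    out["flagged_high_variance"] = out["log2_ratio"].abs() > cfg.max_abs_log2
    return out


def trimmed_gene_log2(
    log2_values: Sequence[float], trim_frac: float = 0.10
) -> tuple[float, int]:
    """Symmetric trimmed mean of a gene's unflagged bin log2 ratios.

    Returns (value, n_bins_used).  Falls back to the median (with a logged
    note) if trimming would remove every bin.  Raises on empty input: a
    gene with zero usable bins is *missing*, not zero.
    """
    if not 0 <= trim_frac < 0.5:
        raise ValueError(f"trim_frac must be in [0, 0.5), got {trim_frac}")
    x = np.asarray(log2_values, dtype=float)
    if x.size == 0:
        raise ValueError("no unflagged bins; gene must be reported as missing")
    n_cut = int(x.size * trim_frac)
    if 2 * n_cut >= x.size:
        logger.info("trimming would remove all %d bins; falling back to median", x.size)
        return float(np.median(x)), int(x.size)
    return float(stats.trim_mean(x, trim_frac)), int(x.size)


def gene_profiles(
    bins: pd.DataFrame,
    registry: GeneRegistry,
    sample_id: str,
    config: CnaConfig | None = None,
) -> dict[str, GeneCnaProfile]:
    """Aggregate one sample's bins into per-gene trimmed-average log2 values.

    Genes in the registry's excluded set (ATRX) are never emitted; genes
    with no usable bins are absent from the result (missing, not zero).
    """
    cfg = config or CnaConfig()
    flagged = flag_bins(bins, cfg)
    usable = flagged[~(flagged["flagged_low_depth"] | flagged["flagged_high_variance"])]
    if cfg.recenter and len(usable):
        usable = usable.assign(log2_ratio=usable["log2_ratio"] - usable["log2_ratio"].median())
    excluded = set(registry.excluded_genes)
    profiles: dict[str, GeneCnaProfile] = {}
    for gene, iv in registry.genes.items():
        if gene in excluded:
            continue
        mask = (
            (usable["chrom"] == iv.chrom)
            & (usable["start"] < iv.end)
            & (usable["end"] > iv.start)
        )
        values = usable.loc[mask, "log2_ratio"].to_numpy()
        if values.size == 0:
            continue
        log2, n_used = trimmed_gene_log2(values, cfg.trim_frac)
        profiles[gene] = GeneCnaProfile(sample_id=sample_id, gene=gene, log2=log2, n_bins_used=n_used)
    return profiles


def healthy_reference(
    panel_log2: Mapping[str, Sequence[float]],
    config: CnaConfig | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-gene (mean, SD) over the healthy background panel.

    Sample SD (ddof=1), floored at ``sd_floor`` so degenerate panels never
    divide by ~zero; a floored gene logs a warning.  Raises naming the gene
    when fewer panel samples than the configured minimum are available.
    """
    cfg = config or CnaConfig()
    ref = {}
    for gene, values in panel_log2.items():
        x = np.asarray(values, dtype=float)
        if x.size < cfg.min_panel_samples:
            raise ValueError(
                f"gene {gene}: {x.size} panel samples < required {cfg.min_panel_samples}"
            )
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        if sd < cfg.sd_floor:
            logger.warning("gene %s: panel SD %.4g floored at %g", gene, sd, cfg.sd_floor)
            sd = cfg.sd_floor
        ref[gene] = (mean, sd)
    return ref


def gene_zscore(log2: float, ref: tuple[float, float]) -> float:
    """Healthy-referenced z-score: (log2 - panel mean) / panel SD."""
    mean, sd = ref
    return (log2 - mean) / sd


def attach_zscores(
    profiles: dict[str, GeneCnaProfile],
    reference: Mapping[str, tuple[float, float]],
) -> dict[str, GeneCnaProfile]:
    """Fill the z field of each profile from the panel reference (in place)."""
    for gene, prof in profiles.items():
        if gene not in reference:
            raise KeyError(f"no healthy reference for gene {gene}")
        prof.z = gene_zscore(prof.log2, reference[gene])
    return profiles


def chr8q_composite(
    profiles: Mapping[str, GeneCnaProfile], registry: GeneRegistry
) -> tuple[float, float | None, int] | None:
    """Unweighted mean over available chr8q candidate-oncogene profiles.

    Returns (log2, z, n_genes) or None when every chr8q gene is missing
    (downstream imputation handles the None).
    """
    members = [profiles[g] for g in registry.chr8q_genes if g in profiles]
    if not members:
        return None
    log2 = float(np.mean([m.log2 for m in members]))
    zs = [m.z for m in members if m.z is not None]
    z = float(np.mean(zs)) if len(zs) == len(members) else None
    return log2, z, len(members)


def expected_loss_log2(tf: float, copies_lost: int = 1) -> float:
    """Expected log2 shift for a clonal deletion at tumor fraction ``tf``."""
    return float(np.log2(1.0 - copies_lost * tf / 2.0))


def expected_gain_log2(tf: float, copies_gained: int = 1) -> float:
    """Expected log2 shift for a clonal gain at tumor fraction ``tf``."""
    return float(np.log2(1.0 + copies_gained * tf / 2.0))
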