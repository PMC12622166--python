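"""Assembly of the integrated per-sample feature matrix.

Per feature gene (CDKN2A, CDKN2B, TP53, SUZ12, EED) and the chr8q
composite, the matrix carries three continuous copy-number columns
(trimmed-average log2, cohort-scaled log2, healthy-referenced z) plus,
per tumor-suppressor locus, the ordinal SNV severity rank (0-6) and a
multi-hit indicator, the 3-level SV category per SV feature gene, and the
chr8-duplication flag.  Continuous CNA columns are standardized before
model inclusion; ordinal columns pass through unscaled.  Scaling
parameters are returned separately so cross-validation can refit them
inside each training fold (no leakage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CDKN2AB, GeneRegistry, SampleRecord
from .cna import GeneCnaProfile, chr8q_composite

logger = logging.getLogger(__name__)

__all__ = ["FeatureConfig", "build_feature_matrix", "scale_features", "cna_columns"]

CHR8Q = "chr8q"
CNA_FEATURE_UNITS = ("CDKN2A", "CDKN2B", "TP53", "SUZ12", "EED", CHR8Q)
SNV_FEATURE_LOCI = (CDKN2AB, "TP53", "SUZ12", "EED")


@dataclass
class FeatureConfig:
    #: impute missing CNA values to 0 (copy-neutral prior) or cohort median
    impute: str = "zero"
    #: manually excluded variant keys (known germline in unrelated patients)
    excluded_variant_keys: frozenset = frozenset()


def cna_columns() -> list[str]:
    cols = []
    for unit in CNA_FEATURE_UNITS:
        cols += [f"cna_log2_{unit}", f"cna_scaled_{unit}", f"cna_z_{unit}"]
    return cols


def feature_columns() -> list[str]:
    """Fixed feature ordering used across every cohort."""
    cols = cna_columns()
    for locus in SNV_FEATURE_LOCI:
        cols += [f"snv_rank_{locus}", f"snv_multi_{locus}"]
    for gene in ("TP53", "SUZ12", "EED"):
        cols.append(f"sv_cat_{gene}")
    cols.append("chr8_dup")
    return cols


def build_feature_matrix(
    samples: Sequence[SampleRecord],
    cna: Mapping[str, Mapping[str, GeneCnaProfile]],
    snv: Mapping[str, Mapping[str, dict]],
    sv: Mapping[str, tuple[dict, bool]],
    registry: GeneRegistry,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """One row per case cfDNA sample, fixed column order, label attached.

    ``cna`` maps sample_id -> gene -> profile (z already attached);
    ``snv`` maps sample_id -> locus -> {max_rank, multi_hit};
    ``sv`` maps sample_id -> ({gene: category}, chr8_dup).

    Missing CNA units are imputed to copy-neutral 0 (count logged);
    absent SNV/SV summaries encode as 0/none by construction.  A sample
    present in the manifest but absent from *all* three inputs raises —
    silent feature/label misalignment is worse than a crash.
    """
    cfg = config or FeatureConfig()
    ordered = sorted(samples, key=lambda r: r.sample_id)
    rows = {}
    n_imputed = 0
    for rec in ordered:
        sid = rec.sample_id
        if sid not in cna and sid not in snv and sid not in sv:
            raise ValueError(
                f"sample {sid} is in the manifest but absent from every input"
            )
        profiles = cna.get(sid, {})
        row: dict[str, float] = {}
        for unit in CNA_FEATURE_UNITS:
            if unit == CHR8Q:
                comp = chr8q_composite(profiles, registry)
                log2, z = (comp[0], comp[1]) if comp else (None, None)
            else:
                prof = profiles.get(unit)
                log2, z = (prof.log2, prof.z) if prof else (None, None)
            if log2 is None:
                n_imputed += 1
                log2, z = 0.0, 0.0
            row[f"cna_log2_{unit}"] = log2
            row[f"cna_z_{unit}"] = 0.0 if z is None else z
            row[f"cna_scaled_{unit}"] = np.nan  # filled after cohort SD known
        gene_snv = snv.get(sid, {})
        for locus in SNV_FEATURE_LOCI:
            entry = gene_snv.get(locus, {"max_rank": 0, "multi_hit": False})
            row[f"snv_rank_{locus}"] = int(entry["max_rank"])
            row[f"snv_multi_{locus}"] = int(bool(entry["multi_hit"]))
        categories, chr8_dup = sv.get(sid, ({}, False))
        for gene in ("TP53", "SUZ12", "EED"):
            row[f"sv_cat_{gene}"] = int(categories.get(gene, 0))
        row["chr8_dup"] = int(chr8_dup)
        rows[sid] = row
    if n_imputed:
        logger.info("imputed %d missing CNA values to copy-neutral 0", n_imputed)
    matrix = pd.DataFrame.from_dict(rows, orient="index")

    # cohort-scaled CNA: log2 divided by the per-unit SD across the cohort
    for unit in CNA_FEATURE_UNITS:
        col = matrix[f"cna_log2_{unit}"]
        sd = float(col.std(ddof=1))
        matrix[f"cna_scaled_{unit}"] = col / sd if sd > 0 else 0.0

    matrix = matrix[feature_columns()]
    matrix.index.name = "sample_id"
    matrix["label"] = [r.class_label.value for r in ordered]
    return matrix


def scale_features(
    matrix: pd.DataFrame,
    train_index: Sequence | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Standardize continuous CNA columns; ordinal columns pass through.

    Mean/SD come from ``train_index`` rows only (all rows when None) and
    are returned so held-out rows can be transformed with training
    parameters.  Zero-variance columns are left at 0 with a warning.
    """
    features = matrix.drop(columns=["label"], errors="ignore")
    train = features.loc[train_index] if train_index is not None else features
    scaled = features.copy().astype(float)
    params: dict[str, tuple[float, float]] = {}
    for col in cna_columns():
        mean = float(train[col].mean())
        sd = float(train[col].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            logger.warning("zero-variance CNA column %s left at 0", col)
            scaled[col] = 0.0
            params[col] = (mean, 0.0)
        else:
            scaled[col] = (features[col] - mean) / sd
            params[col] = (mean, sd)
    if "label" in matrix.columns:
        scaled["label"] = matrix["label"]
    return scaled, params
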