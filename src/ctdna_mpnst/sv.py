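"""Multi-caller structural-variant consensus merging and per-gene burden.

Calls from several SV callers (e.g. Delly, Lumpy, Manta pseudo-outputs)
are merged by single-linkage clustering: two same-type calls join when
both breakpoints lie within 100 bp.  Consensus events are kept when at
least two distinct callers support them and (for non-translocations) the
event spans at least 200 bp.  Plasma events additionally need both
split-read and discordant-pair evidence; events matching anything in the
merged control set are removed, as are events in blacklist regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneRegistry, GenomicInterval, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "SvCall",
    "ConsensusSv",
    "MergeConfig",
    "cluster_calls",
    "merge_calls",
    "cfdna_evidence_filter",
    "remove_control_events",
    "gene_sv_category",
    "read_bedpe",
    "write_bedpe",
]

SVTYPES = ("DEL", "DUP", "INV", "TRA")


@dataclass(frozen=True)
class SvCall:
    """One caller's observation of one structural variant in one sample."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    svtype: str
    caller: str
    sample_id: str
    split_reads: int = 0
    discordant_pairs: int = 0

    def __post_init__(self):
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.split_reads < 0 or self.discordant_pairs < 0:
            raise ValueError("read-support counts must be non-negative")
        if self.svtype != "TRA" and self.chrom1 != self.chrom2:
            raise ValueError(f"{self.svtype} must be intra-chromosomal")

    @property
    def size(self) -> int | None:
        if self.svtype == "TRA":
            return None
        return abs(self.pos2 - self.pos1)


@dataclass
class ConsensusSv:
    """Merged event: representative breakpoints are member-position medians."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    svtype: str
    supporting_callers: frozenset[str]
    member_calls: list[SvCall] = field(default_factory=list)
    split_reads: int = 0
    discordant_pairs: int = 0
    genes_disrupted: list[str] = field(default_factory=list)
    sample_id: str = ""

    @property
    def size(self) -> int | None:
        if self.svtype == "TRA":
            return None
        return abs(self.pos2 - self.pos1)


@dataclass
class MergeConfig:
    max_bp_dist: int = 100
    min_size: int = 200
    min_callers: int = 2
    min_split: int = 2
    min_disc: int = 2


def _low_median(values: Sequence[int]) -> int:
    """Median with ties broken toward the lower value (even-length lists)."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def _compatible(a: SvCall, b: SvCall, max_bp_dist: int) -> bool:
    return (
        a.svtype == b.svtype
        and a.chrom1 == b.chrom1
        and a.chrom2 == b.chrom2
        and abs(a.pos1 - b.pos1) <= max_bp_dist
        and abs(a.pos2 - b.pos2) <= max_bp_dist
    )


def cluster_calls(calls: Sequence[SvCall], max_bp_dist: int = 100) -> list[list[SvCall]]:
    """Single-linkage clusters over the same-type/within-distance relation.

    Calls are canonically sorted first so the partition is invariant to
    input order.  Union-find over all compatible pairs gives the
    transitive closure.
    """
    ordered = sorted(
        calls,
        key=lambda c: (c.svtype, c.chrom1, c.pos1, c.chrom2, c.pos2, c.caller),
    )
    parent = list(range(len(ordered)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if _compatible(ordered[i], ordered[j], max_bp_dist):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[SvCall]] = {}
    for i, call in enumerate(ordered):
        clusters.setdefault(find(i), []).append(call)
    return [clusters[k] for k in sorted(clusters)]


def _consensus_from_cluster(members: list[SvCall]) -> ConsensusSv:
    return ConsensusSv(
        chrom1=members[0].chrom1,
        pos1=_low_median([m.pos1 for m in members]),
        chrom2=members[0].chrom2,
        pos2=_low_median([m.pos2 for m in members]),
        svtype=members[0].svtype,
        supporting_callers=frozenset(m.caller for m in members),
        member_calls=members,
        split_reads=max(m.split_reads for m in members),
        discordant_pairs=max(m.discordant_pairs for m in members),
        sample_id=members[0].sample_id,
    )


def merge_calls(
    calls: Sequence[SvCall],
    max_bp_dist: int = 100,
    min_size: int = 200,
    min_callers: int = 2,
) -> list[ConsensusSv]:
    """Merge one sample's multi-caller calls into consensus events.

    Clusters smaller than ``min_size`` (translocations exempt) or with
    fewer than ``min_callers`` distinct callers are discarded.  Output is
    sorted by chromosome and position.
    """
    events = []
    for members in cluster_calls(calls, max_bp_dist):
        ev = _consensus_from_cluster(members)
        if len(ev.supporting_callers) < min_callers:
            continue
        if ev.svtype != "TRA" and (ev.size or 0) < min_size:
            continue
        events.append(ev)
    events.sort(key=lambda e: (e.chrom1, e.pos1, e.chrom2, e.pos2, e.svtype))
    return events


def cfdna_evidence_filter(
    ev: ConsensusSv,
    min_split: int = 2,
    min_disc: int = 2,
    is_tumor: bool = False,
) -> tuple[bool, list[str]]:
    """Plasma events need BOTH split-read and discordant-pair support.

    Tumor-sample events bypass the depth requirement entirely.
    """
    if is_tumor:
        return True, []
    reasons = []
    if ev.split_reads < min_split:
        reasons.append("SPLIT_READS_LOW")
    if ev.discordant_pairs < min_disc:
        reasons.append("DISCORDANT_PAIRS_LOW")
    return not reasons, reasons


def remove_control_events(
    events: Sequence[ConsensusSv],
    control_events: Sequence[ConsensusSv],
    max_bp_dist: int = 100,
) -> list[ConsensusSv]:
    """Drop events matching any control event (same type, both breakpoints
    within ``max_bp_dist``); an empty control set is the identity."""
    kept = []
    for ev in events:
        hit = next(
            (
                c
                for c in control_events
                if c.svtype == ev.svtype
                and c.chrom1 == ev.chrom1
                and c.chrom2 == ev.chrom2
                and abs(c.pos1 - ev.pos1) <= max_bp_dist
                and abs(c.pos2 - ev.pos2) <= max_bp_dist
            ),
            None,
        )
        if hit is not None:
            logger.info(
                "event %s:%d-%s:%d (%s) removed: matches control at %s:%d",
                ev.chrom1, ev.pos1, ev.chrom2, ev.pos2, ev.svtype, hit.chrom1, hit.pos1,
            )
            continue
        kept.append(ev)
    return kept


def apply_blacklist(
    events: Sequence[ConsensusSv], registry: GeneRegistry
) -> list[ConsensusSv]:
    """Drop events whose breakpoints fall in blacklist/low-complexity regions."""
    kept = []
    for ev in events:
        bp1 = GenomicInterval(ev.chrom1, ev.pos1, ev.pos1 + 1)
        bp2 = GenomicInterval(ev.chrom2, ev.pos2, ev.pos2 + 1)
        if registry.in_blacklist(bp1) or registry.in_blacklist(bp2):
            continue
        kept.append(ev)
    return kept


def annotate_genes(events: Sequence[ConsensusSv], registry: GeneRegistry) -> None:
    """Fill genes_disrupted: breakpoint-in-gene or event-spans-gene (in place)."""
    for ev in events:
        hits = set()
        for chrom, pos in ((ev.chrom1, ev.pos1), (ev.chrom2, ev.pos2)):
            g = registry.gene_at(chrom, pos)
            if g:
                hits.add(g)
        if ev.svtype != "TRA" and ev.chrom1 == ev.chrom2:
            span = GenomicInterval(ev.chrom1, min(ev.pos1, ev.pos2), max(ev.pos1, ev.pos2) + 1)
            hits.update(registry.genes_overlapping(span))
        ev.genes_disrupted = sorted(hits)


def gene_sv_category(
    events: Sequence[ConsensusSv], registry: GeneRegistry
) -> tuple[dict[str, int], bool]:
    """Per-gene event burden as a 3-level category plus the chr8-dup flag.

    Returns ({gene: 0 none / 1 single / 2 multiple}, chr8_dup).
    Translocations are excluded from per-gene features; chr8_dup is true
    when any retained duplication has a breakpoint on chromosome 8.
    """
    annotate_genes(events, registry)
    counts = {g: 0 for g in registry.sv_feature_genes}
    chr8_dup = False
    for ev in events:
        if ev.svtype == "DUP" and "8" in (ev.chrom1, ev.chrom2):
            chr8_dup = True
        if ev.svtype == "TRA":
            continue
        for g in ev.genes_disrupted:
            if g in counts:
                counts[g] += 1
    categories = {g: min(n, 2) for g, n in counts.items()}
    return categories, chr8_dup


# --- BEDPE input/output ------------------------------------------------------

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
    "svtype", "caller", "split_reads", "discordant_pairs",
]


def write_bedpe(calls: Sequence[SvCall] | Sequence[ConsensusSv], path: str | Path) -> None:
    """Write calls or consensus events as BEDPE with caller/support columns."""
    rows = []
    for c in calls:
        caller = (
            ",".join(sorted(c.supporting_callers))
            if isinstance(c, ConsensusSv)
            else c.caller
        )
        rows.append(
            {
                "chrom1": c.chrom1, "start1": c.pos1, "end1": c.pos1 + 1,
                "chrom2": c.chrom2, "start2": c.pos2, "end2": c.pos2 + 1,
                "name": f"{c.svtype}_{c.chrom1}_{c.pos1}", "score": ".",
                "strand1": ".", "strand2": ".",
                "svtype": c.svtype, "caller": caller,
                "split_reads": c.split_reads, "discordant_pairs": c.discordant_pairs,
            }
        )
    pd.DataFrame(rows, columns=BEDPE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bedpe(path: str | Path, sample_id: str = "") -> list[SvCall]:
    """Read per-caller SV calls from BEDPE (one row per caller observation)."""
    df = pd.read_csv(path, sep="\t")
    calls = []
    for row in df.itertuples(index=False):
        for caller in str(row.caller).split(","):
            calls.append(
                SvCall(
                    chrom1=normalize_chrom(str(row.chrom1)),
                    pos1=int(row.start1),
                    chrom2=normalize_chrom(str(row.chrom2)),
                    pos2=int(row.start2),
                    svtype=row.svtype,
                    caller=caller,
                    sample_id=sample_id,
                    split_reads=int(row.split_reads),
                    discordant_pairs=int(row.discordant_pairs),
                )
            )
    return calls
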