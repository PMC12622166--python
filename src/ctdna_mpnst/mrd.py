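"""Tumor-informed longitudinal MRD tracking across serial plasma samples.

A patient's tracked set is built from tumor-confirmed variants (plus
their detectability in pretreatment plasma) or, lacking tumor tissue,
from retained pretreatment plasma variants.  "Detected" at a timepoint
means the variant passes the full cfDNA filter chain in that sample —
raw caller output never counts.  Structural variants match by consensus
breakpoints within 100 bp at both ends.  Molecular clearance, relapse,
and the lead time of molecular relapse over clinical recurrence are
derived from the ordered observation series.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

from .sv import ConsensusSv

logger = logging.getLogger(__name__)

__all__ = [
    "MrdStatus",
    "ClinicalEvent",
    "Observation",
    "MrdTimeline",
    "MrdCall",
    "derive_tracked_set",
    "call_mrd_status",
    "lead_time",
    "match_sv_key",
]


class MrdStatus(str, Enum):
    CLEARANCE = "clearance"
    MOLECULAR_RELAPSE = "molecular_relapse"
    PERSISTENT = "persistent"
    INDETERMINATE = "indeterminate"


class EventType(str, Enum):
    RESECTION = "resection"
    IMAGING_NED = "imaging_NED"
    CLINICAL_RECURRENCE = "clinical_recurrence"


@dataclass(frozen=True)
class ClinicalEvent:
    timepoint_days: int
    event: EventType


@dataclass
class Observation:
    """One plasma draw: per-tracked-variant detection state and AF."""

    timepoint_days: int
    detected: dict[str, bool]
    af: dict[str, float] = field(default_factory=dict)

    @property
    def any_detected(self) -> bool:
        return any(self.detected.values())


@dataclass
class MrdTimeline:
    patient_id: str
    tracked_variants: list[str]
    observations: list[Observation]
    clinical_events: list[ClinicalEvent] = field(default_factory=list)

    def __post_init__(self):
        days = [o.timepoint_days for o in self.observations]
        if days != sorted(days) or len(set(days)) != len(days):
            raise ValueError(
                f"patient {self.patient_id}: observations must be strictly time-ordered"
            )


@dataclass
class MrdCall:
    status: MrdStatus
    first_positive_after_treatment: int | None = None
    lead_time_days: int | None = None


def derive_tracked_set(
    tumor_variant_keys: Sequence,
    pretreatment_plasma_keys: Sequence,
) -> list[tuple[object, str]]:
    """Tracked variants with provenance.

    With tumor tissue available the tumor calls define the set; each is
    tagged ``tumor+plasma`` when also detectable pretreatment, else
    ``tumor_only`` (still trackable).  Without tumor, pretreatment plasma
    variants are tracked as ``plasma_only``.  Both sources empty yields
    an empty set (MRD will be indeterminate, not an error).
    """
    tumor = list(dict.fromkeys(tumor_variant_keys))
    plasma = set(pretreatment_plasma_keys)
    if tumor:
        return [(k, "tumor+plasma" if k in plasma else "tumor_only") for k in tumor]
    return [(k, "plasma_only") for k in dict.fromkeys(pretreatment_plasma_keys)]


def call_mrd_status(timeline: MrdTimeline, treatment_day: int = 0) -> MrdCall:
    """Classify the post-treatment trajectory.

    clearance: every post-treatment draw negative for all tracked variants.
    molecular_relapse: a negative post-treatment draw followed by any
    tracked-variant detection.  persistent: never negative post-treatment.
    indeterminate: no tracked variants or no post-treatment draws.
    Clearance and relapse are mutually exclusive by construction.
    """
    if not timeline.tracked_variants:
        return MrdCall(status=MrdStatus.INDETERMINATE)
    post = [o for o in timeline.observations if o.timepoint_days > treatment_day]
    if not post:
        return MrdCall(status=MrdStatus.INDETERMINATE)
    seen_negative = False
    for obs in post:
        if obs.any_detected:
            if seen_negative:
                return MrdCall(
                    status=MrdStatus.MOLECULAR_RELAPSE,
                    first_positive_after_treatment=obs.timepoint_days,
                )
        else:
            seen_negative = True
    if not seen_negative:
        return MrdCall(
            status=MrdStatus.PERSISTENT,
            first_positive_after_treatment=post[0].timepoint_days,
        )
    if any(o.any_detected for o in post):
        # positive draws existed but only before the first negative
        return MrdCall(status=MrdStatus.CLEARANCE)
    return MrdCall(status=MrdStatus.CLEARANCE)


def lead_time(call: MrdCall, clinical_events: Sequence[ClinicalEvent]) -> int | None:
    """Days by which molecular relapse preceded clinical recurrence.

    Defined only for molecular relapse with a recurrence event at or
    after the first positive draw; the earliest qualifying recurrence is
    used (and logged when several exist).  Molecular detection after the
    clinical diagnosis yields None.
    """
    if call.status is not MrdStatus.MOLECULAR_RELAPSE:
        return None
    if call.first_positive_after_treatment is None:
        return None
    recurrences = sorted(
        e.timepoint_days
        for e in clinical_events
        if e.event is EventType.CLINICAL_RECURRENCE
        and e.timepoint_days >= call.first_positive_after_treatment
    )
    if not recurrences:
        return None
    if len(recurrences) > 1:
        logger.info("multiple clinical recurrences; using earliest at day %d", recurrences[0])
    days = recurrences[0] - call.first_positive_after_treatment
    call.lead_time_days = days
    return days


def match_sv_key(
    tracked: ConsensusSv, observed: Sequence[ConsensusSv], max_bp_dist: int = 100
) -> bool:
    """Does any observed consensus SV match the tracked event?

    Same type, both breakpoints within ``max_bp_dist`` — the same
    tolerance used for control-event removal.
    """
    return any(
        o.svtype == tracked.svtype
        and o.chrom1 == tracked.chrom1
        and o.chrom2 == tracked.chrom2
        and abs(o.pos1 - tracked.pos1) <= max_bp_dist
        and abs(o.pos2 - tracked.pos2) <= max_bp_dist
        for o in observed
    )


def timeline_report(timeline: MrdTimeline, call: MrdCall) -> dict:
    """JSON-serializable per-patient MRD report."""
    return {
        "patient_id": timeline.patient_id,
        "tracked_variants": [str(v) for v in timeline.tracked_variants],
        "status": call.status.value,
        "first_positive_after_treatment": call.first_positive_after_treatment,
        "lead_time_days": call.lead_time_days,
        "observations": [
            {
                "timepoint_days": o.timepoint_days,
                "n_detected": sum(o.detected.values()),
                "detected": {k: bool(v) for k, v in o.detected.items()},
            }
            for o in timeline.observations
        ],
        "clinical_events": [
            {"timepoint_days": e.timepoint_days, "event": e.event.value}
            for e in timeline.clinical_events
        ],
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
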