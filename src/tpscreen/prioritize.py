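"""Monitoring-knowledge prioritization and identification confidence.

This is the second half of the two-step workflow: hits that survived
the chemical gates are weighed against what the monitoring program
knows about their parent pesticides — registration, application
history, detections, and relative soil mobility (K_foc).  Weak chemical
evidence can be rescued by monitoring support; contradicted source
plausibility never deletes a strong identification but flags it as
likely originating elsewhere.

Identification certainty is communicated on the ordinal 1-5 scale
standard in HRMS screening (1 = confirmed by reference standard,
2a = library spectrum match, 2b = diagnostic evidence, 3 = tentative
candidate, 4 = unequivocal molecular formula, 5 = exact mass only).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta
from functools import total_ordering
from typing import Iterable, Sequence

from .data_io import (
    MonitoringApplicationEvent,
    MonitoringDetectionRecord,
    StandardRecord,
)
from .screening import CandidateHit, ScreeningConfig, ms2_tol_da
from .suspects import SuspectEntry

__all__ = [
    "MonitoringEvidence",
    "ConfidenceLevel",
    "collect_monitoring_evidence",
    "decide_retention",
    "assign_confidence_level",
    "confirm_with_standard",
    "dedupe_across_polarity",
    "UniqueStructure",
]

_LEVELS = ("1", "2a", "2b", "3", "4", "5")


@total_ordering
@dataclass(frozen=True)
class ConfidenceLevel:
    """Ordinal identification-confidence level; lower = more confident."""

    value: str

    def __post_init__(self) -> None:
        if self.value not in _LEVELS:
            raise ValueError(f"bad confidence level {self.value!r}")

    @property
    def rank(self) -> int:
        return _LEVELS.index(self.value)

    def __lt__(self, other: "ConfidenceLevel") -> bool:
        return self.rank < other.rank

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class MonitoringEvidence:
    """Per-suspect, per-site summary of what monitoring knows."""

    parent_registered_at_site: bool
    parent_applied_at_site: bool
    last_application_date: date | None
    parent_detected_at_site: bool
    parent_detection_weeks: tuple[date, ...]
    mobility_flag: bool | None  # TP K_foc < parent K_foc (more mobile)
    source_plausibility: str  # supported | neutral | contradicted


def collect_monitoring_evidence(
    suspect: SuspectEntry,
    site: str,
    applications: Iterable[MonitoringApplicationEvent],
    detections: Iterable[MonitoringDetectionRecord],
    registry_sites: dict[str, Sequence[str]],
    sample_date: date,
    lookback_years: int = 10,
    parent_k_foc: dict[str, float] | None = None,
) -> MonitoringEvidence:
    """Summarize parent-pesticide monitoring knowledge for one suspect.

    ``registry_sites`` maps compound_id -> sites with registered use;
    application/detection flags are restricted to a lookback window of
    ``lookback_years`` ending at ``sample_date``.  A suspect that is its
    own parent (target or added parent) is evaluated against itself.

    ``source_plausibility`` is *supported* when any site-local flag is
    true, *contradicted* when the parent has no registration,
    application or detection anywhere, and *neutral* otherwise.
    """
    parents = set(suspect.parent_ids) or {suspect.suspect_id}
    cutoff = sample_date - timedelta(days=round(365.25 * lookback_years))

    registered = any(
        site in registry_sites.get(p, ()) for p in parents
    )
    registered_anywhere = any(registry_sites.get(p) for p in parents)

    apps_here = sorted(
        e.date
        for e in applications
        if e.compound_id in parents and e.site == site and cutoff <= e.date <= sample_date
    )
    apps_anywhere = any(
        e.compound_id in parents and cutoff <= e.date <= sample_date
        for e in applications
    )
    det_weeks = sorted(
        {
            d.week
            for d in detections
            if d.compound_id in parents
            and d.site == site
            and d.concentration_ug_l > 0
            and cutoff <= d.week <= sample_date
        }
    )
    det_anywhere = any(
        d.compound_id in parents and d.concentration_ug_l > 0
        and cutoff <= d.week <= sample_date
        for d in detections
    )

    mobility: bool | None = None
    if suspect.k_foc is not None and parent_k_foc:
        pk = [parent_k_foc[p] for p in parents if p in parent_k_foc]
        if pk:
            mobility = suspect.k_foc < min(pk)

    applied = bool(apps_here)
    detected = bool(det_weeks)
    if registered or applied or detected:
        plaus = "supported"
    elif not (registered_anywhere or apps_anywhere or det_anywhere):
        plaus = "contradicted"
    else:
        plaus = "neutral"

    return MonitoringEvidence(
        parent_registered_at_site=registered,
        parent_applied_at_site=applied,
        last_application_date=apps_here[-1] if apps_here else None,
        parent_detected_at_site=detected,
        parent_detection_weeks=tuple(det_weeks),
        mobility_flag=mobility,
        source_plausibility=plaus,
    )


def decide_retention(
    hit: CandidateHit, ev: MonitoringEvidence
) -> tuple[str, str]:
    """Retain-or-discard decision integrating monitoring knowledge.

    Strong/moderate chemical evidence always retains.  Weak-evidence
    hits are rescued when monitoring shows the parent applied or
    detected at the site; otherwise they are discarded.  Contradicted
    source plausibility never discards a strong hit — it attaches a
    source warning (the identified structure likely came from a
    different source than the presumed parent).
    """
    tier = hit.chem_evidence_tier
    if tier in ("strong", "moderate"):
        if ev.source_plausibility == "contradicted":
            hit.source_warning = True
            return "retain", "chemical evidence; source contradicted by monitoring"
        return "retain", "chemical evidence"
    if ev.parent_applied_at_site or ev.parent_detected_at_site:
        return "retain", "monitoring rescue"
    return "discard", "weak evidence without monitoring support"


def assign_confidence_level(
    hit: CandidateHit,
    ev: MonitoringEvidence,
    library_had_record: bool,
    formula_unequivocal: bool,
    total_diagnostics: int | None = None,
    total_library_peaks: int | None = None,
) -> ConfidenceLevel:
    """Map accumulated evidence onto the 1-5 confidence scale.

    2a: full library-spectrum match (>= 2 library fragments including
    every diagnostic one the library lists, ``total_diagnostics``);
    2b: >= 2 diagnostic fragments without a full match; 3: exactly one
    supporting fragment; 4: no usable fragments but the molecular
    formula is unequivocal (e.g. the isotope pattern fixes the chlorine
    count and a single suspect formula fits); 5: exact mass only.
    Level 1 is reserved for standard confirmation.
    """
    all_diag = (
        hit.n_diagnostic_matched == total_diagnostics
        if total_diagnostics is not None
        else hit.n_diagnostic_matched >= 2
    )
    full_spectrum = (
        hit.n_library_matched == total_library_peaks
        if total_library_peaks is not None
        else True
    )
    if library_had_record and hit.n_library_matched >= 2 and all_diag and full_spectrum:
        level = "2a"
    elif hit.n_diagnostic_matched >= 2:
        level = "2b"
    elif max(hit.n_diagnostic_matched, hit.n_library_matched) == 1:
        level = "3"
    elif formula_unequivocal:
        level = "4"
    else:
        level = "5"
    lvl = ConfidenceLevel(level)
    hit.confidence_level = lvl.value
    return lvl


def confirm_with_standard(
    hit: CandidateHit,
    observed_rt: float,
    observed_ms2: Sequence[tuple[float, float]],
    standard: StandardRecord,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> str:
    """Compare a retained hit against a purchased reference standard.

    Confirmed (level 1) iff the retention times agree within the RT
    tolerance and at least two standard fragments are recovered in the
    observed MS2; otherwise the hit is a false positive.
    """
    if abs(observed_rt - standard.rt) > cfg.rt_tol_min:
        return "false_positive"
    matched = sum(
        1
        for frag_mz, _ in standard.ms2
        if any(abs(mz - frag_mz) <= ms2_tol_da(frag_mz, cfg) for mz, _ in observed_ms2)
    )
    if matched >= 2:
        hit.confidence_level = "1"
        return "confirmed_level_1"
    return "false_positive"


@dataclass(frozen=True)
class UniqueStructure:
    """One suspect structure after cross-polarity deduplication."""

    suspect_id: str
    polarities: tuple[str, ...]
    confidence_level: ConfidenceLevel
    source_warning: bool
    sites: tuple[str, ...]
    hits: tuple[CandidateHit, ...]


def dedupe_across_polarity(hits: Iterable[CandidateHit]) -> list[UniqueStructure]:
    """Collapse retained hits to one record per suspect structure.

    Detections of the same suspect in both ionization polarities (and in
    several samples) merge into a single structure keeping the best
    (lowest) confidence level.  Idempotent.
    """
    by_suspect: dict[str, list[CandidateHit]] = {}
    for h in hits:
        by_suspect.setdefault(h.suspect_id, []).append(h)
    out = []
    for sid in sorted(by_suspect):
        group = by_suspect[sid]
        levels = [ConfidenceLevel(h.confidence_level) for h in group if h.confidence_level]
        best = min(levels) if levels else ConfidenceLevel("5")
        out.append(
            UniqueStructure(
                suspect_id=sid,
                polarities=tuple(sorted({h.polarity for h in group})),
                confidence_level=best,
                source_warning=any(h.source_warning for h in group),
                sites=tuple(sorted({h.site for h in group})),
                hits=tuple(group),
            )
        )
    return out
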