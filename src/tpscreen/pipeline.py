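"""End-to-end orchestration of the screening workflow.

Stage order: suspect-list assembly -> exact-mass matching -> peak/RT
gates -> fragment scoring -> monitoring-knowledge retention ->
confidence levels -> cross-polarity deduplication -> reference-standard
confirmation -> semiquantification -> report.

The pipeline is purely functional over its inputs: identical inputs
give identical outputs, and every gate decision can be captured in a
JSON-lines audit log.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path
from typing import Sequence

import pandas as pd

from .data_io import (
    Feature,
    MonitoringApplicationEvent,
    MonitoringDetectionRecord,
    SpectralLibraryRecord,
    StandardRecord,
    read_applications,
    read_detections,
    read_feature_table,
    read_spectral_library,
    read_standards,
    write_report,
)
from .prioritize import (
    ConfidenceLevel,
    UniqueStructure,
    assign_confidence_level,
    collect_monitoring_evidence,
    confirm_with_standard,
    decide_retention,
    dedupe_across_polarity,
)
from .screening import (
    CandidateHit,
    RtModel,
    ScreeningConfig,
    assess_peak_quality,
    fit_rt_model,
    match_suspects,
    observe_chlorines,
    rt_plausible,
    score_fragments,
)
from .semiquant import fit_matrix_calibration, semiquantify
from .suspects import (
    KeyMetaboliteRecord,
    RegistryEntry,
    SuspectEntry,
    build_suspect_list,
)

__all__ = ["PipelineInputs", "PipelineResult", "run_pipeline", "load_inputs", "run"]

IS_PREFIX = "IS_"


@dataclass
class PipelineInputs:
    """Everything one screening run consumes, in memory."""

    registry: list[RegistryEntry]
    metabolites: list[KeyMetaboliteRecord]
    features: list[Feature]
    library: list[SpectralLibraryRecord]
    applications: list[MonitoringApplicationEvent] = field(default_factory=list)
    detections: list[MonitoringDetectionRecord] = field(default_factory=list)
    standards: list[StandardRecord] = field(default_factory=list)
    rt_calibrants: list[tuple[float, float]] = field(default_factory=list)
    calibration: pd.DataFrame | None = None  # compound_id, site, level_ug_l, area, is_area


@dataclass
class PipelineResult:
    counts: dict[str, int]
    report_rows: list[dict]
    unique_structures: list[UniqueStructure]
    confirmed_ids: list[str]
    false_positive_ids: list[str]
    audit: list[dict] = field(default_factory=list)


def _audit(log: list[dict], stage: str, hit: CandidateHit, outcome: str, **extra) -> None:
    log.append(
        {"stage": stage, "suspect_id": hit.suspect_id, "feature_id": hit.feature_id,
         "outcome": outcome, **extra}
    )


def run_pipeline(
    inputs: PipelineInputs,
    cfg: ScreeningConfig = ScreeningConfig(),
    disable_monitoring: bool = False,
    lookback_years: int = 10,
    audit_path: str | Path | None = None,
) -> PipelineResult:
    """Execute the full workflow over in-memory inputs.

    With ``disable_monitoring`` the retention step keeps only hits with
    strong or moderate chemical evidence — the chemistry-only baseline
    against which monitoring integration is measured.
    """
    audit: list[dict] = []
    suspects = build_suspect_list(inputs.registry, inputs.metabolites)
    by_id = {s.suspect_id: s for s in suspects}
    lib_by_name = {(r.name, r.adduct): r for r in inputs.library}

    sample_features = [f for f in inputs.features
                      if not f.feature_id.startswith(IS_PREFIX)]
    is_areas: dict[tuple[str, date, str], float] = {
        (f.site, f.week, f.polarity): f.area
        for f in inputs.features
        if f.feature_id.startswith(IS_PREFIX)
    }
    feat_by_id = {f.feature_id: f for f in sample_features}

    # -- stage 1: exact-mass matching ----------------------------------
    hits = match_suspects(sample_features, suspects, cfg.ms1_tol_ppm)
    counts = {"matched": len(hits)}

    # -- stage 2: peak shape + retention plausibility ------------------
    rt_model: RtModel | None = None
    if len(inputs.rt_calibrants) >= cfg.min_calibrants:
        rt_model = fit_rt_model(inputs.rt_calibrants, cfg.min_calibrants)
    survivors: list[CandidateHit] = []
    for h in hits:
        f = feat_by_id[h.feature_id]
        pa = assess_peak_quality(f.trace, cfg.min_points, cfg.asymmetry_range,
                                 cfg.min_snr)
        h.peak_quality = "pass" if pa.passed else "fail"
        h.peak_score = pa.score
        if not pa.passed:
            _audit(audit, "peak_quality", h, "fail", reason=pa.reason)
            continue
        s = by_id[h.suspect_id]
        descriptor = math.log10(s.k_foc) if s.k_foc else None
        if rt_model is not None:
            h.rt_plausible = rt_plausible(f.rt, descriptor, rt_model,
                                          cfg.rt_window_spreads)
        if h.rt_plausible == "fail":
            _audit(audit, "rt_plausibility", h, "fail")
            continue
        survivors.append(h)
    counts["after_peak_rt"] = len(survivors)

    # -- stage 3: fragment evidence ------------------------------------
    frag_survivors: list[CandidateHit] = []
    for h in survivors:
        f = feat_by_id[h.feature_id]
        s = by_id[h.suspect_id]
        adduct = "[M+H]+" if h.polarity == "positive" else "[M-H]-"
        rec = lib_by_name.get((s.name, adduct))
        score_fragments(h, f.ms2, rec, s.formula, cfg)
        observe_chlorines(h, f.isotope_cluster, s.formula)
        # a populated spectrum that matches nothing and cannot be
        # explained by the precursor composition refutes the candidate
        contradicted = (
            bool(f.ms2)
            and h.n_library_matched == 0
            and h.subformula_plausible_fraction < 0.5
        )
        if contradicted:
            _audit(audit, "fragments", h, "discard",
                   plausible_fraction=h.subformula_plausible_fraction)
            continue
        frag_survivors.append(h)
    counts["after_fragments"] = len(frag_survivors)

    # -- stage 4: monitoring-knowledge retention -----------------------
    registry_sites = {r.compound_id: list(r.registered_sites)
                      for r in inputs.registry}
    parent_k_foc = {m.parent_id: m.parent_k_foc for m in inputs.metabolites
                    if m.parent_k_foc is not None}
    sample_date = max((f.week for f in sample_features), default=date(2017, 12, 31))
    retained: list[CandidateHit] = []
    for h in frag_survivors:
        s = by_id[h.suspect_id]
        ev = collect_monitoring_evidence(
            s, h.site, inputs.applications, inputs.detections, registry_sites,
            sample_date, lookback_years, parent_k_foc,
        )
        if disable_monitoring:
            decision = ("retain", "chemical evidence") \
                if h.chem_evidence_tier in ("strong", "moderate") \
                else ("discard", "weak evidence (monitoring disabled)")
        else:
            decision = decide_retention(h, ev)
        h.rationale = decision[1]
        _audit(audit, "retention", h, decision[0], rationale=decision[1])
        if decision[0] != "retain":
            continue
        rec = lib_by_name.get(
            (s.name, "[M+H]+" if h.polarity == "positive" else "[M-H]-")
        )
        f = feat_by_id[h.feature_id]
        unequivocal = _formula_unequivocal(h, f, suspects, cfg)
        assign_confidence_level(
            h, ev, library_had_record=rec is not None,
            formula_unequivocal=unequivocal,
            total_diagnostics=len(rec.diagnostic_mzs) if rec else None,
            total_library_peaks=len(rec.peaks) if rec else None,
        )
        retained.append(h)
    counts["retained"] = len(retained)

    # -- stage 5: dedup + confirmation ---------------------------------
    uniques = dedupe_across_polarity(retained)
    counts["unique"] = len(uniques)
    std_by_id = {r.suspect_id: r for r in inputs.standards}
    confirmed: list[str] = []
    false_pos: list[str] = []
    final: list[UniqueStructure] = []
    for u in uniques:
        std = std_by_id.get(u.suspect_id)
        if std is None:
            final.append(u)
            continue
        best = min(u.hits, key=lambda h: ConfidenceLevel(h.confidence_level or "5").rank)
        f = feat_by_id[best.feature_id]
        verdict = confirm_with_standard(best, f.rt, f.ms2, std, cfg)
        if verdict == "confirmed_level_1":
            confirmed.append(u.suspect_id)
            final.append(
                UniqueStructure(u.suspect_id, u.polarities, ConfidenceLevel("1"),
                                u.source_warning, u.sites, u.hits)
            )
        else:
            false_pos.append(u.suspect_id)
    counts["confirmed"] = len(confirmed)
    counts["false_positives"] = len(false_pos)

    # -- stage 6: semiquantification + report --------------------------
    report_rows = []
    for u in final:
        s = by_id[u.suspect_id]
        ranges = _semiquant_structure(u, s, inputs, is_areas, feat_by_id)
        last_app = max(
            (e.date for e in inputs.applications
             if e.compound_id in (s.parent_ids or (s.suspect_id,))),
            default=None,
        )
        report_rows.append(
            {
                "suspect_id": u.suspect_id,
                "name": s.name,
                "formula": s.formula,
                "confidence_level": str(u.confidence_level),
                "polarities": ";".join(u.polarities),
                "parent_ids": ";".join(s.parent_ids),
                "sites": ";".join(u.sites),
                "concentration_range": ranges,
                "source_warning": u.source_warning,
                "last_application": last_app.isoformat() if last_app else "",
            }
        )
    report_rows.sort(key=lambda r: (ConfidenceLevel(r["confidence_level"]).rank,
                                    r["name"]))

    if audit_path is not None:
        with open(audit_path, "w") as fh:
            for rec in audit:
                fh.write(json.dumps(rec, default=str) + "\n")

    return PipelineResult(counts, report_rows, final, confirmed, false_pos, audit)


def _formula_unequivocal(
    hit: CandidateHit, feature: Feature, suspects: Sequence[SuspectEntry],
    cfg: ScreeningConfig,
) -> bool:
    """Exactly one suspect formula fits the measured m/z and the
    chlorine count read from the isotope pattern."""
    if hit.chlorine_count_observed is None:
        return False
    from .chem import parse_formula

    fitting = []
    for s in suspects:
        expected = s.expected_mz(feature.polarity)
        if abs(feature.mz - expected) / expected * 1e6 <= cfg.ms1_tol_ppm:
            if parse_formula(s.formula)["Cl"] == hit.chlorine_count_observed:
                fitting.append(s.suspect_id)
    return len(fitting) == 1


def _semiquant_structure(
    u: UniqueStructure,
    s: SuspectEntry,
    inputs: PipelineInputs,
    is_areas: dict[tuple[str, date, str], float],
    feat_by_id: dict[str, Feature],
) -> str:
    if inputs.calibration is None or len(inputs.calibration) == 0:
        return ""
    cal = inputs.calibration
    cal = cal[cal["compound_id"] == u.suspect_id]
    if len(cal) == 0:
        return ""
    parts = []
    for site in u.sites:
        rows = cal[cal["site"] == site]
        if len(rows) == 0:
            continue
        pts = [
            (float(r["level_ug_l"]), float(r["area"]) / float(r["is_area"]))
            for _, r in rows.iterrows()
            if float(r["level_ug_l"]) > 0
        ]
        blanks = [
            float(r["area"]) / float(r["is_area"])
            for _, r in rows.iterrows()
            if float(r["level_ug_l"]) == 0
        ]
        curve = fit_matrix_calibration(u.suspect_id, site, pts, blanks)
        responses = []
        for h in u.hits:
            if h.site != site:
                continue
            f = feat_by_id[h.feature_id]
            is_area = is_areas.get((f.site, f.week, f.polarity))
            if is_area:
                responses.append(f.area / is_area / max(f.volume_l, 1e-12))
        if not responses:
            continue
        label, _note = semiquantify(max(responses), curve)
        parts.append(f"{site}:{label}")
    return ";".join(parts)


def load_inputs(paths: dict[str, str | Path]) -> PipelineInputs:
    """Assemble :class:`PipelineInputs` from a path mapping (keys:
    registry, metabolites, features, library, applications, detections,
    standards, rt_calibrants, calibration; only the first three are
    mandatory)."""
    from .synthetic import read_metabolites_csv, read_registry_csv

    features, rejects = read_feature_table(paths["features"])
    rt_cal: list[tuple[float, float]] = []
    if paths.get("rt_calibrants"):
        df = pd.read_csv(paths["rt_calibrants"])
        rt_cal = [(float(r["descriptor"]), float(r["rt"])) for _, r in df.iterrows()]
    return PipelineInputs(
        registry=read_registry_csv(paths["registry"]),
        metabolites=read_metabolites_csv(paths["metabolites"]),
        features=features,
        library=read_spectral_library(paths["library"]) if paths.get("library") else [],
        applications=read_applications(paths["applications"])
        if paths.get("applications") else [],
        detections=read_detections(paths["detections"])
        if paths.get("detections") else [],
        standards=read_standards(paths["standards"])
        if paths.get("standards") else [],
        rt_calibrants=rt_cal,
        calibration=pd.read_csv(paths["calibration"])
        if paths.get("calibration") else None,
    )


def run(
    config: dict | str | Path,
    out_base: str | Path | None = None,
    disable_monitoring: bool = False,
) -> PipelineResult:
    """Run from a JSON config (or dict) of input paths; optionally write
    the CSV/JSON report to ``out_base``."""
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    paths = config.get("inputs", config)
    cfg = ScreeningConfig(**config.get("screening", {}))
    result = run_pipeline(
        load_inputs(paths),
        cfg,
        disable_monitoring=disable_monitoring
        or bool(config.get("disable_monitoring", False)),
        lookback_years=int(config.get("lookback_years", 10)),
        audit_path=config.get("audit_path"),
    )
    if out_base is not None:
        write_report(result.report_rows, out_base)
    return result
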