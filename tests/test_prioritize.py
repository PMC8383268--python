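"""Monitoring evidence, retention, confidence levels, confirmation, dedup."""

from __future__ import annotations

from datetime import date

import pytest

from tpscreen.data_io import (
    MonitoringApplicationEvent,
    MonitoringDetectionRecord,
    StandardRecord,
)
from tpscreen.prioritize import (
    ConfidenceLevel,
    MonitoringEvidence,
    assign_confidence_level,
    collect_monitoring_evidence,
    confirm_with_standard,
    decide_retention,
    dedupe_across_polarity,
)
from tpscreen.screening import CandidateHit
from tpscreen.suspects import KeyMetaboliteRecord, RegistryEntry, build_suspect_list

WEEK = date(2017, 5, 1)
SAMPLE_DATE = date(2017, 9, 1)


def tp_suspect(parent_id="CLZ", tp_formula="C4H4ClN3O", k_foc=None,
               parent_k_foc=None):
    registry = [RegistryEntry(parent_id, parent_id.lower(), "C10H8ClN3O",
                              "monitored_target", None, ("M",))]
    mets = [KeyMetaboliteRecord(parent_id, f"{parent_id}-TP1", "tp-one",
                                tp_formula, k_foc, parent_k_foc)]
    suspects = build_suspect_list(registry, mets)
    return next(s for s in suspects if s.origin == "key_metabolite")


def hit(tier="weak", sid="CLZ-TP1", pol="positive", **kw):
    defaults = dict(
        suspect_id=sid, feature_id=f"F-{sid}-{pol}", site="M", week=WEEK,
        polarity=pol, mass_error_ppm=0.4, peak_quality="pass",
        rt_plausible="pass", chem_evidence_tier=tier,
    )
    defaults.update(kw)
    return CandidateHit(**defaults)


class TestCollectEvidence:
    def test_historical_application_within_lookback_supports(self):
        """A parent last applied years before the campaign still counts
        inside the 10-year lookback, as does detection during the year."""
        s = tp_suspect()
        ev = collect_monitoring_evidence(
            s, "M",
            [MonitoringApplicationEvent("M", date(2014, 5, 15), "CLZ", 500.0)],
            [MonitoringDetectionRecord("M", date(2017, 6, 5), "CLZ", 0.05)],
            {"CLZ": ["M"]}, SAMPLE_DATE,
        )
        assert ev.parent_applied_at_site
        assert ev.last_application_date == date(2014, 5, 15)
        assert ev.parent_detected_at_site
        assert ev.source_plausibility == "supported"

    def test_parent_without_any_use_is_contradicted(self):
        s = tp_suspect(parent_id="FOL", tp_formula="C8H6O4")
        ev = collect_monitoring_evidence(s, "M", [], [], {"FOL": []}, SAMPLE_DATE)
        assert not ev.parent_registered_at_site
        assert ev.source_plausibility == "contradicted"

    def test_mobility_flag_from_k_foc(self):
        s = tp_suspect(parent_id="TFV", tp_formula="C13H16ClNO2",
                       k_foc=242.0, parent_k_foc=186000.0)
        ev = collect_monitoring_evidence(
            s, "M", [], [], {"TFV": ["M"]}, SAMPLE_DATE,
            parent_k_foc={"TFV": 186000.0},
        )
        assert ev.mobility_flag is True

    def test_mobility_absent_without_both_k_foc(self):
        s = tp_suspect()
        ev = collect_monitoring_evidence(s, "M", [], [], {"CLZ": ["M"]},
                                         SAMPLE_DATE)
        assert ev.mobility_flag is None

    def test_application_outside_lookback_ignored(self):
        s = tp_suspect()
        ev = collect_monitoring_evidence(
            s, "M",
            [MonitoringApplicationEvent("M", date(2001, 5, 15), "CLZ", 500.0)],
            [], {"CLZ": []}, SAMPLE_DATE, lookback_years=10,
        )
        assert not ev.parent_applied_at_site


def ev(applied=False, detected=False, registered=True,
       plaus=None) -> MonitoringEvidence:
    if plaus is None:
        plaus = "supported" if (applied or detected or registered) else "contradicted"
    return MonitoringEvidence(
        parent_registered_at_site=registered,
        parent_applied_at_site=applied,
        last_application_date=date(2014, 5, 1) if applied else None,
        parent_detected_at_site=detected,
        parent_detection_weeks=(WEEK,) if detected else (),
        mobility_flag=None,
        source_plausibility=plaus,
    )


class TestRetention:
    def test_weak_with_application_is_rescued(self):
        decision, rationale = decide_retention(hit("weak"), ev(applied=True))
        assert decision == "retain"
        assert "monitoring" in rationale

    def test_weak_without_support_is_discarded(self):
        decision, _ = decide_retention(
            hit("weak"), ev(registered=False, plaus="contradicted")
        )
        assert decision == "discard"

    def test_strong_contradicted_keeps_with_source_warning(self):
        """The identity stands; only the presumed source is questioned."""
        h = hit("strong")
        decision, rationale = decide_retention(
            h, ev(registered=False, plaus="contradicted")
        )
        assert decision == "retain"
        assert h.source_warning
        assert "contradicted" in rationale

    def test_moderate_always_retained(self):
        decision, _ = decide_retention(hit("moderate"), ev(registered=True))
        assert decision == "retain"


class TestConfidenceLevels:
    def test_ordering(self):
        ranks = [ConfidenceLevel(v) for v in ("1", "2a", "2b", "3", "4", "5")]
        assert ranks == sorted(ranks)
        assert ConfidenceLevel("1") < ConfidenceLevel("2a") < ConfidenceLevel("5")

    def test_two_diagnostics_without_full_spectrum_is_2b(self):
        h = hit("strong", n_diagnostic_matched=2, n_library_matched=2)
        level = assign_confidence_level(
            h, ev(applied=True), library_had_record=True,
            formula_unequivocal=False, total_diagnostics=2, total_library_peaks=3,
        )
        assert level.value == "2b"

    def test_full_library_spectrum_is_2a(self):
        h = hit("strong", n_diagnostic_matched=2, n_library_matched=3)
        level = assign_confidence_level(
            h, ev(applied=True), library_had_record=True,
            formula_unequivocal=False, total_diagnostics=2, total_library_peaks=3,
        )
        assert level.value == "2a"

    def test_single_fragment_is_3(self):
        h = hit("moderate", n_diagnostic_matched=1, n_library_matched=1)
        level = assign_confidence_level(h, ev(), library_had_record=True,
                                        formula_unequivocal=False)
        assert level.value == "3"

    def test_unequivocal_formula_without_fragments_is_4(self):
        """Isotope pattern fixes the chlorine count and a single suspect
        formula fits: tentative identification at level 4."""
        h = hit("weak", chlorine_count_observed=1, chlorine_count_expected=1)
        level = assign_confidence_level(h, ev(applied=True),
                                        library_had_record=False,
                                        formula_unequivocal=True)
        assert level.value == "4"

    def test_exact_mass_only_is_5(self):
        h = hit("weak")
        level = assign_confidence_level(h, ev(), library_had_record=False,
                                        formula_unequivocal=False)
        assert level.value == "5"

    def test_adding_a_diagnostic_never_worsens_the_level(self):
        """Monotonicity of the evidence-to-level mapping."""
        for n in range(4):
            h1 = hit("weak", n_diagnostic_matched=n, n_library_matched=n)
            h2 = hit("weak", n_diagnostic_matched=n + 1, n_library_matched=n + 1)
            l1 = assign_confidence_level(h1, ev(), True, False)
            l2 = assign_confidence_level(h2, ev(), True, False)
            assert l2 <= l1


class TestConfirmation:
    standard = StandardRecord("CLZ-TP1", 3.0,
                              ((100.99010, 100.0), (116.99759, 60.0)))

    def test_matching_rt_and_fragments_confirms(self):
        h = hit("strong")
        verdict = confirm_with_standard(
            h, 3.05, [(100.99010, 90.0), (116.99759, 40.0)], self.standard
        )
        assert verdict == "confirmed_level_1"
        assert h.confidence_level == "1"

    def test_rt_match_without_fragments_is_false_positive(self):
        verdict = confirm_with_standard(hit("strong"), 3.0, [], self.standard)
        assert verdict == "false_positive"

    def test_rt_mismatch_is_false_positive(self):
        verdict = confirm_with_standard(
            hit("strong"), 4.5, [(100.99010, 90.0), (116.99759, 40.0)],
            self.standard,
        )
        assert verdict == "false_positive"


class TestDedup:
    def test_dual_polarity_merges(self):
        hits = [hit("strong", sid="A", pol="positive",
                    confidence_level="2b"),
                hit("strong", sid="A", pol="negative", confidence_level="3"),
                hit("weak", sid="B", pol="negative", confidence_level="5")]
        uniq = dedupe_across_polarity(hits)
        assert len(uniq) == 2
        a = next(u for u in uniq if u.suspect_id == "A")
        assert a.polarities == ("negative", "positive")
        assert a.confidence_level.value == "2b"  # best level kept

    def test_all_unique_is_identity(self):
        hits = [hit("weak", sid=f"S{i}") for i in range(5)]
        assert len(dedupe_across_polarity(hits)) == 5

    def test_idempotent(self):
        hits = [hit("strong", sid="A", pol="positive", confidence_level="2b"),
                hit("strong", sid="A", pol="negative", confidence_level="2b")]
        once = dedupe_across_polarity(hits)
        twice = dedupe_across_polarity([h for u in once for h in u.hits])
        assert [u.suspect_id for u in once] == [u.suspect_id for u in twice]
        assert [u.polarities for u in once] == [u.polarities for u in twice]
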