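"""Exact-mass matching, peak gating, RT plausibility, fragment scoring."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from tpscreen.data_io import Feature, SpectralLibraryRecord
from tpscreen.pipeline import run_pipeline
from tpscreen.screening import (
    CandidateHit,
    ScreeningConfig,
    assess_peak_quality,
    fit_rt_model,
    match_suspects,
    rt_plausible,
    score_fragments,
)
from tpscreen.suspects import KeyMetaboliteRecord, RegistryEntry, build_suspect_list

from conftest import scenario_inputs

WEEK = date(2017, 5, 1)


def make_feature(mz, polarity="positive", rt=3.0, ms2=(), feature_id="F001"):
    return Feature(
        feature_id=feature_id, site="M", week=WEEK, polarity=polarity,
        mz=mz, rt=rt, area=1e4,
        trace=[(rt + dt, 1e4 * np.exp(-0.5 * (dt / 0.1) ** 2))
               for dt in np.linspace(-0.4, 0.4, 21)],
        ms2=list(ms2),
    )


@pytest.fixture(scope="module")
def chloridazon_suspects():
    registry = [RegistryEntry("CLZ", "chloridazon", "C10H8ClN3O",
                              "monitored_target")]
    mets = [KeyMetaboliteRecord("CLZ", "CLZ-TP1", "desphenyl-chloridazon",
                                "C4H4ClN3O", 100.0, 200.0)]
    return build_suspect_list(registry, mets)


class TestMatching:
    def test_desphenyl_chloridazon_within_1ppm(self, chloridazon_suspects):
        hits = match_suspects([make_feature(146.01155)], chloridazon_suspects, 5.0)
        assert [h.suspect_id for h in hits] == ["CLZ-TP1"]
        assert abs(hits[0].mass_error_ppm) < 1.0

    def test_10ppm_offset_misses_at_5ppm(self, chloridazon_suspects):
        mz = 146.01155 * (1 + 10e-6)
        assert match_suspects([make_feature(mz)], chloridazon_suspects, 5.0) == []

    def test_empty_features(self, chloridazon_suspects):
        assert match_suspects([], chloridazon_suspects, 5.0) == []

    def test_order_independence(self, chloridazon_suspects):
        feats = [make_feature(146.01155, feature_id="A"),
                 make_feature(146.01156, feature_id="B")]
        a = match_suspects(feats, chloridazon_suspects, 5.0)
        b = match_suspects(list(reversed(feats)), chloridazon_suspects, 5.0)
        assert [(h.suspect_id, h.feature_id) for h in a] == \
               [(h.suspect_id, h.feature_id) for h in b]


class TestPeakQuality:
    def test_clean_gaussian_passes(self):
        rng = np.random.default_rng(5)
        t = np.linspace(2.5, 3.5, 20)
        y = 5000 * np.exp(-0.5 * ((t - 3.0) / 0.1) ** 2) + rng.normal(0, 100, 20)
        pa = assess_peak_quality(list(zip(t, np.clip(y, 0, None))))
        assert pa.passed
        assert pa.score > 0.5

    def test_three_point_spike_fails(self):
        pa = assess_peak_quality([(1.0, 0.0), (1.1, 100.0), (1.2, 0.0)])
        assert not pa.passed
        assert "points" in pa.reason

    def test_flat_trace_fails(self):
        pa = assess_peak_quality([(float(i), 0.0) for i in range(10)])
        assert not pa.passed

    def test_low_snr_fails(self):
        rng = np.random.default_rng(6)
        t = np.linspace(2.5, 3.5, 20)
        y = np.abs(rng.normal(100, 80, 20))
        y[10] += 120  # apex barely above noise
        pa = assess_peak_quality(list(zip(t, y)), min_snr=3.0)
        assert not pa.passed


class TestRtModel:
    def test_colinear_calibrants_pass_on_line(self):
        cal = [(d, 2.0 * d + 1.0) for d in range(1, 11)]
        model = fit_rt_model(cal)
        assert model.slope == pytest.approx(2.0)
        assert rt_plausible(2.0 * 3.0 + 1.0, 3.0, model) == "pass"

    def test_far_off_line_fails(self):
        cal = [(float(d), 2.0 * d + 1.0 + 0.05 * (-1) ** d) for d in range(1, 11)]
        model = fit_rt_model(cal)
        off = model.predict(3.0) + 10 * model.residual_spread
        assert rt_plausible(off, 3.0, model) == "fail"

    def test_missing_descriptor_is_unknown(self):
        model = fit_rt_model([(d, 2.0 * d) for d in range(1, 11)])
        assert rt_plausible(5.0, None, model) == "unknown"

    def test_too_few_calibrants(self):
        with pytest.raises(ValueError):
            fit_rt_model([(1.0, 1.0), (2.0, 2.0)])


CHLORIDAZON_TP1_LIB = SpectralLibraryRecord(
    name="desphenyl-chloridazon", formula="C4H4ClN3O", adduct="[M+H]+",
    peaks=((100.99010, 100.0), (116.99759, 60.0), (110.0, 20.0)),
    diagnostic_mzs=(100.99010, 116.99759),
)


def fresh_hit():
    return CandidateHit(
        suspect_id="CLZ-TP1", feature_id="F001", site="M", week=WEEK,
        polarity="positive", mass_error_ppm=0.3,
    )


class TestFragmentScoring:
    def test_two_diagnostic_fragments_give_strong(self):
        ms2 = [(100.99010, 100.0), (116.99759, 55.0)]
        hit = score_fragments(fresh_hit(), ms2, CHLORIDAZON_TP1_LIB, "C4H4ClN3O")
        assert hit.n_diagnostic_matched == 2
        assert hit.n_library_matched == 2
        assert hit.chem_evidence_tier == "strong"

    def test_empty_ms2_is_weak(self):
        hit = score_fragments(fresh_hit(), [], CHLORIDAZON_TP1_LIB, "C4H4ClN3O")
        assert hit.chem_evidence_tier == "weak"
        assert hit.n_library_matched == 0

    def test_peak_heavier_than_precursor_counts_implausible(self):
        ms2 = [(500.0, 100.0)]  # far above the [M+H]+ at 146
        hit = score_fragments(fresh_hit(), ms2, None, "C4H4ClN3O")
        assert hit.subformula_plausible_fraction == 0.0

    def test_subformula_fraction_counts_explainable_peaks(self):
        ms2 = [(100.99010, 100.0), (321.4, 90.0)]  # one real, one impossible
        hit = score_fragments(fresh_hit(), ms2, None, "C4H4ClN3O")
        assert hit.subformula_plausible_fraction == pytest.approx(0.5)


class TestCascadeMonotonicity:
    def test_counts_non_increasing_through_gates(self, default_scenario):
        """Mirrors the cascade structure: matching >= peak/RT gate >=
        fragment gate >= retention cannot add hits."""
        res = run_pipeline(scenario_inputs(default_scenario))
        c = res.counts
        assert c["matched"] >= c["after_peak_rt"] >= c["after_fragments"]
        assert c["retained"] <= c["after_fragments"]
        assert c["unique"] <= c["retained"]

    def test_spiked_library_tps_reach_strong(self, default_scenario):
        """Every spiked TP with a library record yields at least one
        strong-tier retained hit (recall property)."""
        res = run_pipeline(scenario_inputs(default_scenario))
        truth = default_scenario.truth
        strong_ids = {
            h.suspect_id
            for u in res.unique_structures
            for h in u.hits
            if h.chem_evidence_tier == "strong"
        }
        for tid, has_lib in truth.has_library.items():
            if has_lib:
                assert tid in strong_ids
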