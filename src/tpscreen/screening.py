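"""Chemical-evidence screening: exact-mass matching, peak-quality and
retention-plausibility gates, and MS2 fragment scoring.

The screening half of the workflow asks only "does the measured data
support this suspect chemically?"  Monitoring knowledge is layered on
afterwards by :mod:`tpscreen.prioritize`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .chem import (
    ADDUCT_FOR_POLARITY,
    ElementalFormula,
    IsotopePattern,
    enumerate_subformulas,
    estimate_chlorine_count,
    parse_formula,
    simulate_isotope_pattern,
)
from .data_io import Feature, SpectralLibraryRecord
from .suspects import SuspectEntry

__all__ = [
    "ScreeningConfig",
    "CandidateHit",
    "RtModel",
    "PeakAssessment",
    "match_suspects",
    "assess_peak_quality",
    "fit_rt_model",
    "rt_plausible",
    "score_fragments",
]


@dataclass(frozen=True)
class ScreeningConfig:
    """All gate thresholds in one place; every value is a convention,
    none is instrument-mandated, and all are overridable."""

    ms1_tol_ppm: float = 5.0
    ms2_tol_ppm: float = 10.0
    ms2_tol_mda: float = 5.0  # absolute floor for low masses, milli-Da
    min_points: int = 7
    asymmetry_range: tuple[float, float] = (0.5, 2.0)
    min_snr: float = 3.0
    rt_window_spreads: float = 3.0
    min_calibrants: int = 5
    ms2_intensity_floor: float = 0.05  # fraction of base peak
    rt_tol_min: float = 0.2  # standard-confirmation RT tolerance, minutes


def ms2_tol_da(mz: float, cfg: ScreeningConfig) -> float:
    """MS2 match tolerance: ppm-scaled, with an absolute milli-Da floor."""
    return max(mz * cfg.ms2_tol_ppm * 1e-6, cfg.ms2_tol_mda * 1e-3)


@dataclass
class CandidateHit:
    """A suspect x feature pairing accumulating evidence as it passes
    through the cascade."""

    suspect_id: str
    feature_id: str
    site: str
    week: object
    polarity: str
    mass_error_ppm: float
    peak_quality: str = "pending"  # pass | fail | pending
    peak_score: float = 0.0
    rt_plausible: str = "unknown"  # pass | fail | unknown
    n_diagnostic_matched: int = 0
    n_library_matched: int = 0
    subformula_plausible_fraction: float = 0.0
    chlorine_count_observed: int | None = None
    chlorine_count_expected: int | None = None
    chem_evidence_tier: str = "weak"  # strong | moderate | weak
    source_warning: bool = False
    rationale: str = ""
    confidence_level: str | None = None


@dataclass(frozen=True)
class RtModel:
    """Linear retention model: rt = slope * descriptor + intercept."""

    slope: float
    intercept: float
    residual_spread: float
    n_calibrants: int

    def predict(self, descriptor: float) -> float:
        return self.slope * descriptor + self.intercept


@dataclass(frozen=True)
class PeakAssessment:
    passed: bool
    score: float
    reason: str = ""


def match_suspects(
    features: Iterable[Feature],
    suspects: Iterable[SuspectEntry],
    tol_ppm: float = 5.0,
) -> list[CandidateHit]:
    """Exact-mass matching of features against the suspect list.

    Emits a hit for every (feature, suspect) pair whose m/z agree within
    ``tol_ppm`` in the feature's polarity; a feature may hit several
    suspects and vice versa.  Deterministic and independent of input
    order (output sorted by suspect, feature).
    """
    suspects = list(suspects)
    hits: list[CandidateHit] = []
    for f in features:
        for s in suspects:
            expected = s.expected_mz(f.polarity)
            err_ppm = (f.mz - expected) / expected * 1e6
            if abs(err_ppm) <= tol_ppm:
                hits.append(
                    CandidateHit(
                        suspect_id=s.suspect_id,
                        feature_id=f.feature_id,
                        site=f.site,
                        week=f.week,
                        polarity=f.polarity,
                        mass_error_ppm=err_ppm,
                    )
                )
    hits.sort(key=lambda h: (h.suspect_id, h.feature_id))
    return hits


def _gaussian(t, a, mu, sigma, c):
    return a * np.exp(-0.5 * ((t - mu) / sigma) ** 2) + c


def assess_peak_quality(
    trace: Sequence[tuple[float, float]],
    min_points: int = 7,
    symmetry_range: tuple[float, float] = (0.5, 2.0),
    min_snr: float = 3.0,
) -> PeakAssessment:
    """Gate a chromatographic trace on point count, shape and S/N.

    A peak passes when it has at least ``min_points`` samples, its
    left/right half-height widths are within ``symmetry_range`` of each
    other, and the apex rises ``min_snr`` times above the baseline noise
    (estimated from the outer 20% of the trace).  The score combines the
    three sub-criteria into [0, 1].
    """
    t = np.asarray([p[0] for p in trace], dtype=float)
    y = np.asarray([p[1] for p in trace], dtype=float)
    n = len(t)
    if n < min_points:
        return PeakAssessment(False, 0.0, "insufficient points")
    apex_idx = int(np.argmax(y))
    apex = y[apex_idx]
    edge = max(1, n // 5)
    baseline = np.concatenate([y[:edge], y[-edge:]])
    base_level = float(np.median(baseline))
    noise = float(np.std(baseline))
    if apex <= 0 or apex <= base_level:
        return PeakAssessment(False, 0.0, "no apex above baseline")
    snr = (apex - base_level) / max(noise, 1e-9 * apex, 1e-12)
    # half-height crossing on each side of the apex
    half = base_level + (apex - base_level) / 2.0
    left = apex_idx - np.argmax(y[apex_idx::-1] <= half)
    right = apex_idx + np.argmax(y[apex_idx:] <= half)
    wl = t[apex_idx] - t[max(left, 0)]
    wr = t[min(right, n - 1)] - t[apex_idx]
    if wl <= 0 or wr <= 0:
        return PeakAssessment(False, 0.0, "apex at trace edge")
    asym = wr / wl
    lo, hi = symmetry_range
    ok = snr >= min_snr and lo <= asym <= hi
    snr_score = min(snr / (4 * min_snr), 1.0)
    asym_score = max(0.0, 1.0 - abs(math.log(asym)) / abs(math.log(hi)))
    score = float(np.clip(0.5 * snr_score + 0.5 * asym_score, 0.0, 1.0))
    reason = "" if ok else ("low S/N" if snr < min_snr else "asymmetric peak")
    return PeakAssessment(bool(ok), score if ok else min(score, 0.49), reason)


def fit_rt_model(
    calibrants: Sequence[tuple[float, float]], min_calibrants: int = 5
) -> RtModel:
    """Least-squares retention line over (hydrophobicity descriptor, rt)
    calibrant pairs."""
    if len(calibrants) < min_calibrants:
        raise ValueError(
            f"need >= {min_calibrants} calibrants, got {len(calibrants)}"
        )
    x = np.array([c[0] for c in calibrants], dtype=float)
    y = np.array([c[1] for c in calibrants], dtype=float)
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    spread = float(np.std(resid, ddof=2)) if len(x) > 2 else float(np.std(resid))
    spread = max(spread, 1e-6 * max(1.0, float(np.ptp(y))))  # guard exact lines
    return RtModel(float(res.slope), float(res.intercept), spread, len(x))


def rt_plausible(
    observed_rt: float,
    descriptor: float | None,
    model: RtModel,
    window_spreads: float = 3.0,
) -> str:
    """Classify an observed retention time against the model.

    Returns ``"unknown"`` (never ``"fail"``) when the suspect has no
    hydrophobicity descriptor.
    """
    if descriptor is None:
        return "unknown"
    dev = abs(observed_rt - model.predict(descriptor))
    return "pass" if dev <= window_spreads * model.residual_spread else "fail"


def _match_peak(target: float, peaks: Sequence[tuple[float, float]], tol: float) -> bool:
    return any(abs(mz - target) <= tol for mz, _ in peaks)


def score_fragments(
    hit: CandidateHit,
    ms2: Sequence[tuple[float, float]],
    library: SpectralLibraryRecord | None,
    precursor_formula: str | ElementalFormula,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> CandidateHit:
    """Score MS2 evidence for a matched hit and assign its tier.

    Counts library fragments (and the diagnostic subset) recovered in
    the observed spectrum, and the fraction of observed peaks above the
    intensity floor explainable as subformulas of the precursor ion.
    Tier: *strong* with >= 2 diagnostic matches or (>= 2 library matches
    and >= 80% plausible); *moderate* with exactly one diagnostic or
    library match and >= 50% plausible; *weak* otherwise.
    """
    if isinstance(precursor_formula, str):
        precursor_formula = parse_formula(precursor_formula)
    charge = +1 if hit.polarity == "positive" else -1
    # ion composition: neutral molecule +/- one proton (H)
    ion_counts = dict(precursor_formula.element_counts)
    ion_counts["H"] = ion_counts.get("H", 0) + charge
    if ion_counts["H"] < 0:
        ion_counts["H"] = 0
    ion = ElementalFormula(ion_counts)

    n_lib = 0
    n_diag = 0
    if library is not None:
        for frag_mz, _ in library.peaks:
            if _match_peak(frag_mz, ms2, ms2_tol_da(frag_mz, cfg)):
                n_lib += 1
        for diag_mz in library.diagnostic_mzs:
            if _match_peak(diag_mz, ms2, ms2_tol_da(diag_mz, cfg)):
                n_diag += 1

    frac = 0.0
    if ms2:
        base = max(i for _, i in ms2)
        considered = [(mz, i) for mz, i in ms2 if i >= cfg.ms2_intensity_floor * base]
        if considered:
            plausible = sum(
                1
                for mz, _ in considered
                if enumerate_subformulas(ion, mz, charge, cfg.ms2_tol_ppm)
            )
            frac = plausible / len(considered)

    if n_diag >= 2 or (n_lib >= 2 and frac >= 0.8):
        tier = "strong"
    elif max(n_diag, n_lib) == 1 and frac >= 0.5:
        tier = "moderate"
    else:
        tier = "weak"

    hit.n_library_matched = n_lib
    hit.n_diagnostic_matched = n_diag
    hit.subformula_plausible_fraction = frac
    hit.chem_evidence_tier = tier
    return hit


def observe_chlorines(
    hit: CandidateHit,
    isotope_cluster: Sequence[tuple[float, float]],
    suspect_formula: str,
) -> CandidateHit:
    """Attach observed vs expected chlorine counts from the isotope cluster."""
    f = parse_formula(suspect_formula)
    hit.chlorine_count_expected = f["Cl"]
    if isotope_cluster:
        peaks = sorted(isotope_cluster)
        off0, ab0 = peaks[0]
        if ab0 > 0:
            pat_peaks = [(0.0, 1.0)] + [
                (round(off - off0), ab / ab0) for off, ab in peaks[1:]
            ]
            # drop duplicate offsets, keep increasing
            seen: dict[float, float] = {}
            for off, ab in pat_peaks:
                if off not in seen and (not seen or off > max(seen)):
                    seen[off] = ab
            try:
                pat = IsotopePattern(tuple(seen.items()))
                hit.chlorine_count_observed = estimate_chlorine_count(pat).count
            except ValueError:
                pass
    return hit
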