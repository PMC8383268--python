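"""Range-binned semiquantification against matrix-matched calibration.

Newly identified compounds rarely have validated quantitative methods,
so concentrations are reported as ordinal ranges rather than point
estimates.  Sample responses (internal-standard-normalized, blank-
subtracted peak areas) are compared with a three-level matrix-matched
calibration line at 0.1, 1 and 10 ug/L, and binned into <0.1, 0.1-1,
1-10 or >10 ug/L.  Two fallbacks mirror practice: a curve without
linearity only supports "detected", and when the 0.1 ug/L calibration
level itself was not detected the lowest reportable range widens to
<1 ug/L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CALIBRATION_LEVELS",
    "RANGE_LABELS",
    "CalibrationCurve",
    "fit_matrix_calibration",
    "semiquantify",
    "range_for_concentration",
]

#: Nominal matrix-matched calibration levels, ug/L.
CALIBRATION_LEVELS: tuple[float, ...] = (0.1, 1.0, 10.0)

#: The closed set of reportable labels.
RANGE_LABELS: tuple[str, ...] = ("<0.1", "0.1-1", "1-10", ">10", "<1", "detected")


@dataclass(frozen=True)
class CalibrationCurve:
    """IS-normalized, blank-subtracted calibration line for one compound
    at one site."""

    compound_id: str
    site: str
    points: tuple[tuple[float, float], ...]  # (nominal ug/L, normalized response)
    slope: float
    intercept: float
    r_squared: float
    linearity_ok: bool
    lowest_point_detected: bool


def fit_matrix_calibration(
    compound_id: str,
    site: str,
    points: Sequence[tuple[float, float]],
    blank_responses: Sequence[float] = (),
    r2_threshold: float = 0.98,
) -> CalibrationCurve:
    """Least-squares calibration line through blank-subtracted responses.

    ``points`` are (nominal concentration, IS-normalized area); blank
    responses (already IS-normalized) define the subtraction level and
    the noise floor.  ``linearity_ok`` requires R^2 >= ``r2_threshold``
    and a positive slope; ``lowest_point_detected`` requires the lowest
    nominal level's response to rise above blank + noise.  With fewer
    than two detected points the curve is returned unusable
    (``linearity_ok=False``) rather than raising.
    """
    blank = float(np.mean(blank_responses)) if len(blank_responses) else 0.0
    noise = float(np.std(blank_responses)) if len(blank_responses) > 1 else 0.0
    corrected = [(c, r - blank) for c, r in points]
    detected = [(c, r) for c, r in corrected if r > 3 * noise]

    lowest_level = min((c for c, _ in points), default=None)
    lowest_detected = (
        lowest_level is not None and any(c == lowest_level for c, _ in detected)
    )

    if len(detected) < 2:
        return CalibrationCurve(
            compound_id, site, tuple(corrected), 0.0, 0.0, 0.0, False, lowest_detected
        )
    x = np.array([c for c, _ in detected])
    y = np.array([r for _, r in detected])
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if len(detected) > 2 else 1.0
    if len(detected) == 2:
        # two points define a line exactly; linearity judged on slope only
        r2 = 1.0
    ok = bool(r2 >= r2_threshold and res.slope > 0)
    return CalibrationCurve(
        compound_id,
        site,
        tuple(corrected),
        float(res.slope),
        float(res.intercept),
        r2,
        ok,
        lowest_detected,
    )


def range_for_concentration(c: float) -> str:
    """Bin a concentration into the four ranges (left-closed bins)."""
    if c < 0.1:
        return "<0.1"
    if c < 1.0:
        return "0.1-1"
    if c < 10.0:
        return "1-10"
    return ">10"


def semiquantify(
    sample_response: float, curve: CalibrationCurve
) -> tuple[str, str]:
    """Assign a concentration range to a detected compound.

    Returns ``(label, note)``.  A non-linear curve yields "detected";
    a curve whose lowest level was not detected widens any estimate
    below 1 ug/L to "<1"; a negative back-calculated concentration is
    clamped to "<0.1" with an audit note.
    """
    if not curve.linearity_ok:
        return "detected", "no linearity in matrix-matched calibration"
    est = (sample_response - curve.intercept) / curve.slope
    note = ""
    if est < 0:
        return "<0.1", "negative back-calculated concentration"
    if not curve.lowest_point_detected and est < 1.0:
        return "<1", "lowest calibration level not detected"
    return range_for_concentration(est), note
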