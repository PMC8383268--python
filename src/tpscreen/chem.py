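"""Elemental-formula arithmetic for small-molecule HRMS screening.

Everything downstream — suspect m/z values, fragment plausibility,
chlorine counting from isotope patterns — reduces to the operations in
this module: parsing Hill-notation formulas, monoisotopic masses, ion
m/z for singly charged species (with electron-mass correction),
unit-mass-resolution isotope patterns, and exhaustive subformula
enumeration under a ppm window.

Isotope masses and natural abundances come from the NIST tables shipped
with :mod:`pyteomics`; the proton and electron masses used for ion m/z
are derived from the same tables so that all printed values are
internally consistent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
from pyteomics import mass as _ptm_mass

__all__ = [
    "SUPPORTED_ELEMENTS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "AdductSpec",
    "M_PLUS_H",
    "M_MINUS_H",
    "IsotopePattern",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "simulate_isotope_pattern",
    "ChlorineEstimate",
    "estimate_chlorine_count",
    "enumerate_subformulas",
    "rdbe",
]

#: Element symbols accepted anywhere in the package (CHNOSP + halogens).
SUPPORTED_ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "S", "P", "F", "Cl", "Br")

ELECTRON_MASS: float = _ptm_mass.nist_mass["e*"][0][0]
#: Mass of the proton: monoisotopic H minus one electron.
PROTON_MASS: float = _ptm_mass.nist_mass["H"][1][0] - ELECTRON_MASS

# lightest (= monoisotopic for CHNOSPF/Cl/Br) isotope mass per element
_MONO_MASS: dict[str, float] = {
    el: _ptm_mass.nist_mass[el][0][0] for el in SUPPORTED_ELEMENTS
}


class FormulaError(ValueError):
    """Raised for unparseable or chemically unsupported formulas."""


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition (neutral molecule or ionic fragment).

    Counts are non-negative; the empty composition is permitted only as
    an arithmetic identity (mass 0), never as a parsed formula.
    """

    element_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, n in self.element_counts.items():
            if el not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element symbol: {el!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise FormulaError(f"negative or non-integer count for {el}: {n!r}")
        # drop explicit zeros so equality is structural
        object.__setattr__(
            self,
            "element_counts",
            {el: int(n) for el, n in self.element_counts.items() if n},
        )

    def __getitem__(self, el: str) -> int:
        return self.element_counts.get(el, 0)

    def __bool__(self) -> bool:
        return bool(self.element_counts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.element_counts.items())))

    def __le__(self, other: "ElementalFormula") -> bool:
        """Element-wise subset test (self fits inside other)."""
        return all(n <= other[el] for el, n in self.element_counts.items())

    def hill(self) -> str:
        """Hill-notation string: C, H first (when carbon present), rest
        alphabetical."""
        counts = self.element_counts
        if "C" in counts:
            order = ["C", "H"] + sorted(el for el in counts if el not in ("C", "H"))
        else:
            order = sorted(counts)
        parts = []
        for el in order:
            n = counts.get(el, 0)
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged electrospray adduct ([M+H]+ or [M-H]-)."""

    label: str
    polarity: str  # "positive" | "negative"
    proton_delta: int  # +1 or -1
    charge: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if abs(self.charge) != 1:
            raise ValueError("only singly charged species are supported")
        if (self.charge > 0) != (self.polarity == "positive"):
            raise ValueError("polarity inconsistent with charge sign")


M_PLUS_H = AdductSpec("[M+H]+", "positive", +1, +1)
M_MINUS_H = AdductSpec("[M-H]-", "negative", -1, -1)

ADDUCT_FOR_POLARITY = {"positive": M_PLUS_H, "negative": M_MINUS_H}


@dataclass(frozen=True)
class IsotopePattern:
    """Relative isotopologue abundances at unit-mass-offset resolution.

    ``peaks`` is an ordered list of ``(mass offset from monoisotopic in
    Da, relative abundance)`` with the monoisotopic peak first at offset
    0 and abundance 1.0.
    """

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("isotope pattern needs at least one peak")
        off0, ab0 = self.peaks[0]
        if off0 != 0.0 or abs(ab0 - 1.0) > 1e-9:
            raise ValueError("first peak must be (0, 1.0)")
        offs = [p[0] for p in self.peaks]
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("offsets must be strictly increasing")
        if any(p[1] < 0 for p in self.peaks):
            raise ValueError("abundances must be non-negative")

    def abundance_at(self, offset: float, tol: float = 0.5) -> float:
        """Abundance of the peak nearest ``offset`` (0 if none within tol)."""
        best = 0.0
        best_d = tol
        for off, ab in self.peaks:
            d = abs(off - offset)
            if d <= best_d:
                best, best_d = ab, d
        return best

    @property
    def a2_ratio(self) -> float:
        """A+2 abundance relative to the monoisotopic peak."""
        return self.abundance_at(2.0)


_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-like formula string such as ``"C4H4ClN3O"``.

    Raises :class:`FormulaError` for empty input or any token that is
    not a supported element symbol.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unknown element {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    f = ElementalFormula(counts)
    if not f:
        raise FormulaError(f"formula {text!r} has no atoms")
    return f


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic (lightest-isotope) mass of a composition in Da."""
    return sum(n * _MONO_MASS[el] for el, n in f.element_counts.items())


def ion_mz(f: ElementalFormula, adduct: AdductSpec | int) -> float:
    """m/z of a singly charged ion.

    Two calling modes, matching how compositions are written down:

    * ``adduct`` is an :class:`AdductSpec` — ``f`` is the *neutral*
      molecule and the proton is added/removed:
      ``m/z = M + proton_delta * m_p``.
    * ``adduct`` is an integer charge (+1/-1) — ``f`` is already the
      *ionic* composition (e.g. a fragment written as C4H7O2+) and only
      the electron-mass correction applies:
      ``m/z = M - charge * m_e``.

    Values are never rounded internally.
    """
    if isinstance(adduct, AdductSpec):
        return monoisotopic_mass(f) + adduct.proton_delta * PROTON_MASS
    charge = int(adduct)
    if abs(charge) != 1:
        raise ValueError("only singly charged species are supported")
    return monoisotopic_mass(f) - charge * ELECTRON_MASS


# per-element single-atom isotope distributions over integer mass offsets,
# derived from NIST natural abundances (offset = mass number - lightest)
def _atom_distribution(el: str) -> np.ndarray:
    iso = _ptm_mass.nist_mass[el]
    entries = [(num, m, ab) for num, (m, ab) in iso.items() if num != 0 and ab > 0]
    entries.sort()
    base = entries[0][0]
    size = entries[-1][0] - base + 1
    dist = np.zeros(size)
    for num, _m, ab in entries:
        dist[num - base] = ab
    return dist


_ATOM_DIST: dict[str, np.ndarray] = {el: _atom_distribution(el) for el in SUPPORTED_ELEMENTS}


def simulate_isotope_pattern(f: ElementalFormula, n_peaks: int = 4) -> IsotopePattern:
    """Aggregated isotope pattern of ``f`` at unit-mass resolution.

    The per-element natural-abundance distributions are convolved over
    all atoms (exponentiation by repeated convolution); the result is
    normalized to the monoisotopic peak.  Offsets are reported as
    integer Da — adequate for A+2/A chlorine scoring, not for fine
    isotope structure.
    """
    if n_peaks < 2:
        raise ValueError("n_peaks must be >= 2")
    dist = np.array([1.0])
    for el, n in f.element_counts.items():
        atom = _ATOM_DIST[el]
        # square-and-multiply over convolution keeps this cheap for big counts
        acc = np.array([1.0])
        base = atom
        k = n
        while k:
            if k & 1:
                acc = np.convolve(acc, base)
            base = np.convolve(base, base)
            k >>= 1
        dist = np.convolve(dist, acc)
        dist = dist[:n_peaks]  # truncate: higher offsets never feed back
    dist = dist[:n_peaks]
    if dist[0] <= 0:
        raise ValueError("degenerate composition: zero monoisotopic abundance")
    rel = dist / dist[0]
    peaks = tuple((float(k), float(rel[k])) for k in range(len(rel)))
    return IsotopePattern(peaks)


class ChlorineEstimate(NamedTuple):
    count: int
    low_confidence: bool


# A+2/A (and A+4/A) for a pure Cl_k pattern; C/H/N/O contributions to A+2
# are < 0.01 for pesticide-sized molecules and do not move the argmin.
def _cl_reference_ratios(max_cl: int = 3) -> list[tuple[float, float]]:
    out = []
    for k in range(max_cl + 1):
        if k == 0:
            out.append((0.0, 0.0))
            continue
        pat = simulate_isotope_pattern(ElementalFormula({"Cl": k}), n_peaks=5)
        out.append((pat.abundance_at(2.0), pat.abundance_at(4.0)))
    return out


_CL_REF = _cl_reference_ratios()


def estimate_chlorine_count(
    observed: IsotopePattern, tolerance: float = 0.08
) -> ChlorineEstimate:
    """Count chlorines from the observed A+2/A ratio.

    Returns the k in {0..3} whose simulated A+2/A ratio is nearest the
    observed one.  When the best and runner-up k are within ``tolerance``
    of each other the A+4/A ratio breaks the tie and the result is
    flagged low-confidence.  A missing A+2 peak counts as abundance 0.
    """
    r2 = observed.a2_ratio
    r4 = observed.abundance_at(4.0)
    errors = sorted(
        (abs(r2 - ref2), abs(r4 - ref4), k) for k, (ref2, ref4) in enumerate(_CL_REF)
    )
    best_err, _, best_k = errors[0]
    second_err, _, second_k = errors[1]
    low_conf = (second_err - best_err) < tolerance
    if low_conf:
        # A+4 tie-break between the two closest candidates
        cand = [errors[0], errors[1]]
        cand.sort(key=lambda t: (t[1], t[0]))
        best_k = cand[0][2]
    return ChlorineEstimate(int(best_k), bool(low_conf))


def rdbe(f: ElementalFormula) -> float:
    """Ring-plus-double-bond equivalents (may be half-integer for ions)."""
    return (
        f["C"]
        - (f["H"] + f["F"] + f["Cl"] + f["Br"]) / 2.0
        + (f["N"] + f["P"]) / 2.0
        + 1.0
    )


def enumerate_subformulas(
    precursor: ElementalFormula,
    target_mz: float,
    charge: int,
    tol_ppm: float = 5.0,
    rdbe_min: float = -0.5,
) -> list[ElementalFormula]:
    """All ionic compositions inside ``precursor`` matching ``target_mz``.

    Exhaustive depth-first search over the bounded element lattice with
    mass pruning; candidates must be element-wise <= the precursor ion
    composition, pass the RDBE >= ``rdbe_min`` plausibility filter, and
    have an ion m/z (electron-corrected for ``charge``) within
    ``tol_ppm`` of the target.  Sorted by absolute mass error.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if abs(int(charge)) != 1:
        raise ValueError("only singly charged species are supported")
    tol_da = target_mz * tol_ppm * 1e-6
    target_mass = target_mz + int(charge) * ELECTRON_MASS  # neutral-frame mass
    elements = [el for el in SUPPORTED_ELEMENTS if precursor[el] > 0]
    masses = [_MONO_MASS[el] for el in elements]
    maxima = [precursor[el] for el in elements]

    results: list[tuple[float, ElementalFormula]] = []
    counts = [0] * len(elements)

    # remaining maximum mass achievable from position i onward
    suffix_max = [0.0] * (len(elements) + 1)
    for i in range(len(elements) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + masses[i] * maxima[i]

    def walk(i: int, acc_mass: float) -> None:
        if acc_mass - target_mass > tol_da:
            return
        if acc_mass + suffix_max[i] < target_mass - tol_da:
            return
        if i == len(elements):
            if abs(acc_mass - target_mass) <= tol_da:
                f = ElementalFormula(
                    {el: c for el, c in zip(elements, counts) if c}
                )
                if f and rdbe(f) >= rdbe_min:
                    err = abs((monoisotopic_mass(f) - int(charge) * ELECTRON_MASS) - target_mz)
                    results.append((err, f))
            return
        for c in range(maxima[i] + 1):
            counts[i] = c
            walk(i + 1, acc_mass + c * masses[i])
        counts[i] = 0

    walk(0, 0.0)
    results.sort(key=lambda t: (t[0], t[1].hill()))
    return [f for _err, f in results]
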