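"""Readers and writers for on-disk artifacts.

Formats are all plain text: CSV for picked-feature tables, monitoring
metadata, reference standards, calibration data and reports; MSP (via
matchms) for the spectral library.  Chromatogram traces, observed
isotope clusters and MS2 peak lists travel inside the feature CSV as
``;``-delimited ``x:y`` sub-fields, so one file fully describes one
sample batch.

Readers never silently drop input: malformed feature rows are collected
into a reject list with a reason, and schema violations raise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from matchms import Spectrum
from matchms.exporting import save_as_msp
from matchms.importing import load_from_msp

from .chem import M_MINUS_H, M_PLUS_H, ion_mz, parse_formula

__all__ = [
    "Feature",
    "SpectralLibraryRecord",
    "MonitoringApplicationEvent",
    "MonitoringDetectionRecord",
    "StandardRecord",
    "SchemaError",
    "read_feature_table",
    "write_feature_table",
    "read_spectral_library",
    "write_spectral_library",
    "read_applications",
    "write_applications",
    "read_detections",
    "write_detections",
    "read_standards",
    "write_standards",
    "write_report",
]


class SchemaError(ValueError):
    pass


@dataclass
class Feature:
    """One picked LC-HRMS peak from one sample."""

    feature_id: str
    site: str
    week: date  # ISO week start
    polarity: str  # "positive" | "negative"
    mz: float
    rt: float  # minutes
    area: float
    trace: list[tuple[float, float]]  # (time, intensity)
    isotope_cluster: list[tuple[float, float]] = field(default_factory=list)
    ms2: list[tuple[float, float]] = field(default_factory=list)
    volume_l: float = 1.0  # extracted water volume for this sample

    def validate(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if self.rt < 0:
            raise ValueError("rt must be non-negative")
        if not self.trace:
            raise ValueError("trace must be non-empty")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")


@dataclass(frozen=True)
class SpectralLibraryRecord:
    """Reference MS2 spectrum with optional diagnostic-fragment flags."""

    name: str
    formula: str
    adduct: str  # "[M+H]+" | "[M-H]-"
    peaks: tuple[tuple[float, float], ...]  # (mz, relative intensity)
    diagnostic_mzs: tuple[float, ...] = ()
    mass_warning: bool = False  # a fragment exceeds the precursor mass

    @property
    def precursor_mz(self) -> float:
        f = parse_formula(self.formula)
        return ion_mz(f, M_PLUS_H if self.adduct == "[M+H]+" else M_MINUS_H)


@dataclass(frozen=True)
class MonitoringApplicationEvent:
    site: str
    date: date
    compound_id: str
    dose_g_ha: float

    def __post_init__(self) -> None:
        if self.dose_g_ha <= 0:
            raise ValueError("dose must be positive")


@dataclass(frozen=True)
class MonitoringDetectionRecord:
    site: str
    week: date
    compound_id: str
    concentration_ug_l: float

    def __post_init__(self) -> None:
        if self.concentration_ug_l < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class StandardRecord:
    """Reference-standard measurement used for level-1 confirmation."""

    suspect_id: str
    rt: float
    ms2: tuple[tuple[float, float], ...]


# ---------------------------------------------------------------- features

_FEATURE_COLUMNS = [
    "feature_id", "site", "week", "polarity", "mz", "rt", "area",
    "volume_l", "trace", "isotope_cluster", "ms2",
]


def _encode_pairs(pairs: Iterable[tuple[float, float]]) -> str:
    return ";".join(f"{a:.6f}:{b:.6f}" for a, b in pairs)


def _decode_pairs(text: str) -> list[tuple[float, float]]:
    if not text or str(text) == "nan":
        return []
    out = []
    for tok in str(text).split(";"):
        a, b = tok.split(":")
        out.append((float(a), float(b)))
    return out


def write_feature_table(features: Sequence[Feature], path: str | Path) -> None:
    rows = [
        {
            "feature_id": f.feature_id,
            "site": f.site,
            "week": f.week.isoformat(),
            "polarity": f.polarity,
            "mz": f"{f.mz:.6f}",
            "rt": f"{f.rt:.4f}",
            "area": f"{f.area:.4f}",
            "volume_l": f"{f.volume_l:.4f}",
            "trace": _encode_pairs(f.trace),
            "isotope_cluster": _encode_pairs(f.isotope_cluster),
            "ms2": _encode_pairs(f.ms2),
        }
        for f in features
    ]
    pd.DataFrame(rows, columns=_FEATURE_COLUMNS).to_csv(path, index=False)


def read_feature_table(
    path: str | Path,
) -> tuple[list[Feature], list[dict]]:
    """Parse a feature CSV.

    Returns ``(features, rejects)``: malformed rows are reported with a
    reason instead of being silently dropped.  A missing mandatory
    column raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, keep_default_na=False, dtype=str)
    missing = set(_FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"feature table missing columns: {sorted(missing)}")
    features: list[Feature] = []
    rejects: list[dict] = []
    for idx, row in df.iterrows():
        try:
            f = Feature(
                feature_id=row["feature_id"],
                site=row["site"],
                week=date.fromisoformat(row["week"]),
                polarity=row["polarity"],
                mz=float(row["mz"]),
                rt=float(row["rt"]),
                area=float(row["area"]),
                volume_l=float(row["volume_l"]),
                trace=_decode_pairs(row["trace"]),
                isotope_cluster=_decode_pairs(row["isotope_cluster"]),
                ms2=_decode_pairs(row["ms2"]),
            )
            f.validate()
            features.append(f)
        except (ValueError, KeyError) as exc:
            rejects.append({"row": int(idx), "feature_id": row.get("feature_id", ""),
                            "reason": str(exc)})
    return features, rejects


# ----------------------------------------------------------------- library

_MASS_TOL_PPM = 10.0


def write_spectral_library(
    records: Sequence[SpectralLibraryRecord], path: str | Path
) -> None:
    path = Path(path)
    if path.exists():
        path.unlink()  # matchms appends
    spectra = []
    for r in records:
        mz = np.array([p[0] for p in r.peaks], dtype=float)
        inten = np.array([p[1] for p in r.peaks], dtype=float)
        order = np.argsort(mz)
        comment = "diagnostic=" + ",".join(f"{d:.5f}" for d in r.diagnostic_mzs)
        spectra.append(
            Spectrum(
                mz=mz[order],
                intensities=inten[order],
                metadata={
                    "compound_name": r.name,
                    "formula": r.formula,
                    "adduct": r.adduct,
                    "comment": comment,
                },
                metadata_harmonization=False,
            )
        )
    save_as_msp(spectra, str(path))


def read_spectral_library(path: str | Path) -> list[SpectralLibraryRecord]:
    """Load an MSP library.

    Diagnostic flags are parsed from a ``diagnostic=...`` comment field.
    A record without peaks raises; a fragment heavier than its precursor
    (by more than 10 ppm) sets ``mass_warning`` on load.
    """
    records = []
    raw = Path(path).read_text()
    n_declared = sum(
        1 for line in raw.splitlines() if line.lower().startswith("num peaks")
    )
    for i, spec in enumerate(load_from_msp(str(path), metadata_harmonization=False)):
        if spec is None or len(spec.peaks.mz) == 0:
            raise SchemaError(f"library record {i} is truncated or has no peaks")
        meta = spec.metadata
        name = meta.get("compound_name") or meta.get("name")
        formula = meta.get("formula")
        adduct = meta.get("adduct")
        if not (name and formula and adduct):
            raise SchemaError(f"library record {i} missing name/formula/adduct")
        diag: tuple[float, ...] = ()
        comment = meta.get("comment", "")
        if "diagnostic=" in comment:
            body = comment.split("diagnostic=", 1)[1].split(";")[0]
            diag = tuple(float(x) for x in body.split(",") if x)
        rec = SpectralLibraryRecord(
            name=name,
            formula=formula,
            adduct=adduct,
            peaks=tuple(zip(spec.peaks.mz.tolist(), spec.peaks.intensities.tolist())),
            diagnostic_mzs=diag,
        )
        limit = rec.precursor_mz * (1 + _MASS_TOL_PPM * 1e-6)
        if any(mz > limit for mz, _ in rec.peaks):
            rec = SpectralLibraryRecord(
                **{**rec.__dict__, "mass_warning": True}
            )
        records.append(rec)
    if len(records) != n_declared:
        raise SchemaError(
            f"library declares {n_declared} records but {len(records)} parsed "
            f"(record {len(records)} truncated or empty)"
        )
    return records


# -------------------------------------------------------------- monitoring

def write_applications(
    events: Sequence[MonitoringApplicationEvent], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {"site": e.site, "date": e.date.isoformat(),
             "compound_id": e.compound_id, "dose_g_ha": e.dose_g_ha}
            for e in events
        ],
        columns=["site", "date", "compound_id", "dose_g_ha"],
    ).to_csv(path, index=False)


def read_applications(path: str | Path) -> list[MonitoringApplicationEvent]:
    df = pd.read_csv(path)
    return [
        MonitoringApplicationEvent(
            site=str(r["site"]), date=date.fromisoformat(str(r["date"])),
            compound_id=str(r["compound_id"]), dose_g_ha=float(r["dose_g_ha"]),
        )
        for _, r in df.iterrows()
    ]


def write_detections(
    records: Sequence[MonitoringDetectionRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {"site": r.site, "week": r.week.isoformat(),
             "compound_id": r.compound_id,
             "concentration_ug_l": r.concentration_ug_l}
            for r in records
        ],
        columns=["site", "week", "compound_id", "concentration_ug_l"],
    ).to_csv(path, index=False)


def read_detections(path: str | Path) -> list[MonitoringDetectionRecord]:
    df = pd.read_csv(path)
    return [
        MonitoringDetectionRecord(
            site=str(r["site"]), week=date.fromisoformat(str(r["week"])),
            compound_id=str(r["compound_id"]),
            concentration_ug_l=float(r["concentration_ug_l"]),
        )
        for _, r in df.iterrows()
    ]


def write_standards(records: Sequence[StandardRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"suspect_id": r.suspect_id, "rt": f"{r.rt:.4f}",
             "ms2": _encode_pairs(r.ms2)}
            for r in records
        ],
        columns=["suspect_id", "rt", "ms2"],
    ).to_csv(path, index=False)


def read_standards(path: str | Path) -> list[StandardRecord]:
    df = pd.read_csv(path, keep_default_na=False, dtype=str)
    return [
        StandardRecord(
            suspect_id=r["suspect_id"], rt=float(r["rt"]),
            ms2=tuple(_decode_pairs(r["ms2"])),
        )
        for _, r in df.iterrows()
    ]


# ------------------------------------------------------------------ report

_LEVEL_ORDER = {"1": 0, "2a": 1, "2b": 2, "3": 3, "4": 4, "5": 5}

_REPORT_COLUMNS = [
    "suspect_id", "name", "formula", "confidence_level", "polarities",
    "parent_ids", "sites", "concentration_range", "source_warning",
    "last_application",
]


def write_report(rows: Sequence[dict], path_base: str | Path) -> tuple[Path, Path]:
    """Write the final per-structure report as CSV and JSON.

    One row per unique structure, ordered by confidence level (most
    confident first) then name; the two files carry identical fields.
    """
    path_base = Path(path_base)
    ordered = sorted(
        rows,
        key=lambda r: (_LEVEL_ORDER.get(str(r.get("confidence_level")), 9),
                       str(r.get("name", ""))),
    )
    norm = [{col: r.get(col, "") for col in _REPORT_COLUMNS} for r in ordered]
    csv_path = path_base.with_suffix(".csv")
    json_path = path_base.with_suffix(".json")
    pd.DataFrame(norm, columns=_REPORT_COLUMNS).to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(norm, indent=1, default=str) + "\n")
    return csv_path, json_path
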