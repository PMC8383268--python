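"""Suspect-list assembly.

The screenable list is the union of (i) the monitored target pesticides,
(ii) the regulatory "key metabolites" of those targets, (iii) a small
set of additional parents of monitoring interest, and (iv) the key
metabolites of those additional parents.  Every entry carries its
neutral monoisotopic mass and both-polarity expected m/z so that the
screening engine never recomputes chemistry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import (
    M_MINUS_H,
    M_PLUS_H,
    ElementalFormula,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "RegistryEntry",
    "KeyMetaboliteRecord",
    "SuspectEntry",
    "SuspectListError",
    "build_suspect_list",
    "non_target_subset",
    "write_suspect_csv",
    "read_suspect_csv",
]

ADDITION_CATEGORIES = (
    "newly_registered",
    "seed_treatment",
    "tp_only_monitored_parent",
    "special_concern",
)


class SuspectListError(ValueError):
    pass


@dataclass(frozen=True)
class RegistryEntry:
    """One pesticide in the monitoring registry."""

    compound_id: str
    name: str
    formula: str
    role: str  # "monitored_target" | "additional_parent"
    addition_category: str | None = None
    registered_sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ("monitored_target", "additional_parent"):
            raise SuspectListError(f"{self.compound_id}: bad role {self.role!r}")
        has_cat = self.addition_category is not None
        if has_cat != (self.role == "additional_parent"):
            raise SuspectListError(
                f"{self.compound_id}: addition_category present iff additional_parent"
            )
        if has_cat and self.addition_category not in ADDITION_CATEGORIES:
            raise SuspectListError(
                f"{self.compound_id}: unknown category {self.addition_category!r}"
            )


@dataclass(frozen=True)
class KeyMetaboliteRecord:
    """A parent -> key-metabolite link from a properties-database table."""

    parent_id: str
    tp_id: str
    tp_name: str
    formula: str
    k_foc: float | None = None  # mL/g; lower = more mobile
    parent_k_foc: float | None = None


@dataclass(frozen=True)
class SuspectEntry:
    """One screenable compound with precomputed ion m/z in both polarities."""

    suspect_id: str
    name: str
    formula: str
    neutral_mass: float
    expected_mz_pos: float
    expected_mz_neg: float
    origin: str  # "target" | "key_metabolite" | "added_parent"
    parent_ids: tuple[str, ...] = ()
    k_foc: float | None = None

    def __post_init__(self) -> None:
        if self.origin not in ("target", "key_metabolite", "added_parent"):
            raise SuspectListError(f"bad origin {self.origin!r}")
        if (self.origin == "key_metabolite") != bool(self.parent_ids):
            raise SuspectListError(
                f"{self.suspect_id}: parent_ids non-empty iff key_metabolite"
            )

    def expected_mz(self, polarity: str) -> float:
        return self.expected_mz_pos if polarity == "positive" else self.expected_mz_neg


def _norm_name(name: str) -> str:
    return re.sub(r"[\s\-_]+", "", name).lower()


def _entry(
    suspect_id: str,
    name: str,
    formula: ElementalFormula,
    origin: str,
    parent_ids: Sequence[str] = (),
    k_foc: float | None = None,
) -> SuspectEntry:
    return SuspectEntry(
        suspect_id=suspect_id,
        name=name,
        formula=formula.hill(),
        neutral_mass=monoisotopic_mass(formula),
        expected_mz_pos=ion_mz(formula, M_PLUS_H),
        expected_mz_neg=ion_mz(formula, M_MINUS_H),
        origin=origin,
        parent_ids=tuple(sorted(set(parent_ids))),
        k_foc=k_foc,
    )


def build_suspect_list(
    registry: Iterable[RegistryEntry],
    metabolites: Iterable[KeyMetaboliteRecord],
    collapse_shared: bool = True,
) -> list[SuspectEntry]:
    """Assemble the suspect list from registry and key-metabolite tables.

    Targets and additional parents each contribute one entry; every key
    metabolite contributes one entry linked to its parent(s).  With
    ``collapse_shared`` (default) a metabolite structure listed under
    several parents — identified by canonical formula plus normalized
    name — appears once with merged ``parent_ids``.

    Raises :class:`SuspectListError` when a metabolite references a
    parent absent from the registry.
    """
    registry = list(registry)
    by_id = {r.compound_id: r for r in registry}
    out: list[SuspectEntry] = []
    for r in sorted(registry, key=lambda r: r.compound_id):
        origin = "target" if r.role == "monitored_target" else "added_parent"
        out.append(_entry(r.compound_id, r.name, parse_formula(r.formula), origin))

    merged: dict[object, dict] = {}
    for m in sorted(metabolites, key=lambda m: m.tp_id):
        if m.parent_id not in by_id:
            raise SuspectListError(
                f"metabolite {m.tp_id!r} references unknown parent {m.parent_id!r}"
            )
        f = parse_formula(m.formula)
        key = (f.hill(), _norm_name(m.tp_name)) if collapse_shared else m.tp_id
        slot = merged.setdefault(
            key,
            {"tp_id": m.tp_id, "name": m.tp_name, "formula": f, "parents": set(),
             "k_foc": m.k_foc},
        )
        slot["parents"].add(m.parent_id)
        if slot["k_foc"] is None:
            slot["k_foc"] = m.k_foc
    for slot in merged.values():
        out.append(
            _entry(
                slot["tp_id"],
                slot["name"],
                slot["formula"],
                "key_metabolite",
                parent_ids=sorted(slot["parents"]),
                k_foc=slot["k_foc"],
            )
        )
    return out


def non_target_subset(suspects: Iterable[SuspectEntry]) -> list[SuspectEntry]:
    """Suspects excluding the routinely monitored target compounds."""
    return [s for s in suspects if s.origin != "target"]


_CSV_COLUMNS = [
    "suspect_id",
    "name",
    "formula",
    "neutral_mass",
    "mz_M_plus_H",
    "mz_M_minus_H",
    "origin",
    "parent_ids",
    "k_foc",
]


def write_suspect_csv(suspects: Sequence[SuspectEntry], path: str | Path) -> None:
    rows = [
        {
            "suspect_id": s.suspect_id,
            "name": s.name,
            "formula": s.formula,
            "neutral_mass": f"{s.neutral_mass:.6f}",
            "mz_M_plus_H": f"{s.expected_mz_pos:.6f}",
            "mz_M_minus_H": f"{s.expected_mz_neg:.6f}",
            "origin": s.origin,
            "parent_ids": ";".join(s.parent_ids),
            "k_foc": "" if s.k_foc is None else s.k_foc,
        }
        for s in suspects
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_suspect_csv(path: str | Path) -> list[SuspectEntry]:
    """Load a suspect-list CSV, revalidating chemistry on every row."""
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SuspectListError(f"suspect CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        f = parse_formula(row["formula"])
        entry = _entry(
            row["suspect_id"],
            row["name"],
            f,
            row["origin"],
            parent_ids=[p for p in str(row["parent_ids"]).split(";") if p],
            k_foc=float(row["k_foc"]) if str(row["k_foc"]) != "" else None,
        )
        if abs(entry.expected_mz_pos - float(row["mz_M_plus_H"])) > 1e-4:
            raise SuspectListError(
                f"{entry.suspect_id}: stored m/z inconsistent with formula"
            )
        out.append(entry)
    return out
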