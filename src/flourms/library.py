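"""Compound libraries: target standards, suspect lists, non-target tables.

Ships four reconstructed delimited-text libraries (grape-seed / olive-stone
target standards and suspects) plus two transcribed non-target annotation
tables. Reference retention times and expected fragment lists in the
libraries are synthetic stand-ins, flagged as such in the provenance
column; records whose printed m/z disagrees with their printed formula by
more than 5 ppm carry an ``inconsistent`` flag and are excluded from
mass-consistency guarantees rather than silently corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional

import pandas as pd

from .chem_core import Formula, FormulaError, mz_deprotonated, parse_formula, ppm_error

__all__ = [
    "CompoundRecord",
    "LibraryFixture",
    "load_builtin_library",
    "load_library_file",
    "validate_library",
    "BUILTIN_LIBRARIES",
]

COMPOUND_CLASSES = {
    "phenolic acid", "flavonoid", "flavonoid glycoside", "stilbene",
    "secoiridoid", "lignan", "coumarin", "triterpenoid", "anthocyanin",
    "organic acid", "phenol", "lipid", "polyphenol", "other",
    "terpenoid", "monoterpenoid", "flavone", "lipid derivative",
    "triterpenoid acid", "",
}

BUILTIN_LIBRARIES = (
    "gsf_targets", "osf_targets", "gsf_suspects", "osf_suspects",
    "nontarget_table1", "nontarget_table2",
)


@dataclass(frozen=True)
class CompoundRecord:
    name: str
    formula: Optional[Formula]
    compound_class: str = ""
    role: str = "suspect"  # target | suspect | internal_standard | nontarget
    reference_rt: Optional[float] = None
    expected_fragments: tuple = ()
    semi_quant_reference: Optional[str] = None
    printed_mz: Optional[float] = None
    printed_rt: Optional[float] = None
    vip: Optional[float] = None
    finder_score: Optional[float] = None
    provenance: str = ""
    flag: str = ""

    def __post_init__(self) -> None:
        if self.role == "target" and self.reference_rt is None:
            raise ValueError(f"target {self.name!r} lacks a reference RT")
        if self.role == "suspect" and self.formula is None:
            raise ValueError(f"suspect {self.name!r} lacks a formula")

    @property
    def theoretical_mz(self) -> Optional[float]:
        if self.formula is None or self.formula["H"] < 1:
            return None
        return mz_deprotonated(self.formula)


@dataclass
class LibraryFixture:
    name: str
    records: List[CompoundRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.name, r.printed_mz, r.printed_rt) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate records in {self.name!r}: {sorted(dupes)}")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_name(self, name: str) -> CompoundRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def with_role(self, *roles: str) -> List[CompoundRecord]:
        return [r for r in self.records if r.role in roles]

    @property
    def internal_standard(self) -> Optional[CompoundRecord]:
        cands = self.with_role("internal_standard")
        if len(cands) > 1:
            raise ValueError("internal standard must be unique")
        return cands[0] if cands else None


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return float(v)


def _library_from_frame(name: str, df: pd.DataFrame) -> LibraryFixture:
    df = df.fillna("")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        formula = None
        ftext = str(d.get("formula", "")).strip()
        if ftext:
            try:
                formula = parse_formula(ftext)
            except FormulaError:
                formula = None  # verbatim junk stays flagged in the CSV
        frags = tuple(
            float(x) for x in str(d.get("fragments", "")).split(";") if x.strip()
        )
        records.append(CompoundRecord(
            name=str(d.get("name") or d.get("analyte") or
                     f"feature {d.get('printed_mz')}@{d.get('printed_rt')}"),
            formula=formula,
            compound_class=str(d.get("compound_class", "")).strip().lower(),
            role=str(d.get("role", "nontarget") or "nontarget"),
            reference_rt=_opt_float(d.get("reference_rt")),
            expected_fragments=frags,
            semi_quant_reference=(str(d["semi_quant_reference"]) or None)
            if "semi_quant_reference" in d else None,
            printed_mz=_opt_float(d.get("printed_mz")),
            printed_rt=_opt_float(d.get("printed_rt")),
            vip=_opt_float(d.get("vip")),
            finder_score=_opt_float(d.get("finder_score")),
            provenance=str(d.get("provenance", "") or d.get("reference", "")),
            flag=str(d.get("flag", "") or d.get("consistency", "")),
        ))
    return LibraryFixture(name=name, records=records)


def load_builtin_library(which: str) -> LibraryFixture:
    """Load one of the packaged libraries by name.

    ``gsf_targets``/``osf_targets``: the reconstructed standard list (incl.
    the hesperidin internal standard). ``gsf_suspects``/``osf_suspects``:
    named suspect compounds with same-class semi-quantification references.
    ``nontarget_table1``/``nontarget_table2``: the transcribed non-target
    annotation tables (olive-stone and grape-seed VIP features).
    """
    if which not in BUILTIN_LIBRARIES:
        raise KeyError(f"unknown builtin library {which!r}; choose from {BUILTIN_LIBRARIES}")
    with resources.files("flourms.data").joinpath(f"{which}.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    return _library_from_frame(which, df)


def load_library_file(path, name: Optional[str] = None, sep: str = ",") -> LibraryFixture:
    """Load a user-supplied library from delimited text (same columns as the
    packaged fixtures)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    return _library_from_frame(name or str(path), df)


def validate_library(fixture: LibraryFixture, ppm_tol: float = 5.0) -> pd.DataFrame:
    """Per-record mass-consistency report.

    For every record carrying both a printed m/z and a parseable formula,
    computes the signed ppm error of the printed value against the
    theoretical [M - H]- m/z and flags |ppm| > ppm_tol as inconsistent.
    Records lacking either quantity are reported with status ``skipped``.
    Pure: same fixture, same report.
    """
    rows = []
    for r in fixture.records:
        theo = r.theoretical_mz
        if r.printed_mz is None or theo is None:
            rows.append((r.name, r.printed_mz, None, None, "skipped"))
            continue
        err = ppm_error(r.printed_mz, theo)
        status = "consistent" if abs(err) <= ppm_tol else "inconsistent"
        rows.append((r.name, r.printed_mz, theo, err, status))
    return pd.DataFrame(
        rows, columns=["name", "printed_mz", "theoretical_mz", "ppm_error", "status"]
    )
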