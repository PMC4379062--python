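"""Sample sheets and concentration matrices.

A :class:`ConcentrationDataset` couples a metabolite panel with per-sample
annotations (participant, aliquot role, handling condition, freeze-thaw
count, kit plate) and a samples x metabolites matrix of concentrations in
micromolar.  Missing measurements stay missing (``NaN``); they are never
imputed and are handled per operation downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .panel import PanelDefinition

ROLES = ("reference", "handling", "ftc", "pool", "zero")
TEMPERATURES = ("dry_ice", "wet_ice", "rt", "n/a")
HANDLING_DELAYS = (12, 24, 36)

SHEET_COLUMNS = [
    "sample_id",
    "participant",
    "role",
    "temperature",
    "delay_h",
    "thaw_count",
    "plate",
]


class DatasetValidationError(ValueError):
    """Raised when a sample sheet or concentration table violates an invariant."""


@dataclass(frozen=True)
class SampleAnnotation:
    """Metadata for one measured aliquot."""

    sample_id: str
    participant: str
    role: str
    temperature: str
    delay_h: int
    thaw_count: int
    plate: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DatasetValidationError(
                f"{self.sample_id}: unknown role {self.role!r}"
            )
        if self.temperature not in TEMPERATURES:
            raise DatasetValidationError(
                f"{self.sample_id}: unknown temperature {self.temperature!r}"
            )
        if self.role == "handling":
            if self.temperature not in ("dry_ice", "wet_ice", "rt"):
                raise DatasetValidationError(
                    f"{self.sample_id}: handling sample needs a storage temperature"
                )
            if self.delay_h not in HANDLING_DELAYS:
                raise DatasetValidationError(
                    f"{self.sample_id}: handling delay must be one of "
                    f"{HANDLING_DELAYS}, got {self.delay_h}"
                )
        elif self.role == "reference":
            if self.delay_h != 0 or self.thaw_count != 1:
                raise DatasetValidationError(
                    f"{self.sample_id}: reference sample must have delay 0 "
                    "and a single thaw"
                )
        elif self.role == "ftc":
            if self.thaw_count not in (2, 3, 4) or self.delay_h != 0:
                raise DatasetValidationError(
                    f"{self.sample_id}: freeze-thaw sample must have delay 0 "
                    "and 2-4 thaws"
                )
        if self.thaw_count not in (1, 2, 3, 4):
            raise DatasetValidationError(
                f"{self.sample_id}: thaw_count must be in 1..4"
            )


@dataclass
class ConcentrationDataset:
    """Panel + annotations + concentration matrix (uM).

    ``values`` is indexed by ``sample_id`` with one column per panel
    metabolite, in panel order.  All non-missing entries are >= 0.
    """

    panel: PanelDefinition
    annotations: list[SampleAnnotation]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        ids = [a.sample_id for a in self.annotations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetValidationError(f"duplicate sample_id: {dupes}")
        if len(self.values) != len(self.annotations):
            raise DatasetValidationError(
                f"{len(self.values)} value rows but {len(self.annotations)} "
                "annotated samples"
            )
        if list(self.values.index) != ids:
            raise DatasetValidationError(
                "value row order does not match the sample sheet"
            )
        if list(self.values.columns) != self.panel.ids:
            unknown = set(self.values.columns) - set(self.panel.ids)
            if unknown:
                raise DatasetValidationError(
                    f"columns not in panel: {sorted(unknown)}"
                )
            raise DatasetValidationError(
                "concentration columns must match the panel ids in order"
            )
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            bad = self.values.columns[(vals < 0).any(axis=0)].tolist()
            raise DatasetValidationError(f"negative concentrations in {bad}")
        # one plate per participant (subject samples only)
        plates: dict[str, str] = {}
        for a in self.annotations:
            if a.role in ("reference", "handling", "ftc"):
                if plates.setdefault(a.participant, a.plate) != a.plate:
                    raise DatasetValidationError(
                        f"participant {a.participant} appears on several plates"
                    )

    # -- convenience --------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [a.sample_id for a in self.annotations]

    @property
    def sheet(self) -> pd.DataFrame:
        """Sample annotations as a DataFrame (column order fixed)."""
        if not self.annotations:
            return pd.DataFrame(columns=SHEET_COLUMNS)
        df = pd.DataFrame([dataclasses.asdict(a) for a in self.annotations])
        return df[SHEET_COLUMNS]

    def roles(self) -> pd.Series:
        return pd.Series(
            [a.role for a in self.annotations], index=self.sample_ids, name="role"
        )

    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.annotations:
            if a.role in ("reference", "handling", "ftc"):
                seen.setdefault(a.participant, None)
        return list(seen)

    def subset_roles(self, roles: Iterable[str]) -> "ConcentrationDataset":
        keep = set(roles)
        anns = [a for a in self.annotations if a.role in keep]
        ids = [a.sample_id for a in anns]
        return ConcentrationDataset(self.panel, anns, self.values.loc[ids])

    def subset_metabolites(self, keep_ids: Sequence[str]) -> "ConcentrationDataset":
        sub = self.panel.subset(keep_ids)
        return ConcentrationDataset(sub, list(self.annotations), self.values[sub.ids])

    def subset_participants(self, participants: Iterable[str]) -> "ConcentrationDataset":
        keep = set(participants)
        anns = [
            a
            for a in self.annotations
            if a.role in ("pool", "zero") or a.participant in keep
        ]
        ids = [a.sample_id for a in anns]
        return ConcentrationDataset(self.panel, anns, self.values.loc[ids])


# ---------------------------------------------------------------------------
# CSV round trip


def _annotation_from_row(row: pd.Series, line: int) -> SampleAnnotation:
    try:
        return SampleAnnotation(
            sample_id=str(row["sample_id"]),
            participant=str(row["participant"]),
            role=str(row["role"]),
            temperature=str(row["temperature"]),
            delay_h=int(row["delay_h"]),
            thaw_count=int(row["thaw_count"]),
            plate=str(row["plate"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, DatasetValidationError):
            raise
        raise DatasetValidationError(f"sample sheet line {line}: {exc}") from exc


def read_dataset(
    concentration_table: Union[str, Path],
    sample_sheet: Union[str, Path],
    panel: PanelDefinition,
) -> ConcentrationDataset:
    """Read the CSV pair written by :func:`write_dataset`.

    The concentration table holds samples in rows (first column
    ``sample_id``) and metabolites in columns; metabolite columns must be a
    subset of the panel.  Empty cells are missing values.  Both files are
    joined on ``sample_id``; the sheet defines the sample order.
    """
    try:
        conc = pd.read_csv(concentration_table, dtype={"sample_id": str})
        # the temperature field legitimately holds "n/a"; disable NA parsing
        sheet = pd.read_csv(sample_sheet, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise DatasetValidationError(f"malformed CSV: {exc}") from exc

    missing_cols = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise DatasetValidationError(f"sample sheet lacks columns {missing_cols}")
    if "sample_id" not in conc.columns:
        raise DatasetValidationError("concentration table lacks a sample_id column")

    met_cols = [c for c in conc.columns if c != "sample_id"]
    unknown = set(met_cols) - set(panel.ids)
    if unknown:
        raise DatasetValidationError(
            f"concentration table has columns not in the panel: {sorted(unknown)}"
        )

    annotations = [
        _annotation_from_row(row, line + 2) for line, row in sheet.iterrows()
    ]
    sample_ids = [a.sample_id for a in annotations]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({i for i in sample_ids if sample_ids.count(i) > 1})
        raise DatasetValidationError(f"duplicate sample_id in sheet: {dupes}")

    conc = conc.set_index("sample_id")
    if conc.index.has_duplicates:
        dupes = sorted(conc.index[conc.index.duplicated()].unique())
        raise DatasetValidationError(
            f"duplicate sample_id in concentration table: {dupes}"
        )
    absent = [s for s in sample_ids if s not in conc.index]
    if absent:
        raise DatasetValidationError(
            f"samples in sheet but not in concentration table: {absent}"
        )

    sub = panel.subset(met_cols) if set(met_cols) != set(panel.ids) else panel
    values = conc.loc[sample_ids, sub.ids].astype(float)
    values.index.name = None
    return ConcentrationDataset(sub, annotations, values)


def write_dataset(
    dataset: ConcentrationDataset,
    concentration_table: Union[str, Path],
    sample_sheet: Union[str, Path],
) -> None:
    """Write the dataset as a CSV pair; inverse of :func:`read_dataset`.

    Concentrations are written with ``repr`` round-trip precision; missing
    cells are written as empty fields, never as zeros.
    """
    out = dataset.values.copy()
    out.insert(0, "sample_id", dataset.sample_ids)
    out.to_csv(concentration_table, index=False, float_format="%.17g")
    dataset.sheet.to_csv(sample_sheet, index=False)
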