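"""Definition of the targeted serum metabolite panel.

The panel mirrors a flow-injection MS/MS kit quantifying 163 metabolites in
serum: 14 amino acids, the sum of hexoses, free carnitine, 40 acylcarnitines,
15 sphingomyelins, 77 phosphatidylcholines (diacyl and acyl-alkyl) and
15 lysophosphatidylcholines.  Lipid species are named ``class(x:y)`` where
``x`` is the total number of carbon atoms and ``y`` the number of double
bonds in the fatty-acid side chain(s).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

#: valid metabolite classes
MCLASSES = (
    "amino_acid",
    "hexose",
    "carnitine",
    "acylcarnitine",
    "sphingomyelin",
    "pc_aa",
    "pc_ae",
    "lyso_pc",
)

#: classes whose names carry a carbon:double-bond annotation
LIPID_CLASSES = frozenset(
    {"acylcarnitine", "sphingomyelin", "pc_aa", "pc_ae", "lyso_pc"}
)

_CHAIN_RE = re.compile(r"\(?(?:O-)?(\d+):(\d+)\)?")
_ACYL_RE = re.compile(r"^C(\d+)(?::(\d+))?")


def parse_chain(metabolite_id: str) -> tuple[Optional[int], Optional[int]]:
    """Parse carbon count and double-bond count from a short metabolite name.

    Handles the ``PC(38:4)`` / ``PC(O-34:1)`` / ``SM(OH)(22:1)`` /
    ``lysoPC(18:0)`` family as well as acylcarnitine names such as ``C10:2``
    or ``C4-OH`` (the leading acyl chain is parsed; modifier suffixes are
    ignored).  Returns ``(None, None)`` when no chain annotation is present.
    """
    if metabolite_id.startswith("C") and metabolite_id[1:2].isdigit():
        m = _ACYL_RE.match(metabolite_id)
        if m:
            return int(m.group(1)), int(m.group(2) or 0)
    matches = _CHAIN_RE.findall(metabolite_id)
    if matches:
        # for SM(OH)(22:1)-style names the chain is the last (x:y) group
        x, y = matches[-1]
        return int(x), int(y)
    return None, None


@dataclass(frozen=True)
class MetaboliteDescriptor:
    """One metabolite of the panel.

    Parameters
    ----------
    id : str
        Short name, e.g. ``"lysoPC(18:0)"`` or ``"C10:2"``.
    full_name : str
        Descriptive name.
    mclass : str
        One of :data:`MCLASSES`.
    carbons, double_bonds : int or None
        Chain annotation; present exactly for lipid classes.
    """

    id: str
    full_name: str
    mclass: str
    carbons: Optional[int] = None
    double_bonds: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mclass not in MCLASSES:
            raise ValueError(f"unknown metabolite class {self.mclass!r}")
        is_lipid = self.mclass in LIPID_CLASSES
        has_chain = self.carbons is not None and self.double_bonds is not None
        if is_lipid and not has_chain:
            raise ValueError(f"{self.id}: lipid class requires carbons/double_bonds")
        if not is_lipid and (self.carbons is not None or self.double_bonds is not None):
            raise ValueError(f"{self.id}: chain annotation only valid for lipid classes")
        if has_chain and (self.carbons < 0 or self.double_bonds < 0):
            raise ValueError(f"{self.id}: chain annotation must be nonnegative")


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered collection of :class:`MetaboliteDescriptor`."""

    metabolites: tuple[MetaboliteDescriptor, ...]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate metabolite ids in panel: {dupes}")

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def __len__(self) -> int:
        return len(self.metabolites)

    def __getitem__(self, metabolite_id: str) -> MetaboliteDescriptor:
        for m in self.metabolites:
            if m.id == metabolite_id:
                return m
        raise KeyError(metabolite_id)

    def __contains__(self, metabolite_id: str) -> bool:
        return any(m.id == metabolite_id for m in self.metabolites)

    def class_of(self, metabolite_id: str) -> str:
        return self[metabolite_id].mclass

    def ids_of_class(self, *mclasses: str) -> list[str]:
        wanted = set(mclasses)
        return [m.id for m in self.metabolites if m.mclass in wanted]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in MCLASSES}
        for m in self.metabolites:
            counts[m.mclass] += 1
        return counts

    def subset(self, keep_ids: Iterable[str]) -> "PanelDefinition":
        keep = set(keep_ids)
        unknown = keep - set(self.ids)
        if unknown:
            raise KeyError(f"ids not in panel: {sorted(unknown)}")
        return PanelDefinition(tuple(m for m in self.metabolites if m.id in keep))


# ---------------------------------------------------------------------------
# default 163-metabolite panel

_AMINO_ACIDS = {
    "Arg": "Arginine",
    "Gln": "Glutamine",
    "Gly": "Glycine",
    "His": "Histidine",
    "Met": "Methionine",
    "Orn": "Ornithine",
    "Phe": "Phenylalanine",
    "Pro": "Proline",
    "Ser": "Serine",
    "Thr": "Threonine",
    "Trp": "Tryptophan",
    "Tyr": "Tyrosine",
    "Val": "Valine",
    "xLeu": "Leucine+Isoleucine",
}

_ACYLCARNITINES = [
    "C2", "C3", "C3:1", "C3-OH", "C3-DC",
    "C4", "C4:1", "C4-OH",
    "C5", "C5:1", "C5:1-DC", "C5-OH", "C5-DC", "C5-M-DC",
    "C6", "C6:1", "C7-DC",
    "C8", "C8:1", "C9",
    "C10", "C10:1", "C10:2",
    "C12", "C12:1", "C12-DC",
    "C14", "C14:1", "C14:2", "C14:1-OH", "C14:2-OH",
    "C16", "C16:1", "C16:2", "C16-OH", "C16:1-OH", "C16:2-OH",
    "C18", "C18:1", "C18:2",
]

_SPHINGOMYELINS = [
    "SM(16:0)", "SM(16:1)", "SM(18:0)", "SM(18:1)", "SM(20:2)",
    "SM(22:3)", "SM(24:0)", "SM(24:1)", "SM(26:0)", "SM(26:1)",
    "SM(OH)(14:1)", "SM(OH)(16:1)", "SM(OH)(22:1)", "SM(OH)(22:2)",
    "SM(OH)(24:1)",
]

_PC_AA = [
    "PC(24:0)", "PC(26:0)", "PC(28:1)", "PC(30:0)", "PC(30:2)",
    "PC(32:0)", "PC(32:1)", "PC(32:2)", "PC(32:3)",
    "PC(34:1)", "PC(34:2)", "PC(34:3)", "PC(34:4)",
    "PC(36:0)", "PC(36:1)", "PC(36:2)", "PC(36:3)", "PC(36:4)",
    "PC(36:5)", "PC(36:6)",
    "PC(38:0)", "PC(38:1)", "PC(38:3)", "PC(38:4)", "PC(38:5)", "PC(38:6)",
    "PC(40:1)", "PC(40:2)", "PC(40:3)", "PC(40:4)", "PC(40:5)", "PC(40:6)",
    "PC(42:0)", "PC(42:1)", "PC(42:2)", "PC(42:4)", "PC(42:5)", "PC(42:6)",
]

_PC_AE = [
    "PC(O-30:0)", "PC(O-30:1)", "PC(O-30:2)",
    "PC(O-32:1)", "PC(O-32:2)",
    "PC(O-34:0)", "PC(O-34:1)", "PC(O-34:2)", "PC(O-34:3)",
    "PC(O-36:0)", "PC(O-36:1)", "PC(O-36:2)", "PC(O-36:3)", "PC(O-36:4)",
    "PC(O-36:5)",
    "PC(O-38:0)", "PC(O-38:1)", "PC(O-38:2)", "PC(O-38:3)", "PC(O-38:4)",
    "PC(O-38:5)", "PC(O-38:6)",
    "PC(O-40:0)", "PC(O-40:1)", "PC(O-40:2)", "PC(O-40:3)", "PC(O-40:4)",
    "PC(O-40:5)", "PC(O-40:6)",
    "PC(O-42:0)", "PC(O-42:1)", "PC(O-42:2)", "PC(O-42:3)", "PC(O-42:4)",
    "PC(O-42:5)",
    "PC(O-44:3)", "PC(O-44:4)", "PC(O-44:5)", "PC(O-44:6)",
]

_LYSO_PC = [
    "lysoPC(6:0)", "lysoPC(14:0)", "lysoPC(16:0)", "lysoPC(16:1)",
    "lysoPC(17:0)", "lysoPC(18:0)", "lysoPC(18:1)", "lysoPC(18:2)",
    "lysoPC(20:3)", "lysoPC(20:4)", "lysoPC(24:0)", "lysoPC(26:0)",
    "lysoPC(26:1)", "lysoPC(28:0)", "lysoPC(28:1)",
]

_FULL_PREFIX = {
    "acylcarnitine": "Acylcarnitine",
    "sphingomyelin": "Sphingomyelin",
    "pc_aa": "Diacylphosphatidylcholine",
    "pc_ae": "Acylalkylphosphatidylcholine",
    "lyso_pc": "Lysophosphatidylcholine",
}


def _lipid(metabolite_id: str, mclass: str) -> MetaboliteDescriptor:
    carbons, dbs = parse_chain(metabolite_id)
    return MetaboliteDescriptor(
        id=metabolite_id,
        full_name=f"{_FULL_PREFIX[mclass]} {metabolite_id}",
        mclass=mclass,
        carbons=carbons,
        double_bonds=dbs,
    )


def build_p150_panel() -> PanelDefinition:
    """Return the default 163-metabolite serum panel.

    Class counts are 14 amino acids + 1 hexose + 1 free carnitine +
    40 acylcarnitines + 15 sphingomyelins + 77 phosphatidylcholines +
    15 lysophosphatidylcholines = 163.
    """
    mets: list[MetaboliteDescriptor] = []
    for short, full in _AMINO_ACIDS.items():
        mets.append(MetaboliteDescriptor(short, full, "amino_acid"))
    mets.append(MetaboliteDescriptor("H1", "Sum of hexoses", "hexose"))
    mets.append(MetaboliteDescriptor("C0", "Free carnitine", "carnitine"))
    mets.extend(_lipid(i, "acylcarnitine") for i in _ACYLCARNITINES)
    mets.extend(_lipid(i, "sphingomyelin") for i in _SPHINGOMYELINS)
    mets.extend(_lipid(i, "pc_aa") for i in _PC_AA)
    mets.extend(_lipid(i, "pc_ae") for i in _PC_AE)
    mets.extend(_lipid(i, "lyso_pc") for i in _LYSO_PC)
    return PanelDefinition(tuple(mets))
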