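"""Structures, descriptor tables and the canonical 18-agent reference data.

The central exchange object is :class:`DescriptorTable`, an ordered
collection of per-compound molecular-property records (the nine properties
used throughout the screening pipeline: Log P, topological polar surface
area, heavy-atom count, formula weight, H-bond acceptor and donor counts,
Rule-of-5 violations, rotatable bonds and molecular volume).

Two reference tables for the 18 nitrosourea agents (lomustine plus 17
analogs) are embedded verbatim: the descriptor table and the brain/blood
partitioning table (Log BB, BB) they imply. These are the canonical inputs
for the statistics layer; descriptors computed from structures are a
parallel path with documented tolerances, never a silent substitute.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

from .errors import FormatError, InputError, ParseError, StructureError

RDLogger.DisableLog("rdApp.*")  # rdkit parse noise; errors surface as exceptions

#: SMILES of the nitrosourea warhead common to every agent,
#: O=C(NHR)N(N=O)CH2CH2Cl, with the R attachment left open.
NITROSOUREA_CORE_SMARTS = "O=C(N)N(N=O)CCCl"

#: Lomustine: cyclohexyl R-group on the nitrosourea core.
LOMUSTINE_SMILES = "ClCCN(N=O)C(=O)NC1CCCCC1"


@dataclasses.dataclass(frozen=True)
class Molecule:
    """A parsed structure: identifier, canonical SMILES and the RDKit mol."""

    identifier: str
    smiles: str
    mol: Chem.Mol = dataclasses.field(compare=False, repr=False)

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()


def parse_smiles(smiles: str, identifier: str = "") -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Aromaticity is perceived and implicit hydrogens resolved by RDKit.
    Raises :class:`StructureError` (echoing the input) on invalid SMILES.
    """
    if not smiles or not smiles.strip():
        raise StructureError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    return Molecule(identifier=identifier, smiles=Chem.MolToSmiles(mol), mol=mol)


# Required DescriptorRecord fields and their dtypes ("volume" is optional).
_NUMERIC_FIELDS: tuple[tuple[str, type], ...] = (
    ("log_p", float),
    ("psa", float),
    ("n_atoms", int),
    ("fw", float),
    ("n_on", int),
    ("n_ohnh", int),
    ("n_ro5_violations", int),
    ("n_rot", int),
)

#: Case-insensitive header aliases accepted by :func:`read_descriptor_csv`.
COLUMN_ALIASES: Mapping[str, str] = {
    "agent": "agent_id",
    "agent_id": "agent_id",
    "drug": "agent_id",
    "id": "agent_id",
    "log p": "log_p",
    "log_p": "log_p",
    "logp": "log_p",
    "polar surface area": "psa",
    "polar surface area (angstroms^2)": "psa",
    "psa": "psa",
    "tpsa": "psa",
    "number of atoms": "n_atoms",
    "n_atoms": "n_atoms",
    "atoms": "n_atoms",
    "molecular weight": "fw",
    "formula weight": "fw",
    "fw": "fw",
    "mw": "fw",
    "number of o & n": "n_on",
    "n_on": "n_on",
    "number of -oh and -nhn": "n_ohnh",
    "n_ohnh": "n_ohnh",
    "violations of rule of 5": "n_ro5_violations",
    "n_ro5_violations": "n_ro5_violations",
    "ro5_violations": "n_ro5_violations",
    "number of rotatable bonds": "n_rot",
    "n_rot": "n_rot",
    "nrot": "n_rot",
    "volume": "volume",
    "volume (angstroms^3)": "volume",
    "molecular volume": "volume",
}


@dataclasses.dataclass(frozen=True)
class DescriptorRecord:
    """The nine per-compound molecular properties, one table row.

    ``volume`` (Å³) may be absent; it participates only in correlations,
    clustering and path analysis, which drop it with a notice.
    """

    agent_id: str
    log_p: float
    psa: float
    n_atoms: int
    fw: float
    n_on: int
    n_ohnh: int
    n_ro5_violations: int
    n_rot: int
    volume: float | None = None

    def __post_init__(self) -> None:
        if self.fw <= 0:
            raise ValueError(f"fw must be positive, got {self.fw}")
        if self.psa < 0:
            raise ValueError(f"psa must be non-negative, got {self.psa}")
        for name in ("n_atoms", "n_on", "n_ohnh", "n_rot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_ro5_violations not in (0, 1, 2, 3, 4):
            raise ValueError(
                f"n_ro5_violations must be in 0..4, got {self.n_ro5_violations}"
            )

    def require(self, fields: Iterable[str]) -> None:
        """Raise :class:`InputError` naming any missing/None field."""
        for f in fields:
            if getattr(self, f, None) is None:
                raise InputError(f"record {self.agent_id!r} lacks field {f!r}")


class DescriptorTable:
    """Ordered collection of :class:`DescriptorRecord` with unique ids."""

    def __init__(
        self, records: Sequence[DescriptorRecord], provenance: str = "computed"
    ) -> None:
        ids = [r.agent_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate agent_ids: {dupes}")
        has_vol = {r.volume is not None for r in records}
        if len(has_vol) > 1:
            raise FormatError("volume must be present for all records or none")
        self.records: tuple[DescriptorRecord, ...] = tuple(records)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DescriptorRecord]:
        return iter(self.records)

    def __getitem__(self, agent_id: str) -> DescriptorRecord:
        for r in self.records:
            if r.agent_id == agent_id:
                return r
        raise KeyError(agent_id)

    @property
    def has_volume(self) -> bool:
        return bool(self.records) and self.records[0].volume is not None

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a DataFrame indexed by agent_id."""
        rows = [dataclasses.asdict(r) for r in self.records]
        df = pd.DataFrame(rows).set_index("agent_id")
        if not self.has_volume:
            df = df.drop(columns=["volume"])
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "computed") -> "DescriptorTable":
        records = []
        for agent_id, row in df.iterrows():
            vol = row.get("volume")
            records.append(
                DescriptorRecord(
                    agent_id=str(agent_id),
                    log_p=float(row["log_p"]),
                    psa=float(row["psa"]),
                    n_atoms=int(row["n_atoms"]),
                    fw=float(row["fw"]),
                    n_on=int(row["n_on"]),
                    n_ohnh=int(row["n_ohnh"]),
                    n_ro5_violations=int(row["n_ro5_violations"]),
                    n_rot=int(row["n_rot"]),
                    volume=None if vol is None or (isinstance(vol, float) and math.isnan(vol)) else float(vol),
                )
            )
        return cls(records, provenance=provenance)


# ---------------------------------------------------------------------------
# Embedded reference data: the 18 nitrosourea agents.
# Columns: agent, log_p, psa, n_atoms, fw, n_on, n_ohnh, ro5, n_rot, volume.
_TABLE1 = (
    ("1", 2.965, 61.772, 15, 233.7, 5, 1, 0, 4, 208.8),
    ("2", 2.188, 61.771, 12, 191.6, 5, 1, 0, 4, 163.1),
    ("3", 2.268, 61.771, 13, 207.7, 5, 1, 0, 5, 185.5),
    ("4", 2.034, 61.771, 13, 205.6, 5, 1, 0, 5, 179.9),
    ("5", 2.457, 61.771, 13, 203.6, 5, 1, 0, 5, 174.2),
    ("6", 2.583, 61.771, 16, 268.1, 5, 1, 0, 4, 222.3),
    ("7", 1.975, 61.771, 13, 205.6, 5, 1, 0, 6, 180.1),
    ("8", 2.276, 61.771, 16, 251.7, 5, 1, 0, 4, 213.7),
    ("9", 2.429, 61.771, 14, 217.7, 5, 1, 0, 5, 190.5),
    ("10", 2.359, 61.771, 14, 219.7, 5, 1, 0, 5, 196.1),
    ("11", 2.476, 61.771, 16, 267.8, 5, 1, 0, 8, 236.9),
    ("12", 1.537, 81.999, 15, 237.7, 6, 2, 0, 6, 210.4),
    ("13", 3.184, 61.771, 16, 312.6, 5, 1, 0, 4, 226.7),
    ("14", 2.498, 61.771, 13, 207.7, 5, 1, 0, 6, 185.7),
    ("15", 2.635, 61.771, 15, 231.7, 5, 1, 0, 6, 206.9),
    ("16", 3.924, 61.771, 17, 261.7, 5, 1, 0, 8, 246.5),
    ("17", 3.182, 61.771, 16, 245.7, 5, 1, 0, 6, 223.5),
    ("18", 2.459, 61.771, 14, 219.7, 5, 1, 0, 4, 191.9),
)

# Published brain/blood partitioning of the same agents: (agent, Log BB, BB).
_TABLE3 = (
    ("1, lomustine", -0.325, 0.473),
    ("2", -0.443, 0.361),
    ("3", -0.430, 0.372),
    ("4", -0.466, 0.342),
    ("5", -0.402, 0.396),
    ("6", -0.383, 0.414),
    ("7", -0.475, 0.335),
    ("8", -0.429, 0.372),
    ("9", -0.406, 0.393),
    ("10", -0.416, 0.383),
    ("11", -0.399, 0.399),
    ("12", -0.841, 0.144),
    ("13", -0.291, 0.512),
    ("14", -0.396, 0.402),
    ("15", -0.375, 0.422),
    ("16", -0.179, 0.662),
    ("17", -0.292, 0.511),
    ("18", -0.401, 0.397),
)


def builtin_table1() -> DescriptorTable:
    """The embedded 18-agent descriptor table (provenance ``fixture``)."""
    records = [
        DescriptorRecord(
            agent_id=a, log_p=lp, psa=ps, n_atoms=na, fw=fw,
            n_on=on, n_ohnh=oh, n_ro5_violations=v, n_rot=nr, volume=vol,
        )
        for a, lp, ps, na, fw, on, oh, v, nr, vol in _TABLE1
    ]
    return DescriptorTable(records, provenance="fixture")


def builtin_table3() -> list[tuple[str, float, float]]:
    """The embedded (agent_id, Log BB, BB) reference rows for the 18 agents."""
    return [tuple(row) for row in _TABLE3]


# ---------------------------------------------------------------------------
# CSV / report I/O

_CSV_COLUMNS = [
    "agent_id", "log_p", "psa", "n_atoms", "fw",
    "n_on", "n_ohnh", "n_ro5_violations", "n_rot", "volume",
]


def read_descriptor_csv(path: str | Path, provenance: str = "computed") -> DescriptorTable:
    """Read a descriptor table from CSV (comma-separated, UTF-8, header row).

    Header names are matched case-insensitively against :data:`COLUMN_ALIASES`
    ("Molecular weight" → ``fw``, "Number of O & N" → ``n_on``, ...). Raises
    :class:`FormatError` for a missing required column and :class:`ParseError`
    citing row and column for a non-numeric cell.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    rename = {}
    for col in raw.columns:
        key = col.strip().lower()
        # tolerate unicode dash / spacing variants in donor column header
        key = key.replace("–", "-").replace("−", "-")
        if key in COLUMN_ALIASES:
            rename[col] = COLUMN_ALIASES[key]
    df = raw.rename(columns=rename)
    required = ["agent_id"] + [f for f, _ in _NUMERIC_FIELDS]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")
    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        kwargs: dict = {"agent_id": str(row["agent_id"]).strip()}
        for field, typ in _NUMERIC_FIELDS:
            cell = row[field]
            try:
                kwargs[field] = typ(float(cell))
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"row {i + 1}, column {field!r}: cannot parse {cell!r}"
                ) from exc
        if "volume" in df.columns and pd.notna(row["volume"]):
            try:
                kwargs["volume"] = float(row["volume"])
            except ValueError as exc:
                raise ParseError(
                    f"row {i + 1}, column 'volume': cannot parse {row['volume']!r}"
                ) from exc
        records.append(DescriptorRecord(**kwargs))
    return DescriptorTable(records, provenance=provenance)


def write_descriptor_csv(table: DescriptorTable, path: str | Path) -> None:
    """Write a descriptor table as CSV (round-trips via read_descriptor_csv)."""
    df = table.to_frame().reset_index()
    cols = [c for c in _CSV_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def write_report(results: Sequence[Mapping], path: str | Path, fmt: str = "csv") -> None:
    """Write per-compound screening/BBB results to ``path``.

    ``results`` is a non-empty sequence of flat mappings (identical keys).
    Column order follows the first record; floats are serialized with 6+
    significant digits. ``fmt`` is ``csv`` or ``json``.
    """
    if not results:
        raise InputError("refusing to write an empty report")
    if fmt not in ("csv", "json"):
        raise FormatError(f"unknown report format: {fmt!r}")
    columns = list(results[0].keys())
    df = pd.DataFrame(list(results))[columns]
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.6g")
    else:
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)


def read_report(path: str | Path, fmt: str = "csv") -> pd.DataFrame:
    if fmt == "csv":
        return pd.read_csv(path)
    with open(path) as fh:
        return pd.DataFrame(json.load(fh))
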