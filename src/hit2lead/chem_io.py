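"""Compound library and assay-table I/O.

Libraries are read from whitespace-separated SMILES files (``smiles id`` per
line, ``#`` comments ignored) or SDF V2000; 3D coordinates are carried only
when the source provides them (SDF).  Activity tables are CSV with columns
``compound_id, ic50_molar, assay``; IC50 values are molar and must be
positive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Compound",
    "ActivityRecord",
    "LibraryParseResult",
    "read_library",
    "write_library",
    "read_activity_table",
    "EmptyLibraryError",
]


class EmptyLibraryError(ValueError):
    """No parseable compound record was found in the input."""


@dataclass
class Compound:
    """A molecule with optional 3D coordinates.

    Parameters
    ----------
    id : str
        Unique identifier within a library.
    smiles : str
        SMILES string; must parse with RDKit.
    conformer : list of (element, x, y, z) or None
        Heavy-atom (plus any explicit-H) coordinates in Angstrom, in the
        atom order of the molecular graph.
    props : dict
        Free-form string properties (e.g. SDF tags).
    """

    id: str
    smiles: str
    conformer: list[tuple[str, float, float, float]] | None = None
    props: dict[str, str] = field(default_factory=dict)

    def to_mol(self, with_coords: bool = False) -> Chem.Mol:
        """Parse the SMILES into an RDKit Mol; optionally attach the conformer.

        Coordinates are matched to graph atoms by position: heavy atoms in
        file order.  Raises ``ValueError`` on unparseable SMILES or on a
        conformer whose heavy-atom count disagrees with the graph.
        """
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for compound {self.id!r}: {self.smiles!r}")
        if with_coords:
            if self.conformer is None:
                raise ValueError(f"compound {self.id!r} has no conformer")
            heavy = [(el, x, y, z) for el, x, y, z in self.conformer if el != "H"]
            if len(heavy) != mol.GetNumAtoms():
                raise ValueError(
                    f"compound {self.id!r}: conformer has {len(heavy)} heavy atoms, "
                    f"graph has {mol.GetNumAtoms()}"
                )
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, (_el, x, y, z) in enumerate(heavy):
                conf.SetAtomPosition(i, (float(x), float(y), float(z)))
            mol.AddConformer(conf, assignId=True)
        return mol

    @property
    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_mol())


@dataclass(frozen=True)
class ActivityRecord:
    """One assay measurement: compound id, IC50 in molar, assay tag."""

    compound_id: str
    ic50: float
    assay: str

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValueError(f"ic50 must be > 0, got {self.ic50} for {self.compound_id!r}")


@dataclass
class LibraryParseResult:
    compounds: list[Compound]
    n_skipped: int


def _read_smiles(path: Path) -> LibraryParseResult:
    compounds: list[Compound] = []
    skipped = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        cid = parts[1] if len(parts) > 1 else f"line{lineno}"
        if Chem.MolFromSmiles(smiles) is None:
            skipped += 1
            continue
        compounds.append(Compound(id=cid, smiles=smiles))
    return LibraryParseResult(compounds, skipped)


def _read_sdf(path: Path) -> LibraryParseResult:
    compounds: list[Compound] = []
    skipped = 0
    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        conformer = None
        if mol.GetNumConformers() > 0:
            conf = mol.GetConformer()
            conformer = [
                (atom.GetSymbol(), *map(float, conf.GetAtomPosition(atom.GetIdx())))
                for atom in mol.GetAtoms()
            ]
        props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        compounds.append(
            Compound(id=cid, smiles=Chem.MolToSmiles(mol), conformer=conformer, props=props)
        )
    return LibraryParseResult(compounds, skipped)


def read_library(
    path: str | Path, format: Literal["smiles", "sdf"] | None = None
) -> LibraryParseResult:
    """Read a compound library from a SMILES (.smi) or SDF V2000 file.

    Unparseable records are skipped and counted in ``n_skipped``.  Raises
    :class:`EmptyLibraryError` if no record parses, ``FileNotFoundError``
    if the file is missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "smiles"
    result = _read_smiles(path) if format == "smiles" else _read_sdf(path)
    if not result.compounds:
        raise EmptyLibraryError(f"no parseable records in {path}")
    return result


def write_library(compounds: Iterable[Compound], path: str | Path) -> None:
    """Write compounds as a whitespace-separated SMILES file (no coordinates)."""
    path = Path(path)
    lines = [f"{c.smiles}\t{c.id}" for c in compounds]
    path.write_text("\n".join(lines) + "\n")


def read_activity_table(path: str | Path) -> list[ActivityRecord]:
    """Read a CSV of ``compound_id, ic50_molar, assay`` rows.

    IC50s are molar.  A non-numeric or non-positive IC50 raises ``ValueError``
    naming the offending row.
    """
    path = Path(path)
    records: list[ActivityRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"compound_id", "ic50_molar", "assay"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"expected columns {sorted(required)}, got {reader.fieldnames}")
        for rowno, row in enumerate(reader, start=2):
            try:
                ic50 = float(row["ic50_molar"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"row {rowno}: non-numeric ic50 {row['ic50_molar']!r}") from exc
            if not ic50 > 0:
                raise ValueError(f"row {rowno}: ic50 must be > 0, got {ic50}")
            records.append(ActivityRecord(row["compound_id"], ic50, row["assay"]))
    return records
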