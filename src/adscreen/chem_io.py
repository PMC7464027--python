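"""Molecule model, parsing, canonicalization and file I/O.

All structure handling is delegated to RDKit. Aromaticity is perceived with
RDKit's default (RDKit aromaticity model) everywhere in the package, because
every descriptor downstream depends on a single consistent perception model.
Hydrogens are kept implicit on the graph; descriptor code that needs them
(element entropy, Gasteiger hydrogen charges) queries implicit H counts
explicitly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty on stderr for every parse failure; we report through
# logging + exceptions instead.
RDLogger.DisableLog("rdApp.error")


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the input id."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A molecule with a stable identifier and canonical SMILES.

    Attributes
    ----------
    id : str
        Caller-supplied identifier, preserved through I/O round trips.
    smiles : str
        RDKit canonical SMILES (aromatic form).
    mol : rdkit.Chem.Mol
        The sanitized molecular graph (implicit hydrogens).
    """

    id: str
    smiles: str
    mol: Chem.Mol = field(compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.mol.GetNumAtoms() == 0:
            raise MoleculeParseError(f"{self.id!r}: molecule has no atoms")


def parse_molecule(text: str, id: str) -> MoleculeRecord:
    """Parse a SMILES string into a :class:`MoleculeRecord`.

    The stored SMILES is the RDKit canonical form, so any two SMILES spellings
    of the same molecule produce identical records.

    Raises
    ------
    MoleculeParseError
        If the SMILES is malformed; the message names ``id``.
    """
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise MoleculeParseError(f"cannot parse SMILES for input {id!r}: {text!r}")
    return MoleculeRecord(id=id, smiles=Chem.MolToSmiles(mol), mol=mol)


def from_mol(mol: Chem.Mol, id: str) -> MoleculeRecord:
    """Wrap an already-built RDKit molecule, re-canonicalizing through SMILES."""
    smiles = Chem.MolToSmiles(mol)
    parsed = Chem.MolFromSmiles(smiles)
    if parsed is None:
        raise MoleculeParseError(f"molecule {id!r} does not survive canonical round trip")
    return MoleculeRecord(id=id, smiles=Chem.MolToSmiles(parsed), mol=parsed)


def read_molecule_table(path: str | Path) -> list[MoleculeRecord]:
    """Read molecules from a CSV (columns ``id``, ``smiles``) or SMILES file.

    A ``.csv`` extension selects the CSV dialect (comma separated, header row,
    UTF-8). Any other extension is read as a SMILES file: one molecule per
    line, ``SMILES[ whitespace ID]``. Rows that fail to parse are logged as
    warnings and skipped — never silently dropped without a log record.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If no row parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"molecule table not found: {path}")

    rows: list[tuple[str, str]] = []  # (id, smiles)
    if path.suffix.lower() == ".csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise ValueError(f"{path}: CSV must have a header with a 'smiles' column")
            for i, row in enumerate(reader):
                rows.append((row.get("id") or f"row{i + 1}", row["smiles"]))
    else:
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                rows.append((parts[1].strip() if len(parts) > 1 else f"line{i + 1}", parts[0]))

    records: list[MoleculeRecord] = []
    failures = 0
    for rid, smiles in rows:
        try:
            records.append(parse_molecule(smiles, rid))
        except MoleculeParseError as exc:
            failures += 1
            logger.warning("skipping unparsable row: %s", exc)
    if not records:
        raise ValueError(f"{path}: no parsable molecules ({failures} failures)")
    return records


def write_molecule_table(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write records as a two-column CSV (id, smiles)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles"])
        for rec in records:
            writer.writerow([rec.id, rec.smiles])


def write_sdf(
    records: Sequence[MoleculeRecord],
    props: Mapping[str, Mapping[str, object]] | None,
    path: str | Path,
) -> None:
    """Write molecules to an SDF (V2000) with one property tag per named value.

    ``props`` maps molecule id -> {property name -> value}. An empty record
    list yields an empty but valid file.
    """
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.Mol(rec.mol)
            mol.SetProp("_Name", rec.id)
            mol.SetProp("id", rec.id)
            for key, value in (props or {}).get(rec.id, {}).items():
                mol.SetProp(str(key), str(value))
            writer.write(mol)
    finally:
        writer.close()


def read_sdf(path: str | Path) -> tuple[list[MoleculeRecord], dict[str, dict[str, str]]]:
    """Read an SDF written by :func:`write_sdf`; returns (records, props)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SDF not found: {path}")
    records: list[MoleculeRecord] = []
    props: dict[str, dict[str, str]] = {}
    if path.stat().st_size == 0:  # SDMolSupplier rejects an empty file
        return records, props
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            logger.warning("skipping unreadable SDF record %d in %s", i, path)
            continue
        rid = mol.GetProp("id") if mol.HasProp("id") else (mol.GetProp("_Name") or f"sdf{i}")
        records.append(from_mol(mol, rid))
        props[rid] = {
            k: mol.GetProp(k) for k in mol.GetPropNames() if k not in ("id",)
        }
    return records, props
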