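"""Combinatorial scaffold x R-group library enumeration.

A scaffold carries marked attachment points ("ports"), written in SMILES as
atom-mapped dummy atoms ``[*:k]`` bonded to exactly one real atom by a single
bond. An R-group carries exactly one port. A product is built by fusing an
R-group port to a scaffold port (both dummies removed, their neighbours
bonded) or by capping an unused scaffold port with hydrogen.

Enumeration cycles exhaustively through all R-group combinations over all
port subsets of size ``min_substituents``..n, so the number of products of a
single scaffold with n ports and r R-groups (before any symmetry collapse)
is sum_{k=min..n} C(n,k) * r^k, which for min=1 is (1+r)^n - 1.

Enumeration order is deterministic: scaffolds in input order, port subsets in
lexicographic order of the sorted port labels, R-groups in input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb
from typing import Iterator, Mapping, Sequence

from rdkit import Chem

from .chem_io import MoleculeRecord, from_mol

logger = logging.getLogger(__name__)

#: Sentinel assignment meaning "cap this port with hydrogen".
HYDROGEN = "H"


class PortError(ValueError):
    """Raised for malformed port structure or an illegal attachment."""


def _find_ports(mol: Chem.Mol) -> dict[int, int]:
    """Map port label (atom map number of a dummy atom) -> dummy atom index."""
    ports: dict[int, int] = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            label = atom.GetAtomMapNum()
            if label == 0:
                raise PortError("dummy atom without an atom-map port label")
            if label in ports:
                raise PortError(f"duplicate port label {label}")
            if atom.GetDegree() != 1:
                raise PortError(f"port {label} must bond exactly one real atom")
            bond = atom.GetBonds()[0]
            if bond.GetBondType() != Chem.BondType.SINGLE:
                raise PortError(f"port {label} must attach via a single bond")
            ports[label] = atom.GetIdx()
    return ports


@dataclass(frozen=True)
class ScaffoldSpec:
    """A core structure with n >= 0 labelled attachment ports."""

    id: str
    smiles: str
    mol: Chem.Mol = field(init=False, compare=False, repr=False)
    ports: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise PortError(f"scaffold {self.id!r}: cannot parse {self.smiles!r}")
        object.__setattr__(self, "mol", mol)
        object.__setattr__(self, "ports", tuple(sorted(_find_ports(mol))))


@dataclass(frozen=True)
class RGroupSpec:
    """A substituent fragment with exactly one port."""

    id: str
    smiles: str
    mol: Chem.Mol = field(init=False, compare=False, repr=False)
    port: int = field(init=False)

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise PortError(f"R-group {self.id!r}: cannot parse {self.smiles!r}")
        ports = _find_ports(mol)
        if len(ports) != 1:
            raise PortError(f"R-group {self.id!r} must have exactly 1 port, found {len(ports)}")
        object.__setattr__(self, "mol", mol)
        object.__setattr__(self, "port", next(iter(ports)))


@dataclass
class LibrarySpec:
    """Full enumeration request: scaffolds x R-groups with a substituent floor."""

    scaffolds: Sequence[ScaffoldSpec]
    rgroups: Sequence[RGroupSpec]
    min_substituents: int = 1
    deduplicate: bool = False

    def __post_init__(self) -> None:
        if self.min_substituents < 0:
            raise ValueError("min_substituents must be >= 0")


def attach(
    scaffold: ScaffoldSpec,
    assignment: Mapping[int, "RGroupSpec | str"],
    id: str | None = None,
) -> MoleculeRecord:
    """Build one product by resolving every scaffold port.

    ``assignment`` maps each port label either to an :class:`RGroupSpec` or to
    the sentinel :data:`HYDROGEN`. Fusion uses RDKit ``molzip`` on matched
    dummy-atom map labels; H-capped ports are deleted so the valence is filled
    implicitly.

    Raises
    ------
    PortError
        If a port is missing from the assignment or the fused product fails
        valence sanitization; the message names scaffold, port and R-group.
    """
    missing = set(scaffold.ports) - set(assignment)
    if missing:
        raise PortError(f"scaffold {scaffold.id!r}: unassigned ports {sorted(missing)}")

    # H-capped ports are deleted up front so molzip only ever sees matched
    # label pairs; the freed valences fill with implicit hydrogens.
    core = Chem.RWMol(scaffold.mol)
    h_ports = {p for p in scaffold.ports if assignment[p] == HYDROGEN}
    for idx in sorted(
        (a.GetIdx() for a in core.GetAtoms()
         if a.GetAtomicNum() == 0 and a.GetAtomMapNum() in h_ports),
        reverse=True,
    ):
        core.RemoveAtom(idx)

    pieces: list[Chem.Mol] = [core.GetMol()]
    # Relabel each R-group's single port to the scaffold port it joins so
    # molzip pairs them; labels are unique per product by construction.
    for label in scaffold.ports:
        rg = assignment[label]
        if rg == HYDROGEN:
            continue
        assert isinstance(rg, RGroupSpec)
        frag = Chem.Mol(rg.mol)
        for atom in frag.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomMapNum(label)
        pieces.append(frag)

    combined = pieces[0]
    for frag in pieces[1:]:
        combined = Chem.CombineMols(combined, frag)

    try:
        zipped = Chem.molzip(combined) if len(pieces) > 1 else combined
        Chem.SanitizeMol(zipped)
    except Exception as exc:  # RDKit raises several exception types here
        detail = {k: (v if isinstance(v, str) else v.id) for k, v in assignment.items()}
        raise PortError(
            f"cannot assemble product on scaffold {scaffold.id!r} with {detail}: {exc}"
        ) from exc

    if id is None:
        parts = [scaffold.id] + [
            f"{label}:{assignment[label] if assignment[label] == HYDROGEN else assignment[label].id}"
            for label in scaffold.ports
            if assignment[label] != HYDROGEN
        ]
        id = "|".join(parts) if len(parts) > 1 else f"{scaffold.id}|parent"
    return from_mol(zipped, id)


def raw_count(n_ports: int, n_rgroups: int, min_substituents: int = 1) -> int:
    """Closed-form product count: sum_{k=min..n} C(n,k) * r^k, no enumeration."""
    if min(n_ports, n_rgroups, min_substituents) < 0:
        raise ValueError("arguments must be >= 0")
    return sum(
        comb(n_ports, k) * n_rgroups**k
        for k in range(min_substituents, n_ports + 1)
    )


def enumerate_library(
    spec: LibrarySpec, strict: bool = False
) -> Iterator[MoleculeRecord]:
    """Stream every combinatorial product of the library spec.

    Yields products lazily so arbitrarily large libraries never need to be
    held in memory. With ``deduplicate`` only the first occurrence of each
    canonical SMILES is yielded. A failing combination is logged and skipped
    unless ``strict``, in which case it aborts the stream.
    """
    seen: set[str] = set()
    for scaffold in spec.scaffolds:
        ports = scaffold.ports
        for k in range(spec.min_substituents, len(ports) + 1):
            for subset in combinations(ports, k):
                for combo in product(spec.rgroups, repeat=k):
                    assignment: dict[int, RGroupSpec | str] = {p: HYDROGEN for p in ports}
                    assignment.update(dict(zip(subset, combo)))
                    try:
                        rec = attach(scaffold, assignment)
                    except PortError as exc:
                        if strict:
                            raise
                        logger.warning("skipping combination: %s", exc)
                        continue
                    if spec.deduplicate:
                        if rec.smiles in seen:
                            continue
                        seen.add(rec.smiles)
                    yield rec


def load_fragment_csv(path, kind: str = "scaffold"):
    """Load ScaffoldSpec/RGroupSpec rows from a CSV with columns id, smiles."""
    import csv as _csv
    from pathlib import Path as _Path

    cls = ScaffoldSpec if kind == "scaffold" else RGroupSpec
    out = []
    with _Path(path).open(newline="", encoding="utf-8") as fh:
        for row in _csv.DictReader(fh):
            out.append(cls(id=row["id"], smiles=row["smiles"]))
    return out
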