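"""2D molecular descriptors for the QSAR models and drug-likeness filters.

The per-atom primitives — PEOE (Gasteiger) partial charges, Wildman–Crippen
atomic logP and molar-refractivity contributions, and Labute's
connectivity-based approximate accessible van der Waals surface areas — are
taken from RDKit.  Everything built on top of them is implemented here:

* subdivided ("binned") surface-area descriptors ``PEOE_VSA±k``,
  ``SlogP_VSAk``, ``SMR_VSAk`` with the bin tables shipped in
  ``data/vsa_bins.yaml``;
* Burden-matrix eigenvalue (BCUT) descriptors with a chosen atomic property
  on the diagonal;
* the petitjean topological shape index, the element-distribution entropy
  ``a_ICM``, simple counts, a reactive-substructure flag driven by a SMARTS
  data file, and a linear aqueous-solubility estimate ``logS``.

Descriptor names follow the conventional spellings used with these models
(``PEOE_VSA-3``, ``BCUT_SLOGP_3``, ``a_Nn``, ...); an alias table maps
variant spellings onto one canonical key.
"""

from __future__ import annotations

import math
from functools import lru_cache
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors, rdPartialCharges

from .chem_io import MoleculeRecord

__all__ = [
    "DescriptorVector",
    "peoe_charges",
    "crippen_contributions",
    "vsa_areas",
    "binned_vsa",
    "bcut",
    "petitjean",
    "a_icm",
    "simple_counts",
    "reactive_flag",
    "log_s",
    "descriptor_vector",
    "molecular_properties",
    "supported_descriptors",
    "canonical_name",
]

DescriptorVector = dict[str, float]


class DescriptorError(ValueError):
    """Raised for unknown descriptor names or uncomputable inputs."""


def _mol(m: "MoleculeRecord | Chem.Mol") -> Chem.Mol:
    return m.mol if isinstance(m, MoleculeRecord) else m


# ---------------------------------------------------------------------------
# per-atom primitives

def peoe_charges(m: "MoleculeRecord | Chem.Mol", include_h: bool = False) -> np.ndarray:
    """Gasteiger PEOE partial charges per heavy atom.

    With ``include_h`` each heavy atom's charge additionally absorbs the
    charges of its implicit hydrogens, so the vector sums to the molecule's
    total formal charge.  The plain per-heavy-atom charges (hydrogens kept
    separate) are what the binned VSA descriptors consume.
    """
    mol = Chem.Mol(_mol(m))
    try:
        rdPartialCharges.ComputeGasteigerCharges(mol, throwOnParamFailure=True)
    except Exception as exc:
        raise DescriptorError(f"PEOE charges unavailable: {exc}") from exc
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
    if include_h:
        q = q + np.array([a.GetDoubleProp("_GasteigerHCharge") for a in mol.GetAtoms()])
    if not np.all(np.isfinite(q)):
        raise DescriptorError("non-finite PEOE charge (missing electronegativity parameters?)")
    return q


def crippen_contributions(
    m: "MoleculeRecord | Chem.Mol", include_h: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Wildman–Crippen per-heavy-atom (logP, MR) contributions.

    The plain heavy-atom contributions (hydrogen atom types kept separate,
    as the subdivided-surface-area bin tables assume) are the default.  With
    ``include_h`` each hydrogen's contribution is folded into its heavy
    atom, so the columns sum exactly to the molecular logP and molar
    refractivity.
    """
    mol = _mol(m)
    if mol.GetNumAtoms() == 0:
        raise DescriptorError("no atoms to type")
    if not include_h:
        arr = np.array(rdMolDescriptors._CalcCrippenContribs(mol), dtype=float)
        return arr[:, 0], arr[:, 1]
    molh = Chem.AddHs(mol)
    arr = np.array(rdMolDescriptors._CalcCrippenContribs(molh), dtype=float)
    n_heavy = mol.GetNumAtoms()
    logp, mr = arr[:, 0].copy(), arr[:, 1].copy()
    for atom in molh.GetAtoms():
        if atom.GetAtomicNum() == 1:
            heavy = atom.GetNeighbors()[0].GetIdx()
            logp[heavy] += logp[atom.GetIdx()]
            mr[heavy] += mr[atom.GetIdx()]
    return logp[:n_heavy], mr[:n_heavy]


def vsa_areas(m: "MoleculeRecord | Chem.Mol") -> np.ndarray:
    """Labute approximate accessible van der Waals surface area per heavy atom (A^2)."""
    contribs, _h = rdMolDescriptors._CalcLabuteASAContribs(_mol(m))
    return np.array(list(contribs), dtype=float)


# ---------------------------------------------------------------------------
# binned (subdivided) surface areas

@lru_cache(maxsize=1)
def _bin_config() -> dict:
    text = resources.files("adscreen.data").joinpath("vsa_bins.yaml").read_text()
    return yaml.safe_load(text)


def _peoe_bin_interval(bin_id: str) -> tuple[float, float]:
    cfg = _bin_config()["peoe"]
    width, max_bin = float(cfg["width"]), int(cfg["max_bin"])
    sign, k = bin_id[0], int(bin_id[1:])
    if sign not in "+-" or not 0 <= k <= max_bin:
        raise DescriptorError(f"unknown PEOE_VSA bin {bin_id!r}")
    if sign == "+":
        return (width * k, math.inf if k == max_bin else width * (k + 1))
    return (-math.inf if k == max_bin else -width * (k + 1), -width * k)


def _boundary_bin_interval(family: str, k: int) -> tuple[float, float]:
    bounds = [float(b) for b in _bin_config()[family]["boundaries"]]
    if not 0 <= k <= len(bounds):
        raise DescriptorError(f"unknown {family} bin {k} (0..{len(bounds)})")
    lo = -math.inf if k == 0 else bounds[k - 1]
    hi = math.inf if k == len(bounds) else bounds[k]
    return lo, hi


def binned_vsa(m: "MoleculeRecord | Chem.Mol", property: str, bin_id: "str | int") -> float:
    """Sum of per-atom VSA over atoms whose property lies in the bin.

    ``property`` is one of ``peoe_charge`` (bin ids ``'+0'..'+6'``,
    ``'-0'..'-6'``), ``slogp`` or ``smr`` (integer bin ids).  Every bin is
    the half-open interval [lo, hi), so the bins of one family partition the
    real line and their VSA sums add up to the total surface area exactly.
    """
    mol = _mol(m)
    areas = vsa_areas(mol)
    if property == "peoe_charge":
        values = peoe_charges(mol)
        lo, hi = _peoe_bin_interval(str(bin_id))
    elif property in ("slogp", "smr"):
        logp, mr = crippen_contributions(mol)
        values = logp if property == "slogp" else mr
        lo, hi = _boundary_bin_interval(property, int(bin_id))
    else:
        raise DescriptorError(f"unknown VSA property {property!r}")
    mask = (values >= lo) & (values < hi)
    return float(areas[mask].sum())


# ---------------------------------------------------------------------------
# Burden-matrix eigenvalue descriptors

def _burden_matrix(mol: Chem.Mol, diag: np.ndarray) -> np.ndarray:
    """Symmetric Burden connectivity matrix with an atomic property diagonal.

    Off-diagonal entries are 0.1 x (conventional bond order, aromatic = 1.5)
    for bonded pairs, +0.01 if either end is terminal, and 0.001 for
    non-bonded pairs — Burden's original weighting.
    """
    n = mol.GetNumAtoms()
    B = np.full((n, n), 0.001)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        w = 0.1 * bond.GetBondTypeAsDouble()
        if bond.GetBeginAtom().GetDegree() == 1 or bond.GetEndAtom().GetDegree() == 1:
            w += 0.01
        B[i, j] = B[j, i] = w
    np.fill_diagonal(B, diag)
    return B


def bcut(m: "MoleculeRecord | Chem.Mol", property: str, index: int) -> float:
    """BCUT descriptor: a pick from the Burden-matrix eigenvalue spectrum.

    ``property`` selects the diagonal: ``slogp`` (Wildman–Crippen atomic
    logP) or ``peoe_charge`` (Gasteiger charge).  ``index`` in 0..3 selects
    four quartile positions of the ascending eigenvalue spectrum: 0 = lowest
    eigenvalue, 3 = highest, 1 and 2 the interior tertile positions.
    """
    if not 0 <= index <= 3:
        raise DescriptorError("BCUT index must be in 0..3")
    mol = _mol(m)
    if mol.GetNumAtoms() < 1:
        raise DescriptorError("BCUT needs at least one heavy atom")
    if property == "slogp":
        diag, _ = crippen_contributions(mol)
    elif property == "peoe_charge":
        diag = peoe_charges(mol)
    else:
        raise DescriptorError(f"unknown BCUT property {property!r}")
    eig = np.linalg.eigvalsh(_burden_matrix(mol, np.asarray(diag)))
    pos = round(index * (len(eig) - 1) / 3)
    return float(eig[pos])


# ---------------------------------------------------------------------------
# topology, entropy, counts

def petitjean(m: "MoleculeRecord | Chem.Mol") -> float:
    """Topological shape index (diameter - radius) / diameter in [0, 0.5].

    Eccentricities are graph distances over the heavy-atom skeleton.
    Raises on a single-atom or disconnected graph, where diameter or the
    distance matrix is degenerate.
    """
    mol = _mol(m)
    n = mol.GetNumAtoms()
    if n < 2:
        raise DescriptorError("petitjean undefined for a single-atom graph")
    dmat = Chem.GetDistanceMatrix(mol)
    if not np.all(np.isfinite(dmat)) or np.any(dmat > 1e7):
        raise DescriptorError("petitjean undefined for a disconnected graph")
    ecc = dmat.max(axis=1)
    diameter, radius = float(ecc.max()), float(ecc.min())
    return (diameter - radius) / diameter


def a_icm(m: "MoleculeRecord | Chem.Mol") -> float:
    """Shannon entropy (bits) of the element distribution, implicit H included."""
    mol = _mol(m)
    counts: dict[int, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetAtomicNum()] = counts.get(atom.GetAtomicNum(), 0) + 1
        nh = atom.GetTotalNumHs()
        if nh:
            counts[1] = counts.get(1, 0) + nh
    total = sum(counts.values())
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def simple_counts(m: "MoleculeRecord | Chem.Mol") -> dict[str, float]:
    """Count/property panel used by the models and the drug-likeness rules.

    ``chiral_u`` counts stereocenters whose configuration is unassigned;
    ``rings`` is the SSSR count; hydrogen-bond donors/acceptors use the
    classic N+O counting (donors = N-H and O-H groups, acceptors = N + O
    atoms).
    """
    mol = _mol(m)
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    return {
        "chiral_u": float(sum(1 for _idx, tag in centers if tag == "?")),
        "rings": float(rdMolDescriptors.CalcNumRings(mol)),
        "a_Nn": float(sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7)),
        "heavy_atoms": float(mol.GetNumHeavyAtoms()),
        "atoms": float(mol.GetNumHeavyAtoms() + sum(a.GetTotalNumHs() for a in mol.GetAtoms())),
        "carbons": float(sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)),
        "heteroatoms": float(rdMolDescriptors.CalcNumHeteroatoms(mol)),
        "HBD": float(Lipinski.NHOHCount(mol)),
        "HBA": float(Lipinski.NOCount(mol)),
        "RotB": float(Lipinski.NumRotatableBonds(mol)),
        "MW": float(Descriptors.MolWt(mol)),
        "TPSA": float(rdMolDescriptors.CalcTPSA(mol)),
    }


@lru_cache(maxsize=1)
def _reactive_patterns() -> list[tuple[str, Chem.Mol]]:
    text = resources.files("adscreen.data").joinpath("reactive.smarts").read_text()
    patterns = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            name, smarts = line.split("\t")
        except ValueError as exc:
            raise DescriptorError(f"malformed reactive pattern line: {line!r}") from exc
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise DescriptorError(f"unparsable reactive SMARTS for {name!r}: {smarts!r}")
        patterns.append((name, query))
    return patterns


def reactive_flag(m: "MoleculeRecord | Chem.Mol") -> int:
    """1 if any shipped reactive-substructure alert matches, else 0."""
    return int(bool(reactive_matches(m)))


def reactive_matches(m: "MoleculeRecord | Chem.Mol") -> list[str]:
    """Names of the reactive-alert categories that match the molecule."""
    mol = _mol(m)
    return [name for name, query in _reactive_patterns() if mol.HasSubstructMatch(query)]


def log_s(m: "MoleculeRecord | Chem.Mol") -> float:
    """Estimated log10 aqueous solubility (mol/L).

    Delaney's ESOL linear model: logS = 0.16 - 0.63 clogP - 0.0062 MW
    + 0.066 RB - 0.74 AP, with AP the aromatic-heavy-atom proportion and
    clogP the Crippen logP.  A linear estimate is sufficient here because
    only the ordering and rough scale of solubility feed the models.
    """
    mol = _mol(m)
    logp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    rb = Lipinski.NumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    ap = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / heavy if heavy else 0.0
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


# ---------------------------------------------------------------------------
# the named-descriptor registry

_ALIASES = {
    "a_nn": "a_Nn",
    "a_icm": "a_ICM",
    "bcut_slogp_3": "BCUT_SLOGP_3",
    "bcut_peoe_1": "BCUT_PEOE_1",
    "logp": "SlogP",
    "slogp": "SlogP",
    "mr": "SMR",
    "smr": "SMR",
    "logs": "logS",
    "b_rotn": "RotB",
    "rotb": "RotB",
    "weight": "MW",
    "mw": "MW",
    "tpsa": "TPSA",
    "hbd": "HBD",
    "hba": "HBA",
}

_COUNT_KEYS = (
    "chiral_u", "rings", "a_Nn", "heavy_atoms", "atoms", "carbons",
    "heteroatoms", "HBD", "HBA", "RotB", "MW", "TPSA",
)


def _registry() -> dict[str, Callable[[Chem.Mol], float]]:
    reg: dict[str, Callable[[Chem.Mol], float]] = {}
    for prop, prefix in (("peoe_charge", "PEOE_VSA"), ("slogp", "SlogP_VSA"), ("smr", "SMR_VSA")):
        if prop == "peoe_charge":
            for sign in "+-":
                for k in range(7):
                    reg[f"{prefix}{sign}{k}"] = (
                        lambda m, p=prop, b=f"{sign}{k}": binned_vsa(m, p, b)
                    )
        else:
            nbins = len(_bin_config()[prop]["boundaries"]) + 1
            for k in range(nbins):
                reg[f"{prefix}{k}"] = lambda m, p=prop, b=k: binned_vsa(m, p, b)
    for i in range(4):
        reg[f"BCUT_SLOGP_{i}"] = lambda m, i=i: bcut(m, "slogp", i)
        reg[f"BCUT_PEOE_{i}"] = lambda m, i=i: bcut(m, "peoe_charge", i)
    reg["petitjean"] = petitjean
    reg["a_ICM"] = a_icm
    reg["reactive"] = lambda m: float(reactive_flag(m))
    reg["logS"] = log_s
    reg["SlogP"] = lambda m: float(Crippen.MolLogP(_mol(m)))
    reg["SMR"] = lambda m: float(Crippen.MolMR(_mol(m)))
    reg["VSA_total"] = lambda m: float(vsa_areas(m).sum())
    for key in _COUNT_KEYS:
        reg[key] = lambda m, k=key: simple_counts(m)[k]
    return reg


@lru_cache(maxsize=1)
def _cached_registry() -> dict[str, Callable]:
    return _registry()


def canonical_name(name: str) -> str:
    """Resolve spelling variants (case, a_nN vs a_Nn, ...) to the canonical key."""
    reg = _cached_registry()
    if name in reg:
        return name
    alias = _ALIASES.get(name.lower())
    if alias and alias in reg:
        return alias
    lowered = {k.lower(): k for k in reg}
    if name.lower() in lowered:
        return lowered[name.lower()]
    raise DescriptorError(
        f"unknown descriptor {name!r}; supported: {', '.join(sorted(reg))}"
    )


def supported_descriptors() -> list[str]:
    return sorted(_cached_registry())


def descriptor_vector(m: "MoleculeRecord | Chem.Mol", names: Sequence[str]) -> DescriptorVector:
    """Compute the requested descriptors; every requested name is present.

    An unknown name raises immediately (listing the supported names) and a
    non-finite value raises rather than being passed through as a silent 0.
    """
    reg = _cached_registry()
    out: DescriptorVector = {}
    for name in names:
        value = float(reg[canonical_name(name)](m))
        if not math.isfinite(value):
            raise DescriptorError(f"descriptor {name} is non-finite")
        out[name] = value
    return out


def molecular_properties(m: "MoleculeRecord | Chem.Mol") -> dict[str, float]:
    """The property panel the drug-likeness filters consume."""
    props = simple_counts(m)
    props["logP"] = float(Crippen.MolLogP(_mol(m)))
    props["MR"] = float(Crippen.MolMR(_mol(m)))
    return props


def descriptor_table(
    records: Iterable[MoleculeRecord], names: Sequence[str]
):
    """DataFrame of descriptors: one molecule per row, one descriptor per column."""
    import pandas as pd

    rows = {rec.id: descriptor_vector(rec, names) for rec in records}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(names))
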