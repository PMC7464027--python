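"""Deterministic synthetic inputs for every stage of the pipeline.

Three generator families, all seedable and free of global RNG state:

* molecule fixtures — substituted aromatics enumerated from three stand-in
  scaffolds (chalcone-like, flavone-like, curcumin-like; NOT the published
  core structures, which are figure-only) with the 23 classical R-groups,
  spanning charged, chiral, multi-ring and reactive chemistry;
* regression datasets y = intercept + X beta + N(0, sd) with the ground
  truth carried alongside, standing in for curated inhibitor training sets;
* screening scenarios that simulate an active/decoy screen with chosen
  sensitivity/specificity and return the (D, A, Ht, Ha) count quadruple.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem_io import MoleculeRecord
from .combigen import LibrarySpec, RGroupSpec, ScaffoldSpec, enumerate_library

__all__ = [
    "TABLE_RGROUPS",
    "STANDIN_SCAFFOLDS",
    "RegressionScenario",
    "ScreeningScenario",
    "make_molecule_fixtures",
    "make_regression",
    "make_screening",
]

#: The 23 classical substituents used for combinatorial decoration
#: (hydroxy through benzyloxy), written with a single [*:1] port.
TABLE_RGROUPS: tuple[tuple[str, str], ...] = (
    ("OH", "[*:1]O"),
    ("OMe", "[*:1]OC"),
    ("OEt", "[*:1]OCC"),
    ("OAc", "[*:1]OC(C)=O"),
    ("F", "[*:1]F"),
    ("Cl", "[*:1]Cl"),
    ("Br", "[*:1]Br"),
    ("I", "[*:1]I"),
    ("NO2", "[*:1][N+](=O)[O-]"),
    ("NH2", "[*:1]N"),
    ("NMe2", "[*:1]N(C)C"),
    ("NHAc", "[*:1]NC(C)=O"),
    ("allyl", "[*:1]CC=C"),
    ("COOH", "[*:1]C(=O)O"),
    ("COOMe", "[*:1]C(=O)OC"),
    ("COOEt", "[*:1]C(=O)OCC"),
    ("CN", "[*:1]C#N"),
    ("CONH2", "[*:1]C(N)=O"),
    ("SO2NH2", "[*:1]S(N)(=O)=O"),
    ("SH", "[*:1]S"),
    ("SMe", "[*:1]SC"),
    ("SEt", "[*:1]SCC"),
    ("OBn", "[*:1]OCc1ccccc1"),
)

#: Synthetic stand-in scaffolds with two ports each.  These are plausible
#: chalcone/flavone/curcuminoid cores chosen for test coverage; they are
#: not any published scaffold set.
STANDIN_SCAFFOLDS: tuple[tuple[str, str], ...] = (
    ("chalcone_standin", "O=C(/C=C/c1ccc([*:2])cc1)c1ccc([*:1])cc1"),
    ("flavone_standin", "O=c1cc(-c2ccc([*:2])cc2)oc2ccc([*:1])cc12"),
    ("curcumin_standin", "COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1[*:1]"),
    ("chroman_standin", "O[C@H]1CC(=O)c2ccc([*:1])cc2O1"),
)


def table_rgroup_specs() -> list[RGroupSpec]:
    return [RGroupSpec(name, smi) for name, smi in TABLE_RGROUPS]


def standin_scaffold_specs() -> list[ScaffoldSpec]:
    return [ScaffoldSpec(name, smi) for name, smi in STANDIN_SCAFFOLDS]


#: Hand-picked audit molecules guaranteeing every reactive-alert category
#: appears in the fixture panel even though the R-group table alone cannot
#: produce, e.g., a metal or an azide.
_REACTIVE_AUDIT: tuple[tuple[str, str], ...] = (
    ("audit_metal", "CC[Al](CC)CC"),
    ("audit_phospho", "CCOP(=O)(OCC)OCC"),
    ("audit_het_het", "NNc1ccccc1"),
    ("audit_thiol", "CCS"),
    ("audit_acyl_halide", "CC(=O)Cl"),
    ("audit_michael", "C=CC(C)=O"),
    ("audit_azide", "CCN=[N+]=[N-]"),
    ("audit_ester", "CC(=O)OCC"),
)


def make_molecule_fixtures(seed: int = 0, n: int = 100) -> list[MoleculeRecord]:
    """A deterministic fixture panel of ~``n`` substituted aromatics.

    Products are enumerated from the stand-in scaffolds with the full
    R-group table (single substitutions exhaustively, so every functional
    group class appears), then thinned to ``n`` by a seeded choice that
    always keeps one representative per R-group.  The panel exercises all
    descriptor code paths: charged bins (nitro, sulfonamide), unassigned
    stereocenters (chroman core), fused rings, thiols/esters/enones for the
    reactive alerts.
    """
    from itertools import islice

    rgroups = table_rgroup_specs()
    singles: list[MoleculeRecord] = []
    seen: set[str] = set()
    # Single substitutions lead each scaffold's stream (port-subset size
    # ascends), so islice(n_ports * n_rgroups) takes exactly the k=1 layer
    # of every scaffold and the enumeration stays bounded.
    for scaffold in standin_scaffold_specs():
        layer = len(scaffold.ports) * len(rgroups)
        for rec in islice(
            enumerate_library(LibrarySpec([scaffold], rgroups, 1, False)), layer
        ):
            if rec.smiles not in seen:
                seen.add(rec.smiles)
                singles.append(rec)
    # one representative per R-group first (they lead the stream), then a
    # seeded subsample of the rest
    rng = np.random.default_rng(seed)
    n_rgroups = len(rgroups)
    head = singles[:n_rgroups]
    tail = singles[n_rgroups:]
    from .chem_io import parse_molecule

    audit = [parse_molecule(smi, name) for name, smi in _REACTIVE_AUDIT]
    budget = max(n - len(head) - len(audit), 0)
    if len(tail) > budget:
        keep = rng.choice(len(tail), size=budget, replace=False)
        tail = [tail[i] for i in sorted(keep)]
    return head + tail + audit


@dataclass(frozen=True)
class RegressionScenario:
    """Ground-truth linear regression setup standing in for a QSAR dataset.

    Defaults mirror a mid-sized curated inhibitor series: 150 training and
    65 validation compounds over 11 descriptors with residual noise of
    0.4 pIC50 units — the scale of inter-laboratory IC50 reproducibility.
    """

    n_train: int = 150
    n_val: int = 65
    p: int = 11
    beta: tuple[float, ...] | None = None
    intercept: float = 1.0
    noise_sd: float = 0.4
    seed: int = 0

    def coefficients(self) -> np.ndarray:
        if self.beta is not None:
            if len(self.beta) != self.p:
                raise ValueError("beta length must equal p")
            return np.asarray(self.beta, dtype=float)
        rng = np.random.default_rng(self.seed + 1)
        return rng.normal(0.0, 1.0, size=self.p)


def make_regression(
    scenario: RegressionScenario,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict]:
    """Generate (X_train, y_train, X_val, y_val, truth) for the scenario."""
    if scenario.n_train <= scenario.p:
        raise ValueError("need n_train > p for an identifiable fit")
    rng = np.random.default_rng(scenario.seed)
    beta = scenario.coefficients()
    X_train = rng.normal(size=(scenario.n_train, scenario.p))
    X_val = rng.normal(size=(scenario.n_val, scenario.p))
    y_train = (
        scenario.intercept
        + X_train @ beta
        + rng.normal(0.0, scenario.noise_sd, size=scenario.n_train)
    )
    y_val = (
        scenario.intercept
        + X_val @ beta
        + rng.normal(0.0, scenario.noise_sd, size=scenario.n_val)
    )
    truth = {"beta": beta, "intercept": scenario.intercept, "noise_sd": scenario.noise_sd}
    return X_train, y_train, X_val, y_val, truth


@dataclass(frozen=True)
class ScreeningScenario:
    """Active/decoy screen simulation with chosen retrieval rates.

    Defaults use a database of the scale of a processed decoy-library
    screen: ~27k molecules with ~650 actives and a query of 80%
    sensitivity / 98.5% specificity.
    """

    D: int = 27024
    A: int = 655
    sensitivity: float = 0.8
    specificity: float = 0.985
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1 and 0 <= self.specificity <= 1):
            raise ValueError("rates must be in [0, 1]")
        if not 0 < self.A < self.D:
            raise ValueError("need 0 < A < D")


def make_screening(scenario: ScreeningScenario) -> tuple[int, int, int, int]:
    """Simulate one screen; returns the count quadruple (D, A, Ht, Ha).

    Ha ~ Binomial(A, sensitivity); false positives ~ Binomial(D - A,
    1 - specificity); Ht = Ha + FP.
    """
    rng = np.random.default_rng(scenario.seed)
    ha = int(rng.binomial(scenario.A, scenario.sensitivity))
    fp = int(rng.binomial(scenario.D - scenario.A, 1.0 - scenario.specificity))
    return scenario.D, scenario.A, ha + fp, ha
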