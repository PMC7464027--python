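"""Linear QSAR models: shipped PLS equations, refitting, and IC50 handling.

The four shipped equations (AT/AF for acetylcholinesterase, BT/BF for
beta-secretase 1) live in ``data/qsar_models.yaml`` as plain coefficient
tables; :func:`predict` is their literal linear evaluation.  New models can
be fitted with NIPALS partial least squares (scikit-learn's
``PLSRegression``) on any descriptor matrix, and datasets can be divided by
a MOE-style diverse-subset ranking or uniformly at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.spatial.distance import cdist
from sklearn.cross_decomposition import PLSRegression

from .descriptors import DescriptorVector, canonical_name

__all__ = [
    "QSARModel",
    "ActivityRecord",
    "load_shipped_models",
    "predict",
    "pic50_from_ic50",
    "residual",
    "fit_pls",
    "diverse_split",
]


@dataclass(frozen=True)
class QSARModel:
    """A linear pIC50 model: intercept plus named coefficient terms."""

    name: str
    target: str
    intercept: float
    terms: Mapping[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"model {self.name!r} has no terms")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.terms)


@dataclass
class ActivityRecord:
    """Observed and/or predicted activity for one compound.

    ``ic50`` is a molar concentration.  If both an IC50 and a pIC50 are
    supplied they must agree (pIC50 = -log10 IC50) within 0.005, the slack
    of a value printed to two decimals.
    """

    compound_id: str
    ic50: float | None = None
    pic50: float | None = None
    predicted_pic50: float | None = None

    def __post_init__(self) -> None:
        if self.ic50 is not None and self.pic50 is not None:
            if abs(self.pic50 - pic50_from_ic50(self.ic50)) > 0.005:
                raise ValueError(
                    f"{self.compound_id}: inconsistent IC50 {self.ic50} vs pIC50 {self.pic50}"
                )


def load_models(path: str | Path) -> dict[str, QSARModel]:
    """Load a YAML model file ({models: {name: {target, intercept, terms}}})."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return _models_from_mapping(data)


def _models_from_mapping(data: Mapping) -> dict[str, QSARModel]:
    out = {}
    for name, spec in data["models"].items():
        terms = {k: float(v) for k, v in spec["terms"].items()}
        for term in terms:
            canonical_name(term)  # model files must name computable descriptors
        out[name] = QSARModel(
            name=name,
            target=spec["target"],
            intercept=float(spec["intercept"]),
            terms=terms,
            provenance=spec.get("provenance", ""),
        )
    return out


def load_shipped_models() -> dict[str, QSARModel]:
    """The four frozen AChE/BACE-1 equations shipped with the package."""
    text = resources.files("adscreen.data").joinpath("qsar_models.yaml").read_text()
    return _models_from_mapping(yaml.safe_load(text))


def predict(model: QSARModel, d: DescriptorVector) -> float:
    """Evaluate intercept + sum(coefficient x descriptor value).

    Descriptor names are alias-normalized on both sides, so a vector keyed
    ``a_Nn`` satisfies a model term spelled ``a_nN``.

    Raises
    ------
    KeyError
        If the vector is missing any model term (named in the message).
    """
    lookup = {canonical_name(k): v for k, v in d.items()}
    total = model.intercept
    for term, coeff in model.terms.items():
        key = canonical_name(term)
        if key not in lookup:
            raise KeyError(f"descriptor vector is missing model term {term!r}")
        total += coeff * lookup[key]
    return total


def pic50_from_ic50(ic50: float) -> float:
    """pIC50 = -log10(IC50 in mol/L); strictly decreasing in IC50."""
    if not ic50 > 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    return -math.log10(ic50)


def residual(predicted: float, measured: float) -> float:
    """Absolute prediction error |predicted - measured| in pIC50 units."""
    if not (math.isfinite(predicted) and math.isfinite(measured)):
        raise ValueError("residual requires finite inputs")
    return abs(predicted - measured)


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    feature_names: Sequence[str] | None = None,
    name: str = "pls_fit",
    target: str = "custom",
) -> QSARModel:
    """Fit a PLS regression and collapse it to an intercept + coefficients model.

    PLS latent components are estimated by NIPALS on centered (unscaled)
    data; because the model is linear in X the fit reduces exactly to
    ``y_hat = intercept + X @ beta``, which is what gets stored.  At full
    rank PLS reproduces the ordinary least-squares solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y length")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("degenerate X: every column has zero variance")
    n_components = min(n_components, X.shape[1], X.shape[0] - 1)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    beta = pls.coef_.ravel()
    intercept = float(y.mean() - X.mean(axis=0) @ beta)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    return QSARModel(
        name=name,
        target=target,
        intercept=intercept,
        terms=dict(zip(feature_names, beta.tolist())),
        provenance=f"NIPALS PLS, {n_components} components, n = {len(y)}",
    )


def fit_pls_auto(
    X: np.ndarray, y: np.ndarray, *, max_components: int | None = None, **kw
) -> QSARModel:
    """Fit PLS choosing the component count by leave-one-out q2 maximization."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    upper = min(X.shape[1], X.shape[0] - 2)
    if max_components is not None:
        upper = min(upper, max_components)
    best, best_q2 = 1, -np.inf
    ss_tot = np.sum((y - y.mean()) ** 2)
    for a in range(1, max(upper, 1) + 1):
        press = 0.0
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            m = fit_pls(X[mask], y[mask], a)
            beta = np.array([m.terms[f"x{j}"] for j in range(X.shape[1])])
            press += (y[i] - (m.intercept + X[i] @ beta)) ** 2
        q2 = 1 - press / ss_tot
        if q2 > best_q2:
            best, best_q2 = a, q2
    model = fit_pls(X, y, best, **kw)
    return QSARModel(
        name=model.name,
        target=model.target,
        intercept=model.intercept,
        terms=model.terms,
        provenance=model.provenance + f"; components chosen by LOO q2 = {best_q2:.4f}",
    )


def predict_matrix(model: QSARModel, X: np.ndarray, feature_names: Sequence[str]) -> np.ndarray:
    """Vectorized :func:`predict` over a matrix with named columns."""
    idx = {canonical_name(n): j for j, n in enumerate(feature_names)}
    beta = np.zeros(X.shape[1])
    for term, coeff in model.terms.items():
        key = canonical_name(term)
        if key not in idx:
            raise KeyError(f"matrix is missing model term {term!r}")
        beta[idx[key]] += coeff
    return model.intercept + np.asarray(X, dtype=float) @ beta


def diverse_split(
    X: np.ndarray,
    fraction: float,
    seed: int | None = None,
    *,
    method: str = "diverse",
) -> tuple[np.ndarray, np.ndarray]:
    """Split row indices into (training, validation) sets.

    ``diverse`` ranks rows by a greedy max–min Euclidean distance sweep
    (first pick = row farthest from the centroid; each next pick maximizes
    its minimum distance to the already-picked rows, ties to the lower
    index) and assigns the top ``fraction`` to training, so the training set
    spans descriptor space.  ``random`` permutes rows uniformly under
    ``seed``.  Both modes are deterministic given their inputs.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_train = round(n * fraction)
    if n_train < 1 or n - n_train < 1:
        raise ValueError(f"cannot split {n} rows into non-empty {fraction:.0%} sets")

    if method == "random":
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
    elif method == "diverse":
        dist = cdist(X, X)
        first = int(np.argmax(np.linalg.norm(X - X.mean(axis=0), axis=1)))
        order_list = [first]
        min_dist = dist[first].copy()
        for _ in range(n - 1):
            min_dist[order_list] = -np.inf
            nxt = int(np.argmax(min_dist))
            order_list.append(nxt)
            min_dist = np.minimum(min_dist, dist[nxt])
        order = np.array(order_list)
    else:
        raise ValueError(f"unknown split method {method!r}")
    return np.sort(order[:n_train]), np.sort(order[n_train:])
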