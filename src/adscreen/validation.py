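"""QSAR validation arithmetic and pharmacophore screening statistics.

Two families live here:

* **Regression metrics** for (observed, predicted) pIC50 pairs: RMSE and R2,
  their leave-one-out counterparts, external predictivity R2_pred and QF3^2,
  Lin's concordance correlation coefficient, and Roy's rm^2 metric family
  with its standard pass/fail thresholds for external validation
  (rm2 >= 0.65, CCC >= 0.85, mean rm2 >= 0.5, delta rm2 <= 0.2,
  QF3^2 > 0.6).

* **Screening statistics** for an active/decoy virtual-screening run
  summarized by the quadruple (D, A, Ht, Ha): yield and recall percentages,
  enrichment factor, false positive/negative counts, and the Guner–Henry
  goodness-of-hit score

      GH = [Ha (3A + Ht) / (4 Ht A)] * [1 - (Ht - Ha)/(D - A)],

  which is 1 for the ideal model (Ht = Ha = A) and tends to 0 as the hit
  list stops recovering actives.

Roy's rm^2 uses the squared Pearson correlation r^2 together with the
through-origin determination coefficient r0^2 (slope k = sum(x y)/sum(x^2)):
rm^2 = r^2 (1 - sqrt(r^2 - r0^2)), computed with predicted values on the
y-axis against observed on the x-axis; the primed variant swaps the axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PredictionPairs",
    "MetricReport",
    "ScreeningStats",
    "rmse",
    "r2",
    "loo_metrics",
    "external_metrics",
    "screening_stats",
    "EXTERNAL_THRESHOLDS",
]

#: Threshold battery for declaring a model externally predictive.
EXTERNAL_THRESHOLDS = {
    "rm2_min": 0.65,
    "ccc_min": 0.85,
    "rm2_bar_min": 0.5,
    "delta_rm2_max": 0.2,
    "qf3_2_min": 0.6,
}


@dataclass
class PredictionPairs:
    """Paired observed/predicted activities plus training-set context.

    ``training_mean`` anchors R2_pred; QF3^2 additionally needs the
    training-set mean squared deviation, supplied either directly
    (``training_msd``) or via the raw ``training_observed`` values.
    """

    observed: Sequence[float]
    predicted: Sequence[float]
    training_mean: float | None = None
    training_msd: float | None = None
    training_observed: Sequence[float] | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.observed.shape != self.predicted.shape or self.observed.ndim != 1:
            raise ValueError("observed and predicted must be equal-length 1-D")
        if len(self.observed) < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.all(np.isfinite(self.observed)) and np.all(np.isfinite(self.predicted))):
            raise ValueError("non-finite activity value")
        if self.training_observed is not None:
            tr = np.asarray(self.training_observed, dtype=float)
            if self.training_mean is None:
                self.training_mean = float(tr.mean())
            if self.training_msd is None:
                self.training_msd = float(np.mean((tr - tr.mean()) ** 2))

    @property
    def n_val(self) -> int:
        return len(self.observed)


@dataclass(frozen=True)
class MetricReport:
    """The full external-validation metric battery for one prediction set."""

    rmse: float
    r2: float
    r2_pred: float | None
    rm2: float
    rm2_prime: float
    rm2_bar: float
    delta_rm2: float
    ccc: float
    qf3_2: float | None
    pass_external: bool
    thresholds: dict = field(default_factory=lambda: dict(EXTERNAL_THRESHOLDS))


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square error sqrt(mean((y_hat - y)^2))."""
    y = np.asarray(observed, dtype=float)
    yh = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((yh - y) ** 2)))


def r2(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Determination coefficient 1 - SS_res/SS_tot about the observed mean."""
    y = np.asarray(observed, dtype=float)
    yh = np.asarray(predicted, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r2 undefined: observed values have zero variance")
    return 1.0 - float(np.sum((yh - y) ** 2)) / ss_tot


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x - x.mean(), y - y.mean()
    denom = math.sqrt(float(vx @ vx) * float(vy @ vy))
    if denom == 0:
        return 0.0
    return (float(vx @ vy) / denom) ** 2


def _origin_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Determination coefficient of the y-vs-x regression forced through origin."""
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("through-origin slope undefined: sum(x^2) = 0")
    k = float(x @ y) / sxx
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r0^2 undefined: zero variance on the y-axis")
    return 1.0 - float(np.sum((y - k * x) ** 2)) / ss_tot


def roy_rm2(x: np.ndarray, y: np.ndarray) -> float:
    """Roy's rm^2 = r^2 (1 - sqrt(r^2 - r0^2)) for y plotted against x."""
    rsq = _pearson_r2(x, y)
    r0sq = _origin_r2(x, y)
    return rsq * (1.0 - math.sqrt(max(rsq - r0sq, 0.0)))


def rm2_as_printed(x: np.ndarray, y: np.ndarray) -> float:
    """The typographically flattened variant r2*(1 - r2 - r02).

    Kept only for comparability checks; it is not used for model decisions
    because the standard rm^2 definition is what the published thresholds
    (0.65 / 0.5 / 0.2) were derived for.
    """
    rsq = _pearson_r2(x, y)
    return rsq * (1.0 - rsq - _origin_r2(x, y))


def ccc(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient (agreement about y = x)."""
    y = np.asarray(observed, dtype=float)
    yh = np.asarray(predicted, dtype=float)
    n = len(y)
    vy, vyh = y - y.mean(), yh - yh.mean()
    denom = float(vy @ vy) + float(vyh @ vyh) + n * (y.mean() - yh.mean()) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both series constant and equal")
    return 2.0 * float(vy @ vyh) / denom


def loo_metrics(
    X: np.ndarray,
    y: np.ndarray,
    fit: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]],
) -> tuple[float, float]:
    """Leave-one-out cross-validated (RMSE_LOO, R2_LOO).

    ``fit(X, y)`` must return a predictor callable.  Each of the n folds
    refits on n-1 points and predicts the held-out one; the two statistics
    are computed on the stacked held-out predictions, with R2_LOO anchored
    to the full-sample observed mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("LOO needs at least 3 samples")
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        try:
            predictor = fit(X[mask], y[mask])
            preds[i] = float(np.asarray(predictor(X[i : i + 1])).ravel()[0])
        except Exception as exc:
            raise RuntimeError(f"LOO fold {i} (holding out row {i}) failed: {exc}") from exc
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R2_LOO undefined: zero variance in y")
    r2_loo = 1.0 - float(np.sum((preds - y) ** 2)) / ss_tot
    return rmse(y, preds), r2_loo


def external_metrics(pairs: PredictionPairs) -> MetricReport:
    """Full external-validation battery on a validation prediction set.

    R2_pred and QF3^2 require the training context carried by ``pairs``
    (training mean, and for QF3^2 the training mean squared deviation);
    they are reported as None when that context is absent, in which case
    the pass decision treats the missing statistic as failed.
    """
    y, yh = pairs.observed, pairs.predicted

    rm2 = roy_rm2(y, yh)        # predicted on the y-axis vs observed
    rm2_prime = roy_rm2(yh, y)  # axes swapped
    rm2_bar = (rm2 + rm2_prime) / 2.0
    delta_rm2 = abs(rm2 - rm2_prime)
    ccc_val = ccc(y, yh)

    r2_pred = None
    if pairs.training_mean is not None:
        denom = float(np.sum((y - pairs.training_mean) ** 2))
        if denom == 0:
            raise ValueError("R2_pred undefined: validation set equals training mean")
        r2_pred = 1.0 - float(np.sum((yh - y) ** 2)) / denom

    qf3 = None
    if pairs.training_msd is not None:
        if pairs.training_msd == 0:
            raise ValueError("QF3^2 undefined: zero training variance")
        qf3 = 1.0 - float(np.mean((y - yh) ** 2)) / pairs.training_msd

    t = EXTERNAL_THRESHOLDS
    pass_external = (
        rm2 >= t["rm2_min"]
        and ccc_val >= t["ccc_min"]
        and rm2_bar >= t["rm2_bar_min"]
        and delta_rm2 <= t["delta_rm2_max"]
        and qf3 is not None
        and qf3 > t["qf3_2_min"]
    )
    return MetricReport(
        rmse=rmse(y, yh),
        r2=r2(y, yh),
        r2_pred=r2_pred,
        rm2=rm2,
        rm2_prime=rm2_prime,
        rm2_bar=rm2_bar,
        delta_rm2=delta_rm2,
        ccc=ccc_val,
        qf3_2=qf3,
        pass_external=pass_external,
    )


@dataclass(frozen=True)
class ScreeningStats:
    """Hit-list quality statistics for one screening run."""

    D: int
    A: int
    Ht: int
    Ha: int
    yield_pct: float
    ratio_pct: float
    EF: float
    FN: int
    FP: int
    GH: float


def screening_stats(D: int, A: int, Ht: int, Ha: int) -> ScreeningStats:
    """Derive all screening statistics from the count quadruple.

    D molecules were screened, of which A are known actives; the query
    returned Ht hits, Ha of them active.  Requires Ha <= Ht <= D,
    Ha <= A < D, Ht > 0 and A > 0.
    """
    if not (0 <= Ha <= Ht <= D and Ha <= A <= D):
        raise ValueError(f"inconsistent counts D={D}, A={A}, Ht={Ht}, Ha={Ha}")
    if Ht == 0 or A == 0:
        raise ValueError("Ht and A must be positive")
    if D <= A:
        raise ValueError("database must contain decoys (D > A)")
    if Ht - Ha > D - A:
        raise ValueError(f"false positives Ht-Ha={Ht - Ha} exceed decoys D-A={D - A}")
    gh = (Ha * (3 * A + Ht) / (4 * Ht * A)) * (1 - (Ht - Ha) / (D - A))
    return ScreeningStats(
        D=D,
        A=A,
        Ht=Ht,
        Ha=Ha,
        yield_pct=100.0 * Ha / Ht,
        ratio_pct=100.0 * Ha / A,
        EF=(Ha * D) / (Ht * A),
        FN=A - Ha,
        FP=Ht - Ha,
        GH=gh,
    )


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero, the convention of printed tables."""
    factor = 10**decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)
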