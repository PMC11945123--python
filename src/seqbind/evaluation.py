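"""Regression metrics, median-threshold AUC, k-fold CV, unit conversions and
active/decoy screening statistics.

The AUC of a regression model is obtained by binarizing the *experimental*
affinities at their median (above the median = high-affinity) and ranking the
continuous predictions against those labels (Mann-Whitney/midrank tie
convention).  Screening statistics compare predicted affinities of active
versus decoy ligands per receptor with a Welch unequal-variance t-test and a
pK 6 (1 uM) activity threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score, roc_auc_score
from sklearn.model_selection import KFold

#: gas constant in kcal/(mol K) and default absolute temperature
GAS_CONSTANT_KCAL = 1.9872e-3
DEFAULT_TEMPERATURE_K = 298.15

#: activity threshold: pK 6, i.e. 1 uM
ACTIVITY_THRESHOLD_PK = 6.0


@dataclass
class MetricsReport:
    pcc: float
    r2: float
    mse: float
    mae: float
    auc: float | None
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FoldResult:
    fold: int
    train_ids: list
    test_ids: list
    metrics: MetricsReport


@dataclass
class ThermoContext:
    R: float = GAS_CONSTANT_KCAL
    T: float = DEFAULT_TEMPERATURE_K


@dataclass
class DecoyAnalysis:
    receptor: str
    mean_active: float
    mean_decoy: float
    mean_difference: float
    welch_t: float
    p_value: float
    n_active: int
    n_decoy: int
    active_quartiles: tuple[float, float, float]
    decoy_quartiles: tuple[float, float, float]
    n_active_above_threshold: int
    n_decoy_above_threshold: int


def regression_metrics(y, yhat, with_auc: bool = False) -> MetricsReport:
    """Pearson r, R^2, MSE and MAE (pK units) of predictions against truth."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) != len(yhat) or len(y) < 2:
        raise ValueError("need two equal-length vectors of at least 2 entries")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("non-finite values in metric inputs")
    if y.std() == 0 or yhat.std() == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return MetricsReport(
        pcc=float(stats.pearsonr(y, yhat).statistic),
        r2=float(r2_score(y, yhat)),
        mse=float(mean_squared_error(y, yhat)),
        mae=float(mean_absolute_error(y, yhat)),
        auc=median_auc(y, yhat) if with_auc else None,
        n=len(y),
    )


def median_auc(y, scores) -> float:
    """AUC after binarizing true affinities at their median.

    Labels: 1 iff y > median(y).  The continuous predictions are used as
    ranking scores (ties midranked), so a constant predictor scores 0.5.
    """
    y = np.asarray(y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(y) < 4:
        raise ValueError("median-threshold AUC needs at least 4 points")
    labels = (y > np.median(y)).astype(int)
    if labels.min() == labels.max():
        raise ValueError("all affinities equal: one label class is empty")
    return float(roc_auc_score(labels, scores))


def kfold_cv(dataset, y, model_factory, k: int = 10, seed: int = 0,
             repeats: int = 1) -> tuple[list[FoldResult], MetricsReport]:
    """Shuffled k-fold cross-validation over an indexable dataset.

    ``model_factory(fold_seed)`` must return an object with ``fit(subset, y)``
    and ``predict(subset)``; the dataset must support ``.subset(indices)`` or
    numpy fancy indexing.  The averaged report is the arithmetic mean of the
    per-fold metrics; ``repeats`` reruns the whole split with derived seeds.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    folds: list[FoldResult] = []
    for rep in range(repeats):
        rep_seed = seed + 1000 * rep
        kf = KFold(n_splits=k, shuffle=True, random_state=rep_seed)
        for fold, (train_idx, test_idx) in enumerate(kf.split(np.arange(n))):
            model = model_factory(rep_seed + fold)
            train_ds = _take(dataset, train_idx)
            test_ds = _take(dataset, test_idx)
            model.fit(train_ds, y[train_idx])
            pred = np.asarray(model.predict(test_ds), dtype=float)
            metrics = regression_metrics(y[test_idx], pred, with_auc=True)
            folds.append(FoldResult(fold=rep * k + fold,
                                    train_ids=list(map(int, train_idx)),
                                    test_ids=list(map(int, test_idx)),
                                    metrics=metrics))
    averaged = MetricsReport(
        pcc=float(np.mean([f.metrics.pcc for f in folds])),
        r2=float(np.mean([f.metrics.r2 for f in folds])),
        mse=float(np.mean([f.metrics.mse for f in folds])),
        mae=float(np.mean([f.metrics.mae for f in folds])),
        auc=float(np.mean([f.metrics.auc for f in folds])),
        n=n,
    )
    return folds, averaged


def _take(dataset, idx):
    if hasattr(dataset, "subset"):
        return dataset.subset(idx)
    if isinstance(dataset, np.ndarray):
        return dataset[idx]
    return [dataset[i] for i in idx]


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

_CONC_SCALE = {"M": 1.0, "uM": 1e-6, "nM": 1e-9}
SUPPORTED_UNITS = ("pK", "dG", "M", "uM", "nM")


def convert_affinity(value: float, from_unit: str, to_unit: str,
                     thermo: ThermoContext | None = None) -> float:
    """Convert between pK, free energy (kcal/mol) and concentrations.

    The hub quantity is the molar dissociation constant: Kd = exp(dG / RT)
    and pK = -log10(Kd); concentration scaling is exact.
    """
    thermo = thermo or ThermoContext()
    if from_unit not in SUPPORTED_UNITS or to_unit not in SUPPORTED_UNITS:
        raise ValueError(f"units must be among {SUPPORTED_UNITS}")
    if from_unit == "pK":
        kd = 10.0 ** (-value)
    elif from_unit == "dG":
        kd = math.exp(value / (thermo.R * thermo.T))
    else:
        if value <= 0:
            raise ValueError("concentration must be positive")
        kd = value * _CONC_SCALE[from_unit]
    if to_unit == "pK":
        return -math.log10(kd)
    if to_unit == "dG":
        return thermo.R * thermo.T * math.log(kd)
    return kd / _CONC_SCALE[to_unit]


# ---------------------------------------------------------------------------
# active/decoy screening
# ---------------------------------------------------------------------------

def active_decoy_analysis(active_scores, decoy_scores, receptor: str = "",
                          threshold: float = ACTIVITY_THRESHOLD_PK) -> DecoyAnalysis:
    """Welch t-test and summary statistics for one receptor's screen."""
    a = np.asarray(active_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    if len(a) < 2 or len(d) < 2:
        raise ValueError("both groups need at least 2 predictions")
    t_res = stats.ttest_ind(a, d, equal_var=False)
    return DecoyAnalysis(
        receptor=receptor,
        mean_active=float(a.mean()),
        mean_decoy=float(d.mean()),
        mean_difference=float(a.mean() - d.mean()),
        welch_t=float(t_res.statistic),
        p_value=float(t_res.pvalue),
        n_active=len(a),
        n_decoy=len(d),
        active_quartiles=tuple(np.percentile(a, [25, 50, 75])),
        decoy_quartiles=tuple(np.percentile(d, [25, 50, 75])),
        n_active_above_threshold=int((a >= threshold).sum()),
        n_decoy_above_threshold=int((d >= threshold).sum()),
    )


def write_metrics_json(path, report: MetricsReport, folds: list[FoldResult] | None = None):
    payload = {"averaged": report.to_dict()}
    if folds is not None:
        payload["folds"] = [{"fold": f.fold, **f.metrics.to_dict()} for f in folds]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
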