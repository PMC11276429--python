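"""Model evaluation: RMSE/MAPE, three-way model comparison, per-fruit
breakdown, and one-at-a-time hyperparameter sweeps.

RMSE carries the units of stress (MPa); MAPE is scale-free and therefore
the metric used for qualitative model ordering.  The comparison evaluates
the trained LSTM and the two globally-calibrated classical models on
exactly the same pooled test points, since the classical models — once
their single parameter set is fixed — predict from time and strain alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import lstm_core
from .classical_models import CaputoParams, MaxwellParams, caputo_stress, maxwell_stress
from .lstm_core import LSTMConfig, LSTMParams
from .preprocessing import RelaxationCurve
from .synthetic_data import POSITIONS, SIZE_CLASSES, FruitSample

__all__ = [
    "MetricReport",
    "SweepResult",
    "rmse",
    "mape",
    "classical_predict",
    "compare_models",
    "per_fruit_report",
    "reports_to_frame",
    "sweep",
    "select_best",
    "DEFAULT_GRIDS",
    "plot_comparison",
]

#: One-at-a-time sweep grids around the base configuration.  Ranges follow
#: the tuning protocol for this problem (neurons 40–60, initial lr
#: 0.001–0.009, drop period 70–90, epochs 400–900); step sizes chosen so
#: every operating point discussed in the tuning analysis is on-grid.
DEFAULT_GRIDS: dict[str, list] = {
    "hidden_size": [40, 44, 48, 52, 56, 60],
    "initial_lr": [round(0.001 * k, 3) for k in range(1, 10)],
    "lr_drop_period": list(range(70, 92, 2)),
    "epochs": list(range(400, 901, 50)),
}


@dataclass(frozen=True)
class MetricReport:
    """RMSE/MAPE for one model over one scope (whole test set or one
    size × position cell)."""

    model: str
    scope: str
    rmse: float
    mape: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 1:
            raise ValueError("a metric report needs at least one point")


@dataclass(frozen=True)
class SweepResult:
    """Train/test metrics at one grid point of one hyperparameter."""

    param: str
    value: float
    train_rmse: float
    train_mape: float
    test_rmse: float
    test_mape: float


def rmse(observed, predicted) -> float:
    """Root mean square error, in the units of the observations (MPa here)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have identical shapes")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def mape(observed, predicted) -> float:
    """Mean absolute percentage error, in percent.

    Requires strictly nonzero observations — relaxation stress is strictly
    positive, so a zero here flags broken preprocessing.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have identical shapes")
    if np.any(observed == 0):
        raise ValueError("MAPE is undefined for zero observed values")
    return float(np.mean(np.abs((observed - predicted) / observed)) * 100.0)


def classical_predict(params: MaxwellParams | CaputoParams, curve: RelaxationCurve) -> np.ndarray:
    """Stress predicted by a fitted classical model on a curve's time grid,
    using that fruit's own initial strain."""
    if isinstance(params, MaxwellParams):
        return maxwell_stress(params, curve.times, curve.strain0)
    return caputo_stress(params, curve.times, curve.strain0)


def _pool_lstm(curves, lstm_params, normalizer):
    obs, pred = [], []
    for c in curves:
        obs.append(c.stress)
        pred.append(lstm_core.predict(lstm_params, normalizer, c))
    return np.concatenate(obs), np.concatenate(pred)


def compare_models(
    test_curves: Sequence[RelaxationCurve],
    lstm_params: LSTMParams,
    normalizer,
    maxwell_params: MaxwellParams,
    caputo_params: CaputoParams,
) -> list[MetricReport]:
    """Pooled test-set metrics for the LSTM and both classical models.

    All three reports are computed on exactly the same point set; the
    classical models predict from each fruit's time grid and initial strain
    with one global parameter set.
    """
    test_curves = list(test_curves)
    if not test_curves:
        raise ValueError("compare_models needs at least one test curve")
    obs = np.concatenate([c.stress for c in test_curves])
    _, lstm_pred = _pool_lstm(test_curves, lstm_params, normalizer)
    maxwell_pred = np.concatenate([classical_predict(maxwell_params, c) for c in test_curves])
    caputo_pred = np.concatenate([classical_predict(caputo_params, c) for c in test_curves])
    reports = []
    for name, pred in (("LSTM", lstm_pred), ("Maxwell", maxwell_pred), ("Caputo", caputo_pred)):
        reports.append(MetricReport(name, "test", rmse(obs, pred), mape(obs, pred), obs.size))
    return reports


def per_fruit_report(
    test_curves: Sequence[RelaxationCurve],
    samples: Mapping[str, FruitSample] | Sequence[FruitSample],
    lstm_params: LSTMParams,
    normalizer,
) -> dict[tuple[str, str], MetricReport | None]:
    """LSTM metrics per (size_class, position) cell over the test curves.

    Returns all six cells; a cell with no test curves maps to None (an
    explicit absent marker, never a zero metric).
    """
    if not isinstance(samples, Mapping):
        samples = {s.id: s for s in samples}
    cells: dict[tuple[str, str], list[RelaxationCurve]] = {
        (sz, pos): [] for sz in SIZE_CLASSES for pos in POSITIONS
    }
    for c in test_curves:
        s = samples[c.sample_id]
        cells[(s.size_class, s.position)].append(c)

    out: dict[tuple[str, str], MetricReport | None] = {}
    for key, curves in cells.items():
        if not curves:
            out[key] = None
            continue
        obs, pred = _pool_lstm(curves, lstm_params, normalizer)
        out[key] = MetricReport("LSTM", f"{key[0]}/{key[1]}", rmse(obs, pred), mape(obs, pred), obs.size)
    return out


def reports_to_frame(reports: Iterable[MetricReport | None]) -> pd.DataFrame:
    """Tabulate metric reports (absent cells excluded) for CSV export."""
    rows = [
        {"model": r.model, "scope": r.scope, "rmse_mpa": r.rmse, "mape_pct": r.mape, "n_points": r.n_points}
        for r in reports if r is not None
    ]
    return pd.DataFrame(rows, columns=["model", "scope", "rmse_mpa", "mape_pct", "n_points"])


def _train_and_score(train_curves, test_curves, normalizer, config: LSTMConfig):
    seqs, targets = lstm_core.make_sequences(train_curves, normalizer)
    params, _ = lstm_core.train(seqs, targets, config)
    tr_obs, tr_pred = _pool_lstm(train_curves, params, normalizer)
    te_obs, te_pred = _pool_lstm(test_curves, params, normalizer)
    return (rmse(tr_obs, tr_pred), mape(tr_obs, tr_pred),
            rmse(te_obs, te_pred), mape(te_obs, te_pred))


def sweep(
    train_curves: Sequence[RelaxationCurve],
    test_curves: Sequence[RelaxationCurve],
    normalizer,
    base_config: LSTMConfig,
    grids: Mapping[str, Sequence] | None = None,
    progress: bool = False,
) -> list[SweepResult]:
    """One-at-a-time hyperparameter sweep around a base configuration.

    For each named hyperparameter, trains once per grid value (all other
    settings held at the base configuration, same seed) and records train
    and test metrics.
    """
    grids = dict(grids) if grids is not None else dict(DEFAULT_GRIDS)
    results: list[SweepResult] = []
    for param, values in grids.items():
        if not hasattr(base_config, param):
            raise ValueError(f"unknown hyperparameter {param!r}")
        for value in values:
            config = replace(base_config, **{param: value})
            tr_rmse, tr_mape, te_rmse, te_mape = _train_and_score(
                train_curves, test_curves, normalizer, config)
            results.append(SweepResult(param, value, tr_rmse, tr_mape, te_rmse, te_mape))
            if progress:
                print(f"sweep {param}={value}: test rmse {te_rmse:.3e}, mape {te_mape:.3f}%")
    return results


def select_best(results: Sequence[SweepResult]) -> SweepResult:
    """Grid point with minimum test RMSE; ties broken by lower test MAPE."""
    if not results:
        raise ValueError("select_best needs at least one sweep result")
    return min(results, key=lambda r: (r.test_rmse, r.test_mape))


def plot_comparison(curve: RelaxationCurve, predictions: Mapping[str, np.ndarray], path) -> None:
    """Observed vs predicted stress for one fruit, one line per model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.times, curve.stress, "k.", ms=3, label="observed")
    for name, pred in predictions.items():
        ax.plot(curve.times, pred, label=name)
    ax.set_xlabel("time since hold start (s)")
    ax.set_ylabel("relaxation stress (MPa)")
    ax.set_title(f"fruit {curve.sample_id}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
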