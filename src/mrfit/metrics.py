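"""Goodness-of-fit statistics and model-order selection.

R^2 compares residual scatter to the spread of the observed moisture ratios;
the adjusted variant penalizes the ``n + 1`` estimated coefficients so models
of different order can be ranked on one scale.  RMSE is reported on the
moisture-ratio scale (dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import DryingDataset
from .errors import DegenerateDataError
from .model import PolynomialModel, predict

__all__ = [
    "FitMetrics",
    "r_squared",
    "adjusted_r_squared",
    "rmse",
    "evaluate_model",
    "select_order",
]


@dataclass(frozen=True)
class FitMetrics:
    """R^2, adjusted R^2 and RMSE of one model on one dataset."""

    r2: float
    adj_r2: float
    rmse: float
    order: int
    kmax: int


def _check_lengths(predicted, observed):
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be 1-D arrays of equal length")
    return p, o


def r_squared(predicted, observed) -> float:
    """Fitting coefficient ``1 - RSS/TSS`` about the observed mean."""
    p, o = _check_lengths(predicted, observed)
    if o.size < 2:
        raise ValueError("need at least two observations")
    tss = float(np.sum((o - o.mean()) ** 2))
    if tss == 0.0:
        raise DegenerateDataError("observed series has zero variance; R^2 undefined")
    rss = float(np.sum((p - o) ** 2))
    return 1.0 - rss / tss


def adjusted_r_squared(r2: float, kmax: int, order: int) -> float:
    """R^2 adjusted for the ``order + 1`` estimated coefficients.

    ``adjR^2 = 1 - (1 - R^2) * (kmax - 1) / (kmax - (order + 1))``; requires
    ``kmax > order + 1`` so the correction factor stays positive.
    """
    if kmax <= order + 1:
        raise ValueError("kmax must exceed the number of coefficients (order + 1)")
    return 1.0 - (1.0 - r2) * (kmax - 1) / (kmax - (order + 1))


def rmse(predicted, observed) -> float:
    """Root-mean-square prediction error; the square root of the MLF."""
    p, o = _check_lengths(predicted, observed)
    if o.size < 1:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def evaluate_model(model: PolynomialModel, dataset: DryingDataset) -> FitMetrics:
    """Score a fixed model on a dataset without re-estimating anything.

    Used both for in-sample reporting and for validation on a second batch of
    drying data; the dataset's own mean and record count enter the formulas,
    and the model's order is used in the adjusted-R^2 penalty even though no
    parameters are re-fitted.
    """
    pred = predict(model, dataset.shrinkage)
    r2 = r_squared(pred, dataset.moisture_ratio)
    if dataset.kmax > model.order + 1:
        adj = adjusted_r_squared(r2, dataset.kmax, model.order)
    else:
        adj = float("nan")
    return FitMetrics(
        r2=r2,
        adj_r2=adj,
        rmse=rmse(pred, dataset.moisture_ratio),
        order=model.order,
        kmax=dataset.kmax,
    )


def select_order(dataset, orders, algorithm="mlp-i-ie", config=None):
    """Fit every candidate order and pick the one with the largest adjusted R^2.

    Parameters
    ----------
    dataset
        Drying data to fit.
    orders
        Candidate polynomial orders; each must satisfy ``kmax > order + 1``.
    algorithm
        ``"mlp-ie"``, ``"mlp-i-ie"`` or ``"ols"`` (exact least squares).
    config
        Estimator configuration.  When omitted, a search budget generous
        enough for reliable convergence on well-conditioned data is used
        (population 50, 300 generations, initialization on [-15, 15]).

    Returns
    -------
    (best_order, table)
        The adjusted-R^2-maximizing order (ties broken toward the smaller,
        more parsimonious order) and a DataFrame with one row per candidate:
        order, coefficients, R^2, adjusted R^2, RMSE.
    """
    from .evolution import EvolutionConfig, run_mlp_ie
    from .improved import ImprovedScheduleConfig, run_mlp_i_ie
    from .model import ols_fit

    orders = list(orders)
    if not orders:
        raise ValueError("orders must be non-empty")
    for n in orders:
        if dataset.kmax <= n + 1:
            raise ValueError(f"kmax={dataset.kmax} too small for order {n}")

    rows = []
    best_order = None
    best_adj = -np.inf
    for n in sorted(orders):
        if algorithm == "ols":
            model = ols_fit(dataset, n)
            metrics = evaluate_model(model, dataset)
        elif algorithm == "mlp-ie":
            cfg = config or EvolutionConfig(
                population_size=50, generations=300, init_low=-15.0, init_high=15.0
            )
            result = run_mlp_ie(dataset, n, cfg)
            model = result.model
            metrics = result.metrics
        elif algorithm == "mlp-i-ie":
            cfg = config or ImprovedScheduleConfig(
                population_size=50, generations=300, init_low=-15.0, init_high=15.0
            )
            result = run_mlp_i_ie(dataset, n, cfg)
            model = result.model
            metrics = result.metrics
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        rows.append(
            {
                "order": n,
                "gamma": model.gamma.tolist(),
                "r2": metrics.r2,
                "adj_r2": metrics.adj_r2,
                "rmse": metrics.rmse,
            }
        )
        # adjusted-R^2 differences below 1e-12 count as ties, which keep the
        # smaller (more parsimonious) order
        if metrics.adj_r2 > best_adj + 1e-12:
            best_adj = metrics.adj_r2
            best_order = n
    return best_order, pd.DataFrame(rows)
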