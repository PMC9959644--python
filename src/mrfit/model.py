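"""Polynomial moisture-ratio model and its maximum-likelihood fitness.

The moisture ratio of a drying slice is modelled as a polynomial in the
measured shrinkage,

    MR(k) = r0 + r1*S(k) + ... + rn*S(k)^n + w(k),

with ``w`` white Gaussian noise of variance ``sigma^2``.  Profiling the
Gaussian likelihood over ``sigma^2`` reduces maximum-likelihood estimation of
the coefficient vector ``gamma = (r0..rn)`` to minimizing the mean squared
residual, called the maximum-likelihood fitness (MLF) here.  Because the MLF
is a convex quadratic in ``gamma``, its global minimizer is the ordinary
least-squares solution; :func:`ols_fit` computes it in closed form and serves
as the exact oracle against which the stochastic estimators are judged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .dataset import DryingDataset
from .errors import SingularDesignError

__all__ = [
    "PolynomialModel",
    "NoiseModel",
    "moisture_content",
    "moisture_ratio",
    "information_vector",
    "predict",
    "mlf",
    "noise_variance_mle",
    "log_likelihood_profile",
    "ols_fit",
]


@dataclass(frozen=True)
class PolynomialModel:
    """Polynomial of ``order`` n with coefficient vector ``gamma`` (length n+1)."""

    order: int
    gamma: np.ndarray

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if self.order < 0:
            raise ValueError("order must be non-negative")
        if g.size != self.order + 1:
            raise ValueError(f"gamma must have length order+1 = {self.order + 1}, got {g.size}")
        if not np.all(np.isfinite(g)):
            raise ValueError("gamma must be finite")
        object.__setattr__(self, "gamma", g)

    def predict(self, shrinkage) -> np.ndarray | float:
        return predict(self, shrinkage)

    def to_json(self, path=None) -> str:
        payload = json.dumps({"order": self.order, "gamma": self.gamma.tolist()}, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "PolynomialModel":
        if hasattr(source, "read"):
            data = json.load(source)
        elif str(source).lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                data = json.load(fh)
        return cls(order=int(data["order"]), gamma=np.asarray(data["gamma"], dtype=float))


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian observation noise with variance ``sigma2``."""

    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("variance must be non-negative")


def moisture_content(mass: float, dry_mass: float) -> float:
    """Dry-basis moisture content ``(m - m_d)/m_d`` in g water per g dry matter."""
    if dry_mass <= 0:
        raise ValueError("dry mass must be positive")
    if mass < dry_mass:
        raise ValueError("total mass cannot be below the dry mass")
    return (mass - dry_mass) / dry_mass


def moisture_ratio(mc_t: float, mc_0: float) -> float:
    """Moisture content normalized by its initial value."""
    if mc_0 <= 0:
        raise ValueError("initial moisture content must be positive")
    if mc_t < 0:
        raise ValueError("moisture content cannot be negative")
    return mc_t / mc_0


def information_vector(shrinkage: float, order: int) -> np.ndarray:
    """Regressor vector ``[1, S, S^2, ..., S^order]`` for one shrinkage value."""
    if order < 0:
        raise ValueError("order must be non-negative")
    if not np.isfinite(shrinkage):
        raise ValueError("shrinkage must be finite")
    return np.power(float(shrinkage), np.arange(order + 1))


def predict(model: PolynomialModel, shrinkage) -> np.ndarray | float:
    """Noise-free model prediction of the moisture ratio at given shrinkage."""
    s = np.asarray(shrinkage, dtype=float)
    out = np.vander(np.atleast_1d(s), model.order + 1, increasing=True) @ model.gamma
    return float(out[0]) if s.ndim == 0 else out


def _residuals(gamma, dataset: DryingDataset) -> np.ndarray:
    gamma = np.asarray(gamma, dtype=float)
    X = dataset.design_matrix(gamma.size - 1)
    return dataset.moisture_ratio - X @ gamma


def mlf(gamma, dataset: DryingDataset) -> float:
    """Maximum-likelihood fitness: mean squared residual over all records.

    Equals the square of the RMSE; the profiled Gaussian log-likelihood is a
    strictly decreasing function of this quantity, so minimizing it maximizes
    the likelihood.
    """
    r = _residuals(gamma, dataset)
    return float(np.mean(r * r))


def noise_variance_mle(gamma, dataset: DryingDataset) -> NoiseModel:
    """Maximum-likelihood noise variance: residual mean square at ``gamma``."""
    return NoiseModel(sigma2=mlf(gamma, dataset))


def log_likelihood_profile(gamma, dataset: DryingDataset) -> float:
    """Gaussian log-likelihood with the noise variance profiled out.

    Returns ``-(kmax/2) * (ln 2*pi + 1) - (kmax/2) * ln lambda(gamma)`` where
    ``lambda`` is :func:`mlf`.  A perfect fit (``lambda = 0``) yields ``+inf``
    rather than an exception.
    """
    lam = mlf(gamma, dataset)
    kmax = dataset.kmax
    const = -0.5 * kmax * (math.log(2.0 * math.pi) + 1.0)
    if lam == 0.0:
        return math.inf
    return const - 0.5 * kmax * math.log(lam)


def ols_fit(dataset: DryingDataset, order: int) -> PolynomialModel:
    """Exact least-squares fit of the polynomial model (the MLF minimizer).

    Solves the Vandermonde least-squares system by QR-backed ``lstsq``.  The
    result is the global optimum of the convex MLF landscape, so it bounds the
    achievable fitness of any evolutionary search on the same data.

    Raises
    ------
    SingularDesignError
        If ``kmax < order + 1`` or the design matrix is rank deficient
        (e.g. all shrinkage values identical while ``order >= 1``).
    """
    Q = order + 1
    if dataset.kmax < Q:
        raise SingularDesignError(
            f"need at least {Q} records to identify an order-{order} model, have {dataset.kmax}"
        )
    X = dataset.design_matrix(order)
    gamma, _, rank, _ = np.linalg.lstsq(X, dataset.moisture_ratio, rcond=None)
    if rank < Q:
        raise SingularDesignError(
            f"design matrix rank {rank} < {Q}; shrinkage values do not identify the model"
        )
    return PolynomialModel(order=order, gamma=gamma)
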