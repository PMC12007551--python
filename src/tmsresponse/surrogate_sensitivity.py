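"""Generalized polynomial chaos surrogates and Sobol sensitivity indices.

A threshold map y(theta, delta) is expanded on a total-order basis of
polynomials orthonormal with respect to the joint input measure: Legendre
polynomials for uniformly distributed inputs, Jacobi polynomials for
beta-distributed ones.  With inputs standardized to x in [-1, 1], a
beta(p, q) density is proportional to (1-x)^(q-1) (1+x)^(p-1), i.e. the
Jacobi weight with alpha = q - 1 and beta = p - 1 (two beta conventions
circulate; this mapping is fixed here and exercised by an orthonormality
check in the test suite).

Coefficients are estimated by seeded, oversampled least-squares regression
(point collocation).  Because the basis is orthonormal, the output variance
decomposes as the sum of squared non-constant coefficients, and Sobol
indices are ratios of coefficient groups sharing a multi-index support.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable

import numpy as np
from scipy.special import betaln, eval_jacobi, gammaln

from .errors import ConfigurationError, RangeError, SurrogateConditioningError

__all__ = [
    "ParameterDistribution",
    "GPCModel",
    "basis_size",
    "multi_indices",
    "sample_parameters",
    "build_gpc",
    "evaluate_gpc",
    "sobol_indices",
    "save_gpc",
    "load_gpc",
]

# input distributions fitted to field-parameter histograms on a deep cortical
# layer of a realistic head model (convenience constructors below)
THETA_BETA = (1.51, 1.56, 0.0, 180.0)
DELTA_BETA = (13.86, 13.78, -30.0, 30.0)


@dataclass(frozen=True)
class ParameterDistribution:
    """Uniform or (scaled) beta distribution on a finite support."""

    kind: str  # "uniform" | "beta"
    support: tuple[float, float]
    shape: tuple[float, float] | None = None  # (p, q) for beta

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "beta"):
            raise ConfigurationError(f"unknown distribution kind {self.kind!r}")
        lo, hi = self.support
        if not lo < hi:
            raise ConfigurationError("support must satisfy min < max")
        if self.kind == "beta":
            if self.shape is None or self.shape[0] <= 0 or self.shape[1] <= 0:
                raise ConfigurationError("beta requires shape p, q > 0")

    @staticmethod
    def uniform(lo: float, hi: float) -> "ParameterDistribution":
        return ParameterDistribution("uniform", (lo, hi))

    @staticmethod
    def beta(p: float, q: float, lo: float, hi: float) -> "ParameterDistribution":
        return ParameterDistribution("beta", (lo, hi), (p, q))

    @staticmethod
    def theta_beta() -> "ParameterDistribution":
        p, q, lo, hi = THETA_BETA
        return ParameterDistribution.beta(p, q, lo, hi)

    @staticmethod
    def delta_beta() -> "ParameterDistribution":
        p, q, lo, hi = DELTA_BETA
        return ParameterDistribution.beta(p, q, lo, hi)

    def standardize(self, x: np.ndarray) -> np.ndarray:
        """Physical values -> canonical [-1, 1]."""
        lo, hi = self.support
        return 2.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo) - 1.0

    def unstandardize(self, t: np.ndarray) -> np.ndarray:
        lo, hi = self.support
        return lo + (np.asarray(t, dtype=float) + 1.0) * (hi - lo) / 2.0

    @property
    def mean(self) -> float:
        lo, hi = self.support
        if self.kind == "uniform":
            return 0.5 * (lo + hi)
        p, q = self.shape
        return lo + (hi - lo) * p / (p + q)

    @property
    def variance(self) -> float:
        lo, hi = self.support
        if self.kind == "uniform":
            return (hi - lo) ** 2 / 12.0
        p, q = self.shape
        return (hi - lo) ** 2 * p * q / ((p + q) ** 2 * (p + q + 1.0))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.support
        if self.kind == "uniform":
            return rng.uniform(lo, hi, size=n)
        p, q = self.shape
        return lo + (hi - lo) * rng.beta(p, q, size=n)

    # -- orthonormal basis -------------------------------------------------

    def _jacobi_ab(self) -> tuple[float, float]:
        p, q = self.shape
        return q - 1.0, p - 1.0  # alpha, beta

    def eval_orthonormal(self, degree: int, t: np.ndarray) -> np.ndarray:
        """Polynomial of given degree, orthonormal under this measure on [-1,1]."""
        t = np.asarray(t, dtype=float)
        if self.kind == "uniform":
            return eval_jacobi(degree, 0.0, 0.0, t) * math.sqrt(2.0 * degree + 1.0)
        a, b = self._jacobi_ab()
        # E[P_n^2] under the normalized beta density:
        #   h_n / (2^(a+b+1) B(a+1, b+1)) with h_n the classical Jacobi norm
        n = degree
        log_hn = ((a + b + 1.0) * math.log(2.0)
                  + gammaln(n + a + 1.0) + gammaln(n + b + 1.0)
                  - math.log(2.0 * n + a + b + 1.0)
                  - gammaln(n + a + b + 1.0) - gammaln(n + 1.0))
        log_norm2 = log_hn - (a + b + 1.0) * math.log(2.0) - betaln(a + 1.0, b + 1.0)
        return eval_jacobi(n, a, b, t) * math.exp(-0.5 * log_norm2)


def basis_size(order: int, dims: int) -> int:
    """Number of multi-indices with total degree <= order: C(order + dims, dims)."""
    if order < 0 or dims < 1:
        raise ConfigurationError("order must be >= 0 and dims >= 1")
    return math.comb(order + dims, dims)


def multi_indices(order: int, dims: int) -> np.ndarray:
    """All multi-indices of total degree <= order, graded-lexicographic."""
    if order < 0 or dims < 1:
        raise ConfigurationError("order must be >= 0 and dims >= 1")
    idx = [mi for mi in product(range(order + 1), repeat=dims) if sum(mi) <= order]
    idx.sort(key=lambda mi: (sum(mi), mi))
    return np.array(idx, dtype=np.int64)


def sample_parameters(dists, n: int, seed: int) -> np.ndarray:
    """Seeded i.i.d. draws from the per-dimension distributions, shape (n, dims)."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return np.column_stack([d.sample(n, rng) for d in dists])


@dataclass
class GPCModel:
    order: int
    dims: int
    multi_indices: np.ndarray  # (Nc, dims)
    coefficients: np.ndarray  # (Nc,)
    input_distributions: list[ParameterDistribution]
    conditioning: dict = field(default_factory=dict)

    @property
    def n_coefficients(self) -> int:
        return len(self.coefficients)


def _design_matrix(model_dists, mindices: np.ndarray, X_std: np.ndarray) -> np.ndarray:
    n, dims = X_std.shape
    # per-dimension 1-D basis evaluations up to the max degree, then products
    max_deg = int(mindices.max()) if len(mindices) else 0
    per_dim = [
        np.stack([model_dists[d].eval_orthonormal(k, X_std[:, d])
                  for k in range(max_deg + 1)])
        for d in range(dims)
    ]
    Psi = np.ones((n, len(mindices)))
    for j, mi in enumerate(mindices):
        for d in range(dims):
            if mi[d] > 0:
                Psi[:, j] *= per_dim[d][mi[d]]
    return Psi


def build_gpc(
    target: Callable[[np.ndarray], np.ndarray],
    dists,
    order: int = 15,
    n_train: int | None = None,
    seed: int = 0,
    condition_limit: float = 1e8,
) -> GPCModel:
    """Least-squares gPC regression of ``target`` on the orthonormal basis.

    ``target`` maps an (n, dims) array of physical parameter values to n
    outputs.  ``n_train`` defaults to 2.5x the basis size (oversampled
    collocation); it must be at least 2x the basis size.
    """
    dists = list(dists)
    dims = len(dists)
    mindices = multi_indices(order, dims)
    nc = len(mindices)
    if n_train is None:
        n_train = int(math.ceil(2.5 * nc))
    if n_train < 2 * nc:
        raise ConfigurationError(
            f"n_train={n_train} must be >= 2*Nc={2 * nc} for stable regression"
        )
    X = sample_parameters(dists, n_train, seed)
    y = np.asarray(target(X), dtype=float)
    if y.shape != (n_train,):
        raise ConfigurationError("target must return one value per sample row")
    X_std = np.column_stack([d.standardize(X[:, i]) for i, d in enumerate(dists)])
    Psi = _design_matrix(dists, mindices, X_std)
    cond = float(np.linalg.cond(Psi))
    if cond > condition_limit:
        raise SurrogateConditioningError(
            f"regression matrix condition number {cond:.3g} exceeds "
            f"{condition_limit:.3g}; increase n_train or lower the order"
        )
    coeff, *_ = np.linalg.lstsq(Psi, y, rcond=None)
    resid = y - Psi @ coeff
    denom = float(np.std(y)) or 1.0
    diag = {
        "condition_number": cond,
        "n_train": n_train,
        "seed": seed,
        "train_rms_residual": float(np.sqrt(np.mean(resid ** 2))),
        "train_nrmsd": float(np.sqrt(np.mean(resid ** 2)) / denom),
        "sampling": "seeded i.i.d. collocation, least-squares regression",
    }
    return GPCModel(order, dims, mindices, coeff, dists, diag)


def evaluate_gpc(m: GPCModel, *coords: np.ndarray) -> np.ndarray:
    """Evaluate the surrogate at query vectors (one per dimension): Psi @ c.

    Builds the (N_query, Nc) matrix row-wise from the basis polynomials and
    applies the coefficient vector.  Out-of-support queries are rejected.
    """
    if len(coords) != m.dims:
        raise ConfigurationError(f"expected {m.dims} coordinate vectors")
    cols = []
    n = None
    for d, (c, dist) in enumerate(zip(coords, m.input_distributions)):
        c = np.atleast_1d(np.asarray(c, dtype=float))
        if n is None:
            n = len(c)
        elif len(c) != n:
            raise ConfigurationError("coordinate vectors must have equal length")
        lo, hi = dist.support
        if len(c) and (c.min() < lo - 1e-9 or c.max() > hi + 1e-9):
            raise RangeError(f"dimension {d} query outside support [{lo}, {hi}]")
        cols.append(dist.standardize(c))
    if n == 0:
        return np.empty(0)
    X_std = np.column_stack(cols)
    Psi = _design_matrix(m.input_distributions, m.multi_indices, X_std)
    return Psi @ m.coefficients


def sobol_indices(m: GPCModel) -> dict[str, float]:
    """Variance fractions from squared orthonormal coefficients.

    For two dimensions, returns S_theta (first input alone), S_delta (second
    alone) and S_theta_delta (interaction); in general, one entry per
    non-empty multi-index support, keyed 'S_' + underscore-joined dimension
    names.  Indices are non-negative and sum to 1.
    """
    c2 = m.coefficients ** 2
    degs = m.multi_indices
    total_var = float(c2[1:].sum()) if len(c2) > 1 else 0.0
    if total_var <= 0.0:
        raise ConfigurationError("zero-variance model: Sobol indices undefined")
    names = ["theta", "delta"] if m.dims == 2 else [f"x{i}" for i in range(m.dims)]
    out: dict[str, float] = {}
    for j in range(1, len(c2)):
        support = tuple(i for i in range(m.dims) if degs[j, i] > 0)
        key = "S_" + "_".join(names[i] for i in support)
        out[key] = out.get(key, 0.0) + float(c2[j]) / total_var
    return out


# ---------------------------------------------------------------------------
# JSON persistence
# ---------------------------------------------------------------------------

def save_gpc(m: GPCModel, path) -> None:
    payload = {
        "order": m.order,
        "dims": m.dims,
        "multi_indices": m.multi_indices.tolist(),
        "coefficients": m.coefficients.tolist(),
        "input_distributions": [
            {"kind": d.kind, "support": list(d.support),
             "shape": list(d.shape) if d.shape else None}
            for d in m.input_distributions
        ],
        "conditioning": m.conditioning,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_gpc(path) -> GPCModel:
    with open(path) as fh:
        payload = json.load(fh)
    dists = [
        ParameterDistribution(d["kind"], tuple(d["support"]),
                              tuple(d["shape"]) if d["shape"] else None)
        for d in payload["input_distributions"]
    ]
    return GPCModel(payload["order"], payload["dims"],
                    np.array(payload["multi_indices"], dtype=np.int64),
                    np.array(payload["coefficients"]), dists,
                    payload.get("conditioning", {}))
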