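"""Synthetic ordinal data: continuous factor scores discretised at fixed cutpoints.

Continuous data are drawn either multivariate normal or multivariate
non-normal (marginal skewness 2, excess kurtosis 7 by default).  The
non-normal generator is the independent-generator (IG) construction: a
Cholesky mix of independent Fleishman-polynomial components whose third
and fourth cumulants are solved so the *mixed* marginals hit the targets.
When the component moment system leaves the Fleishman-feasible region the
generator falls back to the Vale-Maurelli construction (per-marginal
Fleishman transforms of a normal with matched intermediate correlations);
both routes satisfy the same moment-level contract (target covariance and
marginal skewness/kurtosis).

Discretisation uses fixed threshold sets on the latent standard-normal
scale: category c is assigned when tau_{c-1} < x <= tau_c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .population import ConditionSpec, draw_factor_model

THRESHOLDS = {
    (4, False): (-0.67, 0.0, 0.67),
    (4, True): (0.0, 0.43, 0.97),
    (5, False): (-0.84, -0.25, 0.25, 0.84),
    (5, True): (0.08, 0.25, 0.62, 1.11),
}


class InfeasibleMomentsError(ValueError):
    """Raised when a (skewness, excess kurtosis) pair cannot be generated."""


@dataclass(frozen=True)
class ThresholdSet:
    categories: int
    skewed: bool
    cutpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cutpoints) != self.categories - 1:
            raise ValueError("need categories - 1 cutpoints")
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ValueError("cutpoints must be strictly increasing")


def threshold_table(categories: int, skewed: bool) -> ThresholdSet:
    """The fixed cutpoint set for 4- or 5-category items."""
    key = (int(categories), bool(skewed))
    if key not in THRESHOLDS:
        raise ValueError(f"unsupported category count {categories}")
    return ThresholdSet(categories=key[0], skewed=key[1], cutpoints=THRESHOLDS[key])


@dataclass
class OrdinalDataset:
    """n x p matrix of 1..C category codes plus its generating condition."""

    values: np.ndarray
    condition: Optional[ConditionSpec] = None
    truth: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be an n x p matrix")
        if self.values.min() < 1:
            raise ValueError("category codes start at 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        cols = [f"item{j + 1}" for j in range(self.p)]
        pd.DataFrame(self.values, columns=cols).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, condition=None, truth=None) -> "OrdinalDataset":
        values = pd.read_csv(path).to_numpy(dtype=np.int64)
        return cls(values=values, condition=condition, truth=truth)


def sample_normal(Sigma: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. rows from N(0, Sigma) via a Cholesky factor."""
    Sigma = np.asarray(Sigma, dtype=float)
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Sigma must be positive definite") from exc
    return rng.standard_normal((int(n), Sigma.shape[0])) @ L.T


def fleishman_coefficients(skew: float, exkurt: float) -> tuple[float, float, float, float]:
    """Coefficients (a, b, c, d) with a = -c for Y = a + bZ + cZ^2 + dZ^3.

    Y has mean 0, variance 1, the requested skewness and excess kurtosis.
    Raises :class:`InfeasibleMomentsError` outside the attainable region.
    """

    def equations(v):
        b, c, d = v
        f1 = b * b + 6 * b * d + 2 * c * c + 15 * d * d - 1.0
        f2 = 2 * c * (b * b + 24 * b * d + 105 * d * d + 2) - skew
        f3 = 24 * (
            b * d
            + c * c * (1 + b * b + 28 * b * d)
            + d * d * (12 + 48 * b * d + 141 * c * c + 225 * d * d)
        ) - exkurt
        return (f1, f2, f3)

    for start in ((1.0, 0.0, 0.0), (0.9, skew / 6.0, 0.01), (0.75, 0.3, 0.05)):
        sol, info, ier, _ = optimize.fsolve(equations, start, full_output=True)
        if ier == 1 and np.max(np.abs(info["fvec"])) < 1e-10:
            b, c, d = sol
            return (-c, b, c, d)
    raise InfeasibleMomentsError(
        f"no Fleishman solution for skewness {skew}, excess kurtosis {exkurt}"
    )


def _fleishman_transform(Z: np.ndarray, coef) -> np.ndarray:
    a, b, c, d = coef
    return a + Z * (b + Z * (c + Z * d))


def _ig_component_moments(A: np.ndarray, skew: float, exkurt: float):
    """Per-component (skew, exkurt) so that X = V A' hits the marginal targets.

    Third/fourth cumulants of independent components add through the cubed
    and fourth-powered mixing weights, giving two triangular linear systems.
    """
    g1 = np.linalg.solve(A**3, np.full(A.shape[0], float(skew)))
    g2 = np.linalg.solve(A**4, np.full(A.shape[0], float(exkurt)))
    return g1, g2


def _vale_maurelli_intermediate(rho: float, coef) -> float:
    """Intermediate normal correlation reproducing rho after the transform."""
    _, b, c, d = coef
    c1 = b * b + 6 * b * d + 9 * d * d
    c2 = 2 * c * c
    c3 = 6 * d * d
    roots = np.roots([c3, c2, c1, -rho])
    real = roots[np.abs(roots.imag) < 1e-8].real
    real = real[(real >= -1.0) & (real <= 1.0)]
    if real.size == 0:
        raise InfeasibleMomentsError(f"no intermediate correlation for rho={rho}")
    return float(real[np.argmin(np.abs(real - rho))])


def sample_nonnormal(
    Sigma: np.ndarray,
    n: int,
    rng: np.random.Generator,
    skew: float = 2.0,
    exkurt: float = 7.0,
    method: str = "auto",
) -> np.ndarray:
    """Non-normal data with covariance Sigma and target marginal moments.

    ``method``: "ig", "vm" (Vale-Maurelli), or "auto" (IG with VM fallback).
    """
    Sigma = np.asarray(Sigma, dtype=float)
    p = Sigma.shape[0]
    try:
        A = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Sigma must be positive definite") from exc

    if skew == 0.0 and exkurt == 0.0:
        return sample_normal(Sigma, n, rng)

    if method not in ("auto", "ig", "vm"):
        raise ValueError(f"unknown method {method!r}")

    if method in ("auto", "ig"):
        try:
            g1, g2 = _ig_component_moments(A, skew, exkurt)
            coefs = [fleishman_coefficients(g1[i], g2[i]) for i in range(p)]
            Z = rng.standard_normal((int(n), p))
            V = np.column_stack(
                [_fleishman_transform(Z[:, i], coefs[i]) for i in range(p)]
            )
            return V @ A.T
        except InfeasibleMomentsError:
            if method == "ig":
                raise

    # Vale-Maurelli: common marginal transform, matched intermediate correlations
    coef = fleishman_coefficients(skew, exkurt)
    Rz = np.eye(p)
    for i in range(p):
        for j in range(i):
            r = _vale_maurelli_intermediate(Sigma[i, j], coef)
            Rz[i, j] = Rz[j, i] = r
    w, U = np.linalg.eigh(Rz)
    if w[0] <= 1e-8:  # clip to keep the intermediate matrix PD
        w = np.clip(w, 1e-8, None)
        Rz = U @ np.diag(w) @ U.T
        d = np.sqrt(np.diag(Rz))
        Rz = Rz / np.outer(d, d)
    Z = sample_normal(Rz, n, rng)
    return _fleishman_transform(Z, coef)


def discretize(
    X: np.ndarray,
    thresholds: ThresholdSet,
    condition: Optional[ConditionSpec] = None,
    truth: Optional[int] = None,
) -> OrdinalDataset:
    """Assign category c where tau_{c-1} < x <= tau_c (tau_0/tau_C infinite)."""
    cut = np.asarray(thresholds.cutpoints, dtype=float)
    codes = np.searchsorted(cut, np.asarray(X, dtype=float), side="left") + 1
    return OrdinalDataset(values=codes.astype(np.int64), condition=condition, truth=truth)


def generate_dataset(cond: ConditionSpec, rng=None) -> OrdinalDataset:
    """Full generator for one condition: model draw, continuous sample, discretise.

    A pure function of (cond, seed): ``rng`` defaults to a generator seeded
    with ``cond.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(cond.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    model = draw_factor_model(cond, rng)
    if cond.nonnormal:
        X = sample_nonnormal(model.Sigma, cond.n, rng)
    else:
        X = sample_normal(model.Sigma, cond.n, rng)
    tset = threshold_table(cond.categories, cond.skewed_thresholds)
    return discretize(X, tset, condition=cond, truth=cond.m)
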