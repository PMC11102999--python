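"""Population factor models for ordinal-data dimensionality simulations.

A simulation condition fixes the design of a common-factor model
``Sigma = Lambda Phi Lambda' + diag(Psi)``: the number of factors m,
indicators per factor k, uniform ranges for primary and cross loadings,
a compound-symmetric factor correlation rho, the sample size, number of
ordinal categories and the type of underlying continuous distribution.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np

PRIMARY_RANGES: Mapping[str, tuple[float, float]] = {
    "low": (0.35, 0.50),
    "medium": (0.50, 0.65),
    "high": (0.65, 0.80),
}
CROSS_RANGES: Mapping[str, tuple[float, float]] = {
    "low": (0.0, 0.10),
    "medium": (0.10, 0.20),
    "high": (0.20, 0.30),
}
SAMPLE_SIZES = (300, 600, 1000)
N_FACTORS = (1, 2, 4)
INDICATORS = (5, 10)
RHOS = (0.0, 0.3, 0.6)
CATEGORIES = (4, 5)
DIST_TYPES = ("normal", "normal-skewed", "non-normal", "non-normal-skewed")


class ImproperModelError(RuntimeError):
    """Raised when no proper loading draw is found within the retry budget."""


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the simulation design.

    ``primary_level`` / ``cross_level`` are labels mapping to uniform
    loading ranges (low/medium/high); ``cross_level`` is inert when m=1.
    ``dist_type`` combines the underlying continuous distribution
    (normal vs non-normal with skewness 2, excess kurtosis 7) with the
    threshold shape used for discretisation ("-skewed" = asymmetric).
    """

    n: int
    m: int
    k: int
    primary_level: str
    cross_level: str
    rho: float
    categories: int
    dist_type: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n not in SAMPLE_SIZES:
            raise ValueError(f"n must be one of {SAMPLE_SIZES}, got {self.n}")
        if self.m not in N_FACTORS:
            raise ValueError(f"m must be one of {N_FACTORS}, got {self.m}")
        if self.k not in INDICATORS:
            raise ValueError(f"k must be one of {INDICATORS}, got {self.k}")
        if self.primary_level not in PRIMARY_RANGES:
            raise ValueError(f"unknown primary_level {self.primary_level!r}")
        if self.cross_level not in CROSS_RANGES:
            raise ValueError(f"unknown cross_level {self.cross_level!r}")
        if float(self.rho) not in RHOS:
            raise ValueError(f"rho must be one of {RHOS}, got {self.rho}")
        if self.m == 1 and self.rho != 0:
            raise ValueError("a single-factor model requires rho = 0")
        if self.categories not in CATEGORIES:
            raise ValueError(f"categories must be one of {CATEGORIES}")
        if self.dist_type not in DIST_TYPES:
            raise ValueError(f"unknown dist_type {self.dist_type!r}")

    @property
    def p(self) -> int:
        """Total number of items."""
        return self.m * self.k

    @property
    def nonnormal(self) -> bool:
        return self.dist_type.startswith("non-normal")

    @property
    def skewed_thresholds(self) -> bool:
        return self.dist_type.endswith("-skewed")

    def condition_id(self) -> int:
        """Stable mixed-radix index into the full factorial grid."""
        digits = (
            SAMPLE_SIZES.index(self.n),
            INDICATORS.index(self.k),
            N_FACTORS.index(self.m),
            RHOS.index(float(self.rho)),
            tuple(PRIMARY_RANGES).index(self.primary_level),
            tuple(CROSS_RANGES).index(self.cross_level),
            DIST_TYPES.index(self.dist_type),
            CATEGORIES.index(self.categories),
        )
        radices = (3, 2, 3, 3, 3, 3, 4, 2)
        cid = 0
        for d, r in zip(digits, radices):
            cid = cid * r + d
        return cid

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, row: Mapping) -> "ConditionSpec":
        return cls(
            n=int(row["n"]),
            m=int(row["m"]),
            k=int(row["k"]),
            primary_level=str(row["primary_level"]),
            cross_level=str(row["cross_level"]),
            rho=float(row["rho"]),
            categories=int(row["categories"]),
            dist_type=str(row["dist_type"]),
            seed=int(row.get("seed", 0)),
        )


@dataclass
class FactorModel:
    """Loadings, factor correlations, uniquenesses and implied Sigma."""

    Lambda: np.ndarray
    Phi: np.ndarray
    Psi: np.ndarray
    Sigma: np.ndarray
    proper: bool = True

    @property
    def p(self) -> int:
        return self.Lambda.shape[0]

    @property
    def m(self) -> int:
        return self.Lambda.shape[1]


def build_population_matrix(Lambda: np.ndarray, Phi: np.ndarray) -> FactorModel:
    """Complete a factor model: Psi_i = 1 - (Lambda Phi Lambda')_ii, then Sigma.

    Propriety (all Psi_i > 0 and Sigma positive definite) is reported via
    ``FactorModel.proper`` rather than raised, so callers can redraw.
    """
    Lambda = np.asarray(Lambda, dtype=float)
    if Lambda.ndim == 1:
        Lambda = Lambda[:, None]
    Phi = np.asarray(Phi, dtype=float)
    if not np.all(np.isfinite(Lambda)):
        raise ValueError("Lambda must be finite")
    if Phi.shape != (Lambda.shape[1],) * 2 or not np.allclose(Phi, Phi.T):
        raise ValueError("Phi must be a symmetric m x m matrix")
    if not np.allclose(np.diag(Phi), 1.0):
        raise ValueError("Phi must have a unit diagonal")

    common = Lambda @ Phi @ Lambda.T
    Psi = 1.0 - np.diag(common)
    Sigma = common + np.diag(Psi)
    Sigma = (Sigma + Sigma.T) / 2.0
    proper = bool(np.all(Psi > 0))
    if proper:
        proper = bool(np.linalg.eigvalsh(Sigma)[0] > 0)
    return FactorModel(Lambda=Lambda, Phi=Phi, Psi=Psi, Sigma=Sigma, proper=proper)


def compound_symmetric(m: int, rho: float) -> np.ndarray:
    Phi = np.full((m, m), float(rho))
    np.fill_diagonal(Phi, 1.0)
    return Phi


def draw_factor_model(
    cond: ConditionSpec,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> FactorModel:
    """Draw loadings for a condition, redrawing improper models.

    Each item loads on exactly one primary factor (uniform in the range of
    ``primary_level``) and, when m > 1, receives one cross-loading on the
    cyclically-next factor (uniform in the range of ``cross_level``).
    Raises :class:`ImproperModelError` once the retry budget is exhausted.
    """
    lo_p, hi_p = PRIMARY_RANGES[cond.primary_level]
    lo_c, hi_c = CROSS_RANGES[cond.cross_level]
    Phi = compound_symmetric(cond.m, cond.rho)
    p = cond.p
    for _ in range(max_retries):
        Lambda = np.zeros((p, cond.m))
        for f in range(cond.m):
            rows = slice(f * cond.k, (f + 1) * cond.k)
            Lambda[rows, f] = rng.uniform(lo_p, hi_p, size=cond.k)
            if cond.m > 1:
                Lambda[rows, (f + 1) % cond.m] = rng.uniform(lo_c, hi_c, size=cond.k)
        model = build_population_matrix(Lambda, Phi)
        if model.proper:
            return model
    raise ImproperModelError(
        f"no proper loading draw in {max_retries} attempts for condition "
        f"(m={cond.m}, rho={cond.rho}, primary={cond.primary_level}, "
        f"cross={cond.cross_level})"
    )
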