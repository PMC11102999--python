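"""Two-step maximum-likelihood polychoric correlations.

Step one estimates per-item thresholds as normal quantiles of cumulative
category proportions; step two maximises each pair's contingency-table
likelihood over the latent correlation, holding thresholds fixed.  The
assembled matrix is repaired to positive definiteness by eigenvalue
clipping when needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from . import _polycore
from ._polycore import BIG, RHO_CAP, STATUS_BOUNDARY, STATUS_FALLBACK, STATUS_OK
from .generate import OrdinalDataset

PD_EPS = 1e-4
_STATUS_NAMES = {STATUS_OK: "ok", STATUS_BOUNDARY: "boundary", STATUS_FALLBACK: "fallback"}


class DegenerateColumnError(ValueError):
    """A column with fewer than two observed categories."""


@dataclass
class PolychoricMatrix:
    """Estimated latent correlation matrix with per-pair diagnostics."""

    R: np.ndarray
    repaired: bool
    pairwise_estimates: pd.DataFrame = field(repr=False, default=None)

    @property
    def p(self) -> int:
        return self.R.shape[0]

    def to_csv(self, path, items=None) -> None:
        items = items or [f"item{j + 1}" for j in range(self.p)]
        pd.DataFrame(self.R, index=items, columns=items).to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "PolychoricMatrix":
        R = pd.read_csv(path, index_col=0).to_numpy(dtype=float)
        return cls(R=R, repaired=False)


def estimate_thresholds(column: np.ndarray, C: int) -> np.ndarray:
    """Thresholds tau_c = Phi^{-1}(cumulative proportion through category c).

    Empty categories are collapsed into the adjacent lower category, so the
    returned vector may be shorter than C - 1.
    """
    column = np.asarray(column)
    counts = np.bincount(column, minlength=C + 1)[1:]
    nonzero = counts[counts > 0]
    if nonzero.size < 2:
        raise DegenerateColumnError("column has a single observed category")
    cum = np.cumsum(nonzero) / column.size
    return ndtri(cum[:-1])


def _collapse_codes(values: np.ndarray, C: int):
    """0-based codes with empty categories removed, plus thresholds per column."""
    n, p = values.shape
    codes = np.empty((n, p), dtype=np.int64)
    ncat = np.empty(p, dtype=np.int64)
    max_c = 0
    taus = []
    bad = []
    for j in range(p):
        col = values[:, j]
        counts = np.bincount(col, minlength=C + 1)[1:]
        keep = np.flatnonzero(counts > 0)
        if keep.size < 2:
            bad.append(j)
            taus.append(np.empty(0))
            ncat[j] = keep.size
            continue
        remap = np.full(C + 1, -1, dtype=np.int64)
        remap[keep + 1] = np.arange(keep.size)
        codes[:, j] = remap[col]
        ncat[j] = keep.size
        cum = np.cumsum(counts[keep]) / n
        taus.append(ndtri(cum[:-1]))
        max_c = max(max_c, keep.size)
    if bad:
        raise DegenerateColumnError(
            f"degenerate (single-category) columns: {bad}"
        )
    tau = np.full((p, max_c + 1), BIG)
    tau[:, 0] = -BIG
    for j in range(p):
        tj = taus[j]
        tau[j, 1 : 1 + tj.size] = tj
        tau[j, 1 + tj.size] = BIG
    return codes, ncat, tau


def estimate_polychoric(
    table: np.ndarray,
    tx: np.ndarray,
    ty: np.ndarray,
    rho_cap: float = RHO_CAP,
    xtol: float = 1e-6,
) -> float:
    """ML latent correlation for one contingency table with fixed thresholds.

    ``tx``/``ty`` are the finite interior cutpoints (lengths C_x - 1, C_y - 1).
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("table must be nonnegative")
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    if rows.sum() < 2 or cols.sum() < 2:
        raise ValueError("table needs mass in at least two rows and two columns")
    c1, c2 = table.shape
    txp = np.concatenate(([-BIG], np.asarray(tx, dtype=float), [BIG]))
    typ = np.concatenate(([-BIG], np.asarray(ty, dtype=float), [BIG]))
    rho, nll = _polycore.fit_rho(table, txp, typ, c1, c2, -rho_cap, rho_cap, xtol)
    if not np.isfinite(nll):
        raise RuntimeError("likelihood not finite; estimation failed")
    if rho > rho_cap - 1e-3:
        return rho_cap
    if rho < -rho_cap + 1e-3:
        return -rho_cap
    return float(rho)


def _repair_pd(R: np.ndarray, eps: float = PD_EPS):
    """Clip eigenvalues below eps and rescale to unit diagonal."""
    w, U = np.linalg.eigh(R)
    if w[0] >= eps:
        return R, False
    w = np.clip(w, eps, None)
    R2 = U @ np.diag(w) @ U.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return (R2 + R2.T) / 2.0, True


def polychoric_matrix(
    data,
    rho_cap: float = RHO_CAP,
    xtol: float = 1e-6,
    eps: float = PD_EPS,
) -> PolychoricMatrix:
    """Pairwise polychoric correlation matrix of an ordinal dataset.

    Accepts an :class:`OrdinalDataset` or a plain integer matrix of 1..C
    codes.  Raises :class:`DegenerateColumnError` when a column has fewer
    than two observed categories.
    """
    if isinstance(data, OrdinalDataset):
        values = data.values
        C = data.condition.categories if data.condition is not None else int(values.max())
    else:
        values = np.asarray(data, dtype=np.int64)
        C = int(values.max())
    if values.shape[1] < 2:
        raise ValueError("need at least two items")
    codes, ncat, tau = _collapse_codes(values, C)
    R, status = _polycore.poly_matrix_kernel(codes, ncat, tau, rho_cap, xtol)
    iu = np.triu_indices(values.shape[1], 1)
    pairs = pd.DataFrame(
        {
            "i": iu[0],
            "j": iu[1],
            "rho": R[iu],
            "status": [_STATUS_NAMES[s] for s in status[iu]],
        }
    )
    R, repaired = _repair_pd(R, eps)
    return PolychoricMatrix(R=R, repaired=repaired, pairwise_estimates=pairs)
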