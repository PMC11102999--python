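"""Parallel analysis with polychoric correlations.

Observed principal-component eigenvalues of the polychoric matrix are
compared position by position with reference eigenvalues obtained by
independently permuting each ordinal column (which preserves every
column's category margins) and re-running the polychoric + PCA pipeline.
Components are retained while the observed eigenvalue exceeds the
reference statistic (mean or 95th percentile) at every earlier position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _polycore
from .generate import OrdinalDataset
from .polychoric import _collapse_codes, _repair_pd, polychoric_matrix

RULES = ("mean", "q95")


@dataclass
class PAResult:
    observed_eigs: np.ndarray
    ref_mean: np.ndarray
    ref_q95: np.ndarray
    n_retained: int
    rule: str
    n_iter: int = 0

    def to_frame(self, n_lead: int = 3) -> pd.DataFrame:
        row = {"rule": self.rule, "n_iter": self.n_iter, "n_retained": self.n_retained}
        for i in range(min(n_lead, self.observed_eigs.size)):
            row[f"eig{i + 1}"] = self.observed_eigs[i]
        return pd.DataFrame([row])


def pca_eigenvalues(R: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of a correlation matrix (full spectrum)."""
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    return np.sort(np.linalg.eigvalsh(R))[::-1]


def reference_eigenvalues(
    data,
    n_iter: int,
    rng: np.random.Generator,
    max_retries: int = 3,
):
    """Positionwise mean and 95th percentile of permutation-reference spectra."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if isinstance(data, OrdinalDataset):
        values = data.values
        C = data.condition.categories if data.condition is not None else int(values.max())
    else:
        values = np.asarray(data, dtype=np.int64)
        C = int(values.max())
    codes, ncat, tau = _collapse_codes(values, C)
    n, p = codes.shape
    spectra = np.empty((n_iter, p))
    for it in range(n_iter):
        for attempt in range(max_retries):
            perm = np.empty_like(codes)
            for j in range(p):
                perm[:, j] = codes[rng.permutation(n), j]
            R, _ = _polycore.poly_matrix_kernel(perm, ncat, tau, _polycore.RHO_CAP, 1e-6)
            R, _ = _repair_pd(R)
            eigs = np.linalg.eigvalsh(R)
            if np.all(np.isfinite(eigs)):
                spectra[it] = np.sort(eigs)[::-1]
                break
        else:
            raise RuntimeError("reference iterate failed repeatedly")
    return spectra.mean(axis=0), np.quantile(spectra, 0.95, axis=0)


def pa_retain(observed: np.ndarray, reference: np.ndarray, rule: str = "mean") -> int:
    """Largest m with observed_i > reference_i for every i <= m (stop at first failure)."""
    observed = np.asarray(observed, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if observed.shape != reference.shape:
        raise ValueError("observed and reference must have the same length")
    n = 0
    for obs, ref in zip(observed, reference):
        if obs > ref:
            n += 1
        else:
            break
    return n


def pa_nfactors(
    data,
    rng: np.random.Generator,
    rule: str = "mean",
    n_iter: int = 20,
) -> PAResult:
    """Full polychoric parallel analysis of an ordinal dataset."""
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    R = polychoric_matrix(data).R
    observed = pca_eigenvalues(R)
    ref_mean, ref_q95 = reference_eigenvalues(data, n_iter, rng)
    reference = ref_mean if rule == "mean" else ref_q95
    return PAResult(
        observed_eigs=observed,
        ref_mean=ref_mean,
        ref_q95=ref_q95,
        n_retained=pa_retain(observed, reference, rule),
        rule=rule,
        n_iter=n_iter,
    )
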