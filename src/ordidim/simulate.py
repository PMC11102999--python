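"""Monte-Carlo driver: condition grid, replications, accuracy metrics, GLM summary.

The full factorial design crosses sample size (3) x indicators per factor
(2) x factors (3) x inter-factor correlation (3) x primary loadings (3) x
cross-loadings (3) x distribution type (4) x categories (2) = 3,888
conditions; single-factor conditions with nonzero inter-factor
correlation are excluded as meaningless.  Per replication both retention
methods see the same generated dataset; estimates are scored as correct /
underfactoring / overfactoring against the generating factor count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ega import EGAConfig, ega_nfactors
from .generate import generate_dataset
from .parallel import pa_nfactors
from .population import (
    CATEGORIES,
    CROSS_RANGES,
    DIST_TYPES,
    INDICATORS,
    N_FACTORS,
    PRIMARY_RANGES,
    RHOS,
    SAMPLE_SIZES,
    ConditionSpec,
    ImproperModelError,
)

logger = logging.getLogger(__name__)

METHODS = ("PA", "EGA")

RESULT_COLUMNS = [
    "condition_id", "n", "m", "k", "primary_level", "cross_level", "rho",
    "categories", "dist_type", "rep", "method", "estimated", "truth", "correct",
]

DESIGN_FACTORS = [
    "n", "m", "k", "primary_level", "cross_level", "rho", "categories", "dist_type",
]


@dataclass
class CellResult:
    condition: ConditionSpec
    rep: int
    method: str
    estimated: Optional[int]
    truth: int

    @property
    def correct(self) -> bool:
        return self.estimated is not None and self.estimated == self.truth

    @property
    def under(self) -> bool:
        return self.estimated is not None and self.estimated < self.truth

    @property
    def over(self) -> bool:
        return self.estimated is not None and self.estimated > self.truth

    def to_row(self) -> dict:
        c = self.condition
        return {
            "condition_id": c.condition_id(),
            "n": c.n, "m": c.m, "k": c.k,
            "primary_level": c.primary_level, "cross_level": c.cross_level,
            "rho": c.rho, "categories": c.categories, "dist_type": c.dist_type,
            "rep": self.rep, "method": self.method,
            "estimated": self.estimated, "truth": self.truth,
            "correct": int(self.correct),
        }


@dataclass
class AggregateReport:
    overall: pd.DataFrame
    per_cell: pd.DataFrame
    table1: pd.DataFrame = field(repr=False, default=None)


def build_grid(full: bool = True, overrides: Optional[Mapping[str, Sequence]] = None):
    """All conditions of the factorial design, with exclusions applied.

    ``overrides`` restricts individual design factors to subsets of their
    levels, e.g. ``{"n": [300], "dist_type": ["normal"]}``.
    """
    levels = {
        "n": list(SAMPLE_SIZES),
        "k": list(INDICATORS),
        "m": list(N_FACTORS),
        "rho": list(RHOS),
        "primary_level": list(PRIMARY_RANGES),
        "cross_level": list(CROSS_RANGES),
        "dist_type": list(DIST_TYPES),
        "categories": list(CATEGORIES),
    }
    if overrides:
        for key, vals in overrides.items():
            if key not in levels:
                raise KeyError(f"unknown design factor {key!r}")
            vals = list(vals)
            bad = [v for v in vals if v not in levels[key]]
            if bad:
                raise ValueError(f"invalid levels for {key}: {bad}")
            levels[key] = vals
    grid = []
    for combo in itertools.product(*levels.values()):
        row = dict(zip(levels, combo))
        if row["m"] == 1 and row["rho"] != 0:
            continue  # excluded: meaningless crossing
        grid.append(ConditionSpec(**row))
    return grid


def full_crossing_size() -> int:
    """Size of the unrestricted factorial crossing (before exclusions)."""
    return 3 * 2 * 3 * 3 * 3 * 3 * 4 * 2


def _run_method(method: str, data, rng, ega_config, pa_rule, pa_n_iter):
    if method == "PA":
        return int(pa_nfactors(data, rng, rule=pa_rule, n_iter=pa_n_iter).n_retained)
    if method == "EGA":
        return int(ega_nfactors(data, rng, config=ega_config).n_factors)
    raise ValueError(f"unknown method {method!r}")


def run_cell(
    cond: ConditionSpec,
    reps: int,
    methods: Iterable[str] = METHODS,
    seed: int = 0,
    ega_config: Optional[EGAConfig] = None,
    pa_rule: str = "mean",
    pa_n_iter: int = 20,
):
    """Replicate one condition; returns a list of :class:`CellResult`.

    Per-replication seeds derive deterministically from
    (seed, condition_id, rep), so any cell can be reproduced in isolation.
    A condition whose loading draws are never proper yields an empty list
    (the infeasible / "n/a" case); method failures within a replication
    are logged and recorded as missing estimates.
    """
    methods = list(methods)
    cid = cond.condition_id()
    results: list[CellResult] = []
    for rep in range(int(reps)):
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(cid, rep))
        rng_data, rng_pa, rng_ega = (np.random.default_rng(s) for s in ss.spawn(3))
        try:
            data = generate_dataset(cond, rng_data)
        except ImproperModelError:
            logger.warning("condition %d infeasible (improper model); cell is n/a", cid)
            return []
        for method in methods:
            rng_m = rng_pa if method == "PA" else rng_ega
            try:
                est = _run_method(method, data, rng_m, ega_config, pa_rule, pa_n_iter)
            except Exception:
                logger.exception("%s failed on condition %d rep %d", method, cid, rep)
                est = None
            results.append(
                CellResult(condition=cond, rep=rep, method=method, estimated=est,
                           truth=cond.m)
            )
    return results


def results_to_frame(results: Iterable[CellResult]) -> pd.DataFrame:
    rows = [r.to_row() for r in results]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df["estimated"] = df["estimated"].astype("Int64")
    return df


def run_grid(
    grid: Sequence[ConditionSpec],
    reps: int,
    methods: Iterable[str] = METHODS,
    seed: int = 0,
    ega_config: Optional[EGAConfig] = None,
    pa_rule: str = "mean",
    pa_n_iter: int = 20,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every condition of a grid and stack per-replication rows."""
    all_results: list[CellResult] = []
    for idx, cond in enumerate(grid):
        if progress:
            logger.info("condition %d/%d (id %d)", idx + 1, len(grid), cond.condition_id())
        all_results.extend(
            run_cell(cond, reps, methods, seed, ega_config, pa_rule, pa_n_iter)
        )
    return results_to_frame(all_results)


def _score(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    est = df["estimated"]
    df["correct"] = (est.notna() & (est == df["truth"])).astype(int)
    df["under"] = (est.notna() & (est < df["truth"])).astype(int)
    df["over"] = (est.notna() & (est > df["truth"])).astype(int)
    df["missing"] = est.isna().astype(int)
    return df


def evaluate(results, by: Optional[Sequence[str]] = None) -> AggregateReport:
    """Accuracy / underfactoring / overfactoring percentages.

    ``overall`` aggregates per method; ``per_cell`` per method x condition
    (or per the factors in ``by``); ``table1`` is a wide pivot shaped like
    the study's summary table: rows = distribution x m x rho x loading
    levels, columns = method x k x n, averaged over the category factor.
    """
    df = results_to_frame(results) if not isinstance(results, pd.DataFrame) else results
    if df.empty:
        raise ValueError("no results to evaluate")
    df = _score(df)
    agg = {"correct": "mean", "under": "mean", "over": "mean", "missing": "mean"}

    def _pct(frame):
        out = frame.agg(agg) * 100.0
        return out.rename(
            columns={"correct": "accuracy", "under": "underfactoring",
                     "over": "overfactoring"}
        )

    overall = _pct(df.groupby("method")).reset_index()
    cell_by = ["method"] + (list(by) if by else DESIGN_FACTORS)
    per_cell = _pct(df.groupby(cell_by)).reset_index()

    piv = df.copy()
    piv["acc"] = piv["correct"] * 100.0
    table1 = piv.pivot_table(
        index=["dist_type", "m", "rho", "primary_level", "cross_level"],
        columns=["method", "k", "n"],
        values="acc",
        aggfunc="mean",
    )
    return AggregateReport(overall=overall, per_cell=per_cell, table1=table1)


def logistic_summary(results, ridge: float = 0.0) -> pd.DataFrame:
    """Logistic model of correctness: method main effect + method x factor
    two-way interactions, with dummy-coded design factors.

    Returns a coefficient table with odds ratios.  Constant factors are
    dropped with a logged notice; an aliased (rank-deficient) design
    raises with the offending columns named.  ``ridge`` > 0 switches to an
    L2-stabilised fit for separated data.
    """
    import statsmodels.api as sm

    df = results_to_frame(results) if not isinstance(results, pd.DataFrame) else results
    df = _score(df)
    if df["method"].nunique() < 2:
        raise ValueError("need at least two methods for the comparison model")

    factors = []
    for f in DESIGN_FACTORS:
        if df[f].nunique() > 1:
            factors.append(f)
        else:
            logger.info("design factor %r has a single level; dropped from the model", f)

    X = pd.DataFrame({"Intercept": np.ones(len(df))})
    method_levels = sorted(df["method"].unique())
    method_dummy = (df["method"] == method_levels[1]).astype(float)
    X[f"method[{method_levels[1]}]"] = method_dummy
    for f in factors:
        dummies = pd.get_dummies(df[f].astype(str), prefix=f, drop_first=True).astype(float)
        for col in dummies:
            X[col] = dummies[col]
            X[f"method[{method_levels[1]}]:{col}"] = method_dummy * dummies[col]

    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, _, piv = qr(X.to_numpy(), pivoting=True)
        aliased = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"non-identifiable model; aliased terms: {aliased}")

    model = sm.GLM(df["correct"].to_numpy(), X, family=sm.families.Binomial())
    if ridge > 0:
        fit = model.fit_regularized(alpha=ridge, L1_wt=0.0)
        params = pd.Series(fit.params, index=X.columns)
        out = pd.DataFrame({"coef": params, "odds_ratio": np.exp(params)})
    else:
        fit = model.fit()
        out = pd.DataFrame(
            {
                "coef": fit.params,
                "se": fit.bse,
                "odds_ratio": np.exp(fit.params),
                "or_low": np.exp(fit.conf_int()[0]),
                "or_high": np.exp(fit.conf_int()[1]),
            }
        )
        if not fit.converged:
            logger.warning("GLM did not converge (possible separation); "
                           "consider ridge > 0")
    out.index.name = "term"
    return out.reset_index()
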