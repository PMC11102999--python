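import numpy as np
import pytest

import ordidim as od


@pytest.fixture(scope="session")
def stratified_results():
    """Both methods on a stratified subgrid: one n=300, k=5, 4-category,
    normal-data condition per stratum of m x rho x primary-loading level,
    20 replications each.  Shared across the aggregate-level tests."""
    strata = []
    for m in (1, 2, 4):
        for rho in (0.0, 0.3, 0.6):
            if m == 1 and rho != 0:
                continue
            for prim in ("low", "medium", "high"):
                strata.append(
                    od.ConditionSpec(
                        n=300, m=m, k=5, primary_level=prim,
                        cross_level="medium" if m > 1 else "low",
                        rho=rho, categories=4, dist_type="normal",
                    )
                )
    return od.run_grid(strata, reps=20, methods=["PA", "EGA"], seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
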