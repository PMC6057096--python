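import numpy as np
import pytest

import polyglia as pg


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort():
    """A 300-subject cohort with a planted single driver, fully wired."""
    spec = pg.ArchitectureSpec.single_driver(20, seed=42)
    gm = pg.simulate_genotypes(spec, 300, missing_rate=0.02)
    cov = pg.simulate_covariates(300, seed=42)
    pheno, truth = pg.simulate_phenotypes(gm, spec, cov)
    table = pg.weight_table(spec, "trait")
    return dict(spec=spec, genotypes=gm, covariates=cov, phenotypes=pheno, truth=truth, table=table)


def ols_fit(y, X):
    """Closed-form OLS oracle: (beta, se, t) via the normal equations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    s2 = resid @ resid / (n - p)
    se = np.sqrt(s2 * np.diag(xtx_inv))
    return beta, se, beta / se


@pytest.fixture
def make_design(rng):
    def _make(n=100, p=3, noise=1.0, beta=None):
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        if beta is None:
            beta = np.arange(1, p + 1, dtype=float)
        y = X @ beta + noise * rng.normal(size=n)
        return y, X, np.asarray(beta, dtype=float)

    return _make
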