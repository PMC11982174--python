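import numpy as np
import pytest
from scipy import stats

import trialbayes as tb
from trialbayes import datasets


@pytest.fixture(scope="session")
def packaged_estimates():
    """Reconstructed effect estimates for the two packaged subgroups."""
    return [tb.effect_from_summary(s) for s in datasets.subgroup_summaries()]


@pytest.fixture(scope="session")
def packaged_fit():
    """Meta-analysis fit of the packaged studies under the default priors."""
    return tb.fit_nnhm(datasets.meta_studies())


@pytest.fixture(scope="session")
def packaged_fit_jeffreys():
    return tb.fit_nnhm(datasets.meta_studies(), tau_prior=tb.jeffreys_prior())


def mc_bf10(t, n_a, n_b, prior, n_draws, rng, df_convention="total"):
    """Monte-Carlo prior-predictive estimate of BF10, independent of the
    quadrature path: average the noncentral-t likelihood over prior draws.

    The likelihood is evaluated with scipy's noncentral-t density wherever
    scipy returns a finite value (it fails at large df with moderate-to-large
    noncentrality); the failed evaluations, all far out in the likelihood's
    Gaussian-decaying tail, are filled with the package's stable log-density,
    which is required to agree with scipy on the finite subset.  Draws with
    noncentrality more than 40 from t contribute densities below 1e-300 and
    count as zero.

    Returns (estimate, monte-carlo standard error).
    """
    import warnings

    from trialbayes._nct import log_nct_pdf

    df = n_a + n_b if df_convention == "total" else n_a + n_b - 2
    n_eff = n_a * n_b / (n_a + n_b)
    delta = prior.rvs(n_draws, rng)
    nc = delta * np.sqrt(n_eff)
    vals = np.zeros(n_draws)
    safe_idx = np.flatnonzero(np.abs(nc - t) < 40.0)
    scipy_ok = np.zeros(n_draws, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for chunk in np.array_split(safe_idx, max(1, safe_idx.size // 4096)):
            try:
                v = stats.nct.pdf(t, df, nc[chunk])
            except OverflowError:
                continue
            ok = np.isfinite(v)
            vals[chunk[ok]] = v[ok]
            scipy_ok[chunk[ok]] = True
    fill = np.zeros(n_draws, dtype=bool)
    fill[safe_idx] = True
    fill &= ~scipy_ok
    if fill.any():
        vals[fill] = np.exp(log_nct_pdf(t, df, nc[fill]))
    # cross-validate the two density implementations where both work
    finite = scipy_ok & (vals > 1e-280)
    sample = np.flatnonzero(finite)[:: max(1, int(finite.sum()) // 500)]
    if sample.size:
        ours = np.exp(log_nct_pdf(t, df, nc[sample]))
        np.testing.assert_allclose(vals[sample], ours, rtol=1e-6)
    m0 = stats.t.pdf(t, df)
    bf = vals.mean() / m0
    se = vals.std(ddof=1) / np.sqrt(n_draws) / m0
    return bf, se
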