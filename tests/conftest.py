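import numpy as np
import pytest

from biokin.expofit import FitResult, LU177_LAMBDA_PHYS, model_from_params, n_free_params


def make_fit(form, params, cov=None, n_points=10, lambda_phys=LU177_LAMBDA_PHYS, **kw):
    """Assemble a FitResult directly from parameters (no optimisation)."""
    params = np.asarray(params, dtype=float)
    k = n_free_params(form)
    if cov is None:
        cov = np.zeros((k, k))
    return FitResult(
        model=model_from_params(form, params, lambda_phys),
        form=form,
        params=params,
        covariance=np.asarray(cov, dtype=float),
        aicc=0.0,
        n_points=n_points,
        **kw,
    )


def random_valid_model(rng, forms=("mono", "bi", "bi_uptake")):
    """A random (form, params) pair satisfying the rate-floor and sign rules."""
    form = forms[rng.integers(len(forms))]
    if form == "mono":
        params = np.array([rng.uniform(1, 100), rng.uniform(2e-2, 1.0)])
    elif form == "bi":
        params = np.array(
            [rng.uniform(1, 50), rng.uniform(0.1, 1.0), rng.uniform(1, 50), rng.uniform(5e-3, 5e-2)]
        )
    else:
        params = np.array([rng.uniform(1, 50), rng.uniform(5e-3, 5e-2), rng.uniform(0.1, 1.0)])
    return form, params


def random_delta_regime_fit(rng, forms=("mono", "bi", "bi_uptake"), param_cv=0.02):
    """A random fit with a random PSD covariance scaled to ~param_cv per
    parameter, i.e. inside the regime where first-order propagation holds."""
    form, params = random_valid_model(rng, forms)
    k = n_free_params(form)
    g = rng.normal(size=(k, k))
    cov = g @ g.T
    s = param_cv * np.abs(params) / np.sqrt(np.diag(cov))
    cov = cov * np.outer(s, s)
    return make_fit(form, params, cov)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
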