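"""Independent numerical oracles used to validate the model machinery.

The marginal likelihood oracle integrates the Poisson-lognormal mixture by
adaptive quadrature, group by group, with no shared code with the Laplace
implementation it checks.
"""

import numpy as np
from scipy import integrate, special


def exact_marginal_loglik_grouped_intercept(y, eta0, groups, sd):
    """Exact marginal log-likelihood for a single normal random intercept.

    Model: y_i ~ Poisson(exp(eta0_i + u_{g(i)})), u_g ~ N(0, sd^2) iid.
    Observation-level intercepts (OLRE) are the special case where every
    observation is its own group.  Computed as a product over groups of
    one-dimensional adaptive quadratures.
    """
    y = np.asarray(y, dtype=float)
    eta0 = np.asarray(eta0, dtype=float)
    groups = np.asarray(groups)
    ll = 0.0
    for g in np.unique(groups):
        mask = groups == g
        yg, eg = y[mask], eta0[mask]

        def integrand(u):
            logf = (
                np.sum(yg * (eg + u) - np.exp(eg + u) - special.gammaln(yg + 1))
                - 0.5 * u * u / sd**2
                - 0.5 * np.log(2 * np.pi * sd**2)
            )
            return np.exp(logf)

        val, _err = integrate.quad(integrand, -12 * sd, 12 * sd, limit=400)
        ll += np.log(val)
    return ll


def pearson_r_by_formula(x, y):
    """Pearson correlation from the raw definition (moment sums)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x * x).sum() - sx**2) * np.sqrt(n * (y * y).sum() - sy**2)
    return num / den
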