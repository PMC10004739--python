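"""Independent weighted-least-squares oracles for checking the estimators.

Built on statsmodels so the check does not share code with the package's
closed-form normal equations. statsmodels scales standard errors by the
residual mean square; summary-data MR treats the outcome variances as known,
so the oracle divides the reported SEs by sqrt(mse_resid) to put them on the
fixed-effect (known-variance) scale.
"""

import numpy as np
import statsmodels.api as sm


def wls_through_origin(bx, by, sy):
    """(slope, fixed-effect SE) of by on bx weighted by 1/sy^2."""
    fit = sm.WLS(np.asarray(by), np.asarray(bx), weights=1.0 / np.asarray(sy) ** 2).fit()
    scale = np.sqrt(fit.mse_resid)
    return float(fit.params[0]), float(fit.bse[0] / scale)


def wls_with_intercept(bx, by, sy):
    """((intercept, slope), their fixed-effect SEs) of by on bx."""
    design = sm.add_constant(np.asarray(bx))
    fit = sm.WLS(np.asarray(by), design, weights=1.0 / np.asarray(sy) ** 2).fit()
    scale = np.sqrt(fit.mse_resid)
    return (
        (float(fit.params[0]), float(fit.params[1])),
        (float(fit.bse[0] / scale), float(fit.bse[1] / scale)),
    )


def multi_wls(bmat, by, sy):
    """(coefs, fixed-effect SEs) of by on the columns of bmat, no intercept."""
    fit = sm.WLS(np.asarray(by), np.asarray(bmat), weights=1.0 / np.asarray(sy) ** 2).fit()
    scale = np.sqrt(fit.mse_resid)
    return np.asarray(fit.params, dtype=float), np.asarray(fit.bse / scale, dtype=float)
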