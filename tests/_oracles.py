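"""Independent numerical oracles used by the test suite.

These are deliberately implemented from first principles (scipy
optimization over the closed-form restricted likelihood) rather than by
calling package code, so they can serve as external references for the
package's Bayesian variance-component machinery.
"""

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar


def reml_variance_ratio(y: np.ndarray, K: np.ndarray) -> float:
    """REML estimate of sigma_g^2 / sigma_e^2 for y = mu + g + e, g ~ N(0, K sg2).

    Profiles the residual variance out of the restricted likelihood of
    the single-kernel mixed model with an intercept and maximizes over
    the variance ratio by bounded scalar search.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    I = np.eye(n)

    def neg2reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        V = lam * K + I
        c, low = cho_factor(V, lower=True)
        logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv_y = cho_solve((c, low), y)
        Vinv_X = cho_solve((c, low), X)
        XtVinvX = float((X.T @ Vinv_X).item())
        beta = float((X.T @ Vinv_y).item()) / XtVinvX
        resid = y - beta
        # y' P y with P the REML projection under V
        yPy = float(resid @ cho_solve((c, low), resid))
        return logdet_V + np.log(XtVinvX) + (n - 1) * np.log(yPy)

    res = minimize_scalar(neg2reml, bounds=(-8.0, 8.0), method="bounded")
    return float(np.exp(res.x))
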