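"""Independent straight-line reference implementation of the belief-update
equations, written directly from their algebraic statement with numpy
scalars and no shared code with the package. Used to pin the package filter
to the written equations on small sessions."""

import numpy as np


def reference_filter(choices, outcomes, p, n_options=3):
    """Filter a session step by step; returns dict of per-trial lists.

    ``p`` is any object with attributes mu3_0, sigma3_0, mu2_0, sigma2_0,
    kappa, omega, theta, phi2, m2, phi3, m3.
    """
    mu2 = np.full(n_options, float(p.mu2_0))
    sigma2 = np.full(n_options, float(p.sigma2_0))
    mu3 = float(p.mu3_0)
    sigma3 = float(p.sigma3_0)
    out = {k: [] for k in ("xhat2", "xhat3", "mu2", "mu3", "sigma2", "sigma3", "mhat", "delta1", "delta2")}

    for choice, y in zip(choices, outcomes):
        c = choice - 1
        # predictions (AR(1) drift toward the attractors)
        xhat3 = mu3 + p.phi3 * (p.m3 - mu3)
        xhat2 = mu2 + p.phi2 * (p.m2 - mu2)
        vol = np.exp(min(p.kappa * xhat3 + p.omega, 30.0))
        sigma2hat = sigma2 + vol
        sigma3hat = sigma3 + p.theta
        mhat = 1.0 / (1.0 + np.exp(-np.clip(xhat2, -40.0, 40.0)))

        # level-2 update of the chosen option
        delta1 = y - mhat[c]
        pi2 = 1.0 / sigma2hat[c] + mhat[c] * (1.0 - mhat[c])
        mu2_new = xhat2.copy()
        sigma2_new = sigma2hat.copy()
        mu2_new[c] = xhat2[c] + delta1 / pi2
        sigma2_new[c] = 1.0 / pi2

        # level-3 update driven by the chosen option's volatility PE
        w2 = vol / sigma2hat[c]
        delta2 = (sigma2_new[c] + (mu2_new[c] - xhat2[c]) ** 2) / sigma2hat[c] - 1.0
        pi3 = 1.0 / sigma3hat + 0.5 * p.kappa**2 * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        assert pi3 > 0, "reference filter unstable"
        mu3_new = xhat3 + 0.5 * p.kappa * w2 * delta2 / pi3
        sigma3_new = 1.0 / pi3

        out["xhat2"].append(xhat2)
        out["xhat3"].append(xhat3)
        out["mu2"].append(mu2_new)
        out["mu3"].append(mu3_new)
        out["sigma2"].append(sigma2_new)
        out["sigma3"].append(sigma3_new)
        out["mhat"].append(mhat)
        out["delta1"].append(delta1)
        out["delta2"].append(delta2)

        mu2, sigma2, mu3, sigma3 = mu2_new, sigma2_new, mu3_new, sigma3_new

    return {k: np.array(v) for k, v in out.items()}
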