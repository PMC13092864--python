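"""Shared numerical oracles for the test suite."""

import numpy as np
from scipy.special import ive


def rice_mean(mu: float, sigma: float) -> float:
    """Mean of ||(mu, 0) + N(0, sigma^2 I_2)|| (Rice distribution).

    Overflow-safe for large mu/sigma via exponentially scaled Bessel
    functions: E = sigma*sqrt(pi/2)*e^{-x}[(1+2x)I0(x) + 2x I1(x)],
    x = mu^2/(4 sigma^2) — the exact expectation of a jittered step length.
    """
    x = mu**2 / (4.0 * sigma**2)
    return float(
        sigma
        * np.sqrt(np.pi / 2.0)
        * ((1.0 + 2.0 * x) * ive(0, x) + 2.0 * x * ive(1, x))
    )
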