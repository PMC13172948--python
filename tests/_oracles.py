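"""Independent brute-force oracles for the disproportionality estimators.

Deliberately coded from the defining formulas with scalar ``math``
arithmetic and a bisection-based gamma-quantile inversion, sharing no
code path with the package implementation.
"""

import math

from scipy.optimize import brentq
from scipy.special import gammainc, ndtri


def z_quantile(level: float) -> float:
    return ndtri((1.0 + level) / 2.0)


def ror_oracle(a, b, c, d, level=0.95):
    point = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = z_quantile(level)
    return point, math.exp(math.log(point) - z * se), math.exp(math.log(point) + z * se)


def prr_oracle(a, b, c, d, level=0.95):
    point = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    z = z_quantile(level)
    return point, math.exp(math.log(point) - z * se), math.exp(math.log(point) + z * se)


def gamma_quantile_oracle(q, shape, rate):
    """Invert the regularized gamma CDF by bisection (scale-free in x/rate)."""
    f = lambda x: gammainc(shape, rate * x) - q
    hi = shape / rate
    while f(hi) < 0:
        hi *= 2.0
    lo = 0.0
    return brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)


def ic_oracle(a, b, c, d, level=0.95):
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    point = math.log2((a + 0.5) / (e + 0.5))
    shape = a + 0.5
    rate = 1.0 + 0.5 / e
    lo = math.log2(gamma_quantile_oracle((1 - level) / 2, shape, rate) / e)
    hi = math.log2(gamma_quantile_oracle((1 + level) / 2, shape, rate) / e)
    return point, lo, hi
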