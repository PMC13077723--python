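"""Independent oracles used by the statistical tests.

Deliberately take a different computational route from the package:
exact rational arithmetic for the information component, and direct
numerical integration of the unnormalized posterior for the gamma-Poisson
shrinkage quantities (never the conjugate closed form).
"""

import math
from fractions import Fraction

import numpy as np
from scipy import integrate, optimize


def bcpnn_fraction_oracle(a, b, c, d, alpha1=1, beta1=1, alpha=2, beta=2, gamma11=1):
    """E(IC), V(IC), IC-2SD with all inner ratios as exact fractions."""
    C = Fraction(a + b + c + d)
    cx, cy, cxy = Fraction(a + b), Fraction(a + c), Fraction(a)
    a1, b1, al, be, g11 = (Fraction(x) for x in (alpha1, beta1, alpha, beta, gamma11))
    g = g11 * (C + al) * (C + be) / ((cx + a1) * (cy + b1))
    ratio = (cxy + g11) * (C + al) * (C + be) / ((C + g) * (cx + a1) * (cy + b1))
    ic = math.log2(ratio.numerator) - math.log2(ratio.denominator)
    v = ((C - cxy + g - g11) / ((cxy + g11) * (1 + C + g))
         + (C - cx + al - a1) / ((cx + a1) * (1 + C + al))
         + (C - cy + be - b1) / ((cy + b1) * (1 + C + be)))
    v_ic = float(v) / math.log(2) ** 2
    return ic, v_ic, ic - 2.0 * math.sqrt(v_ic)


def _log_posterior_density(lam, a, e, theta):
    """log of the unnormalized posterior: prior(lam) * Poisson(a; lam*e)."""
    a1, b1, a2, b2, w = theta
    lp1 = (math.log(w) + a1 * math.log(b1) - math.lgamma(a1)
           + (a1 - 1) * np.log(lam) - b1 * lam)
    lp2 = (math.log(1 - w) + a2 * math.log(b2) - math.lgamma(a2)
           + (a2 - 1) * np.log(lam) - b2 * lam)
    prior = np.logaddexp(lp1, lp2)
    return prior + a * np.log(lam) - lam * e - math.lgamma(a + 1) + a * math.log(e)


def ebgm_quadrature_oracle(a, e, theta):
    """(posterior mean of log2 lambda -> 2**., 5th percentile) by quadrature."""
    mode = max((a + 1.0) / (e + 1.0), 1e-6)
    scale = _log_posterior_density(mode, a, e, theta)

    def dens(lam):
        return np.exp(_log_posterior_density(lam, a, e, theta) - scale)

    hi = mode
    while dens(hi) > 1e-14 * dens(mode):
        hi *= 2.0
    z, _ = integrate.quad(dens, 0, hi, limit=400, points=[mode])
    num, _ = integrate.quad(lambda x: np.log2(x) * dens(x), 0, hi,
                            limit=400, points=[mode])
    ebgm = 2.0 ** (num / z)

    def cdf(x):
        val, _ = integrate.quad(dens, 0, x, limit=400)
        return val / z

    lo_b, hi_b = 1e-12, hi
    ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo_b, hi_b, xtol=1e-12)
    return ebgm, ebgm05


def quantile_type7_oracle(values, q):
    """Linear interpolation between order statistics, written out longhand."""
    xs = sorted(values)
    n = len(xs)
    h = (n - 1) * q
    lo = math.floor(h)
    if lo >= n - 1:
        return xs[-1]
    return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])
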