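"""Independent brute-force oracles used only by the tests.

Kept deliberately separate from the package: each oracle evaluates a
definition directly (power series, contingency table, closed-form
statistic) without sharing any code path with the implementation.
"""

from decimal import Decimal, getcontext

import numpy as np


def _cmul(a, b):
    return (a[0] * b[0] - a[1] * b[1], a[0] * b[1] + a[1] * b[0])


def _cdiv(a, b):
    den = b[0] * b[0] + b[1] * b[1]
    return ((a[0] * b[0] + a[1] * b[1]) / den, (a[1] * b[0] - a[0] * b[1]) / den)


def bessel_ratio_series(z: complex, terms: int = 250, prec: int = 80) -> complex:
    """I0(z)/I1(z) by summing the defining power series.

    Complex arithmetic over Decimal with ``prec`` digits: for |z| large
    with arg(z) near ±π/2 the series terms alternate and cancel by tens of
    orders of magnitude, so float64 summation would be meaningless.

        I0(z) = sum_k (z²/4)^k / (k!)²
        I1(z) = (z/2) · sum_k (z²/4)^k / (k!·(k+1)!)
    """
    getcontext().prec = prec
    zr = (Decimal(float(z.real)), Decimal(float(z.imag)))
    q = _cmul(zr, zr)
    q = (q[0] / 4, q[1] / 4)
    t0 = (Decimal(1), Decimal(0))
    t1 = (Decimal(1), Decimal(0))
    s0, s1 = t0, t1
    for k in range(1, terms):
        t0 = _cmul(t0, q)
        t0 = (t0[0] / (k * k), t0[1] / (k * k))
        t1 = _cmul(t1, q)
        t1 = (t1[0] / (k * (k + 1)), t1[1] / (k * (k + 1)))
        s0 = (s0[0] + t0[0], s0[1] + t0[1])
        s1 = (s1[0] + t1[0], s1[1] + t1[1])
    denom = _cmul((zr[0] / 2, zr[1] / 2), s1)
    r = _cdiv(s0, denom)
    return complex(r[0], r[1])


def phi_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Phi coefficient from the 2×2 pixel contingency table."""
    a = mask_a.ravel().astype(bool)
    b = mask_b.ravel().astype(bool)
    n11 = np.sum(a & b)
    n10 = np.sum(a & ~b)
    n01 = np.sum(~a & b)
    n00 = np.sum(~a & ~b)
    num = n11 * n00 - n10 * n01
    den = np.sqrt(float(n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
    return float(num / den)
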