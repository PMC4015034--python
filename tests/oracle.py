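"""Independent oracle implementations for cross-checking statistics.

These re-derive the neutrality-test constant chains directly from the
published formulas (Tajima 1989; Fu & Li 1993 with the Simonsen et al.
1995 F-variance correction), using plain scalar arithmetic and explicit
loops, deliberately sharing no code with the package.
"""

import math


def harmonic(n, power=1):
    total = 0.0
    for i in range(1, n):
        total += 1.0 / i**power
    return total


def tajima_d_oracle(eta):
    """Tajima's D from a spectrum list, via the 1989 constant chain."""
    n = len(eta) - 1
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    S = sum(eta[1:-1])
    if S <= 0:
        return None
    pi = sum(i * (n - i) * eta[i] for i in range(1, n)) / (n * (n - 1) / 2.0)
    tw = S / a1
    return (pi - tw) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fuli_d_oracle(eta):
    """Fu & Li's unfolded D from a spectrum list."""
    n = len(eta) - 1
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    S = sum(eta[1:-1])
    if S <= 0:
        return None
    cn = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    vD = 1.0 + a1 * a1 / (a2 + a1 * a1) * (cn - (n + 1.0) / (n - 1))
    uD = a1 - 1.0 - vD
    return (S - a1 * eta[1]) / math.sqrt(uD * S + vD * S * S)


def fuli_f_oracle(eta):
    """Fu & Li's unfolded F (corrected variance) from a spectrum list."""
    n = len(eta) - 1
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    an1 = harmonic(n + 1)
    S = sum(eta[1:-1])
    if S <= 0:
        return None
    cn = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    vF = (cn + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (
        a1 * a1 + a2
    )
    uF = (
        1.0
        + (n + 1.0) / (3.0 * (n - 1))
        - 4.0 * (n + 1.0) / ((n - 1) * (n - 1)) * (an1 - 2.0 * n / (n + 1))
    ) / a1 - vF
    pi = sum(i * (n - i) * eta[i] for i in range(1, n)) / (n * (n - 1) / 2.0)
    return (pi - eta[1]) / math.sqrt(uF * S + vF * S * S)
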