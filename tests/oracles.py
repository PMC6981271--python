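"""Independent textbook oracles used by the test suite.

Deliberately shares no code with the package: the Welch statistic and
degrees of freedom are written straight from their definitions, and the
two-tailed p value is obtained by numerically integrating the Student-t
density (written from the gamma function), not from a CDF routine.
"""

import math

from scipy.integrate import quad


def t_density(x: float, df: float) -> float:
    log_c = (
        math.lgamma((df + 1) / 2.0)
        - math.lgamma(df / 2.0)
        - 0.5 * math.log(df * math.pi)
    )
    return math.exp(log_c - ((df + 1) / 2.0) * math.log1p(x * x / df))


def welch_oracle(x, y):
    """(t, df, two-tailed p) from first principles."""
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    v1 = sum((xi - m1) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - m2) ** 2 for yi in y) / (n2 - 1)
    se1, se2 = v1 / n1, v2 / n2
    t = (m1 - m2) / math.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    tail = t_tail(abs(t), df)
    return t, df, 2.0 * tail


def t_tail(t: float, df: float) -> float:
    """P(T > t) for t >= 0 by numerical integration of the density.

    Uses the substitution u = t/x to map the infinite tail onto (0, 1],
    which keeps the quadrature accurate far into the tail where direct
    integration over [t, inf) loses the mass concentrated near t.
    """
    if t == 0.0:
        return 0.5
    tail, _ = quad(
        lambda u: t_density(t / u, df) * t / (u * u),
        0.0,
        1.0,
        epsabs=1e-300,
        epsrel=1e-12,
        limit=200,
    )
    return tail


def classify_oracle(a: float, b: float, n: float, m: float) -> str:
    """Literal re-evaluation of the two pass-criteria inequality chains."""
    root = math.sqrt(n)
    if a > root and b > 1.0 / (a * a - n) + m:
        return "P_SIGNIFICANT"
    if a < -root and b > 1.0 / (a * a - n) + m:
        return "NP_SIGNIFICANT"
    return "NON_SIGNIFICANT"
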