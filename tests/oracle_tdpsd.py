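"""Independent, deliberately naive reference implementation of the seven
descriptors, written straight from their defining formulas with plain Python
loops.  Kept free of any import from the package's feature module so the two
routes cannot share a bug."""

import math


def oracle_features(x, lam=0.1, eps=1e-12):
    n = len(x)
    m0_bar = math.sqrt(sum(v * v for v in x))
    d1 = [x[j] - x[j - 1] for j in range(1, n)]
    m2_bar = math.sqrt(sum(v * v for v in d1))
    d2 = [d1[j] - d1[j - 1] for j in range(1, len(d1))]
    m4_bar = math.sqrt(sum(v * v for v in d2))

    def transform(m_bar):
        return 0.0 if m_bar == 0.0 else m_bar**lam / lam

    m0, m2, m4 = transform(m0_bar), transform(m2_bar), transform(m4_bar)

    def safe_log(arg):
        return math.log(abs(arg) + eps)

    def safe_ratio(num, den):
        floor = eps if eps > 0 else 5e-324
        return num / max(abs(den), floor)

    f1 = safe_log(m0)
    f2 = safe_log(m0 - m2)
    f3 = safe_log(m0 - m4)
    f4 = safe_log(safe_ratio(m0, math.sqrt(abs(m0 - m2)) * math.sqrt(abs(m0 - m4))))
    f5 = safe_log(safe_ratio(m2, math.sqrt(m0 * m4)))
    mean = sum(x) / n
    std = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    f6 = safe_log(safe_ratio(std, mean))
    teager = sum(x[j] * x[j] - x[j - 1] * x[j + 1] for j in range(1, n - 1))
    f7 = safe_log(teager)
    return [f1, f2, f3, f4, f5, f6, f7]
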