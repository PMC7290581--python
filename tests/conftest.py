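import numpy as np
import pandas as pd
import pytest

from mircad.ct import CtMatrix


@pytest.fixture
def toy_ct() -> CtMatrix:
    """6 samples x 3 miRNAs on 2 plates, one non-detect."""
    values = pd.DataFrame(
        {
            "m1": [20.0, 21.0, 22.0, 23.0, 20.5, 22.5],
            "m2": [25.0, 26.0, np.nan, 27.0, 25.5, 26.5],
            "m3": [28.0, 29.0, 30.0, 31.0, 28.5, 30.5],
        },
        index=["s1", "s2", "s3", "s4", "s5", "s6"],
    )
    plate = pd.Series(["A", "A", "B", "B", "A", "B"], index=values.index)
    return CtMatrix(values=values, plate=plate)


def km_restricted_mean_oracle(values, censored) -> float:
    """Mass-redistribution restricted mean (Efron's redistribute-to-the-right).

    Independent of the product-limit implementation: each censored
    observation passes its probability mass equally to all strictly later
    observations in the (value, events-first) sort order; mass stranded at
    the end stays at the largest observation, matching the restriction of
    the mean to the observed range.
    """
    vals = np.asarray(values, dtype=float)
    cens = np.asarray(censored, dtype=bool)
    order = np.lexsort((cens, vals))  # events precede censorings at ties
    v = vals[order]
    c = cens[order]
    n = len(v)
    mass = np.full(n, 1.0 / n)
    for i in range(n):
        if c[i]:
            later = np.arange(i + 1, n)
            if len(later):
                mass[later] += mass[i] / len(later)
                mass[i] = 0.0
            # else: censored at the very end keeps its mass there
    return float(np.sum(mass * v))


def logrank_oracle(values, censored, group_a_mask):
    """Direct observed-minus-expected log-rank over distinct event values."""
    vals = np.asarray(values, dtype=float)
    cens = np.asarray(censored, dtype=bool)
    a = np.asarray(group_a_mask, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(vals[~cens])):
        at_risk = vals >= t
        n = at_risk.sum()
        n1 = (at_risk & a).sum()
        d = ((vals == t) & ~cens).sum()
        d1 = ((vals == t) & ~cens & a).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2
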