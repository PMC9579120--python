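"""Independent numerical oracles used by the test suite."""

import numpy as np


def bessel_i_series(order: int, x: float, terms: int = 80) -> float:
    """Power-series oracle for the modified Bessel function I_order(x).

    Independent of scipy.special: I_v(x) = sum_k (x/2)^(2k+v) / (k! (k+v)!).
    Converges fast for the moderate arguments used in tests.
    """
    total = 0.0
    for k in range(terms):
        log_term = (2 * k + order) * np.log(x / 2.0) - (
            sum(np.log(j) for j in range(1, k + 1))
            + sum(np.log(j) for j in range(1, k + order + 1))
        )
        total += np.exp(log_term)
    return total
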