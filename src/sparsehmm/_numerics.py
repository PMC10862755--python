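"""Log-space numerics shared across the package.

All dynamic-programming values are natural-log odds ratios ("nats").
Probability zero is represented by -inf, which is the additive identity
under log-sum-exp accumulation.
"""

from __future__ import annotations

import numpy as np

NEG_INF = -np.inf

#: nats per bit; scores are reported in bits as score_nats / LN2.
LN2 = float(np.log(2.0))


def logsumexp2(a, b):
    """Elementwise log(e^a + e^b); -inf is absorbing-neutral, never NaN."""
    return np.logaddexp(a, b)


def logsumexp3(a, b, c):
    return np.logaddexp(np.logaddexp(a, b), c)


def logsumexp4(a, b, c, d):
    return np.logaddexp(np.logaddexp(a, b), np.logaddexp(c, d))


def log_chain_forward(source: np.ndarray, step: float) -> np.ndarray:
    """Solve v[j] = logaddexp(source[j], v[j-1] + step), v[-1] = -inf.

    Vectorized via the substitution w[j] = v[j] - (j+1)*step, which turns the
    affine recurrence into a plain running log-sum.  `source` may be 1-D or
    2-D (chain runs along axis 0).
    """
    n = source.shape[0]
    if n == 0 or not np.isfinite(step):
        # step == -inf: the chain never extends, so v[j] == source[j]
        return source.copy()
    j = np.arange(1, n + 1, dtype=float)
    if source.ndim == 2:
        j = j[:, None]
    w = np.logaddexp.accumulate(source - j * step, axis=0)
    return w + j * step


def log_chain_backward(source: np.ndarray, step: float) -> np.ndarray:
    """Solve v[j] = logaddexp(source[j], v[j+1] + step), v[n] = -inf."""
    return log_chain_forward(source[::-1], step)[::-1]


def max_chain_forward(source: np.ndarray, step: float) -> np.ndarray:
    """Max-plus analogue of :func:`log_chain_forward`."""
    n = source.shape[0]
    if n == 0 or not np.isfinite(step):
        return source.copy()
    j = np.arange(1, n + 1, dtype=float)
    if source.ndim == 2:
        j = j[:, None]
    w = np.maximum.accumulate(source - j * step, axis=0)
    return w + j * step
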