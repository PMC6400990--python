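"""Small numerical helpers shared across modules.

All p-values in the package are two-sided normal tails.  Cohort sample
sizes are in the tens of thousands, so the normal and t references are
indistinguishable and the normal is used throughout; extreme statistics
are handled in log space so nothing underflows internally.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import stats

__all__ = ["z_to_p", "z_to_log10p", "round_sig"]


def z_to_p(z):
    """Two-sided normal tail probability of ``z`` (vectorised).

    Returns 0.0 (an underflowed double) only at the output boundary; use
    :func:`z_to_log10p` when the magnitude itself is needed.
    """
    return 2.0 * stats.norm.sf(np.abs(z))


def z_to_log10p(z):
    """log10 of the two-sided normal tail, computed without underflow.

    Valid for arbitrarily large ``|z|`` (the log-tail is evaluated
    directly, never via the probability).
    """
    return (math.log(2.0) + stats.norm.logsf(np.abs(z))) / math.log(10.0)


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (display only).

    Decision rules in the package always use exact values; this mirrors
    how thresholds are quoted in reports.
    """
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = sig - 1 - math.floor(math.log10(abs(x)))
    return round(x, ndigits)
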