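"""Shared statistical engine.

The rank-sum test here backs both the caller's read-attribute bias filters and
the clinical covariate comparisons, so that a single, well-tested engine defines
the package's p-values.  Small tie-free problems are evaluated by exact
enumeration of the rank distribution; everything else uses the tie-corrected
normal approximation with continuity correction.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

from .errors import UndefinedTestError

__all__ = ["rank_sum_test", "EXACT_MAX_MIN_N"]

#: exact enumeration is used when the smaller group has at most this many values
#: and the pooled data are tie-free
EXACT_MAX_MIN_N = 8

_ALTERNATIVES = {"two_sided": "two-sided", "two-sided": "two-sided",
                 "greater": "greater", "less": "less"}


def rank_sum_test(x, y, alternative: str = "two_sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value comparing samples ``x`` and ``y``.

    Parameters
    ----------
    x, y
        Numeric vectors; must both be nonempty.
    alternative
        ``"two_sided"`` (default), ``"greater"`` (x tends larger), or ``"less"``.

    Returns
    -------
    float
        p-value in (0, 1].

    Raises
    ------
    UndefinedTestError
        If either vector is empty.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise UndefinedTestError("rank-sum test requires two nonempty samples")
    try:
        alt = _ALTERNATIVES[alternative]
    except KeyError:
        raise UndefinedTestError(f"unknown alternative {alternative!r}") from None

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence either way
        return 1.0

    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= EXACT_MAX_MIN_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = _st.mannwhitneyu(x, y, alternative=alt, method=method,
                           use_continuity=True)
    p = float(res.pvalue)
    if not np.isfinite(p):  # fully tied within groups under the approximation
        return 1.0
    return min(max(p, np.finfo(float).tiny), 1.0)
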