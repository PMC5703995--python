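"""Statistical machinery: two-tailed Mann-Whitney tests, cumulative
percentage distributions, and binned distribution differencing.

The Mann-Whitney test uses exact enumeration for small tie-free samples
(n*m <= 400) and the normal approximation with tie and continuity
corrections otherwise.  pKas flagged ">15" participate in rank tests as
values tied above the largest numeric observation — rank tests need only
the ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

EXACT_LIMIT = 400


@dataclass
class MannWhitneyResult:
    u: float
    p_value: float
    n: int
    m: int
    method: str  # "exact" | "normal-approximation"


def mann_whitney_two_tailed(x, y) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test of two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires non-empty samples")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if x.size * y.size <= EXACT_LIMIT and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "normal-approximation"
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
    return MannWhitneyResult(u=float(res.statistic),
                             p_value=float(min(res.pvalue, 1.0)),
                             n=int(x.size), m=int(y.size), method=method)


def flagged_to_sentinel(values, flags) -> np.ndarray:
    """Map high-flagged entries (pKa '>15') to a common sentinel above the
    largest numeric value so they rank tied at the top."""
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    out = values.copy()
    numeric = values[~flags]
    sentinel = (numeric.max() if numeric.size else 0.0) + 1.0
    out[flags] = sentinel
    return out


@dataclass
class Ecdf:
    support: np.ndarray        # sorted numeric values
    cumulative_pct: np.ndarray # right-continuous, reaches 100 - sentinel share
    sentinel_pct: float        # share of flagged (">15") observations

    def __call__(self, v: float) -> float:
        return float(np.interp(v, self.support, self.cumulative_pct,
                               left=0.0, right=self.cumulative_pct[-1]))


def ecdf(values, flags=None) -> Ecdf:
    """Cumulative percentage distribution; flagged values occupy a sentinel
    bin above the numeric support so the curve still completes to 100%."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("ecdf of empty sample")
    flags = (np.zeros(values.size, dtype=bool) if flags is None
             else np.asarray(flags, dtype=bool))
    numeric = np.sort(values[~flags])
    n = values.size
    sentinel_pct = 100.0 * flags.sum() / n
    cumulative = 100.0 * np.arange(1, numeric.size + 1) / n
    return Ecdf(support=numeric, cumulative_pct=cumulative,
                sentinel_pct=float(sentinel_pct))


def distribution_difference(a, b, bins) -> np.ndarray:
    """Per-bin percentage difference a% - b% on a common binning; sums to
    zero over the full support."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    bins = np.asarray(bins, dtype=float)
    for name, v in (("a", a), ("b", b)):
        if v.size and (v.min() < bins[0] or v.max() > bins[-1]):
            raise ValueError(f"bins do not cover the range of sample {name}")
    pa = 100.0 * np.histogram(a, bins=bins)[0] / a.size
    pb = 100.0 * np.histogram(b, bins=bins)[0] / b.size
    return pa - pb
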