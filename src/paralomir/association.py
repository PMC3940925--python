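"""Pearson correlation screens with significance calls.

Used for three pair universes: major/minor forms of one precursor,
clustered miRNAs, and intragenic miRNA vs host gene.  R and the two-sided
p-value come from the exact null distribution of the sample correlation
under bivariate normality (the t-transform with n−2 degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationResult:
    pair_a: str
    pair_b: str
    r: float
    p: float
    n: int
    significant: bool
    positive: bool
    defined: bool = True  # False when either vector is constant


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def correlate_pairs(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    pairs: list[tuple[str, str]],
    alpha: float = 0.01,
    bh: bool = False,
) -> list[CorrelationResult]:
    """Pearson R and two-sided p for each (row of matrix_a, row of matrix_b) pair.

    Both matrices must share the tissue columns.  Constant vectors leave R
    undefined; such pairs are returned flagged (``defined=False``) and are
    excluded from significance tallies.  ``bh`` applies a Benjamini–
    Hochberg adjustment before thresholding (off by default).
    """
    if list(matrix_a.columns) != list(matrix_b.columns):
        raise ValueError("matrices do not share tissue columns")
    n = matrix_a.shape[1]
    results = []
    for a, b in pairs:
        x = matrix_a.loc[a].to_numpy(dtype=float)
        y = matrix_b.loc[b].to_numpy(dtype=float)
        if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            results.append(CorrelationResult(a, b, np.nan, np.nan, n, False, False, False))
            continue
        r, p = stats.pearsonr(x, y)
        results.append(CorrelationResult(a, b, float(r), float(p), n, False, r > 0))
    pvals = np.array([res.p for res in results if res.defined])
    if bh and len(pvals):
        adjusted = iter(_bh_adjust(pvals))
        for res in results:
            if res.defined:
                res.p = float(next(adjusted))
    for res in results:
        if res.defined:
            res.significant = res.p < alpha
    return results


def summarize_positive_fraction(
    results: list[CorrelationResult],
) -> tuple[int, int, int]:
    """(significant-positive count, total defined pairs, rounded percent)."""
    defined = [res for res in results if res.defined]
    total = len(defined)
    if total == 0:
        raise ValueError("no defined correlation results to summarize")
    pos = sum(1 for res in defined if res.significant and res.positive)
    return pos, total, positive_fraction_percent(pos, total)


def positive_fraction_percent(n_positive: int, n_total: int) -> int:
    """Percent of positively correlated pairs, rounded to the nearest integer."""
    if n_total == 0:
        raise ValueError("zero total pairs")
    return int(round(100.0 * n_positive / n_total))


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair_a": r.pair_a, "pair_b": r.pair_b, "r": r.r, "p": r.p,
                "n": r.n, "significant": r.significant, "positive": r.positive,
                "defined": r.defined,
            }
            for r in results
        ]
    )
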