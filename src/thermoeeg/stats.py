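"""Statistical chain: KS normality, Mann-Whitney U, Kruskal-Wallis + post-hoc.

The battery mirrors the study's analysis order: a one-sample
Kolmogorov-Smirnov check against a normal with the sample's own mean/SD
(a Lilliefors-corrected variant is available, since estimating the
parameters makes the plain KS p-value conservative), a two-sided
Mann-Whitney U independence check with tie correction, and a
Kruskal-Wallis omnibus (H referred to a chi-square distribution) with
uncorrected pairwise post-hoc comparisons. The default post-hoc is a
Dunn-style z-test on pooled ranks; a Tukey-HSD-on-ranks variant is
switchable. The conventional significance threshold is 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

ALPHA = 0.05


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    name: str
    statistic: float
    pvalue: float
    group_sizes: List[int]
    pairwise: Optional[pd.DataFrame] = None
    detail: Dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.pvalue < ALPHA


def normality_test(sample: Sequence[float], lilliefors: bool = False) -> TestResult:
    """One-sample KS test against a normal with estimated mean/SD.

    With ``lilliefors=True`` the p-value comes from the Lilliefors table
    (appropriate when the reference parameters are estimated from the same
    sample); the plain KS p-value, reported by default, is conservative.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D sample with n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample has no defined normality test")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        name = "lilliefors"
    else:
        stat, p = _stats.kstest(x, "norm", args=(x.mean(), sd))
        name = "ks-1sample"
    return TestResult(name, float(stat), float(p), [len(x)])


def independence_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> TestResult:
    """Two-sided Mann-Whitney U with tie correction."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    res = _stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(
        "mann-whitney-u", float(res.statistic), float(res.pvalue),
        [len(a), len(b)],
    )


def _dunn_pairwise(groups: List[np.ndarray], names: List[str]) -> pd.DataFrame:
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = _stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    # tie correction on the pooled ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12 - tie_term
    k = len(groups)
    mat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
            if se == 0:
                p = 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = 2 * _stats.norm.sf(abs(z))
            mat[i, j] = mat[j, i] = p
    return pd.DataFrame(mat, index=names, columns=names)


def _tukey_pairwise(groups: List[np.ndarray], names: List[str]) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    pooled = np.concatenate(groups)
    ranks = _stats.rankdata(pooled)
    labels = np.concatenate([[nm] * len(g) for nm, g in zip(names, groups)])
    res = pairwise_tukeyhsd(ranks, labels)
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    table = res.summary().data[1:]
    for row in table:
        g1, g2, p = str(row[0]), str(row[1]), float(row[3])
        mat.loc[g1, g2] = mat.loc[g2, g1] = p
    return mat


def kruskal_posthoc(
    groups: Sequence[Sequence[float]],
    names: Optional[Sequence[str]] = None,
    posthoc: str = "dunn",
) -> TestResult:
    """Kruskal-Wallis omnibus plus uncorrected pairwise post-hoc p-values.

    ``posthoc`` selects ``"dunn"`` (pairwise z on pooled ranks) or
    ``"tukey"`` (Tukey HSD on the pooled ranks). No multiple-comparison
    correction is applied to the pairwise matrix. With exactly two groups
    the call routes to :func:`independence_test`.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if names is None:
        names = [f"group{i}" for i in range(len(arrays))]
    names = list(names)
    if len(arrays) == 2:
        return independence_test(arrays[0], arrays[1])
    if len(arrays) < 3:
        raise ValueError("need at least 3 groups (or exactly 2 for the U test)")
    for g in arrays:
        if len(g) < 2:
            raise ValueError("every group needs n >= 2")
    try:
        h, p = _stats.kruskal(*arrays)
    except ValueError:
        h, p = np.nan, np.nan
    if not np.isfinite(h):  # all values identical: no rank variation beyond ties
        h, p = 0.0, 1.0
    if posthoc == "dunn":
        pairwise = _dunn_pairwise(arrays, names)
    elif posthoc == "tukey":
        pairwise = _tukey_pairwise(arrays, names)
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}; use 'dunn' or 'tukey'")
    return TestResult(
        f"kruskal-wallis+{posthoc}", float(h), float(p),
        [len(g) for g in arrays], pairwise=pairwise,
    )


def results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Flatten test results (one row per test, plus one per post-hoc pair)."""
    rows = []
    for r in results:
        rows.append(
            {"test": r.name, "comparison": "omnibus", "statistic": r.statistic,
             "pvalue": r.pvalue, "n": "/".join(map(str, r.group_sizes))}
        )
        if r.pairwise is not None:
            cols = list(r.pairwise.columns)
            for i, gi in enumerate(cols):
                for gj in cols[i + 1 :]:
                    rows.append(
                        {"test": r.name, "comparison": f"{gi} vs {gj}",
                         "statistic": np.nan,
                         "pvalue": float(r.pairwise.loc[gi, gj]),
                         "n": ""}
                    )
    return pd.DataFrame(rows)
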