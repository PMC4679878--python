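"""Nonparametric comparison layer: rank-sum, Kruskal-Wallis, Mann-Kendall,
and a pairwise class-comparison report with optional Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: combined-sample size at or below which the rank-sum test is evaluated
#: exactly by permutation enumeration rather than by normal approximation
EXACT_RANKSUM_MAX_N = 20


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    n_per_group: tuple
    groups: tuple = ()
    corrected_p: Optional[float] = None

    def bonferroni(self, n_comparisons: int) -> "GroupComparison":
        """Return a copy with corrected_p = min(1, p * n_comparisons)."""
        return GroupComparison(
            test=self.test,
            statistic=self.statistic,
            p_value=self.p_value,
            n_per_group=self.n_per_group,
            groups=self.groups,
            corrected_p=min(1.0, self.p_value * n_comparisons),
        )


def ranksum(sample_a, sample_b) -> GroupComparison:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    Small combined samples (n <= 20, no ties) are evaluated exactly by
    enumerating the permutation distribution of U; otherwise the tie-corrected
    normal approximation is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ranksum needs two nonempty samples")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size + b.size <= EXACT_RANKSUM_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        test="ranksum",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(a.size, b.size),
    )


def kruskal_wallis(samples: Sequence) -> GroupComparison:
    """Kruskal-Wallis H test with tie correction; chi-square p with
    (groups - 1) degrees of freedom."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ValueError("kruskal_wallis needs >= 2 nonempty samples")
    h, p = stats.kruskal(*samples)
    return GroupComparison(
        test="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        n_per_group=tuple(s.size for s in samples),
    )


def mann_kendall(series) -> GroupComparison:
    """Mann-Kendall monotonic trend test on an ordered series.

    S = sum over i < j of sign(x_j - x_i); its variance uses the standard
    tie correction, and the two-sided p-value comes from the normal
    approximation with continuity correction.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"mann_kendall needs at least 3 observations, got {n}")
    diffs = np.sign(x[None, :] - x[:, None])
    s = float(np.triu(diffs, k=1).sum())
    _, tie_counts = np.unique(x, return_counts=True)
    var_s = n * (n - 1) * (2 * n + 5) / 18.0
    var_s -= np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5)) / 18.0
    if var_s <= 0:  # all values tied
        z = 0.0
    elif s > 0:
        z = (s - 1.0) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1.0) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return GroupComparison(
        test="mann_kendall", statistic=s, p_value=float(p), n_per_group=(n,)
    )


def pairwise_class_report(
    records: Mapping[str, Sequence[Mapping[str, float]]] | pd.DataFrame,
    class_labels: Optional[Sequence[str]] = None,
    correction: str = "none",
) -> pd.DataFrame:
    """Rank-sum comparisons of every metric across every unordered class pair.

    ``records`` is either a DataFrame with a class-label column named
    ``class`` plus one numeric column per metric, or a mapping
    class -> list of per-subject metric dicts.  Bonferroni correction (when
    requested) is over the number of class pairs, per metric.  Returns a long
    DataFrame with columns: metric, class_a, class_b, statistic, p_value,
    corrected_p, p_display (3-decimal display rounding of the reported p).
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError("correction must be 'none' or 'bonferroni'")
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "class" not in df.columns:
            raise ValueError("DataFrame input needs a 'class' column")
    else:
        rows = []
        for label, recs in records.items():
            for rec in recs:
                rows.append({"class": label, **rec})
        df = pd.DataFrame(rows)
    classes = list(class_labels) if class_labels is not None else sorted(df["class"].unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to compare")
    for c in classes:
        if (df["class"] == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members")
    metrics = [c for c in df.columns if c != "class"]
    pairs = [(a, b) for i, a in enumerate(classes) for b in classes[i + 1 :]]
    out = []
    for metric in metrics:
        for a, b in pairs:
            cmp = ranksum(
                df.loc[df["class"] == a, metric], df.loc[df["class"] == b, metric]
            )
            if correction == "bonferroni":
                cmp = cmp.bonferroni(len(pairs))
            reported = cmp.corrected_p if cmp.corrected_p is not None else cmp.p_value
            out.append(
                {
                    "metric": metric,
                    "class_a": a,
                    "class_b": b,
                    "statistic": cmp.statistic,
                    "p_value": cmp.p_value,
                    "corrected_p": cmp.corrected_p,
                    "p_display": f"{reported:.3f}",
                }
            )
    return pd.DataFrame(out)
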