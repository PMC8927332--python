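"""Residual batch-effect detection with the two-sample Kolmogorov-Smirnov test.

The success metric for harmonization is the percentage of features — out of
the ORIGINAL feature count, even after features have been dropped — whose
distributions differ significantly (p < alpha, strict) between levels of a
batch effect. The KS test is used (rather than a rank test) because feature
distributions are often multimodal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data import validate_batch, validate_feature_matrix

__all__ = ["KSReport", "ks_feature_pvalues", "percent_significant", "ks_report"]

#: switch from the exact to the asymptotic two-sample KS p-value above this
#: combined sample size
EXACT_N_LIMIT = 1000


def _ks_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    method = "exact" if (len(a) + len(b)) <= EXACT_N_LIMIT else "asymp"
    return float(stats.ks_2samp(a, b, method=method).pvalue)


def ks_feature_pvalues(features: pd.DataFrame, batch: pd.Series) -> pd.Series:
    """Per-feature KS p-value for distributional differences across batch levels.

    For two levels this is the two-sided two-sample KS p-value. For more
    levels it is the minimum over all pairwise comparisons (no multiplicity
    correction): a feature is as significant as its most discordant pair.
    Each level must hold at least 3 samples.
    """
    features = validate_feature_matrix(features)
    batch = validate_batch(batch, features.index, min_per_level=3)
    levels = sorted(batch.unique())
    groups = {lv: features.loc[batch == lv].to_numpy() for lv in levels}
    n_feat = features.shape[1]
    pvals = np.ones(n_feat)
    for lv_a, lv_b in combinations(levels, 2):
        a, b = groups[lv_a], groups[lv_b]
        pair = np.array([_ks_pvalue(a[:, g], b[:, g]) for g in range(n_feat)])
        pvals = np.minimum(pvals, pair)
    return pd.Series(pvals, index=features.columns, name=str(batch.name))


@dataclass(frozen=True)
class KSReport:
    """Per-feature KS p-values plus the percent-significant summary.

    ``denominator`` is the original feature count: when features were dropped
    upstream, the percentage is still reported out of the original number,
    so a dropped feature can never count as significant but still dilutes
    the percentage.
    """

    batch_effect: str
    p_values: pd.Series
    significant: pd.Series
    alpha: float
    denominator: int

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    @property
    def percent_significant(self) -> float:
        return 100.0 * self.n_significant / self.denominator

    def __str__(self) -> str:
        return (
            f"KSReport({self.batch_effect!r}: {self.n_significant}/{self.denominator} "
            f"significant at p<{self.alpha} = {round(self.percent_significant)}%)"
        )


def percent_significant(
    p_values: pd.Series,
    alpha: float = 0.05,
    denominator: int | None = None,
    batch_effect: str | None = None,
) -> KSReport:
    """Summarize p-values into a :class:`KSReport`.

    Significance is strict (p < alpha). ``denominator`` defaults to the
    number of p-values supplied and must not be smaller than it.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    arr = np.asarray(p_values, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if denominator is None:
        denominator = len(p_values)
    if denominator < len(p_values):
        raise ValueError(
            f"denominator ({denominator}) is smaller than the number of p-values "
            f"supplied ({len(p_values)}); it must be the original feature count"
        )
    significant = pd.Series(arr < alpha, index=p_values.index, name="significant")
    name = batch_effect if batch_effect is not None else str(p_values.name)
    return KSReport(
        batch_effect=name,
        p_values=p_values,
        significant=significant,
        alpha=alpha,
        denominator=int(denominator),
    )


def ks_report(
    features: pd.DataFrame,
    batch: pd.Series,
    alpha: float = 0.05,
    denominator: int | None = None,
) -> KSReport:
    """Convenience: KS p-values and summary in one call."""
    pvals = ks_feature_pvalues(features, batch)
    return percent_significant(pvals, alpha=alpha, denominator=denominator)
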