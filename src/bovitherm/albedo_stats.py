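"""Statistical comparison of per-color albedo replicates.

Albedo is a proportion, so replicate values are arcsine-transformed
(``arcsin(sqrt(p))``, the variance-stabilizing form) before a Shapiro–Wilk
normality check. Group location is compared with a Kruskal–Wallis rank test
(hide color as the factor), and the ordered one-sided alternatives

* HA1: white albedo > red albedo,
* HA2: red albedo > black albedo,
* HA3: white albedo > black albedo

are evaluated with exact Wilcoxon rank-sum tests — replicate counts of three
per color make asymptotic p-values meaningless — together with Cohen's *d*
effect sizes on the raw albedo scale. Colors are assigned compact-letter
significance groups by connected components of the not-significantly-different
graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

#: Ordered one-sided contrasts (each read "first > second").
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("white", "red"),
    ("red", "black"),
    ("white", "black"),
)


def arcsine_transform(p):
    """Variance-stabilizing arcsine transform ``arcsin(sqrt(p))`` (radians)."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk normality test, returning (W, p).

    Requires at least three non-identical values; delegates to the standard
    scipy routine.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 values")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    w, p = stats.shapiro(arr)
    return float(w), float(p)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal–Wallis H test over two or more groups, returning (H, p).

    H is computed from mid-rank sums with the standard tie correction; the
    p-value uses the chi-square approximation with (g - 1) degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("Kruskal-Wallis requires at least 3 values in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # all observations tied: no evidence of location differences
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def cohens_d(group_a, group_b) -> float:
    """Cohen's *d*: mean difference over the pooled standard deviation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Cohen's d requires at least 2 values per group")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        raise ValueError("Cohen's d is undefined when the pooled SD is zero")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def exact_rank_sum_one_sided(greater, lesser) -> float:
    """Exact one-sided Wilcoxon rank-sum p-value for H1: greater > lesser."""
    res = stats.mannwhitneyu(greater, lesser, alternative="greater", method="exact")
    return float(res.pvalue)


@dataclass(frozen=True)
class GroupComparisonReport:
    """Result of a per-color albedo comparison."""

    summary: pd.DataFrame  # color, n, mean, se
    shapiro: pd.DataFrame  # color, W, p (NaN where undefined)
    kruskal_h: float
    kruskal_p: float
    contrasts: pd.DataFrame  # greater, lesser, cohens_d, p_one_sided, significant
    letters: Mapping[str, str]
    alpha: float


def _letter_groups(
    colors: Sequence[str],
    means: Mapping[str, float],
    nonsignificant_pairs: set[frozenset],
) -> dict[str, str]:
    """Compact letters via connected components of the non-significant graph."""
    ordered = sorted(colors, key=lambda c: means[c], reverse=True)
    component = {c: None for c in ordered}
    comp_id = 0
    for c in ordered:
        if component[c] is not None:
            continue
        stack = [c]
        while stack:
            cur = stack.pop()
            if component[cur] is not None:
                continue
            component[cur] = comp_id
            stack.extend(
                other
                for other in ordered
                if component[other] is None
                and frozenset((cur, other)) in nonsignificant_pairs
            )
        comp_id += 1
    letters = "abcdefghijklmnopqrstuvwxyz"
    return {c: letters[component[c]] for c in ordered}


def compare_albedo_groups(
    estimates: pd.DataFrame,
    alpha: float = 0.05,
    contrasts: Sequence[tuple[str, str]] | None = None,
    arcsine: bool = True,
    effect_size_scale: str = "raw",
) -> GroupComparisonReport:
    """Compare replicate albedo estimates across hide colors.

    Parameters
    ----------
    estimates : DataFrame
        Must carry ``label`` (hide color) and ``albedo_abs`` columns, one row
        per replicate image per color; at least two colors with at least two
        replicates each.
    alpha : float
        Significance level; a contrast is declared significant when its exact
        one-sided p-value is <= alpha (with tiny replicate counts the smallest
        attainable p equals alpha exactly for n = 3 vs 3 at alpha = 0.05).
    contrasts : sequence of (greater, lesser), optional
        Ordered one-sided alternatives. Defaults to the white>red, red>black,
        white>black family when those colors are present, otherwise to all
        pairs ordered by descending group mean.
    arcsine : bool
        Apply the arcsine transform before the normality check and rank tests
        (rank statistics are invariant to it; the Shapiro–Wilk check is not).
    effect_size_scale : {"raw", "transformed"}
        Scale on which Cohen's d is computed.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if effect_size_scale not in ("raw", "transformed"):
        raise ValueError("effect_size_scale must be 'raw' or 'transformed'")
    groups = {
        str(color): sub["albedo_abs"].to_numpy(dtype=float)
        for color, sub in estimates.groupby("label")
    }
    if len(groups) < 2:
        raise ValueError("need at least two colors to compare")
    for color, values in groups.items():
        if values.size < 2:
            raise ValueError(f"color {color!r} has fewer than 2 replicates")
    transformed = (
        {c: arcsine_transform(v) for c, v in groups.items()} if arcsine else groups
    )

    summary = pd.DataFrame(
        {
            "color": list(groups),
            "n": [groups[c].size for c in groups],
            "mean": [groups[c].mean() for c in groups],
            "se": [groups[c].std(ddof=1) / np.sqrt(groups[c].size) for c in groups],
        }
    )

    shapiro_rows = []
    for color, values in transformed.items():
        try:
            w, p = shapiro_wilk(values)
        except ValueError:
            w, p = np.nan, np.nan
        shapiro_rows.append({"color": color, "W": w, "p": p})
    shapiro = pd.DataFrame(shapiro_rows)

    h, kw_p = kruskal_wallis(*transformed.values())

    means = {c: groups[c].mean() for c in groups}
    if contrasts is None:
        if all(c in groups for c, _ in DEFAULT_CONTRASTS) and len(groups) == 3:
            contrasts = DEFAULT_CONTRASTS
        else:
            ordered = sorted(groups, key=lambda c: means[c], reverse=True)
            contrasts = [
                (ordered[i], ordered[j])
                for i in range(len(ordered))
                for j in range(i + 1, len(ordered))
            ]
    rows = []
    nonsig: set[frozenset] = set()
    for greater, lesser in contrasts:
        d_groups = groups if effect_size_scale == "raw" else transformed
        d = cohens_d(d_groups[greater], d_groups[lesser])
        p = exact_rank_sum_one_sided(transformed[greater], transformed[lesser])
        significant = p <= alpha
        if not significant:
            nonsig.add(frozenset((greater, lesser)))
        rows.append(
            {
                "greater": greater,
                "lesser": lesser,
                "cohens_d": d,
                "p_one_sided": p,
                "significant": significant,
            }
        )
    contrast_table = pd.DataFrame(rows)
    letters = _letter_groups(list(groups), means, nonsig)
    return GroupComparisonReport(
        summary=summary,
        shapiro=shapiro,
        kruskal_h=h,
        kruskal_p=kw_p,
        contrasts=contrast_table,
        letters=letters,
        alpha=alpha,
    )


class AlbedoGroupComparer(BaseEstimator):
    """Estimator wrapper for the per-color albedo comparison.

    Attributes (after :meth:`fit`): ``report_`` (the full
    :class:`GroupComparisonReport`), ``letters_``, ``kruskal_h_``,
    ``kruskal_p_``.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        arcsine: bool = True,
        effect_size_scale: str = "raw",
    ):
        self.alpha = alpha
        self.arcsine = arcsine
        self.effect_size_scale = effect_size_scale

    def fit(self, estimates: pd.DataFrame, y=None):
        self.report_ = compare_albedo_groups(
            estimates,
            alpha=self.alpha,
            arcsine=self.arcsine,
            effect_size_scale=self.effect_size_scale,
        )
        self.letters_ = dict(self.report_.letters)
        self.kruskal_h_ = self.report_.kruskal_h
        self.kruskal_p_ = self.report_.kruskal_p
        return self
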