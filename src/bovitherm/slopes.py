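"""Per-hide-color regression of dT on ambient temperature and slope comparison.

For each hide color, dT (animal surface minus ambient temperature) is
regressed on ambient temperature by ordinary least squares, with r-squared,
the two-sided slope p-value and 95% prediction bands (the out-of-sample
variance formula, so the band is narrowest at the predictor mean). Slope
heterogeneity across colors is then tested with an ANCOVA: an F-test of the
color-by-temperature interaction block, followed by all pairwise slope
contrasts adjusted with the studentized-range (Tukey) correction. Because the
color groups typically have unequal residual variances, a Brown–Forsythe
(median-centered) Levene test and a Kruskal–Wallis test on dT by color
accompany the ANCOVA as robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.base import BaseEstimator

from .albedo_stats import kruskal_wallis


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of dT on ambient temperature for one hide color."""

    color: str
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    p_value: float  # two-sided test of zero slope
    resid_sd: float
    n: int
    x_mean: float
    sxx: float
    df_resid: int

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def prediction_band(self, x, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """95% (by default) prediction band for a single future observation.

        Half-width ``t * s * sqrt(1 + 1/n + (x - xbar)^2 / Sxx)``; minimized
        at the predictor mean.
        """
        x = np.asarray(x, dtype=float)
        t_crit = stats.t.ppf(0.5 + level / 2.0, self.df_resid)
        half = t_crit * self.resid_sd * np.sqrt(
            1.0 + 1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx
        )
        center = self.predict(x)
        return center - half, center + half


def fit_color_regressions(
    data: pd.DataFrame,
    response: str = "delta_t",
    predictor: str = "temp_amb",
    color_col: str = "color",
) -> dict[str, SlopeFit]:
    """Fit one simple linear regression per hide color.

    Every color must contribute at least three observations (two parameters
    plus one residual degree of freedom).
    """
    fits: dict[str, SlopeFit] = {}
    for color, sub in data.groupby(color_col):
        if len(sub) < 3:
            raise ValueError(f"color {color!r} has fewer than 3 observations")
        x = sub[predictor].to_numpy(dtype=float)
        y = sub[response].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"color {color!r}: predictor is constant")
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
        fits[str(color)] = SlopeFit(
            color=str(color),
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            slope_se=float(res.bse[1]),
            r_squared=float(res.rsquared),
            p_value=float(res.pvalues[1]),
            resid_sd=resid_sd,
            n=len(sub),
            x_mean=float(x.mean()),
            sxx=float(((x - x.mean()) ** 2).sum()),
            df_resid=int(res.df_resid),
        )
    return fits


@dataclass(frozen=True)
class SlopeComparisonReport:
    """ANCOVA slope-heterogeneity results with robustness checks."""

    fits: Mapping[str, SlopeFit]
    interaction_f: float
    interaction_p: float
    pairwise: pd.DataFrame  # color_a, color_b, slope_diff, se, q, p_tukey
    levene_stat: float
    levene_p: float
    kruskal_h: float
    kruskal_p: float


def ancova_slopes(
    data: pd.DataFrame,
    response: str = "delta_t",
    predictor: str = "temp_amb",
    color_col: str = "color",
) -> SlopeComparisonReport:
    """Test whether regression slopes differ across hide colors.

    The interaction F compares the common-slope ANCOVA against the separate-
    slopes model; pairwise slope differences use the studentized-range (Tukey)
    adjustment over the all-pairs family. The separate-slopes model is
    parameterized with one slope per color, so its slope estimates coincide
    exactly with the stratified per-color regressions.
    """
    colors = sorted(map(str, data[color_col].unique()))
    if len(colors) < 2:
        raise ValueError("slope comparison requires at least two colors")
    fits = fit_color_regressions(data, response, predictor, color_col)

    df = data[[response, predictor, color_col]].copy()
    df.columns = ["y", "x", "color"]
    reduced = smf.ols("y ~ C(color) + x", data=df).fit()
    # per-color intercepts and slopes, no shared reference level
    full = smf.ols("y ~ C(color) + C(color):x - 1", data=df).fit()
    if reduced.ssr - full.ssr <= 1e-12 * max(1.0, full.ssr):
        # degenerate perfect-fit case: no interaction signal at all
        f_stat, f_p = 0.0, 1.0
    else:
        f_stat, f_p, _ = full.compare_f_test(reduced)

    slope_names = {c: f"C(color)[{c}]:x" for c in colors}
    cov = full.cov_params()
    k = len(colors)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = colors[i], colors[j]
            diff = full.params[slope_names[a]] - full.params[slope_names[b]]
            var = (
                cov.loc[slope_names[a], slope_names[a]]
                + cov.loc[slope_names[b], slope_names[b]]
                - 2 * cov.loc[slope_names[a], slope_names[b]]
            )
            se = float(np.sqrt(var))
            q = abs(diff) * np.sqrt(2.0) / se
            p = float(stats.studentized_range.sf(q, k, full.df_resid))
            rows.append(
                {
                    "color_a": a,
                    "color_b": b,
                    "slope_diff": float(diff),
                    "se": se,
                    "q": float(q),
                    "p_tukey": p,
                }
            )
    pairwise = pd.DataFrame(rows)

    groups = [data.loc[data[color_col] == c, response].to_numpy(dtype=float) for c in colors]
    lev_stat, lev_p = stats.levene(*groups, center="median")
    kw_h, kw_p = kruskal_wallis(*groups)
    return SlopeComparisonReport(
        fits=fits,
        interaction_f=float(f_stat),
        interaction_p=float(f_p),
        pairwise=pairwise,
        levene_stat=float(lev_stat),
        levene_p=float(lev_p),
        kruskal_h=kw_h,
        kruskal_p=kw_p,
    )


class ColorSlopeAnalyzer(BaseEstimator):
    """Estimator wrapper for the stratified slope analysis.

    Attributes (after :meth:`fit`): ``fits_`` (color -> :class:`SlopeFit`),
    ``report_`` (full :class:`SlopeComparisonReport`), ``slopes_``
    (color -> slope estimate).
    """

    def __init__(
        self,
        response: str = "delta_t",
        predictor: str = "temp_amb",
        color_col: str = "color",
    ):
        self.response = response
        self.predictor = predictor
        self.color_col = color_col

    def fit(self, X: pd.DataFrame, y=None):
        self.report_ = ancova_slopes(
            X, self.response, self.predictor, self.color_col
        )
        self.fits_ = dict(self.report_.fits)
        self.slopes_ = {c: f.slope for c, f in self.fits_.items()}
        return self

    def plot(self, X: pd.DataFrame, path=None):
        """Scatter + fitted line + 95% prediction band per color."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for color, fit in self.fits_.items():
            sub = X[X[self.color_col] == color]
            x = np.linspace(sub[self.predictor].min(), sub[self.predictor].max(), 100)
            lo, hi = fit.prediction_band(x)
            ax.scatter(sub[self.predictor], sub[self.response], s=6, alpha=0.4, label=color)
            ax.plot(x, fit.predict(x))
            ax.plot(x, lo, linestyle="--", linewidth=0.8)
            ax.plot(x, hi, linestyle="--", linewidth=0.8)
        ax.set_xlabel(self.predictor)
        ax.set_ylabel(self.response)
        ax.legend()
        if path is not None:
            fig.savefig(path, dpi=100)
            plt.close(fig)
        return fig
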