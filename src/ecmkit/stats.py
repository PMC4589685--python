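"""Condition-level normalization and correlation reporting.

Cross-metric comparisons (speed vs alignment, pore size vs alignment,
...) are made on min-max-normalized condition means so that units do not
bias the regressions.  Each pair is summarized by an ordinary
least-squares fit: slope, squared Pearson correlation r^2, and the
two-sided p-value for a nonzero slope (t distribution, n - 2 df).
Group comparisons (one-way ANOVA with Tukey post-test) are thin wrappers
over standard routines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DegenerateScaleError, InvalidInputError


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Rescale a metric column to [0, 1]: (v - min) / (max - min)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidInputError("need at least 2 values to normalize")
    lo, hi = np.nanmin(v), np.nanmax(v)
    if not np.isfinite(lo) or hi == lo:
        raise DegenerateScaleError("constant column: min-max scale is degenerate")
    return (v - lo) / (hi - lo)


@dataclass
class CorrelationResult:
    """OLS summary of one metric pair on normalized axes."""

    x_metric: str
    y_metric: str
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n_points: int
    excluded: tuple = ()


def regress(xs: Sequence[float], ys: Sequence[float],
            x_metric: str = "x", y_metric: str = "y") -> CorrelationResult:
    """Ordinary least squares of y on x with slope significance.

    r^2 is the squared Pearson correlation; p is the two-sided test of
    zero slope via the t distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("x and y must have equal length")
    if x.size < 3:
        raise InvalidInputError("need at least 3 points for regression")
    if np.ptp(x) == 0:
        raise DegenerateScaleError("zero variance in x: regression degenerate")
    fit = sps.linregress(x, y)
    return CorrelationResult(
        x_metric=x_metric, y_metric=y_metric,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), p_slope=float(fit.pvalue), n_points=int(x.size),
    )


def correlation_report(
    table: pd.DataFrame,
    pairs: Iterable[tuple[str, str]],
    exclude: Optional[dict[tuple[str, str], Sequence[str]]] = None,
    out_dir: Optional[str] = None,
) -> pd.DataFrame:
    """Min-max normalize condition means and regress each metric pair.

    ``table`` is indexed by condition label with one column per metric
    (condition means).  ``exclude`` maps a pair to condition labels left
    out of that regression — exclusions are always explicit, never
    automatic, and are recorded verbatim in the output.  With ``out_dir``
    a scatter + fit-line figure is written per pair.
    """
    exclude = exclude or {}
    results = []
    for pair in pairs:
        xm, ym = pair
        for m in (xm, ym):
            if m not in table.columns:
                raise ConfigError(f"unknown metric {m!r}; table has {list(table.columns)}")
        dropped = tuple(exclude.get(pair, ()))
        unknown = [d for d in dropped if d not in table.index]
        if unknown:
            raise ConfigError(f"excluded conditions not in table: {unknown}")
        sub = table.drop(index=list(dropped))[[xm, ym]].dropna()
        xn = minmax_normalize(sub[xm].to_numpy())
        yn = minmax_normalize(sub[ym].to_numpy())
        res = regress(xn, yn, x_metric=xm, y_metric=ym)
        res.excluded = dropped
        results.append(res)
        if out_dir is not None:
            _plot_pair(sub.index, xn, yn, res, out_dir)
    return pd.DataFrame(
        [
            {"x_metric": r.x_metric, "y_metric": r.y_metric, "slope": r.slope,
             "intercept": r.intercept, "r_squared": r.r_squared, "p_slope": r.p_slope,
             "n_points": r.n_points, "excluded": ";".join(r.excluded)}
            for r in results
        ]
    )


def _plot_pair(labels, xn, yn, res: CorrelationResult, out_dir: str) -> None:
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(xn, yn, color="k", zorder=3)
    for lab, x, y in zip(labels, xn, yn):
        ax.annotate(str(lab), (x, y), fontsize=7, xytext=(3, 3), textcoords="offset points")
    grid = np.linspace(0, 1, 50)
    ax.plot(grid, res.intercept + res.slope * grid, "r-")
    ax.set_xlabel(f"normalized {res.x_metric}")
    ax.set_ylabel(f"normalized {res.y_metric}")
    ax.set_title(
        f"slope={res.slope:.2f}, r$^2$={res.r_squared:.2f}, p={res.p_slope:.3g}", fontsize=9
    )
    fig.tight_layout()
    path = pathlib.Path(out_dir) / f"corr_{res.x_metric}_vs_{res.y_metric}.png"
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def anova_tukey(groups: dict[str, Sequence[float]], alpha: float = 0.05):
    """One-way ANOVA across condition groups with a Tukey HSD post-test.

    Reporting convenience delegated to standard routines; returns
    ``(anova_p, tukey_table)``.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise InvalidInputError("need at least 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    _, p = sps.f_oneway(*arrays)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    codes = np.concatenate([[k] * len(a) for k, a in zip(labels, arrays)])
    tukey = pairwise_tukeyhsd(values, codes, alpha=alpha)
    frame = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return float(p), frame
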