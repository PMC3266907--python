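"""Thermal tolerance versus geographic range size.

Across species, a wider realized thermal tolerance should permit a wider
latitudinal and longitudinal distribution.  This module quantifies that
relationship by ordinary least squares of log-transformed range size on
the maximum thermal tolerance range, reporting Pearson r, R-squared and a
two-sided p-value from the t distribution with n-2 degrees of freedom.
R-squared is invariant to the logarithm base (an affine change of y), so
the base only affects slope and intercept.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .thermal import SpeciesThermalSummary, summaries_to_frame

__all__ = [
    "RegressionResult",
    "tolerance_range_regression",
    "association_report",
]


@dataclass
class RegressionResult:
    axis: str  # "lat" | "lon"
    n: int
    slope: float
    intercept: float
    r: float
    r_squared: float
    pvalue: float
    log_base: float
    excluded: List[str]

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "r_squared": self.r_squared,
            "pvalue": self.pvalue,
            "log_base": self.log_base,
            "excluded": list(self.excluded),
        }


def _as_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries
    return summaries_to_frame(list(summaries))


def tolerance_range_regression(
    summaries,
    axis: str = "lat",
    log_base: float = 10.0,
) -> RegressionResult:
    """OLS of log(range size) on the maximum thermal tolerance range.

    ``summaries`` is a sequence of :class:`SpeciesThermalSummary` or a
    DataFrame with columns ``species``, ``max_range_c`` and
    ``lat_range``/``lon_range``.  Species with non-positive range on the
    chosen axis are excluded with a warning (log undefined); at least 3
    usable species and non-degenerate variance are required.
    """
    if axis not in ("lat", "lon"):
        raise ValueError("axis must be 'lat' or 'lon'")
    if log_base <= 0 or log_base == 1:
        raise ValueError("log base must be positive and != 1")
    df = _as_frame(summaries)
    col = f"{axis}_range"
    usable = df[df[col] > 0]
    excluded = sorted(df.loc[df[col] <= 0, "species"])
    if excluded:
        warnings.warn(
            f"excluded species with non-positive {axis} range: {excluded}"
        )
    if len(usable) < 3:
        raise ValueError(f"need >= 3 species with positive {axis} range")
    x = usable["max_range_c"].to_numpy(dtype=float)
    y = np.log(usable[col].to_numpy(dtype=float)) / np.log(log_base)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in regression input")
    fit = stats.linregress(x, y)
    return RegressionResult(
        axis=axis,
        n=len(usable),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        pvalue=float(fit.pvalue),
        log_base=float(log_base),
        excluded=excluded,
    )


def association_report(
    results: Sequence[RegressionResult],
    out_dir: str,
    summaries=None,
    plot: bool = False,
) -> pd.DataFrame:
    """Write coefficient CSV + JSON (and optionally a labelled scatter
    plot per axis) under ``out_dir``; returns the coefficient table."""
    results = list(results)
    if not results:
        raise ValueError("no regression results to report")
    os.makedirs(out_dir, exist_ok=True)
    table = pd.DataFrame([r.to_dict() for r in results]).drop(columns="excluded")
    table.to_csv(os.path.join(out_dir, "association.csv"), index=False)
    with open(os.path.join(out_dir, "association.json"), "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)
    if plot:
        _plot(results, _as_frame(summaries), out_dir)
    return table


def _plot(results, df: pd.DataFrame, out_dir: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(results), figsize=(5 * len(results), 4))
    axes = np.atleast_1d(axes)
    for ax, res in zip(axes, results):
        col = f"{res.axis}_range"
        sub = df[df[col] > 0]
        x = sub["max_range_c"]
        y = np.log(sub[col]) / np.log(res.log_base)
        ax.scatter(x, y, s=18, color="k")
        for _, row in sub.iterrows():
            ax.annotate(
                str(row["species"])[:4],
                (row["max_range_c"], np.log(row[col]) / np.log(res.log_base)),
                fontsize=7,
                xytext=(3, 3),
                textcoords="offset points",
            )
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, res.intercept + res.slope * xs, color="0.4")
        ax.set_xlabel("max thermal tolerance range (deg C)")
        ax.set_ylabel(f"log{res.log_base:g}({res.axis} range)")
        ax.set_title(f"R$^2$ = {res.r_squared:.3f} (p = {res.pvalue:.3g})")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "association.svg"))
    plt.close(fig)
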