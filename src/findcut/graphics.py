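"""Visual aids: smoothed hazard-ratio curve, Kaplan-Meier plot, profiles.

The smoothed HR curve fits a Cox model with a natural cubic spline basis in
the risk factor and plots the fitted log hazard ratio relative to a
reference value (by default the curve minimizer, the "safest" value of the
factor), with pointwise 95% bands from the coefficient covariance.  All
plot functions are pure renderers: they write a figure file and return its
path without mutating their inputs; the underlying curve data can be dumped
as TSV so figures are reproducible without the plotting layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .data_model import CohortTable
from .exceptions import ConfigurationError
from .model_selection import AICProfile
from .search import SearchResult
from .stats_core import KMCurve, TestResult

logger = logging.getLogger(__name__)

__all__ = [
    "HRCurve",
    "smooth_hr_curve",
    "plot_hr_curve",
    "plot_km",
    "plot_profiles",
    "natural_spline_basis",
]

_Z95 = 1.959963984540054


def natural_spline_basis(x, knots) -> np.ndarray:
    """Natural cubic spline basis (linear beyond boundary knots).

    With K knots the returned matrix has K-1 columns (no intercept column),
    the standard truncated-power construction: x itself plus
    d_k(x) - d_{K-1}(x) for k = 1..K-2, where
    d_k(x) = [(x - k_k)^3_+ - (x - k_K)^3_+] / (k_K - k_k).
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    K = len(knots)
    if K < 3:
        raise ConfigurationError("need at least 3 distinct knots")

    def d(k):
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[k])

    dlast = d(K - 2)
    cols = [x] + [d(k) - dlast for k in range(K - 2)]
    return np.column_stack(cols)


@dataclass
class HRCurve:
    """Fitted ln HR(z) relative to ``z_ref`` with pointwise 95% bands."""

    z_grid: np.ndarray
    log_hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    z_ref: float
    df_spline: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": self.z_grid,
                "log_hr": self.log_hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    @property
    def argmin_z(self) -> float:
        return float(self.z_grid[np.argmin(self.log_hr)])


def smooth_hr_curve(
    cohort: CohortTable,
    df_spline: int = 4,
    z_ref: float | None = None,
    n_grid: int = 200,
) -> HRCurve:
    """Spline-Cox smoothed hazard-ratio curve over the observed z range.

    ``df_spline`` natural-cubic-spline degrees of freedom (knots at evenly
    spaced quantiles between the 5th and 95th percentiles).  ``z_ref``
    defaults to the fitted-curve minimizer, where ln HR is pinned to 0.
    """
    if cohort.mode != "survival":
        raise ConfigurationError("the smoothed HR curve requires a survival outcome")
    z, time, event = cohort.z, cohort.time, cohort.event
    if event.sum() < 20:
        warnings.warn(
            "fewer than 20 events; the smoothed HR curve will be unstable",
            stacklevel=2,
        )
    knots = np.unique(np.quantile(z, np.linspace(0.05, 0.95, df_spline + 1)))
    if len(knots) < max(3, df_spline + 1):
        raise ConfigurationError(
            f"too few distinct risk-factor values for a df={df_spline} spline basis"
        )
    B = natural_spline_basis(z, knots)
    df = pd.DataFrame(B, columns=[f"s{j}" for j in range(B.shape[1])])
    df["_t"] = time
    df["_e"] = event
    cph = CoxPHFitter(penalizer=1e-6)  # tiny ridge for numerical stability
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_t", event_col="_e")
    beta = cph.params_.to_numpy()
    cov = cph.variance_matrix_.to_numpy()
    grid = np.linspace(z.min(), z.max(), n_grid)
    Bg = natural_spline_basis(grid, knots)
    eta = Bg @ beta
    if z_ref is None:
        z_ref = float(grid[np.argmin(eta)])
    Bref = natural_spline_basis(np.array([z_ref]), knots)
    D = Bg - Bref  # contrast vs the reference value
    log_hr = D @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, cov, D), 0.0))
    return HRCurve(
        z_grid=grid,
        log_hr=log_hr,
        ci_low=log_hr - _Z95 * se,
        ci_high=log_hr + _Z95 * se,
        z_ref=z_ref,
        df_spline=df_spline,
    )


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_hr_curve(curve: HRCurve, path, z_values=None, cuts=None):
    """Render the smoothed HR curve, optionally with a histogram of z
    beneath it and vertical lines at chosen cutpoints."""
    plt = _plt()
    if z_values is not None:
        fig, (ax, axh) = plt.subplots(
            2, 1, sharex=True, height_ratios=[4, 1], figsize=(7, 5)
        )
    else:
        fig, ax = plt.subplots(figsize=(7, 4))
        axh = None
    ax.plot(curve.z_grid, np.exp(curve.log_hr), color="C0")
    ax.fill_between(
        curve.z_grid, np.exp(curve.ci_low), np.exp(curve.ci_high), alpha=0.2
    )
    ax.axhline(1.0, color="grey", lw=0.8, ls=":")
    ax.annotate(
        f"ref = {curve.z_ref:g}",
        (curve.z_ref, 1.0),
        textcoords="offset points",
        xytext=(5, 5),
    )
    if cuts is not None:
        for c in cuts:
            ax.axvline(c, color="C3", ls="--", lw=0.9)
    ax.set_ylabel("hazard ratio")
    ax.set_yscale("log")
    if axh is not None:
        axh.hist(z_values, bins=40, color="grey")
        axh.set_ylabel("count")
        axh.set_xlabel("risk factor")
    else:
        ax.set_xlabel("risk factor")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_km(curves: list[KMCurve], logrank: TestResult | None, path):
    """Step Kaplan-Meier curves per risk group with a log-rank annotation."""
    if not curves:
        raise ConfigurationError("no Kaplan-Meier curves to plot")
    plt = _plt()
    fig, ax = plt.subplots(figsize=(7, 5))
    for c in curves:
        ax.step(
            c.times,
            c.survival,
            where="post",
            label=f"group {c.group} (n={c.n}, events={c.n_events})",
        )
    if logrank is not None and len(curves) > 1:
        ax.text(
            0.05,
            0.05,
            f"log-rank p = {logrank.p:.3g}",
            transform=ax.transAxes,
        )
    ax.set_xlabel("time (years)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_profiles(
    profile: AICProfile | None, surface: SearchResult | None, path_prefix
) -> list:
    """AIC-vs-K line plot and the criterion surface (curve for one cut,
    lower-triangular heat map for two)."""
    plt = _plt()
    paths = []
    if profile is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        e = profile.entries.sort_values("k")
        ax.plot(e["k"], e["aic"], marker="o")
        ax.axvline(profile.best_k, color="C3", ls="--", lw=0.9)
        ax.set_xlabel("number of cutpoints K")
        ax.set_ylabel("AIC")
        ax.set_xticks(e["k"])
        fig.tight_layout()
        p = f"{path_prefix}_aic.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)
    if surface is not None:
        surf = surface.surface
        if len(surf) == 0:
            raise ConfigurationError("empty search surface")
        fig, ax = plt.subplots(figsize=(6, 4.5))
        if surface.k == 1:
            ax.plot(surf["cut1"], surf["value"], lw=1)
            ax.axvline(surface.best.cuts[0], color="C3", ls="--", lw=0.9)
            ax.set_xlabel("cutpoint")
            ax.set_ylabel(surface.criterion)
        else:
            pv = surf.pivot_table(index="cut2", columns="cut1", values="value")
            im = ax.pcolormesh(pv.columns, pv.index, pv.to_numpy(), shading="auto")
            fig.colorbar(im, ax=ax, label=surface.criterion)
            ax.plot(*surface.best.cuts[:2], "r*", ms=12)
            ax.set_xlabel("cut 1")
            ax.set_ylabel("cut 2")
        fig.tight_layout()
        p = f"{path_prefix}_surface.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)
    return paths
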