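"""Plots over metastatement results: scatter with OLS trend, 1D/2D histograms.

Every plotting function returns its underlying numbers (points, bin counts,
fit parameters) so analyses and tests never have to parse images.  Figures
are written only when a filename is given; the format follows the file
extension (PNG at 300 dpi by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from confmeta.geometry import IgnoreList  # noqa: E402
from confmeta.metastatement import Node, evaluate, unparse  # noqa: E402
from confmeta.sdf_core import ABSENT, Ensemble  # noqa: E402


class PlotError(ValueError):
    pass


def _statement_label(stmt: Node | str) -> str:
    return stmt if isinstance(stmt, str) else unparse(stmt)


def _numeric_singles(
    ens: Ensemble, stmt: Node | str, ignore: IgnoreList | None
) -> list[float | None]:
    out: list[float | None] = []
    for v in evaluate(stmt, ens, ignore):
        if v is ABSENT or isinstance(v, (dict, list, str)):
            out.append(None)
        else:
            out.append(float(v))
    return out


def _paired(ens, x_stmt, y_stmt, ignore):
    xs = _numeric_singles(ens, x_stmt, ignore)
    ys = _numeric_singles(ens, y_stmt, ignore)
    pairs = [(x, y) for x, y in zip(xs, ys) if x is not None and y is not None]
    return np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])


@dataclass
class ScatterResult:
    x: np.ndarray
    y: np.ndarray
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    figure: object = None


@dataclass
class HistResult:
    counts: np.ndarray
    edges: tuple[np.ndarray, ...]
    figure: object = None


def _save(fig, filename: str | None) -> None:
    if filename:
        fig.savefig(filename, dpi=300)


def ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares y = a*x + b with R² = 1 − SSres/SStot."""
    if len(x) < 2:
        raise PlotError("trend line needs at least 2 points")
    a, b = np.polyfit(x, y, 1)
    pred = a * x + b
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    # guard tiny negative round-off on near-perfect fits
    if -1e-12 < r2 < 0:
        r2 = 0.0
    if ss_res < 1e-12 * max(ss_tot, 1.0):
        r2 = 1.0
    return float(a), float(b), r2


def scatter(
    ens: Ensemble,
    x_stmt: Node | str,
    y_stmt: Node | str,
    trend: bool = False,
    save: str | None = None,
    ignore: IgnoreList | None = None,
) -> ScatterResult:
    """Scatter of two per-record statements; records ABSENT in either axis
    are dropped pairwise.  With ``trend`` an OLS line and R² are added."""
    x, y = _paired(ens, x_stmt, y_stmt, ignore)
    if len(x) == 0:
        raise PlotError("no records produced values on both axes")
    res = ScatterResult(x, y)
    fig, ax = plt.subplots()
    ax.scatter(x, y, s=12)
    ax.set_xlabel(_statement_label(x_stmt))
    ax.set_ylabel(_statement_label(y_stmt))
    if trend:
        a, b, r2 = ols_fit(x, y)
        res.slope, res.intercept, res.r_squared = a, b, r2
        xs = np.array([x.min(), x.max()])
        ax.plot(xs, a * xs + b, color="red")
        ax.set_title(f"y = {a:.4g}x + {b:.4g},  R² = {r2:.4f}")
    res.figure = fig
    _save(fig, save)
    plt.close(fig)
    return res


def hist1d(
    ens: Ensemble,
    stmt: Node | str,
    bins: int = 20,
    save: str | None = None,
    ignore: IgnoreList | None = None,
) -> HistResult:
    """Equal-width histogram over [min, max]; the right-most edge is
    inclusive, so the counts always sum to the contributing records."""
    values = [v for v in _numeric_singles(ens, stmt, ignore) if v is not None]
    if not values:
        raise PlotError("statement produced no numeric values")
    arr = np.asarray(values, dtype=float)
    counts, edges = np.histogram(arr, bins=bins, range=(arr.min(), arr.max()))
    fig, ax = plt.subplots()
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge")
    ax.set_xlabel(_statement_label(stmt))
    ax.set_ylabel("count")
    res = HistResult(counts, (edges,), fig)
    _save(fig, save)
    plt.close(fig)
    return res


def hist2d(
    ens: Ensemble,
    x_stmt: Node | str,
    y_stmt: Node | str,
    bins: tuple[int, int] = (15, 15),
    save: str | None = None,
    ignore: IgnoreList | None = None,
) -> HistResult:
    """2D histogram (heatmap) of two statements with pairwise ABSENT drops."""
    x, y = _paired(ens, x_stmt, y_stmt, ignore)
    if len(x) == 0:
        raise PlotError("no records produced values on both axes")
    counts, xedges, yedges = np.histogram2d(x, y, bins=bins)
    fig, ax = plt.subplots()
    ax.pcolormesh(xedges, yedges, counts.T)
    ax.set_xlabel(_statement_label(x_stmt))
    ax.set_ylabel(_statement_label(y_stmt))
    res = HistResult(counts, (xedges, yedges), fig)
    _save(fig, save)
    plt.close(fig)
    return res
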