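"""Marey-map estimation of local homologous recombination rate.

A Marey map plots genetic position (cM) against physical position (bp) for
the markers of a linkage map; the slope of a smooth fit through the points
is the local recombination rate in cM/Mb. Markers are curated to enforce
the monotonicity a genetic map implies, a tricube-weighted local polynomial
(loess) is fitted per chromosome, and its analytic first derivative is
evaluated at 1 Mb window midpoints.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._loess import loess_fit

__all__ = ["curate_markers", "local_rate", "MareyMap", "MareyResults"]


def _lnds_keep(values: np.ndarray) -> np.ndarray:
    """Indices of a longest non-decreasing subsequence (patience sorting)."""
    tails: list[float] = []  # smallest tail value of each subsequence length
    tail_idx: list[int] = []
    prev = np.full(len(values), -1)
    for i, v in enumerate(values):
        j = bisect_right(tails, v)
        if j == len(tails):
            tails.append(v)
            tail_idx.append(i)
        else:
            tails[j] = v
            tail_idx[j] = i
        prev[i] = tail_idx[j - 1] if j > 0 else -1
    keep = []
    i = tail_idx[-1]
    while i >= 0:
        keep.append(i)
        i = prev[i]
    return np.asarray(keep[::-1])


def curate_markers(markers: pd.DataFrame, min_markers: int = 5) -> pd.DataFrame:
    """Remove aberrant markers so cM is non-decreasing in physical order.

    Duplicate physical positions are collapsed to their median cM; then the
    minimal set of monotonicity-violating markers is dropped by retaining a
    longest non-decreasing subsequence of cM values. Chromosomes left with
    fewer than ``min_markers`` markers are excluded with a warning.
    """
    out = []
    for chrom, grp in markers.groupby("chrom", sort=False, observed=True):
        grp = grp.sort_values("pos_bp", kind="stable")
        collapsed = (
            grp.groupby("pos_bp", as_index=False)
            .agg(marker=("marker", "first"), cM=("cM", "median"))
            .assign(chrom=chrom)
        )
        keep = _lnds_keep(collapsed["cM"].to_numpy())
        cur = collapsed.iloc[keep]
        if len(cur) < min_markers:
            warnings.warn(f"{chrom}: fewer than {min_markers} markers after curation; excluded")
            continue
        out.append(cur[["marker", "chrom", "pos_bp", "cM"]])
    if not out:
        return pd.DataFrame(columns=["marker", "chrom", "pos_bp", "cM"])
    return pd.concat(out, ignore_index=True)


def local_rate(
    markers: pd.DataFrame,
    chrom_lengths: dict,
    window_bp: int = 1_000_000,
    span: float = 0.2,
    degree: int = 2,
) -> pd.DataFrame:
    """Loess-smoothed recombination rate (cM/Mb) at 1 Mb window midpoints.

    The rate is the analytic first derivative of the local polynomial fit of
    cM on bp, clipped below at 0. Windows whose midpoint falls outside the
    chromosome's marker span get NaN.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        grp = markers[markers["chrom"] == chrom].sort_values("pos_bp")
        n_win = int(np.ceil(length / window_bp))
        mid = (np.arange(n_win) + 0.5) * window_bp
        rate = np.full(n_win, np.nan)
        fitted = np.full(n_win, np.nan)
        if len(grp) >= degree + 2:
            x = grp["pos_bp"].to_numpy(dtype=float)
            y = grp["cM"].to_numpy(dtype=float)
            inside = (mid >= x.min()) & (mid <= x.max())
            if inside.any():
                vals, slopes = loess_fit(x, y, mid[inside], span=span, degree=degree)
                fitted[inside] = vals
                rate[inside] = np.clip(slopes * 1e6, 0.0, None)  # cM/bp -> cM/Mb
        for w in range(n_win):
            rows.append(
                {
                    "chrom": chrom,
                    "window": w,
                    "start": w * window_bp,
                    "end": min((w + 1) * window_bp, length),
                    "cM_fit": fitted[w],
                    "hr_rate": rate[w],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MareyResults:
    """Curated markers and per-window recombination rates."""

    markers: pd.DataFrame
    rates: pd.DataFrame
    span: float
    degree: int

    def map_lengths(self) -> pd.Series:
        """Genetic length (cM) per chromosome from the curated markers."""
        g = self.markers.groupby("chrom", observed=True)["cM"]
        return g.max() - g.min()

    def integrated_rates(self, window_bp: int = 1_000_000) -> pd.Series:
        """Sum of window rates x window size (cM) per chromosome."""
        r = self.rates.dropna(subset=["hr_rate"])
        return r.groupby("chrom", observed=True)["hr_rate"].sum() * window_bp / 1e6

    def summary(self) -> str:
        ml = self.map_lengths()
        ir = self.integrated_rates()
        lines = [
            "Marey map summary",
            "=================",
            f"chromosomes: {len(ml)}  markers: {len(self.markers)}",
            f"loess span={self.span} degree={self.degree}",
            "chrom  map_cM  integrated_cM",
        ]
        for chrom in ml.index:
            lines.append(f"{chrom}  {ml[chrom]:8.2f}  {ir.get(chrom, float('nan')):8.2f}")
        return "\n".join(lines)

    def plot(self, chrom, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.markers[self.markers["chrom"] == chrom]
        r = self.rates[self.rates["chrom"] == chrom]
        ax.plot(m["pos_bp"] / 1e6, m["cM"], ".", ms=3, label="markers")
        ax.plot(r["start"] / 1e6 + 0.5, r["cM_fit"], "-", label="loess fit")
        ax.set_xlabel("physical position (Mb)")
        ax.set_ylabel("genetic position (cM)")
        ax.set_title(str(chrom))
        ax.legend()
        return ax


class MareyMap:
    """Marey map over a marker table (marker, chrom, pos_bp, cM)."""

    def __init__(self, markers: pd.DataFrame, chrom_lengths: dict,
                 window_bp: int = 1_000_000, span: float = 0.2, degree: int = 2,
                 min_markers: int = 5):
        self.markers = markers
        self.chrom_lengths = chrom_lengths
        self.window_bp = int(window_bp)
        self.span = float(span)
        self.degree = int(degree)
        self.min_markers = int(min_markers)

    def fit(self) -> MareyResults:
        curated = curate_markers(self.markers, self.min_markers)
        rates = local_rate(
            curated, self.chrom_lengths, self.window_bp, self.span, self.degree
        )
        return MareyResults(markers=curated, rates=rates, span=self.span, degree=self.degree)
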