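"""Association statistics: correlations between HE frequency and genomic
features at chromosome and 1 Mb-window scales, proportion/Fisher tests for
aneuploidy event contrasts, and loess profile smoothing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._loess import loess_fit

__all__ = [
    "pearson",
    "two_prop_test",
    "fisher_2x2",
    "smooth_profile",
    "build_window_table",
    "build_chrom_table",
    "build_reports",
]


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value (n-2 df).

    Pairs with a missing value in either vector are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def two_prop_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided test of equal proportions (2x2 chi-square, Yates-corrected).

    Matches R's ``prop.test(c(x1, x2), c(n1, n2))``.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError("successes must lie in [0, n]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    if table.sum(axis=0).min() == 0:  # both all-success or all-failure
        return 1.0
    _, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(p)


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact test on a 2x2 count table."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def smooth_profile(positions, values, span: float = 0.2, degree: int = 2) -> np.ndarray:
    """Loess-smooth a positional profile, evaluated at the input positions."""
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if positions.size < 10:
        raise ValueError("need at least 10 points to smooth")
    fitted, _ = loess_fit(positions, values, positions, span=span, degree=degree)
    return fitted


# ---------------------------------------------------------------------------
# report tables

#: feature columns of the window-scale correlation report, in display order
WINDOW_FEATURES = [
    ("SNPs", "n_snp"),
    ("Small indels (1-99 bp)", "n_small_indel"),
    ("Large indels (>=100 bp)", "n_large_indel"),
    ("TIPs", "n_tip"),
    ("Retrotransposon TIPs", "n_tip_retrotransposon"),
    ("DNA transposon TIPs", "n_tip_DNA_transposon"),
    ("MITE TIPs", "n_tip_MITE"),
    ("Shared TEs", "n_shared"),
    ("Shared retrotransposons", "n_shared_retrotransposon"),
    ("Shared DNA transposons", "n_shared_DNA_transposon"),
    ("Shared MITEs", "n_shared_MITE"),
]

CHROM_FEATURES = [
    ("Physical length", "length_bp"),
    ("Genetic length", "length_cm"),
    ("% gene bases", "pct_gene"),
    ("% TE bases", "pct_te"),
    ("% retrotransposon bases", "pct_retrotransposon"),
    ("% DNA transposon bases", "pct_DNA_transposon"),
    ("% MITE bases", "pct_MITE"),
]


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def build_window_table(
    he_freq: pd.DataFrame,
    hr_rates: pd.DataFrame | None = None,
    variant_density: pd.DataFrame | None = None,
    base_fractions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join the per-window tracks on their shared (chrom, window) tiling."""
    out = he_freq.copy()
    for other in (hr_rates, variant_density, base_fractions):
        if other is None:
            continue
        cols = [c for c in other.columns if c not in ("start", "end")]
        out = out.merge(other[cols], on=["chrom", "window"], how="left")
    return out


def build_chrom_table(
    chrom_features: pd.DataFrame,
    he_counts: pd.DataFrame,
    map_lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-chromosome feature table with mean HE count across individuals."""
    mean_he = he_counts.groupby("chrom", observed=True)["n_he"].mean().rename("mean_he")
    out = chrom_features.merge(mean_he, on="chrom", how="left")
    if map_lengths is not None:
        out = out.merge(map_lengths.rename("length_cm"), on="chrom", how="left")
    return out


def _correlation_rows(df: pd.DataFrame, target: str, feature_list) -> pd.DataFrame:
    rows = []
    for label, col in feature_list:
        if col not in df.columns or df[col].dropna().empty:
            rows.append({"feature": label, "r": np.nan, "p": np.nan, "signif": ""})
            continue
        try:
            r, p = pearson(df[target], df[col])
        except ValueError:
            r, p = np.nan, np.nan
        rows.append({"feature": label, "r": r, "p": p, "signif": _stars(p)})
    return pd.DataFrame(rows)


def build_reports(
    chrom_table: pd.DataFrame | None,
    window_table: pd.DataFrame | None,
    span: float = 0.2,
    degree: int = 2,
) -> dict:
    """Chromosome-scale and window-scale correlation reports plus smoothed
    per-chromosome HE/HR profiles.

    Returns a dict with keys ``chromosome_correlations`` (HE count vs
    chromosome features), ``window_correlations`` (local HE frequency vs
    variant/TE densities, two-tier significance stars), ``he_vs_hr``
    ((r, p) of local HE frequency vs local HR rate), and ``profiles``.
    """
    out: dict = {}
    if chrom_table is not None:
        feats = [(lbl, col) for lbl, col in CHROM_FEATURES if col in chrom_table.columns]
        out["chromosome_correlations"] = _correlation_rows(chrom_table, "mean_he", feats)
    if window_table is not None:
        out["window_correlations"] = _correlation_rows(
            window_table, "he_frequency", WINDOW_FEATURES
        )
        extra = [(lbl, col) for lbl, col in
                 [("Gene base fraction", "frac_gene"),
                  ("Retrotransposon base fraction", "frac_retrotransposon"),
                  ("DNA transposon base fraction", "frac_DNA_transposon"),
                  ("MITE base fraction", "frac_MITE")]
                 if col in window_table.columns]
        if extra:
            out["window_feature_correlations"] = _correlation_rows(
                window_table, "he_frequency", extra
            )
        if "hr_rate" in window_table.columns and window_table["hr_rate"].notna().sum() >= 3:
            r, p = pearson(window_table["he_frequency"], window_table["hr_rate"])
            out["he_vs_hr"] = {"r": r, "p": p}
        profiles = []
        for chrom, grp in window_table.groupby("chrom", sort=False, observed=True):
            grp = grp.sort_values("window").copy()
            mid = grp["start"].to_numpy(dtype=float) + 0.5e6
            if len(grp) >= 10:
                grp["he_smooth"] = smooth_profile(mid, grp["he_frequency"], span, degree)
                if "hr_rate" in grp.columns and grp["hr_rate"].notna().sum() >= 10:
                    ok = grp["hr_rate"].notna().to_numpy()
                    sm = np.full(len(grp), np.nan)
                    sm[ok] = smooth_profile(mid[ok], grp.loc[ok, "hr_rate"], span, degree)
                    grp["hr_smooth"] = sm
            profiles.append(grp)
        out["profiles"] = pd.concat(profiles, ignore_index=True) if profiles else pd.DataFrame()
    return out
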