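"""Genomic feature summaries: base-coverage fractions, TE classification,
and per-window variant densities.

TE insertions observed at population frequency > 0.95 in a parent count as
present and < 0.05 as absent; a presence/absence contrast between the two
parents is a transposon insertion polymorphism (TIP), presence in both is a
shared TE, and anything in between is left unclassified and excluded from
downstream association tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "TE_CLASSES",
    "merge_intervals",
    "percent_bases",
    "window_base_fractions",
    "classify_te",
    "classify_te_table",
    "window_variant_density",
    "chromosome_features",
]

TE_CLASSES = ("retrotransposon", "DNA_transposon", "MITE")


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent half-open intervals."""
    if len(starts) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    ms, me = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= me[-1]:
            me[-1] = max(me[-1], e[i])
        else:
            ms.append(s[i])
            me.append(e[i])
    return np.asarray(ms), np.asarray(me)


def percent_bases(
    track: pd.DataFrame,
    chrom: str,
    start: int = 0,
    end: int | None = None,
    cls: str | None = None,
    chrom_lengths: dict | None = None,
    warn_clip: bool = True,
) -> float:
    """Fraction of a region's bases covered by a feature track.

    Overlapping intervals are merged before summing. Intervals extending
    outside the region are clipped with a warning.
    """
    if end is None:
        if chrom_lengths is None or chrom not in chrom_lengths:
            raise ValueError("end or chrom_lengths required")
        end = chrom_lengths[chrom]
    if end <= start:
        raise ValueError("empty region")
    sel = track[track["chrom"] == chrom]
    if cls is not None:
        sel = sel[sel["class"] == cls]
    if sel.empty:
        return 0.0
    s = sel["start"].to_numpy()
    e = sel["end"].to_numpy()
    overlap = (e > start) & (s < end)
    s, e = s[overlap], e[overlap]
    if warn_clip and len(s) and ((s < start).any() or (e > end).any()):
        warnings.warn("intervals extend outside the region; clipped")
    s = np.clip(s, start, end)
    e = np.clip(e, start, end)
    ms, me = merge_intervals(s, e)
    return float((me - ms).sum() / (end - start))


def window_base_fractions(
    track: pd.DataFrame,
    chrom_lengths: dict,
    window_bp: int = 1_000_000,
    classes: tuple | None = None,
) -> pd.DataFrame:
    """Per-1 Mb-window covered-base fraction, one column per feature class."""
    if classes is None:
        classes = tuple(track["class"].unique()) if "class" in track.columns else (None,)
    rows = []
    for chrom, length in chrom_lengths.items():
        n_win = int(np.ceil(length / window_bp))
        for w in range(n_win):
            ws, we = w * window_bp, min((w + 1) * window_bp, length)
            row = {"chrom": chrom, "window": w, "start": ws, "end": we}
            for cls in classes:
                key = f"frac_{cls}" if cls else "frac"
                row[key] = percent_bases(track, chrom, ws, we, cls=cls, warn_clip=False)
            rows.append(row)
    return pd.DataFrame(rows)


def classify_te(freq_a: float, freq_b: float, hi: float = 0.95, lo: float = 0.05) -> str:
    """Presence/absence status of one TE insertion from parental frequencies.

    Returns 'shared' (present/present), 'TIP_A' (present only in parent A),
    'TIP_B', or 'unclassified' when either frequency is indeterminate.
    """
    if not (0.0 <= freq_a <= 1.0 and 0.0 <= freq_b <= 1.0):
        raise ValueError("frequencies must be in [0, 1]")

    def state(f):
        if f > hi:
            return "present"
        if f < lo:
            return "absent"
        return "indeterminate"

    sa, sb = state(freq_a), state(freq_b)
    if sa == "present" and sb == "present":
        return "shared"
    if sa == "present" and sb == "absent":
        return "TIP_A"
    if sa == "absent" and sb == "present":
        return "TIP_B"
    return "unclassified"


def classify_te_table(
    te_table: pd.DataFrame, hi: float = 0.95, lo: float = 0.05
) -> pd.DataFrame:
    """Vectorised classify_te over a TE table with freq_9311/freq_nip columns."""
    fa = te_table["freq_9311"].to_numpy(dtype=float)
    fb = te_table["freq_nip"].to_numpy(dtype=float)
    if ((fa < 0) | (fa > 1) | (fb < 0) | (fb > 1)).any():
        raise ValueError("frequencies must be in [0, 1]")
    pa, aa = fa > hi, fa < lo
    pb, ab = fb > hi, fb < lo
    status = np.full(len(te_table), "unclassified", dtype=object)
    status[pa & pb] = "shared"
    status[pa & ab] = "TIP_A"
    status[aa & pb] = "TIP_B"
    out = te_table.copy()
    out["status"] = status
    return out


def window_variant_density(
    snps: pd.DataFrame,
    indels: pd.DataFrame,
    te_table: pd.DataFrame,
    chrom_lengths: dict,
    window_bp: int = 1_000_000,
    large_indel_bp: int = 100,
) -> pd.DataFrame:
    """Per-window counts of SNPs, small/large indels, TIPs and shared TEs.

    Indels of length 1..large_indel_bp-1 are small and >= large_indel_bp
    large, so the two classes partition all lengths >= 1. TE insertions are
    classified from their parental frequencies; unclassified insertions are
    not counted.
    """
    if len(indels) and (indels["length"] <= 0).any():
        raise ValueError("indel length must be >= 1")
    te = classify_te_table(te_table) if len(te_table) else te_table.assign(status=[])

    rows = []
    for chrom, length in chrom_lengths.items():
        n_win = int(np.ceil(length / window_bp))
        base = {c: np.zeros(n_win) for c in ["n_snp", "n_small_indel", "n_large_indel"]}
        for cls in TE_CLASSES:
            base[f"n_tip_{cls}"] = np.zeros(n_win)
            base[f"n_shared_{cls}"] = np.zeros(n_win)

        def widx(positions):
            return np.clip(((np.asarray(positions) - 1) // window_bp).astype(int), 0, n_win - 1)

        if len(snps):
            sel = snps[snps["chrom"] == chrom]
            np.add.at(base["n_snp"], widx(sel["pos"]), 1)
        if len(indels):
            sel = indels[indels["chrom"] == chrom]
            small = sel["length"] < large_indel_bp
            np.add.at(base["n_small_indel"], widx(sel.loc[small, "pos"]), 1)
            np.add.at(base["n_large_indel"], widx(sel.loc[~small, "pos"]), 1)
        if len(te):
            sel = te[te["chrom"] == chrom]
            for cls in TE_CLASSES:
                c = sel[sel["class"] == cls]
                tip = c["status"].isin(["TIP_A", "TIP_B"])
                np.add.at(base[f"n_tip_{cls}"], widx(c.loc[tip, "pos"]), 1)
                shared = c["status"] == "shared"
                np.add.at(base[f"n_shared_{cls}"], widx(c.loc[shared, "pos"]), 1)

        for w in range(n_win):
            row = {"chrom": chrom, "window": w, "start": w * window_bp,
                   "end": min((w + 1) * window_bp, length)}
            row.update({k: v[w] for k, v in base.items()})
            rows.append(row)
    df = pd.DataFrame(rows)
    df["n_tip"] = sum(df[f"n_tip_{c}"] for c in TE_CLASSES)
    df["n_shared"] = sum(df[f"n_shared_{c}"] for c in TE_CLASSES)
    return df


def chromosome_features(
    genes: pd.DataFrame,
    tes: pd.DataFrame,
    chrom_lengths: dict,
) -> pd.DataFrame:
    """Per-chromosome gene/TE covered-base percentages (0-100)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        row = {
            "chrom": chrom,
            "length_bp": length,
            "pct_gene": 100 * percent_bases(genes, chrom, 0, length),
            "pct_te": 100 * percent_bases(tes, chrom, 0, length),
        }
        for cls in TE_CLASSES:
            row[f"pct_{cls}"] = 100 * percent_bases(tes, chrom, 0, length, cls=cls)
        rows.append(row)
    return pd.DataFrame(rows)
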