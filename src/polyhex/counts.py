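"""Allelic count tables and the control-based site bias filter.

Diagnostic SNP sites distinguish the two parental homoeologs; each site of
each individual carries a pair of read counts (count_9311, count_nip). In
balanced control samples (reciprocal F1 hybrids, a 1:1 parental mix) every
site should show a ~1:1 ratio, so sites that are two-fold biased toward
either parent in ANY control are unreliable (mismapping, collapsed repeats)
and are excluded genome-wide before genotyping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "COUNT_COLUMNS",
    "load_counts",
    "write_counts",
    "load_panel",
    "write_panel",
    "control_bias_mask",
    "write_mask",
    "load_mask",
]

COUNT_COLUMNS = ("individual", "chrom", "pos", "count_9311", "count_nip")


def load_counts(path, valid_chroms=None) -> pd.DataFrame:
    """Read an allelic count TSV (individual, chrom, pos, count_9311, count_nip).

    Raises ValueError naming the first offending line on malformed rows,
    negative counts, or chromosomes outside ``valid_chroms``.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"individual": str, "chrom": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: malformed counts file: {exc}") from exc
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df[list(COUNT_COLUMNS)]
    for col in ("pos", "count_9311", "count_nip"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != np.floor(converted.fillna(0)))
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}:{line}: non-integer value in column '{col}'")
        df[col] = converted.astype(np.int64)
    for col in ("count_9311", "count_nip"):
        neg = df[col] < 0
        if neg.any():
            line = int(np.argmax(neg.to_numpy())) + 2
            raise ValueError(f"{path}:{line}: negative count in column '{col}'")
    if (df["pos"] < 1).any():
        line = int(np.argmax((df["pos"] < 1).to_numpy())) + 2
        raise ValueError(f"{path}:{line}: positions are 1-based and must be >= 1")
    if valid_chroms is not None:
        unknown = ~df["chrom"].isin(list(valid_chroms))
        if unknown.any():
            line = int(np.argmax(unknown.to_numpy())) + 2
            raise ValueError(f"{path}:{line}: unknown chromosome '{df['chrom'].iloc[line - 2]}'")
    return df.sort_values(["individual", "chrom", "pos"], kind="stable").reset_index(drop=True)


def write_counts(table: pd.DataFrame, path) -> None:
    table[list(COUNT_COLUMNS)].to_csv(path, sep="\t", index=False)


def load_panel(path) -> pd.DataFrame:
    """Read a SNP panel TSV (chrom, pos), positions strictly increasing per chromosome."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos"} <= set(df.columns):
        raise ValueError(f"{path}: panel needs columns chrom, pos")
    for chrom, grp in df.groupby("chrom", sort=False, observed=True):
        if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
            raise ValueError(f"{path}: positions not strictly increasing on {chrom}")
    return df.reset_index(drop=True)


def write_panel(panel: pd.DataFrame, path) -> None:
    panel[["chrom", "pos"]].to_csv(path, sep="\t", index=False)


def control_bias_mask(
    controls: list[pd.DataFrame],
    ratio: float = 2.0,
    zero_floor: int = 4,
    min_depth: int = 2,
) -> pd.DataFrame:
    """Mask sites that look parent-biased in any balanced control sample.

    A site is masked as ``biased_control`` if in any control
    max(a, b) >= ratio * min(a, b) with min > 0, or one side is zero while
    the other reaches ``zero_floor`` reads. Sites whose total depth in any
    control falls below ``min_depth`` are masked as ``low_coverage``.

    Masking is monotone in the control set: adding a control can only
    remove sites.
    """
    if not controls:
        raise ValueError("at least one control sample is required")
    key = None
    biased = None
    lowcov = None
    for ctrl in controls:
        ctrl = ctrl.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        k = ctrl[["chrom", "pos"]]
        if key is None:
            key = k
            biased = np.zeros(len(k), dtype=bool)
            lowcov = np.zeros(len(k), dtype=bool)
        elif len(k) != len(key) or not (
            k["pos"].to_numpy() == key["pos"].to_numpy()
        ).all() or not (k["chrom"].to_numpy() == key["chrom"].to_numpy()).all():
            raise ValueError("control tables must cover the same sites in the same order")
        a = ctrl["count_9311"].to_numpy(dtype=float)
        b = ctrl["count_nip"].to_numpy(dtype=float)
        hi = np.maximum(a, b)
        lo = np.minimum(a, b)
        biased |= ((lo > 0) & (hi >= ratio * lo)) | ((lo == 0) & (hi >= zero_floor))
        lowcov |= (a + b) < min_depth
    mask = key.copy()
    reason = np.where(biased, "biased_control", np.where(lowcov, "low_coverage", "ok"))
    mask["keep"] = ~(biased | lowcov)
    mask["reason"] = reason
    return mask


def write_mask(mask: pd.DataFrame, path) -> None:
    mask[["chrom", "pos", "keep", "reason"]].to_csv(path, sep="\t", index=False)


def load_mask(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["keep"] = df["keep"].astype(bool)
    return df
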