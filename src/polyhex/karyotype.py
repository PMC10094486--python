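"""Depth painting and copy-number karyotyping of tetraploid individuals.

In a euploid tetraploid (4 copies of every chromosome) the total allelic
read depth at diagnostic SNP sites is flat along the genome. A gained or
lost chromosome (or large segment) shifts the local depth to (4 +- k)/4 of
the genome-wide mean, i.e. to one of the rungs 0.5x, 0.75x, 1.25x, 1.5x for
k = -2, -1, +1, +2. Chromosomes are binned into 1 Mb windows, each window's
mean per-site depth is expressed relative to the global mean, windows are
assigned to the nearest rung, and whole-chromosome and segmental calls are
summarised from the window states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosage import apply_mask

__all__ = [
    "window_depths",
    "classify_windows",
    "summarize_karyotype",
    "KaryotypeModel",
    "KaryotypeResults",
]

#: relative-depth rung -> copy-number state of a tetraploid chromosome
RUNGS = ((0.50, -2), (0.75, -1), (1.00, 0), (1.25, 1), (1.50, 2))


def window_depths(
    counts: pd.DataFrame,
    mask: pd.DataFrame | None = None,
    window_bp: int = 1_000_000,
    min_sites: int = 5,
) -> pd.DataFrame:
    """Per-window mean allelic depth for one individual's count table.

    Per-site depth is count_9311 + count_nip over kept sites; the global
    depth is the mean per-site depth over all kept sites genome-wide and
    normalises each window's mean to ``rel_depth``. Windows with fewer than
    ``min_sites`` contributing sites are flagged ``excluded``.
    """
    tab = apply_mask(counts, mask)
    if tab.empty:
        raise ValueError("no kept sites genome-wide; cannot compute window depths")
    depth = (tab["count_9311"] + tab["count_nip"]).to_numpy(dtype=float)
    global_depth = float(depth.mean())
    win = ((tab["pos"].to_numpy() - 1) // window_bp).astype(int)
    df = pd.DataFrame({"chrom": tab["chrom"].to_numpy(), "window": win, "depth": depth})
    agg = (
        df.groupby(["chrom", "window"], sort=False, observed=True)["depth"]
        .agg(n_sites="size", mean_depth="mean")
        .reset_index()
    )
    agg["start"] = agg["window"] * window_bp
    agg["end"] = (agg["window"] + 1) * window_bp
    agg["rel_depth"] = agg["mean_depth"] / global_depth
    agg["excluded"] = agg["n_sites"] < min_sites
    agg.attrs["global_depth"] = global_depth
    return agg.sort_values(["chrom", "window"], kind="stable").reset_index(drop=True)


def classify_windows(
    wd: pd.DataFrame,
    cutoffs: tuple = (0.5, 0.75, 1.25, 1.5),
    delta: float = 0.05,
) -> pd.DataFrame:
    """Assign each window to the copy-number rung nearest its rel_depth.

    Rungs are the depth cutoffs plus the euploid 1.0, mapping to states
    -2, -1, 0, +1, +2. Equidistant ties resolve toward the less extreme
    state. ``delta`` flags windows within +-delta of their rung as
    high-confidence (``in_band``); excluded windows carry no state.
    """
    rungs = sorted(set(cutoffs) | {1.0})
    if len(rungs) != 5:
        raise ValueError("expected four distinct cutoffs around 1.0")
    states = [-2, -1, 0, 1, 2]
    rel = wd["rel_depth"].to_numpy()
    dist = np.abs(rel[:, None] - np.asarray(rungs)[None, :])
    # prefer the less extreme state on exact ties
    pref = np.argsort([abs(s) for s in states], kind="stable")
    best = pref[np.argmin(dist[:, pref], axis=1)]
    out = wd.copy()
    state = np.array([states[i] for i in best], dtype=float)
    state[wd["excluded"].to_numpy()] = np.nan
    out["state"] = state
    out["in_band"] = np.min(dist, axis=1) <= delta
    return out


def summarize_karyotype(
    states: pd.DataFrame,
    modal_threshold: float = 0.8,
    min_run: int = 3,
    window_bp: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Whole-chromosome calls plus segmental events from window states.

    The whole-chromosome state is the modal window state when it covers at
    least ``modal_threshold`` of classified windows, else 0. Segmental
    events are maximal runs of >= ``min_run`` consecutive windows sharing a
    non-zero state different from the whole-chromosome state. Confidence is
    the fraction of classified windows agreeing with the chromosome call.
    """
    calls, events = [], []
    for chrom, grp in states.groupby("chrom", sort=False, observed=True):
        grp = grp.sort_values("window")
        cls = grp[~grp["state"].isna()]
        if cls.empty:
            calls.append({"chrom": chrom, "state": None, "confidence": np.nan, "n_windows": 0})
            continue
        vals = cls["state"].astype(int)
        mode = int(vals.value_counts().idxmax())
        frac = float((vals == mode).mean())
        whole = mode if frac >= modal_threshold else 0
        calls.append(
            {
                "chrom": chrom,
                "state": whole,
                "confidence": float((vals == whole).mean()),
                "n_windows": len(vals),
            }
        )
        # runs of equal non-zero state differing from the chromosome call
        widx = cls["window"].to_numpy()
        v = vals.to_numpy()
        i = 0
        while i < len(v):
            j = i
            while (
                j + 1 < len(v)
                and v[j + 1] == v[i]
                and widx[j + 1] == widx[j] + 1
            ):
                j += 1
            if v[i] != 0 and v[i] != whole and (j - i + 1) >= min_run:
                events.append(
                    {
                        "chrom": chrom,
                        "start": int(widx[i] * window_bp),
                        "end": int((widx[j] + 1) * window_bp),
                        "offset": int(v[i]),
                        "n_windows": j - i + 1,
                    }
                )
            i = j + 1
    return (
        pd.DataFrame(calls, columns=["chrom", "state", "confidence", "n_windows"]),
        pd.DataFrame(events, columns=["chrom", "start", "end", "offset", "n_windows"]),
    )


@dataclass
class KaryotypeResults:
    """Window depth painting and copy-number calls for a set of individuals."""

    windows: pd.DataFrame
    calls: pd.DataFrame
    events: pd.DataFrame
    window_bp: int

    def euploid_individuals(self) -> list:
        """Individuals with every chromosome in state 0 and no segmental events."""
        ok = []
        for ind, grp in self.calls.groupby("individual", sort=False, observed=True):
            aberrant = grp["state"].isna() | (grp["state"] != 0)
            has_event = (
                not self.events.empty
                and (self.events["individual"] == ind).any()
            )
            if not aberrant.any() and not has_event:
                ok.append(ind)
        return ok

    def aneuploid_fraction(self) -> float:
        inds = self.calls["individual"].unique()
        return 1.0 - len(self.euploid_individuals()) / len(inds)

    def summary(self) -> str:
        inds = self.calls["individual"].unique()
        n_aneu = sum(
            (grp["state"].fillna(0) != 0).any()
            for _, grp in self.calls.groupby("individual", observed=True)
        )
        lines = [
            "Karyotype summary",
            "=================",
            f"individuals:                 {len(inds)}",
            f"with aneuploid chromosomes:  {n_aneu}",
            f"segmental events:            {len(self.events)}",
            f"euploid individuals:         {len(self.euploid_individuals())}",
        ]
        return "\n".join(lines)

    def plot(self, individual, ax=None, cutoffs=(0.5, 0.75, 1.25, 1.5)):
        """Depth-painting plot: one dot per window, rungs as dashed lines."""
        import matplotlib.pyplot as plt

        wd = self.windows[self.windows["individual"] == individual]
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        offset = 0
        for i, (chrom, grp) in enumerate(wd.groupby("chrom", sort=False, observed=True)):
            x = offset + grp["start"].to_numpy() / 1e6
            ax.plot(x, grp["rel_depth"], ".", ms=3, color="k" if i % 2 == 0 else "grey")
            offset = x.max() + 1 if len(x) else offset
        for c in cutoffs:
            ax.axhline(c, ls="--", lw=0.6, color="orange")
        ax.axhline(1.0, ls="--", lw=0.6, color="red")
        ax.set_xlabel("genome position (Mb, chromosomes concatenated)")
        ax.set_ylabel("relative depth")
        ax.set_title(str(individual))
        return ax


class KaryotypeModel:
    """Depth-based karyotyper over a multi-individual allelic count table."""

    def __init__(
        self,
        counts: pd.DataFrame,
        mask: pd.DataFrame | None = None,
        window_bp: int = 1_000_000,
        min_sites: int = 5,
        cutoffs: tuple = (0.5, 0.75, 1.25, 1.5),
        delta: float = 0.05,
        modal_threshold: float = 0.8,
        min_run: int = 3,
    ):
        self.counts = counts
        self.mask = mask
        self.window_bp = int(window_bp)
        self.min_sites = int(min_sites)
        self.cutoffs = tuple(cutoffs)
        self.delta = float(delta)
        self.modal_threshold = float(modal_threshold)
        self.min_run = int(min_run)

    def fit(self) -> KaryotypeResults:
        all_wd, all_calls, all_events = [], [], []
        for ind, tab in self.counts.groupby("individual", sort=False, observed=True):
            wd = window_depths(tab, self.mask, self.window_bp, self.min_sites)
            wd = classify_windows(wd, self.cutoffs, self.delta)
            calls, events = summarize_karyotype(
                wd, self.modal_threshold, self.min_run, self.window_bp
            )
            for df, acc in ((wd, all_wd), (calls, all_calls), (events, all_events)):
                df = df.copy()
                df.insert(0, "individual", ind)
                acc.append(df)
        cat = lambda lst: pd.concat(lst, ignore_index=True) if lst else pd.DataFrame()
        return KaryotypeResults(
            windows=cat(all_wd),
            calls=cat(all_calls),
            events=cat(all_events),
            window_bp=self.window_bp,
        )
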