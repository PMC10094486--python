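"""Likelihood-based dosage genotyping and homoeologous-exchange calling.

A segmental allotetraploid carries four chromosome copies split between two
parental subgenomes (here labelled 9311 and Nipponbare). At any locus the
subgenome dosage is one of five ratios 0:4, 1:3, 2:2, 3:1, 4:0 (counted as
d = copies of the 9311 homoeolog). Homoeologous exchange (HE) creates a
mosaic of dosage segments along a chromosome; the transition regions between
segments of different dosage are the HE regions.

The caller works on per-site homoeolog-specific read counts:

1. consecutive kept SNP sites are grouped into bins of ``bin_snps`` sites;
2. each bin's pooled counts (a, b) are genotyped by a G-test of goodness of
   fit against the five dosage hypotheses — the dosage with the smallest G
   (equivalently the largest binomial likelihood) wins;
3. runs of equal dosage are merged into fragments, fragments shorter than
   ``min_fragment`` bins are removed and flanking fragments re-merged until
   a fixpoint;
4. each junction between surviving fragments of different dosage is an HE
   region, spanning from the last SNP of the left fragment to the first SNP
   of the right fragment.

The pure-dosage hypotheses 0:4 and 4:0 would expect a 9311-read fraction of
exactly 0 or 1, under which any discordant read gives an infinite G; the
mis-attribution rate ``epsilon`` replaces those extremes by eps and 1-eps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2

__all__ = [
    "DOSAGES",
    "GENOTYPE_LABELS",
    "expected_fraction",
    "g_stat",
    "genotype_bin",
    "bin_sites",
    "genotype_bins",
    "segment_fragments",
    "call_he",
    "window_he_frequency",
    "DosageModel",
    "DosageResults",
]

#: dosage = copies of the 9311 homoeolog out of four chromosome copies
DOSAGES = (0, 1, 2, 3, 4)
GENOTYPE_LABELS = {0: "0:4", 1: "1:3", 2: "2:2", 3: "3:1", 4: "4:0"}
LABEL_TO_DOSAGE = {v: k for k, v in GENOTYPE_LABELS.items()}

#: deterministic tie-break preference: 2:2 first, then smaller |d-2|, then lower d
_TIE_ORDER = (2, 1, 3, 0, 4)


def expected_fraction(dosage: int, epsilon: float) -> float:
    """Expected 9311-read fraction under a dosage hypothesis."""
    if dosage == 0:
        return epsilon
    if dosage == 4:
        return 1.0 - epsilon
    return dosage / 4.0


def g_stat(a, b, dosage: int, epsilon: float = 0.005):
    """G-test statistic for counts (a, b) against one dosage hypothesis.

    G = 2 * sum O * ln(O / E) over the two read classes, with 0*ln(0) = 0.
    a are reads attributed to 9311, b to Nipponbare.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a + b
    if np.any(n <= 0):
        raise ValueError("g_stat undefined for bins with zero total reads")
    p = expected_fraction(dosage, epsilon)
    g = 2.0 * (xlogy(a, a / (n * p)) + xlogy(b, b / (n * (1.0 - p))))
    return g if g.ndim else float(g)


def g_pvalue(g):
    """Upper chi-square(1) tail probability of a G statistic."""
    return chi2.sf(g, df=1)


def genotype_bin(a, b, epsilon: float = 0.005):
    """Assign the best-fitting dosage to pooled bin counts.

    Returns ``(dosage, G, p)``; vectorised over arrays. The winning dosage
    minimises G (= maximises the binomial likelihood); exact ties resolve
    toward 2:2, then toward the smaller \\|d-2\\|, then the lower d.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    scalar = a.ndim == 0
    a, b = np.atleast_1d(a), np.atleast_1d(b)
    best_g = np.full(a.shape, np.inf)
    best_d = np.zeros(a.shape, dtype=np.int64)
    for d in _TIE_ORDER:
        g = np.atleast_1d(g_stat(a, b, d, epsilon))
        better = g < best_g  # strict: earlier (preferred) entry wins ties
        best_g = np.where(better, g, best_g)
        best_d = np.where(better, d, best_d)
    p = g_pvalue(best_g)
    if scalar:
        return int(best_d[0]), float(best_g[0]), float(p[0])
    return best_d, best_g, p


def bin_sites(panel: pd.DataFrame, mask: pd.DataFrame | None = None, k: int = 10) -> pd.DataFrame:
    """Group kept SNP sites into bins of ``k`` consecutive sites per chromosome.

    A trailing partial bin with at least ceil(k/2) sites stands alone;
    a smaller remainder merges into the previous bin. Chromosomes with fewer
    than ``k`` kept sites are skipped with a warning.

    Returns a frame with one row per bin: chrom, bin, start_pos, end_pos,
    n_sites, i0/i1 (half-open row range into the kept-site table).
    """
    if k < 2:
        raise ValueError("bin size k must be >= 2")
    kept = apply_mask(panel, mask)
    rows = []
    offset = 0
    for chrom, grp in kept.groupby("chrom", sort=False, observed=True):
        m = len(grp)
        if m < k:
            warnings.warn(f"chromosome {chrom}: only {m} kept sites (< {k}); skipped")
            offset += m
            continue
        n_full, rem = divmod(m, k)
        sizes = [k] * n_full
        if rem >= (k + 1) // 2:
            sizes.append(rem)
        elif rem:
            sizes[-1] += rem
        pos = grp["pos"].to_numpy()
        i = 0
        for b, size in enumerate(sizes):
            rows.append(
                {
                    "chrom": chrom,
                    "bin": b,
                    "start_pos": int(pos[i]),
                    "end_pos": int(pos[i + size - 1]),
                    "n_sites": size,
                    "i0": offset + i,
                    "i1": offset + i + size,
                }
            )
            i += size
        offset += m
    return pd.DataFrame(
        rows, columns=["chrom", "bin", "start_pos", "end_pos", "n_sites", "i0", "i1"]
    )


def apply_mask(table: pd.DataFrame, mask: pd.DataFrame | None) -> pd.DataFrame:
    """Subset a (chrom, pos)-keyed table to kept sites of a site mask."""
    if mask is None:
        return table
    kept = mask.loc[mask["keep"], ["chrom", "pos"]]
    return table.merge(kept, on=["chrom", "pos"], how="inner")


def genotype_bins(
    counts: pd.DataFrame,
    bins: pd.DataFrame,
    epsilon: float = 0.005,
) -> pd.DataFrame:
    """Pool counts within bins and genotype each bin.

    ``counts`` must be a single individual's table row-aligned with the
    kept-site table the bins were built from.
    """
    a_site = counts["count_9311"].to_numpy(dtype=float)
    b_site = counts["count_nip"].to_numpy(dtype=float)
    i0 = bins["i0"].to_numpy()
    i1 = bins["i1"].to_numpy()
    ca = np.concatenate([[0.0], np.cumsum(a_site)])
    cb = np.concatenate([[0.0], np.cumsum(b_site)])
    a = ca[i1] - ca[i0]
    b = cb[i1] - cb[i0]
    out = bins.copy()
    out["a"] = a
    out["b"] = b
    total = a + b
    callable_ = total > 0
    dosage = np.full(len(out), -1, dtype=np.int64)
    g = np.full(len(out), np.nan)
    p = np.full(len(out), np.nan)
    if callable_.any():
        d_, g_, p_ = genotype_bin(a[callable_], b[callable_], epsilon)
        dosage[callable_] = d_
        g[callable_] = g_
        p[callable_] = p_
    if (~callable_).any():
        warnings.warn(f"{int((~callable_).sum())} bins with zero reads flagged no-call")
    out["dosage"] = dosage
    out["G"] = g
    out["p"] = p
    return out


def _coalesce(runs: list[list]) -> list[list]:
    """Merge adjacent same-dosage runs, absorbing any removed gap between them."""
    merged: list[list] = []
    for r in runs:
        if merged and merged[-1][0] == r[0]:
            merged[-1][2] = r[2]
        else:
            merged.append(list(r))
    return merged


def segment_fragments(bins: pd.DataFrame, min_fragment: int = 5) -> pd.DataFrame:
    """Merge genotyped bins into dosage fragments and prune short islands.

    Maximal runs of equal dosage become fragments; any fragment spanning
    fewer than ``min_fragment`` bins is removed, flanking fragments of equal
    dosage re-merge (absorbing the removed bins), and the pass repeats until
    stable. Fragment widths count all bins in the fragment's span.
    """
    frames = []
    for chrom, grp in bins.groupby("chrom", sort=False, observed=True):
        grp = grp.sort_values("bin")
        called = grp[grp["dosage"] >= 0]
        if called.empty:
            warnings.warn(f"chromosome {chrom}: no callable bins; zero fragments")
            continue
        d = called["dosage"].to_numpy()
        idx = called["bin"].to_numpy()
        # RLE over called bins: [dosage, first_bin, last_bin]
        runs: list[list] = []
        for dose, b in zip(d, idx):
            if runs and runs[-1][0] == dose and b == runs[-1][2] + 1:
                runs[-1][2] = b
            else:
                runs.append([int(dose), int(b), int(b)])
        while True:
            runs = _coalesce(runs)
            kept = [r for r in runs if r[2] - r[1] + 1 >= min_fragment]
            if len(kept) == len(runs):
                break
            runs = kept
        if not runs:
            warnings.warn(f"chromosome {chrom}: all fragments shorter than {min_fragment} bins")
            continue
        by_bin = grp.set_index("bin")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "first_bin": [r[1] for r in runs],
                    "last_bin": [r[2] for r in runs],
                    "dosage": [r[0] for r in runs],
                    "genotype": [GENOTYPE_LABELS[r[0]] for r in runs],
                    "n_bins": [r[2] - r[1] + 1 for r in runs],
                    "start_pos": [int(by_bin.at[r[1], "start_pos"]) for r in runs],
                    "end_pos": [int(by_bin.at[r[2], "end_pos"]) for r in runs],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "chrom", "first_bin", "last_bin", "dosage", "genotype",
                "n_bins", "start_pos", "end_pos",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def call_he(fragments: pd.DataFrame) -> pd.DataFrame:
    """HE regions: the junction intervals between adjacent dosage fragments.

    Each region spans (half-open, bp) from the last SNP of the left fragment
    to the first SNP of the right fragment.
    """
    regions = []
    for chrom, grp in fragments.groupby("chrom", sort=False, observed=True):
        grp = grp.sort_values("first_bin").reset_index(drop=True)
        for i in range(len(grp) - 1):
            left, right = grp.loc[i], grp.loc[i + 1]
            regions.append(
                {
                    "chrom": chrom,
                    "start": int(left["end_pos"]),
                    "end": int(right["start_pos"]),
                    "left_genotype": left["genotype"],
                    "right_genotype": right["genotype"],
                }
            )
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "left_genotype", "right_genotype"])


def window_he_frequency(
    regions: pd.DataFrame,
    n_individuals: int,
    chrom_lengths: dict,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Per-window HE frequency across individuals.

    Each HE region contributes one event to the window containing its
    midpoint; frequency = events / n_individuals.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        n_win = int(np.ceil(length / window_bp))
        counts = np.zeros(n_win)
        if len(regions):
            sel = regions[regions["chrom"] == chrom]
            if len(sel):
                mid = (sel["start"].to_numpy() + sel["end"].to_numpy()) / 2.0
                widx = np.clip((mid // window_bp).astype(int), 0, n_win - 1)
                np.add.at(counts, widx, 1.0)
        for w in range(n_win):
            rows.append(
                {
                    "chrom": chrom,
                    "window": w,
                    "start": w * window_bp,
                    "end": min((w + 1) * window_bp, length),
                    "he_count": counts[w],
                    "he_frequency": counts[w] / n_individuals,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DosageResults:
    """Fitted dosage mosaic of one or more tetraploid individuals."""

    bins: pd.DataFrame
    fragments: pd.DataFrame
    he_regions: pd.DataFrame
    epsilon: float
    bin_snps: int
    min_fragment: int
    individuals: list = field(default_factory=list)

    @property
    def he_counts(self) -> pd.DataFrame:
        """HE count per individual x chromosome (0 where none called)."""
        if self.he_regions.empty:
            base = pd.DataFrame(columns=["individual", "chrom", "n_he"])
        else:
            base = (
                self.he_regions.groupby(["individual", "chrom"], observed=True)
                .size()
                .rename("n_he")
                .reset_index()
            )
        chroms = self.bins["chrom"].unique()
        full = pd.MultiIndex.from_product(
            [self.individuals, chroms], names=["individual", "chrom"]
        ).to_frame(index=False)
        out = full.merge(base, on=["individual", "chrom"], how="left")
        out["n_he"] = out["n_he"].fillna(0).astype(int)
        return out

    def mean_he_per_individual(self) -> float:
        """Mean genome-wide HE count per individual."""
        per_ind = self.he_counts.groupby("individual", observed=True)["n_he"].sum()
        return float(per_ind.mean())

    def chromosome_he_means(self) -> pd.Series:
        """Mean HE count per chromosome across individuals."""
        return self.he_counts.groupby("chrom", observed=True)["n_he"].mean()

    def summary(self) -> str:
        lines = [
            "Dosage / homoeologous-exchange call summary",
            "===========================================",
            f"individuals:        {len(self.individuals)}",
            f"bins genotyped:     {int((self.bins['dosage'] >= 0).sum())}",
            f"fragments:          {len(self.fragments)}",
            f"HE regions:         {len(self.he_regions)}",
            f"mean HEs/individual: {self.mean_he_per_individual():.2f}"
            if self.individuals
            else "mean HEs/individual: n/a",
            f"epsilon={self.epsilon}, bin_snps={self.bin_snps}, min_fragment={self.min_fragment}",
        ]
        return "\n".join(lines)


class DosageModel:
    """G-test dosage genotyper / HE caller over an allelic count table.

    Parameters
    ----------
    counts
        Long-format table (individual, chrom, pos, count_9311, count_nip),
        one row per individual x SNP site, sites ordered within chromosome.
    mask
        Optional site mask (chrom, pos, keep, reason); masked-out sites are
        dropped before binning.
    epsilon
        Read mis-attribution rate replacing the 0/1 expectations of the
        pure-dosage hypotheses.
    bin_snps, min_fragment
        Bin size in SNP sites and minimum fragment width in bins.
    """

    def __init__(self, counts, mask=None, epsilon=0.005, bin_snps=10, min_fragment=5):
        if not 0 <= epsilon < 0.25:
            raise ValueError("epsilon must be in [0, 0.25) to keep 0:4 separable from 1:3")
        self.counts = counts
        self.mask = mask
        self.epsilon = float(epsilon)
        self.bin_snps = int(bin_snps)
        self.min_fragment = int(min_fragment)

    def fit(self, individuals=None) -> DosageResults:
        counts = self.counts
        if individuals is not None:
            counts = counts[counts["individual"].isin(individuals)]
        all_bins, all_frags, all_he = [], [], []
        inds = list(pd.unique(counts["individual"]))
        for ind, tab in counts.groupby("individual", sort=False, observed=True):
            tab = apply_mask(tab, self.mask)
            panel = tab[["chrom", "pos"]]
            bins = bin_sites(panel, mask=None, k=self.bin_snps)
            bins = genotype_bins(tab.reset_index(drop=True), bins, self.epsilon)
            frags = segment_fragments(bins, self.min_fragment)
            he = call_he(frags)
            for df, acc in ((bins, all_bins), (frags, all_frags), (he, all_he)):
                df = df.copy()
                df.insert(0, "individual", ind)
                acc.append(df)
        cat = lambda lst: pd.concat(lst, ignore_index=True) if lst else pd.DataFrame()
        return DosageResults(
            bins=cat(all_bins),
            fragments=cat(all_frags),
            he_regions=cat(all_he),
            epsilon=self.epsilon,
            bin_snps=self.bin_snps,
            min_fragment=self.min_fragment,
            individuals=inds,
        )
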