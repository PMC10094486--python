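"""Synthetic segmental-allotetraploid populations with known ground truth.

The generator emulates the statistical structure the analysis assumes for a
rice-like genome: a panel of diagnostic SNPs distinguishing the two parental
homoeologs (9311 vs Nipponbare) along 12 chromosomes; tetraploid individuals
whose subgenome dosage forms a mosaic of segments created by homoeologous
exchange (HE) breakpoints; occasional whole-chromosome and segmental copy
number changes; and per-site allelic read counts with Poisson total depth
and a binomial parental split subject to a mis-attribution rate epsilon.

Feature tracks follow the canonical rice layout: retrotransposons enriched
in centromeric/pericentromeric regions, genes and MITEs enriched distally,
and a genetic map whose recombination rate is suppressed centrally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "ParentPanel",
    "TruthIndividual",
    "build_parent_panel",
    "draw_mosaic",
    "emit_counts",
    "simulate_population",
    "intensity_from_tracks",
    "write_truth",
    "load_truth",
    "write_bed",
]

WINDOW_BP = 1_000_000


@dataclass
class SimConfig:
    """Parameters of the synthetic tetraploid population.

    Defaults approximate the study system: a 12-chromosome rice-like genome,
    ~20x resequencing depth, an S2-like HE rate of ~3 breakpoints per
    chromosome pair per individual, and per-chromosome aneuploidy
    probabilities matching the observed ~19 gain/loss events in 240
    chromosome sets.
    """

    n_chromosomes: int = 12
    chrom_length_bp: int = 30_000_000
    snp_density: float = 1.0  # expected SNPs per kbp
    per_site_depth: float = 20.0
    error_rate: float = 0.005  # P(read attributed to the wrong parent)
    he_intensity: np.ndarray | None = None  # per-1Mb-window relative intensity
    mean_he_per_chrom: float = 3.0
    p_chrom_gain: float = 0.04
    p_chrom_loss: float = 0.04
    p_segmental: float = 0.015
    seg_length_bp: tuple = (3_000_000, 10_000_000)
    n_individuals: int = 20
    seed: int = 0
    generation: str = "S2"

    @property
    def n_windows(self) -> int:
        return int(np.ceil(self.chrom_length_bp / WINDOW_BP))

    @property
    def chrom_names(self) -> list[str]:
        return [f"Chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict:
        return {c: self.chrom_length_bp for c in self.chrom_names}

    def validate(self) -> "SimConfig":
        for name in ("p_chrom_gain", "p_chrom_loss", "p_segmental"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25) to keep 0:4 separable from 1:3")
        if self.chrom_length_bp < 5_000_000:
            raise ValueError("chrom_length_bp must be >= 5 Mb")
        if self.snp_density < 0 or self.per_site_depth <= 0:
            raise ValueError("snp_density must be >= 0 and per_site_depth > 0")
        if self.he_intensity is not None:
            arr = np.asarray(self.he_intensity, dtype=float)
            if arr.ndim == 1:
                ok = arr.size == self.n_windows
            else:
                ok = arr.shape == (self.n_chromosomes, self.n_windows)
            if not ok:
                raise ValueError(
                    "he_intensity needs one value per 1 Mb window "
                    f"({self.n_windows} per chromosome)"
                )
            if (arr < 0).any():
                raise ValueError("he_intensity must be nonnegative")
        return self


@dataclass
class ParentPanel:
    """Parental resources: SNP panel, feature tracks, TE table, genetic map."""

    snp: pd.DataFrame        # chrom, pos (1-based, strictly increasing)
    genes: pd.DataFrame      # chrom, start, end (0-based half-open)
    tes: pd.DataFrame        # chrom, start, end, class
    te_table: pd.DataFrame   # chrom, pos, class, freq_9311, freq_nip
    genetic_map: pd.DataFrame  # marker, chrom, pos_bp, cM
    chrom_lengths: dict


@dataclass
class TruthIndividual:
    """Ground-truth dosage mosaic and copy-number events of one individual.

    ``segments[chrom]`` is a list of (start, end, dosage) tuples in 0-based
    half-open bp tiling the chromosome; dosage is the count of 9311 copies
    out of four. ``chrom_offset[chrom]`` is the whole-chromosome copy-number
    offset applied to ``offset_parent[chrom]``; ``seg_events[chrom]`` lists
    (start, end, offset, parent) segmental gains/losses.
    """

    name: str
    generation: str
    segments: dict = field(default_factory=dict)
    chrom_offset: dict = field(default_factory=dict)
    offset_parent: dict = field(default_factory=dict)
    seg_events: dict = field(default_factory=dict)

    @property
    def euploid(self) -> bool:
        return all(v == 0 for v in self.chrom_offset.values()) and not any(
            self.seg_events.get(c) for c in self.segments
        )

    def breakpoints(self, chrom) -> list[int]:
        """True HE breakpoint positions (segment junctions) on a chromosome."""
        segs = self.segments[chrom]
        return [s[0] for s in segs[1:]]

    def n_breakpoints(self) -> int:
        return sum(len(self.breakpoints(c)) for c in self.segments)


# ---------------------------------------------------------------------------
# parental resources

#: per-class interval mean length (bp), target count per Mb, and radial
#: density profile w(t) with t = 0 at the centromere-proxy chromosome middle
#: and t = 1 at the telomeres; profiles average ~1 over t.
_FEATURE_LAYOUT = {
    "gene": (3000, 83, lambda t: 0.4 + 1.2 * t),
    "retrotransposon": (7000, 31, lambda t: 1.8 - 1.6 * t),
    "DNA_transposon": (2500, 24, lambda t: np.ones_like(t)),
    "MITE": (400, 125, lambda t: 0.3 + 1.4 * t),
}


def _radial(cfg: SimConfig) -> np.ndarray:
    centers = (np.arange(cfg.n_windows) + 0.5) * WINDOW_BP
    half = cfg.chrom_length_bp / 2.0
    return np.clip(np.abs(centers - half) / half, 0.0, 1.0)


def build_parent_panel(cfg: SimConfig, rng: np.random.Generator | None = None) -> ParentPanel:
    """Draw the diploid-parent resources for a simulated genome.

    SNP positions are a homogeneous Poisson process at ``snp_density``;
    gene/TE intervals follow class-specific radial density gradients; the TE
    table carries per-parent insertion frequencies; the genetic map is a
    monotone cM(x) with a suppressed-rate central region.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = cfg.chrom_length_bp
    t = _radial(cfg)

    snp_frames, gene_rows, te_rows, te_table_rows, map_frames = [], [], [], [], []
    for chrom in cfg.chrom_names:
        n_exp = L * cfg.snp_density / 1000.0
        n = int(rng.poisson(n_exp)) if n_exp > 0 else 0
        if n == 0:
            raise ValueError(f"no SNP sites drawn on {chrom} (snp_density too low)")
        pos = np.unique(rng.integers(1, L + 1, size=n))
        snp_frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))

        for cls, (mean_len, per_mb, profile) in _FEATURE_LAYOUT.items():
            counts = rng.poisson(per_mb * profile(t))
            for w, c in enumerate(counts):
                if c == 0:
                    continue
                starts = rng.integers(w * WINDOW_BP, min((w + 1) * WINDOW_BP, L), size=c)
                lens = np.maximum(50, rng.gamma(4.0, mean_len / 4.0, size=c)).astype(int)
                ends = np.minimum(starts + lens, L)
                for s, e in zip(starts, ends):
                    row = {"chrom": chrom, "start": int(s), "end": int(e), "class": cls}
                    if cls == "gene":
                        gene_rows.append(row)
                    else:
                        te_rows.append(row)
                        te_table_rows.append(_te_insertion(rng, chrom, int(s), cls))

        map_frames.append(_genetic_map(cfg, rng, chrom, t))

    snp = pd.concat(snp_frames, ignore_index=True)
    genes = pd.DataFrame(gene_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    tes = pd.DataFrame(te_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    te_table = (
        pd.DataFrame(te_table_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    )
    gmap = pd.concat(map_frames, ignore_index=True)
    return ParentPanel(
        snp=snp,
        genes=genes[["chrom", "start", "end", "class"]],
        tes=tes,
        te_table=te_table,
        genetic_map=gmap,
        chrom_lengths=cfg.chrom_lengths,
    )


def _te_insertion(rng, chrom, pos, cls):
    u = rng.random()
    if u < 0.55:  # shared between parents
        fa, fb = 1.0 - 0.04 * rng.random(), 1.0 - 0.04 * rng.random()
    elif u < 0.75:  # 9311-only TIP
        fa, fb = 1.0 - 0.04 * rng.random(), 0.04 * rng.random()
    elif u < 0.95:  # Nipponbare-only TIP
        fa, fb = 0.04 * rng.random(), 1.0 - 0.04 * rng.random()
    else:  # intermediate frequency, unclassifiable
        fa, fb = rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9)
    return {
        "chrom": chrom,
        "pos": pos,
        "class": cls,
        "freq_9311": round(float(fa), 4),
        "freq_nip": round(float(fb), 4),
    }


def _genetic_map(cfg, rng, chrom, t, mean_rate_cm_mb=4.0, marker_spacing_bp=200_000):
    # window-level rate profile: suppressed centrally, scaled to the target mean
    profile = 0.05 + 0.95 * t**1.5
    rate = mean_rate_cm_mb * profile / profile.mean()  # cM/Mb per window
    pos = np.arange(marker_spacing_bp // 2, cfg.chrom_length_bp, marker_spacing_bp)
    pos = pos + rng.integers(-marker_spacing_bp // 4, marker_spacing_bp // 4, size=pos.size)
    pos = np.clip(pos, 1, cfg.chrom_length_bp)
    win = np.minimum(pos // WINDOW_BP, cfg.n_windows - 1)
    cum = np.concatenate([[0.0], np.cumsum(rate)])  # cM at window boundaries
    frac = (pos - win * WINDOW_BP) / WINDOW_BP
    cm = cum[win] + frac * rate[win]
    return pd.DataFrame(
        {
            "marker": [f"{chrom}_m{i:04d}" for i in range(pos.size)],
            "chrom": chrom,
            "pos_bp": pos.astype(int),
            "cM": np.round(cm, 6),
        }
    )


def intensity_from_tracks(
    gene_frac: np.ndarray, retro_frac: np.ndarray
) -> np.ndarray:
    """HE-breakpoint intensity proportional to gene content and inversely
    related to retrotransposon content, normalised to mean 1 per chromosome."""
    gene_frac = np.asarray(gene_frac, dtype=float)
    retro_frac = np.asarray(retro_frac, dtype=float)
    intensity = (0.05 + gene_frac) * np.clip(1.05 - retro_frac, 0.0, None)
    mean = intensity.mean(axis=-1, keepdims=True)
    return np.where(mean > 0, intensity / mean, 1.0)


# ---------------------------------------------------------------------------
# tetraploid individuals


def _chrom_intensity(cfg: SimConfig, chrom_idx: int) -> np.ndarray:
    if cfg.he_intensity is None:
        return np.ones(cfg.n_windows)
    arr = np.asarray(cfg.he_intensity, dtype=float)
    return arr if arr.ndim == 1 else arr[chrom_idx]


def draw_mosaic(
    cfg: SimConfig, panel: ParentPanel, rng: np.random.Generator, name: str = "ind"
) -> TruthIndividual:
    """Draw one tetraploid individual's dosage mosaic and copy-number events.

    Per chromosome the HE breakpoint count is Poisson(``mean_he_per_chrom``),
    positions are sampled proportional to the per-window intensity, and each
    breakpoint steps the 9311 dosage by +-1 (a single reciprocal crossover),
    reflected at the 0 and 4 boundaries. Aneuploidy and segmental events are
    drawn at the configured probabilities and recorded as offsets on one
    homoeolog chosen uniformly.
    """
    ind = TruthIndividual(name=name, generation=cfg.generation)
    L = cfg.chrom_length_bp
    for ci, chrom in enumerate(cfg.chrom_names):
        weights = _chrom_intensity(cfg, ci)
        if weights.sum() <= 0:
            warnings.warn(f"{chrom}: all-zero HE intensity; sampling breakpoints uniformly")
            weights = np.ones_like(weights)
        n_bp = rng.poisson(cfg.mean_he_per_chrom)
        if n_bp > 0:
            win = rng.choice(weights.size, size=n_bp, p=weights / weights.sum())
            bp = win * WINDOW_BP + rng.integers(0, WINDOW_BP, size=n_bp)
            bp = np.unique(np.clip(bp, 1, L - 1))
        else:
            bp = np.array([], dtype=int)
        d = 2
        bounds = np.concatenate([[0], bp, [L]])
        segs = []
        for s, e in zip(bounds[:-1], bounds[1:]):
            segs.append((int(s), int(e), int(d)))
            if d == 0:
                d += 1
            elif d == 4:
                d -= 1
            else:
                d += int(rng.choice([-1, 1]))
        ind.segments[chrom] = segs

        u = rng.random()
        if u < cfg.p_chrom_gain:
            ind.chrom_offset[chrom] = 1
        elif u < cfg.p_chrom_gain + cfg.p_chrom_loss:
            ind.chrom_offset[chrom] = -1
        else:
            ind.chrom_offset[chrom] = 0
        ind.offset_parent[chrom] = str(rng.choice(["9311", "nip"]))

        events = []
        if rng.random() < cfg.p_segmental:
            lo, hi = cfg.seg_length_bp
            length = int(rng.integers(lo, hi + 1))
            length = min(length, L)
            start = int(rng.integers(0, L - length + 1))
            events.append(
                (start, start + length, int(rng.choice([-1, 1])), str(rng.choice(["9311", "nip"])))
            )
        ind.seg_events[chrom] = events
    return ind


def emit_counts(
    truth: TruthIndividual,
    panel: ParentPanel,
    cfg: SimConfig,
    rng: np.random.Generator,
    expected: bool = False,
) -> pd.DataFrame:
    """Sample the allelic count table implied by an individual's truth.

    At each SNP site with local total copy number ``c`` (4 plus any offsets)
    and effective 9311 copies ``d_eff``, the total read count is
    Poisson(per_site_depth * c / 4) and the 9311-attributed count is
    Binomial(n, p) with p = (d_eff/c)(1 - eps) + (1 - d_eff/c) eps.
    With ``expected=True`` counts are set to their (rounded) expectations,
    the infinite-depth limit used for round-trip checks.
    """
    eps = cfg.error_rate
    frames = []
    for chrom in cfg.chrom_names:
        pos = panel.snp.loc[panel.snp["chrom"] == chrom, "pos"].to_numpy()
        segs = truth.segments[chrom]
        seg_ends = np.array([s[1] for s in segs])
        seg_d = np.array([s[2] for s in segs])
        d = seg_d[np.searchsorted(seg_ends, pos - 1, side="right")].astype(float)

        total = np.full(pos.size, 4.0)
        d_eff = d.copy()
        off = truth.chrom_offset.get(chrom, 0)
        if off:
            total += off
            if truth.offset_parent.get(chrom) == "9311":
                d_eff = np.clip(d + off, 0.0, total)
        for s, e, o, parent in truth.seg_events.get(chrom, []):
            inside = (pos - 1 >= s) & (pos - 1 < e)
            total = np.where(inside, total + o, total)
            if parent == "9311":
                d_eff = np.where(inside, np.clip(d_eff + o, 0.0, total), d_eff)
        d_eff = np.clip(d_eff, 0.0, total)

        frac = d_eff / total
        p = frac * (1.0 - eps) + (1.0 - frac) * eps
        lam = cfg.per_site_depth * total / 4.0
        if expected:
            n = np.round(lam).astype(np.int64)
            a = np.round(n * p).astype(np.int64)
        else:
            n = rng.poisson(lam)
            a = rng.binomial(n, p)
        frames.append(
            pd.DataFrame(
                {
                    "individual": truth.name,
                    "chrom": chrom,
                    "pos": pos,
                    "count_9311": a,
                    "count_nip": n - a,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_population(
    cfg: SimConfig, panel: ParentPanel | None = None
) -> tuple[ParentPanel, list[TruthIndividual], pd.DataFrame]:
    """Panel + truth + counts for a full population under one seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if panel is None:
        panel = build_parent_panel(cfg, rng)
    truths, frames = [], []
    for i in range(cfg.n_individuals):
        truth = draw_mosaic(cfg, panel, rng, name=f"{cfg.generation}-{i + 1:02d}")
        truths.append(truth)
        frames.append(emit_counts(truth, panel, cfg, rng))
    counts = pd.concat(frames, ignore_index=True)
    return panel, truths, counts


def simulate_controls(
    cfg: SimConfig, panel: ParentPanel, rng: np.random.Generator, n_controls: int = 3
) -> list[pd.DataFrame]:
    """Balanced control samples (F1-like, true ratio 1:1 at every site)."""
    controls = []
    for i in range(n_controls):
        truth = TruthIndividual(name=f"control-{i + 1}", generation="F1")
        for chrom in cfg.chrom_names:
            truth.segments[chrom] = [(0, cfg.chrom_length_bp, 2)]
            truth.chrom_offset[chrom] = 0
            truth.offset_parent[chrom] = "9311"
            truth.seg_events[chrom] = []
        controls.append(emit_counts(truth, panel, cfg, rng))
    return controls


# ---------------------------------------------------------------------------
# serialisation


def write_truth(truths: list[TruthIndividual], path) -> None:
    payload = []
    for t in truths:
        d = asdict(t)
        d["segments"] = {c: [list(s) for s in v] for c, v in t.segments.items()}
        d["seg_events"] = {c: [list(s) for s in v] for c, v in t.seg_events.items()}
        payload.append(d)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_truth(path) -> list[TruthIndividual]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for d in payload:
        out.append(
            TruthIndividual(
                name=d["name"],
                generation=d["generation"],
                segments={c: [tuple(s) for s in v] for c, v in d["segments"].items()},
                chrom_offset=d["chrom_offset"],
                offset_parent=d["offset_parent"],
                seg_events={c: [tuple(s) for s in v] for c, v in d["seg_events"].items()},
            )
        )
    return out


def write_bed(track: pd.DataFrame, path) -> None:
    """BED (0-based half-open): chrom, start, end [, class]."""
    cols = ["chrom", "start", "end"] + (["class"] if "class" in track.columns else [])
    track[cols].to_csv(path, sep="\t", index=False, header=False)
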