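"""End-to-end orchestration: simulate -> mask -> karyotype -> call-HE ->
features -> marey -> associate, with a YAML run config, a file manifest and
deterministic re-runs under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, counts as counts_mod, features as features_mod
from .dosage import DosageModel, window_he_frequency
from .karyotype import KaryotypeModel
from .marey import MareyMap
from .simulate import (
    SimConfig,
    build_parent_panel,
    emit_counts,
    draw_mosaic,
    simulate_controls,
    write_bed,
    write_truth,
)

log = logging.getLogger("polyhex")

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Parameters and paths of a pipeline run; round-trips through YAML."""

    out_dir: str = "polyhex_run"
    mode: str = "full"  # simulate | analyze | full
    seed: int = 0

    # simulate-mode generator settings (SimConfig fields)
    sim: dict = dataclasses.field(default_factory=dict)

    # analyze-mode inputs (TSV paths); ignored when simulating
    counts_path: str | None = None
    mask_path: str | None = None
    panel_path: str | None = None
    markers_path: str | None = None

    # analysis parameters (defaults follow the study's protocol)
    epsilon: float = 0.005
    bin_snps: int = 10
    min_fragment: int = 5
    window_bp: int = 1_000_000
    min_sites: int = 5
    cutoffs: tuple = (0.5, 0.75, 1.25, 1.5)
    delta: float = 0.05
    loess_span: float = 0.2
    loess_degree: int = 2
    te_hi: float = 0.95
    te_lo: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        cfg = cls(**payload)
        cfg.cutoffs = tuple(cfg.cutoffs)
        return cfg

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["cutoffs"] = list(self.cutoffs)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False, float_format="%.6g")
    tmp.replace(path)
    manifest[path.name] = {
        "rows": int(len(df)),
        "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
    }


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    config.to_yaml(out / "config.yaml")

    if config.mode not in ("simulate", "analyze", "full"):
        raise ValueError(f"unknown mode '{config.mode}'")

    sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
    panel = None
    truths = None

    if config.mode in ("simulate", "full"):
        log.info("stage simulate: seed=%d", config.seed)
        rng = np.random.default_rng(sim_cfg.seed)
        panel = build_parent_panel(sim_cfg, rng)
        truths = [
            draw_mosaic(sim_cfg, panel, rng, name=f"{sim_cfg.generation}-{i + 1:02d}")
            for i in range(sim_cfg.n_individuals)
        ]
        counts = pd.concat(
            [emit_counts(t, panel, sim_cfg, rng) for t in truths], ignore_index=True
        )
        controls = simulate_controls(sim_cfg, panel, rng)
        _write(counts, out / "counts.tsv", manifest)
        _write(panel.snp, out / "panel.tsv", manifest)
        _write(panel.genetic_map, out / "genetic_map.tsv", manifest)
        _write(panel.te_table, out / "te_table.tsv", manifest)
        write_bed(panel.genes, out / "genes.bed")
        write_bed(panel.tes, out / "tes.bed")
        write_truth(truths, out / "truth.json")
        for i, ctrl in enumerate(controls):
            _write(ctrl, out / f"control_{i + 1}.tsv", manifest)
        mask = counts_mod.control_bias_mask(controls)
        _write(mask, out / "mask.tsv", manifest)
        markers = panel.genetic_map
        chrom_lengths = panel.chrom_lengths
        genes, tes, te_table = panel.genes, panel.tes, panel.te_table
        if config.mode == "simulate":
            _finalise(out, manifest)
            return out
    else:  # analyze
        for name, p in (("counts", config.counts_path), ("panel", config.panel_path)):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"stage analyze: missing {name} file ({p})")
        counts = counts_mod.load_counts(config.counts_path)
        snp = counts_mod.load_panel(config.panel_path)
        mask = counts_mod.load_mask(config.mask_path) if config.mask_path else None
        markers = (
            pd.read_csv(config.markers_path, sep="\t", dtype={"chrom": str})
            if config.markers_path
            else None
        )
        chrom_lengths = {
            c: int(g["pos"].max()) for c, g in snp.groupby("chrom", observed=True)
        }
        genes = tes = te_table = None

    log.info("stage karyotype: %d individuals", counts["individual"].nunique())
    karyo = KaryotypeModel(
        counts,
        mask=mask,
        window_bp=config.window_bp,
        min_sites=config.min_sites,
        cutoffs=config.cutoffs,
        delta=config.delta,
    ).fit()
    _write(karyo.calls, out / "karyotype.tsv", manifest)
    _write(karyo.events, out / "segmental_events.tsv", manifest)
    _write(karyo.windows, out / "depth_windows.tsv", manifest)

    euploid = karyo.euploid_individuals()
    log.info("stage call-he: %d euploid of %d individuals",
             len(euploid), counts["individual"].nunique())
    dosage = DosageModel(
        counts,
        mask=mask,
        epsilon=config.epsilon,
        bin_snps=config.bin_snps,
        min_fragment=config.min_fragment,
    ).fit(individuals=euploid)
    _write(dosage.fragments, out / "fragments.tsv", manifest)
    _write(dosage.he_regions, out / "he_regions.tsv", manifest)
    _write(dosage.he_counts, out / "he_counts.tsv", manifest)
    he_windows = window_he_frequency(
        dosage.he_regions, max(len(euploid), 1), chrom_lengths, config.window_bp
    )
    _write(he_windows, out / "he_windows.tsv", manifest)

    window_table = he_windows
    chrom_table = None
    if markers is not None:
        log.info("stage marey")
        marey_res = MareyMap(
            markers, chrom_lengths, config.window_bp, config.loess_span, config.loess_degree
        ).fit()
        _write(marey_res.rates, out / "hr_rates.tsv", manifest)
        window_table = assoc.build_window_table(he_windows, marey_res.rates)
    if genes is not None:
        log.info("stage features")
        chrom_feats = features_mod.chromosome_features(genes, tes, chrom_lengths)
        dens = features_mod.window_variant_density(
            panel.snp, pd.DataFrame(columns=["chrom", "pos", "length"]),
            te_table, chrom_lengths, config.window_bp,
        )
        fracs = features_mod.window_base_fractions(
            pd.concat([genes, tes], ignore_index=True), chrom_lengths, config.window_bp
        )
        _write(chrom_feats, out / "chrom_features.tsv", manifest)
        _write(dens, out / "window_variants.tsv", manifest)
        _write(fracs, out / "window_fractions.tsv", manifest)
        window_table = assoc.build_window_table(window_table, dens, fracs)
        chrom_table = assoc.build_chrom_table(
            chrom_feats, dosage.he_counts,
            marey_res.map_lengths() if markers is not None else None,
        )
        _write(chrom_table, out / "chrom_table.tsv", manifest)

    log.info("stage associate")
    _write(window_table, out / "window_table.tsv", manifest)
    reports = assoc.build_reports(
        chrom_table, window_table, config.loess_span, config.loess_degree
    )
    if "chromosome_correlations" in reports:
        _write(reports["chromosome_correlations"], out / "fig2_table.tsv", manifest)
    if "window_correlations" in reports:
        _write(reports["window_correlations"], out / "table1_correlations.tsv", manifest)
    if "profiles" in reports:
        _write(reports["profiles"], out / "fig3_profiles.tsv", manifest)
    if "he_vs_hr" in reports:
        (out / "he_vs_hr.json").write_text(json.dumps(reports["he_vs_hr"], indent=1))

    _finalise(out, manifest)
    return out


def _finalise(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
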