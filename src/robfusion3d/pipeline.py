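"""End-to-end orchestration: simulate -> matrices -> topology/compartments/TADs
-> recombination, from a single YAML config, with a machine-readable report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import compartments as comp
from . import recomb
from . import tads as tadmod
from . import topology as topo
from .genome import GenomeAssembly, Karyotype, mouse_like_lengths, simulate_genome
from .matrix import (
    bin_pairs,
    ice_normalize,
    mask_low_count_bins,
    scale_to_depth,
)
from .profiles import default_foci_params, default_profile
from .simulate import simulate_contact_pairs, simulate_foci_cells, write_foci

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("robfusion3d")

#: the six Rb fusions of the study's VIL karyotype, with their zygosity
DEFAULT_FUSIONS = {
    ("chr3", "chr8"): "heterozygous",
    ("chr6", "chr10"): "heterozygous",
    ("chr5", "chr15"): "heterozygous",
    ("chr9", "chr11"): "homozygous",
    ("chr12", "chr13"): "homozygous",
    ("chr4", "chr14"): "homozygous",
}


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 1
    n_chrom: int = 20
    genome_scale: float = 1.0
    sizes_path: str | None = None
    resolution: int = 500_000
    tad_resolution: int = 50_000
    tad_zoom_bp: int = 20_000_000
    tad_zoom_pairs: int = 400_000
    n_pairs: int = 1_000_000
    cell_types: list[str] = field(default_factory=lambda: ["RS"])
    fusions: dict[tuple[str, str], str] = field(default_factory=lambda: dict(DEFAULT_FUSIONS))
    min_count: float = 10
    z_threshold: float = 2.58
    overlap_threshold: float = 0.75
    het_bounds: tuple[float, float] = (1.2, 1.6)
    hom_threshold: float = 1.8
    insulation_window: int = 10
    tad_delta: float = 0.5
    foci_n_cells: int = 40
    foci_n_individuals: int = 3

    def validate(self) -> None:
        if self.sizes_path is not None and not Path(self.sizes_path).exists():
            raise FileNotFoundError(f"chromosome sizes file not found: {self.sizes_path}")
        if not 0 < self.overlap_threshold < 1:
            raise ValueError("overlap_threshold must be in (0, 1)")
        if self.z_threshold <= 0 or self.min_count < 0:
            raise ValueError("thresholds out of range")
        if not self.het_bounds[0] < self.het_bounds[1] <= self.hom_threshold:
            raise ValueError("zygosity bounds must satisfy lo < hi <= hom_threshold")
        for cell_type in self.cell_types:
            if cell_type not in ("fibroblast", "PD", "RS"):
                raise ValueError(f"unknown cell type {cell_type}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fusions = raw.pop("fusions", None)
    cfg = PipelineConfig(**raw)
    if fusions is not None:
        cfg.fusions = {tuple(sorted(k.split("|"))): v for k, v in fusions.items()}
    cfg.validate()
    return cfg


def _load_genome(cfg: PipelineConfig) -> GenomeAssembly:
    if cfg.sizes_path is not None:
        names, lengths = [], {}
        with open(cfg.sizes_path) as fh:
            for line in fh:
                chrom, size = line.split()[:2]
                names.append(chrom)
                lengths[chrom] = int(size)
        return GenomeAssembly(names, lengths, {c: 0 for c in names})
    return simulate_genome(
        cfg.n_chrom, mouse_like_lengths(cfg.n_chrom, cfg.genome_scale), seed=cfg.seed
    )


def _prepare(genome, karyotype, profile, cfg, seed):
    """Simulate, bin and mask one map; return (raw, ICE-balanced) versions.

    Pair-ratio statistics (fusion detection, zygosity) run on the masked raw
    map, where the fused-pair excess is linear in penetrance; compartments,
    TADs and region calling use the balanced map.
    """
    pairs = simulate_contact_pairs(genome, karyotype, profile, cfg.n_pairs, seed=seed)
    mat = bin_pairs(pairs, genome, cfg.resolution)
    raw = mask_low_count_bins(mat, cfg.min_count)
    return pairs, raw, ice_normalize(raw)


def _tad_zoom_map(profile, cfg: PipelineConfig, seed: int):
    """Deeply sampled single-chromosome map for sub-megabase (TAD) analysis."""
    zoom = simulate_genome(1, [cfg.tad_zoom_bp], seed=seed)
    pairs = simulate_contact_pairs(
        zoom, Karyotype([], {}), profile, cfg.tad_zoom_pairs, seed=seed
    )
    mat = mask_low_count_bins(bin_pairs(pairs, zoom, cfg.tad_resolution), cfg.min_count)
    return scale_to_depth(mat)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full synthetic study and write ``report.json`` under the outdir."""
    cfg.validate()
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

    genome = _load_genome(cfg)
    rb_karyotype = Karyotype(list(cfg.fusions), dict(cfg.fusions))
    st_karyotype = Karyotype([], {})
    report: dict = {
        "seed": cfg.seed,
        "resolution": cfg.resolution,
        "n_pairs": cfg.n_pairs,
        "genome": {"n_chrom": cfg.n_chrom, "scale": cfg.genome_scale},
        "cell_types": {},
    }

    for ci, cell_type in enumerate(cfg.cell_types):
        logger.info("simulating %s maps", cell_type)
        profile = default_profile(cell_type)
        seed = cfg.seed * 1000 + ci
        rb_pairs, rb_raw, rb = _prepare(genome, rb_karyotype, profile, cfg, seed)
        st_pairs, st_raw, st = _prepare(genome, st_karyotype, profile, cfg, seed + 500)
        entry: dict = {}

        candidates = topo.detect_fusions(rb_raw)
        entry["detected_fusions"] = [
            sorted((r.chrom1, r.chrom2)) for r in candidates.itertuples()
        ]
        if cell_type == "RS":
            calls = topo.classify_fusion_zygosity(
                rb_raw,
                [tuple(p) for p in rb_karyotype.fusions],
                het_bounds=cfg.het_bounds,
                hom_threshold=cfg.hom_threshold,
            )
            entry["zygosity"] = {
                "|".join(c.chrom_pair): {
                    "ratio": round(c.interaction_ratio, 4),
                    "zygosity": c.zygosity,
                }
                for c in calls
            }
        regions = topo.call_trans_interaction_regions(rb, st, cfg.z_threshold)
        entry["n_trans_regions"] = int(len(regions.bins))
        regions.bins.to_csv(
            outdir / f"{cell_type}_trans_regions.bed", sep="\t", header=False, index=False
        )

        density = genome.gene_density_at(cfg.resolution)
        track_rb = comp.call_compartments(rb, density)
        track_st = comp.call_compartments(st, density)
        entry["compartment_switch"] = {
            k: v
            for k, v in comp.compartment_switch_ratio(track_rb, track_st).items()
            if not isinstance(v, np.ndarray)
        }
        entry["compartment_mean_size_rb"] = comp.compartment_sizes(track_rb)["overall"]

        # TADs are sub-megabase features needing locally deep maps: zoom in on
        # a single chromosome-sized region at fine resolution and matched depth
        rb_fine = _tad_zoom_map(profile, cfg, seed + 11)
        st_fine = _tad_zoom_map(profile, cfg, seed + 511)
        ins_rb = tadmod.insulation_score(rb_fine, cfg.insulation_window)
        ins_st = tadmod.insulation_score(st_fine, cfg.insulation_window)
        tads_rb = tadmod.call_tads(ins_rb, cfg.tad_delta)
        tads_st = tadmod.call_tads(ins_st, cfg.tad_delta)
        if len(tads_rb.domains) and len(tads_st.domains):
            reorg = tadmod.classify_tad_reorganization(
                tads_rb, tads_st, cfg.overlap_threshold
            )
            entry["tad_classes"] = reorg.frequencies
        entry["n_tads_rb"] = int(len(tads_rb.domains))
        entry["mean_tad_length_rb"] = tads_rb.mean_length
        entry["insulation_variance"] = tadmod.insulation_variance_compare(ins_rb, ins_st)
        report["cell_types"][cell_type] = entry

    logger.info("simulating foci tables")
    params = default_foci_params()
    tables = []
    arms = {"AcrRb": 7, "MetHet": 3, "MetHom": 3}
    for ind in range(cfg.foci_n_individuals):
        tables.append(
            simulate_foci_cells(
                params,
                cfg.foci_n_cells,
                arms,
                seed=cfg.seed * 77 + ind,
                individual_id=f"Rb{ind + 1}",
            )
        )
    import pandas as pd

    foci_table = pd.concat(tables, ignore_index=True)
    foci_path = outdir / "foci.tsv"
    write_foci(foci_table, foci_path)
    cells = recomb.read_foci(foci_path)
    counts = recomb.summarize_counts(cells)
    report["recombination"] = {
        "count_proportions": {
            g: {k: float(v) for k, v in d.items()} for g, d in counts["proportions"].items()
        },
        "chi_square_p": counts.get("p_value"),
        "mean_density": {
            g: float(v) for g, v in recomb.co_density(cells)["mean_density"].items()
        },
        "interindividual_cv": recomb.interindividual_cv(cells)["cv"].tolist(),
    }

    report["runtime_s"] = round(time.time() - t0, 2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    logger.info("report written to %s", outdir / "report.json")
    return report
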