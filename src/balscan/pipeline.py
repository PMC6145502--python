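"""End-to-end workflows: the candidate-region scan and the selection inference.

``run_scan`` chains the windowed Tajima's D scan (with empirical
genome-background and coalescent-simulated null thresholds), the focal-SNP
nSL matched-frequency percentile, the gene-level MK/DoS table and the
branch-site LRT table. ``run_inference`` chains the (s, age) grid-rejection
step, summary statistics of accepted simulations, and the conditional
allele-age estimate. Every output directory carries a manifest with the
seed, a hash of the resolved configuration and package versions, so a rerun
with the same config and seed reproduces every file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

import balscan
from balscan.coalescent_sim import conditional_allele_age, null_tajima_distribution
from balscan.coding_selection import MKCounts, lrt_table, mk_test
from balscan.demography import DemographyConfig, load_demography, toy_ooa
from balscan.forward_sim import (
    AcceptanceRule,
    accepted_statistics,
    grid_rejection_inference,
    sample_accepted_panels,
)
from balscan.haplotype_scan import matched_frequency_percentile, nsl_unstandardized
from balscan.panel import HaplotypePanel
from balscan.sfs_scan import empirical_threshold, scan_rows, window_scan
from balscan.synthetic_data import ScenarioSpec, generate_genome_background, generate_panel
from balscan.variant_io import read_haplotype_panel, write_scan_tsv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for a scan or inference run."""

    out_dir: str = "balscan_out"
    seed: int = 0
    # input panel: either a VCF + popmap, or a synthetic scenario
    vcf: str | None = None
    popmap: str | None = None
    scenario: dict = field(default_factory=dict)
    demography: str | None = None  # YAML path; None -> scenario default
    # scan stage
    window: int = 10_000
    step: int = 2_000
    percentile: float = 0.95
    n_background: int = 150
    n_null_reps: int = 150
    # nSL stage
    nsl_draws: int = 1_000
    nsl_tol: float = 0.05
    # MK / LRT stage
    mk_counts: str | None = None  # TSV gene, d_n, d_s, p_n, p_s
    lnl_table: str | None = None  # TSV gene, lnl_null, lnl_alt (None: shipped)
    # inference stage
    s_grid: tuple = (0.0, 0.15, 0.025)
    age_grid: tuple = (200.0, 500.0, 100.0)
    grid_reps: int = 30
    observed_freqs: dict = field(default_factory=lambda: {"AFR": 0.07, "EUR": 0.45, "ASN": 0.30})
    tolerance_pp: float = 5.0
    intro_pop: str = "EUR"
    n_accepted_panels: int = 8
    # allele age stage: a merged single population of the quoted effective
    # size, mirroring the integrated-population convention of the TMRCA step
    age_pop_size: float = 10_000.0
    age_sample_sizes: dict = field(default_factory=lambda: {"ALL": 50})
    age_derived_counts: dict = field(default_factory=lambda: {"ALL": 15})
    age_n_accepted: int = 150

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def config_hash(self) -> str:
        doc = asdict(self)
        doc.pop("out_dir", None)  # where results land does not change them
        canon = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _resolve_demography(config: RunConfig) -> DemographyConfig:
    if config.demography is not None:
        return load_demography(config.demography)
    return toy_ooa()


def _load_panel(config: RunConfig) -> HaplotypePanel:
    if config.vcf is not None:
        if config.popmap is None:
            raise ValueError("a popmap TSV is required with a VCF input")
        return read_haplotype_panel(config.vcf, config.popmap)
    spec = ScenarioSpec(seed=config.seed, **config.scenario)
    return generate_panel(spec)


def _write_manifest(out: Path, config: RunConfig, stage: str, timers: dict) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "versions": {
            "balscan": balscan.__version__,
            "numpy": np.__version__,
        },
        "stage_seconds": timers,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _shipped_lnl_rows() -> list[tuple[str, float, float]]:
    from importlib import resources

    text = resources.files("balscan.data").joinpath("branch_site_lnl.tsv").read_text()
    return _parse_lnl(text.splitlines())


def _parse_lnl(lines) -> list[tuple[str, float, float]]:
    rows = []
    header_seen = False
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # header row
            continue
        gene, l0, l1 = line.split("\t")
        rows.append((gene, float(l0), float(l1)))
    return rows


def run_scan(config: RunConfig) -> dict:
    """Candidate-region scan: D track + thresholds, focal nSL, MK and LRT tables.

    Returns a summary dict and writes TSV reports plus a manifest under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timers: dict[str, float] = {}
    header = [f"seed={config.seed}", f"config_hash={config.config_hash()}"]

    t0 = time.time()
    panel = _load_panel(config)
    pops = panel.population_names()
    timers["load_panel"] = time.time() - t0

    # windowed Tajima's D, per population
    t0 = time.time()
    stats = window_scan(panel, config.window, config.step)
    timers["window_scan"] = time.time() - t0

    # empirical threshold from neutral genome background
    t0 = time.time()
    bg_spec = ScenarioSpec(
        scenario_name="neutral",
        sample_sizes={p: int(np.sum(panel.populations == p)) for p in pops},
        target_freqs={p: 0.0 for p in pops},
        region_length=config.window,
        seed=config.seed + 1,
        **{
            k: v
            for k, v in config.scenario.items()
            if k in ("mutation_rate", "recombination_rate", "demography")
        },
    )
    background = generate_genome_background(config.n_background, bg_spec)
    from balscan.panel import GenomicWindow
    from balscan.sfs_scan import tajimas_d_components

    emp_thresholds = {}
    for p in pops:
        vals = [
            tajimas_d_components(b, GenomicWindow(b.chrom, 0, config.window), population=p).tajima_d
            for b in background
        ]
        emp_thresholds[p] = empirical_threshold(
            [v for v in vals if v is not None], config.percentile
        )
    timers["empirical_null"] = time.time() - t0

    # coalescent-simulated null threshold
    t0 = time.time()
    dem = bg_spec.resolved_demography()
    null = null_tajima_distribution(
        dem,
        bg_spec.sample_sizes,
        window=config.window,
        n_reps=max(100, config.n_null_reps),
        seed=config.seed + 2,
        percentile=config.percentile,
    )
    timers["simulated_null"] = time.time() - t0

    # scan rows with per-population empirical flags
    rows = []
    for st in stats:
        row = scan_rows([st], threshold=emp_thresholds.get(st.population))[0]
        row["sim_threshold"] = null.thresholds.get(st.population)
        rows.append(row)
    write_scan_tsv(rows, out / "tajima_scan.tsv", header_lines=header)

    # focal nSL and matched-frequency percentile
    t0 = time.time()
    nsl_rows = []
    if panel.focal_index is not None:
        for p in pops:
            res = nsl_unstandardized(panel, panel.focal_index, population=p)
            pct = None
            if res.defined:
                try:
                    pct, _ = matched_frequency_percentile(
                        panel,
                        panel.focal_index,
                        n_draws=config.nsl_draws,
                        tol=config.nsl_tol,
                        population=p,
                        rng=config.seed + 3,
                    )
                except ValueError as exc:
                    logger.warning("nSL percentile unavailable for %s: %s", p, exc)
            nsl_rows.append(
                {
                    "population": p,
                    "focal_pos": panel.positions[panel.focal_index],
                    "derived_freq": res.derived_frequency,
                    "sl_a": res.sl_a,
                    "sl_d": res.sl_d,
                    "nsl": res.nsl,
                    "null_draws": config.nsl_draws,
                    "percentile": pct,
                }
            )
        write_scan_tsv(nsl_rows, out / "nsl_focal.tsv", header_lines=header)
    timers["nsl"] = time.time() - t0

    # MK / DoS table
    mk_rows = []
    if config.mk_counts is not None:
        with open(config.mk_counts) as fh:
            lines = [l.strip() for l in fh if l.strip() and not l.startswith("#")]
        for line in lines[1:]:
            gene, dn, ds, pn, ps = line.split("\t")
            counts = MKCounts(
                d_n=float(dn), d_s=float(ds), p_n=float(pn), p_s=float(ps), gene=gene
            )
            direction, p_val, dos = mk_test(counts)
            mk_rows.append(
                {
                    "gene": gene, "d_n": counts.d_n, "d_s": counts.d_s,
                    "p_n": counts.p_n, "p_s": counts.p_s,
                    "dos": dos, "fisher_p": p_val, "direction": direction,
                }
            )
        write_scan_tsv(mk_rows, out / "mk_dos.tsv", header_lines=header)

    # branch-site LRT table
    lnl_rows = (
        _shipped_lnl_rows()
        if config.lnl_table is None
        else _parse_lnl(open(config.lnl_table))
    )
    lrt = lrt_table(lnl_rows)
    write_scan_tsv(
        [
            {
                "gene": r.gene, "lnl_null": r.lnl_null, "lnl_alt": r.lnl_alt,
                "chi2": r.chi2, "p_value": r.p_value, "q_value": r.q_value,
            }
            for r in lrt
        ],
        out / "branch_site_lrt.tsv",
        header_lines=header,
    )

    _write_manifest(out, config, "scan", timers)
    focal_flagged = {}
    if panel.focal_index is not None:
        fp = panel.positions[panel.focal_index]
        for p in pops:
            ds = [
                st.tajima_d
                for st in stats
                if st.population == p and st.defined and st.window.contains_position(fp)
            ]
            focal_flagged[p] = bool(ds and max(ds) > emp_thresholds[p])
    return {
        "panel": panel,
        "stats": stats,
        "empirical_thresholds": emp_thresholds,
        "simulated_thresholds": null.thresholds,
        "focal_window_flagged": focal_flagged,
        "nsl": nsl_rows,
        "mk": mk_rows,
        "lrt": lrt,
        "out_dir": str(out),
    }


def run_inference(config: RunConfig) -> dict:
    """Selection inference: grid rejection, accepted-run statistics, allele age."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timers: dict[str, float] = {}
    header = [f"seed={config.seed}", f"config_hash={config.config_hash()}"]
    dem = (
        load_demography(config.demography)
        if config.demography is not None
        else toy_ooa()
    )
    rule = AcceptanceRule(observed=config.observed_freqs, tolerance_pp=config.tolerance_pp)

    t0 = time.time()
    cells = grid_rejection_inference(
        dem,
        tuple(config.s_grid),
        tuple(config.age_grid),
        n_reps=config.grid_reps,
        rule=rule,
        seed=config.seed,
        intro_pop=config.intro_pop,
    )
    timers["grid"] = time.time() - t0
    grid_tsv = [
        {
            "s": c.s, "age": c.age, "n_reps": c.n_reps,
            "n_accepted": c.n_accepted,
            "n_lost": int(c.lost.sum()), "n_fixed": int(c.fixed.sum()),
        }
        for c in cells
    ]
    write_scan_tsv(grid_tsv, out / "grid_acceptance.tsv", header_lines=header)

    t0 = time.time()
    accepted_stats = {}
    n_acc = sum(c.n_accepted for c in cells)
    if n_acc and config.n_accepted_panels > 0:
        panels = sample_accepted_panels(
            dem, cells, rule,
            sample_sizes={p: 40 for p in config.observed_freqs},
            region_length=10_000,
            max_panels=config.n_accepted_panels,
            seed=config.seed + 1,
            intro_pop=config.intro_pop,
        )
        if panels:
            accepted_stats = accepted_statistics(panels)
            rows = []
            for p, d in accepted_stats.items():
                rows.append(
                    {
                        "population": p,
                        "n_tajima": d["tajima_d"].size,
                        "tajima_d_median": (
                            float(np.median(d["tajima_d"])) if d["tajima_d"].size else None
                        ),
                        "n_nsl": d["nsl"].size,
                        "nsl_median": float(np.median(d["nsl"])) if d["nsl"].size else None,
                    }
                )
            write_scan_tsv(rows, out / "accepted_statistics.tsv", header_lines=header)
    timers["accepted_stats"] = time.time() - t0

    t0 = time.time()
    from balscan.demography import PopulationConfig

    age_dem = DemographyConfig(
        populations=[
            PopulationConfig(name=p, initial_size=config.age_pop_size)
            for p in config.age_sample_sizes
        ],
        mutation_rate=0.0,
        recombination_rate=0.0,
        generation_time=dem.generation_time,
        name="merged_age_model",
    )
    age_est = conditional_allele_age(
        age_dem,
        config.age_sample_sizes,
        config.age_derived_counts,
        n_accepted=config.age_n_accepted,
        seed=config.seed + 2,
        match="total",
    )
    timers["allele_age"] = time.time() - t0
    write_scan_tsv(
        [
            {
                "age_gen": age_est.age_mean, "age_se_gen": age_est.age_se,
                "age_years": age_est.age_years, "age_se_years": age_est.age_se_years,
                "tmrca_gen": age_est.tmrca_mean, "tmrca_years": age_est.tmrca_years,
                "n_accepted": age_est.n_accepted, "n_attempts": age_est.n_attempts,
            }
        ],
        out / "allele_age.tsv",
        header_lines=header,
    )

    _write_manifest(out, config, "inference", timers)
    return {
        "cells": cells,
        "n_accepted_total": n_acc,
        "accepted_stats": accepted_stats,
        "age": age_est,
        "out_dir": str(out),
    }
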