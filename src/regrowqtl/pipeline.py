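"""End-to-end orchestration: simulate/load -> segregation tests -> filter
cascade -> genome scans -> rendered report.

Two scan variants are first-class, mirroring the two marker sets a
practitioner would map on: (a) the post-missingness-imputation matrix (all
markers that survive coverage/MAF/missingness), and (b) the fully filtered
matrix after the model chi-square filter and haplotype-cluster collapsing.
Their permutation thresholds belong to different marker sets and are
reported separately.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import Dataset, PhenotypeTable, chromosome_sort_key
from .filters import CascadeResult, FilterConfig, run_filter_cascade
from .io import (load_segregation_counts, read_genotype_table,
                 read_phenotypes, write_genotype_table, write_phenotypes)
from .scan import (ScanConfig, ScanResult, build_genetic_map, calc_genoprob,
                   call_intervals, permutation_threshold, scan_binary_em)
from .segregation import SegModel, best_fit_model
from .simulate import (CausalModel, GenomeSpec, NoiseSpec, default_genome,
                       simulate_f2_population)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class SimSpec:
    """Simulation input source for a pipeline run."""

    n_plants: int = 200
    genome: GenomeSpec = field(default_factory=default_genome)
    causal: CausalModel = field(default_factory=CausalModel)
    noise: NoiseSpec = field(default_factory=NoiseSpec)


@dataclass
class RunConfig:
    """Exactly one input source: files, simulation, or packaged phenotypes."""

    simulate: SimSpec | None = None
    genotype_path: str | None = None
    map_path: str | None = None
    phenotype_path: str | None = None
    packaged_phenotypes: bool = False
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    scan_cfg: ScanConfig = field(default_factory=ScanConfig)
    candidate_k: tuple[int, ...] = (1, 2, 3)
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        sources = sum([self.simulate is not None,
                       self.phenotype_path is not None
                       or self.genotype_path is not None,
                       self.packaged_phenotypes])
        if sources != 1:
            raise ConfigError("exactly one input source required "
                              "(simulate, file paths, or packaged "
                              "phenotypes)")


@dataclass
class ScanSection:
    label: str
    result: ScanResult
    threshold: float
    n_markers: int


@dataclass
class RunReport:
    segregation: pd.DataFrame
    filter_counts: pd.DataFrame | None
    scans: list[ScanSection]
    provenance: dict[str, Any]
    skipped: list[str] = field(default_factory=list)


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: enc(getattr(o, f.name))
                    for f in dataclasses.fields(o)}
        if isinstance(o, (list, tuple)):
            return [enc(x) for x in o]
        if isinstance(o, dict):
            return {str(k): enc(v) for k, v in o.items()}
        return o
    blob = json.dumps(enc(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _segregation_table(tables: dict[str, tuple[int, int]],
                       candidate_k: tuple[int, ...]) -> pd.DataFrame:
    rows = []
    models = [SegModel(k) for k in candidate_k]
    for name, (n_r, n_nr) in tables.items():
        best, results = best_fit_model(n_r, n_nr, models)
        row: dict[str, Any] = {"generation": name, "total": n_r + n_nr,
                               "n_R": n_r, "n_NR": n_nr}
        for res in results:
            row[f"p_{res.model.label}"] = res.p
        row["best_model"] = best.label
        rows.append(row)
    return pd.DataFrame(rows)


def _run_scan(d: Dataset, cfg: ScanConfig, label: str,
              rng: np.random.Generator) -> ScanSection:
    gmap = build_genetic_map(d.genotypes.markers)
    gp = calc_genoprob(d, gmap, cfg)
    result = scan_binary_em(gp, d.phenotypes, cfg)
    perm = permutation_threshold(gp, d.phenotypes, cfg, rng)
    result.threshold = perm.threshold
    result.intervals = call_intervals(result, perm.threshold)
    return ScanSection(label, result, perm.threshold,
                       d.genotypes.n_markers)


def _counts_frame(cascade: CascadeResult) -> pd.DataFrame:
    stages = list(cascade.survivor_counts)
    chroms = sorted({c for s in stages
                     for c in cascade.survivor_counts[s]},
                    key=chromosome_sort_key)
    rows = [{"chromosome": c,
             **{s: cascade.survivor_counts[s].get(c, 0) for s in stages}}
            for c in chroms]
    rows.append({"chromosome": "total",
                 **{s: sum(cascade.survivor_counts[s].values())
                    for s in stages}})
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig) -> RunReport:
    """Execute the full workflow for the configured input source."""
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    skipped: list[str] = []
    dataset: Dataset | None = None
    seg_tables: dict[str, tuple[int, int]] = {}

    if cfg.simulate is not None:
        spec = cfg.simulate
        dataset, truth = simulate_f2_population(
            spec.n_plants, spec.genome, spec.causal, spec.noise,
            seed=cfg.seed)
        if outdir:
            truth.write(outdir / "truth.tsv")
            write_genotype_table(dataset.genotypes,
                                 outdir / "genotypes.tsv")
            write_phenotypes(dataset.phenotypes, outdir / "phenotypes.tsv")
        _, n_r, n_nr = dataset.phenotypes.counts()
        seg_tables["simulated-F2"] = (n_r, n_nr)
    elif cfg.packaged_phenotypes:
        for row in load_segregation_counts().itertuples():
            seg_tables[row.generation] = (int(row.n_R), int(row.n_NR))
        skipped += ["filter cascade (no genotype matrix)",
                    "genome scans (no genotype matrix)"]
    else:
        phen = read_phenotypes(cfg.phenotype_path)
        _, n_r, n_nr = phen.counts()
        seg_tables["input"] = (n_r, n_nr)
        if cfg.genotype_path:
            geno = read_genotype_table(cfg.genotype_path,
                                       map_path=cfg.map_path)
            dataset = Dataset.join(geno, phen)
        else:
            skipped += ["filter cascade (no genotype matrix)",
                        "genome scans (no genotype matrix)"]

    seg = _segregation_table(seg_tables, cfg.candidate_k)

    filter_counts = None
    scans: list[ScanSection] = []
    if dataset is not None:
        cascade = run_filter_cascade(dataset, cfg.filter_cfg)
        filter_counts = _counts_frame(cascade)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 1]).generate_state(1)[0])
        scans.append(_run_scan(cascade.after_impute, cfg.scan_cfg,
                               "post-missingness (all markers)", rng))
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 2]).generate_state(1)[0])
        scans.append(_run_scan(cascade.after_collapse, cfg.scan_cfg,
                               "post-model-filter (collapsed clusters)",
                               rng))
        if outdir:
            write_genotype_table(cascade.after_collapse.genotypes,
                                 outdir / "genotypes_filtered.tsv")

    report = RunReport(seg, filter_counts, scans, {
        "seed": cfg.seed, "config_hash": _config_hash(cfg),
        "version": __version__})
    report.skipped = skipped
    if outdir:
        docs = report_render(report, "markdown")
        (outdir / "report.md").write_text(docs["report"], encoding="utf-8")
        docs = report_render(report, "tsv")
        for name, text in docs.items():
            (outdir / f"{name}.tsv").write_text(text, encoding="utf-8")
    return report


def _fmt_seg(seg: pd.DataFrame) -> pd.DataFrame:
    out = seg.copy()
    for c in out.columns:
        if c.startswith("p_"):
            out[c] = out[c].map(lambda p: f"{p:.4f}")
    return out


def report_render(r: RunReport, format: str = "markdown") -> dict[str, str]:
    """Render the report deterministically: p-values at 4 decimals, LOD at
    2.  Returns named documents (markdown: single 'report'; tsv: one per
    section)."""
    seg = _fmt_seg(r.segregation)
    scan_frames = {}
    for sec in r.scans:
        pos = sec.result.positions
        mask = pos["is_marker"].to_numpy()
        prof = pd.DataFrame({
            "chromosome": pos["chromosome"][mask].to_numpy(),
            "position_bp": pos["position_bp"][mask].to_numpy(),
            "lod": [f"{v:.2f}" for v in sec.result.lod[mask]]})
        iv = pd.DataFrame(
            [{"chromosome": i.chromosome, "start_bp": i.start_bp,
              "end_bp": i.end_bp, "peak_bp": i.peak_bp,
              "peak_lod": f"{i.peak_lod:.2f}"}
             for i in sec.result.intervals])
        scan_frames[sec.label] = (prof, iv, sec.threshold)

    if format == "tsv":
        docs = {"segregation": seg.to_csv(sep="\t", index=False)}
        if r.filter_counts is not None:
            docs["filter_counts"] = r.filter_counts.to_csv(sep="\t",
                                                           index=False)
        for i, (label, (prof, iv, thr)) in enumerate(scan_frames.items(), 1):
            docs[f"scan{i}_lod"] = prof.to_csv(sep="\t", index=False)
            docs[f"scan{i}_intervals"] = (
                iv.to_csv(sep="\t", index=False) if len(iv)
                else "none significant\n")
        return docs
    if format != "markdown":
        raise ValueError(f"unknown format {format!r}")

    lines = [f"# regrowqtl run report",
             "",
             f"seed: {r.provenance['seed']}  ",
             f"config: {r.provenance['config_hash']}  ",
             f"version: {r.provenance['version']}",
             "", "## Segregation models", "",
             seg.to_markdown(index=False)]
    if r.filter_counts is not None:
        lines += ["", "## SNP filtration survivors", "",
                  r.filter_counts.to_markdown(index=False)]
    for label, (prof, iv, thr) in scan_frames.items():
        lines += ["", f"## Genome scan: {label}", "",
                  f"permutation LOD threshold: {thr:.2f}", ""]
        if len(iv):
            lines.append(iv.to_markdown(index=False))
        else:
            lines.append("none significant")
    for s in r.skipped:
        lines += ["", f"_skipped: {s}_"]
    return {"report": "\n".join(lines) + "\n"}
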