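"""End-to-end orchestration: simulate → QC → relationship matrices → AI-REML
→ ssGBLUP → weighted GWAS → windows → annotation, from one YAML config.

Every stage writes diff-able TSV artifacts into the run directory plus a
machine-readable ``summary.json``.  One global seed drives all randomness;
per-stage streams are split deterministically so reruns are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_windows, load_genes, overlap_qtl, read_qtl_bed
from .genomic import (allele_frequencies, blend_G, build_G,
                      genomic_inbreeding, qc_filter)
from .gwas import manhattan_plot, report_windows, run_wssgblup, windows_frame
from .pedigree import PedigreeTable, build_Ainv, compute_inbreeding, extract_A22
from .reml import ai_reml
from .simulate import SimConfig, simulate_dataset
from .singlestep import ModelSpec, build_Hinv, build_mme, solve_mme

log = logging.getLogger("ssgblup")


@dataclass
class RunConfig:
    """Pipeline settings; every analysis default is the study value
    (QC 0.05/0.90/0.90/0.15; τ=1.0, ω=0.7; 0.95·G + 0.05·A22; 10-SNP
    windows, 1% threshold, three weighting iterations)."""

    out_dir: str = "ssgblup_run"
    seed: int = 1
    # inputs; None = simulate
    pedigree_csv: str | None = None
    phenotype_csv: str | None = None
    plink_prefix: str | None = None
    genotyped_ids_file: str | None = None
    gff3: str | None = None
    qtl_bed: str | None = None
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    # QC thresholds
    maf_min: float = 0.05
    snp_call_min: float = 0.90
    animal_call_min: float = 0.90
    hwe_dev_max: float = 0.15
    autosomes_only: bool = True
    # single-step / REML
    tau: float = 1.0
    omega: float = 0.7
    g_weight: float = 0.95
    a_weight: float = 0.05
    reml_max_iter: int = 100
    reml_tol: float = 1e-8
    # GWAS
    window_size: int = 10
    threshold_pct: float = 1.0
    n_weight_iterations: int = 3
    flank_bp: int = 100_000
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
            log.info("stage %s: done", name)
            return out
        return wrapped
    return deco


def load_inputs(cfg: RunConfig):
    """Read pedigree/phenotypes/genotypes from files, or simulate them."""
    if cfg.pedigree_csv:
        ped = PedigreeTable.read_csv(cfg.pedigree_csv)
        phen = pd.read_csv(cfg.phenotype_csv)
        from .plinkio import read_plink

        geno = read_plink(cfg.plink_prefix)
        if cfg.genotyped_ids_file:
            with open(cfg.genotyped_ids_file) as fh:
                gids = [ln.strip() for ln in fh if ln.strip()]
            keep = [i for i, a in enumerate(geno.animal_ids) if a in set(gids)]
            geno = geno.subset(animal_idx=keep)
        truth = None
    else:
        sim = SimConfig(**{"seed": cfg.seed, **cfg.simulate})
        ped, geno_all, phen, truth, gids = simulate_dataset(sim)
        keep = list(ped.positions(gids))
        geno = geno_all.subset(animal_idx=keep)
    return ped, phen, geno, truth


def summarize_inbreeding(ped: PedigreeTable, G_raw) -> dict:
    """Mean pedigree F next to mean(diag(G)) − 1 for the genotyped set."""
    f = compute_inbreeding(ped)
    return {"mean_pedigree_F": float(np.mean(f)),
            "mean_genomic_F": genomic_inbreeding(G_raw)}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the summary dict (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    summary: dict = {"version": __version__, "seed": cfg.seed}
    try:
        ped, phen, geno, truth = _stage("inputs")(load_inputs)(cfg)
        ped.write_csv(out / "pedigree.csv")
        phen.to_csv(out / "phenotypes.csv", index=False)

        geno_qc, qc_rep = _stage("qc")(qc_filter)(
            geno, maf_min=cfg.maf_min, snp_call_min=cfg.snp_call_min,
            animal_call_min=cfg.animal_call_min, hwe_dev_max=cfg.hwe_dev_max,
            autosomes_only=cfg.autosomes_only)
        qc_rep.write_tsv(out / "qc_report.tsv")
        summary["qc"] = {"snps_in": qc_rep.n_snps_in, "snps_out": qc_rep.n_snps_out,
                         "animals_in": qc_rep.n_animals_in,
                         "animals_out": qc_rep.n_animals_out}

        def relmat():
            f = compute_inbreeding(ped)
            Ainv = build_Ainv(ped, f)
            A22, A22inv = extract_A22(ped, geno_qc.animal_ids)
            p = allele_frequencies(geno_qc)
            G = build_G(geno_qc, p)
            Gb = blend_G(G, A22, g_weight=cfg.g_weight, a_weight=cfg.a_weight)
            return f, Ainv, A22, A22inv, G, Gb

        f, Ainv, A22, A22inv, G, Gb = _stage("relationship_matrices")(relmat)()
        summary["inbreeding"] = summarize_inbreeding(ped, G)

        spec = ModelSpec(tau=cfg.tau, omega=cfg.omega)
        gpos = ped.positions(geno_qc.animal_ids)

        def reml_stage():
            Ginv = np.linalg.inv(Gb.values)
            Hinv = build_Hinv(Ainv, Ginv, A22inv, gpos, tau=cfg.tau, omega=cfg.omega)
            system = build_mme(spec, phen, ped, Hinv)
            vc, work = ai_reml(system, max_iter=cfg.reml_max_iter, tol=cfg.reml_tol)
            return Hinv, system, vc, work

        Hinv, system, vc, work = _stage("reml")(reml_stage)()
        vc.write_tsv(out / "variance_components.tsv")
        summary["variance_components"] = {
            "G0": vc.G0.tolist(), "R0": vc.R0.tolist(),
            "h2": vc.h2.tolist(), "se_h2": vc.se_h2.tolist(),
            "r_G": vc.r_G, "se_r_G": vc.se_r_G,
            "loglik": vc.loglik, "iterations": vc.iterations,
        }

        sol = _stage("ssgblup")(solve_mme)(system, vc.G0, vc.R0)
        sol.write_tsv(out / "gebv.tsv")

        def gwas_stage():
            all_windows = []
            all_sets = []
            for t in (0, 1):
                sets, wins = run_wssgblup(
                    phen, ped, geno_qc, A22, A22inv, Ainv, vc.G0, vc.R0,
                    spec=spec, n_iterations=cfg.n_weight_iterations,
                    focal_trait=t, g_weight=cfg.g_weight, a_weight=cfg.a_weight,
                    window_size=cfg.window_size)
                all_sets.append(sets)
                all_windows.extend(wins)
                sets[-1].write_tsv(out / f"snp_effects_trait{t + 1}.tsv")
            return all_sets, all_windows

        sets, windows = _stage("gwas")(gwas_stage)()
        windows_frame(windows).to_csv(out / "windows_all.tsv", sep="\t", index=False)
        top = report_windows(windows, threshold_pct=cfg.threshold_pct)
        summary["n_windows_above_threshold"] = int(len(top))
        if cfg.make_plots:
            for t in ("trait1", "trait2"):
                manhattan_plot(windows, t, out / f"manhattan_{t}.png",
                               threshold_pct=cfg.threshold_pct)

        def annotate_stage():
            tbl = top
            if cfg.gff3 and len(top):
                genes = load_genes(cfg.gff3)
                tbl = annotate_windows(top, genes, flank_bp=cfg.flank_bp)
            if cfg.qtl_bed and len(top):
                qtl = read_qtl_bed(cfg.qtl_bed)
                overlap_qtl(tbl, qtl).to_csv(out / "qtl_overlap.tsv",
                                             sep="\t", index=False)
            return tbl

        top_annot = _stage("annotation")(annotate_stage)()
        drop = [c for c in ("gene_ids",) if c in top_annot.columns]
        top_annot.drop(columns=drop).to_csv(out / "windows_significant.tsv",
                                            sep="\t", index=False)

        with open(out / "summary.json", "w") as fhj:
            json.dump(summary, fhj, indent=2, sort_keys=True)
        return summary
    finally:
        log.removeHandler(fh)
        fh.close()
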