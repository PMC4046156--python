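"""End-to-end orchestration of the analysis stages.

A run directory (as produced by ``nucmir simulate`` or assembled by hand from
real exports) holds the standard input files::

    ct_whole.tsv / samples_whole.tsv           whole-cell CT matrix
    ct_fractions.tsv / samples_fractions.tsv   nuclear+cytoplasmic CT matrix
    assay_classes.tsv                          marker annotations (optional)
    expression.tsv / samples_expression.tsv    log2 mRNA matrix
    mirnas.fasta / utrs.fasta / pri_mirnas.fasta

``run_pipeline`` executes ingest -> detectability -> miRNA DE -> clustering ->
(optional cross-species) -> moderated-t mRNA DE -> anti-correlated target
pairs -> stage-specific pairs -> fraction QC -> contamination regression ->
nuclear-enrichment calls -> pri-miRNA duplex scan -> candidate table, writing
TSV reports, a structured log (with wall times) and a machine-readable
``summary.json`` whose bytes depend only on the inputs, configuration and
seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import de as de_mod
from . import duplex as duplex_mod
from . import fractionation as frac_mod
from . import targets as targets_mod
from .ctmatrix import CtMatrix, collapse_replicates, detectability_filter
from .errors import ConfigurationError, QCError
from .io import (
    read_ct_table,
    read_expression_matrix,
    read_fasta,
    read_sample_sheet,
    write_json,
)

ALL_STAGES = (
    "ingest", "mirna_de", "cluster", "cross_species", "mrna_de", "targets",
    "fractions", "priscan",
)


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    ct_threshold: float = 30.0
    ct_high: float = 25.0
    min_fold: float = 2.0
    ratio_threshold: float = 0.1
    mfe_cut: float = -30.0
    alpha: float = 0.05
    p_cut: float = 0.05
    comparison: tuple = ("granulocyte", "promyelocyte")
    controls: list | None = None
    n_shuffles: int = 200
    window: int = 60
    step: int = 10
    seed: int = 0
    strict: bool = False
    human_folds: str | None = None
    # pri-miRNA screen: scan only the strongest nuclear candidates (ranked by
    # their best N:C ratio across cell types); shuffle calibration per
    # (miRNA, transcript) is the pipeline's dominant cost
    max_pri_queries: int = 8

    @classmethod
    def from_yaml(cls, path, **overrides):
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "comparison" in data:
            data["comparison"] = tuple(data["comparison"])
        return cls(**data)

    def validate(self):
        for name, lo, hi in (
            ("alpha", 0.0, 1.0), ("p_cut", 0.0, 1.0), ("ratio_threshold", 0.0, None),
        ):
            v = getattr(self, name)
            if v < lo or (hi is not None and v > hi):
                raise ConfigurationError(f"{name}={v} out of range")
        if self.min_fold < 1.0:
            raise ConfigurationError("min_fold must be >= 1")
        if self.mfe_cut >= 0:
            raise ConfigurationError("mfe_cut must be negative (kcal/mol)")


class _Log:
    def __init__(self):
        self.records = []

    def stage(self, name, t0, **counts):
        self.records.append(
            {"stage": name, "wall_s": round(time.perf_counter() - t0, 3), **counts}
        )

    def write(self, path):
        lines = [json.dumps(r, sort_keys=True) for r in self.records]
        Path(path).write_text("\n".join(lines) + "\n")


def _expression_profiles(collapsed: CtMatrix, fraction: str) -> pd.DataFrame:
    """Entity x cell-type log2 expression profiles from a collapsed CT frame
    (expression = -CT, relative scale; monotone in abundance)."""
    cols = {
        s.cell_type: -collapsed.values[s.sample_id]
        for s in collapsed.samples
        if s.fraction == fraction
    }
    return pd.DataFrame(cols)


def run_pipeline(cfg: PipelineConfig, stages=ALL_STAGES) -> dict:
    cfg.validate()
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log()
    # config echo excludes filesystem locations so that identical analyses
    # produce byte-identical summaries regardless of where they ran
    summary: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
            if k not in ("input_dir", "output_dir")
        },
        "counts": {},
    }
    counts = summary["counts"]
    test, ref = cfg.comparison

    # ------------------------------------------------------------ ingest
    t0 = time.perf_counter()
    classes_path = indir / "assay_classes.tsv"
    assay_class = {}
    if classes_path.exists():
        cdf = pd.read_csv(classes_path, sep="\t")
        assay_class = dict(zip(cdf["assay"], cdf["assay_class"]))
    whole = read_ct_table(
        indir / "ct_whole.tsv", indir / "samples_whole.tsv", assay_class
    )
    whole_c = collapse_replicates(whole).subset_fraction("whole")
    counts["assays"] = len(whole.assays)
    counts["whole_samples"] = len(whole.samples)
    log.stage("ingest", t0, assays=len(whole.assays))

    mirna_calls = None
    if "mirna_de" in stages:
        t0 = time.perf_counter()
        detectable = detectability_filter(whole_c, cfg.ct_threshold)
        mirna_calls = de_mod.mirna_differential(
            whole_c, min_fold=cfg.min_fold, ct_threshold=cfg.ct_threshold
        )
        de_set = de_mod.de_entities(mirna_calls)
        counts["detectable_mirnas"] = len(detectable)
        counts["de_mirnas"] = len(de_set)
        pd.DataFrame(
            [
                {
                    "entity": c.entity,
                    "comparison": f"{c.comparison[0]}_vs_{c.comparison[1]}",
                    "fold": c.fold,
                    "direction": c.direction,
                    "passes": c.passes,
                }
                for c in mirna_calls
            ]
        ).to_csv(outdir / "mirna_de.tsv", sep="\t", index=False)
        log.stage("mirna_de", t0, detectable=len(detectable), de=len(de_set))

    if "cluster" in stages and mirna_calls is not None:
        t0 = time.perf_counter()
        clust = de_mod.cluster_high_expressers(
            whole_c, mirna_calls, ct_high=cfg.ct_high
        )
        counts["clustered_mirnas"] = len(clust.selected)
        pd.DataFrame({"leaf_order": clust.entities}).to_csv(
            outdir / "cluster_leaves.tsv", sep="\t", index=False
        )
        if not clust.empty:
            pd.DataFrame(
                clust.linkage, columns=["left", "right", "height", "size"]
            ).to_csv(outdir / "cluster_linkage.tsv", sep="\t", index=False)
        log.stage("cluster", t0, selected=len(clust.selected))

    if "cross_species" in stages and cfg.human_folds and mirna_calls is not None:
        t0 = time.perf_counter()
        hf = pd.read_csv(indir / cfg.human_folds, sep="\t")
        fold_b = dict(zip(hf.iloc[:, 0], hf.iloc[:, 1]))
        fold_a = {
            c.entity: math.log2(c.fold)
            for c in mirna_calls
            if tuple(c.comparison) == (test, ref)
        }
        conc = de_mod.cross_species_concordance(fold_a, fold_b)
        summary["cross_species"] = {
            "rho": conc.rho, "p": conc.p, "n_common": conc.n_common,
            "r_squared": conc.r_squared, "table": conc.table,
        }
        log.stage("cross_species", t0, n_common=conc.n_common)

    gene_de = None
    if "mrna_de" in stages:
        t0 = time.perf_counter()
        expr = read_expression_matrix(
            indir / "expression.tsv", indir / "samples_expression.tsv"
        )
        groups = {
            s.sample_id: s.cell_type
            for s in expr.samples
            if s.cell_type in (test, ref)
        }
        gene_de = de_mod.moderated_t_de(
            expr, groups, comparison=(test, ref),
            min_fold=cfg.min_fold, alpha=cfg.alpha,
        )
        counts["significant_genes"] = len(gene_de.significant_genes())
        gene_de.as_frame().to_csv(outdir / "mrna_de.tsv", sep="\t")
        log.stage("mrna_de", t0, significant=counts["significant_genes"])

    if "targets" in stages and gene_de is not None and mirna_calls is not None:
        t0 = time.perf_counter()
        utrs = read_fasta(indir / "utrs.fasta")
        mirnas = {
            name: targets_mod.MatureMiRNA(name, seq)
            for name, seq in read_fasta(indir / "mirnas.fasta").items()
        }
        pairs = targets_mod.anticorrelated_pairs(
            mirna_calls, gene_de, utrs, mirnas, comparison=(test, ref)
        )
        counts["target_pairs"] = len(pairs)
        targets_mod.pairs_frame(pairs).to_csv(
            outdir / "target_pairs.tsv", sep="\t", index=False
        )
        # stage-specific pairing over the whole-cell profiles
        mirna_prof = _expression_profiles(whole_c, "whole")
        expr2 = read_expression_matrix(
            indir / "expression.tsv", indir / "samples_expression.tsv"
        )
        gene_prof = pd.DataFrame(
            {
                ct: expr2.values[
                    [s.sample_id for s in expr2.samples if s.cell_type == ct]
                ].mean(axis=1)
                for ct in dict.fromkeys(s.cell_type for s in expr2.samples)
            }
        )
        stage_counts = {}
        ss_rows = []
        for stage_label in mirna_prof.columns:
            ss = targets_mod.stage_specific_pairs(
                mirna_prof, gene_prof, pairs, stage_label
            )
            stage_counts[stage_label] = len(ss)
            ss_rows.extend(ss)
        counts["stage_specific_pairs"] = stage_counts
        targets_mod.pairs_frame(ss_rows).to_csv(
            outdir / "stage_specific_pairs.tsv", sep="\t", index=False
        )
        log.stage("targets", t0, pairs=len(pairs))

    fp = None
    enrichment = None
    if "fractions" in stages or "priscan" in stages:
        t0 = time.perf_counter()
        fr_ct = read_ct_table(
            indir / "ct_fractions.tsv", indir / "samples_fractions.tsv", assay_class
        )
        fp = frac_mod.FractionPairMatrix(fr_ct)
        qc = frac_mod.marker_qc(fp)
        qc_pass = all(q.passed for q in qc)
        counts["qc_pass"] = qc_pass
        pd.DataFrame(
            [
                {
                    "cell_type": q.cell_type,
                    **{f"nuc:{k}": v for k, v in q.nuclear_marker_folds.items()},
                    **{f"cyt:{k}": v for k, v in q.cytoplasmic_marker_folds.items()},
                    "passed": q.passed,
                }
                for q in qc
            ]
        ).to_csv(outdir / "fraction_qc.tsv", sep="\t", index=False)
        if not qc_pass and cfg.strict:
            log.write(outdir / "run.log")
            raise QCError("marker QC failed and --strict is set")

        fits = [
            frac_mod.contamination_regression(fp, ct, cfg.ct_threshold)
            for ct in fp.cell_types
        ]
        pd.DataFrame([f.__dict__ for f in fits]).to_csv(
            outdir / "contamination.tsv", sep="\t", index=False
        )
        summary["contamination"] = {
            f.cell_type: {
                "slope": f.slope, "intercept": f.intercept,
                "r_squared": f.r_squared,
                "implied_fraction": f.implied_contamination_fraction,
            }
            for f in fits
        }
        enrichment = frac_mod.call_nuclear_enriched(
            fp,
            controls=cfg.controls,
            ratio_threshold=cfg.ratio_threshold,
            ct_threshold=cfg.ct_threshold,
            alpha=cfg.alpha,
        )
        frac_mod.enrichment_frame(enrichment).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
        enriched_mirnas = sorted(
            {r.assay for r in enrichment if r.call == "nuclear_enriched"}
        )
        counts["nuclear_enriched_mirnas"] = len(enriched_mirnas)
        summary["nuclear_enriched"] = enriched_mirnas
        log.stage("fractions", t0, qc_pass=qc_pass, enriched=len(enriched_mirnas))

    if "priscan" in stages and enrichment is not None:
        t0 = time.perf_counter()
        pris = read_fasta(indir / "pri_mirnas.fasta")
        mirna_seqs = read_fasta(indir / "mirnas.fasta")
        # rank enriched assays by their strongest N:C ratio and screen the top
        best_ratio = {
            r.assay: max(
                (x.nc_ratio for x in enrichment
                 if x.assay == r.assay and not math.isnan(x.nc_ratio)),
                default=0.0,
            )
            for r in enrichment
            if r.call == "nuclear_enriched"
        }
        enriched_mirnas = sorted(
            best_ratio, key=lambda a: (-best_ratio[a], a)
        )[: cfg.max_pri_queries]
        counts["pri_queries"] = len(enriched_mirnas)
        hits = []
        for mi, name in enumerate(enriched_mirnas):
            if name not in mirna_seqs:
                continue
            m = targets_mod.MatureMiRNA(name, mirna_seqs[name])
            for ti, (tname, tseq) in enumerate(sorted(pris.items())):
                cal = duplex_mod.calibrate_p(
                    m, tseq,
                    n_shuffles=cfg.n_shuffles,
                    seed=int((cfg.seed * 1009 + mi * 101 + ti) % (2**31 - 1)),
                    window=cfg.window, step=cfg.step, transcript_name=tname,
                )
                hits.append(cal.hit)
        nuc_prof = _expression_profiles(collapse_replicates(fp.source), "nuclear")
        mat_prof = _expression_profiles(collapse_replicates(fp.source), "cytoplasmic")
        cand = duplex_mod.nuclear_target_candidates(
            hits, nuc_prof, mat_prof, comparison=(test, ref),
            mfe_cut=cfg.mfe_cut, p_cut=cfg.p_cut,
        )
        counts["pri_hits_scanned"] = len(hits)
        counts["pri_candidates"] = len(cand)
        pd.DataFrame(
            [
                {
                    "mirna": h.mirna, "transcript": h.transcript,
                    "t_start": h.t_start, "t_end": h.t_end, "mfe": h.mfe,
                    "p_empirical": h.p_empirical, "p_gumbel": h.p_gumbel,
                }
                for h in hits
            ]
        ).to_csv(outdir / "pri_hits.tsv", sep="\t", index=False)
        cand.to_csv(outdir / "pri_candidates.tsv", sep="\t", index=False)
        log.stage("priscan", t0, hits=len(hits), candidates=len(cand))

    log.write(outdir / "run.log")
    write_json(summary, outdir / "summary.json")
    return summary


def render_report(cfg: PipelineConfig) -> list[str]:
    """Cluster heatmap and nuclear-vs-cytoplasmic CT scatter figures (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    indir = Path(cfg.input_dir)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    classes_path = indir / "assay_classes.tsv"
    assay_class = {}
    if classes_path.exists():
        cdf = pd.read_csv(classes_path, sep="\t")
        assay_class = dict(zip(cdf["assay"], cdf["assay_class"]))

    whole = read_ct_table(
        indir / "ct_whole.tsv", indir / "samples_whole.tsv", assay_class
    )
    whole_c = collapse_replicates(whole).subset_fraction("whole")
    calls = de_mod.mirna_differential(whole_c, cfg.min_fold, cfg.ct_threshold)
    clust = de_mod.cluster_high_expressers(whole_c, calls, ct_high=cfg.ct_high)
    if not clust.empty:
        mat = -whole_c.values.loc[clust.entities]
        mat = mat.sub(mat.mean(axis=1), axis=0)
        fig, ax = plt.subplots(figsize=(6, max(3, 0.2 * len(clust.entities))))
        im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="YlOrRd")
        ax.set_xticks(range(mat.shape[1]))
        ax.set_xticklabels([s.cell_type for s in whole_c.samples], rotation=45)
        ax.set_yticks(range(len(clust.entities)))
        ax.set_yticklabels(clust.entities, fontsize=5)
        fig.colorbar(im, ax=ax, label="relative log2 expression")
        fig.tight_layout()
        path = outdir / "cluster_heatmap.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(str(path))

    fr_path = indir / "ct_fractions.tsv"
    if fr_path.exists():
        fr_ct = read_ct_table(fr_path, indir / "samples_fractions.tsv", assay_class)
        fp = frac_mod.FractionPairMatrix(fr_ct)
        n = len(fp.cell_types)
        fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
        for ax, cell_type in zip(axes[0], fp.cell_types):
            x = fp.ct_cyto[cell_type]
            y = fp.ct_nuc[cell_type]
            ax.scatter(x, y, s=8, alpha=0.6)
            lim = [15, 40]
            ax.plot(lim, lim, "k--", lw=0.8)
            ax.set_xlabel("cytoplasmic CT")
            ax.set_ylabel("nuclear CT")
            ax.set_title(cell_type)
        fig.tight_layout()
        path = outdir / "fraction_scatter.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(str(path))
    return written
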