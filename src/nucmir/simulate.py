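"""Synthetic TLDA / microarray / sequence data with planted ground truth.

Every input the pipeline consumes can be generated here with known truth, so
each stage is testable without any external download:

* a whole-cell CT matrix across the four differentiation stages with planted
  fold changes,
* paired nuclear/cytoplasmic CT matrices built from a cytoplasmic-contamination
  mixing model (a null miRNA's nuclear signal is ``contamination_fraction``
  times its cytoplasmic abundance; planted nuclear-enriched miRNAs instead get
  ``true_nc_ratio`` times), plus marker RNAs planted at purity folds inside the
  conventionally observed ranges,
* a replicated log2 mRNA expression matrix whose planted target genes move
  opposite to their miRNA between promyelocytes and granulocytes, with 3'UTRs
  carrying one planted seed site per true pair (accidental seed matches of any
  panel miRNA are scrubbed by point mutation and the scrub count recorded),
* pri-miRNA transcripts carrying planted (near-)perfect reverse complements of
  nuclear-enriched miRNAs.

CT noise is Gaussian on the cycle scale (multiplicative lognormal on
abundance), the standard qPCR error behaviour. All randomness derives from
``SimulationConfig.seed`` through independent named streams, so any output is
reproducible from the config alone.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ctmatrix import STAGES, CtMatrix, ExpressionMatrix, SampleMeta
from .errors import ConfigurationError, ValidationError
from .fractionation import FractionPairMatrix
from .io import (
    write_ct_table,
    write_expression_matrix,
    write_fasta,
    write_json,
    write_sample_sheet,
)
from .targets import MatureMiRNA, reverse_complement, scan_utr

_RNA_BASES = np.array(list("ACGU"))

NUCLEAR_MARKER = "SnoRNA-sim"
CYTO_MARKER = "Y1-sim"


@dataclass
class SimulationConfig:
    n_mirnas: int = 200
    n_genes: int = 500
    stages: tuple = STAGES
    n_replicates: int = 3
    sigma_ct: float = 0.25
    contamination_fraction: float = 0.1
    n_de_mirnas: int = 30
    de_fold: float = 4.0
    n_nuclear_enriched: int = 6
    true_nc_ratio: float = 2.0
    n_true_target_pairs: int = 30
    utr_length_range: tuple = (200, 800)
    detection_limit_ct: float = 35.0
    seed: int = 0
    # mRNA arm
    gene_effect_log2: float = 1.5
    gene_noise_sd: float = 0.25
    # pri-miRNA arm
    pri_length_range: tuple = (500, 2000)
    n_pri_transcripts: int = 12
    pri_plant_mismatches: int = 0
    # markers (inside the conventional 8-56x nuclear / 4-9x cytoplasmic ranges)
    nuclear_marker_fold: float = 16.0
    cyto_marker_fold: float = 6.0
    mirna_length: int = 22

    def __post_init__(self):
        if self.n_de_mirnas + self.n_nuclear_enriched > self.n_mirnas:
            raise ConfigurationError("more planted assays than total miRNAs")
        if self.n_true_target_pairs > self.n_genes:
            raise ConfigurationError("more true target pairs than genes")
        if self.n_true_target_pairs > 0 and self.n_de_mirnas == 0:
            raise ConfigurationError("target pairs require planted DE miRNAs")
        if self.sigma_ct < 0:
            raise ConfigurationError("sigma_ct must be >= 0")
        if not (0.0 < self.contamination_fraction < 1.0):
            raise ConfigurationError("contamination_fraction must be in (0, 1)")
        if len(self.stages) < 2:
            raise ConfigurationError("need at least two stages")
        if self.utr_length_range[0] < 20:
            raise ConfigurationError("UTRs must be long enough to hold a seed site")


@dataclass
class GroundTruth:
    """Everything planted, serialisable alongside the emitted files."""

    de_mirnas: dict = field(default_factory=dict)  # name -> {stage: true log2 fold}
    nuclear_enriched: dict = field(default_factory=dict)  # name -> true N:C ratio
    markers: dict = field(default_factory=dict)  # name -> class
    contamination_fraction: float = float("nan")
    target_pairs: list = field(default_factory=list)  # {mirna, gene, site_type, ...}
    gene_effects: dict = field(default_factory=dict)  # gene -> log2 fold (test vs ref)
    comparison: tuple = ()
    scrubbed_sites: int = 0
    unresolved_collisions: int = 0
    pri_sites: list = field(default_factory=list)  # {mirna, transcript, start, end}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["comparison"] = list(self.comparison)
        return d


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(_RNA_BASES[rng.integers(0, 4, size=length)])


def simulate_mirnas(cfg: SimulationConfig) -> list[MatureMiRNA]:
    """The miRNA panel: random mature sequences with stable names."""
    rng = _rng(cfg, 1)
    width = len(str(cfg.n_mirnas))
    return [
        MatureMiRNA(f"mir-{i + 1:0{width}d}", _random_rna(rng, cfg.mirna_length))
        for i in range(cfg.n_mirnas)
    ]


def _ref_stage(stages) -> str:
    """Reference stage for the planted comparison: promyelocytes when the
    canonical four stages are used (the conventional pairing with
    granulocytes), else the first stage."""
    return stages[1] if len(stages) >= 3 else stages[0]


def _plan(cfg: SimulationConfig):
    """Deterministic experimental design shared by all simulators.

    Returns (names, baseline_ct, de_lfc, enriched) where ``de_lfc`` maps DE
    miRNA -> true log2 fold in the last stage (granulocyte) relative to all
    earlier stages (alternating up/down), and ``enriched`` is the set of
    planted nuclear-enriched assays (disjoint from the DE set).
    """
    rng = _rng(cfg, 2)
    width = len(str(cfg.n_mirnas))
    names = [f"mir-{i + 1:0{width}d}" for i in range(cfg.n_mirnas)]
    baseline = rng.uniform(20.0, 29.0, size=cfg.n_mirnas)
    order = rng.permutation(cfg.n_mirnas)
    de_idx = order[: cfg.n_de_mirnas]
    enr_idx = order[cfg.n_de_mirnas : cfg.n_de_mirnas + cfg.n_nuclear_enriched]
    lfc = math.log2(cfg.de_fold)
    de_lfc = {
        names[i]: (lfc if k % 2 == 0 else -lfc) for k, i in enumerate(de_idx)
    }
    enriched = {names[i] for i in enr_idx}
    return names, dict(zip(names, baseline)), de_lfc, enriched


def _noisy(rng, true_ct, sigma, limit):
    v = true_ct + rng.normal(0.0, sigma) if sigma > 0 else true_ct
    v = min(max(v, 0.0), 40.0)
    return float("nan") if v > limit else v


def simulate_ct_experiment(
    cfg: SimulationConfig,
) -> tuple[CtMatrix, FractionPairMatrix, GroundTruth]:
    """Whole-cell and fractionated CT matrices with planted truth.

    The DE shift is applied in the final stage (granulocytes): an "up" miRNA
    has its granulocyte CT lowered by log2(de_fold) cycles. Nuclear abundance
    is ``true_nc_ratio x`` cytoplasmic for planted enriched assays and
    ``contamination_fraction x`` cytoplasmic otherwise, i.e.
    ``ct_nuc = ct_cyto - log2(ratio)``. Noisy CTs beyond the detection limit
    are emitted as UNDETERMINED.
    """
    names, baseline, de_lfc, enriched = _plan(cfg)
    rng = _rng(cfg, 3)
    stages = list(cfg.stages)
    peak_stage = stages[-1]
    truth = GroundTruth(
        de_mirnas={
            n: {s: (l if s == peak_stage else 0.0) for s in stages}
            for n, l in de_lfc.items()
        },
        nuclear_enriched={n: cfg.true_nc_ratio for n in sorted(enriched)},
        markers={NUCLEAR_MARKER: "nuclear_marker", CYTO_MARKER: "cytoplasmic_marker"},
        contamination_fraction=cfg.contamination_fraction,
        comparison=(peak_stage, _ref_stage(stages)),
    )

    def true_ct_whole(name, stage):
        ct = baseline[name]
        if name in de_lfc and stage == peak_stage:
            ct -= de_lfc[name]  # up => more template => lower CT
        return ct

    marker_whole = {NUCLEAR_MARKER: 22.0, CYTO_MARKER: 20.0}
    all_assays = names + [NUCLEAR_MARKER, CYTO_MARKER]
    assay_class = dict(truth.markers)

    # whole-cell matrix
    cols, metas = {}, []
    for stage in stages:
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"{stage}_whole_r{rep}"
            metas.append(SampleMeta(sid, stage, "whole", rep))
            col = [
                _noisy(rng, true_ct_whole(n, stage), cfg.sigma_ct,
                       cfg.detection_limit_ct)
                for n in names
            ]
            col += [
                _noisy(rng, marker_whole[m], cfg.sigma_ct, cfg.detection_limit_ct)
                for m in (NUCLEAR_MARKER, CYTO_MARKER)
            ]
            cols[sid] = col
    whole = CtMatrix(pd.DataFrame(cols, index=all_assays), metas, assay_class)

    # fractionated matrix: cytoplasmic tracks whole-cell truth; nuclear is the
    # mixing model. Markers get their planted purity folds.
    nuc_shift = {
        n: -math.log2(cfg.true_nc_ratio if n in enriched
                      else cfg.contamination_fraction)
        for n in names
    }
    marker_nuc = {
        NUCLEAR_MARKER: 22.0,
        CYTO_MARKER: 20.0 + math.log2(cfg.cyto_marker_fold),
    }
    marker_cyto = {
        NUCLEAR_MARKER: 22.0 + math.log2(cfg.nuclear_marker_fold),
        CYTO_MARKER: 20.0,
    }
    cols, metas = {}, []
    for stage in stages:
        for fraction in ("nuclear", "cytoplasmic"):
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{stage}_{fraction}_r{rep}"
                metas.append(SampleMeta(sid, stage, fraction, rep))
                col = []
                for n in names:
                    ct = true_ct_whole(n, stage)
                    if fraction == "nuclear":
                        ct += nuc_shift[n]
                    col.append(
                        _noisy(rng, ct, cfg.sigma_ct, cfg.detection_limit_ct)
                    )
                source = marker_nuc if fraction == "nuclear" else marker_cyto
                col += [
                    _noisy(rng, source[m], cfg.sigma_ct, cfg.detection_limit_ct)
                    for m in (NUCLEAR_MARKER, CYTO_MARKER)
                ]
                cols[sid] = col
    fractions = CtMatrix(pd.DataFrame(cols, index=all_assays), metas, assay_class)
    return whole, FractionPairMatrix(fractions), truth


# ---------------------------------------------------------------------------
# transcriptome (mRNA arm + UTRs)
# ---------------------------------------------------------------------------


def _site_for(m: MatureMiRNA, site_type: str) -> str:
    if site_type == "8mer":
        return reverse_complement(m.sequence[1:8]) + "A"
    if site_type == "7mer-m8":
        return reverse_complement(m.sequence[1:8])
    if site_type == "7mer-A1":
        return reverse_complement(m.sequence[1:7]) + "A"
    raise ValidationError(f"unknown site type {site_type!r}")


def _scrub_accidental_sites(
    utrs: dict[str, str],
    mirnas: list[MatureMiRNA],
    planted: dict[tuple[str, str], tuple[int, int]],
    rng: np.random.Generator,
    max_passes: int = 20,
) -> tuple[int, int]:
    """Point-mutate away seed matches that were not planted.

    ``planted`` maps (miRNA name, gene) -> (start, end) of the planted site.
    Returns (n_scrubbed, n_unresolved); an accidental site lying entirely
    inside a planted span of a *different* pair cannot be broken without
    destroying the plant and is left in place (counted unresolved).
    """
    protected: dict[str, list[tuple[int, int]]] = {}
    for (mname, gene), (s, e) in planted.items():
        protected.setdefault(gene, []).append((s, e))
    n_scrubbed = unresolved = 0
    for _ in range(max_passes):
        dirty = False
        for m in mirnas:
            for gene, utr in utrs.items():
                for site in scan_utr(utr, m):
                    span = planted.get((m.name, gene))
                    if span is not None and site.utr_start >= span[0] and site.utr_end <= span[1]:
                        continue  # the planted site itself (8mer also spans its 7mers)
                    # mutate a base inside the site but outside protected spans
                    cand = [
                        i
                        for i in range(site.utr_start, site.utr_end)
                        if not any(s <= i < e for s, e in protected.get(gene, []))
                    ]
                    if not cand:
                        unresolved += 1
                        continue
                    i = cand[len(cand) // 2]
                    old = utrs[gene][i]
                    new = str(rng.choice([b for b in "ACGU" if b != old]))
                    utrs[gene] = utrs[gene][:i] + new + utrs[gene][i + 1 :]
                    n_scrubbed += 1
                    dirty = True
        if not dirty:
            return n_scrubbed, 0
    return n_scrubbed, unresolved


def simulate_transcriptome(
    cfg: SimulationConfig, mirnas: list[MatureMiRNA] | None = None
) -> tuple[ExpressionMatrix, dict[str, str], GroundTruth]:
    """Replicated log2 expression matrix + 3'UTRs with planted target pairs.

    Each true pair links a planted-DE miRNA (round-robin) to a distinct gene:
    the gene's expression moves ``gene_effect_log2`` in the direction opposite
    to the miRNA between the two compared stages, and its UTR receives one
    seed site of a type drawn uniformly from {8mer, 7mer-m8, 7mer-A1} at a
    recorded position. Non-target genes get independent noise and carry no
    seed match of any panel miRNA (accidental matches scrubbed, counts
    recorded).
    """
    if mirnas is None:
        mirnas = simulate_mirnas(cfg)
    by_name = {m.name: m for m in mirnas}
    names, _, de_lfc, _ = _plan(cfg)
    stages = list(cfg.stages)
    test, ref = stages[-1], _ref_stage(stages)
    rng = _rng(cfg, 4)

    width = len(str(cfg.n_genes))
    genes = [f"gene-{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    lengths = rng.integers(
        cfg.utr_length_range[0], cfg.utr_length_range[1] + 1, size=cfg.n_genes
    )
    utrs = {g: _random_rna(rng, int(L)) for g, L in zip(genes, lengths)}

    de_names = sorted(de_lfc)
    order = rng.permutation(cfg.n_genes)
    target_genes = [genes[i] for i in order[: cfg.n_true_target_pairs]]
    truth = GroundTruth(comparison=(test, ref))
    planted: dict[tuple[str, str], tuple[int, int]] = {}
    gene_lfc = {g: 0.0 for g in genes}
    for k, gene in enumerate(target_genes):
        mname = de_names[k % len(de_names)]
        m = by_name[mname]
        site_type = ("8mer", "7mer-m8", "7mer-A1")[int(rng.integers(0, 3))]
        site = _site_for(m, site_type)
        utr = utrs[gene]
        start = int(rng.integers(0, len(utr) - len(site) + 1))
        utrs[gene] = utr[:start] + site + utr[start + len(site):]
        planted[(mname, gene)] = (start, start + len(site))
        gene_lfc[gene] = -math.copysign(cfg.gene_effect_log2, de_lfc[mname])
        truth.target_pairs.append(
            {
                "mirna": mname,
                "gene": gene,
                "site_type": site_type,
                "start": start,
                "end": start + len(site),
                "mirna_log2_fold": de_lfc[mname],
                "gene_log2_fold": gene_lfc[gene],
            }
        )
    truth.gene_effects = {g: l for g, l in gene_lfc.items() if l != 0.0}
    truth.scrubbed_sites, truth.unresolved_collisions = _scrub_accidental_sites(
        utrs, mirnas, planted, rng
    )

    base = rng.uniform(6.0, 12.0, size=cfg.n_genes)
    cols, metas = {}, []
    for stage in stages:
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"{stage}_mrna_r{rep}"
            metas.append(SampleMeta(sid, stage, "whole", rep))
            shift = np.array(
                [gene_lfc[g] if stage == test else 0.0 for g in genes]
            )
            cols[sid] = base + shift + rng.normal(0.0, cfg.gene_noise_sd, cfg.n_genes)
    expr = ExpressionMatrix(pd.DataFrame(cols, index=genes), metas)
    return expr, utrs, truth


# ---------------------------------------------------------------------------
# pri-miRNA transcripts
# ---------------------------------------------------------------------------


def simulate_pri_targets(
    cfg: SimulationConfig, nuclear_mirnas: list[MatureMiRNA]
) -> tuple[dict[str, str], GroundTruth]:
    """Random pri-miRNA transcripts, some carrying planted binding sites.

    Transcripts are named ``pri-<mature name>`` for panel miRNAs. Each nuclear
    miRNA gets one target transcript with an embedded reverse complement of
    its full sequence (``pri_plant_mismatches`` point mismatches allowed);
    remaining transcripts are unplanted decoys.
    """
    if not nuclear_mirnas:
        raise ConfigurationError("need at least one nuclear miRNA")
    names, _, _, _ = _plan(cfg)
    rng = _rng(cfg, 5)
    n_tr = max(cfg.n_pri_transcripts, len(nuclear_mirnas))
    hosts = [n for n in names if n not in {m.name for m in nuclear_mirnas}][:n_tr]
    truth = GroundTruth()
    pris: dict[str, str] = {}
    for k, host in enumerate(hosts):
        L = int(rng.integers(cfg.pri_length_range[0], cfg.pri_length_range[1] + 1))
        seq = _random_rna(rng, L)
        tname = f"pri-{host}"
        if k < len(nuclear_mirnas):
            m = nuclear_mirnas[k]
            site = reverse_complement(m.sequence)
            if cfg.pri_plant_mismatches > 0:
                pos = rng.choice(
                    len(site), size=cfg.pri_plant_mismatches, replace=False
                )
                site = list(site)
                for i in pos:
                    site[i] = str(rng.choice([b for b in "ACGU" if b != site[i]]))
                site = "".join(site)
            start = int(rng.integers(0, L - len(site) + 1))
            seq = seq[:start] + site + seq[start + len(site):]
            truth.pri_sites.append(
                {
                    "mirna": m.name,
                    "transcript": tname,
                    "start": start,
                    "end": start + len(site),
                    "mismatches": cfg.pri_plant_mismatches,
                }
            )
        pris[tname] = seq
    return pris, truth


# ---------------------------------------------------------------------------
# run directory emission
# ---------------------------------------------------------------------------


def emit_run(cfg: SimulationConfig, outdir) -> Path:
    """Generate every pipeline input under one directory, truth included."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mirnas = simulate_mirnas(cfg)
    whole, fractions, ct_truth = simulate_ct_experiment(cfg)
    expr, utrs, tx_truth = simulate_transcriptome(cfg, mirnas)
    nuclear = [m for m in mirnas if m.name in ct_truth.nuclear_enriched]
    pris, pri_truth = simulate_pri_targets(cfg, nuclear)

    write_ct_table(whole, out / "ct_whole.tsv")
    write_sample_sheet(whole.samples, out / "samples_whole.tsv")
    write_ct_table(fractions.source, out / "ct_fractions.tsv")
    write_sample_sheet(fractions.source.samples, out / "samples_fractions.tsv")
    pd.DataFrame(
        [(a, c) for a, c in sorted(ct_truth.markers.items())],
        columns=["assay", "assay_class"],
    ).to_csv(out / "assay_classes.tsv", sep="\t", index=False)
    write_expression_matrix(expr, out / "expression.tsv")
    write_sample_sheet(expr.samples, out / "samples_expression.tsv")
    write_fasta({m.name: m.sequence for m in mirnas}, out / "mirnas.fasta")
    write_fasta(utrs, out / "utrs.fasta")
    write_fasta(pris, out / "pri_mirnas.fasta")

    truth = ct_truth.to_dict()
    tx = tx_truth.to_dict()
    for key in ("target_pairs", "gene_effects", "scrubbed_sites",
                "unresolved_collisions"):
        truth[key] = tx[key]
    truth["pri_sites"] = pri_truth.to_dict()["pri_sites"]
    write_json(truth, out / "ground_truth.json")
    write_json(asdict(cfg) | {"stages": list(cfg.stages)}, out / "config.json")
    return out
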