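"""Nuclear/cytoplasmic fractionation analysis.

Fractions are prepared on a cell-equivalent basis: equal input volumes from the
same lysate split, so nuclear and cytoplasmic CT values compare directly with
no housekeeping normalisation. The nuclear:cytoplasmic (N:C) expression ratio
of an assay is then simply ``2**(ct_cyto - ct_nuc)``.

Because fractionation is imperfect, the nuclear pool carries a low-level
carry-over of cytoplasmic RNA. If a fraction ``alpha`` of cytoplasmic material
contaminates the nucleus and a miRNA has no true nuclear pool, its nuclear CT
is ``ct_cyto + log2(1/alpha)``: regressing nuclear CT on cytoplasmic CT across
assays therefore gives slope ~1 and an intercept whose antilog is the
contamination fraction. Genuinely nuclear miRNAs stand out from that
regression and from cytoplasmic-control miRNAs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ctmatrix import CtMatrix, collapse_replicates
from .errors import ConfigurationError, InsufficientDataError, QCError

CALLS = ("nuclear_enriched", "candidate", "cytoplasmic", "not_detectable")


class FractionPairMatrix:
    """Paired nuclear/cytoplasmic CT values per assay and cell type.

    Holds both the replicate-collapsed CT frames (assay x cell type, used for
    ratio ranking and regression) and the per-replicate frames (used for the
    enrichment t-tests).
    """

    def __init__(self, ct: CtMatrix):
        fractions = {s.fraction for s in ct.samples}
        if not {"nuclear", "cytoplasmic"} <= fractions:
            raise ConfigurationError(
                "FractionPairMatrix needs both nuclear and cytoplasmic samples"
            )
        ct = CtMatrix(
            ct.values[[s.sample_id for s in ct.samples if s.fraction != "whole"]],
            [s for s in ct.samples if s.fraction != "whole"],
            ct.assay_class,
        )
        self.source = ct
        collapsed = collapse_replicates(ct)
        cell_types = collapsed.cell_types()
        for cell_type in cell_types:
            have = {
                s.fraction for s in collapsed.samples if s.cell_type == cell_type
            }
            if not {"nuclear", "cytoplasmic"} <= have:
                raise ConfigurationError(
                    f"cell type {cell_type!r} lacks a nuclear or cytoplasmic column"
                )
        self.cell_types = cell_types
        self.assays = ct.assays
        self.assay_class = ct.assay_class
        self.ct_nuc = pd.DataFrame(
            {c: collapsed.values[f"{c}:nuclear"] for c in cell_types}
        )
        self.ct_cyto = pd.DataFrame(
            {c: collapsed.values[f"{c}:cytoplasmic"] for c in cell_types}
        )
        # per-replicate frames keyed by (cell_type, fraction), columns = replicate
        self._reps: dict[tuple[str, str], pd.DataFrame] = {}
        for cell_type in cell_types:
            for fraction in ("nuclear", "cytoplasmic"):
                cols = {
                    s.replicate: ct.values[s.sample_id]
                    for s in ct.samples
                    if s.cell_type == cell_type and s.fraction == fraction
                }
                self._reps[(cell_type, fraction)] = pd.DataFrame(cols).sort_index(
                    axis=1
                )

    def class_of(self, assay: str) -> str:
        return self.assay_class.get(assay, "miRNA")

    def mirna_assays(self) -> list[str]:
        return [a for a in self.assays if self.class_of(a) == "miRNA"]

    def replicate_log2_ratios(self, assay: str, cell_type: str) -> np.ndarray:
        """Per-replicate log2 N:C ratios (ct_cyto - ct_nuc), replicate-paired."""
        nuc = self._reps[(cell_type, "nuclear")].loc[assay]
        cyt = self._reps[(cell_type, "cytoplasmic")].loc[assay]
        common = nuc.index.intersection(cyt.index)
        vals = (cyt[common] - nuc[common]).to_numpy(dtype=float)
        return vals[np.isfinite(vals)]


def nc_ratio(ct_nuc: float, ct_cyto: float) -> float:
    """Nuclear:cytoplasmic expression ratio ``2**(ct_cyto - ct_nuc)``.

    Returns NaN (not detectable) if either CT is undetermined.
    """
    if ct_nuc is None or ct_cyto is None or math.isnan(ct_nuc) or math.isnan(ct_cyto):
        return float("nan")
    return float(2.0 ** (ct_cyto - ct_nuc))


@dataclass
class MarkerQC:
    cell_type: str
    nuclear_marker_folds: dict[str, float]
    cytoplasmic_marker_folds: dict[str, float]
    passed: bool


def marker_qc(
    fp: FractionPairMatrix,
    min_nuclear_fold: float = 4.0,
    min_cyto_fold: float = 2.0,
) -> list[MarkerQC]:
    """Fraction-purity QC from marker RNAs.

    A nuclear marker (e.g. SnoRNA) must be enriched in the nuclear pool
    (fold = 2**(ct_cyto - ct_nuc) >= min_nuclear_fold); a cytoplasmic marker
    (e.g. Y1 RNA) must be enriched in the cytoplasm
    (fold = 2**(ct_nuc - ct_cyto) >= min_cyto_fold). QC passes for a cell type
    iff every marker fold meets its threshold.
    """
    markers = {
        "nuclear_marker": [a for a in fp.assays if fp.class_of(a) == "nuclear_marker"],
        "cytoplasmic_marker": [
            a for a in fp.assays if fp.class_of(a) == "cytoplasmic_marker"
        ],
    }
    for cls, names in markers.items():
        if not names:
            raise QCError(f"no {cls} assay present; cannot QC fractions")
    out = []
    for cell_type in fp.cell_types:
        nuc_folds = {
            a: nc_ratio(fp.ct_nuc.at[a, cell_type], fp.ct_cyto.at[a, cell_type])
            for a in markers["nuclear_marker"]
        }
        cyt_folds = {
            a: nc_ratio(fp.ct_cyto.at[a, cell_type], fp.ct_nuc.at[a, cell_type])
            for a in markers["cytoplasmic_marker"]
        }
        ok = all(f >= min_nuclear_fold for f in nuc_folds.values()) and all(
            f >= min_cyto_fold for f in cyt_folds.values()
        )
        out.append(MarkerQC(cell_type, nuc_folds, cyt_folds, bool(ok)))
    return out


@dataclass
class ContaminationFit:
    cell_type: str
    slope: float
    intercept: float
    r_squared: float
    implied_contamination_fraction: float
    n: int


def contamination_regression(
    fp: FractionPairMatrix, cell_type: str, detect_threshold: float = 30.0
) -> ContaminationFit:
    """OLS of nuclear CT on cytoplasmic CT over detectable non-marker assays.

    Under pure carry-over contamination the fit has slope ~1 and intercept
    log2(1/alpha); the implied contamination fraction 2**(-intercept) is
    reported (meaningful when slope is close to 1).
    """
    if cell_type not in fp.cell_types:
        raise ConfigurationError(f"unknown cell type {cell_type!r}")
    assays = fp.mirna_assays()
    x = fp.ct_cyto.loc[assays, cell_type].to_numpy(dtype=float)
    y = fp.ct_nuc.loc[assays, cell_type].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & (x < detect_threshold)
    if keep.sum() < 10:
        raise InsufficientDataError(
            f"{cell_type}: only {int(keep.sum())} detectable assay pairs (<10)"
        )
    fit = stats.linregress(x[keep], y[keep])
    return ContaminationFit(
        cell_type=cell_type,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        implied_contamination_fraction=float(2.0 ** (-fit.intercept)),
        n=int(keep.sum()),
    )


@dataclass
class EnrichmentResult:
    assay: str
    cell_type: str
    ct_nuc: float
    ct_cyto: float
    nc_ratio: float
    control_baseline: float
    p_value: float
    call: str
    ratio_gt_1: bool = False


def select_controls(
    fp: FractionPairMatrix, n_controls: int = 10, ct_threshold: float = 30.0
) -> list[str]:
    """Default cytoplasmic-control set: the ``n_controls`` detectable non-marker
    assays with the lowest N:C ratio consistently across cell types (ranked by
    mean collapsed ratio; must be detectable in the cytoplasm of every cell
    type and have a defined ratio everywhere)."""
    ratios = 2.0 ** (fp.ct_cyto - fp.ct_nuc)
    candidates = []
    for a in fp.mirna_assays():
        cyto = fp.ct_cyto.loc[a]
        r = ratios.loc[a]
        if (cyto < ct_threshold).all() and np.isfinite(r.to_numpy()).all():
            candidates.append((float(r.mean()), a))
    if len(candidates) < n_controls:
        raise ConfigurationError(
            f"only {len(candidates)} eligible control assays (<{n_controls})"
        )
    candidates.sort()
    return [a for _, a in candidates[:n_controls]]


def call_nuclear_enriched(
    fp: FractionPairMatrix,
    controls: Sequence[str] | None = None,
    ratio_threshold: float = 0.1,
    ct_threshold: float = 30.0,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Call nuclear-enriched miRNAs per assay per cell type.

    An assay is considered at all only if its nuclear CT is below
    ``ct_threshold`` in at least one cell type (otherwise every cell type gets
    ``not_detectable``). Per cell type:

    * ``cytoplasmic``      — N:C ratio <= ratio_threshold;
    * ``candidate``        — ratio > ratio_threshold;
    * ``nuclear_enriched`` — candidate whose per-replicate log2 ratios exceed
      the pooled control replicate log2 ratios by a one-sided Welch t-test at
      p < alpha.

    Ratios greater than 1 (more nuclear than cytoplasmic) are flagged.
    Controls default to :func:`select_controls`.
    """
    if controls is None:
        controls = select_controls(fp, ct_threshold=ct_threshold)
    controls = list(controls)
    if not controls:
        raise ConfigurationError("control set must not be empty")
    missing = [c for c in controls if c not in fp.assays]
    if missing:
        raise ConfigurationError(f"controls not present in matrix: {missing}")

    control_reps: dict[str, np.ndarray] = {}
    control_baseline: dict[str, float] = {}
    for cell_type in fp.cell_types:
        pooled = [fp.replicate_log2_ratios(c, cell_type) for c in controls]
        control_reps[cell_type] = (
            np.concatenate(pooled) if pooled else np.empty(0)
        )
        lin = [
            nc_ratio(fp.ct_nuc.at[c, cell_type], fp.ct_cyto.at[c, cell_type])
            for c in controls
        ]
        lin = [v for v in lin if not math.isnan(v)]
        control_baseline[cell_type] = float(np.mean(lin)) if lin else float("nan")

    out: list[EnrichmentResult] = []
    for assay in fp.mirna_assays():
        if assay in controls:
            continue
        nuc_row = fp.ct_nuc.loc[assay]
        detectable = bool((nuc_row.dropna() < ct_threshold).any())
        for cell_type in fp.cell_types:
            ct_n = float(fp.ct_nuc.at[assay, cell_type])
            ct_c = float(fp.ct_cyto.at[assay, cell_type])
            ratio = nc_ratio(ct_n, ct_c)
            baseline = control_baseline[cell_type]
            if not detectable or math.isnan(ratio):
                out.append(
                    EnrichmentResult(
                        assay, cell_type, ct_n, ct_c, ratio, baseline,
                        float("nan"), "not_detectable",
                    )
                )
                continue
            if ratio <= ratio_threshold:
                call, p = "cytoplasmic", float("nan")
            else:
                call = "candidate"
                reps = fp.replicate_log2_ratios(assay, cell_type)
                ctrl = control_reps[cell_type]
                if len(reps) >= 2 and len(ctrl) >= 2:
                    p = float(
                        stats.ttest_ind(
                            reps, ctrl, equal_var=False, alternative="greater"
                        ).pvalue
                    )
                    if p < alpha:
                        call = "nuclear_enriched"
                else:
                    p = float("nan")
                    warnings.warn(
                        f"{assay}/{cell_type}: <2 replicate ratios; "
                        "cannot test enrichment"
                    )
            out.append(
                EnrichmentResult(
                    assay, cell_type, ct_n, ct_c, ratio, baseline, p, call,
                    ratio_gt_1=bool(ratio > 1.0),
                )
            )
    return out


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
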