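"""Core data containers and CT-scale conversions.

A TaqMan low-density array (TLDA) experiment yields a matrix of cycle-threshold
(CT) values: one row per assay (miRNA or control RNA), one column per sample.
Lower CT means more template; under 100% amplification efficiency a difference
of one cycle is a two-fold difference in abundance. CT values that never
crossed threshold within the run are reported by the instrument as
"Undetermined"; we keep them as a distinct sentinel (NaN internally) and never
impute them — treating an undetermined well as CT=40 would fabricate signal in
downstream ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedResultError, ValidationError

#: Canonical differentiation stages, in maturation order.
STAGES = ("LSK", "promyelocyte", "myelocyte", "granulocyte")

FRACTIONS = ("whole", "nuclear", "cytoplasmic")

ASSAY_CLASSES = ("miRNA", "nuclear_marker", "cytoplasmic_marker")

#: Sentinel for "Undetermined" CT wells. Distinct from any valid CT in [0, 40].
UNDETERMINED = float("nan")

CT_MIN, CT_MAX = 0.0, 40.0


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one TLDA sample (column)."""

    sample_id: str
    cell_type: str
    fraction: str
    replicate: int = 1

    def __post_init__(self):
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.fraction not in FRACTIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: fraction must be one of {FRACTIONS}, "
                f"got {self.fraction!r}"
            )
        if not self.cell_type:
            raise ValidationError(f"sample {self.sample_id!r}: cell_type must be set")
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )


class CtMatrix:
    """CT values indexed by assay x sample with per-sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        CT values in cycles; rows indexed by assay name, columns by sample_id.
        NaN encodes the UNDETERMINED sentinel.
    samples : sequence of SampleMeta
        One entry per column, in column order.
    assay_class : mapping, optional
        assay name -> one of ``ASSAY_CLASSES``; assays absent from the mapping
        default to ``"miRNA"``.
    replicate_counts : pandas.DataFrame, optional
        Number of replicate wells averaged into each cell (set by
        :func:`collapse_replicates`).
    """

    def __init__(self, values, samples, assay_class=None, replicate_counts=None):
        samples = list(samples)
        if len(samples) != values.shape[1]:
            raise ValidationError(
                f"{len(samples)} sample annotations for {values.shape[1]} columns"
            )
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("sample_id values must be unique within a matrix")
        if list(values.columns) != ids:
            values = values.copy()
            values.columns = ids
        arr = values.to_numpy(dtype=float)
        bad = (~np.isnan(arr)) & ((arr < CT_MIN) | (arr > CT_MAX))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"CT value {arr[i, j]} outside [{CT_MIN}, {CT_MAX}] at assay "
                f"{values.index[i]!r}, sample {values.columns[j]!r}"
            )
        self.values = values.astype(float)
        self.samples = samples
        self.assay_class = dict(assay_class or {})
        for a, c in self.assay_class.items():
            if c not in ASSAY_CLASSES:
                raise ValidationError(f"assay {a!r}: unknown assay class {c!r}")
        self.replicate_counts = replicate_counts

    # -- basic introspection -------------------------------------------------
    @property
    def assays(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def class_of(self, assay: str) -> str:
        return self.assay_class.get(assay, "miRNA")

    def marker_assays(self) -> dict[str, list[str]]:
        out = {"nuclear_marker": [], "cytoplasmic_marker": []}
        for a in self.assays:
            c = self.class_of(a)
            if c in out:
                out[c].append(a)
        return out

    def cell_types(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.cell_type not in seen:
                seen.append(s.cell_type)
        return seen

    def subset_fraction(self, fraction: str) -> "CtMatrix":
        """Matrix restricted to samples of one fraction."""
        keep = [s for s in self.samples if s.fraction == fraction]
        if not keep:
            raise ConfigurationError(f"no samples with fraction {fraction!r}")
        cols = [s.sample_id for s in keep]
        return CtMatrix(self.values[cols], keep, self.assay_class)

    def __repr__(self):
        return (
            f"<CtMatrix {len(self.assays)} assays x {len(self.samples)} samples, "
            f"{int(np.isnan(self.values.to_numpy()).sum())} undetermined>"
        )


class ExpressionMatrix:
    """log2 expression values, genes x samples."""

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleMeta]):
        samples = list(samples)
        if len(samples) != values.shape[1]:
            raise ValidationError(
                f"{len(samples)} sample annotations for {values.shape[1]} columns"
            )
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("sample_id values must be unique within a matrix")
        if list(values.columns) != ids:
            values = values.copy()
            values.columns = ids
        if not np.isfinite(values.to_numpy(dtype=float)).all():
            raise ValidationError("ExpressionMatrix values must be finite")
        self.values = values.astype(float)
        self.samples = samples

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def __repr__(self):
        return f"<ExpressionMatrix {self.values.shape[0]} genes x {self.values.shape[1]} samples>"


@dataclass(frozen=True)
class FoldChange:
    """Linear fold change of one entity between two cell types."""

    entity: str
    group_test: str
    group_ref: str
    fold: float
    log2_fold: float
    detectable: bool = True

    def __post_init__(self):
        if self.fold <= 0:
            raise ValidationError("fold must be positive")
        if not math.isclose(self.fold, 2.0 ** self.log2_fold, rel_tol=1e-9):
            raise ValidationError("fold and log2_fold are inconsistent")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def collapse_replicates(m: CtMatrix) -> CtMatrix:
    """Average replicate wells into one column per (cell_type, fraction).

    The arithmetic mean of CT values is the geometric mean of the linear
    expression values, the conventional qPCR treatment. Undetermined wells are
    excluded from the mean; a group in which every replicate is undetermined
    stays UNDETERMINED. The number of wells contributing to each mean is
    recorded in ``replicate_counts``.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    order: list[tuple[str, str]] = []
    for s in m.samples:
        key = (s.cell_type, s.fraction)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s.sample_id)

    cols, metas, counts = {}, [], {}
    for cell_type, fraction in order:
        ids = groups[(cell_type, fraction)]
        block = m.values[ids]
        mean = block.mean(axis=1, skipna=True)
        n = block.notna().sum(axis=1)
        sid = f"{cell_type}:{fraction}"
        cols[sid] = mean
        counts[sid] = n
        metas.append(SampleMeta(sid, cell_type, fraction, replicate=1))
    values = pd.DataFrame(cols, index=m.values.index)
    return CtMatrix(values, metas, m.assay_class, replicate_counts=pd.DataFrame(counts))


def relative_expression(ct_test: float, ct_ref: float, efficiency: float = 2.0) -> float:
    """Linear expression of the test condition relative to the reference.

    ``efficiency ** (ct_ref - ct_test)``; with the default 100% efficiency this
    is ``2**dCT``. Lower CT means higher expression.
    """
    if ct_test is None or ct_ref is None or math.isnan(ct_test) or math.isnan(ct_ref):
        raise UndefinedResultError(
            "relative expression is undefined for undetermined CT values"
        )
    if efficiency <= 1.0:
        raise ValidationError("amplification efficiency must exceed 1.0")
    return float(efficiency ** (ct_ref - ct_test))


def detectability_filter(m: CtMatrix, threshold: float = 30.0) -> set[str]:
    """Assays reliably detected: CT strictly below ``threshold`` in >=1 column.

    RT-qPCR quantification is only trusted below CT 30, so downstream
    differential calls are restricted to this set. Undetermined wells never
    satisfy the test.
    """
    arr = m.values.to_numpy()
    with np.errstate(invalid="ignore"):
        hit = np.nan_to_num(arr, nan=np.inf) < threshold
    keep = hit.any(axis=1)
    return {a for a, k in zip(m.assays, keep) if k}


def ct_to_expression(m: CtMatrix, reference: str = "assay_mean") -> ExpressionMatrix:
    """Convert a (collapsed) CT matrix to relative log2 expression.

    Each assay's expression is expressed relative to its own mean CT across
    columns (``log2 expr = mean_ct - ct``), which preserves within-assay
    profiles — the only thing stage-specific comparisons use. Undetermined
    cells become the assay's minimum observed expression minus one log2 unit
    (a floor, flagged nowhere else; assays with no detected value are dropped).
    """
    vals = m.values.copy()
    keep = vals.notna().any(axis=1)
    vals = vals.loc[keep]
    centred = vals.rsub(vals.mean(axis=1), axis=0)  # mean_ct - ct
    floor = centred.min(axis=1) - 1.0
    centred = centred.apply(lambda col: col.fillna(floor), axis=0)
    return ExpressionMatrix(centred, m.samples)
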