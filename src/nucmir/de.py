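"""Differential expression: miRNA CT fold changes, signed-rank testing,
clustering of highly expressed miRNAs, cross-species concordance, and the
empirical-Bayes moderated t for the mRNA microarray arm.

The miRNA arm works directly on collapsed CT values: a fold change between two
stages is ``2**(CT_ref - CT_test)``, and an assay is called differentially
expressed when that fold is at least ``min_fold`` (or at most ``1/min_fold``)
in some pairwise stage comparison and the assay is detectable (CT < 30 in at
least one stage).

The mRNA arm shrinks per-gene variances toward a prior estimated across genes
(empirical Bayes): the posterior variance
``s_tilde^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)`` replaces the per-gene
variance in the two-sample t, and the reference distribution gains the prior
degrees of freedom (t with ``d0 + d_g`` df).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import digamma, polygamma

from .ctmatrix import CtMatrix, ExpressionMatrix, detectability_filter
from .errors import (
    ConfigurationError,
    DegeneratePriorError,
    InsufficientDataError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# miRNA arm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeCall:
    """One entity's fold change in one ordered stage comparison."""

    entity: str
    comparison: tuple[str, str]  # (test, ref)
    fold: float
    direction: str  # "up" | "down"
    passes: bool
    p_value: float | None = None


def mirna_differential(
    m: CtMatrix, min_fold: float = 2.0, ct_threshold: float = 30.0
) -> list[DeCall]:
    """Pairwise fold changes for every detectable assay on a collapsed matrix.

    ``m`` must hold one column per cell type (whole-cell, replicates already
    collapsed). For each detectable assay and ordered pair (test, ref) of cell
    types, fold = 2**(CT_ref - CT_test); the call passes iff fold >= min_fold
    or fold <= 1/min_fold (inclusive: "2-fold or more"). Assays failing the
    CT < ct_threshold detectability rule never pass. Comparisons involving an
    undetermined CT are skipped.
    """
    cell_types = m.cell_types()
    if len(cell_types) < 2:
        raise ConfigurationError("differential expression needs >=2 cell types")
    col_of = {s.cell_type: s.sample_id for s in m.samples}
    detectable = detectability_filter(m, ct_threshold)
    calls: list[DeCall] = []
    for assay in m.assays:
        if m.class_of(assay) != "miRNA":
            continue
        det = assay in detectable
        for test, ref in itertools.permutations(cell_types, 2):
            ct_test = m.values.at[assay, col_of[test]]
            ct_ref = m.values.at[assay, col_of[ref]]
            if math.isnan(ct_test) or math.isnan(ct_ref):
                continue
            fold = 2.0 ** (ct_ref - ct_test)
            passes = det and (fold >= min_fold or fold <= 1.0 / min_fold)
            calls.append(
                DeCall(
                    entity=assay,
                    comparison=(test, ref),
                    fold=fold,
                    direction="up" if fold >= 1.0 else "down",
                    passes=passes,
                )
            )
    return calls


def de_entities(calls: Sequence[DeCall], min_comparisons: int = 1) -> set[str]:
    """Entities passing in at least ``min_comparisons`` unordered comparisons."""
    passed: dict[str, set[frozenset]] = {}
    for c in calls:
        if c.passes:
            passed.setdefault(c.entity, set()).add(frozenset(c.comparison))
    return {e for e, comps in passed.items() if len(comps) >= min_comparisons}


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank on dCT values
# ---------------------------------------------------------------------------


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p for the signed-rank statistic.

    ``ranks2`` are the (mid-)ranks doubled so they are integers; ``w2`` is the
    doubled observed W+ (sum of positive-difference ranks). The null assigns
    each rank a sign independently with probability 1/2; the distribution of
    W+ is built by convolution, which enumerates all 2^n sign assignments.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= 2.0 ** len(ranks2)
    w2 = int(round(w2))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_delta_ct(
    delta_ct_a: Sequence[float],
    delta_ct_b: Sequence[float],
    paired: bool = True,
    exact_limit: int = 25,
) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired dCT values.

    Zero differences are dropped (Wilcoxon's original treatment) and ties take
    mid-ranks. The exact null distribution is enumerated for n <= exact_limit;
    above that a normal approximation with continuity correction and tie
    correction is used. If every difference is zero the test is degenerate and
    p = 1.0 is returned with a warning.
    """
    a = np.asarray(delta_ct_a, dtype=float)
    b = np.asarray(delta_ct_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValidationError("paired test requires equal-length inputs")
        d = a - b
    else:
        # unpaired fallback: rank-sum on pooled values
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; signed-rank p set to 1.0")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        return _signed_rank_exact_p(np.round(2.0 * ranks), 2.0 * w_plus)
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    diff = w_plus - mean
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# clustering of highly expressed miRNAs
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    entities: list[str]  # leaf order
    linkage: np.ndarray | None
    distance_metric: str
    linkage_method: str
    selected: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return self.linkage is None


def cluster_high_expressers(
    m: CtMatrix,
    de_calls: Sequence[DeCall],
    ct_high: float = 25.0,
    min_passing: int = 1,
    distance_metric: str = "correlation",
    linkage_method: str = "average",
) -> ClusterResult:
    """Hierarchically cluster highly expressed, differentially regulated miRNAs.

    Selects assays with CT strictly below ``ct_high`` in at least one cell type
    that pass differential expression in >= ``min_passing`` stage comparisons,
    then clusters their mean-centred expression profiles (expression = -CT, so
    correlations reflect expression trajectories). Default distance is Pearson
    correlation distance (1 - r) with average linkage; euclidean/complete are
    available alternates.
    """
    high = detectability_filter(m, ct_high)
    de = de_entities(de_calls, min_comparisons=min_passing)
    selected = [a for a in m.assays if a in high and a in de]
    if len(selected) < 2:
        warnings.warn("fewer than 2 assays selected; returning empty clustering")
        return ClusterResult(selected, None, distance_metric, linkage_method, selected)
    profiles = -m.values.loc[selected].to_numpy()
    profiles = np.where(np.isnan(profiles), np.nanmin(profiles) - 1.0, profiles)
    profiles = profiles - profiles.mean(axis=1, keepdims=True)
    if distance_metric == "correlation":
        # guard against zero-variance rows, where correlation is undefined
        sd = profiles.std(axis=1)
        profiles[sd == 0] += np.linspace(-1e-9, 1e-9, profiles.shape[1])
    link = hierarchy.linkage(profiles, method=linkage_method, metric=distance_metric)
    order = hierarchy.leaves_list(link)
    return ClusterResult(
        [selected[i] for i in order], link, distance_metric, linkage_method, selected
    )


# ---------------------------------------------------------------------------
# cross-species concordance
# ---------------------------------------------------------------------------

_SPECIES_PREFIXES = ("mmu-", "hsa-", "rno-")


def default_name_mapper(name: str) -> str:
    n = name.strip().lower()
    for p in _SPECIES_PREFIXES:
        if n.startswith(p):
            n = n[len(p):]
            break
    return n


@dataclass
class ConcordanceResult:
    rho: float
    p: float
    n_common: int
    r_squared: float
    table: dict[str, int]  # direction agreement counts among A's DE entities


def cross_species_concordance(
    fold_a: Mapping[str, float],
    fold_b: Mapping[str, float],
    name_mapper: Callable[[str], str] = default_name_mapper,
    min_fold: float = 2.0,
) -> ConcordanceResult:
    """Spearman concordance of log2 fold changes between two species' panels.

    Names are normalised (default: species prefix stripped, case-insensitive)
    before intersecting. Reports Spearman rho and two-sided p over the common
    entities, the R^2 of the fold-fold least-squares fit, and up/down direction
    agreement counts restricted to entities passing |fold| >= min_fold in
    dataset A.
    """
    a = {name_mapper(k): v for k, v in fold_a.items()}
    b = {name_mapper(k): v for k, v in fold_b.items()}
    common = sorted(set(a) & set(b))
    if len(common) < 3:
        raise InsufficientDataError(
            f"only {len(common)} entities common after name mapping (need >=3)"
        )
    xa = np.array([a[k] for k in common])
    xb = np.array([b[k] for k in common])
    rho, p = stats.spearmanr(xa, xb)
    r_squared = stats.linregress(xa, xb).rvalue ** 2
    lf = math.log2(min_fold)
    table = {"up_up": 0, "up_down": 0, "down_up": 0, "down_down": 0}
    for va, vb in zip(xa, xb):
        if abs(va) < lf:
            continue
        key = ("up" if va > 0 else "down") + "_" + ("up" if vb > 0 else "down")
        table[key] += 1
    return ConcordanceResult(float(rho), float(p), len(common), float(r_squared), table)


# ---------------------------------------------------------------------------
# moderated t (empirical Bayes shrinkage)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModeratedTResult:
    gene: str
    log2_fold: float
    s2_gene: float
    s2_prior: float
    d_prior: float
    s2_posterior: float
    t_moderated: float
    df_total: float
    p_moderated: float
    significant: bool


@dataclass
class ModeratedTDE:
    results: list[ModeratedTResult]
    groups: tuple[str, str]  # (test, ref)
    s2_prior: float
    d_prior: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results]).set_index("gene")

    def significant_genes(self) -> set[str]:
        return {r.gene for r in self.results if r.significant}


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Monotone decreasing target; the iteration below (on 1/y, following the
    standard variance-stabilised update) converges from y0 = 0.5 + 1/x.
    """
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Under the scaled chi-square model, ``e_g = log(s2_g) - digamma(df/2)
    + log(df/2)`` has mean ``log(s0^2) + digamma(d0/2) - log(d0/2)`` and excess
    variance ``trigamma(d0/2)`` over ``trigamma(df/2)``; inverting the trigamma
    yields d0 and then s0^2. Genes with zero (or non-finite) sample variance
    are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if not ok.any():
        raise DegeneratePriorError("all gene variances are zero; cannot fit prior")
    z = np.log(s2[ok])
    e = z - float(digamma(df / 2.0)) + math.log(df / 2.0)
    n = len(e)
    if n < 2:
        return math.inf, float(np.exp(e.mean()))
    mean_e = float(e.mean())
    var_e = float(((e - mean_e) ** 2).sum() / (n - 1))
    excess = var_e - float(polygamma(1, df / 2.0))
    if excess <= 0:
        # no evidence of variance heterogeneity: infinitely informative prior
        return math.inf, float(math.exp(mean_e))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = math.exp(mean_e + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return float(d0), float(s0_2)


def moderated_t_de(
    x: ExpressionMatrix,
    groups: Mapping[str, str] | Sequence[str],
    comparison: tuple[str, str] | None = None,
    min_fold: float = 2.0,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> ModeratedTDE:
    """Two-group moderated-t differential expression on log2 expression.

    ``groups`` labels each sample (mapping sample_id -> label, or a sequence in
    column order); exactly two labels must appear unless ``comparison`` picks
    the (test, ref) pair. A gene is significant iff its moderated p <= alpha
    and |fold| >= min_fold. ``prior_df`` overrides the estimated d0; 0 recovers
    the ordinary two-sample t exactly (no shrinkage, d_g degrees of freedom).
    """
    ids = [s.sample_id for s in x.samples]
    if isinstance(groups, Mapping):
        labels = [groups.get(i) for i in ids]
    else:
        labels = list(groups)
        if len(labels) != len(ids):
            raise ConfigurationError("one group label per sample required")
    present = [l for l in dict.fromkeys(labels) if l is not None]
    if comparison is None:
        if len(present) != 2:
            raise ConfigurationError(
                f"need exactly two group labels, got {present}; pass `comparison`"
            )
        test, ref = present
    else:
        test, ref = comparison
        for g in (test, ref):
            if g not in present:
                raise ConfigurationError(f"group {g!r} has no samples")
    idx1 = [i for i, l in enumerate(labels) if l == test]
    idx2 = [i for i, l in enumerate(labels) if l == ref]
    n1, n2 = len(idx1), len(idx2)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need >=2 samples per group")
    arr = x.values.to_numpy(dtype=float)
    g1, g2 = arr[:, idx1], arr[:, idx2]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    log2_fold = m1 - m2
    df_gene = n1 + n2 - 2
    ss = ((g1 - m1[:, None]) ** 2).sum(axis=1) + ((g2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_gene

    if prior_df is None:
        d0, s0_2 = estimate_variance_prior(s2, df_gene)
    elif prior_df == 0:
        d0, s0_2 = 0.0, float(np.nan)
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_variance_prior(s2, df_gene)
    if d0 == 0.0:
        s2_post = s2.copy()
    elif math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + df_gene * s2) / (d0 + df_gene)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2_fold / se, np.inf * np.sign(log2_fold))
    df_total = d0 + df_gene
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    lf = math.log2(min_fold)
    results = [
        ModeratedTResult(
            gene=g,
            log2_fold=float(log2_fold[i]),
            s2_gene=float(s2[i]),
            s2_prior=float(s0_2) if not math.isnan(s0_2) else float("nan"),
            d_prior=float(d0),
            s2_posterior=float(s2_post[i]),
            t_moderated=float(t[i]),
            df_total=float(df_total),
            p_moderated=float(min(1.0, p[i])),
            significant=bool(p[i] <= alpha and abs(log2_fold[i]) >= lf),
        )
        for i, g in enumerate(x.genes)
    ]
    return ModeratedTDE(results, (test, ref), float(s0_2), float(d0))
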