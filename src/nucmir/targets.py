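"""Seed-match target scanning and anti-correlation integration.

A miRNA recognises its targets primarily through its seed, nucleotides 2-8
from the 5' end. The canonical site types on a 3'UTR (read 5'->3') are, in
decreasing strength:

* 8mer     — Watson-Crick match to the reverse complement of miRNA positions
             2-8, followed by an A (opposite miRNA position 1);
* 7mer-m8  — match to the reverse complement of positions 2-8, no following A;
* 7mer-A1  — match to the reverse complement of positions 2-7, followed by an A.

The A opposite position 1 must be a genomic A regardless of the miRNA's first
nucleotide. Overlapping matches at one locus report only the strongest type.

Candidate miRNA->mRNA pairs combine a seed match with opposite-direction
expression changes between two differentiation stages (a repressive miRNA that
goes up should push its target down).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .de import DeCall, ModeratedTDE
from .errors import ConfigurationError, ValidationError

_RNA = set("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


def normalize_rna(seq: str, what: str = "sequence") -> str:
    """Uppercase, DNA->RNA (T->U); reject anything outside ACGU."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA
    if bad:
        raise ValidationError(f"{what}: invalid characters {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3', RNA alphabet, length >= 8."""

    name: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(
            self, "sequence", normalize_rna(self.sequence, f"miRNA {self.name!r}")
        )
        if len(self.sequence) < 8:
            raise ValidationError(
                f"miRNA {self.name!r}: length {len(self.sequence)} < 8; "
                "seed positions 2-8 must exist"
            )


def seed_region(m: MatureMiRNA) -> str:
    """Seed: nucleotides 2-8 (1-based) of the mature sequence, length 7."""
    return m.sequence[1:8]


@dataclass(frozen=True)
class SeedMatch:
    match_type: str
    utr_start: int  # 0-based inclusive
    utr_end: int  # 0-based exclusive
    site_sequence: str

    def __post_init__(self):
        expected = 8 if self.match_type == "8mer" else 7
        if self.match_type not in SITE_TYPES:
            raise ValidationError(f"unknown site type {self.match_type!r}")
        if self.utr_end - self.utr_start != expected:
            raise ValidationError(
                f"{self.match_type} site must span {expected} nt, got "
                f"[{self.utr_start}, {self.utr_end})"
            )


def scan_utr(
    utr: str, m: MatureMiRNA, on_invalid: str = "error"
) -> list[SeedMatch]:
    """All seed-match sites of ``m`` in ``utr`` (DNA or RNA accepted).

    Each locus (occurrence of the position 2-7 core) is reported at most once
    with the strongest applicable type (8mer > 7mer-m8 > 7mer-A1). Coordinates
    are 0-based half-open on the input UTR. ``on_invalid='skip'`` replaces
    non-ACGU characters with 'N' (which can never match) instead of raising.
    """
    if not utr:
        return []
    s = utr.upper().replace("T", "U")
    bad = set(s) - _RNA
    if bad:
        if on_invalid == "skip":
            s = "".join(c if c in _RNA else "N" for c in s)
        else:
            raise ValidationError(f"UTR: invalid characters {sorted(bad)}")
    rc6 = reverse_complement(m.sequence[1:7])  # pairs miRNA positions 7..2
    m8_comp = reverse_complement(m.sequence[7])  # pairs miRNA position 8
    matches: list[SeedMatch] = []
    pos = s.find(rc6)
    while pos != -1:
        end6 = pos + 6
        has_a1 = end6 < len(s) and s[end6] == "A"
        has_m8 = pos >= 1 and s[pos - 1] == m8_comp
        if has_m8 and has_a1:
            matches.append(SeedMatch("8mer", pos - 1, end6 + 1, s[pos - 1 : end6 + 1]))
        elif has_m8:
            matches.append(SeedMatch("7mer-m8", pos - 1, end6, s[pos - 1 : end6]))
        elif has_a1:
            matches.append(SeedMatch("7mer-A1", pos, end6 + 1, s[pos : end6 + 1]))
        pos = s.find(rc6, pos + 1)
    return matches


@dataclass
class TargetPair:
    mirna: str
    gene: str
    mirna_log2_fold: float
    gene_log2_fold: float
    gene_p: float
    matches: list[SeedMatch]
    rationale: str  # "anti_correlated" or "stage_specific:<stage>"
    known_validated: bool = False


def anticorrelated_pairs(
    mirna_de: Sequence[DeCall],
    gene_de: ModeratedTDE,
    utrs: Mapping[str, str],
    mirnas: Mapping[str, MatureMiRNA],
    comparison: tuple[str, str] | None = None,
    validated: Mapping[str, set] | None = None,
) -> list[TargetPair]:
    """miRNA->mRNA pairs with opposite significant changes and >=1 seed site.

    The miRNA must pass its fold filter and the gene its fold/moderated-p
    filter on the *same* (test, ref) comparison; their directions must be
    opposite; and the gene's 3'UTR must carry at least one seed match for the
    miRNA. ``validated`` optionally annotates known (miRNA -> {genes}) pairs.
    """
    if comparison is None:
        comparison = gene_de.groups
    elif tuple(comparison) != tuple(gene_de.groups):
        raise ConfigurationError(
            f"gene DE computed on {gene_de.groups}, requested {comparison}"
        )
    if not any(tuple(c.comparison) == tuple(comparison) for c in mirna_de):
        raise ConfigurationError(
            f"no miRNA DE calls for comparison {comparison}; "
            "were the two DE sets computed on the same comparison?"
        )
    mirna_calls = {
        c.entity: c
        for c in mirna_de
        if tuple(c.comparison) == tuple(comparison) and c.passes
    }
    sig_genes = [r for r in gene_de.results if r.significant]
    pairs: list[TargetPair] = []
    for name, call in sorted(mirna_calls.items()):
        if name not in mirnas:
            continue
        m = mirnas[name]
        m_lfc = math.log2(call.fold)
        for g in sig_genes:
            if m_lfc * g.log2_fold >= 0:
                continue  # same direction (or a zero fold): not anti-correlated
            utr = utrs.get(g.gene)
            if not utr:
                continue
            sites = scan_utr(utr, m)
            if not sites:
                continue
            pairs.append(
                TargetPair(
                    mirna=name,
                    gene=g.gene,
                    mirna_log2_fold=m_lfc,
                    gene_log2_fold=g.log2_fold,
                    gene_p=g.p_moderated,
                    matches=sites,
                    rationale="anti_correlated",
                    known_validated=bool(
                        validated and g.gene in validated.get(name, set())
                    ),
                )
            )
    return pairs


def stage_specific_pairs(
    mirna_profiles: pd.DataFrame,
    gene_profiles: pd.DataFrame,
    pairs: Sequence[TargetPair],
    stage: str,
) -> list[TargetPair]:
    """Pairs whose miRNA peaks and whose gene bottoms out in ``stage``.

    ``*_profiles`` are entity x stage expression tables (higher = more
    expressed) covering all stages. Exact ties at the extremum are excluded
    (conservative); pairs with a missing stage value are skipped with a
    warning.
    """
    if stage not in mirna_profiles.columns or stage not in gene_profiles.columns:
        raise ConfigurationError(f"profiles lack stage {stage!r}")
    out: list[TargetPair] = []
    for p in pairs:
        if p.mirna not in mirna_profiles.index or p.gene not in gene_profiles.index:
            warnings.warn(f"no profile for pair {p.mirna}->{p.gene}; skipped")
            continue
        mrow = mirna_profiles.loc[p.mirna]
        grow = gene_profiles.loc[p.gene]
        if mrow.isna().any() or grow.isna().any():
            warnings.warn(f"missing stage value for pair {p.mirna}->{p.gene}; skipped")
            continue
        m_max = mrow.max()
        g_min = grow.min()
        if (mrow == m_max).sum() != 1 or (grow == g_min).sum() != 1:
            continue  # tied extremum: excluded
        if mrow.idxmax() == stage and grow.idxmin() == stage:
            out.append(
                TargetPair(
                    p.mirna, p.gene, p.mirna_log2_fold, p.gene_log2_fold, p.gene_p,
                    p.matches, f"stage_specific:{stage}", p.known_validated,
                )
            )
    return out


def pairs_frame(pairs: Sequence[TargetPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "mirna": p.mirna,
                "gene": p.gene,
                "mirna_log2_fold": p.mirna_log2_fold,
                "gene_log2_fold": p.gene_log2_fold,
                "gene_p": p.gene_p,
                "n_sites": len(p.matches),
                "site_types": ";".join(s.match_type for s in p.matches),
                "site_coords": ";".join(
                    f"{s.utr_start}-{s.utr_end}" for s in p.matches
                ),
                "rationale": p.rationale,
                "known_validated": p.known_validated,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "gene", "mirna_log2_fold", "gene_log2_fold", "gene_p",
            "n_sites", "site_types", "site_coords", "rationale", "known_validated",
        ],
    )
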