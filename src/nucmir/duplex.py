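"""Intermolecular RNA-RNA duplex minimum free energy (MFE) scanning.

A deliberately simplified hybridisation model: the two strands pair
antiparallel, intermolecular pairs only (no intramolecular structure), with a
nearest-neighbour stacking-energy table over Watson-Crick and G:U wobble pairs
and affine penalties for bulges and internal loops between consecutive pairs.
A dynamic program over (query position, target position) minimises the summed
stack energies plus loop penalties; the optimal duplex and a pairing trace are
returned. Absolute energies are model constants (Turner-style magnitudes,
kcal/mol) — they are not RNAhybrid's, so the conventional -30 kcal/mol
candidate cut is exposed as a parameter everywhere it is used.

Significance of a best hit against a transcript is calibrated by
dinucleotide-preserving shuffles of the transcript (Altschul-Erickson walk on
the dinucleotide multigraph): the best MFE is recomputed per shuffle, a Gumbel
extreme-value distribution is moment-matched to the shuffled minima, and both
the Gumbel tail probability and the empirical rank p-value are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .errors import ConfigurationError, ValidationError
from .targets import MatureMiRNA, normalize_rna

_EULER_GAMMA = 0.5772156649015329

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_BASES = "ACGU"

# pair type ids over (top base, bottom base); -1 = not pairable
_PAIR_NAMES = ("AU", "UA", "CG", "GC", "GU", "UG")
_REV_PAIR = (1, 0, 3, 2, 5, 4)  # AU<->UA, CG<->GC, GU<->UG


def _pair_table(allow_gu: bool) -> np.ndarray:
    t = -np.ones((4, 4), dtype=np.int64)
    t[0, 3], t[3, 0] = 0, 1  # AU, UA
    t[1, 2], t[2, 1] = 2, 3  # CG, GC
    if allow_gu:
        t[2, 3], t[3, 2] = 4, 5  # GU, UG
    return t


def _stack_table() -> np.ndarray:
    """Nearest-neighbour stack energies (kcal/mol) for pair doublets.

    Watson-Crick entries follow the published nearest-neighbour magnitudes;
    wobble-containing stacks are simplified to -1.3 (one G:U) and -0.5 (two).
    Indexed [p1, p2] for consecutive pairs 5'-p1 p2-3' on the query strand, and
    symmetric under reading the duplex from the other strand:
    E[p1][p2] == E[rev(p2)][rev(p1)].
    """
    E = np.zeros((6, 6))
    wc = {
        (0, 0): -0.93,  # 5'AA3'/3'UU5'
        (0, 1): -1.10,  # AU/UA
        (1, 0): -1.33,  # UA/AU
        (2, 1): -2.08,  # CU/GA
        (2, 0): -2.11,  # CA/GU
        (3, 1): -2.24,  # GU/CA
        (3, 0): -2.35,  # GA/CU
        (2, 3): -2.36,  # CG/GC
        (3, 3): -3.26,  # GG/CC
        (3, 2): -3.42,  # GC/CG
    }
    for (p1, p2), v in wc.items():
        E[p1, p2] = v
        E[_REV_PAIR[p2], _REV_PAIR[p1]] = v
    for p1 in range(6):
        for p2 in range(6):
            n_wobble = (p1 >= 4) + (p2 >= 4)
            if n_wobble == 1:
                E[p1, p2] = -1.3
            elif n_wobble == 2:
                E[p1, p2] = -0.5
    return E


@dataclass(frozen=True)
class EnergyModel:
    """Stacking energies plus affine loop penalties for the duplex DP."""

    stack: np.ndarray = field(default_factory=_stack_table)
    bulge_open: float = 3.2
    bulge_extend: float = 0.6
    internal_open: float = 1.7
    internal_extend: float = 0.65
    max_bulge: int = 3
    max_internal: int = 3
    allow_gu: bool = True

    def bulge_penalty(self, length: int) -> float:
        if length < 1:
            raise ValidationError("bulge length must be >= 1")
        return self.bulge_open + self.bulge_extend * length

    def internal_loop_penalty(self, len1: int, len2: int) -> float:
        if len1 < 1 or len2 < 1:
            raise ValidationError("internal loop lengths must be >= 1")
        return self.internal_open + self.internal_extend * (len1 + len2)

    def tables(self):
        """(pair_id 4x4, stack 6x6, bulge[len], internal[len1,len2]) arrays."""
        bulge = np.array(
            [np.inf] + [self.bulge_penalty(i) for i in range(1, self.max_bulge + 1)]
        )
        internal = np.full((self.max_internal + 1, self.max_internal + 1), np.inf)
        for a in range(1, self.max_internal + 1):
            for b in range(1, self.max_internal + 1):
                internal[a, b] = self.internal_loop_penalty(a, b)
        return _pair_table(self.allow_gu), self.stack.copy(), bulge, internal


DEFAULT_MODEL = EnergyModel()


def encode_rna(seq: str, what: str = "sequence") -> np.ndarray:
    s = normalize_rna(seq, what)
    return np.frombuffer(
        bytes(_BASE_INDEX[c] for c in s), dtype=np.uint8
    ).astype(np.int64)


# ---------------------------------------------------------------------------
# dynamic program (numba kernels)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _dp_fill(q, tr, pair_id, stack, bulge, internal, max_bulge, max_internal):
    """Fill E[i,j] = best energy of a duplex whose last pair is (q[i], tr[j]).

    ``tr`` is the target window *reversed*, so both indices advance together
    along the duplex (antiparallel strands). A lone pair costs 0; energy
    accrues from stacks between adjacent pairs and loop penalties for bulged /
    internal-loop gaps (no stack bonus across a loop).
    """
    n, m = len(q), len(tr)
    E = np.full((n, m), np.inf)
    back = np.full((n, m, 2), -1, dtype=np.int64)
    for i in range(n):
        for j in range(m):
            p = pair_id[q[i], tr[j]]
            if p < 0:
                continue
            best = 0.0  # start a new duplex with this lone pair
            bi, bj = -1, -1
            gmax = max_bulge if max_bulge > max_internal else max_internal
            for a in range(0, gmax + 1):
                ii = i - 1 - a
                if ii < 0:
                    break
                for b in range(0, gmax + 1):
                    jj = j - 1 - b
                    if jj < 0:
                        break
                    pp = pair_id[q[ii], tr[jj]]
                    if pp < 0 or E[ii, jj] == np.inf:
                        continue
                    if a == 0 and b == 0:
                        cost = stack[pp, p]
                    elif b == 0:
                        if a > max_bulge:
                            continue
                        cost = bulge[a]
                    elif a == 0:
                        if b > max_bulge:
                            continue
                        cost = bulge[b]
                    else:
                        if a > max_internal or b > max_internal:
                            continue
                        cost = internal[a, b]
                    cand = E[ii, jj] + cost
                    if cand < best:
                        best = cand
                        bi, bj = ii, jj
            E[i, j] = best
            back[i, j, 0] = bi
            back[i, j, 1] = bj
    return E, back


@njit(cache=False)
def _dp_mfe(q, tr, pair_id, stack, bulge, internal, max_bulge, max_internal):
    """Best (most negative) duplex energy only — no traceback arrays."""
    n, m = len(q), len(tr)
    E = np.full((n, m), np.inf)
    mfe = 0.0
    gmax = max_bulge if max_bulge > max_internal else max_internal
    for i in range(n):
        for j in range(m):
            p = pair_id[q[i], tr[j]]
            if p < 0:
                continue
            best = 0.0
            for a in range(0, gmax + 1):
                ii = i - 1 - a
                if ii < 0:
                    break
                for b in range(0, gmax + 1):
                    jj = j - 1 - b
                    if jj < 0:
                        break
                    pp = pair_id[q[ii], tr[jj]]
                    if pp < 0 or E[ii, jj] == np.inf:
                        continue
                    if a == 0 and b == 0:
                        cost = stack[pp, p]
                    elif b == 0:
                        if a > max_bulge:
                            continue
                        cost = bulge[a]
                    elif a == 0:
                        if b > max_bulge:
                            continue
                        cost = bulge[b]
                    else:
                        if a > max_internal or b > max_internal:
                            continue
                        cost = internal[a, b]
                    cand = E[ii, jj] + cost
                    if cand < best:
                        best = cand
            E[i, j] = best
            if best < mfe:
                mfe = best
    return mfe


@njit(cache=False)
def _scan_windows(
    q, t, window, step, pair_id, stack, bulge, internal, max_bulge, max_internal
):
    """Best windowed MFE over a transcript; returns (mfe, window_start)."""
    L = len(t)
    best = 0.0
    best_start = 0
    if L <= window:
        tr = t[::-1]
        best = _dp_mfe(q, tr, pair_id, stack, bulge, internal, max_bulge, max_internal)
        return best, 0
    starts_end = L - window
    k = 0
    done_last = False
    while k <= starts_end:
        tr = t[k : k + window][::-1]
        mfe = _dp_mfe(q, tr, pair_id, stack, bulge, internal, max_bulge, max_internal)
        if mfe < best:
            best = mfe
            best_start = k
        if k == starts_end:
            done_last = True
        k += step
    if not done_last:
        k = starts_end
        tr = t[k : k + window][::-1]
        mfe = _dp_mfe(q, tr, pair_id, stack, bulge, internal, max_bulge, max_internal)
        if mfe < best:
            best = mfe
            best_start = k
    return best, best_start


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


@dataclass
class DuplexHit:
    mirna: str
    transcript: str
    q_start: int
    q_end: int  # 0-based half-open on the miRNA
    t_start: int
    t_end: int  # 0-based half-open on the transcript
    mfe: float  # kcal/mol, <= 0
    pairing_string: str
    pairs: list[tuple[int, int]] = field(default_factory=list)
    p_empirical: float | None = None
    p_gumbel: float | None = None


def _traceback(back, i, j):
    chain = []
    while i >= 0:
        chain.append((int(i), int(j)))
        i, j = back[i, j, 0], back[i, j, 1]
    chain.reverse()
    return chain


def _pairing_diagram(query: str, target_window: str, pairs_qt: list[tuple[int, int]]):
    """Three-line text diagram of the paired region (query on top, 5'->3')."""
    if not pairs_qt:
        return ""
    top, mid, bot = [], [], []
    prev_q, prev_t = None, None
    for qi, tj in pairs_qt:
        if prev_q is not None:
            gq = qi - prev_q - 1
            gt = prev_t - tj - 1
            for k in range(max(gq, gt)):
                top.append(query[prev_q + 1 + k] if k < gq else "-")
                mid.append(" ")
                bot.append(target_window[prev_t - 1 - k] if k < gt else "-")
        top.append(query[qi])
        mid.append("|")
        bot.append(target_window[tj])
        prev_q, prev_t = qi, tj
    return (
        "5'-" + "".join(top) + "-3'\n   " + "".join(mid) + "\n3'-" + "".join(bot) + "-5'"
    )


def duplex_mfe(
    query: str, target_window: str, em: EnergyModel = DEFAULT_MODEL
) -> tuple[float, list[tuple[int, int]]]:
    """Optimal intermolecular duplex energy of ``query`` against one window.

    Returns ``(mfe, pairs)`` where ``pairs`` is the list of (query position,
    window position) base pairs of the optimal duplex in 5'->3' query order
    (0-based, on the *input* window orientation). Sequences admitting no pair
    give (0.0, []).
    """
    q = encode_rna(query, "query")
    t = encode_rna(target_window, "target window")
    if len(q) == 0 or len(t) == 0:
        return 0.0, []
    pair_id, stack, bulge, internal = em.tables()
    tr = t[::-1].copy()
    E, back = _dp_fill(
        q, tr, pair_id, stack, bulge, internal, em.max_bulge, em.max_internal
    )
    finite = np.isfinite(E)
    if not finite.any() or E[finite].min() >= 0.0:
        return 0.0, []
    i, j = np.unravel_index(np.argmin(np.where(finite, E, np.inf)), E.shape)
    mfe = float(E[i, j])
    chain = _traceback(back, i, j)
    m = len(t)
    pairs = [(qi, m - 1 - tj) for qi, tj in chain]
    return mfe, pairs


def scan_transcript(
    m: MatureMiRNA,
    transcript: str,
    em: EnergyModel = DEFAULT_MODEL,
    window: int = 60,
    step: int = 10,
    transcript_name: str = "transcript",
) -> DuplexHit:
    """Best duplex hit of a miRNA against a transcript, scanned in windows.

    Windows of ``window`` nt slide by ``step`` (a final window flush with the
    transcript end is always evaluated; transcripts shorter than the window are
    scanned whole). The minimum-energy hit is reported with transcript-level
    coordinates; ties resolve to the earliest window (deterministic).
    """
    q = encode_rna(m.sequence, f"miRNA {m.name!r}")
    t = encode_rna(transcript, "transcript")
    if step < 1:
        raise ConfigurationError("step must be >= 1")
    pair_id, stack, bulge, internal = em.tables()
    _, best_start = _scan_windows(
        q, t, window, step, pair_id, stack, bulge, internal,
        em.max_bulge, em.max_internal,
    )
    win_seq = normalize_rna(transcript)[best_start : best_start + window]
    mfe, pairs = duplex_mfe(m.sequence, win_seq, em)
    if not pairs:
        return DuplexHit(m.name, transcript_name, 0, 0, 0, 0, 0.0, "", [])
    t_positions = [best_start + tj for _, tj in pairs]
    q_positions = [qi for qi, _ in pairs]
    diagram = _pairing_diagram(m.sequence, win_seq, pairs)
    return DuplexHit(
        mirna=m.name,
        transcript=transcript_name,
        q_start=min(q_positions),
        q_end=max(q_positions) + 1,
        t_start=min(t_positions),
        t_end=max(t_positions) + 1,
        mfe=mfe,
        pairing_string=diagram,
        pairs=[(qi, best_start + tj) for qi, tj in pairs],
    )


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle + extreme-value calibration
# ---------------------------------------------------------------------------


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erickson).

    Random Eulerian walk on the dinucleotide multigraph: for every vertex
    except the terminal character a random "last out-edge" is drawn until the
    chosen last edges form paths leading to the terminal vertex; remaining
    edges are permuted and the walk read off. First/last characters and all
    dinucleotide counts are preserved exactly.
    """
    if len(seq) < 10:
        raise ValidationError("sequence too short to shuffle (<10 nt)")
    s = list(seq)
    first, last = s[0], s[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(s[:-1], s[1:]):
        edges.setdefault(a, []).append(b)
    vertices = sorted(edges)
    # choose last edges forming an arborescence into `last`
    non_terminal = [v for v in vertices if v != last]
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in non_terminal}
        ok = True
        for v in non_terminal:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = rng.permutation(len(rest))
        rest = [rest[i] for i in perm]
        if v in last_edge:
            rest.append(last_edge[v])
        shuffled[v] = rest
    out = [first]
    counters = {v: 0 for v in vertices}
    cur = first
    for _ in range(len(s) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


@dataclass
class CalibrationResult:
    hit: DuplexHit
    p_gumbel: float
    p_empirical: float
    null_mfes: np.ndarray
    n_shuffles: int


def calibrate_p(
    m: MatureMiRNA,
    transcript: str,
    em: EnergyModel = DEFAULT_MODEL,
    n_shuffles: int = 200,
    seed: int = 0,
    window: int = 60,
    step: int = 10,
    transcript_name: str = "transcript",
) -> CalibrationResult:
    """Shuffle-calibrated significance of the best hit against a transcript.

    The transcript is shuffled ``n_shuffles`` times preserving dinucleotide
    counts; the best windowed MFE is recomputed per shuffle. A Gumbel
    distribution is moment-matched to the shuffled minima (on -MFE) and
    ``p_gumbel = P(null MFE <= observed)``; the empirical rank p-value
    ``(1 + #{null <= observed}) / (n_shuffles + 1)`` is reported alongside.
    Deterministic for fixed seed and inputs.
    """
    if n_shuffles < 50:
        raise ConfigurationError("n_shuffles must be >= 50")
    tnorm = normalize_rna(transcript, "transcript")
    rng = np.random.default_rng(seed)
    hit = scan_transcript(m, tnorm, em, window, step, transcript_name)
    q = encode_rna(m.sequence)
    pair_id, stack, bulge, internal = em.tables()
    nulls = np.empty(n_shuffles)
    for k in range(n_shuffles):
        sh = dinucleotide_shuffle(tnorm, rng)
        t = encode_rna(sh)
        nulls[k], _ = _scan_windows(
            q, t, window, step, pair_id, stack, bulge, internal,
            em.max_bulge, em.max_internal,
        )
    x_obs = -hit.mfe
    x = -nulls
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        p_gumbel = 1.0 if x_obs <= float(x.mean()) else 0.0
    else:
        beta = sd * math.sqrt(6.0) / math.pi
        mu = float(x.mean()) - _EULER_GAMMA * beta
        # P(X >= x_obs) under Gumbel(mu, beta)
        p_gumbel = 1.0 - math.exp(-math.exp(-(x_obs - mu) / beta))
    p_emp = (1.0 + float((nulls <= hit.mfe).sum())) / (n_shuffles + 1.0)
    hit.p_empirical = p_emp
    hit.p_gumbel = p_gumbel
    return CalibrationResult(hit, float(p_gumbel), float(p_emp), nulls, n_shuffles)


def nuclear_target_candidates(
    hits: Sequence[DuplexHit],
    nuclear_mirna_profiles: pd.DataFrame,
    mature_mirna_profiles: pd.DataFrame,
    comparison: tuple[str, str],
    mfe_cut: float = -30.0,
    p_cut: float = 0.05,
    transcript_to_mature=lambda name: name[4:] if name.startswith("pri-") else name,
) -> pd.DataFrame:
    """Filter calibrated hits and flag expression anti-correlation.

    Keeps hits with ``mfe < mfe_cut`` (strict) and empirical p < ``p_cut``.
    A retained hit is flagged ``anti_correlated`` when the nuclear miRNA's
    expression change between the two compared stages and the mature miRNA
    product of the targeted primary transcript change in opposite directions.
    Profiles are entity x stage expression tables (higher = more expressed).
    """
    test, ref = comparison
    rows = []
    for h in hits:
        if h.p_empirical is None:
            raise ConfigurationError(
                f"hit {h.mirna}->{h.transcript} has no calibrated p; run calibrate_p"
            )
        if not (h.mfe < mfe_cut and h.p_empirical < p_cut):
            continue
        mature = transcript_to_mature(h.transcript)
        anti = None
        d_nuc = d_mat = float("nan")
        if (
            h.mirna in nuclear_mirna_profiles.index
            and mature in mature_mirna_profiles.index
        ):
            d_nuc = float(
                nuclear_mirna_profiles.at[h.mirna, test]
                - nuclear_mirna_profiles.at[h.mirna, ref]
            )
            d_mat = float(
                mature_mirna_profiles.at[mature, test]
                - mature_mirna_profiles.at[mature, ref]
            )
            anti = bool(d_nuc * d_mat < 0)
        rows.append(
            {
                "mirna": h.mirna,
                "transcript": h.transcript,
                "mature_product": mature,
                "t_start": h.t_start,
                "t_end": h.t_end,
                "mfe": h.mfe,
                "p_empirical": h.p_empirical,
                "p_gumbel": h.p_gumbel,
                "nuclear_delta": d_nuc,
                "mature_delta": d_mat,
                "anti_correlated": anti,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "transcript", "mature_product", "t_start", "t_end", "mfe",
            "p_empirical", "p_gumbel", "nuclear_delta", "mature_delta",
            "anti_correlated",
        ],
    )
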