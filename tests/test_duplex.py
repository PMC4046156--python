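"""Duplex DP against an exhaustive-enumeration oracle, shuffle and
calibration behaviour, and candidate filtering."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from nucmir import (
    ConfigurationError,
    MatureMiRNA,
    ValidationError,
    calibrate_p,
    dinucleotide_shuffle,
    duplex_mfe,
    nuclear_target_candidates,
    scan_transcript,
)
from nucmir.duplex import (
    DEFAULT_MODEL,
    _PAIR_NAMES,
    _REV_PAIR,
    DuplexHit,
    EnergyModel,
    _pair_table,
)
from nucmir.targets import reverse_complement

BASES = np.array(list("ACGU"))


def rand_rna(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def oracle_mfe(query: str, window: str, em: EnergyModel = DEFAULT_MODEL) -> float:
    """Exhaustive enumeration over all legal pairings (chains of antiparallel
    base pairs with bounded gaps), independent of the DP implementation."""
    pair_id = _pair_table(em.allow_gu)
    idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    q = [idx[c] for c in query]
    t = [idx[c] for c in window]
    n, m = len(q), len(t)
    best = [0.0]

    def extend(i, j, energy):
        # current last pair: query i (5'->3'), window j (3'->5' walk, so j
        # decreases as i increases)
        if energy < best[0]:
            best[0] = energy
        p_here = pair_id[q[i], t[j]]
        for a in range(0, max(em.max_bulge, em.max_internal) + 1):
            i2 = i + 1 + a
            if i2 >= n:
                break
            for b in range(0, max(em.max_bulge, em.max_internal) + 1):
                j2 = j - 1 - b
                if j2 < 0:
                    break
                p_next = pair_id[q[i2], t[j2]]
                if p_next < 0:
                    continue
                if a == 0 and b == 0:
                    cost = em.stack[p_here, p_next]
                elif b == 0:
                    if a > em.max_bulge:
                        continue
                    cost = em.bulge_penalty(a)
                elif a == 0:
                    if b > em.max_bulge:
                        continue
                    cost = em.bulge_penalty(b)
                else:
                    if a > em.max_internal or b > em.max_internal:
                        continue
                    cost = em.internal_loop_penalty(a, b)
                extend(i2, j2, energy + cost)

    for i in range(n):
        for j in range(m):
            if pair_id[q[i], t[j]] >= 0:
                extend(i, j, 0.0)
    return best[0]


class TestEnergyModel:
    def test_wc_stacks_negative(self):
        em = DEFAULT_MODEL
        for p1 in range(6):
            for p2 in range(6):
                assert em.stack[p1, p2] < 0

    def test_stack_symmetry(self):
        # reading the duplex from the other strand must give the same energy
        em = DEFAULT_MODEL
        for p1 in range(6):
            for p2 in range(6):
                assert em.stack[p1, p2] == em.stack[_REV_PAIR[p2], _REV_PAIR[p1]]

    def test_loop_penalties_nonnegative_nondecreasing(self):
        em = DEFAULT_MODEL
        bulges = [em.bulge_penalty(i) for i in range(1, 4)]
        assert all(b >= 0 for b in bulges) and bulges == sorted(bulges)
        assert em.internal_loop_penalty(2, 2) >= em.internal_loop_penalty(1, 1) >= 0

    def test_gu_toggle(self):
        em = EnergyModel(allow_gu=False)
        mfe, pairs = duplex_mfe("GGGG", "UUUU", em)  # only G:U wobble possible
        assert mfe == 0.0 and pairs == []
        mfe_gu, pairs_gu = duplex_mfe("GGGG", "UUUU", DEFAULT_MODEL)
        assert mfe_gu < 0.0 and pairs_gu


class TestDuplexMfe:
    def test_gc_duplex_stronger_than_au(self):
        q_gc = "GCGCGCGCGC"
        q_au = "AUAUAUAUAU"
        mfe_gc, pairs = duplex_mfe(q_gc, reverse_complement(q_gc))
        mfe_au, _ = duplex_mfe(q_au, reverse_complement(q_au))
        assert len(pairs) == 10
        # exact value fixed by the embedded table: 9 alternating GC/CG stacks
        expected = sum(
            DEFAULT_MODEL.stack[p1, p2]
            for p1, p2 in zip([3, 2] * 5, ([2, 3] * 5)[:9])
        )
        assert mfe_gc == pytest.approx(expected)
        assert mfe_gc < mfe_au < 0

    def test_no_complementarity_is_zero(self):
        assert duplex_mfe("AAAA", "AAAA") == (0.0, [])

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValidationError):
            duplex_mfe("ANGC", "GCGC")

    def test_oracle_equivalence_random(self, rng):
        for _ in range(100):
            q = rand_rna(rng, int(rng.integers(4, 9)))
            w = rand_rna(rng, int(rng.integers(6, 13)))
            mfe, _ = duplex_mfe(q, w)
            assert mfe == pytest.approx(oracle_mfe(q, w), abs=1e-9)

    def test_flanking_extension_never_hurts(self, rng):
        # adding unpaired flanking nucleotides can only keep or improve the MFE
        for _ in range(30):
            q = rand_rna(rng, 8)
            w = rand_rna(rng, 12)
            mfe, _ = duplex_mfe(q, w)
            mfe_ext, _ = duplex_mfe(q, rand_rna(rng, 3) + w + rand_rna(rng, 3))
            assert mfe_ext <= mfe + 1e-12

    def test_pairs_are_valid_coordinates(self, rng):
        q = rand_rna(rng, 15)
        w = rand_rna(rng, 30)
        mfe, pairs = duplex_mfe(q, w)
        comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
        for qi, tj in pairs:
            assert 0 <= qi < len(q) and 0 <= tj < len(w)
            # every reported pair is a legal pair
            assert w[tj] == comp[q[qi]] or {q[qi], w[tj]} == {"G", "U"}
        # antiparallel: query positions ascend while window positions descend
        assert [qi for qi, _ in pairs] == sorted(qi for qi, _ in pairs)
        assert [tj for _, tj in pairs] == sorted(
            (tj for _, tj in pairs), reverse=True
        )


class TestScanTranscript:
    m = MatureMiRNA("mir-x", "UAGCUUAUCAGACUGAUGUUGA")

    def test_planted_complement_recovered(self, rng):
        tr = rand_rna(rng, 1000)
        site = reverse_complement(self.m.sequence)
        planted = tr[:500] + site + tr[500 + len(site):]
        hit = scan_transcript(self.m, planted)
        assert (hit.t_start, hit.t_end) == (500, 500 + len(site))
        assert hit.q_start == 0 and hit.q_end == len(self.m.sequence)
        # and a random transcript scores strictly worse
        hit_rand = scan_transcript(self.m, tr)
        assert hit_rand.mfe > hit.mfe

    def test_degenerate_window_config(self, rng):
        tr = rand_rna(rng, 40)
        hit_small = scan_transcript(self.m, tr, window=60, step=100)
        mfe_direct, _ = duplex_mfe(self.m.sequence, tr)
        assert hit_small.mfe == pytest.approx(mfe_direct)

    def test_pairing_string_consistent(self, rng):
        tr = rand_rna(rng, 300)
        hit = scan_transcript(self.m, tr)
        if hit.pairs:
            assert hit.pairing_string.count("|") == len(hit.pairs)


class TestDinucleotideShuffle:
    def test_counts_preserved_exactly(self, rng):
        for _ in range(20):
            s = rand_rna(rng, int(rng.integers(20, 300)))
            sh = dinucleotide_shuffle(s, rng)
            assert len(sh) == len(s)
            assert Counter(zip(s, s[1:])) == Counter(zip(sh, sh[1:]))
            assert sh[0] == s[0] and sh[-1] == s[-1]

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValidationError):
            dinucleotide_shuffle("ACGUACG", rng)

    def test_actually_shuffles(self, rng):
        s = rand_rna(rng, 500)
        assert any(dinucleotide_shuffle(s, rng) != s for _ in range(3))


class TestCalibration:
    m = MatureMiRNA("mir-x", "UAGCUUAUCAGACUGAUGUUGA")

    def test_planted_site_has_floor_p(self, rng):
        tr = rand_rna(rng, 600)
        site = reverse_complement(self.m.sequence)
        planted = tr[:300] + site + tr[300 + len(site):]
        cal = calibrate_p(self.m, planted, n_shuffles=100, seed=11)
        assert cal.p_empirical == pytest.approx(1 / 101)
        assert cal.p_gumbel < 0.01

    def test_determinism(self, rng):
        tr = rand_rna(rng, 400)
        c1 = calibrate_p(self.m, tr, n_shuffles=60, seed=5)
        c2 = calibrate_p(self.m, tr, n_shuffles=60, seed=5)
        assert c1.p_empirical == c2.p_empirical
        assert c1.p_gumbel == c2.p_gumbel
        np.testing.assert_array_equal(c1.null_mfes, c2.null_mfes)

    def test_median_observation_has_half_p(self, rng):
        # rank convention: an observation at the null median gets p ~ 0.5
        tr = rand_rna(rng, 400)
        cal = calibrate_p(self.m, tr, n_shuffles=200, seed=9)
        med = float(np.median(cal.null_mfes))
        p_med = (1 + (cal.null_mfes <= med).sum()) / (cal.n_shuffles + 1)
        assert p_med == pytest.approx(0.5, abs=0.07)

    def test_minimum_shuffles_enforced(self, rng):
        with pytest.raises(ConfigurationError):
            calibrate_p(self.m, rand_rna(rng, 100), n_shuffles=10, seed=0)


class TestCandidateFilter:
    def _hit(self, mfe, p, mirna="nuc1", transcript="pri-mat1"):
        return DuplexHit(
            mirna, transcript, 0, 22, 100, 122, mfe, "", [], p_empirical=p,
            p_gumbel=p,
        )

    def _profiles(self):
        stages = ["promyelocyte", "granulocyte"]
        nuc = pd.DataFrame([[1.0, 3.0]], index=["nuc1"], columns=stages)
        mat = pd.DataFrame(
            [[5.0, 2.0], [1.0, 4.0]], index=["mat1", "mat2"], columns=stages
        )
        return nuc, mat

    def test_strong_hit_retained_and_anticorrelated(self):
        nuc, mat = self._profiles()
        out = nuclear_target_candidates(
            [self._hit(-35.2, 0.01)], nuc, mat,
            comparison=("granulocyte", "promyelocyte"),
        )
        assert len(out) == 1
        assert bool(out.iloc[0]["anti_correlated"])  # nuc up, mature down

    def test_mfe_cut_is_strict(self):
        nuc, mat = self._profiles()
        out = nuclear_target_candidates(
            [self._hit(-29.9, 0.01)], nuc, mat,
            comparison=("granulocyte", "promyelocyte"),
        )
        assert out.empty

    def test_same_direction_not_anticorrelated(self):
        nuc, mat = self._profiles()
        out = nuclear_target_candidates(
            [self._hit(-35.0, 0.01, transcript="pri-mat2")], nuc, mat,
            comparison=("granulocyte", "promyelocyte"),
        )
        assert len(out) == 1
        assert not bool(out.iloc[0]["anti_correlated"])  # both trajectories up

    def test_uncalibrated_hit_rejected(self):
        nuc, mat = self._profiles()
        h = self._hit(-35.0, 0.01)
        h.p_empirical = None
        with pytest.raises(ConfigurationError):
            nuclear_target_candidates(
                [h], nuc, mat, comparison=("granulocyte", "promyelocyte")
            )
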