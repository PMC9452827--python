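"""Motif scanning and SNV-induced broken/gained counts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exonskip.motif_scan import (
    MotifDelta,
    MotifSet,
    load_motif_set,
    motif_delta,
    save_motif_set,
    scan_hits,
)

BASES = "ACGT"
dna = st.text(alphabet=BASES, min_size=0, max_size=30)


def kset(*kmers, role="enhancer", name="s"):
    return MotifSet(name=name, role=role, k=len(kmers[0]), entries=frozenset(kmers))


class TestScanHits:
    def test_single_hit_at_reported_offset(self):
        assert scan_hits(kset("GAAGAA"), "TTGAAGAATT") == [(2, "GAAGAA")]

    def test_sequence_shorter_than_k_is_empty(self):
        assert scan_hits(kset("GAAGAA"), "GAAG") == []

    def test_overlapping_occurrences_count_separately(self):
        assert scan_hits(kset("AAA"), "AAAA") == [(0, "AAA"), (1, "AAA")]

    @given(seq=st.text(alphabet=BASES, min_size=3, max_size=12))
    def test_equals_exhaustive_window_enumeration(self, seq):
        mset = kset("ACG", "GGT", "TTA")
        expected = [
            (i, seq[i : i + 3])
            for i in range(len(seq) - 2)
            if seq[i : i + 3] in mset.entries
        ]
        assert scan_hits(mset, seq) == expected

    def test_pwm_kind_thresholds(self):
        # matrix strongly favouring "GAA"; threshold between hit and miss scores
        m = np.full((4, 3), 0.04 / 3)
        for j, b in enumerate("GAA"):
            m[BASES.index(b), j] = 0.96
        m /= m.sum(axis=0)
        mset = MotifSet(
            name="pwm-ese", role="enhancer", k=3, kind="pwm", matrix=m, threshold=3.0
        )
        assert scan_hits(mset, "TTGAATT") == [(2, "pwm-ese")]


class TestMotifDelta:
    def test_no_change_when_alleles_identical(self):
        ese, ess = kset("GAAGAA"), kset("TTTTTT", role="silencer")
        d = motif_delta(ese, ess, "AGAAGAAC", "AGAAGAAC", 3)
        assert d == MotifDelta(0, 0, 0, 0)

    def test_single_planted_enhancer_broken(self):
        # GAAGAA planted at offset 1; mutate its 3rd base (A->C), no new members
        ese, ess = kset("GAAGAA"), kset("CCCCCC", role="silencer")
        d = motif_delta(ese, ess, "TGAAGAAT", "TGACGAAT", 3)
        assert (d.ese_broken, d.ese_gained, d.ess_broken, d.ess_gained) == (1, 0, 0, 0)

    def test_two_broken_enhancers_plus_one_gained_silencer_sums_to_three(self):
        # overlapping enhancers AACTG/ACTGG both span the variant; the
        # substitution C->T destroys both and completes silencer ATTGG... use
        # explicit construction: wt AACTGG, mut AATTGG
        ese = kset("AACTG", "ACTGG")
        ess = kset("AATTG", role="silencer")
        d = motif_delta(ese, ess, "AACTGG", "AATTGG", 2)
        assert d.ese_broken == 2 and d.ess_gained == 1
        assert d.disruption_sum == 3

    def test_hit_not_overlapping_variant_never_counts(self):
        ese, ess = kset("GAA"), kset("CCC", role="silencer")
        # GAA at offset 0 untouched; variant at offset 5
        d = motif_delta(ese, ess, "GAATTTT", "GAATTAT", 5)
        assert d == MotifDelta(0, 0, 0, 0)

    def test_mismatched_window_lengths_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            motif_delta(kset("AAA"), kset("CCC", role="silencer"), "AAAA", "AAA", 1)

    def test_counts_invariant_under_entry_reordering(self):
        entries = ("GAAGAA", "AAGAAG", "TTCTTC")
        wt, mut, off = "TGAAGAAGT", "TGACGAAGT", 3
        ess = kset("CCCCCC", role="silencer")
        d1 = motif_delta(kset(*entries), ess, wt, mut, off)
        d2 = motif_delta(kset(*reversed(entries)), ess, wt, mut, off)
        assert d1 == d2

    def test_motif_in_both_roles_counts_once_per_set(self):
        both = "GAAGAA"
        d = motif_delta(
            kset(both), kset(both, role="silencer"), "TGAAGAAT", "TGACGAAT", 3
        )
        assert d.ese_broken == 1 and d.ess_broken == 1

    @given(
        seq=st.text(alphabet=BASES, min_size=6, max_size=20),
        data=st.data(),
    )
    def test_equals_bruteforce_diff_of_variant_overlapping_hits(self, seq, data):
        """motif_delta on random sequences/sets equals an independent diff of
        scan results restricted to variant-overlapping occurrences."""
        k = 3
        pool = ["".join(p) for p in __import__("itertools").product(BASES, repeat=k)]
        ese_kmers = frozenset(data.draw(st.sets(st.sampled_from(pool), min_size=1, max_size=8)))
        ess_kmers = frozenset(data.draw(st.sets(st.sampled_from(pool), min_size=1, max_size=8)))
        pos = data.draw(st.integers(0, len(seq) - 1))
        alt = data.draw(st.sampled_from([b for b in BASES if b != seq[pos]]))
        mut = seq[:pos] + alt + seq[pos + 1 :]
        ese = MotifSet(name="e", role="enhancer", k=k, entries=ese_kmers)
        ess = MotifSet(name="s", role="silencer", k=k, entries=ess_kmers)
        d = motif_delta(ese, ess, seq, mut, pos)

        def overlap(hits):
            return {(o, m) for o, m in hits if o <= pos <= o + k - 1}

        for mset, broken, gained in (
            (ese, d.ese_broken, d.ese_gained),
            (ess, d.ess_broken, d.ess_gained),
        ):
            wt_hits = overlap(scan_hits(mset, seq))
            mut_hits = overlap(scan_hits(mset, mut))
            assert broken == len(wt_hits - mut_hits)
            assert gained == len(mut_hits - wt_hits)

    def test_disruption_sum_monotone_in_set_growth(self):
        wt, mut, off = "TGAAGAAT", "TGACGAAT", 3
        ess = kset("GACGAA", role="silencer")
        base = motif_delta(kset("GAAGAA"), ess, wt, mut, off).disruption_sum
        bigger = motif_delta(kset("GAAGAA", "AGAAGA"), ess, wt, mut, off).disruption_sum
        assert bigger >= base


def test_motif_set_file_round_trip(tmp_path):
    mset = kset("GAAGAA", "AAGAAG", name="ese-demo")
    p = tmp_path / "ese.txt"
    save_motif_set(mset, p)
    assert load_motif_set(p) == mset


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        MotifDelta(ese_broken=-1)
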