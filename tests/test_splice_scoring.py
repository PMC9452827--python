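"""Splice-site scoring: PWM log-odds, k-mer tables, WT->mutant deltas."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exonskip.splice_scoring import (
    MissingKmerError,
    SpliceSiteModel,
    ZeroBaselineError,
    delta_from_scores,
    load_kmer_table,
    load_pwm_tsv,
    percent_change,
    save_pwm_tsv,
    score_site,
    site_delta,
)

BASES = "ACGT"


def _pwm(matrix, window=None):
    m = np.asarray(matrix, dtype=float)
    return SpliceSiteModel(
        site_type="donor",
        kind="pwm",
        window=window or (0, m.shape[1]),
        matrix=m,
        background=np.full(4, 0.25),
    )


class TestScoreSite:
    def test_uniform_matrix_scores_zero_everywhere(self):
        model = _pwm(np.full((4, 5), 0.25))
        for seq in ("ACGTA", "TTTTT", "GCGCG"):
            assert score_site(model, seq) == pytest.approx(0.0)

    def test_consensus_maximal_and_mismatch_strictly_lower(self):
        # near-one-hot columns for consensus GTAAG
        eps = 1e-3
        cons = "GTAAG"
        m = np.full((4, 5), eps / 3)
        for j, b in enumerate(cons):
            m[BASES.index(b), j] = 1 - eps
        model = _pwm(m)
        best = score_site(model, cons)
        for j in range(5):
            for b in BASES:
                if b == cons[j]:
                    continue
                mut = cons[:j] + b + cons[j + 1 :]
                assert score_site(model, mut) < best

    def test_matches_bruteforce_logodds_on_all_dinucleotides(self):
        """PWM score equals the hand-computed per-position log-odds sum,
        enumerated over all 16 dinucleotide windows."""
        rng = np.random.default_rng(3)
        m = rng.dirichlet(np.ones(4), size=2).T  # (4, 2), columns sum to 1
        bg = np.array([0.3, 0.2, 0.3, 0.2])
        model = SpliceSiteModel(
            site_type="donor", kind="pwm", window=(1, 1), matrix=m, background=bg
        )
        for a, b in itertools.product(BASES, repeat=2):
            expected = math.log2(m[BASES.index(a), 0] / bg[BASES.index(a)]) + math.log2(
                m[BASES.index(b), 1] / bg[BASES.index(b)]
            )
            assert score_site(model, a + b) == pytest.approx(expected, abs=1e-12)

    def test_kmer_lookup_and_missing_entry(self):
        model = SpliceSiteModel(
            site_type="donor", kind="kmer", window=(1, 2),
            table={"AGT": 8.55, "ACT": 2.25},
        )
        assert score_site(model, "agt") == 8.55
        with pytest.raises(MissingKmerError):
            score_site(model, "GGG")

    def test_ambiguous_base_rejected(self):
        model = _pwm(np.full((4, 3), 0.25))
        with pytest.raises(ValueError, match="ambiguous"):
            score_site(model, "ANG")


class TestDeltas:
    @pytest.mark.parametrize(
        "wt,mut,expected_pct",
        [(8.55, 5.41, -36.73), (8.55, 2.25, -73.68), (8.55, 3.78, -55.79)],
    )
    def test_published_donor_score_drops_reproduce_printed_percentages(
        self, wt, mut, expected_pct
    ):
        d = delta_from_scores(wt, mut)
        assert d.flagged_loss
        assert d.percent_change_2dp() == expected_pct

    def test_fixture_scores_reproduce_their_printed_percentages(self):
        from exonskip.fixtures import load_maxent_scores

        for _, row in load_maxent_scores().iterrows():
            assert percent_change(row["wt_score"], row["mut_score"]) == row["printed_pct"]

    def test_identical_windows_give_zero_unflagged_delta(self):
        m = np.tile(np.array([[0.4], [0.3], [0.2], [0.1]]), (1, 4))
        model = _pwm(m)
        d = site_delta(model, "ACGT", "ACGT")
        assert d.delta == 0 and d.percent_change == 0 and not d.flagged_loss

    def test_windows_differing_at_two_positions_rejected(self):
        model = _pwm(np.full((4, 4), 0.25))
        with pytest.raises(ValueError, match="SNV"):
            site_delta(model, "ACGT", "AGCT")

    @pytest.mark.parametrize("wt,mut,expected", [(2.0, 3.0, 50.0), (4.0, 4.0, 0.0)])
    def test_percent_change_formula(self, wt, mut, expected):
        assert percent_change(wt, mut) == expected

    def test_zero_baseline_is_an_error(self):
        with pytest.raises(ZeroBaselineError):
            percent_change(0.0, 3.0)
        assert delta_from_scores(0.0, 3.0).percent_change is None

    @given(wt=st.floats(0.1, 50), mut=st.floats(0.1, 50))
    def test_antisymmetric_under_swap_only_for_equal_scores(self, wt, mut):
        """For positive scores, pc(wt,mut) = -pc(mut,wt) holds exactly when
        the scores coincide: the residual pc(a,b) + pc(b,a) equals
        100·(b-a)^2/(a·b), which is zero iff a = b."""
        pa = 100 * (mut - wt) / wt
        pb = 100 * (wt - mut) / mut
        residual = pa + pb
        assert residual == pytest.approx(100 * (mut - wt) ** 2 / (wt * mut), rel=1e-6)
        if abs(wt - mut) > 1e-6:
            assert residual > 0
        else:
            assert residual == pytest.approx(0.0, abs=1e-6)


def test_destroying_invariant_gt_always_flags_loss():
    """Mutating either base of the invariant GT of a donor window is flagged
    as loss under any PWM trained on GT-containing sites."""
    from exonskip.synthetic import make_donor_pwm

    for seed in (0, 1, 2):
        model = make_donor_pwm(seed)
        wt = "CAGGTAAGT"
        for pos, alts in ((3, "ACT"), (4, "ACG")):  # the G and the T
            for alt in alts:
                mut = wt[:pos] + alt + wt[pos + 1 :]
                assert site_delta(model, wt, mut).flagged_loss


def test_pwm_tsv_round_trip(tmp_path):
    from exonskip.synthetic import make_donor_pwm

    model = make_donor_pwm(5)
    p = tmp_path / "donor.tsv"
    save_pwm_tsv(model, p)
    loaded = load_pwm_tsv(p)
    assert loaded.window == model.window
    np.testing.assert_allclose(loaded.matrix, model.matrix)
    assert score_site(loaded, "CAGGTAAGT") == pytest.approx(
        score_site(model, "CAGGTAAGT")
    )


def test_kmer_table_file(tmp_path):
    p = tmp_path / "table.tsv"
    p.write_text("# donor 3mers\nAGT\t8.55\nACT\t2.25\n")
    model = load_kmer_table(p, site_type="donor", window=(1, 2))
    assert score_site(model, "AGT") == 8.55
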