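"""Synthetic generators: determinism, planted truth, pipeline recovery."""

import numpy as np
import pytest

from exonskip.gene_models import build_model_from_anchors, locate_in_exon
from exonskip.motif_scan import motif_delta, scan_hits
from exonskip.synthetic import (
    PlantedMotif,
    SyntheticGeneSpec,
    digest,
    make_assay_replicates,
    make_motif_sets,
    make_transcript,
    make_variant_cases,
)
from exonskip.triage import context_from_location, select_candidate


class TestMakeTranscript:
    def test_spans_are_cumulative_sums(self):
        st_ = make_transcript(SyntheticGeneSpec("G", (140, 111, 112), seed=1))
        spans = [(e.c_start, e.c_end) for e in st_.model.exons]
        assert spans == [(1, 140), (141, 251), (252, 363)]

    def test_planted_motif_found_where_requested(self, motif_sets):
        ese, _ = motif_sets
        motif = sorted(ese.entries)[0]
        st_ = make_transcript(
            SyntheticGeneSpec(
                "G", (60, 60), planted_motifs=(PlantedMotif(2, 10, motif, "enhancer"),),
                seed=3,
            )
        )
        hits = scan_hits(ese, st_.model.exon(2).sequence)
        assert (10, motif) in hits

    def test_same_seed_identical_output(self):
        spec = SyntheticGeneSpec("G", (80, 90), seed=42)
        a = make_transcript(spec)
        b = make_transcript(spec)
        assert [e.sequence for e in a.model.exons] == [e.sequence for e in b.model.exons]
        assert a.donor_flanks == b.donor_flanks

    def test_different_seeds_differ(self):
        a = make_transcript(SyntheticGeneSpec("G", (200,), seed=1))
        b = make_transcript(SyntheticGeneSpec("G", (200,), seed=2))
        assert digest([a.model.exons[0].sequence]) != digest([b.model.exons[0].sequence])

    def test_conflicting_motif_plants_rejected_naming_both(self):
        with pytest.raises(ValueError, match="collision"):
            make_transcript(
                SyntheticGeneSpec(
                    "G", (30,),
                    planted_motifs=(
                        PlantedMotif(1, 0, "AAAAAA", "enhancer"),
                        PlantedMotif(1, 3, "CCCCCC", "silencer"),
                    ),
                    seed=0,
                )
            )

    def test_planted_strong_donor_has_invariant_gt(self):
        st_ = make_transcript(
            SyntheticGeneSpec("G", (60,), planted_donors={1: "strong"}, seed=5)
        )
        assert st_.donor_window(1)[3:5] == "GT"

    def test_motif_overrunning_exon_rejected(self):
        with pytest.raises(ValueError, match="overruns"):
            SyntheticGeneSpec(
                "G", (10,), planted_motifs=(PlantedMotif(1, 6, "AAAAAA", "enhancer"),)
            )


class TestMakeAssayReplicates:
    def test_zero_noise_returns_truth_exactly(self):
        reps = make_assay_replicates(61.5, 0.0, 5, seed=0)
        assert all(q.exclusion_percent == pytest.approx(61.5) for q in reps)

    def test_sample_mean_near_truth_at_large_n(self):
        n, sd = 10_000, 5.0
        reps = make_assay_replicates(50.0, sd, n, seed=1)
        mean = np.mean([q.exclusion_percent for q in reps])
        assert abs(mean - 50.0) <= 3 * sd / np.sqrt(n)

    def test_values_clipped_to_percent_range(self):
        reps = make_assay_replicates(99.0, 30.0, 200, seed=2)
        assert all(0.0 <= q.exclusion_percent <= 100.0 for q in reps)

    def test_different_seeds_differ(self):
        a = make_assay_replicates(50.0, 2.0, 3, seed=1)
        b = make_assay_replicates(50.0, 2.0, 3, seed=2)
        assert digest([repr(q) for q in a]) != digest([repr(q) for q in b])


class TestGroundTruthRecovery:
    def test_pipeline_reproduces_constructive_labels_exactly(
        self, synthetic_transcript, motif_sets
    ):
        """Running the scanner, filter and consequence predictor on generated
        cases reproduces every construction-time label (exact, all cases)."""
        from exonskip.consequence import skip_exon

        ese, ess = motif_sets
        cases = make_variant_cases(synthetic_transcript, 300, seed=9, ese=ese, ess=ess)
        assert len(cases) == 300
        for case in cases:
            d = motif_delta(ese, ess, case.wt_window, case.mut_window, case.window_offset)
            assert (d.ese_broken, d.ese_gained, d.ess_broken, d.ess_gained) == (
                case.expected_ese_broken,
                case.expected_ese_gained,
                case.expected_ess_broken,
                case.expected_ess_gained,
            )
            ctx = locate_in_exon(case.variant, synthetic_transcript.model)
            assert (ctx.offset5, ctx.offset3) == (case.offset5, case.offset3)
            decision = select_candidate(ctx, d)
            assert decision.selected == case.expected_selected
            assert decision.by_proximity == case.expected_by_proximity
            assert decision.by_regulatory == case.expected_by_regulatory
            cons = skip_exon(synthetic_transcript.model, case.exon_number)
            assert cons.frame_preserved == case.expected_frame_preserved
            assert cons.aa_lost == case.expected_aa_lost

    def test_anchor_round_trip_rebuilds_identical_spans(
        self, synthetic_transcript, motif_sets
    ):
        """Anchors extracted from generated variants rebuild the generated model."""
        ese, ess = motif_sets
        cases = make_variant_cases(synthetic_transcript, 80, seed=4, ese=ese, ess=ess)
        anchors = []
        for case in cases:
            ctx = context_from_location
            loc = case.offset5 if case.offset5 <= case.offset3 else -case.offset3
            anchors.append((case.variant.label, case.exon_number, case.exon_length, loc))
        rebuilt = build_model_from_anchors(anchors, gene_id="SYN1")
        seen = {e.exon_number for e in rebuilt.exons}
        for e in synthetic_transcript.model.exons:
            if e.exon_number in seen:
                r = rebuilt.exon(e.exon_number)
                assert (r.c_start, r.c_end) == (e.c_start, e.c_end)
        assert seen  # at least one exon anchored
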