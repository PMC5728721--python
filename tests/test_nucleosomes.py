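"""Peak calling, reciprocal-overlap classification, dyads and feature filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucmeth import nucleosomes
from nucmeth.errors import InvalidConfigError
from nucmeth.nucleosomes import GROUP_OTHER


def _frags(mids, length=147, chrom="chr1"):
    mids = np.asarray(mids)
    return pd.DataFrame({"chrom": chrom, "start": mids - length // 2,
                         "end": mids - length // 2 + length})


def _peaks(intervals, chrom="chr1"):
    return pd.DataFrame([{"chrom": chrom, "start": s, "end": e,
                          "summit": (s + e) // 2} for s, e in intervals])


class TestFragmentFilter:
    @pytest.mark.parametrize("length,kept", [
        (120, False), (121, True), (179, True), (180, False)])
    def test_exclusive_length_bounds(self, length, kept):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                              "end": [length]})
        assert len(nucleosomes.filter_fragments(frags)) == int(kept)

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        assert nucleosomes.filter_fragments(empty).empty


class TestCallPeaks:
    def test_delta_input_single_summit(self):
        peaks = nucleosomes.call_peaks(_frags([500] * 1000))
        assert len(peaks) == 1
        assert peaks.iloc[0]["summit"] == 500
        assert peaks.iloc[0]["start"] <= 500 < peaks.iloc[0]["end"]

    def test_two_clusters_two_summits(self):
        rng = np.random.default_rng(0)
        mids = np.concatenate([
            np.rint(rng.normal(400, 5, 500)),
            np.rint(rng.normal(600, 5, 500)),
        ]).astype(int)
        peaks = nucleosomes.call_peaks(_frags(mids), bandwidth=20)
        assert len(peaks) == 2
        assert abs(peaks.iloc[0]["summit"] - 400) <= 2
        assert abs(peaks.iloc[1]["summit"] - 600) <= 2

    def test_no_fragments_no_peaks(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        assert nucleosomes.call_peaks(empty).empty

    def test_rejects_nonpositive_bandwidth(self):
        with pytest.raises(InvalidConfigError):
            nucleosomes.call_peaks(_frags([500]), bandwidth=0)


class TestWidthFilter:
    @pytest.mark.parametrize("width,kept", [(140, True), (141, False)])
    def test_boundary(self, width, kept):
        peaks = _peaks([(0, width)])
        assert len(nucleosomes.filter_peak_width(peaks)) == int(kept)

    def test_empty(self):
        assert nucleosomes.filter_peak_width(
            pd.DataFrame(columns=["chrom", "start", "end"])).empty


class TestReciprocalOverlap:
    def test_identity(self):
        a = {"chrom": "chr1", "start": 100, "end": 240}
        assert nucleosomes.reciprocal_overlap(a, a) == (1.0, 1.0)

    def test_hand_computed_fractions(self):
        a = {"chrom": "chr1", "start": 100, "end": 240}
        b = {"chrom": "chr1", "start": 110, "end": 250}
        fa, fb = nucleosomes.reciprocal_overlap(a, b)
        assert fa == pytest.approx(130 / 140)
        assert fb == pytest.approx(130 / 140)

    def test_disjoint(self):
        a = {"chrom": "chr1", "start": 0, "end": 100}
        b = {"chrom": "chr1", "start": 200, "end": 300}
        assert nucleosomes.reciprocal_overlap(a, b) == (0.0, 0.0)

    def test_different_chromosome_rejected(self):
        a = {"chrom": "chr1", "start": 0, "end": 100}
        b = {"chrom": "chr2", "start": 0, "end": 100}
        with pytest.raises(ValueError):
            nucleosomes.reciprocal_overlap(a, b)

    @given(st.integers(0, 500), st.integers(1, 200),
           st.integers(0, 500), st.integers(1, 200))
    @settings(derandomize=True, max_examples=50)
    def test_symmetry(self, s1, w1, s2, w2):
        a = {"chrom": "chr1", "start": s1, "end": s1 + w1}
        b = {"chrom": "chr1", "start": s2, "end": s2 + w2}
        fa, fb = nucleosomes.reciprocal_overlap(a, b)
        gb, ga = nucleosomes.reciprocal_overlap(b, a)
        assert fa == pytest.approx(ga) and fb == pytest.approx(gb)


class TestComputeDyad:
    def test_single_peak_midpoint(self):
        assert nucleosomes.compute_dyad([(100, 240)]) == 170

    def test_union_span_midpoint(self):
        assert nucleosomes.compute_dyad([(100, 240), (110, 250)]) == 175

    def test_invariant_to_multiplicity(self):
        assert nucleosomes.compute_dyad([(0, 140)] * 3) == 70

    def test_endpoint_mean_differs_for_asymmetric_overlap(self):
        members = [(100, 240), (110, 250), (112, 252)]
        union = nucleosomes.compute_dyad(members, method="union_span")
        mean = nucleosomes.compute_dyad(members, method="endpoint_mean")
        assert union == 176 and mean != union

    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError):
            nucleosomes.compute_dyad([])


class TestClassifyPositioning:
    def test_high_overlap_is_group_one(self):
        rep1 = _peaks([(100, 240)])
        rep2 = _peaks([(110, 250)])  # min fraction ~0.93
        calls = nucleosomes.classify_positioning(rep1, rep2)
        assert calls.iloc[0]["group"] == 1
        assert calls.iloc[0]["dyad"] == 175

    def test_exact_threshold_falls_to_lower_group(self):
        # overlap 105 of width 140 on both sides: exactly 0.75 -> group 2
        rep1 = _peaks([(0, 140)])
        rep2 = _peaks([(35, 175)])
        calls = nucleosomes.classify_positioning(rep1, rep2)
        assert calls.iloc[0]["best_overlap"] == pytest.approx(0.75)
        assert calls.iloc[0]["group"] == 2

    def test_no_overlap_is_other(self):
        calls = nucleosomes.classify_positioning(
            _peaks([(0, 140)]), _peaks([(1000, 1140)]))
        assert calls.iloc[0]["group"] == GROUP_OTHER

    def test_partition_is_exhaustive(self, small_fragments):
        reps = [nucleosomes.filter_peak_width(nucleosomes.call_peaks(
            nucleosomes.filter_fragments(f))) for f in small_fragments]
        calls = nucleosomes.classify_positioning(reps[0], reps[1])
        assert len(calls) == len(reps[0])
        assert calls["group"].isin([0, 1, 2, 3, 4]).all()

    def test_dyad_strictly_inside_union_span(self, small_fragments):
        reps = [nucleosomes.filter_peak_width(nucleosomes.call_peaks(
            nucleosomes.filter_fragments(f))) for f in small_fragments]
        calls = nucleosomes.classify_positioning(reps[0], reps[1])
        assert ((calls["dyad"] > calls["start"])
                & (calls["dyad"] < calls["end"])).all()

    def test_multiple_overlaps_widen_the_union_span(self):
        rep1 = _peaks([(100, 240)])
        rep2 = _peaks([(60, 180), (170, 300)])
        calls = nucleosomes.classify_positioning(rep1, rep2)
        assert calls.iloc[0]["start"] == 60
        assert calls.iloc[0]["end"] == 300
        assert calls.iloc[0]["dyad"] == 180


class TestSharedNucleosomes:
    def _calls(self, dyads):
        return pd.DataFrame({"chrom": "chr1", "dyad": dyads})

    @pytest.mark.parametrize("da,db,shared", [
        (100, 120, True), (100, 121, False), (100, 100, True)])
    def test_distance_boundary_inclusive(self, da, db, shared):
        pairs = nucleosomes.shared_nucleosomes(self._calls([da]),
                                               self._calls([db]))
        assert len(pairs) == int(shared)

    def test_each_call_matched_at_most_once(self):
        pairs = nucleosomes.shared_nucleosomes(self._calls([100, 110]),
                                               self._calls([105]))
        assert len(pairs) == 1
        assert pairs.iloc[0]["dyad_a"] == 100  # nearest, ties leftmost


class TestGenicClassification:
    def _parts(self):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": [0, 500, 900],
            "end": [500, 900, 1400],
            "kind": ["exon", "intron", "exon"],
            "gene_id": "g",
        })

    def test_one_bp_exon_overlap_is_exonic(self):
        calls = pd.DataFrame({"chrom": ["chr1"], "start": [499],
                              "end": [640], "dyad": [570]})
        labels = nucleosomes.classify_genic_nucleosomes(calls, self._parts())
        assert labels.iloc[0] == "exonic"

    def test_fully_intronic(self):
        calls = pd.DataFrame({"chrom": ["chr1"], "start": [600],
                              "end": [747], "dyad": [673]})
        labels = nucleosomes.classify_genic_nucleosomes(calls, self._parts())
        assert labels.iloc[0] == "intronic"

    def test_junction_spanning_is_exonic(self):
        calls = pd.DataFrame({"chrom": ["chr1"], "start": [850],
                              "end": [997], "dyad": [923]})
        labels = nucleosomes.classify_genic_nucleosomes(calls, self._parts())
        assert labels.iloc[0] == "exonic"

    def test_outside_genes_unlabeled(self):
        calls = pd.DataFrame({"chrom": ["chr2"], "start": [0],
                              "end": [147], "dyad": [73]})
        labels = nucleosomes.classify_genic_nucleosomes(calls, self._parts())
        assert labels.iloc[0] is None


class TestHeterochromaticTeFilter:
    def _tes(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "feature_id", "mcg", "h3k9me2"])

    def test_passing_te_retained(self):
        tes = self._tes([("chr1", 0, 100, "te1", 0.06, 9.0),
                         ("chr1", 200, 300, "te2", 0.50, 1.0),
                         ("chr1", 400, 500, "te3", 0.50, 2.0),
                         ("chr1", 600, 700, "te4", 0.50, 3.0),
                         ("chr1", 800, 900, "te5", 0.50, 4.0)])
        kept = nucleosomes.filter_heterochromatic_tes(tes)
        assert "te1" in kept["feature_id"].tolist()  # top quintile, mCG 6%

    def test_length_exactly_30_excluded(self):
        tes = self._tes([("chr1", 0, 30, "te1", 0.5, 9.0)])
        assert nucleosomes.filter_heterochromatic_tes(tes).empty

    def test_low_mcg_excluded(self):
        tes = self._tes([("chr1", 0, 100, "te1", 0.04, 9.0)])
        assert nucleosomes.filter_heterochromatic_tes(tes).empty

    def test_missing_score_names_te(self):
        tes = self._tes([("chr1", 0, 100, "te1", np.nan, 9.0)])
        with pytest.raises(InvalidConfigError, match="te1"):
            nucleosomes.filter_heterochromatic_tes(tes)
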