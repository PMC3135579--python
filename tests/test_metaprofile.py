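import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirchrom import (
    CoverageTrack,
    GenomicInterval,
    GenomeSequence,
    ProfileParams,
    center_of,
    content_profile,
    extract_window,
    mean_profile,
    sequence_content,
    smooth_profile,
)
from mirchrom.errors import ValidationError
from mirchrom.metaprofile import content_metaprofile, rolling_content, window_offsets

PARAMS = ProfileParams()


def brute_force_smooth(vector, params=PARAMS):
    """Independent nested-loop oracle for the sliding-window smoothing.

    Window j covers bases [j*step, (j+1)*step); its smoothed value is the
    mean of the smooth_span bases centered on that window, truncated at
    the vector bounds.
    """
    step, span = params.slide_step, params.smooth_span
    out = []
    for j in range(len(vector) // step):
        mid2 = 2 * j * step + step  # twice the continuous window midpoint
        lo = max((mid2 - span) // 2, 0)
        hi = min((mid2 + span) // 2, len(vector))
        total, count = 0.0, 0
        for i in range(lo, hi):
            total += vector[i]
            count += 1
        out.append(total / count)
    return np.array(out)


def test_center_of():
    assert center_of(GenomicInterval("chr1", 100, 170)) == 135
    assert center_of(GenomicInterval("chr1", 0, 2)) == 1
    assert center_of(GenomicInterval("chr1", 10, 11)) == 10


class TestExtractWindow:
    def test_constant_track(self, constant_track):
        vec = extract_window(constant_track(5.0), "chr1", 10_000)
        assert vec.shape == (2000,)
        assert np.all(vec == 5.0)

    def test_minus_strand_reverses(self, random_track):
        track = random_track(0)
        plus = extract_window(track, "chr1", 10_000, "+")
        minus = extract_window(track, "chr1", 10_000, "-")
        assert np.array_equal(minus, plus[::-1])

    def test_boundary_zero_fill(self, constant_track):
        track = constant_track(2.0, length=1000)
        vec = extract_window(track, "chr1", 100)
        # window spans [-900, 1100): first 900 positions are off-chromosome
        assert np.all(vec[:900] == 0.0)
        assert np.all(vec[900:1900] == 2.0)

    def test_unknown_chromosome_rejected(self, constant_track):
        with pytest.raises(ValidationError):
            extract_window(constant_track(1.0), "chrZ", 10_000)


class TestSmoothing:
    def test_constant_is_fixed_point(self):
        out = smooth_profile(np.full(2000, 5.0))
        assert np.allclose(out, 5.0)
        assert out.shape == (200,)

    def test_linear_ramp_returns_window_centers(self):
        """On score(i)=i the smoothed value is the mean base position of
        each 10-nt window (j*10 + 4.5) wherever the neighborhood is interior."""
        out = smooth_profile(np.arange(2000, dtype=float))
        j = np.arange(20, 180)  # interior windows
        assert np.allclose(out[j], j * 10 + 4.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        vec = rng.uniform(0, 10, size=2000)
        assert np.allclose(smooth_profile(vec), brute_force_smooth(vec), atol=1e-12)

    def test_truncation_at_edges_matches_oracle(self):
        rng = np.random.default_rng(43)
        vec = rng.uniform(0, 10, size=200)  # every window near an edge
        assert np.allclose(smooth_profile(vec), brute_force_smooth(vec), atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 10_000),
    )
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 3, size=300)
        y = rng.uniform(0, 3, size=300)
        lhs = smooth_profile(a * x + b * y)
        rhs = a * smooth_profile(x) + b * smooth_profile(y)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError):
            smooth_profile(np.array([]))

    def test_offsets_symmetric_about_zero(self):
        offsets = window_offsets(PARAMS)
        assert np.allclose(offsets, -offsets[::-1])


class TestMeanProfile:
    def test_single_feature_equals_its_window(self, random_track):
        track = random_track(1)
        prof = mean_profile([("chr1", 10_000, "+")], track)
        expected = smooth_profile(extract_window(track, "chr1", 10_000))
        assert np.array_equal(prof.mean, expected)
        assert prof.n_features == 1

    def test_two_constant_features_average(self):
        track = CoverageTrack(
            {"chr1": np.full(20_000, 2.0), "chr2": np.full(20_000, 4.0)}
        )
        prof = mean_profile([("chr1", 10_000, "+"), ("chr2", 10_000, "+")], track)
        assert np.allclose(prof.mean, 3.0)

    def test_duplicated_features_leave_mean_unchanged(self, random_track):
        track = random_track(2)
        feats = [("chr1", 9_000, "+"), ("chr1", 12_000, "-")]
        single = mean_profile(feats, track)
        tripled = mean_profile(feats * 3, track)
        assert np.allclose(single.mean, tripled.mean)
        assert tripled.n_features == 6

    def test_zero_features_rejected(self, random_track):
        with pytest.raises(ValidationError):
            mean_profile([], random_track(3))


class TestSequenceContent:
    def test_all_gc_window(self):
        assert sequence_content("GC" * 50, "gc") == 1.0

    def test_fractional_gc(self):
        seq = "G" * 37 + "A" * 63
        assert sequence_content(seq, "gc") == 37 / 100

    def test_at_dinucleotide_enumeration(self):
        assert sequence_content("ATAT", "at_dinucleotide") == 1.0  # AT, TA, AT

    def test_n_bases_excluded_from_both_counts(self):
        assert sequence_content("GCNN", "gc") == 1.0
        assert np.isnan(sequence_content("NNNN", "gc"))

    def test_gc_plus_at_is_exactly_one(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=100))
            assert sequence_content(seq, "gc") + sequence_content(seq, "at") == 1.0

    def test_dinucleotide_reverse_complement_invariance(self):
        comp = str.maketrans("ACGT", "TGCA")
        rng = np.random.default_rng(10)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=100))
            rc = seq.translate(comp)[::-1]
            for pattern in ("gc_dinucleotide", "at_dinucleotide"):
                assert sequence_content(seq, pattern) == sequence_content(rc, pattern)


class TestContentProfile:
    def test_rolling_matches_per_window_counting(self, tiny_genome):
        seq = tiny_genome.fetch("chr1", 0, 500)
        rolled = rolling_content(seq, "gc", 100)
        for i in range(60, 440, 7):
            window = seq[i - 50 : i + 50]
            assert rolled[i] == pytest.approx(sequence_content(window, "gc"), abs=1e-12)

    def test_profile_window_alignment(self, tiny_genome):
        vec = content_profile(tiny_genome, "chr1", 10_000, "+", "gc")
        assert vec.shape == (2000,)
        window = tiny_genome.fetch("chr1", 10_000 - 50, 10_000 + 50)
        assert vec[1000] == pytest.approx(sequence_content(window, "gc"), abs=1e-12)

    def test_minus_strand_reverses_axis(self, tiny_genome):
        plus = content_profile(tiny_genome, "chr1", 10_000, "+", "gc")
        minus = content_profile(tiny_genome, "chr1", 10_000, "-", "gc")
        assert np.array_equal(minus, plus[::-1])

    def test_gc_and_at_profiles_sum_to_one(self, tiny_genome):
        gc = content_profile(tiny_genome, "chr1", 10_000, "+", "gc")
        at = content_profile(tiny_genome, "chr1", 10_000, "+", "at")
        assert np.all(gc + at == 1.0)

    def test_chromosome_edge_yields_nan_not_error(self, tiny_genome):
        vec = content_profile(tiny_genome, "chr1", 100, "+", "gc")
        assert np.isnan(vec[0])  # window entirely off-chromosome
        assert not np.isnan(vec[-1])

    def test_metaprofile_mean_ignores_nan(self, tiny_genome):
        class FakeAnn:
            def __init__(self, center):
                self.locus = GenomicInterval("chr1", center - 40, center + 40, "+")

        prof = content_metaprofile([FakeAnn(100), FakeAnn(10_000)], tiny_genome, "gc")
        assert not np.isnan(prof.mean[-1])
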