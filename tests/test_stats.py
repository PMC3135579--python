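from itertools import combinations, product

import numpy as np
import pytest

from mirchrom import (
    CoverageTrack,
    GenomicInterval,
    GenomeSequence,
    kendall_tau,
    occupancy_density,
    occupancy_histogram,
    rank_sum_test,
    wilcoxon_signed_rank,
)
from mirchrom.classify import MiRNAAnnotation
from mirchrom.errors import ValidationError
from mirchrom.stats import gc_quintile_bins, _split_sizes


# ---------------------------------------------------------------- oracles

def signed_rank_enumeration_p(diffs, alternative="two-sided"):
    """Exact signed-rank p by full enumeration of all 2^n sign vectors.

    Valid for tie-free, zero-free differences (ranks = rank of |d|).
    """
    d = np.asarray(diffs, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    n = d.size
    count_ge = count_le = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        count_ge += w >= w_obs
        count_le += w <= w_obs
    total = 2 ** n
    if alternative == "greater":
        return count_ge / total
    if alternative == "less":
        return count_le / total
    return min(1.0, 2 * min(count_ge, count_le) / total)


def rank_sum_enumeration_p(x, y, alternative="two-sided"):
    """Exact Mann-Whitney p by enumeration of all C(n+m,n) labelings."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    order = np.argsort(np.argsort(pooled)) + 1  # ranks, tie-free input
    n = x.size
    u_obs = order[:n].sum() - n * (n + 1) / 2
    total = count_ge = count_le = 0
    all_ranks = order
    for subset in combinations(range(pooled.size), n):
        u = all_ranks[list(subset)].sum() - n * (n + 1) / 2
        total += 1
        count_ge += u >= u_obs
        count_le += u <= u_obs
    if alternative == "greater":
        return count_ge / total
    if alternative == "less":
        return count_le / total
    return min(1.0, 2 * min(count_ge, count_le) / total)


def kendall_pair_count_tau(x, y):
    """tau-b by O(n^2) concordant/discordant/tie counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    concordant = discordant = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    # pairs tied in x (incl. both) / in y (incl. both)
    n1 = sum(c * (c - 1) / 2 for c in np.unique(x, return_counts=True)[1])
    n2 = sum(c * (c - 1) / 2 for c in np.unique(y, return_counts=True)[1])
    return (concordant - discordant) / np.sqrt((n0 - n1) * (n0 - n2))


# ---------------------------------------------------------------- tests

class TestSignedRank:
    def test_worked_example(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert res.statistic == 15.0
        assert res.p_value == 2 / 32
        assert res.exact and res.n == 5

    def test_identical_samples_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.p_value == 1.0

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([1, 2, 3, 7, 7], [0, 0, 0, 7, 7])
        assert res.n == 3

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_enumeration_on_seeded_pairs(self, alternative):
        rng = np.random.default_rng(202)
        for _ in range(5):
            d = rng.normal(0, 1, size=12)
            x, y = d, np.zeros(12)
            res = wilcoxon_signed_rank(x, y, alternative)
            assert res.exact
            assert res.p_value == pytest.approx(
                signed_rank_enumeration_p(d, alternative), abs=1e-12
            )

    def test_large_or_tied_samples_use_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1, 1, size=40)
        res = wilcoxon_signed_rank(x, np.zeros(40))
        assert not res.exact
        tied = wilcoxon_signed_rank([1, 2, 2, 3], [0, 0, 0, 0])
        assert not tied.exact

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([1, 2], [1])


class TestRankSum:
    def test_worked_example(self):
        res = rank_sum_test([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)
        assert res.exact

    def test_identical_groups_give_p_one(self):
        res = rank_sum_test([1.0, 2.0], [1.0, 2.0])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_enumeration_on_seeded_groups(self, alternative):
        rng = np.random.default_rng(77)
        for _ in range(5):
            x = rng.normal(0, 1, size=5)
            y = rng.normal(0.5, 1, size=5)
            res = rank_sum_test(x, y, alternative)
            assert res.exact
            assert res.p_value == pytest.approx(
                rank_sum_enumeration_p(x, y, alternative), abs=1e-12
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])


class TestKendall:
    def test_perfect_concordance(self):
        assert kendall_tau([1, 2, 3], [1, 2, 3]).statistic == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert kendall_tau([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_matches_pair_count_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 8, size=30).astype(float)
            y = rng.integers(0, 8, size=30).astype(float)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                continue
            res = kendall_tau(x, y)
            assert res.statistic == pytest.approx(kendall_pair_count_tau(x, y), abs=1e-12)
            assert -1.0 <= res.statistic <= 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        x = rng.permutation(20).astype(float)
        y = rng.permutation(20).astype(float)
        assert kendall_tau(x, -y).statistic == pytest.approx(
            -kendall_tau(x, y).statistic, abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            kendall_tau([1, 1, 1], [1, 2, 3])


class TestGCQuintiles:
    def _annotations(self, n, length=80, spacing=2_000, offset=5_000):
        anns = []
        for i in range(n):
            start = offset + i * spacing
            anns.append(
                MiRNAAnnotation(
                    mirna_id=f"m{i}",
                    locus=GenomicInterval("chr1", start, start + length, "+"),
                    positional_class="intergenic",
                )
            )
        return anns

    def _genome_with_gc_gradient(self, n):
        """Locus i gets GC fraction ~ i/n in its 400-nt core."""
        length = 10_000 + n * 2_000
        rng = np.random.default_rng(12)
        seq = list("".join(rng.choice(list("AT"), size=length)))
        anns = self._annotations(n)
        for i, ann in enumerate(anns):
            c = (ann.locus.start + ann.locus.end) // 2
            gc_frac = (i + 1) / (n + 1)
            core = rng.choice(list("GC"), size=400, p=[0.5, 0.5])
            keep = rng.random(400) < gc_frac
            for k, pos in enumerate(range(c - 200, c + 200)):
                if keep[k]:
                    seq[pos] = core[k]
        return GenomeSequence({"chr1": "".join(seq)}), anns, length

    def test_sizes_differ_by_at_most_one(self):
        assert _split_sizes(10, 5) == [2, 2, 2, 2, 2]
        assert _split_sizes(12, 5) == [3, 3, 2, 2, 2]

    def test_distinct_scores_preserve_order(self, constant_track):
        genome, anns, length = self._genome_with_gc_gradient(10)
        bins = gc_quintile_bins(anns, genome, constant_track(1.0, length=length))
        assert [len(b["members"]) for b in bins] == [2, 2, 2, 2, 2]
        mean_gc = [b["mean_gc"] for b in bins]
        assert mean_gc == sorted(mean_gc)
        # bins are contiguous in GC: ranges must not overlap
        for lo_bin, hi_bin in zip(bins, bins[1:]):
            assert lo_bin["gc_range"][1] <= hi_bin["gc_range"][0]

    def test_membership_invariant_to_input_order(self, constant_track):
        genome, anns, length = self._genome_with_gc_gradient(12)
        track = constant_track(1.0, length=length)
        bins_fwd = gc_quintile_bins(anns, genome, track)
        bins_rev = gc_quintile_bins(anns[::-1], genome, track)
        for a, b in zip(bins_fwd, bins_rev):
            assert {m.mirna_id for m in a["members"]} == {m.mirna_id for m in b["members"]}

    def test_occupancy_coupled_to_gc_is_monotone(self):
        genome, anns, length = self._genome_with_gc_gradient(25)
        from mirchrom.metaprofile import rolling_content

        gc100 = np.nan_to_num(
            rolling_content(genome.fetch("chr1", 0, length), "gc", 100)
        )
        track = CoverageTrack({"chr1": 10.0 * gc100})
        bins = gc_quintile_bins(anns, genome, track)
        core = []
        from mirchrom import core_mean

        for b in bins:
            vals = [
                core_mean(track, GenomicInterval(
                    "chr1",
                    (m.locus.start + m.locus.end) // 2 - 200,
                    (m.locus.start + m.locus.end) // 2 + 200,
                ))
                for m in b["members"]
            ]
            core.append(np.mean(vals))
        assert all(a < b for a, b in zip(core, core[1:]))

    def test_too_few_features_rejected(self, constant_track):
        genome, anns, length = self._genome_with_gc_gradient(10)
        with pytest.raises(ValidationError):
            gc_quintile_bins(anns[:4], genome, constant_track(1.0, length=length))


class TestDensity:
    def test_density_is_sum_over_length(self, constant_track):
        arr = np.zeros(1_000)
        arr[100:170] = 10.0
        track = CoverageTrack({"chr1": arr})
        records, _, _ = occupancy_density(
            {"pre-miRNA": [("m1", GenomicInterval("chr1", 100, 170))]}, track
        )
        assert records[0].density == pytest.approx(10.0)

    def test_constant_track_density_independent_of_length(self, constant_track):
        track = constant_track(4.0)
        features = {
            "exon": [("e1", GenomicInterval("chr1", 0, 100)),
                     ("e2", GenomicInterval("chr1", 500, 5_000))],
        }
        records, summaries, _ = occupancy_density(features, track)
        assert all(r.density == 4.0 for r in records)
        assert summaries["exon"]["mean"] == 4.0

    def test_identical_distributions_give_p_one(self, constant_track):
        track = constant_track(2.0)
        features = {
            "pre-miRNA": [("m1", GenomicInterval("chr1", 0, 70)),
                          ("m2", GenomicInterval("chr1", 200, 280))],
            "exon": [("e1", GenomicInterval("chr1", 400, 500)),
                     ("e2", GenomicInterval("chr1", 600, 800))],
        }
        _, _, tests = occupancy_density(features, track)
        assert tests[("pre-miRNA", "exon")].p_value == 1.0


class TestHistogram:
    def _anns(self, centers):
        return [
            MiRNAAnnotation(
                mirna_id=f"m{i}",
                locus=GenomicInterval("chr1", c - 40, c + 40, "+"),
                positional_class="intergenic",
            )
            for i, c in enumerate(centers)
        ]

    def test_single_bin_captures_all(self, constant_track):
        edges, pct = occupancy_histogram(
            self._anns([5_000]), constant_track(5.0), bin_edges=[0, 10]
        )
        assert pct.tolist() == [100.0]

    def test_binning_percentages(self):
        arr = np.zeros(30_000)
        arr[4_800:5_200] = 1.0
        arr[9_800:10_200] = 1.0
        arr[14_800:15_200] = 3.0
        track = CoverageTrack({"chr1": arr})
        edges, pct = occupancy_histogram(
            self._anns([5_000, 10_000, 15_000]), track, bin_edges=[0, 2, 4]
        )
        assert pct == pytest.approx([200 / 3, 100 / 3])
        assert pct.sum() == pytest.approx(100.0)

    def test_empty_features_rejected(self, constant_track):
        with pytest.raises(ValidationError):
            occupancy_histogram([], constant_track(1.0))

    def test_nonmonotone_edges_rejected(self, constant_track):
        with pytest.raises(ValidationError):
            occupancy_histogram(self._anns([5_000]), constant_track(1.0),
                                bin_edges=[0, 2, 2])
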