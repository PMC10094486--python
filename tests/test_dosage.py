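"""G-test dosage genotyping, fragment segmentation and HE calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyhex.dosage import (
    GENOTYPE_LABELS,
    bin_sites,
    call_he,
    expected_fraction,
    g_stat,
    genotype_bin,
    genotype_bins,
    segment_fragments,
    window_he_frequency,
)


def brute_force_genotype(a, b, eps):
    """Independent oracle: argmax binomial log-likelihood over the five
    dosage hypotheses, with the same deterministic tie preference."""
    best, best_ll = None, -math.inf
    for d in (2, 1, 3, 0, 4):
        p = expected_fraction(d, eps)
        ll = a * math.log(p) + b * math.log(1 - p)
        if ll > best_ll:
            best, best_ll = d, ll
    return best


class TestGStat:
    def test_perfect_fit_gives_zero(self):
        assert g_stat(10, 10, 2) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "a,b,d,expected",
        [
            (20, 20, 3, 11.50728),  # 2*(20 ln(20/30) + 20 ln(20/10))
            (0, 40, 0, 0.40100),    # 2*40*ln(40/39.8) at eps=0.005
        ],
    )
    def test_formula_examples(self, a, b, d, expected):
        assert g_stat(a, b, d, 0.005) == pytest.approx(expected, abs=1e-4)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            g_stat(0, 0, 2)

    @given(
        a=st.integers(0, 400),
        b=st.integers(0, 400),
        d=st.sampled_from([0, 1, 2, 3, 4]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_nonnegative_and_zero_iff_exact(self, a, b, d):
        if a + b == 0:
            return
        g = g_stat(a, b, d, 0.005)
        assert g >= -1e-12
        exact = a / (a + b) == expected_fraction(d, 0.005)
        assert (abs(g) < 1e-9) == exact


class TestGenotypeBin:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(20, 20, 2), (33, 7, 3), (1, 39, 0), (0, 40, 0), (40, 0, 4), (10, 30, 1)],
    )
    def test_examples(self, a, b, expected):
        d, g, p = genotype_bin(a, b, 0.005)
        assert d == expected
        assert g >= 0 and 0 < p <= 1

    def test_matches_likelihood_oracle_small_grid(self):
        eps = 0.005
        for n in range(1, 41):
            for a in range(n + 1):
                d, _, _ = genotype_bin(a, n - a, eps)
                assert d == brute_force_genotype(a, n - a, eps), (a, n - a)

    def test_tie_breaks_toward_2_2(self):
        # a == b fits 2:2 exactly; degenerate single-read bins prefer the
        # least extreme hypothesis consistent with the data
        assert genotype_bin(5, 5)[0] == 2


class TestBinSites:
    @staticmethod
    def panel(n, chrom="Chr01"):
        return pd.DataFrame({"chrom": chrom, "pos": np.arange(1, n + 1) * 100})

    @pytest.mark.parametrize(
        "n_sites,n_bins,last_size",
        [(100, 10, 10), (104, 10, 14), (107, 11, 7), (10, 1, 10)],
    )
    def test_partial_bin_rule(self, n_sites, n_bins, last_size):
        bins = bin_sites(self.panel(n_sites), k=10)
        assert len(bins) == n_bins
        assert bins["n_sites"].iloc[-1] == last_size
        assert bins["n_sites"].sum() == n_sites

    def test_short_chromosome_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            bins = bin_sites(self.panel(7), k=10)
        assert bins.empty

    def test_bin_spans_follow_site_positions(self):
        bins = bin_sites(self.panel(20), k=10)
        assert bins.loc[0, "start_pos"] == 100
        assert bins.loc[0, "end_pos"] == 1000
        assert bins.loc[1, "start_pos"] == 1100


def _bins_frame(genotypes, chrom="Chr01", span=1000):
    """Bin table with the given dosage sequence and regular coordinates."""
    n = len(genotypes)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "bin": np.arange(n),
            "start_pos": np.arange(n) * span + 1,
            "end_pos": (np.arange(n) + 1) * span,
            "n_sites": 10,
            "i0": np.arange(n) * 10,
            "i1": (np.arange(n) + 1) * 10,
            "a": 0.0,
            "b": 0.0,
            "dosage": genotypes,
            "G": 0.0,
            "p": 1.0,
        }
    )


class TestSegmentFragments:
    def test_single_genotype_single_fragment(self):
        frags = segment_fragments(_bins_frame([2] * 10))
        assert len(frags) == 1
        assert frags.loc[0, "n_bins"] == 10
        assert call_he(frags).empty

    def test_island_removed_and_flanks_remerged(self):
        frags = segment_fragments(_bins_frame([2] * 8 + [3] * 3 + [2] * 9))
        assert len(frags) == 1
        assert frags.loc[0, "genotype"] == "2:2"
        assert frags.loc[0, "n_bins"] == 20  # absorbed island counts

    def test_island_between_different_flanks_becomes_he_gap(self):
        frags = segment_fragments(_bins_frame([2] * 6 + [1] * 2 + [3] * 6))
        assert list(frags["genotype"]) == ["2:2", "3:1"]
        he = call_he(frags)
        assert len(he) == 1
        # the 2 removed bins (bins 6-7) fall inside the HE interval
        assert he.loc[0, "start"] == 6 * 1000  # last SNP of left fragment
        assert he.loc[0, "end"] == 8 * 1000 + 1  # first SNP of right fragment

    def test_all_fragments_removed_warns(self):
        with pytest.warns(UserWarning, match="shorter"):
            frags = segment_fragments(_bins_frame([2, 2, 3, 3, 1, 1]))
        assert frags.empty

    @given(
        st.lists(st.sampled_from([0, 1, 2, 3, 4]), min_size=1, max_size=60),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_segmentation_conserves_bins(self, genotypes):
        """Every bin lies in exactly one fragment, HE gap, or trimmed end."""
        frags = segment_fragments(_bins_frame(genotypes))
        n = len(genotypes)
        covered = np.zeros(n, dtype=int)
        for _, f in frags.iterrows():
            covered[f["first_bin"] : f["last_bin"] + 1] += 1
        assert covered.max() <= 1
        if len(frags):
            # uncovered bins are only between/outside fragments, and gaps lie
            # between fragments of different genotype
            assert (np.diff(frags["first_bin"]) > 0).all()
            for i in range(len(frags) - 1):
                assert frags.loc[i, "dosage"] != frags.loc[i + 1, "dosage"]

    def test_adjacent_fragments_always_differ(self):
        frags = segment_fragments(_bins_frame([2] * 6 + [3] * 5 + [2] * 7 + [1] * 6))
        for i in range(len(frags) - 1):
            assert frags.loc[i, "genotype"] != frags.loc[i + 1, "genotype"]


class TestCallHE:
    def test_three_fragments_two_regions(self):
        frags = segment_fragments(_bins_frame([2] * 6 + [3] * 6 + [2] * 6))
        he = call_he(frags)
        assert len(he) == 2
        assert (he["end"] > he["start"]).all()
        assert (he["left_genotype"] != he["right_genotype"]).all()

    def test_junction_coordinates(self):
        frags = segment_fragments(_bins_frame([2] * 5 + [3] * 5))
        he = call_he(frags)
        assert he.loc[0, "start"] == 5 * 1000      # last SNP of left
        assert he.loc[0, "end"] == 5 * 1000 + 1    # first SNP of right


class TestWindowHEFrequency:
    LENGTHS = {"Chr01": 3_000_000}

    def test_empty_regions_zero_track(self):
        f = window_he_frequency(pd.DataFrame(columns=["chrom", "start", "end"]), 2, self.LENGTHS)
        assert (f["he_frequency"] == 0).all()
        assert len(f) == 3

    def test_midpoint_assignment(self):
        regions = pd.DataFrame({"chrom": ["Chr01"], "start": [1_400_000], "end": [1_600_000]})
        f = window_he_frequency(regions, 1, self.LENGTHS)
        assert f.loc[f["window"] == 1, "he_count"].item() == 1
        assert f["he_count"].sum() == 1

    def test_frequency_normalised_by_individuals(self):
        regions = pd.DataFrame(
            {"chrom": ["Chr01"] * 2, "start": [1_400_000] * 2, "end": [1_600_000] * 2}
        )
        f = window_he_frequency(regions, 2, self.LENGTHS)
        assert f.loc[f["window"] == 1, "he_frequency"].item() == pytest.approx(1.0)


class TestGenotypeBins:
    def test_pooled_counts_match_site_sums(self):
        n_sites = 30
        panel = pd.DataFrame({"chrom": "Chr01", "pos": np.arange(1, n_sites + 1) * 50})
        counts = panel.assign(
            individual="ind1",
            count_9311=np.arange(n_sites),
            count_nip=np.full(n_sites, 3),
        )
        bins = bin_sites(panel, k=10)
        gb = genotype_bins(counts, bins)
        assert gb["a"].tolist() == [sum(range(0, 10)), sum(range(10, 20)), sum(range(20, 30))]
        assert (gb["b"] == 30).all()
        assert set(gb["dosage"]) <= set(GENOTYPE_LABELS)

    def test_zero_read_bin_flagged_no_call(self):
        panel = pd.DataFrame({"chrom": "Chr01", "pos": np.arange(1, 21) * 50})
        counts = panel.assign(individual="ind1", count_9311=0, count_nip=0)
        counts.loc[:9, "count_nip"] = 10  # first bin callable, second empty
        bins = bin_sites(panel, k=10)
        with pytest.warns(UserWarning, match="no-call"):
            gb = genotype_bins(counts, bins)
        assert gb.loc[0, "dosage"] == 0
        assert gb.loc[1, "dosage"] == -1 and np.isnan(gb.loc[1, "G"])
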