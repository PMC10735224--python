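"""ZTNB background model, bin counting, peak calling and ranking."""

import numpy as np
import pytest
from scipy import stats

from clipcircuit.intervals import GenomicInterval
from clipcircuit.peaks import (Peak, ZtnbModel, bin_counts, call_peaks,
                               fit_ztnb, rank_peaks)
from clipcircuit.readsets import ReadSet


def _ztnb_sample(rng, mu, alpha, n):
    if alpha == 0:
        draw = rng.poisson(mu, int(n * 1.8) + 50)
    else:
        shape = 1.0 / alpha
        draw = rng.poisson(rng.gamma(shape, mu / shape, int(n * 1.8) + 50))
    draw = draw[draw >= 1]
    assert len(draw) >= n
    return draw[:n]


class TestBinCounts:
    def region(self):
        return GenomicInterval("c", 0, 100, "+")

    def test_no_reads(self):
        bins = bin_counts(ReadSet([], [], [], []), self.region(), 20)
        assert [c for _, c in bins] == [0] * 5

    def test_five_prime_assignment(self):
        # read [10,30)+ has 5' end 10 -> first bin only
        rs = ReadSet(["c"], [10], [30], ["+"])
        bins = bin_counts(rs, self.region(), 20)
        assert [c for _, c in bins] == [1, 0, 0, 0, 0]

    def test_minus_strand_five_prime_is_right_end(self):
        rs = ReadSet(["c"], [10], [30], ["-"])
        bins = bin_counts(rs, GenomicInterval("c", 0, 100, "-"), 20)
        assert [c for _, c in bins] == [0, 1, 0, 0, 0]

    def test_conservation_over_random_reads(self, rng):
        n = 200
        starts = rng.integers(0, 90, n)
        rs = ReadSet(["c"] * n, starts, starts + 10, ["+"] * n)
        bins = bin_counts(rs, self.region(), 17)
        assert sum(c for _, c in bins) == n
        # last bin is short: region length 100, bin 17 -> 6 bins, last 15 nt
        assert len(bins[-1][0]) == 100 - 5 * 17

    def test_invalid_bin_size(self):
        with pytest.raises(ValueError):
            bin_counts(ReadSet([], [], [], []), self.region(), 0)


class TestFitZtnb:
    def test_recovers_zt_poisson(self, rng):
        counts = _ztnb_sample(rng, 3.0, 0.0, 10_000)
        model = fit_ztnb(counts)
        assert model.mu == pytest.approx(3.0, rel=0.05)
        assert model.alpha < 0.05

    def test_recovers_ztnb_parameters_within_ten_percent(self, rng):
        counts = _ztnb_sample(rng, 5.0, 0.5, 10_000)
        model = fit_ztnb(counts)
        assert model.mu == pytest.approx(5.0, rel=0.10)
        assert model.alpha == pytest.approx(0.5, rel=0.10)

    def test_constant_counts_take_poisson_fallback(self):
        with pytest.warns(UserWarning, match="underdispersed"):
            model = fit_ztnb([2] * 20)
        assert model.alpha == 0.0
        # ZT-Poisson mean mu/(1-exp(-mu)) must equal the sample mean 2
        assert model.mu / -np.expm1(-model.mu) == pytest.approx(2.0, abs=1e-6)

    def test_fit_likelihood_beats_moment_initializer(self, rng):
        counts = _ztnb_sample(rng, 8.0, 0.3, 2_000)
        model = fit_ztnb(counts)
        m, v = counts.mean(), counts.var(ddof=1)
        init = ZtnbModel(mu=m, alpha=max((v - m) / m**2, 1e-3), fitted_on=len(counts))
        ll_init = init.logpmf(counts).sum()
        assert model.logpmf(counts).sum() >= ll_init - 1e-9

    def test_requires_ten_bins(self):
        with pytest.raises(ValueError):
            fit_ztnb([1, 2, 3])


class TestZtnbTail:
    def test_sf_matches_bruteforce_pmf_sum(self):
        """Upper tail from the model equals a direct truncated-pmf summation."""
        model = ZtnbModel(mu=4.0, alpha=0.4, fitted_on=100)
        n = 1.0 / model.alpha
        p = n / (n + model.mu)
        pmf0 = stats.nbinom.pmf(0, n, p)
        for k in (1, 2, 3, 5, 10, 25, 60):
            brute = stats.nbinom.pmf(np.arange(k, 3000), n, p).sum() / (1 - pmf0)
            assert model.sf_geq(k) == pytest.approx(brute, abs=1e-10)

    def test_sampling_matches_model_mean(self, rng):
        model = ZtnbModel(mu=2.0, alpha=0.5, fitted_on=0)
        draw = model.rvs(20_000, rng)
        assert draw.min() >= 1
        ks = np.arange(1, 200)
        expect = float((ks * np.exp(model.logpmf(ks))).sum())
        assert draw.mean() == pytest.approx(expect, rel=0.03)


def _bins_from_counts(counts, bin_size=30):
    return [
        (GenomicInterval("c", i * bin_size, (i + 1) * bin_size, "+"), int(c))
        for i, c in enumerate(counts)
    ]


class TestCallPeaks:
    def test_uniform_background_yields_no_peaks(self):
        model = ZtnbModel(mu=5.0, alpha=0.2, fitted_on=100)
        bins = _bins_from_counts([5] * 100)
        assert call_peaks(bins, model, alpha_fdr=0.01) == []

    def test_single_extreme_bin_is_called_alone(self):
        model = ZtnbModel(mu=3.0, alpha=0.2, fitted_on=100)
        counts = [3] * 50
        counts[20] = 300  # 100x the background mean
        peaks = call_peaks(_bins_from_counts(counts), model, alpha_fdr=0.01)
        assert len(peaks) == 1
        assert peaks[0].region.start == 20 * 30
        assert peaks[0].region.end == 21 * 30
        assert peaks[0].total_reads == 300

    def test_adjacent_significant_bins_merge(self):
        model = ZtnbModel(mu=3.0, alpha=0.2, fitted_on=100)
        counts = [3] * 50
        counts[20] = counts[21] = 300
        peaks = call_peaks(_bins_from_counts(counts), model, alpha_fdr=0.01)
        assert len(peaks) == 1
        assert (peaks[0].region.start, peaks[0].region.end) == (600, 660)
        assert peaks[0].total_reads == 600

    def test_no_positive_bins_returns_empty(self):
        model = ZtnbModel(mu=3.0, alpha=0.2, fitted_on=100)
        assert call_peaks(_bins_from_counts([0] * 30), model, 0.01) == []


class TestRankPeaks:
    def peak(self, start, reads, length):
        return Peak(GenomicInterval("c", start, start + length, "+"), reads)

    def test_reads_and_density_rankings_disagree_as_expected(self):
        # 400 reads / 80 nt (density 5.0) vs 100 reads / 10 nt (density 10.0)
        p1, p2 = self.peak(0, 400, 80), self.peak(1000, 100, 10)
        table = rank_peaks([p1, p2]).set_index("start")
        assert table.loc[0, "rank_by_reads"] == 1
        assert table.loc[1000, "rank_by_reads"] == 2
        assert table.loc[0, "rank_by_density"] == 2
        assert table.loc[1000, "rank_by_density"] == 1
        assert table.loc[0, "density"] == 5.0

    def test_single_peak_percentiles(self):
        table = rank_peaks([self.peak(0, 10, 30)])
        assert table["rank_by_reads"].iloc[0] == 1
        assert table["percentile_by_reads"].iloc[0] == 100.0
        assert table["percentile_by_density"].iloc[0] == 100.0

    def test_empty(self):
        assert rank_peaks([]).empty
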