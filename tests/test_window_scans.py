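"""Windowed scans: density, region merging, expectation goodness-of-fit, triage."""

import random

import numpy as np
import pandas as pd
import pytest

from bsascan import (
    BulkSite,
    InputError,
    Region,
    ScanParams,
    density_scan,
    expectation_set,
    merge_flagged_windows,
    triage_region_genes,
    variance_scan,
)
from bsascan.window_scans import EXPRESSED, HIGHLY_EXPRESSED, NOT_EXPRESSED, WindowScore


def sites_at(positions, chrom="1", f_high=1.0, f_low=0.0):
    return [BulkSite(chrom, p, "A", "C", f_high, f_low, 4, 4, 200.0) for p in positions]


class TestDensityScan:
    def test_thirty_one_sites_in_one_window_exceed_threshold(self):
        params = ScanParams()
        sites = sites_at(range(100_000, 100_000 + 31 * 1000, 1000))
        windows = density_scan(sites, params, {"1": 1_000_000})
        flagged = [w for w in windows if w.density > params.min_density]
        assert flagged and all(w.n_snps == 31 for w in flagged)

    def test_no_sites_means_no_counts(self):
        windows = density_scan([], ScanParams(), {"1": 1_000_000})
        assert windows == []  # no sites on any chromosome of the site list

    def test_uniform_sites_match_brute_force_counts(self):
        params = ScanParams(density_window_bp=1_000_000, density_step_bp=200_000)
        positions = list(range(100_000, 2_000_001, 100_000))  # 1 site / 100 kb
        sites = sites_at(positions)
        windows = density_scan(sites, params, {"1": 2_000_000})
        for w in windows:
            brute = sum(1 for p in positions if w.start <= p <= w.end)
            assert w.n_snps == brute
        full = [w for w in windows if w.end - w.start + 1 == 1_000_000]
        assert all(w.n_snps in (10, 11) for w in full)

    def test_every_site_is_covered_and_density_uses_actual_span(self):
        params = ScanParams()
        sites = sites_at([1, 999_999, 1_500_000])
        windows = density_scan(sites, params, {"1": 1_500_000})
        for s in sites:
            assert any(w.start <= s.pos <= w.end for w in windows)
        for w in windows:
            assert w.density == pytest.approx(w.n_snps * 1e6 / (w.end - w.start + 1))

    def test_site_beyond_declared_length_raises(self):
        with pytest.raises(InputError, match="1:2000000"):
            density_scan(sites_at([2_000_000]), ScanParams(), {"1": 1_000_000})


class TestMergeFlaggedWindows:
    def test_overlap_union(self):
        windows = [
            WindowScore("1", 24_800_001, 25_800_000, 31, density=31.0),
            WindowScore("1", 25_000_001, 26_000_000, 35, density=35.0),
        ]
        (region,) = merge_flagged_windows(windows, 30.0)
        assert (region.start, region.end) == (24_800_001, 26_000_000)
        assert region.peak_density == 35.0

    def test_gap_separates_regions_and_threshold_is_strict(self):
        windows = [
            WindowScore("1", 1, 100, 31, density=31.0),
            WindowScore("1", 301, 400, 30, density=30.0),  # exactly 30: NOT flagged
            WindowScore("1", 501, 600, 40, density=40.0),
        ]
        regions = merge_flagged_windows(windows, 30.0)
        assert [(r.start, r.end) for r in regions] == [(1, 100), (501, 600)]

    def test_random_patterns_match_interval_union_oracle(self):
        """Coverage-array oracle on a small coordinate space."""
        rng = random.Random(42)
        for _ in range(300):
            windows = []
            for _ in range(rng.randint(0, 12)):
                start = rng.randint(1, 150)
                end = start + rng.randint(0, 40)
                density = rng.choice([10.0, 31.0, 50.0])
                windows.append(WindowScore("1", start, end, 1, density=density))
            regions = merge_flagged_windows(windows, 30.0)

            covered = np.zeros(260, dtype=bool)
            for w in windows:
                if w.density > 30.0:
                    covered[w.start : w.end + 1] = True
            runs = []
            pos = 1
            while pos < len(covered):
                if covered[pos]:
                    start = pos
                    while pos < len(covered) and covered[pos]:
                        pos += 1
                    runs.append((start, pos - 1))
                else:
                    pos += 1
            assert [(r.start, r.end) for r in regions] == runs


class TestVarianceScan:
    def setup_method(self):
        self.exp_f2_dom = expectation_set("f2_intercross", "dominant_bulk")
        self.exp_f2_rec = expectation_set("f2_intercross", "recessive_bulk")
        self.exp_hom = expectation_set("homozygous_bulks", "high_bulk")

    def test_exact_expectation_match_scores_zero_and_is_best(self):
        sites = sites_at(range(100, 1100, 100), f_high=2 / 3, f_low=0.0)
        (w,) = variance_scan(sites, ScanParams(), self.exp_f2_dom, self.exp_f2_rec)
        assert w.var_high == pytest.approx(0.0, abs=1e-15)
        assert w.var_low == pytest.approx(0.0, abs=1e-15)
        assert w.dfscore == pytest.approx(0.0, abs=1e-15)
        assert w.best and not w.partial

    def test_half_frequencies_against_homozygous_expectations(self):
        # every deviation |0.5 - 0| = 0.5, squared 0.25, mean over both
        # bulks: (1/(2*10)) * 10 * (0.25 + 0.25) = 0.25
        sites = sites_at(range(100, 1100, 100), f_high=0.5, f_low=0.5)
        (w,) = variance_scan(sites, ScanParams(), self.exp_hom, self.exp_hom)
        assert w.dfscore == pytest.approx(0.25)
        assert w.var_high == 0.0  # all frequencies identical
        assert not w.best

    def test_randomized_windows_match_per_site_oracle(self):
        """DFScore equals a loop-and-min recomputation to within 1e-12."""
        rng = random.Random(11)
        params = ScanParams()
        for _ in range(50):
            n = rng.randint(1, 25)
            sites = [
                BulkSite("1", 100 * (i + 1), "A", "C", rng.random(), rng.random(), 4, 4, 200.0)
                for i in range(n)
            ]
            windows = variance_scan(sites, params, self.exp_f2_dom, self.exp_f2_rec)
            i = 0
            for w in windows:
                chunk = sites[i : i + params.var_window_snps]
                total = 0.0
                for s in chunk:
                    dh = min(abs(s.f_high - float(e)) for e in self.exp_f2_dom.values)
                    dl = min(abs(s.f_low - float(e)) for e in self.exp_f2_rec.values)
                    total += dh * dh + dl * dl
                assert w.dfscore == pytest.approx(total / (2 * len(chunk)), abs=1e-12)
                i += params.var_step_snps

    def test_partial_trailing_window_is_emitted(self):
        sites = sites_at(range(100, 1400, 100))  # 13 sites, window 10 step 5
        windows = variance_scan(sites, ScanParams(), self.exp_hom, self.exp_hom)
        assert [w.n_snps for w in windows] == [10, 8]
        assert [w.partial for w in windows] == [False, True]
        assert windows[1].start == sites[5].pos and windows[1].end == sites[-1].pos

    def test_score_invariant_under_window_internal_reordering(self):
        rng = random.Random(5)
        freqs = [(rng.random(), rng.random()) for _ in range(10)]
        sites = [
            BulkSite("1", 100 + i, "A", "C", fh, fl, 4, 4, 200.0)
            for i, (fh, fl) in enumerate(freqs)
        ]
        shuffled_freqs = freqs[:]
        rng.shuffle(shuffled_freqs)
        sites2 = [
            BulkSite("1", 100 + i, "A", "C", fh, fl, 4, 4, 200.0)
            for i, (fh, fl) in enumerate(shuffled_freqs)
        ]
        params = ScanParams()
        (w1,) = variance_scan(sites, params, self.exp_hom, self.exp_hom)
        (w2,) = variance_scan(sites2, params, self.exp_hom, self.exp_hom)
        assert w1.dfscore == pytest.approx(w2.dfscore, abs=1e-12)
        assert w1.var_high == pytest.approx(w2.var_high, abs=1e-12)

    def test_empty_input_gives_empty_output(self):
        assert variance_scan([], ScanParams(), self.exp_hom, self.exp_hom) == []


class TestPeakPosition:
    def test_unique_maximum(self):
        from bsascan import peak_position

        assert peak_position([100, 200, 300], [0.1, 0.9, 0.2]) == 200

    def test_tied_run_reports_midpoint(self):
        from bsascan import peak_position

        # ties across a co-segregating run: report the run's center, not
        # its proximal edge
        pos = [100, 200, 300, 400, 500]
        scores = [0.1, 0.5, 0.5, 0.5, 0.2]
        assert peak_position(pos, scores) == 300

    def test_empty_raises(self):
        from bsascan import peak_position

        with pytest.raises(ValueError):
            peak_position([], [])


class TestTriage:
    def test_expression_classes(self):
        tpm = pd.DataFrame(
            {"s1": [300.0, 0.0, 2.0, 5.0], "s2": [1.0, 0.0, 1.0, 4.0]},
            index=["gHigh", "gOff", "gBoundary", "gMid"],
        )
        coords = {g: ("23", 25_000_000, 25_100_000) for g in tpm.index}
        region = Region(chrom="23", start=24_800_001, end=29_600_000)
        classes = triage_region_genes(tpm, region, coords)
        assert classes["gHigh"] == HIGHLY_EXPRESSED  # log2(300) ~ 8.23 > 8
        assert classes["gOff"] == NOT_EXPRESSED
        # max TPM 2 -> log2 ~ 1: not strictly below 1, not above 8
        assert classes["gBoundary"] == EXPRESSED
        assert classes["gMid"] == EXPRESSED

    def test_genes_outside_region_or_without_coords_are_skipped(self):
        tpm = pd.DataFrame({"s1": [10.0, 10.0]}, index=["gIn", "gOut"])
        coords = {"gIn": ("1", 100, 200), "gOut": ("2", 100, 200)}
        region = Region(chrom="1", start=1, end=1000)
        classes = triage_region_genes(tpm, region, coords)
        assert set(classes) == {"gIn"}

        tpm2 = pd.DataFrame({"s1": [10.0]}, index=["gNoCoords"])
        assert triage_region_genes(tpm2, region, {}) == {}

    def test_negative_tpm_rejected(self):
        tpm = pd.DataFrame({"s1": [-1.0]}, index=["g"])
        with pytest.raises(ValueError):
            triage_region_genes(tpm, Region(chrom="1", start=1, end=10), {"g": ("1", 1, 5)})
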