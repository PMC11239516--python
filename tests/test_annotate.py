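"""RT scores, cumulative origin correlation, expression transform, weighted densities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replifork.annotate import (
    cumulative_origin_correlation,
    resampling_test,
    rt_score,
    span_region_overlap,
    transform_expression,
    weighted_speed_by_region,
    zscore_bulk_tracks,
)


class TestRTScore:
    @pytest.mark.parametrize("early,late,expected", [
        (5, 5, 0.0), (7, 0, 1.0), (0, 3, -1.0), (3, 1, 0.5),
    ])
    def test_values(self, early, late, expected):
        assert rt_score(early, late) == pytest.approx(expected)

    def test_both_zero_is_nan(self):
        assert np.isnan(rt_score(0, 0))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_antisymmetric_and_bounded(self, e, l):
        if e + l == 0:
            return
        s = rt_score(e, l)
        assert -1 <= s <= 1
        assert s == pytest.approx(-rt_score(l, e))


class TestCumulativeOriginCorrelation:
    def _binned(self, counts_by_cell):
        frames = []
        for cell, counts in counts_by_cell.items():
            frames.append(pd.DataFrame({
                "cell": cell, "chrom": "c",
                "bin_start": np.arange(len(counts)) * 100_000,
                "value": counts}))
        return pd.concat(frames, ignore_index=True)

    def test_final_prefix_perfect_correlation(self):
        rng = np.random.default_rng(0)
        counts = {f"c{i}": rng.integers(0, 20, 50).astype(float)
                  for i in range(4)}
        binned = self._binned(counts)
        order = pd.DataFrame({"cell": list(counts),
                              "consensus_position": np.linspace(0, 1, 4)})
        total = sum(counts.values())
        origin = pd.DataFrame({"chrom": "c",
                               "bin_start": np.arange(50) * 100_000,
                               "value": total})
        res = cumulative_origin_correlation(binned, order, origin)
        assert res["pearson"].iloc[-1] == pytest.approx(1.0)

    def test_random_tracks_low_correlation(self):
        rng = np.random.default_rng(1)
        counts = {"c0": rng.poisson(5, 1000).astype(float)}
        binned = self._binned(counts)
        order = pd.DataFrame({"cell": ["c0"], "consensus_position": [0.5]})
        origin = pd.DataFrame({"chrom": "c",
                               "bin_start": np.arange(1000) * 100_000,
                               "value": rng.poisson(5, 1000).astype(float)})
        res = cumulative_origin_correlation(binned, order, origin)
        assert abs(res["pearson"].iloc[0]) < 0.1

    def test_early_cells_near_origins_decline(self):
        """Cells replicating planted origin bins early: the correlation with
        the origin track is highest for the earliest prefix and declines."""
        rng = np.random.default_rng(2)
        n_bins = 200
        origin_bins = rng.choice(n_bins, 30, replace=False)
        origin = pd.DataFrame({"chrom": "c",
                               "bin_start": np.arange(n_bins) * 100_000,
                               "value": 0.0})
        origin.loc[origin_bins, "value"] = 10.0
        counts = {}
        for i in range(10):
            v = rng.poisson(1, n_bins).astype(float)
            if i < 3:  # early cells replicate at origins
                v[origin_bins] += rng.poisson(15, 30)
            else:      # late cells elsewhere
                others = np.setdiff1d(np.arange(n_bins), origin_bins)
                v[rng.choice(others, 30, replace=False)] += rng.poisson(15, 30)
            counts[f"c{i}"] = v
        binned = self._binned(counts)
        order = pd.DataFrame({"cell": [f"c{i}" for i in range(10)],
                              "consensus_position": np.linspace(0, 1, 10)})
        res = cumulative_origin_correlation(binned, order, origin)
        assert res["pearson"].iloc[2] > res["pearson"].iloc[-1]

    def test_zero_variance_prefix_missing(self):
        binned = self._binned({"c0": np.zeros(10)})
        order = pd.DataFrame({"cell": ["c0"], "consensus_position": [0.0]})
        origin = pd.DataFrame({"chrom": "c", "bin_start": np.arange(10) * 100_000,
                               "value": np.arange(10, dtype=float)})
        res = cumulative_origin_correlation(binned, order, origin)
        assert np.isnan(res["pearson"].iloc[0])


class TestTransformExpression:
    def test_log_transform_values(self):
        genes = pd.DataFrame({
            "chrom": "c", "start": [0, 1000, 2000], "end": [500, 1500, 2500],
            "gene": ["g0", "g9", "g999"], "counts": [0, 9, 999]})
        out = transform_expression(genes)
        assert out.set_index("gene")["transformed"].to_dict() == {
            "g0": 0, "g9": 1, "g999": 3}

    def test_overlap_resolved_by_higher_count(self):
        genes = pd.DataFrame({
            "chrom": "c", "start": [0, 500], "end": [1000, 1500],
            "gene": ["low", "high"], "counts": [10, 1000]})
        out = transform_expression(genes)
        seg = out[(out["start"] <= 750) & (out["end"] > 750)]
        assert seg["gene"].iloc[0] == "high"
        # output intervals are disjoint
        for _, grp in out.groupby("chrom"):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_tie_broken_by_earlier_start(self):
        genes = pd.DataFrame({
            "chrom": "c", "start": [0, 500], "end": [1000, 1500],
            "gene": ["first", "second"], "counts": [10, 10]})
        out = transform_expression(genes)
        seg = out[(out["start"] <= 750) & (out["end"] > 750)]
        assert seg["gene"].iloc[0] == "first"

    def test_negative_counts_rejected(self):
        genes = pd.DataFrame({"chrom": "c", "start": [0], "end": [10],
                              "gene": ["g"], "counts": [-1]})
        with pytest.raises(ValueError):
            transform_expression(genes)


class TestWeightedSpeedDensity:
    def _spans(self, rng, n=400):
        start = rng.uniform(0, 10_000_000, n)
        return pd.DataFrame({"chrom": "c", "start": start,
                             "end": start + rng.uniform(20_000, 100_000, n)
                             }).assign(distance=lambda d: d["end"] - d["start"])

    def test_whole_genome_region_equals_unweighted(self):
        rng = np.random.default_rng(3)
        spans = self._spans(rng)
        regions = pd.DataFrame({"chrom": ["c"], "start": [0],
                                "end": [20_000_000]})
        post = np.ones(len(spans))
        dens, (speeds, w_in, w_out) = weighted_speed_by_region(
            spans, post, regions, delta_t=75.0)
        assert np.allclose(w_in, post)
        assert w_out.sum() == 0

    def test_half_overlap_weight(self):
        spans = pd.DataFrame({"chrom": ["c"], "start": [0.0], "end": [1000.0],
                              "distance": [1000.0]})
        regions = pd.DataFrame({"chrom": ["c"], "start": [500], "end": [5000]})
        frac = span_region_overlap(spans, regions)
        assert frac[0] == pytest.approx(0.5)

    def test_overlap_fraction_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        spans = self._spans(rng, n=60)
        regions = pd.DataFrame({
            "chrom": "c", "start": rng.choice(10_000_000, 20, replace=False)})
        regions["end"] = regions["start"] + rng.integers(10_000, 300_000, 20)
        frac = span_region_overlap(spans, regions)
        # brute force against the merged union
        merged = []
        for _, r in regions.sort_values("start").iterrows():
            if merged and r["start"] <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], r["end"])
            else:
                merged.append([r["start"], r["end"]])
        for i, row in spans.reset_index().iterrows():
            ov = sum(max(0, min(e, row["end"]) - max(s, row["start"]))
                     for s, e in merged)
            assert frac[i] == pytest.approx(ov / (row["end"] - row["start"]))

    def test_planted_slow_region_detected(self):
        """Spans inside the 'transcribed' region are built 30% shorter
        (slower forks): the inside density mode falls below the outside mode
        and the resampling test flags the difference."""
        rng = np.random.default_rng(5)
        n = 600
        inside = rng.random(n) < 0.5
        start = np.where(inside, rng.uniform(0, 4_000_000, n),
                         rng.uniform(5_000_000, 9_000_000, n))
        dist = np.where(inside, rng.normal(52_500, 4000, n),
                        rng.normal(75_000, 4000, n))
        spans = pd.DataFrame({"chrom": "c", "start": start,
                              "end": start + dist, "distance": dist})
        regions = pd.DataFrame({"chrom": ["c"], "start": [0],
                                "end": [4_200_000]})
        dens, (speeds, w_in, w_out) = weighted_speed_by_region(
            spans, np.ones(n), regions, delta_t=75.0)
        mode_in = dens["speed"][dens["inside"].idxmax()]
        mode_out = dens["speed"][dens["outside"].idxmax()]
        assert mode_in < mode_out
        res = resampling_test(speeds, w_in, w_out, seed=0)
        assert res["p"] < 0.01
        assert res["mean_a"] < res["mean_b"]


class TestZScoreBulk:
    def _track(self, values):
        return pd.DataFrame({"chrom": "c",
                             "bin_start": np.arange(len(values)) * 50_000,
                             "value": values})

    def test_self_correlation_one(self):
        rng = np.random.default_rng(6)
        a = self._track(rng.random(100))
        out, rho = zscore_bulk_tracks(a, a.copy())
        assert rho == pytest.approx(1.0)
        assert out["z_a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["z_a"].std(ddof=0) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(7)
        a = self._track(rng.random(100))
        b = self._track(-a["value"].to_numpy())
        _, rho = zscore_bulk_tracks(a, b)
        assert rho == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        a = self._track(np.ones(10))
        with pytest.raises(ValueError, match="zero-variance"):
            zscore_bulk_tracks(a, a.copy())
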