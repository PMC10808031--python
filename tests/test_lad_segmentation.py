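"""Student-t HMM fitting, LAD calling, and region comparison."""

import numpy as np
import pandas as pd
import pytest

from conftest import viterbi_bruteforce
from lamina.damid_scores import ScoreTrack
from lamina.lad_segmentation import (
    DegenerateFitError,
    HMMModel,
    LADSet,
    RegionPartition,
    call_lads,
    fit_segment_hmm,
    lad_stats,
    region_comparison,
    viterbi,
)


def simulate_track(n=1000, block=50, mu=(-1.0, 2.0), sigma=0.8, nu=5, seed=0,
                   chrom="c", width=100_000):
    """Track of alternating planted blocks with Student-t noise."""
    rng = np.random.default_rng(seed)
    states = np.zeros(n, dtype=int)
    pos, s = 0, 0
    while pos < n:
        L = int(rng.integers(block // 2, block * 2))
        states[pos: pos + L] = s
        pos += L
        s = 1 - s
    x = np.array(mu)[states] + sigma * rng.standard_t(nu, n)
    iv = pd.DataFrame({"chrom": chrom, "start": np.arange(n) * width,
                       "end": (np.arange(n) + 1) * width})
    return ScoreTrack(iv, x, "bins"), states


class TestFitSegmentHmm:
    def test_recovers_planted_states_at_three_sigma_separation(self):
        track, states = simulate_track(n=1000, mu=(0.0, 2.4), sigma=0.8, seed=3)
        model, path = fit_segment_hmm(track)
        assert np.mean(path == states) >= 0.95

    def test_log_likelihood_is_non_decreasing(self):
        track, _ = simulate_track(n=400, seed=1)
        model, _ = fit_segment_hmm(track)
        ll = np.array(model.log_likelihoods)
        assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))

    def test_constant_observations_raise_degenerate_fit(self):
        iv = pd.DataFrame({"chrom": "c", "start": range(20), "end": range(1, 21)})
        with pytest.raises(DegenerateFitError):
            fit_segment_hmm(ScoreTrack(iv, np.full(20, 1.5), "bins"))

    def test_state_one_always_has_larger_location(self):
        for seed in (0, 1, 2):
            track, _ = simulate_track(n=300, seed=seed)
            model, _ = fit_segment_hmm(track)
            assert model.mu[1] > model.mu[0]
            assert model.lad_state == 1

    def test_missing_observations_are_bridged_by_the_chain(self):
        track, states = simulate_track(n=600, mu=(-1.0, 2.0), seed=4)
        x = track.score.copy()
        holes = np.random.default_rng(0).choice(600, 60, replace=False)
        x[holes] = np.nan
        track2 = ScoreTrack(track.intervals, x, "bins")
        model, path = fit_segment_hmm(track2)
        assert np.mean(path[~np.isnan(x)] == states[~np.isnan(x)]) >= 0.9

    def test_nu_estimation_stays_positive_and_fits(self):
        track, states = simulate_track(n=400, nu=5, seed=7)
        model, path = fit_segment_hmm(track, nu="estimate")
        assert model.nu > 0
        assert np.mean(path == states) >= 0.9

    def test_viterbi_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(11)
        model = HMMModel(
            mu=np.array([-0.5, 1.0]), sigma=np.array([0.6, 0.8]), nu=5.0,
            transitions=np.array([[0.85, 0.15], [0.2, 0.8]]),
            initial=np.array([0.6, 0.4]),
        )
        for T in (1, 5, 8, 12):
            for trial in range(3):
                x = rng.normal(0, 1.5, T)
                missing = rng.random(T) < 0.2
                x[missing] = np.nan
                got = viterbi(x, missing, model)
                exp = viterbi_bruteforce(x, missing, model)
                assert np.array_equal(got, exp)


class TestCallLads:
    def intervals(self, n, chrom="c", width=100_000, offset=0):
        return pd.DataFrame({
            "chrom": chrom,
            "start": offset + np.arange(n) * width,
            "end": offset + (np.arange(n) + 1) * width,
        })

    def test_runs_merge_into_lads(self):
        iv = self.intervals(6)
        lads = call_lads(np.array([1, 1, 1, 0, 0, 1]), iv)
        assert lads.intervals.values.tolist() == [
            ["c", 0, 300_000], ["c", 500_000, 600_000]]

    def test_empty_path_yields_empty_set(self):
        lads = call_lads(np.array([], dtype=int), self.intervals(0))
        assert len(lads) == 0
        assert lad_stats(lads) == (0, None)

    def test_runs_never_merge_across_chromosomes(self):
        iv = pd.concat([self.intervals(3, "chr2L"), self.intervals(3, "chr2R")],
                       ignore_index=True)
        lads = call_lads(np.ones(6, dtype=int), iv)
        assert len(lads) == 2
        assert set(lads.intervals["chrom"]) == {"chr2L", "chr2R"}

    def test_missing_bins_bridged_or_split(self):
        iv = self.intervals(5)
        path = np.array([1, 0, 0, 0, 1])  # HMM state at missing bins ignored
        missing = np.array([False, True, True, True, False])
        bridged = call_lads(path, iv, missing=missing, bridge_missing=True)
        assert bridged.intervals.values.tolist() == [["c", 0, 500_000]]
        split = call_lads(path, iv, missing=missing, bridge_missing=False)
        assert len(split) == 2

    def test_lad_stats_mean_length(self):
        lads = LADSet(pd.DataFrame({"chrom": ["c", "c"], "start": [0, 500_000],
                                    "end": [300_000, 600_000]}))
        n, mean_kb = lad_stats(lads)
        assert n == 2 and mean_kb == pytest.approx(200.0)

    def test_output_disjoint_and_covers_lad_states(self):
        rng = np.random.default_rng(5)
        path = (rng.random(200) < 0.4).astype(int)
        iv = self.intervals(200)
        lads = call_lads(path, iv)
        covered = np.zeros(200, dtype=bool)
        for _, l in lads.intervals.iterrows():
            covered[l["start"] // 100_000: l["end"] // 100_000] = True
        assert np.array_equal(covered, path == 1)


class TestRegionComparison:
    def make_partition(self):
        return RegionPartition(regions={
            "arm": pd.DataFrame({"chrom": ["c"], "start": [0], "end": [300]}),
            "centromere": pd.DataFrame({"chrom": ["c"], "start": [300], "end": [600]}),
        })

    def track(self, values):
        n = len(values)
        iv = pd.DataFrame({"chrom": "c", "start": np.arange(n) * 100,
                           "end": (np.arange(n) + 1) * 100})
        return ScoreTrack(iv, np.asarray(values, float), "bins")

    def test_exact_rank_sum_p_for_shifted_regions(self):
        # arm {1,2,3} vs centromere {4,5,6}: U = 0, exact p = 0.1
        _, table = region_comparison(self.track([1, 2, 3, 4, 5, 6]),
                                     self.make_partition())
        row = table.iloc[0]
        assert row["U"] == 0 and row["pvalue"] == pytest.approx(0.1)
        assert row["exact"]

    def test_identical_regions_give_p_one(self):
        _, table = region_comparison(self.track([1, 2, 3, 1, 2, 3]),
                                     self.make_partition())
        assert table.iloc[0]["pvalue"] == pytest.approx(1.0)

    def test_empty_region_raises_with_name(self):
        with pytest.raises(ValueError, match="centromere"):
            region_comparison(self.track([1, 2, 3]), self.make_partition())

    def test_partition_from_cytoband(self, tmp_path):
        cyto = tmp_path / "cytoBand.txt"
        cyto.write_text(
            "c\t0\t400\tq1\tgneg\n"
            "c\t400\t600\tq2\tacen\n"
            "c\t600\t1000\tq3\tgpos50\n"
        )
        part = RegionPartition.from_cytoband(cyto, telomere_flank=100)
        assert part.regions["centromere"].values.tolist() == [["c", 400, 600]]
        tel = part.regions["telomere"]
        assert len(tel) == 2 and tel["end"].max() == 1000
        arm = part.regions["arm"]
        # arms are everything not centromeric/telomeric
        assert arm["start"].min() == 100 and arm["end"].max() == 900
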