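import warnings

import numpy as np
import pandas as pd
import pytest

from carcinoscope import miniature_genome, profile_from_arm_states
from carcinoscope.genomeprofile import (classify_sv, compute_fga,
                                        count_breakpoints, detect_broken_genes,
                                        estimate_ploidy_purity, gc_correct,
                                        segment_bivariate)
from carcinoscope.segments import SegmentProfile
from carcinoscope.simcohort import (binned_signal_from_profile,
                                    simulate_segment_profile)

MB = 1_000_000


def _flat_bins(n=400, rc=100.0, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "chrom": "chr1", "start": 1 + 100_000 * np.arange(n),
        "end": 100_000 * (np.arange(n) + 1),
        "raw_rc": rc * np.ones(n),
        "gc": np.clip(0.45 + 0.05 * rng.standard_normal(n), 0.2, 0.8)})


class TestGcCorrect:
    def test_unbiased_input_left_alone(self):
        bins = _flat_bins()
        out = gc_correct(bins)
        assert np.max(np.abs(out["corrected_rc"] - 1.0)) < 0.02

    def test_monotone_bias_removed(self):
        bins = _flat_bins(seed=1)
        bins["raw_rc"] = 100.0 * (1 + 0.5 * (bins["gc"] - 0.4))
        out = gc_correct(bins)
        slope = np.polyfit(out["gc"], out["corrected_rc"], 1)[0]
        assert abs(slope) < 0.02

    def test_two_scale_bias_needs_both_windows(self):
        bins = _flat_bins(n=600, seed=2)
        gc_long = bins["gc"].rolling(5, center=True, min_periods=1).mean()
        bins["raw_rc"] = (100.0 * (1 + 0.6 * (bins["gc"] - 0.45))
                          * (1 + 0.8 * (gc_long - 0.45)))
        v_two = np.var(gc_correct(bins)["corrected_rc"] - 1.0)
        v_one = np.var(gc_correct(bins, use_long_window=False)["corrected_rc"] - 1.0)
        assert v_two <= 0.2 * v_one

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="200"):
            gc_correct(_flat_bins(n=50))

    def test_constant_gc_warns_identity(self):
        bins = _flat_bins()
        bins["gc"] = 0.45
        with pytest.warns(UserWarning, match="constant GC"):
            out = gc_correct(bins)
        assert np.allclose(out["corrected_rc"], 1.0)


def _uniform_states(genome, override):
    states = {(c, a): (1, 1) for c in genome.chroms for a in ("p", "q")}
    states.update(override)
    return states


class TestPloidyPurity:
    def test_noiseless_diploid_exact_on_grid(self, genome):
        # gains and losses balance to mean ploidy exactly 2.0
        prof = profile_from_arm_states(genome, _uniform_states(genome, {
            ("chr1", "p"): (2, 1), ("chr2", "p"): (1, 0)}))
        sig = binned_signal_from_profile(prof, seed=0, noiseless=True,
                                         gc_bias=(0.0, 0.0))
        sig.bins["corrected_rc"] = sig.bins["raw_rc"] / sig.bins["raw_rc"].mean()
        fit = estimate_ploidy_purity(sig)
        assert (fit.purity, fit.mean_ploidy) == (1.0, 2.0)

    def test_unidentifiable_flat_signal(self, genome):
        prof = profile_from_arm_states(genome, _uniform_states(genome, {}))
        sig = binned_signal_from_profile(prof, seed=0, noiseless=True,
                                         gc_bias=(0.0, 0.0))
        sig.bins["corrected_rc"] = sig.bins["raw_rc"] / sig.bins["raw_rc"].mean()
        fit = estimate_ploidy_purity(sig)
        assert fit.status == "unidentifiable" and fit.purity is None

    def test_low_purity_sample_fails_qc(self, genome):
        # below ~20% purity the copy-number contrast sits inside the read
        # count calibration noise, so the array-derived purity recorded by the
        # simulator is what QC consumes — and it discards the sample
        from carcinoscope.simcohort import sample_qc
        prof, _ = simulate_segment_profile(2, 0.15, 4, seed=2, genome=genome)
        keep, reason = sample_qc(60, 100 * prof.purity, 8)
        assert not keep and reason == "purity_estimate"


class TestSegmentation:
    def test_noiseless_breakpoint_and_genotype_recovery(self, genome):
        prof = profile_from_arm_states(genome, _uniform_states(genome, {
            ("chr1", "p"): [(15 * MB, 1, 1), (20 * MB, 2, 0), (15 * MB, 1, 1)]}))
        sig = binned_signal_from_profile(prof, seed=0, noiseless=True,
                                         gc_bias=(0.0, 0.0))
        sig.bins["corrected_rc"] = sig.bins["raw_rc"] / sig.bins["raw_rc"].mean()
        dec = segment_bivariate(sig, purity=1.0, mean_ploidy=prof.mean_ploidy,
                                genome=genome)
        reg = dec.segments[(dec.segments["chrom"] == "chr1")
                           & (dec.segments["major_cn"] == 2)
                           & (dec.segments["minor_cn"] == 0)]
        assert len(reg) == 1
        assert abs(reg["start"].iloc[0] - (15 * MB + 1)) <= 100_000
        assert abs(reg["end"].iloc[0] - 35 * MB) <= 100_000

    def test_all_normal_single_state(self, genome):
        prof = profile_from_arm_states(genome, _uniform_states(genome, {}))
        sig = binned_signal_from_profile(prof, seed=1, noiseless=True,
                                         gc_bias=(0.0, 0.0))
        sig.bins["corrected_rc"] = sig.bins["raw_rc"] / sig.bins["raw_rc"].mean()
        dec = segment_bivariate(sig, purity=1.0, mean_ploidy=2.0, genome=genome)
        assert len(dec.segments) == len(genome.chroms)
        assert set(zip(dec.segments["major_cn"], dec.segments["minor_cn"])) == {(1, 1)}

    def test_a2b2_region_decoded_at_low_purity(self, genome):
        prof = profile_from_arm_states(genome, _uniform_states(genome, {
            ("chr1", "p"): [(20 * MB, 2, 2), (30 * MB, 2, 1)],
            ("chr1", "q"): (2, 1), ("chr2", "p"): (3, 1)}))
        prof2 = SegmentProfile(prof.segments, 0.8, genome)
        sig = binned_signal_from_profile(prof2, seed=3)
        sig.bins = gc_correct(sig.bins)
        dec = segment_bivariate(sig, purity=0.8, mean_ploidy=prof2.mean_ploidy,
                                genome=genome)
        reg = dec.segments[(dec.segments["chrom"] == "chr1")
                           & (dec.segments["start"] < 20 * MB)]
        assert (reg["total_cn"] == 4).all() and (reg["minor_cn"] == 2).all()

    def test_segmentation_idempotent(self, genome):
        prof, sig = simulate_segment_profile(3, 0.8, 4, seed=6, genome=genome)
        sig.bins = gc_correct(sig.bins)
        dec = segment_bivariate(sig, 0.8, prof.mean_ploidy, genome=genome)
        resig = binned_signal_from_profile(dec, seed=0, noiseless=True,
                                           gc_bias=(0.0, 0.0))
        resig.bins["corrected_rc"] = (resig.bins["raw_rc"]
                                      / resig.bins["raw_rc"].mean())
        redec = segment_bivariate(resig, 0.8, dec.mean_ploidy, genome=genome)
        pd.testing.assert_frame_equal(
            redec.segments[["chrom", "major_cn", "minor_cn"]],
            dec.segments[["chrom", "major_cn", "minor_cn"]])


def _random_profile(genome, seed, n_chrom_segments=6):
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in genome.chroms:
        bounds = np.sort(rng.choice(
            np.arange(1, genome.length(chrom) // 1000), n_chrom_segments - 1,
            replace=False)) * 1000
        edges = np.concatenate([[0], bounds, [genome.length(chrom)]])
        for i in range(len(edges) - 1):
            a = int(rng.integers(1, 4))
            b = int(rng.integers(0, a + 1))
            rows.append((chrom, edges[i] + 1, edges[i + 1], a + b, a, b))
    return SegmentProfile(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn",
                                    "major_cn", "minor_cn"]), 1.0, genome)


class TestSummaries:
    def test_fga_uniform_zero(self, genome):
        prof = profile_from_arm_states(genome, _uniform_states(genome, {}))
        assert compute_fga(prof) == 0.0

    def test_fga_half_genome(self, genome):
        states = _uniform_states(genome, {(c, a): (2, 1)
                                          for c in ("chr1", "chr2")
                                          for a in ("p", "q")})
        assert compute_fga(profile_from_arm_states(genome, states)) == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fga_matches_per_base_oracle(self, seed):
        toy = miniature_genome(n_chroms=2, chrom_length=10 * MB,
                               centromere=5 * MB)
        prof = _random_profile(toy, seed)
        # brute force on a 1 kb grid
        hits = total = 0
        modal = prof.modal_ploidy
        for _, seg in prof.segments.iterrows():
            n_units = (seg["end"] - seg["start"] + 1) // 1000
            total += n_units
            if seg["total_cn"] != modal:
                hits += n_units
        assert compute_fga(prof) == pytest.approx(hits / total, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_breakpoints_match_adjacency_oracle(self, seed):
        toy = miniature_genome(n_chroms=2, chrom_length=10 * MB,
                               centromere=5 * MB)
        prof = _random_profile(toy, seed)
        n = 0
        for _, grp in prof.segments.groupby("chrom"):
            states = list(zip(grp["major_cn"], grp["minor_cn"]))
            n += sum(states[i] != states[i - 1] for i in range(1, len(states)))
        assert count_breakpoints(prof) == n

    def test_breakpoints_alternating_states(self, genome):
        prof = profile_from_arm_states(genome, _uniform_states(genome, {
            ("chr1", "p"): [(20 * MB, 1, 1), (10 * MB, 2, 1), (20 * MB, 1, 1)]}))
        assert count_breakpoints(prof) == 2

    def test_fga_invariant_under_split(self, genome):
        prof, _ = simulate_segment_profile(3, 1.0, 4, seed=8, genome=genome)
        before = compute_fga(prof)
        segs = prof.segments.copy()
        row = segs.iloc[0].copy()
        mid = (row["start"] + row["end"]) // 2
        first = row.copy()
        first["end"] = mid
        second = row.copy()
        second["start"] = mid + 1
        split = pd.concat([pd.DataFrame([first, second]), segs.iloc[1:]],
                          ignore_index=True)
        assert compute_fga(prof.with_segments(split)) == pytest.approx(before)


class TestStructuralVariants:
    def test_translocation(self):
        assert classify_sv(("chr1", 100, "+"), ("chr5", 200, "-")) == "translocation"

    def test_duplication_convention(self):
        assert classify_sv(("chr1", 100, "-"), ("chr1", 5000, "+")) == "duplication"

    def test_orientation_enumeration_gives_three_intra_classes(self):
        classes = {classify_sv(("chr1", 100, o1), ("chr1", 900, o2))
                   for o1 in "+-" for o2 in "+-"}
        assert classes == {"deletion", "duplication", "inversion"}

    def test_missing_orientation_rejected(self):
        with pytest.raises(ValueError):
            classify_sv(("chr1", 100, None), ("chr1", 900, "+"))

    def test_broken_gene_support_filter(self):
        genes = pd.DataFrame({"chrom": ["chr1", "chr1"],
                              "start": [1000, 50_000],
                              "end": [2000, 60_000],
                              "name": ["GENE1", "GENE2"]})

        def sv(support, pos=1500):
            return pd.DataFrame({
                "chrom1": ["chr1"], "pos1": [pos], "strand1": ["+"],
                "chrom2": ["chr2"], "pos2": [999_999], "strand2": ["-"],
                "sv_class": ["translocation"], "supporting_reads": [support],
                "span": [np.nan]})

        assert detect_broken_genes(sv(16), genes) == ["GENE1"]
        assert detect_broken_genes(sv(15), genes) == []
        assert detect_broken_genes(sv(100, pos=10_000), genes) == []

    def test_unsorted_gene_table_warns(self):
        genes = pd.DataFrame({"chrom": ["chr1", "chr1"],
                              "start": [50_000, 1000],
                              "end": [60_000, 2000],
                              "name": ["GENE2", "GENE1"]})
        sv = pd.DataFrame({
            "chrom1": ["chr1"], "pos1": [1500], "strand1": ["+"],
            "chrom2": ["chr2"], "pos2": [999], "strand2": ["-"],
            "sv_class": ["translocation"], "supporting_reads": [20],
            "span": [np.nan]})
        with pytest.warns(UserWarning, match="not sorted"):
            assert detect_broken_genes(sv, genes) == ["GENE1"]
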