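import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from carcinoscope import miniature_genome, profile_from_arm_states
from carcinoscope.clonal import (build_ccf_table, clone_signature_proportions,
                                 cluster_clones, compute_ccf,
                                 doubling_expected_vafs,
                                 shared_event_fractions, time_genome_doubling,
                                 vaf_factor)
from carcinoscope.simcohort import simulate_paired_components

MB = 1_000_000


class TestCcf:
    def test_diploid_het_clonal(self):
        assert compute_ccf(0.5, 2, 1, 1.0, 1) == 1.0

    def test_post_doubling_single_allele(self):
        # a clonal mutation on one of four alleles reads VAF 0.25 in a pure tumor
        assert compute_ccf(0.25, 4, 2, 1.0, 1) == 1.0

    def test_closed_form_grid(self):
        purity = 0.6
        for vaf in np.linspace(0.05, 0.45, 9):
            expected = vaf * (purity * 2 + 2 * (1 - purity)) / purity
            assert compute_ccf(vaf, 2, 1, purity, 1) == pytest.approx(
                min(expected, 1.2))

    def test_inverse_consistency(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            ccf = rng.uniform(0.05, 1.0)
            purity = rng.uniform(0.2, 1.0)
            cn = int(rng.integers(1, 6))
            m = int(rng.integers(1, max(cn // 2, 1) + 1))
            vaf = ccf * vaf_factor(cn, purity, m)
            back = compute_ccf(vaf, cn, cn - m if cn - m >= 0 else 0, purity, m)
            assert back == pytest.approx(ccf, abs=1e-12)

    def test_zero_multiplicity_rejected(self):
        with pytest.raises(ValueError):
            compute_ccf(0.5, 2, 1, 1.0, 0)


def _planted_table(phis, weights, n, depth=77, q=0.5, seed=7):
    rng = np.random.default_rng(seed)
    truth = rng.choice(len(phis), size=n, p=weights)
    rows = []
    for i in range(n):
        da, db = rng.poisson(depth), rng.poisson(depth)
        rows.append((f"m{i}", rng.binomial(da, phis[truth[i]][0] * q), da,
                     rng.binomial(db, phis[truth[i]][1] * q), db))
    tab = pd.DataFrame(rows, columns=["id", "alt_a", "depth_a", "alt_b",
                                      "depth_b"]).set_index("id")
    tab["q_a"] = q
    tab["q_b"] = q
    return tab, truth


class TestCloneClustering:
    def test_single_clonal_population(self):
        tab, _ = _planted_table([(1.0, 1.0)], [1.0], 300, seed=1)
        nodes = cluster_clones(tab, random_state=0)
        assert len(nodes) == 1
        assert nodes[0].clone_id == "C1" and nodes[0].parent is None

    def test_three_clone_recovery(self):
        phis = [(1.0, 1.0), (0.6, 0.0), (0.0, 0.5)]
        tab, truth = _planted_table(phis, [0.5, 0.25, 0.25], 2000, seed=7)
        nodes = cluster_clones(tab, random_state=1)
        assert len(nodes) == 3
        # map each fitted clone to the nearest planted CCF pair
        assign = np.empty(len(tab), dtype=int)
        mapping = {}
        for ci, node in enumerate(nodes):
            for m in node.mutations:
                assign[int(m[1:])] = ci
            v = np.array([node.ccf["a"], node.ccf["b"]])
            mapping[ci] = int(np.argmin(((np.array(phis) - v) ** 2).sum(axis=1)))
        acc = np.mean([mapping[assign[i]] == truth[i] for i in range(len(tab))])
        assert acc >= 0.90

    def test_private_clones_attached_under_trunk(self):
        phis = [(1.0, 1.0), (0.6, 0.0), (0.0, 0.5)]
        tab, _ = _planted_table(phis, [0.5, 0.25, 0.25], 2000, seed=7)
        nodes = cluster_clones(tab, random_state=1)
        root = [n for n in nodes if n.parent is None]
        assert len(root) == 1 and root[0].clone_id == "C1"
        assert all(n.parent == "C1" for n in nodes if n is not root[0])

    def test_parent_ccf_dominates_children(self):
        phis = [(1.0, 1.0), (0.7, 0.6), (0.3, 0.2)]
        tab, _ = _planted_table(phis, [0.4, 0.3, 0.3], 1500, seed=3)
        nodes = cluster_clones(tab, random_state=2)
        by_id = {n.clone_id: n for n in nodes}
        for n in nodes:
            if n.parent is not None:
                for s in n.ccf:
                    assert by_id[n.parent].ccf[s] >= n.ccf[s] - 0.05

    def test_few_mutations_single_clone_fallback(self):
        tab, _ = _planted_table([(1.0, 1.0)], [1.0], 20, seed=0)
        with pytest.warns(UserWarning, match="single-clone"):
            nodes = cluster_clones(tab)
        assert len(nodes) == 1


class TestSharedEvents:
    def test_identical_sets(self):
        a = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [1, 2, 3],
                          "ref": ["A"] * 3, "alt": ["T"] * 3})
        rep = shared_event_fractions({"snv": a}, {"snv": a.copy()})
        assert rep.table.loc[0, "shared_fraction"] == 1.0

    def test_disjoint_sets(self):
        a = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [1, 2],
                          "ref": ["A"] * 2, "alt": ["T"] * 2})
        b = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [5, 6],
                          "ref": ["A"] * 2, "alt": ["T"] * 2})
        rep = shared_event_fractions({"snv": a}, {"snv": b})
        assert rep.table.loc[0, "shared_fraction"] == 0.0

    def test_empty_classes_undefined(self):
        empty = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        rep = shared_event_fractions({"snv": empty}, {"snv": empty.copy()})
        assert np.isnan(rep.table.loc[0, "shared_fraction"])

    def test_trunk_fraction_recovered_from_simulation(self):
        a, b, _ = simulate_paired_components(0.59, {"n_events": 1000}, seed=2)
        rep = shared_event_fractions({"snv": a}, {"snv": b})
        assert rep.table.loc[0, "shared_fraction"] == pytest.approx(0.59,
                                                                    abs=0.05)

    def test_symmetric_in_sample_order(self):
        a, b, _ = simulate_paired_components(0.5, {"n_events": 400}, seed=5)
        ab = shared_event_fractions({"snv": a}, {"snv": b}).table
        ba = shared_event_fractions({"snv": b}, {"snv": a}).table
        assert ab.loc[0, "shared_fraction"] == ba.loc[0, "shared_fraction"]
        assert ab.loc[0, "n_a_private"] == ba.loc[0, "n_b_private"]

    def test_sv_and_cna_matching(self, genome):
        svs = pd.DataFrame({
            "chrom1": ["chr1", "chr2"], "pos1": [1000, 5000],
            "chrom2": ["chr1", "chr2"], "pos2": [11_000, 9000]})
        moved = svs.copy()
        moved["pos1"] += 500  # within the 1 kb window
        rep = shared_event_fractions({"sv": svs}, {"sv": moved})
        assert rep.table.loc[0, "shared_fraction"] == 1.0
        segs = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [10 * MB],
                             "total_cn": [3], "major_cn": [2], "minor_cn": [1]})
        shifted = segs.copy()
        shifted["end"] = 12 * MB  # reciprocal overlap 10/12 > 0.5
        rep = shared_event_fractions({"cna": segs}, {"cna": shifted})
        assert rep.table.loc[0, "shared_fraction"] == 1.0


class TestDoublingTiming:
    def test_pure_tumor_theoretical_vafs(self):
        assert doubling_expected_vafs(1.0) == (0.5, 0.25)

    def test_contaminated_closed_form(self):
        vb, va = doubling_expected_vafs(0.6)
        assert vb == pytest.approx(2 * 0.6 / (2.4 + 0.8))
        assert va == pytest.approx(0.6 / (2.4 + 0.8))

    def test_classification_matches_likelihood_ratio_oracle(self):
        vb, va = doubling_expected_vafs(0.8)
        depth = 77
        muts = pd.DataFrame({
            "id": [f"m{a}" for a in range(depth + 1)],
            "chrom": "chr1", "pos": np.arange(depth + 1) + 1,
            "alt_count": np.arange(depth + 1),
            "ref_count": depth - np.arange(depth + 1)})
        res = time_genome_doubling(muts, 0.8)
        for alt in range(depth + 1):
            oracle = ("before" if binom.logpmf(alt, depth, vb)
                      >= binom.logpmf(alt, depth, va) else "after")
            assert res.per_mutation["timing"].iloc[alt] == oracle

    def test_recovery_at_depth_77(self):
        rng = np.random.default_rng(1)
        vb, va = doubling_expected_vafs(0.6)
        n = 500
        truth = rng.random(n) < 0.5
        d = rng.poisson(77, n).clip(min=1)
        alt = rng.binomial(d, np.where(truth, vb, va))
        muts = pd.DataFrame({"id": [f"m{i}" for i in range(n)],
                             "chrom": "chr1", "pos": np.arange(n) + 1,
                             "alt_count": alt, "ref_count": d - alt})
        res = time_genome_doubling(muts, 0.6)
        acc = np.mean(np.where(truth, "before", "after")
                      == res.per_mutation["timing"].to_numpy())
        assert acc >= 0.95

    def test_requires_doubled_genome_and_a2b2(self, genome):
        states = {(c, a): (1, 1) for c in genome.chroms for a in ("p", "q")}
        diploid = profile_from_arm_states(genome, states)
        muts = pd.DataFrame({"id": ["m0"], "chrom": ["chr1"], "pos": [100],
                             "alt_count": [30], "ref_count": [40]})
        res = time_genome_doubling(muts, 1.0, profile=diploid)
        assert not res.available and "ploidy" in res.reason
        tetra_no_a2b2 = profile_from_arm_states(
            genome, {k: (3, 1) for k in states})
        res = time_genome_doubling(muts, 1.0, profile=tetra_no_a2b2)
        assert not res.available and "A2B2" in res.reason

    def test_doubling_clone_placement(self):
        rng = np.random.default_rng(2)
        vb, va = doubling_expected_vafs(1.0)
        rows = []
        for i in range(200):  # trunk: pre-doubling
            d = rng.poisson(77)
            rows.append((f"t{i}", "chr1", i + 1, rng.binomial(d, vb), d, "C1"))
        for i in range(200):  # subclone: post-doubling
            d = rng.poisson(77)
            rows.append((f"s{i}", "chr1", 1000 + i, rng.binomial(d, va), d, "C2"))
        muts = pd.DataFrame(rows, columns=["id", "chrom", "pos", "alt_count",
                                           "depth", "clone"])
        muts["ref_count"] = muts["depth"] - muts["alt_count"]
        res = time_genome_doubling(muts, 1.0, clone_order=["C1", "C2"])
        assert res.doubling_clone == "C1"


class TestCloneSignatures:
    def test_single_signature_cohort(self):
        df = pd.DataFrame({"clone": ["C1"] * 30 + ["C2"] * 25,
                           "signature": ["S1"] * 55})
        out = clone_signature_proportions(df)
        assert (out["S1"] == 1.0).all()
        assert not out["low_confidence"].any()

    def test_constant_exposures_recovered(self):
        rng = np.random.default_rng(3)
        rows = []
        for clone, n in (("C1", 400), ("C2", 300), ("C3", 200)):
            sigs = rng.choice(["S1", "S2"], size=n, p=[0.7, 0.3])
            rows += [(clone, s) for s in sigs]
        out = clone_signature_proportions(pd.DataFrame(rows,
                                                       columns=["clone",
                                                                "signature"]))
        assert np.allclose(out["S1"], 0.7, atol=0.05)

    def test_unassigned_excluded_and_counted(self):
        df = pd.DataFrame({"clone": ["C1"] * 25,
                           "signature": ["S1"] * 20 + ["unassigned"] * 5})
        out = clone_signature_proportions(df)
        assert out.attrs["n_excluded_unassigned"] == 5
        assert out.loc["C1", "n_mutations"] == 20
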