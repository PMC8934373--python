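"""Hi-C metric checks against brute-force oracles and planted structure."""

import numpy as np
import pytest

import chromarch as ca
from chromarch import hic_metrics as hm
from conftest import brute_force_ice


def square_matrix(vals, bin_size=500_000, chrom="chr1"):
    vals = np.asarray(vals, dtype=float)
    n = vals.shape[0]
    return ca.ContactMatrix({chrom: n * bin_size}, bin_size, vals)


class TestICE:
    def test_balanced_matrix_is_fixed_point(self):
        n = 8
        mat = np.ones((n, n)) * 4.0
        m = square_matrix(mat)
        out, biases = ca.ice_normalize(m, tol=1e-12)
        assert np.allclose(biases, 1.0)
        assert np.allclose(out.matrix, mat)

    def test_matches_naive_iteration_oracle(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(1, 50, (3, 3)).astype(float)
        mat = np.triu(mat) + np.triu(mat, 1).T
        m = square_matrix(mat)
        out, _ = ca.ice_normalize(m, max_iter=80, tol=0.0, mask_quantile=0.0)
        oracle = brute_force_ice(mat, np.ones(3, bool), 80)
        assert np.allclose(out.matrix, oracle, atol=1e-10)

    def test_zero_coverage_row_masked(self):
        mat = np.array([[4., 2., 0.], [2., 6., 0.], [0., 0., 0.]])
        m = square_matrix(mat)
        out, biases = ca.ice_normalize(m, tol=1e-10)
        assert not out.mask[2]
        assert np.isnan(biases[2])
        s = out.matrix.sum(axis=1)[:2]
        assert s.std() / s.mean() < 1e-8

    def test_row_sum_cv_below_tol(self, toy_matrix):
        m, _ = toy_matrix
        out, _ = ca.ice_normalize(m, tol=1e-6)
        s = out.matrix.sum(axis=1)[out.mask]
        assert s.std() / s.mean() <= 1e-6

    def test_all_masked_raises(self):
        m = square_matrix(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            ca.ice_normalize(m)


class TestDepthNormalize:
    def test_scale_by_total(self):
        mat = np.full((4, 4), 2.0)
        m = square_matrix(mat)
        out = ca.depth_normalize(m)
        assert np.triu(out.matrix).sum() == pytest.approx(1.0)

    def test_different_depths_converge(self):
        base = dict(chrom_lengths={"chr1": 10_000_000}, bin_size=500_000,
                    c_comp=1.0, c_tad=1.0, seed=0)
        m1, _ = ca.gen_contact_matrix(ca.HiCSimConfig(depth=2e5, **base))
        m2, _ = ca.gen_contact_matrix(ca.HiCSimConfig(depth=2e6, **base))
        n1, n2 = ca.depth_normalize(m1), ca.depth_normalize(m2)
        rel = np.abs(n1.matrix - n2.matrix) / np.maximum(n2.matrix, 1e-12)
        near = np.abs(np.subtract.outer(np.arange(20), np.arange(20))) <= 3
        assert np.median(rel[near]) < 0.2  # Poisson noise at low depth

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ca.depth_normalize(square_matrix(np.zeros((4, 4))))


class TestCompartments:
    @pytest.fixture(scope="class")
    def planted(self):
        cfg = ca.HiCSimConfig(chrom_lengths={"chr1": 50_000_000},
                              bin_size=500_000, c_comp=3.0, c_tad=1.0,
                              depth=2e6, seed=2)
        m, truth = ca.gen_contact_matrix(cfg)
        iced, _ = ca.ice_normalize(m)
        return iced, truth

    def test_label_recovery(self, planted):
        iced, truth = planted
        comp = ca.compartment_pc1(iced, truth["gene_density"])
        lab = comp.labels
        ok = lab != ""
        agree = (lab[ok] == truth["class_labels"]["chr1"][ok]).mean()
        assert agree >= 0.95

    def test_gene_density_swap_flips_labels(self, planted):
        iced, truth = planted
        gd = truth["gene_density"]
        flipped = ca.GenomicTrack(dict(gd.chroms), gd.bin_size,
                                  {"chr1": -gd.values_for("chr1")})
        a = ca.compartment_pc1(iced, gd)
        b = ca.compartment_pc1(iced, flipped)
        ok = (a.labels != "") & (b.labels != "")
        assert np.all(a.labels[ok] != b.labels[ok])

    def test_structureless_matrix_low_variance(self):
        cfg = ca.HiCSimConfig(chrom_lengths={"chr1": 50_000_000},
                              bin_size=500_000, c_comp=1.0, c_tad=1.0,
                              depth=2e6, seed=3)
        m, truth = ca.gen_contact_matrix(cfg)
        comp_null = ca.compartment_pc1(m, truth["gene_density"])
        cfg_sig = ca.HiCSimConfig(**{**cfg.__dict__, "c_comp": 3.0})
        ms, ts = ca.gen_contact_matrix(cfg_sig)
        comp_sig = ca.compartment_pc1(ms, ts["gene_density"])
        assert comp_null.variance_explained["chr1"] < \
            comp_sig.variance_explained["chr1"]

    def test_small_chromosome_skipped(self):
        cfg = ca.HiCSimConfig(chrom_lengths={"chr1": 2_000_000},
                              bin_size=500_000, depth=1e5, seed=0)
        m, truth = ca.gen_contact_matrix(cfg)
        with pytest.warns(UserWarning):
            comp = ca.compartment_pc1(m, truth["gene_density"])
        assert np.isnan(comp.pc1).all()

    def test_rescaling_invariance(self, planted):
        iced, truth = planted
        a = ca.compartment_pc1(iced, truth["gene_density"])
        scaled = ca.ContactMatrix(dict(iced.chroms), iced.bin_size,
                                  iced.matrix * 7.3, iced.mask, iced.norm)
        b = ca.compartment_pc1(scaled, truth["gene_density"])
        assert np.array_equal(a.labels, b.labels)


class TestCompartmentSwitch:
    def _track(self, pc1):
        pc1 = np.asarray(pc1, dtype=float)
        labels = np.where(pc1 > 0, "A", np.where(pc1 < 0, "B", ""))
        labels = labels.astype(object)
        labels[np.isnan(pc1)] = ""
        return ca.CompartmentTrack({"chr1": pc1.size * 500_000}, 500_000,
                                   pc1, labels, {}, {})

    def test_identical_tracks_stable(self):
        a = self._track([1, -1, 1, -1.0])
        out = ca.compartment_switch(a, a)
        assert out == {"A_to_B": 0.0, "B_to_A": 0.0, "stable": 1.0}

    def test_sign_flip_switches_everything(self):
        pc1 = np.array([1, -1, 2, -2.0])
        out = ca.compartment_switch(self._track(pc1), self._track(-pc1))
        assert out["A_to_B"] + out["B_to_A"] == pytest.approx(1.0)

    def test_planted_flip_fraction(self):
        rng = np.random.default_rng(0)
        n = 2000
        pc1 = rng.choice([-1.0, 1.0], n)
        flip = rng.random(n) < 0.05
        out = ca.compartment_switch(self._track(pc1),
                                    self._track(np.where(flip, -pc1, pc1)))
        total = out["A_to_B"] + out["B_to_A"]
        se = np.sqrt(0.05 * 0.95 / n)
        assert total == pytest.approx(0.05, abs=4 * se)
        assert out["stable"] + total == pytest.approx(1.0)


class TestInsulationAndTADs:
    @pytest.fixture(scope="class")
    def planted(self):
        bounds = list(range(1_600_000, 16_000_000, 1_600_000))
        cfg = ca.HiCSimConfig(chrom_lengths={"chr1": 16_000_000},
                              bin_size=40_000, c_comp=1.0, c_tad=3.0,
                              tad_boundaries={"chr1": bounds},
                              depth=5e6, seed=3)
        m, truth = ca.gen_contact_matrix(cfg)
        return m, truth, cfg

    def test_planted_boundary_is_local_minimum(self, planted):
        m, truth, _ = planted
        prof = ca.insulation_profile(m)
        strong = [b for c, b, s in prof.boundaries if s >= 0.1]
        for planted_bin in truth["tad_boundaries"]["chr1"]:
            # called boundary bin b puts the edge at b+1
            assert any(abs((b + 1) - planted_bin) <= 1 for b in strong)

    def test_uniform_matrix_no_strong_boundary(self):
        cfg = ca.HiCSimConfig(chrom_lengths={"chr1": 16_000_000},
                              bin_size=40_000, c_comp=1.0, c_tad=1.0,
                              depth=5e6, seed=4)
        m, _ = ca.gen_contact_matrix(cfg)
        prof = ca.insulation_profile(m)
        assert all(s < 0.1 for _, _, s in prof.boundaries)

    def test_replicates_correlate_more_than_contrasts(self):
        bounds = list(range(1_600_000, 16_000_000, 1_600_000))
        base = dict(chrom_lengths={"chr1": 16_000_000}, bin_size=40_000,
                    c_comp=1.0, c_tad=3.0, depth=5e6)
        reps = []
        for seed in (10, 11):
            m, _ = ca.gen_contact_matrix(ca.HiCSimConfig(
                tad_boundaries={"chr1": bounds}, seed=seed, **base))
            reps.append(ca.insulation_profile(m).scores)
        other_bounds = list(range(800_000, 16_000_000, 2_400_000))
        mo, _ = ca.gen_contact_matrix(ca.HiCSimConfig(
            tad_boundaries={"chr1": other_bounds}, seed=12, **base))
        contrast = ca.insulation_profile(mo).scores
        ok = np.isfinite(reps[0]) & np.isfinite(reps[1]) & \
            np.isfinite(contrast)
        r_rep = np.corrcoef(reps[0][ok], reps[1][ok])[0, 1]
        r_con = np.corrcoef(reps[0][ok], contrast[ok])[0, 1]
        assert r_rep >= 0.95
        assert r_rep > r_con

    def test_tad_arithmetic_and_size_filter(self):
        prof = ca.InsulationProfile(
            {"chr1": 2_000_000}, 40_000, 480_000,
            np.zeros(50), np.zeros(50),
            [("chr1", 9, 1.0), ("chr1", 24, 1.0)])
        tads = ca.call_tads(prof)
        assert ("chr1", 400_000, 1_000_000) in tads.intervals
        assert ("chr1", 0, 400_000) in tads.intervals

    def test_small_tad_filtered(self):
        # boundaries 160 kb apart: the block in between is dropped
        prof = ca.InsulationProfile(
            {"chr1": 2_000_000}, 40_000, 480_000,
            np.zeros(50), np.zeros(50),
            [("chr1", 9, 1.0), ("chr1", 13, 1.0)])
        tads = ca.call_tads(prof)
        assert all(e - s >= 200_000 for _, s, e in tads.intervals)
        assert ("chr1", 400_000, 560_000) not in tads.intervals

    def test_no_boundaries_single_tad(self):
        prof = ca.InsulationProfile({"chr1": 2_000_000}, 40_000, 480_000,
                                    np.zeros(50), np.zeros(50), [])
        tads = ca.call_tads(prof)
        assert tads.intervals == [("chr1", 0, 2_000_000)]


class TestTADScore:
    def test_whole_chromosome_tad_scores_one(self):
        rng = np.random.default_rng(1)
        mat = rng.integers(0, 9, (10, 10)).astype(float)
        mat = np.triu(mat) + np.triu(mat, 1).T
        m = square_matrix(mat, bin_size=40_000)
        tads = ca.TADSet([("chr1", 0, 400_000)])
        assert ca.tad_score(m, tads)[0] == pytest.approx(1.0)

    def test_two_equal_blocks(self):
        block = np.full((5, 5), 2.0)
        mat = np.zeros((10, 10))
        mat[:5, :5] = block
        mat[5:, 5:] = block
        m = square_matrix(mat, bin_size=40_000)
        tads = ca.TADSet([("chr1", 0, 200_000), ("chr1", 200_000, 400_000)])
        assert np.allclose(ca.tad_score(m, tads), [0.5, 0.5])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 30, (20, 20)).astype(float)
        mat = np.triu(mat) + np.triu(mat, 1).T
        m = square_matrix(mat, bin_size=40_000)
        tads = ca.TADSet([("chr1", 0, 240_000), ("chr1", 280_000, 600_000)])
        scores = ca.tad_score(m, tads)
        # brute force: sum over all (i <= j) pairs
        total = sum(mat[i, j] for i in range(20) for j in range(i, 20))
        for k, (c, s, e) in enumerate(tads.intervals):
            b0, b1 = s // 40_000, e // 40_000
            intra = sum(mat[i, j] for i in range(b0, b1)
                        for j in range(i, b1))
            assert scores[k] == pytest.approx(intra / total, abs=1e-12)
        assert scores.sum() <= 1.0


class TestPairBoundaries:
    def test_identical_sets(self):
        a = ca.TADSet([("chr1", 0, 400_000), ("chr1", 400_000, 1_000_000)])
        out = ca.pair_boundaries(a, a, bin_size=40_000)
        assert np.all(out["distances"] == 0)
        assert out["frac_within_k_bins"] == 1.0

    def test_shifted_by_one_bin(self):
        a = ca.TADSet([("chr1", 400_000, 1_000_000)])
        b = ca.TADSet([("chr1", 440_000, 1_040_000)])
        out = ca.pair_boundaries(a, b, bin_size=40_000)
        assert np.all(out["distances"] == 40_000)
        assert out["frac_within_k_bins"] == 1.0

    def test_jittered_mean_distance(self):
        rng = np.random.default_rng(3)
        edges = np.arange(1, 50) * 400_000
        jit = edges + rng.choice([-40_000, 40_000], edges.size)
        a = ca.TADSet([("chr1", s, e) for s, e in
                       zip(np.r_[0, edges], np.r_[edges, 20_000_000])])
        b = ca.TADSet([("chr1", s, e) for s, e in
                       zip(np.r_[0, jit], np.r_[jit, 20_000_000])])
        out = ca.pair_boundaries(a, b, bin_size=40_000)
        internal = out["distances"][(out["distances"] > 0)]
        assert np.mean(internal) == pytest.approx(40_000, rel=0.05)


class TestRatios:
    def test_block_diagonal_trans_zero(self):
        cfg = ca.HiCSimConfig(
            chrom_lengths={"chr1": 5_000_000, "chr2": 5_000_000},
            bin_size=500_000, beta=0.0, depth=2e5, seed=0)
        m, _ = ca.gen_contact_matrix(cfg)
        assert all(v == 0.0 for v in ca.trans_ratio(m).values())

    def test_uniform_matrix_closed_form(self):
        # two chromosomes of 4 bins each, every entry equal:
        # per chrom, cis = 10 unordered pairs, trans = 16 ordered cells
        chroms = {"chr1": 2_000_000, "chr2": 2_000_000}
        m = ca.ContactMatrix(chroms, 500_000, np.ones((8, 8)))
        tr = ca.trans_ratio(m)
        assert tr["chr1"] == pytest.approx(16 / 26)

    def test_trans_monotone_in_beta(self):
        vals = []
        for beta in (0.0, 0.01, 0.05):
            cfg = ca.HiCSimConfig(
                chrom_lengths={"chr1": 10_000_000, "chr2": 10_000_000},
                bin_size=500_000, beta=beta, depth=2e6, seed=5)
            m, _ = ca.gen_contact_matrix(cfg)
            vals.append(ca.trans_ratio(m)["chr1"])
        assert vals[0] < vals[1] < vals[2]

    def _comp_track(self, labels, bin_size):
        labels = np.asarray(labels, dtype=object)
        pc1 = np.where(labels == "A", 1.0, -1.0)
        return ca.CompartmentTrack(
            {"chr1": labels.size * bin_size}, bin_size, pc1, labels, {}, {})

    def test_ab_ratio_zero_when_no_mixing(self):
        n, bs = 20, 500_000
        labels = ["A"] * 10 + ["B"] * 10
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                same = (i < 10) == (j < 10)
                if same and abs(i - j) * bs >= 2_000_000:
                    mat[i, j] = mat[j, i] = 5.0
        m = square_matrix(mat, bin_size=bs)
        out = ca.ab_ratio(m, self._comp_track(labels, bs))
        assert out["chr1"] == 0.0

    def test_short_range_pairs_excluded(self):
        n, bs = 20, 500_000
        labels = ["A", "B"] * 10
        mat = np.zeros((n, n))
        mat[0, 3] = mat[3, 0] = 100.0   # 1.5-Mb separation: excluded
        mat[0, 10] = mat[10, 0] = 1.0
        mat[1, 11] = mat[11, 1] = 1.0
        m = square_matrix(mat, bin_size=bs)
        out = ca.ab_ratio(m, self._comp_track(labels, bs))
        # only the two long-range same-class pairs survive -> ratio 0
        assert out["chr1"] == 0.0

    def test_ab_monotone_in_mixing(self):
        vals = []
        for c_comp in (3.0, 2.0, 1.2):
            cfg = ca.HiCSimConfig(chrom_lengths={"chr1": 40_000_000},
                                  bin_size=500_000, c_comp=c_comp,
                                  c_tad=1.0, depth=2e6, seed=6)
            m, truth = ca.gen_contact_matrix(cfg)
            comp = self._comp_track(truth["class_labels"]["chr1"], 500_000)
            vals.append(ca.ab_ratio(m, comp)["chr1"])
        assert vals[0] < vals[1] < vals[2]

    def test_x_chromosome_excludable(self):
        chroms = {"chr1": 2_000_000, "chrX": 2_000_000}
        m = ca.ContactMatrix(chroms, 500_000, np.ones((8, 8)))
        labels = np.array(["A", "B"] * 4, dtype=object)
        comp = ca.CompartmentTrack(chroms, 500_000,
                                   np.where(labels == "A", 1.0, -1.0),
                                   labels, {}, {})
        out = ca.ab_ratio(m, comp, exclude_chroms=("chrX",))
        assert "chrX" not in out
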