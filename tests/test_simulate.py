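import io
import math

import numpy as np
import pytest

from ngstheta.likelihoods import genotype_likelihood, AllelePair
from ngstheta.simulate import (
    GenotypeMatrix,
    SimulationParams,
    counts_to_gls,
    load_empirical_tables,
    neutral_prior,
    read_ms,
    simulate_genotypes_from_sfs,
    simulate_neutral_genotypes,
    simulate_read_counts,
    simulate_reads,
    sweep_like_prior,
)
from ngstheta.spectrum import FrequencySpectrum, theta_estimators


class TestParams:
    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(error_rate=0.0)
        with pytest.raises(ValueError):
            SimulationParams(mean_depth=-1)
        with pytest.raises(ValueError):
            SimulationParams(mu=0.0)


class TestCoalescent:
    def test_same_seed_same_matrix(self):
        p = SimulationParams(L=50_000, seed=9)
        a = simulate_neutral_genotypes(p)
        b = simulate_neutral_genotypes(p)
        assert np.array_equal(a.dosages, b.dosages)
        assert np.array_equal(a.positions, b.positions)

    def test_vanishing_theta_gives_no_sites(self):
        p = SimulationParams(L=10_000, mu=1e-15, seed=4)
        gm = simulate_neutral_genotypes(p)
        assert gm.dosages.shape[0] == 0
        assert gm.true_sfs().counts[0] == 10_000

    def test_watterson_calibration(self):
        # E[S] = a1 * theta * L under the neutral coalescent
        L, n_dip, reps = 200_000, 10, 30
        theta_site = 4 * 10_000 * 2.35e-8
        a1 = sum(1.0 / i for i in range(1, 20))
        expected = a1 * theta_site * L
        S = []
        for seed in range(1, reps + 1):
            gm = simulate_neutral_genotypes(
                SimulationParams(n_diploid=n_dip, L=L, seed=seed)
            )
            S.append(gm.true_sfs().segregating_sites)
        se = np.std(S, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(S) - expected) < 3.5 * se


MS_EXAMPLE = """\
ms 4 2
1 2 3

//
segsites: 2
positions: 0.25 0.5
01
11
00
10

//
segsites: 0
"""


class TestMsReader:
    def test_hand_collapse(self):
        reps = read_ms(io.StringIO(MS_EXAMPLE), L=1000, n_diploid=2)
        assert len(reps) == 2
        gm = reps[0]
        # haplotype pairs (h1,h2), (h3,h4): site1 -> (1,1); site2 -> (2,0)
        assert gm.dosages.tolist() == [[1, 1], [2, 0]]
        # floor(pos*L)+1 mapping
        assert gm.positions.tolist() == [251, 501]
        assert reps[1].dosages.shape[0] == 0

    def test_position_collisions_shift(self):
        text = "//\nsegsites: 2\npositions: 0.5 0.5\n01\n01\n"
        (gm,) = read_ms(io.StringIO(text), L=10)
        assert gm.positions.tolist() == [6, 7]

    def test_odd_haplotypes_rejected(self):
        text = "//\nsegsites: 1\npositions: 0.5\n0\n1\n1\n"
        with pytest.raises(ValueError, match="odd"):
            read_ms(io.StringIO(text), L=10)

    def test_malformed_block_reports_line(self):
        text = "//\nsegsites: nonsense\n"
        with pytest.raises(ValueError, match="line 2"):
            read_ms(io.StringIO(text), L=10)


class TestReadSimulation:
    def test_zero_depth_empty_pileups(self):
        gm = GenotypeMatrix(np.zeros((0, 3), dtype=np.int8), np.zeros(0, int), 50)
        _, _, pileups = simulate_reads(gm, mean_depth=0.0, error_rate=0.01, seed=1)
        assert all(len(b) == 0 for p in pileups for b in p.bases)

    def test_error_free_reads_match_alleles(self):
        gm = GenotypeMatrix(np.zeros((0, 4), dtype=np.int8), np.zeros(0, int), 200)
        positions, pairs, pileups = simulate_reads(
            gm, mean_depth=4.0, error_rate=1e-12, seed=2
        )
        for pair, pile in zip(pairs, pileups):
            for bases in pile.bases:
                assert all(b == pair.first for b in bases)

    def test_depth_and_error_statistics(self):
        gm = GenotypeMatrix(np.zeros((0, 5), dtype=np.int8), np.zeros(0, int), 2000)
        d, e = 4.0, 0.01
        _, pairs, pileups = simulate_reads(gm, mean_depth=d, error_rate=e, seed=3)
        depths, n_err, n_tot = [], 0, 0
        for pair, pile in zip(pairs, pileups):
            for bases in pile.bases:
                depths.append(len(bases))
                n_tot += len(bases)
                n_err += sum(b != pair.first for b in bases)
        n_cells = len(depths)
        assert abs(np.mean(depths) - d) < 3 * math.sqrt(d / n_cells)
        assert abs(n_err / n_tot - e) < 3 * math.sqrt(e / n_tot)

    def test_counts_path_matches_pileup_likelihoods(self):
        # the sufficient-statistic fast path must give the same GLs as
        # evaluating the full pileup
        e = 0.01
        bases, pair = "AACAT", AllelePair("A", "C")
        direct = genotype_likelihood(bases, [e] * 5, pair)
        ka = sum(b == "A" for b in bases)
        kd = sum(b == "C" for b in bases)
        fast = counts_to_gls(np.array([[ka]]), np.array([[kd]]), e)[0, 0]
        assert fast == pytest.approx(direct, abs=1e-5)

    def test_count_moments(self):
        rng_seed = 7
        dosages = np.array([[0, 1, 2]], dtype=np.int8)
        gm = GenotypeMatrix(dosages, np.array([500]), 1000)
        ka, kd, ko1, ko2 = simulate_read_counts(gm, 6.0, 0.005, seed=rng_seed)
        total = ka.astype(int) + kd + ko1 + ko2
        assert abs(total.mean() - 6.0) < 0.1
        row = 499
        assert kd[row, 0] <= 2  # genotype 0: derived reads are errors only
        assert ka[row, 2] <= 2  # genotype 2: ancestral reads are errors only


class TestEmpiricalTables:
    def test_constant_depth(self):
        model = load_empirical_tables([(4, 1.0)], [(20, 1.0)])
        rng = np.random.default_rng(0)
        assert np.all(model.sample_depth(rng, 100) == 4)

    def test_mean_error_matches_quality_mix(self):
        model = load_empirical_tables([(2, 1), (6, 1)], [(28, 1.0)])
        assert model.mean_error == pytest.approx(10 ** (-2.8), rel=1e-9)

    def test_same_seed_same_draws(self):
        model = load_empirical_tables([(1, 1), (3, 2)], [(10, 1), (30, 3)])
        a = model.sample_depth(np.random.default_rng(5), 20)
        b = model.sample_depth(np.random.default_rng(5), 20)
        assert np.array_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            load_empirical_tables([], [(20, 1)])


class TestSpectrumGenerators:
    def test_neutral_prior_shape(self):
        p = neutral_prior(10, 0.001)
        assert p.sum() == pytest.approx(1.0)
        assert p[1] / p[5] == pytest.approx(5.0)

    def test_sweep_prior_matches_requested_moments(self):
        L = 1_000_000
        p = sweep_like_prior(50, 649.8, 567.1, 745.1, L)
        t = theta_estimators(FrequencySpectrum(p * L, 50))
        assert t.tW == pytest.approx(649.8, rel=1e-9)
        assert t.tP == pytest.approx(567.1, rel=1e-9)
        assert t.tFL == pytest.approx(745.1, rel=1e-9)

    def test_genotypes_from_sfs_match_drawn_counts(self):
        probs = neutral_prior(10, 0.02)
        gm = simulate_genotypes_from_sfs(probs, L=5000, n_diploid=5, seed=3)
        assert gm.dosages.sum(axis=1).min() >= 1
        sfs = gm.true_sfs()
        assert sfs.total == 5000
        # empirical segregating fraction close to the generating mass
        seg_prob = probs[1:-1].sum()
        n_seg = sfs.segregating_sites
        assert abs(n_seg - 5000 * seg_prob) < 3 * math.sqrt(5000 * seg_prob)
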