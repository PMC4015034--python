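import math

import numpy as np
import pytest

from ngstheta.spectrum import (
    FrequencySpectrum,
    compute_constants,
    estimator_weights,
    fold,
    fuli_d,
    fuli_f,
    read_sfs,
    standardize_scores,
    tajimas_d,
    theta_estimators,
    write_sfs,
)

from oracle import fuli_d_oracle, fuli_f_oracle, tajima_d_oracle


class TestConstants:
    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            compute_constants(2)

    def test_harmonic_sums_n4(self):
        c = compute_constants(4)
        assert c.a1 == pytest.approx(1 + 1 / 2 + 1 / 3, abs=1e-12)
        assert c.a2 == pytest.approx(1 + 1 / 4 + 1 / 9, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 10, 25, 60])
    def test_finite(self, n):
        c = compute_constants(n)
        for v in (c.e1, c.e2, c.uD, c.vD, c.uF, c.vF):
            assert math.isfinite(v)


class TestThetaEstimators:
    def test_zero_spectrum(self):
        t = theta_estimators(FrequencySpectrum(np.zeros(11), 10))
        assert t.tW == t.tP == t.tFL == t.tH == t.S == 0

    def test_single_pair_identity(self):
        t = theta_estimators(FrequencySpectrum([0, 1, 0], 2))
        assert t.tP == pytest.approx(1.0)

    def test_singleton_spectrum_n4(self):
        t = theta_estimators(FrequencySpectrum([0, 3, 0, 0, 0], 4))
        assert t.S == 3
        assert t.tW == pytest.approx(3 / (1 + 1 / 2 + 1 / 3))
        assert t.tFL == 3
        assert t.tP == pytest.approx(1.5)

    def test_linearity(self, rng):
        eta = rng.uniform(0, 5, size=21)
        base = theta_estimators(FrequencySpectrum(eta, 20))
        for c in (0.25, 3.0, 17.5):
            scaled = theta_estimators(FrequencySpectrum(c * eta, 20))
            for field in ("tW", "tP", "tFL", "tH", "S"):
                assert getattr(scaled, field) == pytest.approx(
                    c * getattr(base, field), rel=1e-12
                )

    @pytest.mark.parametrize("n", [4, 10, 24, 50])
    def test_neutral_expectation_recovers_theta(self, n):
        # under the standard neutral model E[eta_i] = theta / i, and both
        # Watterson and pi estimators must return exactly theta
        theta = 7.3
        eta = np.zeros(n + 1)
        eta[1:n] = theta / np.arange(1, n)
        t = theta_estimators(FrequencySpectrum(eta, n))
        assert t.tW == pytest.approx(theta, rel=1e-12)
        assert t.tP == pytest.approx(theta, rel=1e-12)

    def test_weights_zero_outside_polymorphic(self):
        w = estimator_weights(10)
        for alpha in w.values():
            assert alpha[0] == 0 and alpha[10] == 0


class TestNeutralityTests:
    def test_undefined_when_no_segregating_sites(self):
        sfs = FrequencySpectrum(np.zeros(11), 10)
        assert math.isnan(tajimas_d(sfs))
        assert math.isnan(fuli_d(sfs))
        assert math.isnan(fuli_f(sfs))

    def test_zero_numerator_gives_zero_d(self):
        # eta proportional to theta/i has tP == tW exactly
        n = 10
        eta = np.zeros(n + 1)
        eta[1:n] = 5.0 / np.arange(1, n)
        assert tajimas_d(FrequencySpectrum(eta, n)) == pytest.approx(0.0, abs=1e-12)

    def test_singletons_force_negative_d(self):
        eta = np.zeros(11)
        eta[1] = 5
        assert tajimas_d(FrequencySpectrum(eta, 10)) < 0

    def test_fuli_d_zero_numerator(self):
        n = 6
        a1 = sum(1 / i for i in range(1, n))
        eta = np.zeros(n + 1)
        eta[1] = 2.0
        eta[2] = a1 * 2.0 - 2.0  # S = a1 * eta_1
        assert fuli_d(FrequencySpectrum(eta, n)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 6, 10, 25, 41, 60])
    def test_matches_independent_oracle(self, n, rng):
        for _ in range(20):
            eta = np.zeros(n + 1)
            eta[1:n] = rng.integers(0, 20, size=n - 1)
            if eta[1:n].sum() == 0:
                eta[1] = 3
            sfs = FrequencySpectrum(eta, n)
            lst = eta.tolist()
            assert tajimas_d(sfs) == pytest.approx(tajima_d_oracle(lst), abs=1e-10)
            assert fuli_d(sfs) == pytest.approx(fuli_d_oracle(lst), abs=1e-10)
            assert fuli_f(sfs) == pytest.approx(fuli_f_oracle(lst), abs=1e-10)

    def test_tajimas_d_matches_tskit(self):
        # fully independent check on simulated genealogies
        import msprime

        ts = msprime.sim_ancestry(
            samples=10, sequence_length=2e5, recombination_rate=1e-8,
            population_size=10_000, random_seed=5,
        )
        mts = msprime.sim_mutations(
            ts, rate=2.35e-8, model=msprime.BinaryMutationModel(),
            discrete_genome=False, random_seed=6,
        )
        counts = np.zeros(21)
        for var in mts.variants():
            counts[int(var.genotypes.sum())] += 1
        ours = tajimas_d(FrequencySpectrum(counts, 20))
        assert ours == pytest.approx(float(mts.Tajimas_D()), rel=1e-9)

    def test_d_moves_with_spectrum_shape(self):
        n = 20
        eta = np.zeros(n + 1)
        eta[1:n] = 3.0
        base = tajimas_d(FrequencySpectrum(eta, n))
        rare = eta.copy()
        rare[1] += 10
        mid = eta.copy()
        mid[n // 2] += 10
        assert tajimas_d(FrequencySpectrum(rare, n)) < base
        assert tajimas_d(FrequencySpectrum(mid, n)) > base


class TestFold:
    def test_hand_example(self):
        folded = fold(FrequencySpectrum([1, 2, 3, 4, 5], 4))
        assert folded.counts.tolist() == [6, 6, 3, 0, 0]

    def test_idempotent_and_mass_conserving(self, rng):
        eta = rng.uniform(0, 4, size=13)
        sfs = FrequencySpectrum(eta, 12)
        once = fold(sfs)
        assert once.total == pytest.approx(sfs.total)
        assert np.allclose(fold(once).counts, once.counts)

    def test_symmetric_spectrum_estimators_agree(self, rng):
        n = 10
        eta = np.zeros(n + 1)
        half = rng.uniform(0, 5, size=n // 2)
        eta[1 : n // 2 + 1] = half
        eta[n // 2 : n] = half[::-1]
        sfs = FrequencySpectrum(eta, n)
        t_raw = theta_estimators(sfs)
        t_fold = theta_estimators(fold(sfs))
        assert t_fold.tW == pytest.approx(t_raw.tW)
        assert t_fold.tP == pytest.approx(t_raw.tP)


class TestStandardize:
    def test_identity_reference(self, rng):
        v = rng.normal(size=50)
        z = standardize_scores(v, v)
        assert np.mean(z) == pytest.approx(0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1, rel=1e-12)

    def test_hand_example(self):
        z = standardize_scores([2, 4], [0, 2])
        sd = math.sqrt(2.0)
        assert z == pytest.approx([1 / sd, 3 / sd])

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            standardize_scores([1.0], [2.0, 2.0])

    def test_nan_reference_ignored(self):
        z = standardize_scores([2, 4], [0, 2, math.nan])
        assert z == pytest.approx(standardize_scores([2, 4], [0, 2]))


class TestSfsIO:
    def test_roundtrip(self, tmp_path, rng):
        sfs = FrequencySpectrum(rng.uniform(0, 9, size=9), 8)
        path = tmp_path / "x.sfs"
        write_sfs(path, sfs)
        back = read_sfs(path)
        assert back.n_chrom == 8
        assert np.allclose(back.counts, sfs.counts, rtol=1e-11)


class TestInvariants:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FrequencySpectrum(np.zeros(5), 10)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            FrequencySpectrum([1, -1, 0], 2)
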