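"""RDM comparison machinery: distances, fits, ceilings, group inference."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import seqrecode as sq
from seqrecode.errors import DegenerateInputError, SeqrecodeError
from seqrecode.rsa import PatternMatrix, condition_mask, permutation_rs


def random_rdm(n, rng):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return sq.RDM([str(i) for i in range(n)], m)


class TestCorrelationDistance:
    def test_identical(self, rng):
        u = rng.standard_normal(30)
        assert sq.correlation_distance(u, u) == pytest.approx(0.0)

    def test_negated(self, rng):
        u = rng.standard_normal(30)
        assert sq.correlation_distance(u, -u) == pytest.approx(2.0)

    def test_orthogonal_centred(self):
        u = np.array([1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, 1.0, -1.0, -1.0])
        assert sq.correlation_distance(u, v) == pytest.approx(1.0)

    def test_constant_raises(self):
        with pytest.raises(DegenerateInputError):
            sq.correlation_distance(np.ones(5), np.arange(5.0))


class TestPatternRDM:
    def test_symmetry_and_duplicates(self, rng):
        X = rng.standard_normal((6, 40))
        X[3] = X[0]
        rdm = sq.pattern_rdm(PatternMatrix(X))
        assert np.allclose(rdm.values, rdm.values.T)
        assert np.all(np.diag(rdm.values) == 0)
        assert rdm.values[3, 0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_row_marked_missing(self, rng):
        X = rng.standard_normal((5, 30))
        X[2] = 1.0
        with pytest.warns(UserWarning):
            rdm = sq.pattern_rdm(PatternMatrix(X))
        assert np.isnan(rdm.values[2, 0]) and np.isnan(rdm.values[4, 2])
        assert np.isfinite(rdm.values[1, 0])

    def test_voxel_offset_invariance(self, rng):
        """Correlation distance centres rows, so per-voxel offsets added
        to every pattern shift nothing."""
        X = rng.standard_normal((8, 50))
        offset = rng.standard_normal(50) * 10
        a = sq.pattern_rdm(PatternMatrix(X)).values
        b = sq.pattern_rdm(PatternMatrix(X + offset)).values
        # offsets do change correlation distances per-pair unless constant
        # across voxels; a constant shift per *pattern row* cancels exactly
        c = sq.pattern_rdm(PatternMatrix(X + 3.7)).values
        assert np.allclose(a, c)

    def test_noiseless_item_position_patterns_match_hamming(self, schedule):
        """Patterns built from item-position codes at sigma = 0 order by
        the Hamming model: at enough voxels the random codes are close to
        orthogonal, so pattern distances separate cleanly by Hamming level
        (the model's heavy ties cap raw Spearman below 1)."""
        spec = sq.GroundTruthSpec("item-position", n_voxels=4000,
                                  noise_sigma=(0.0, 0.0), seed=3)
        cohort = sq.simulate_cohort(schedule, spec, n_subjects=1)
        data = sq.pattern_rdm(cohort.patterns[0])
        model = sq.model_rdm(schedule.sequences(), "hamming")
        m = model.lower_triangle()
        d = data.lower_triangle()
        level_max = [d[m == h].max() for h in sorted(np.unique(m))]
        level_min = [d[m == h].min() for h in sorted(np.unique(m))]
        for lo, hi in zip(level_min[1:], level_max[:-1]):
            assert lo > hi  # perfect separation between adjacent levels
        assert spearmanr(m, d).statistic > 0.9


class TestRsaCorrelation:
    def test_perfect_fit(self, rng):
        d = random_rdm(10, rng)
        assert sq.rsa_correlation(d, d) == pytest.approx(1.0)

    def test_rank_reversal(self, rng):
        d = random_rdm(10, rng)
        revv = d.values.max() - d.values
        np.fill_diagonal(revv, 0.0)
        rev = sq.RDM(d.labels, revv)
        assert sq.rsa_correlation(d, rev) == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self, rng):
        """Spearman is a rank statistic: cubing (monotone) the model cells
        changes nothing."""
        a, b = random_rdm(12, rng), random_rdm(12, rng)
        r1 = sq.rsa_correlation(a, b)
        a3 = sq.RDM(a.labels, a.values**3)
        assert sq.rsa_correlation(a3, b) == pytest.approx(r1)

    def test_matches_scipy_on_masked_cells(self, model_rdms, schedule, rng):
        data = random_rdm(72, rng)
        mask = condition_mask(schedule, "novel")
        model = model_rdms["item-position"]
        ours = sq.rsa_correlation(model, data, mask)
        idx = np.tril_indices(72, k=-1)
        sel = mask[idx]
        ref = spearmanr(model.values[idx][sel], data.values[idx][sel]).statistic
        assert ours == pytest.approx(ref)

    def test_too_few_cells(self, rng):
        d = random_rdm(3, rng)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 0] = mask[0, 1] = True
        with pytest.raises(SeqrecodeError):
            sq.rsa_correlation(d, d, mask)

    def test_shuffled_labels_average_to_zero(self, rng):
        model = random_rdm(20, rng)
        data = random_rdm(20, rng)
        rs = permutation_rs(model, data, 400, rng)
        assert abs(rs.mean()) < 0.02
        # permutation values match direct recomputation for one shuffle
        rng2 = np.random.default_rng(11)
        rs_one = permutation_rs(model, data, 1, rng2)
        rng2 = np.random.default_rng(11)
        perm = rng2.permutation(20)
        shuffled = sq.RDM(data.labels, data.values[np.ix_(perm, perm)])
        assert rs_one[0] == pytest.approx(sq.rsa_correlation(model, shuffled))


class TestNoiseCeiling:
    def test_identical_subjects_hit_one(self, rng):
        base = random_rdm(10, rng)
        lower, upper = sq.noise_ceiling([base] * 5)
        assert lower == pytest.approx(1.0)
        assert upper == pytest.approx(1.0)

    def test_lower_below_upper(self, rng):
        rdms = [random_rdm(12, rng) for _ in range(8)]
        lower, upper = sq.noise_ceiling(rdms)
        assert lower <= upper

    def test_independent_subjects_near_zero(self):
        """22 independent random RDMs: leave-one-out ceiling about zero;
        the with-self mean retains the 1/sqrt(n)-ish self-inflation."""
        rng = np.random.default_rng(42)
        rdms = [random_rdm(16, rng) for _ in range(22)]
        lower, upper = sq.noise_ceiling(rdms)
        assert abs(lower) < 0.1
        assert 0 <= upper < 0.4

    def test_needs_two_subjects(self, rng):
        with pytest.raises(SeqrecodeError):
            sq.noise_ceiling([random_rdm(5, rng)])


class TestCeilingPositiveTest:
    def test_zero_correlations_not_significant(self):
        out = sq.ceiling_positive_test(np.zeros(10) + np.linspace(-0.01, 0.01, 10))
        assert not out["significant"]

    def test_constant_correlations_flagged(self):
        out = sq.ceiling_positive_test(np.full(8, 0.4))
        assert out["flag"] == "zero-variance"
        assert not out["significant"]

    def test_consistent_cohort_significant(self, rng):
        r = 0.5 + 0.05 * rng.standard_normal(22)
        out = sq.ceiling_positive_test(r, n_regions=74)
        assert out["significant"]


class TestGroupSignificance:
    def test_sample_count_follows_alpha(self, rng):
        R = rng.standard_normal((4, 101))
        p = sq.group_significance(R, alpha=1e-2, rng=rng)
        assert 0 < p <= 1
        # n = 10/alpha draws: resolution floor is 1/(n+1)
        R[:, -1] = 10.0  # true value far above every permuted value
        p_floor = sq.group_significance(R, alpha=1e-2, rng=rng)
        assert p_floor == pytest.approx(1 / (10 / 1e-2 + 1))

    def test_null_calibration_uniformish(self):
        """p-values under exchangeable null data are roughly uniform."""
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(300):
            R = rng.standard_normal((6, 50))
            ps.append(sq.group_significance(R, alpha=0.05, rng=rng))
        ps = np.array(ps)
        assert abs((ps < 0.25).mean() - 0.25) < 0.07
        assert abs((ps < 0.5).mean() - 0.5) < 0.08

    def test_invalid_alpha(self, rng):
        with pytest.raises(SeqrecodeError):
            sq.group_significance(np.zeros((3, 5)), alpha=0.0, rng=rng)


class TestCrossCondition:
    def test_masks_partition_conditions(self, schedule):
        mu = condition_mask(schedule, "novel")
        mur = condition_mask(schedule, "novel", "repeating")
        assert not (mu & mur).any()
        novel = schedule.condition_indices("novel")
        rep = schedule.condition_indices("repeating")
        assert mu.sum() == len(novel) * (len(novel) - 1)
        assert mur.sum() == 2 * len(novel) * len(rep)

    def test_identical_patterns_flagged(self, schedule):
        """Identical patterns for every trial give a constant data RDM,
        which is flagged as degenerate rather than silently correlated."""
        X = np.tile(np.arange(20.0), (72, 1))
        with pytest.raises(DegenerateInputError):
            sq.cross_condition_rsa(
                [PatternMatrix(X)], schedule,
                sq.model_rdm(schedule.sequences(), "hamming"),
                n_permutations=20, alpha=0.05,
            )

    def test_condition_with_too_few_trials(self, model_rdms):
        from seqrecode.design import Trial, TrialSchedule
        from seqrecode.sequences import Sequence

        tiny = TrialSchedule(
            trials=[
                Trial(1, Sequence.from_string("ABCD"), "novel", 1, True),
                Trial(2, Sequence.from_string("CADB"), "repeating", 1, True),
            ]
        )
        with pytest.raises(SeqrecodeError):
            sq.cross_condition_rsa(
                [PatternMatrix(np.random.default_rng(0).standard_normal((2, 10)))],
                tiny,
                model_rdms["item-position"],
            )
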