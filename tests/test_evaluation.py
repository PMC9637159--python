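"""Fidelity metrics against brute-force oracles."""

import numpy as np
import pytest

import spectgan as sg
from spectgan.evaluation import (
    EvaluationError,
    group_by_pattern,
    sd_summary,
)


class TestMeanCounts:
    def test_uniform_and_zero(self):
        assert sg.mean_counts(np.full((64, 64), 0.5)) == pytest.approx(0.5)
        assert sg.mean_counts(np.zeros((64, 64))) == 0.0

    def test_half_ones(self):
        img = np.zeros((64, 64))
        img[:, :32] = 1.0
        assert sg.mean_counts(img) == pytest.approx(0.5)

    def test_permutation_invariance(self, rng):
        img = rng.random((64, 64))
        shuffled = rng.permutation(img.ravel()).reshape(64, 64)
        assert sg.mean_counts(shuffled) == pytest.approx(sg.mean_counts(img))


class TestLRRatio:
    def test_symmetric_image_is_unity(self, rng):
        half = rng.random((64, 32))
        img = np.hstack([half, half[:, ::-1]])
        assert sg.lr_ratio(img) == pytest.approx(1.0)

    def test_two_to_one(self):
        img = np.ones((64, 64))
        img[:, :32] = 2.0
        assert sg.lr_ratio(img) == pytest.approx(2.0)

    def test_flip_reciprocal_on_random_phantoms(self):
        for seed in range(5):
            s = sg.make_phantom_slice(sg.Level.BG, sg.Pattern.NORMAL, rng_seed=seed)
            assert sg.lr_ratio(s.pixels[:, ::-1]) * sg.lr_ratio(s.pixels) == (
                pytest.approx(1.0, rel=1e-9)
            )

    def test_radiological_convention_swaps(self, rng):
        img = rng.random((64, 64)) + 0.1
        assert sg.lr_ratio(img, radiological=True) == pytest.approx(
            1.0 / sg.lr_ratio(img), rel=1e-9
        )

    def test_zero_right_hemisphere_rejected(self):
        img = np.zeros((64, 64))
        img[:, :32] = 1.0
        with pytest.raises(EvaluationError):
            sg.lr_ratio(img)


class TestPixelwiseMaps:
    def test_identical_images_have_zero_sd(self, rng):
        img = rng.random((64, 64))
        mean, sd = sg.pixelwise_maps([img] * 5)
        assert np.allclose(sd, 0.0)
        assert np.allclose(mean, img)

    def test_two_image_population_convention(self):
        a, b = np.zeros((4, 4)), np.ones((4, 4))
        mean, sd = sg.pixelwise_maps([a, b])
        assert np.allclose(mean, 0.5)
        assert np.allclose(sd, 0.5)  # population (n) convention

    def test_matches_numpy_oracle(self, rng):
        imgs = [rng.random((8, 8)) for _ in range(7)]
        mean, sd = sg.pixelwise_maps(imgs)
        assert np.allclose(sd, np.std(np.stack(imgs), axis=0))
        assert sd_summary(imgs) == pytest.approx(sd.mean())

    def test_single_image_rejected(self, rng):
        with pytest.raises(EvaluationError):
            sg.pixelwise_maps([rng.random((4, 4))])


def _anova_oracle(groups):
    """Hand sums-of-squares one-way ANOVA."""
    from scipy import stats

    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, stats.f.sf(f, dfb, dfw)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        f, p = sg.anova_compare([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # SSB = 4 (df 1), SSW = 1 (df 2) -> F = 8
        f, p = sg.anova_compare([[0, 1], [2, 3]])
        assert f == pytest.approx(8.0, abs=1e-10)
        oracle_f, oracle_p = _anova_oracle([[0, 1], [2, 3]])
        assert f == pytest.approx(oracle_f, abs=1e-10)
        assert p == pytest.approx(oracle_p, abs=1e-10)

    def test_matches_sums_of_squares_oracle_on_random_groups(self, rng):
        for _ in range(10):
            groups = [
                rng.normal(loc=rng.normal(), size=rng.integers(2, 8)).tolist()
                for _ in range(int(rng.integers(2, 5)))
            ]
            f, p = sg.anova_compare(groups)
            of, op = _anova_oracle(groups)
            assert f == pytest.approx(of, abs=1e-10)
            assert p == pytest.approx(op, abs=1e-10)

    def test_p_monotone_in_f(self):
        from scipy import stats

        ps = [stats.f.sf(f, 2, 10) for f in (0.5, 1.0, 2.0, 8.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_degenerate_groups_rejected(self):
        with pytest.raises(EvaluationError):
            sg.anova_compare([[1, 1], [2, 2]])
        with pytest.raises(EvaluationError):
            sg.anova_compare([[1], [2, 3]])


def _labelled_set(rng, n=12, bias=0.0):
    out = {}
    for pattern in sg.Pattern:
        imgs = []
        for _ in range(n):
            img = rng.random((64, 64)) + 0.5 + bias
            imgs.append(img)
        out[pattern] = imgs
    return out


class TestFidelityReport:
    def test_copied_set_yields_unit_pvalues(self, rng):
        real = _labelled_set(rng)
        report = sg.fidelity_report(real, real, real)
        for p in report.pvalues.values():
            assert p == pytest.approx(1.0, abs=1e-6)

    def test_pvalue_count_contract(self, rng):
        report = sg.fidelity_report(
            _labelled_set(rng), _labelled_set(rng), _labelled_set(rng)
        )
        assert len(report.pvalues) == 12  # 2 metrics x 3 patterns x 2 comparisons
        assert len(report.anova) == 6

    def test_biased_generator_detected(self, rng):
        real = {
            p: [np.abs(rng.normal(0.5, 0.05, (64, 64))) + 0.2 for _ in range(50)]
            for p in sg.Pattern
        }
        gen_a = {
            p: [np.abs(rng.normal(0.5, 0.05, (64, 64))) + 0.2 for _ in range(50)]
            for p in sg.Pattern
        }
        # variant-B images biased upward in MC after normalization
        gen_b = {
            p: [np.abs(rng.normal(0.5, 0.05, (64, 64))) + 2.0 for _ in range(50)]
            for p in sg.Pattern
        }
        report = sg.fidelity_report(real, gen_a, gen_b)
        for pattern in sg.Pattern:
            assert report.pvalues[("mc", pattern, "B")] < 0.05

    def test_missing_pattern_rejected(self, rng):
        real = _labelled_set(rng)
        broken = {k: v for k, v in _labelled_set(rng).items() if k != sg.Pattern.NORMAL}
        with pytest.raises(EvaluationError, match="lacks"):
            sg.fidelity_report(real, broken, real)

    def test_accepts_spect_slices(self, tiny_dataset):
        groups = group_by_pattern(tiny_dataset)
        assert set(groups) == set(sg.Pattern)
        for imgs in groups.values():
            for im in imgs:
                assert im.max() == pytest.approx(1.0)
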