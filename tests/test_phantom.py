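"""Phantom simulator: composition, defect structure, neighbors, normalization."""

import numpy as np
import pytest

import spectgan as sg
from spectgan.evaluation import lr_ratio
from spectgan.phantom import TABLE1_COUNTS


class TestComposition:
    def test_reference_composition_cells(self):
        comp = sg.DatasetComposition.table1()
        assert comp.counts[(sg.Level.CER, sg.Pattern.NORMAL)] == 248
        assert comp.counts[(sg.Level.CER, sg.Pattern.BILATERAL)] == 0
        assert comp.counts[(sg.Level.BG, sg.Pattern.UNILATERAL)] == 116
        assert comp.counts[(sg.Level.COR, sg.Pattern.BILATERAL)] == 52
        assert comp.total == 938

    def test_reference_marginals(self):
        comp = sg.DatasetComposition.table1()
        by_pattern = {p: 0 for p in sg.Pattern}
        for (_, pattern), n in comp.counts.items():
            by_pattern[pattern] += n
        assert by_pattern[sg.Pattern.NORMAL] == 551
        assert by_pattern[sg.Pattern.UNILATERAL] == 291
        assert by_pattern[sg.Pattern.BILATERAL] == 96

    def test_scaled_composition_total_and_empty_cells(self):
        comp = sg.DatasetComposition.scaled(90)
        assert comp.total == 90
        assert comp.counts[(sg.Level.CER, sg.Pattern.BILATERAL)] == 0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            sg.DatasetComposition({(sg.Level.CER, sg.Pattern.NORMAL): -1})

    def test_build_dataset_counts_match_exactly(self):
        comp = sg.DatasetComposition.scaled(40)
        slices = sg.build_dataset(comp, rng_seed=3)
        got = {}
        for s in slices:
            got[(s.level, s.pattern)] = got.get((s.level, s.pattern), 0) + 1
        expect = {k: v for k, v in comp.counts.items() if v > 0}
        assert got == expect

    def test_build_dataset_empty_composition(self):
        assert sg.build_dataset(sg.DatasetComposition({}), rng_seed=0) == []

    def test_build_dataset_attaches_neighbors_and_sides(self):
        slices = sg.build_dataset(sg.DatasetComposition.scaled(30), rng_seed=5)
        for s in slices:
            assert s.neighbor is not None
            if s.pattern == sg.Pattern.UNILATERAL:
                assert s.side in (sg.Side.LEFT, sg.Side.RIGHT)
            else:
                assert s.side == sg.Side.NONE


class TestPhantomSlice:
    def test_seeded_determinism(self):
        a = sg.make_phantom_slice(sg.Level.COR, sg.Pattern.NORMAL, rng_seed=1)
        b = sg.make_phantom_slice(sg.Level.COR, sg.Pattern.NORMAL, rng_seed=1)
        assert np.array_equal(a.pixels, b.pixels)

    def test_normal_population_lr_near_unity(self):
        ratios = [
            lr_ratio(
                sg.make_phantom_slice(
                    sg.Level.COR, sg.Pattern.NORMAL, rng_seed=i
                ).pixels
            )
            for i in range(120)
        ]
        assert 0.95 <= np.mean(ratios) <= 1.05

    def test_bilateral_population_lr_near_unity(self):
        ratios = [
            lr_ratio(
                sg.make_phantom_slice(
                    sg.Level.BG, sg.Pattern.BILATERAL, contrast=0.4, rng_seed=i
                ).pixels
            )
            for i in range(120)
        ]
        assert 0.95 <= np.mean(ratios) <= 1.05

    @pytest.mark.parametrize("side", [sg.Side.LEFT, sg.Side.RIGHT])
    @pytest.mark.parametrize("level", list(sg.Level))
    def test_unilateral_lr_direction_every_slice(self, level, side):
        for seed in range(25):
            s = sg.make_phantom_slice(
                level, sg.Pattern.UNILATERAL, side, contrast=0.3, rng_seed=seed
            )
            r = lr_ratio(s.pixels)
            assert (r < 1.0) if side == sg.Side.LEFT else (r > 1.0)

    def test_unilateral_hemisphere_contrast(self):
        s = sg.make_phantom_slice(
            sg.Level.COR, sg.Pattern.UNILATERAL, sg.Side.LEFT, 0.4, rng_seed=1
        )
        left = s.pixels[:, :32].mean()
        right = s.pixels[:, 32:].mean()
        assert left / right == pytest.approx(0.6, abs=0.07)

    def test_invalid_label_combinations(self):
        with pytest.raises(sg.SliceError):
            sg.make_phantom_slice(
                sg.Level.COR, sg.Pattern.NORMAL, sg.Side.LEFT, rng_seed=0
            )
        with pytest.raises(sg.SliceError):
            sg.make_phantom_slice(
                sg.Level.COR, sg.Pattern.UNILATERAL, sg.Side.NONE, rng_seed=0
            )
        with pytest.raises(sg.SliceError):
            sg.make_phantom_slice(
                sg.Level.COR, sg.Pattern.NORMAL, contrast=1.5, rng_seed=0
            )

    def test_levels_are_statistically_distinct(self):
        """Mean images of the three levels differ clearly in structure."""
        means = {}
        for level in sg.Level:
            imgs = [
                sg.make_phantom_slice(level, sg.Pattern.NORMAL, rng_seed=i).pixels
                for i in range(20)
            ]
            m = np.mean(imgs, axis=0)
            means[level] = m / m.max()
        for a in sg.Level:
            for b in sg.Level:
                if a != b:
                    assert np.abs(means[a] - means[b]).mean() > 0.02


class TestNeighbor:
    def test_neighbor_correlated_with_parent(self):
        s = sg.make_phantom_slice(sg.Level.COR, sg.Pattern.NORMAL, rng_seed=4)
        nb = sg.make_neighbor(s, rng_seed=9)
        r = np.corrcoef(s.pixels.ravel(), nb.pixels.ravel())[0, 1]
        assert r > 0.5

    def test_neighbor_inherits_labels(self):
        s = sg.make_phantom_slice(
            sg.Level.BG, sg.Pattern.UNILATERAL, sg.Side.RIGHT, rng_seed=2
        )
        nb = sg.make_neighbor(s, rng_seed=0)
        assert (nb.level, nb.pattern, nb.side) == (s.level, s.pattern, s.side)

    def test_different_seeds_differ(self):
        s = sg.make_phantom_slice(sg.Level.CER, sg.Pattern.NORMAL, rng_seed=4)
        a, b = sg.make_neighbor(s, rng_seed=1), sg.make_neighbor(s, rng_seed=2)
        assert not np.array_equal(a.pixels, b.pixels)


class TestNormalize:
    def test_uniform_slice_becomes_ones(self):
        s = sg.SpectSlice(
            np.full((64, 64), 7.0), sg.Level.COR, sg.Pattern.NORMAL
        )
        out = sg.normalize_slice(s)
        assert np.allclose(out.pixels, 1.0)

    def test_scaling_and_idempotence(self):
        pix = np.zeros((64, 64))
        pix[0, 0], pix[1, 1] = 10.0, 5.0
        s = sg.SpectSlice(pix, sg.Level.COR, sg.Pattern.NORMAL)
        out = sg.normalize_slice(s)
        assert out.pixels[1, 1] == pytest.approx(0.5)
        assert out.pixels.max() == pytest.approx(1.0)
        again = sg.normalize_slice(out)
        assert np.array_equal(out.pixels, again.pixels)

    def test_all_zero_slice_rejected(self):
        s = sg.SpectSlice(np.zeros((64, 64)), sg.Level.COR, sg.Pattern.NORMAL)
        with pytest.raises(sg.SliceError, match="all-zero"):
            sg.normalize_slice(s)

    def test_every_generated_slice_normalizes_to_unit_max(self):
        for seed in range(10):
            s = sg.make_phantom_slice(sg.Level.BG, sg.Pattern.NORMAL, rng_seed=seed)
            assert sg.normalize_slice(s).pixels.max() == pytest.approx(1.0)
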