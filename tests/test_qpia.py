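import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_section, uniform_section
from thrombostage.errors import (
    CardinalityError,
    DegenerateSectionError,
    EmptyRoiError,
    IncompleteError,
    InvariantError,
    ValidationError,
)
from thrombostage.io_model import SectionImage
from thrombostage.qpia import (
    BACKGROUND,
    BLUE,
    OUTSIDE_ROI,
    PINK,
    RED,
    CompositionFractions,
    Palette,
    PixelClassMap,
    WeightingParams,
    aggregate_whole_composition,
    aggregate_whole_elasticity,
    classify_pixels,
    compute_fractions,
    quantify_section,
    red_weight,
    triplicate_mean,
)
from thrombostage.synthetic import SyntheticImageSpec, generate_section_image


class TestClassifyPixels:
    def test_uniform_red_reference(self, palette):
        section = uniform_section(palette.red)
        assert (classify_pixels(section, palette).labels == RED).all()

    def test_uniform_white_is_background(self, palette):
        section = uniform_section((255, 255, 255))
        assert (classify_pixels(section, palette).labels == BACKGROUND).all()

    def test_outside_roi_exactly_where_mask_false(self, palette):
        px = np.zeros((6, 6, 3), dtype=np.uint8)
        px[:] = palette.pink
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        labels = classify_pixels(make_section(px, mask=mask), palette).labels
        np.testing.assert_array_equal(labels == OUTSIDE_ROI, ~mask)
        assert (labels[mask] == PINK).all()

    def test_matches_generator_ground_truth(self, palette):
        spec = SyntheticImageSpec(
            height=64, width=64, target_fractions=(0.5, 0.3, 0.1), color_noise_sd=0, seed=11
        )
        image, mask, truth, _ = generate_section_image(spec, palette)
        section = make_section(image.pixels, mask=mask.mask)
        labels = classify_pixels(section, palette)
        np.testing.assert_array_equal(labels.labels, truth.labels)

    def test_tie_breaks_in_class_order(self):
        # pixel exactly equidistant from the red and pink references
        px = np.zeros((1, 1, 3), dtype=np.uint8)
        px[0, 0] = (100, 100, 100)
        pal = Palette(red=(90, 100, 100), pink=(110, 100, 100), blue=(0, 0, 255))
        labels = classify_pixels(make_section(px), pal)
        assert labels.labels[0, 0] == RED

    def test_empty_roi_raises(self, palette):
        px = np.zeros((4, 4, 3), dtype=np.uint8)
        section = make_section(px)
        object.__setattr__(section.mask, "mask", np.zeros((4, 4), bool))
        with pytest.raises(EmptyRoiError):
            classify_pixels(section, palette)

    def test_dark_red_not_background(self, palette):
        # saturated but bright pixel stays tissue
        section = uniform_section((240, 40, 40))
        assert (classify_pixels(section, palette).labels == RED).all()


class TestRedWeight:
    def test_floor_is_zero(self):
        assert red_weight(1 / 3, WeightingParams(f0=1 / 3, gamma=2)) == 0.0

    @pytest.mark.parametrize("gamma", [0.5, 1.0, 2.0, 5.0])
    def test_saturation_is_one(self, gamma):
        assert red_weight(1.0, WeightingParams(gamma=gamma)) == pytest.approx(1.0)

    def test_closed_form(self):
        w = red_weight(2 / 3, WeightingParams(f0=1 / 3, gamma=2))
        assert w == pytest.approx(0.25)

    def test_below_floor_clamps_to_zero(self):
        assert red_weight(0.1, WeightingParams(f0=1 / 3, gamma=2)) == 0.0

    def test_gamma_zero_is_unit(self):
        assert red_weight(0.0, WeightingParams(gamma=0)) == 1.0
        assert red_weight(0.9, WeightingParams(gamma=0)) == 1.0

    @given(
        f=st.floats(0, 1),
        g=st.floats(0, 1),
        gamma=st.floats(0.1, 8),
    )
    def test_monotone_in_f_red(self, f, g, gamma):
        lo, hi = sorted((f, g))
        params = WeightingParams(gamma=gamma)
        assert red_weight(lo, params) <= red_weight(hi, params) + 1e-12

    def test_vectorized(self):
        w = red_weight(np.array([1 / 3, 2 / 3, 1.0]), WeightingParams(f0=1 / 3, gamma=2))
        np.testing.assert_allclose(w, [0.0, 0.25, 1.0])

    @pytest.mark.parametrize("kw", [{"f0": 1.0}, {"f0": -0.1}, {"gamma": -1.0}])
    def test_param_validation(self, kw):
        with pytest.raises(ValidationError):
            WeightingParams(**kw)


def _label_map(n_red, n_pink, n_blue, n_bg=0):
    total = n_red + n_pink + n_blue + n_bg
    side = int(np.ceil(np.sqrt(total)))
    lab = np.full(side * side, OUTSIDE_ROI, dtype=np.uint8)
    lab[:n_red] = RED
    lab[n_red : n_red + n_pink] = PINK
    lab[n_red + n_pink : n_red + n_pink + n_blue] = BLUE
    lab[n_red + n_pink + n_blue : total] = BACKGROUND
    px = np.full((side, side, 3), 255, dtype=np.uint8)
    px.reshape(-1, 3)[lab == RED] = (255, 0, 0)  # f_red = 1 -> weight 1
    px.reshape(-1, 3)[lab == PINK] = (230, 160, 180)
    px.reshape(-1, 3)[lab == BLUE] = (70, 60, 140)
    return PixelClassMap(labels=lab.reshape(side, side)), SectionImage(pixels=px)


class TestComputeFractions:
    def test_printed_day11_head_masses(self):
        # masses 4739 / 4217 / 1044 with unit weights
        labels, image = _label_map(4739, 4217, 1044)
        cf = compute_fractions(labels, image, WeightingParams(gamma=0))
        assert cf.to_report_dict() == {"Rr": 47.39, "Rp": 42.17, "Rb": 10.44}

    def test_all_red_full_intensity(self):
        labels, image = _label_map(25, 0, 0)
        cf = compute_fractions(labels, image, WeightingParams(f0=1 / 3, gamma=2))
        assert (cf.rr, cf.rp, cf.rb) == (1.0, 0.0, 0.0)

    def test_planted_recovery_noise_free(self, unweighted):
        spec = SyntheticImageSpec(
            height=128, width=128, target_fractions=(0.6, 0.3, 0.1), color_noise_sd=0, seed=5
        )
        image, mask, truth, planted = generate_section_image(spec)
        cf = compute_fractions(truth, image, unweighted)
        assert cf.rr == pytest.approx(planted.rr, abs=0.01)
        assert cf.rp == pytest.approx(planted.rp, abs=0.01)
        assert cf.rb == pytest.approx(planted.rb, abs=0.01)

    def test_all_background_degenerate(self, unweighted):
        labels, image = _label_map(0, 0, 0, n_bg=16)
        with pytest.raises(DegenerateSectionError):
            compute_fractions(labels, image, unweighted)

    @given(
        n_red=st.integers(0, 40),
        n_pink=st.integers(0, 40),
        n_blue=st.integers(0, 40),
        n_bg=st.integers(0, 10),
    )
    def test_conservation_sum_exactly_one(self, n_red, n_pink, n_blue, n_bg):
        if n_red + n_pink + n_blue == 0:
            return
        labels, image = _label_map(n_red, n_pink, n_blue, n_bg)
        cf = compute_fractions(labels, image, WeightingParams(gamma=0))
        assert cf.rr + cf.rp + cf.rb == 1.0

    def test_mask_restriction(self, palette):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        section = make_section(px, mask=mask)
        cf1, _ = quantify_section(section, palette)
        px2 = px.copy()
        px2[~mask] = rng.integers(0, 256, size=(int((~mask).sum()), 3), dtype=np.uint8)
        cf2, _ = quantify_section(make_section(px2, mask=mask), palette)
        assert (cf1.rr, cf1.rp, cf1.rb) == (cf2.rr, cf2.rp, cf2.rb)

    @pytest.mark.parametrize("n", [2, 3])
    def test_scale_invariance(self, palette, n):
        rng = np.random.default_rng(1)
        px = rng.integers(0, 256, size=(12, 12, 3), dtype=np.uint8)
        mask = np.ones((12, 12), bool)
        mask[0:3] = False
        cf1, _ = quantify_section(make_section(px, mask=mask), palette)
        big_px = np.kron(px, np.ones((n, n, 1))).astype(np.uint8)
        big_mask = np.kron(mask, np.ones((n, n))).astype(bool)
        cf2, _ = quantify_section(make_section(big_px, mask=big_mask), palette)
        assert cf1.rr == pytest.approx(cf2.rr, abs=1e-12)
        assert cf1.rp == pytest.approx(cf2.rp, abs=1e-12)

    def test_rr_non_increasing_in_gamma(self, palette):
        spec = SyntheticImageSpec(height=64, width=64, target_fractions=(0.5, 0.3, 0.2), seed=7)
        image, mask, truth, _ = generate_section_image(spec, palette)
        rrs = [
            compute_fractions(truth, image, WeightingParams(gamma=g)).rr
            for g in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(rrs, rrs[1:]))


class TestCompositionFractions:
    def test_remainder_rule(self):
        cf = CompositionFractions.from_red_pink(0.6, 0.3)
        assert cf.rb == pytest.approx(0.1)
        assert cf.rr + cf.rp + cf.rb == 1.0

    def test_sum_violation_rejected(self):
        with pytest.raises(InvariantError):
            CompositionFractions(0.5, 0.5, 0.5)

    def test_negative_rejected(self):
        with pytest.raises(InvariantError):
            CompositionFractions.from_red_pink(0.8, 0.4)


class TestTriplicateMean:
    def test_basic(self):
        assert triplicate_mean((3.0, 3.2, 3.1)) == pytest.approx(3.1)

    @given(x=st.floats(-100, 100))
    def test_idempotent(self, x):
        assert triplicate_mean((x, x, x)) == pytest.approx(x)

    @given(st.tuples(st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)))
    def test_matches_accumulation_oracle(self, triple):
        acc = 0.0
        for v in triple:
            acc += v
        assert triplicate_mean(triple) == pytest.approx(acc / 3, abs=1e-9)

    def test_strict_cardinality(self):
        with pytest.raises(CardinalityError):
            triplicate_mean((1.0, 2.0))

    def test_lenient_fallback(self):
        assert triplicate_mean((1.0, 3.0), strict=False) == pytest.approx(2.0)

    def test_empty_always_fails(self):
        with pytest.raises(CardinalityError):
            triplicate_mean((), strict=False)


class TestAggregation:
    def test_whole_elasticity_start(self):
        assert aggregate_whole_elasticity(2.01, 3.27, 1.79) == 2.36

    def test_whole_elasticity_end(self):
        assert aggregate_whole_elasticity(13.29, 15.91, 10.51) == 13.24

    def test_whole_elasticity_constant(self):
        assert aggregate_whole_elasticity(5, 5, 5) == 5

    def test_missing_part_named(self):
        with pytest.raises(IncompleteError, match="body"):
            aggregate_whole_elasticity(2.0, float("nan"), 3.0)

    def test_whole_composition_identical(self):
        cf = CompositionFractions.from_red_pink(0.5, 0.3)
        out = aggregate_whole_composition(cf, cf, cf)
        assert (out.rr, out.rp, out.rb) == pytest.approx((cf.rr, cf.rp, cf.rb))

    def test_whole_composition_printed_day2_row(self):
        # componentwise-mean oracle on the day-2 per-part Rr percentages
        rows = [(97.02, 2.47), (95.75, 3.54), (92.63, 6.27)]
        parts = [CompositionFractions.from_percents(rr, rp) for rr, rp in rows]
        expected_rr = sum(r for r, _ in rows) / 3 / 100
        out = aggregate_whole_composition(*parts)
        assert out.rr == pytest.approx(expected_rr, abs=1e-12)
        assert round(out.rr * 100, 2) == 95.13

    def test_whole_composition_symmetry(self):
        triples = [
            CompositionFractions(1.0, 0.0, 0.0),
            CompositionFractions(0.0, 1.0, 0.0),
            CompositionFractions(0.0, 0.0, 1.0),
        ]
        out = aggregate_whole_composition(*triples)
        assert (out.rr, out.rp, out.rb) == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_invalid_input_triple_rejected(self):
        bad = object.__new__(CompositionFractions)
        object.__setattr__(bad, "rr", 0.5)
        object.__setattr__(bad, "rp", 0.5)
        object.__setattr__(bad, "rb", 0.5)
        good = CompositionFractions.from_red_pink(0.5, 0.3)
        with pytest.raises(InvariantError):
            aggregate_whole_composition(bad, good, good)


class TestPalette:
    def test_duplicate_colors_rejected(self):
        with pytest.raises(ValidationError):
            Palette(red=(10, 10, 10), pink=(10, 10, 10))

    @pytest.mark.parametrize("kw", [{"b0": 300}, {"s0": 1.5}, {"red": (300, 0, 0)}])
    def test_threshold_ranges(self, kw):
        with pytest.raises(ValidationError):
            Palette(**kw)
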